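"""Report-version deduplication and deleted-case removal.

Among the versions sharing a CASEID, the one with the largest FDA receipt
date wins; receipt-date ties are broken by the largest PRIMARYID (numeric
when both parse as integers, else lexicographic on zero-padded strings).
Deleted-case removal runs after version collapsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import QuarterBundle

logger = logging.getLogger("faersig")

__all__ = ["DedupSummary", "deduplicate", "remove_deleted", "filter_mentions"]


@dataclass
class DedupSummary:
    input_rows: int = 0
    versions_collapsed: int = 0
    deleted_removed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("input_rows", self.input_rows),
                ("versions_collapsed", self.versions_collapsed),
                ("deleted_removed", self.deleted_removed),
            ],
            columns=["step", "count"],
        )


def _primaryid_sort_key(s: pd.Series) -> pd.Series:
    # zero-padding makes lexicographic order match numeric order for digit ids
    width = int(s.str.len().max()) if len(s) else 0
    return s.str.zfill(width)


def deduplicate(demo: pd.DataFrame, summary: DedupSummary | None = None) -> pd.DataFrame:
    """Collapse report versions to exactly one row per caseid.

    Keep the max ``fda_dt`` within a caseid; break ties on max primaryid.
    Output is sorted by caseid, so any permutation of the input yields the
    same frame. Idempotent.
    """
    if summary is not None:
        summary.input_rows = len(demo)
    if demo.empty:
        return demo.copy()
    if demo["primaryid"].duplicated().any():
        raise ValueError("primaryid must be unique per version row")
    work = demo.assign(_pid=_primaryid_sort_key(demo["primaryid"].astype(str)))
    work = work.sort_values(["caseid", "fda_dt", "_pid"], kind="mergesort")
    out = (
        work.groupby("caseid", sort=True)
        .tail(1)
        .drop(columns="_pid")
        .sort_values("caseid", kind="mergesort")
        .reset_index(drop=True)
    )
    if summary is not None:
        summary.versions_collapsed = len(demo) - len(out)
    logger.info("dedup: %d rows -> %d unique caseids", len(demo), len(out))
    return out


def remove_deleted(
    demo: pd.DataFrame,
    deleted_caseids: set[str],
    summary: DedupSummary | None = None,
) -> pd.DataFrame:
    """Drop rows whose caseid appears on the deleted-case list."""
    if not deleted_caseids or demo.empty:
        if summary is not None:
            summary.deleted_removed = 0
        return demo.copy()
    mask = ~demo["caseid"].isin(deleted_caseids)
    removed = int((~mask).sum())
    if summary is not None:
        summary.deleted_removed = removed
    logger.info("deleted-case removal: %d reports dropped", removed)
    return demo.loc[mask].reset_index(drop=True)


def filter_mentions(bundle: QuarterBundle, surviving_demo: pd.DataFrame) -> QuarterBundle:
    """Restrict all mention tables to the surviving primaryids."""
    keep = set(surviving_demo["primaryid"])

    def _filter(df: pd.DataFrame) -> pd.DataFrame:
        return df.loc[df["primaryid"].isin(keep)].reset_index(drop=True)

    return QuarterBundle(
        demo=surviving_demo.reset_index(drop=True),
        drugs=_filter(bundle.drugs),
        reactions=_filter(bundle.reactions),
        outcomes=_filter(bundle.outcomes),
        therapies=_filter(bundle.therapies),
        quarter_label=bundle.quarter_label,
        stats=bundle.stats,
    )
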