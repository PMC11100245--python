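"""Drug-event 2x2 tables at PT or SOC level.

The counting unit is the distinct (report, event-label) pair. A report
contributes one pair per distinct PT (or per distinct mapped primary SOC),
and its pairs carry a single drug-of-interest flag; reports in the cohort
therefore never contribute to the comparator cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import QuarterBundle, VocabularyMap

logger = logging.getLogger("faersig")

__all__ = ["ContingencyTable", "PairUniverse", "build_pairs", "contingency_table", "all_tables"]


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts: a=target&event, b=target&other, c=other&event, d=rest.

    Cells are integers when built from data; the reconstruction path may
    produce real-valued cells.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class PairUniverse:
    """All distinct (report, label) pairs with the drug-of-interest flag."""

    level: str  # "PT" or "SOC"
    pairs: pd.DataFrame  # columns: primaryid, target (bool), label
    unmapped_pts: int = 0

    @property
    def T(self) -> int:
        """Pairs carrying the target drug (== a+b for every label)."""
        return int(self.pairs["target"].sum())

    @property
    def N(self) -> int:
        return len(self.pairs)


def build_pairs(
    bundle: QuarterBundle,
    cohort: set[str],
    vocabulary: VocabularyMap | None = None,
    level: str = "PT",
) -> PairUniverse:
    """Enumerate distinct (report, label) pairs over the whole bundle.

    At SOC level each PT is replaced by its primary SOC name; unmapped PTs
    are excluded and counted in ``unmapped_pts``.
    """
    level = level.upper()
    if level not in {"PT", "SOC"}:
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    reac = bundle.reactions[["primaryid", "pt"]].copy()
    reac["label"] = reac["pt"].str.strip().str.upper()
    unmapped = 0
    if level == "SOC":
        if vocabulary is None:
            raise ValueError("SOC level requires a PT->SOC vocabulary")
        soc = reac["label"].map(lambda p: (vocabulary.lookup(p) or (None,))[0])
        unmapped = int(soc.isna().sum())
        if unmapped:
            logger.warning("SOC mapping: %d reaction rows with unmapped PTs excluded", unmapped)
        reac = reac.assign(label=soc).dropna(subset=["label"])
    pairs = reac[["primaryid", "label"]].drop_duplicates().reset_index(drop=True)
    pairs["target"] = pairs["primaryid"].isin(cohort)
    return PairUniverse(level=level, pairs=pairs[["primaryid", "target", "label"]], unmapped_pts=unmapped)


def contingency_table(universe: PairUniverse, event_label: str) -> ContingencyTable:
    """2x2 table for one event label against the rest of the universe."""
    label = event_label.strip().upper() if universe.level == "PT" else event_label
    is_event = universe.pairs["label"] == label
    a = int((is_event & universe.pairs["target"]).sum())
    event_total = int(is_event.sum())
    T, N = universe.T, universe.N
    c = event_total - a
    return ContingencyTable(a=a, b=T - a, c=c, d=N - T - c)


def all_tables(universe: PairUniverse, min_a: int = 3) -> list[tuple[str, ContingencyTable]]:
    """One table per label with ``a >= min_a``, sorted by a desc, label asc."""
    if min_a < 0:
        raise ValueError("min_a must be >= 0")
    grouped = universe.pairs.groupby("label")["target"].agg(["sum", "count"])
    T, N = universe.T, universe.N
    out = []
    for label, row in grouped.iterrows():
        a, event_total = int(row["sum"]), int(row["count"])
        if a < min_a:
            continue
        c = event_total - a
        out.append((label, ContingencyTable(a=a, b=T - a, c=c, d=N - T - c)))
    out.sort(key=lambda item: (-item[1].a, item[0]))
    return out
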