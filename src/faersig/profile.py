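"""Target-drug cohort selection and descriptive profiling.

The profile covers sex, age bins, reporter occupation, country, report
year, serious outcomes, and time-to-onset bins, each as count plus
percentage of the cohort (half-up, two decimals).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io import QuarterBundle

__all__ = [
    "DrugQuery",
    "ProfileTable",
    "percentage",
    "select_target_reports",
    "profile_cohort",
    "onset_days",
    "AGE_UNIT_YEARS",
    "AGE_BINS",
    "ONSET_BINS",
]

# conversion of FAERS age units to years
AGE_UNIT_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766}

# left-closed, right-open; the printed joints (18/45/65/75) are assigned upward
AGE_BINS = [("<18", 0.0, 18.0), ("18-45", 18.0, 45.0), ("45-65", 45.0, 65.0),
            ("65-75", 65.0, 75.0), (">=75", 75.0, float("inf"))]

# closed integer day ranges as printed
ONSET_BINS = [("0-30", 0, 30), ("31-60", 31, 60), ("61-90", 61, 90), ("91-120", 91, 120),
              ("121-150", 121, 150), ("151-180", 151, 180), ("181-360", 181, 360),
              (">360", 361, None)]

OCCUPATION_LABELS = {
    "CN": "Consumer",
    "PH": "Pharmacist",
    "MD": "Physician",
    "OT": "Other Health Professionals",
    "HP": "Other Health Professionals",
    "LW": "Lawyer",
}

OUTCOME_LABELS = {
    "DE": "Death",
    "DS": "Disability",
    "HO": "Hospitalization",
    "LT": "Life-Threatening",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention",
    "OT": "Other Serious",
}


def percentage(count: int, total: int) -> float:
    """``100*count/total`` rounded half-up to 2 decimals; 0 when total==0."""
    if total == 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DrugQuery:
    """Which drug mentions define the cohort.

    A report joins the cohort when at least one of its mentions has a role
    in ``roles`` and one of the ``match_fields`` contains (case-insensitive
    substring) any of ``names``.
    """

    names: tuple[str, ...]
    roles: frozenset[str] = frozenset({"PS"})
    match_fields: tuple[str, ...] = ("drugname", "active_ingredient")

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("query names must be non-empty")
        if not self.roles:
            raise ValueError("query roles must be non-empty")
        bad = set(self.match_fields) - {"drugname", "active_ingredient"}
        if bad:
            raise ValueError(f"unknown match fields: {sorted(bad)}")


def _mention_mask(drugs: pd.DataFrame, query: DrugQuery) -> pd.Series:
    mask = drugs["role_cod"].isin(query.roles)
    name_mask = pd.Series(False, index=drugs.index)
    columns = {"drugname": "drugname", "active_ingredient": "prod_ai"}
    for fld in query.match_fields:
        col = drugs[columns[fld]].fillna("").str.upper()
        for name in query.names:
            name_mask |= col.str.contains(name.strip().upper(), regex=False)
    return mask & name_mask


def select_target_reports(bundle: QuarterBundle, query: DrugQuery) -> set[str]:
    """Return the primaryids of reports matching the drug query."""
    if bundle.drugs.empty:
        return set()
    return set(bundle.drugs.loc[_mention_mask(bundle.drugs, query), "primaryid"])


@dataclass
class ProfileTable:
    """Descriptive profile; ``categories[factor][label] == (count, pct)``."""

    cohort_size: int
    categories: dict[str, dict[str, tuple[int, float]]] = field(default_factory=dict)

    def check_conservation(self) -> None:
        """Every exhaustive factor must sum to the cohort size."""
        for factor in ("sex", "age", "reporter", "country", "report_year", "onset_days"):
            if factor in self.categories:
                total = sum(c for c, _ in self.categories[factor].values())
                if total != self.cohort_size:
                    raise AssertionError(f"{factor}: counts sum to {total} != {self.cohort_size}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for factor, counts in self.categories.items():
            for label, (count, pct) in counts.items():
                rows.append((factor, label, count, pct))
        return pd.DataFrame(rows, columns=["factor", "category", "count", "percent"])


def _categorize(values: pd.Series, cohort_size: int) -> dict[str, tuple[int, float]]:
    counts = values.value_counts()
    return {str(k): (int(v), percentage(int(v), cohort_size)) for k, v in counts.items()}


def age_in_years(value: float, unit: str | None) -> float | None:
    """Convert an (age, unit) pair to years; None when not interpretable."""
    if value is None or pd.isna(value):
        return None
    factor = AGE_UNIT_YEARS.get(unit or "YR")
    if factor is None:
        return None
    return float(value) * factor


def _age_bin(years: float | None) -> str:
    if years is None:
        return "Unknown"
    for label, lo, hi in AGE_BINS:
        if lo <= years < hi:
            return label
    return "Unknown"


def _to_date(yyyymmdd: int) -> _dt.date | None:
    if yyyymmdd == 0:
        return None
    try:
        return _dt.date(yyyymmdd // 10000, (yyyymmdd // 100) % 100, yyyymmdd % 100)
    except ValueError:
        return None


def onset_days(bundle: QuarterBundle, cohort: set[str], query: DrugQuery) -> dict[str, int]:
    """Bin days from earliest matching therapy start to the event date.

    Only therapy rows whose ``dsg_drug_seq`` links to a mention matching
    the drug query count. Negative differences and missing dates fall in
    ``Unknown``.
    """
    bins = {label: 0 for label, *_ in ONSET_BINS}
    bins["Unknown"] = 0
    if not cohort:
        return bins
    drugs = bundle.drugs
    matching = drugs.loc[_mention_mask(drugs, query), ["primaryid", "drug_seq"]]
    ther = bundle.therapies.merge(
        matching, left_on=["primaryid", "dsg_drug_seq"], right_on=["primaryid", "drug_seq"]
    )
    ther = ther.loc[(ther["start_dt"] > 0) & ther["primaryid"].isin(cohort)]
    start = ther.groupby("primaryid")["start_dt"].min()
    event = bundle.demo.set_index("primaryid")["event_dt"]
    for pid in sorted(cohort):
        ev = _to_date(int(event.get(pid, 0)))
        st = _to_date(int(start.get(pid, 0))) if pid in start.index else None
        if ev is None or st is None:
            bins["Unknown"] += 1
            continue
        days = (ev - st).days
        if days < 0:
            bins["Unknown"] += 1
            continue
        for label, lo, hi in ONSET_BINS:
            if days >= lo and (hi is None or days <= hi):
                bins[label] += 1
                break
    return bins


def profile_cohort(
    bundle: QuarterBundle, cohort: set[str], query: DrugQuery | None = None
) -> ProfileTable:
    """Compute the descriptive profile of ``cohort``.

    ``query`` is needed only for the onset-day factor (to link therapy
    rows to target-drug mentions); when omitted that factor reports all
    reports as Unknown.
    """
    n = len(cohort)
    table = ProfileTable(cohort_size=n)
    demo = bundle.demo.loc[bundle.demo["primaryid"].isin(cohort)]

    table.categories["sex"] = {
        label: (cnt, percentage(cnt, n))
        for label, cnt in (
            ("Female", int((demo["sex"] == "F").sum())),
            ("Male", int((demo["sex"] == "M").sum())),
            ("Unknown", int((demo["sex"] == "UNK").sum())),
        )
    }

    years = demo.apply(lambda r: age_in_years(r["age_value"], r["age_unit"] or None), axis=1) \
        if not demo.empty else pd.Series(dtype=float)
    age_labels = [label for label, *_ in AGE_BINS] + ["Unknown"]
    age_binned = years.map(_age_bin) if not demo.empty else pd.Series(dtype=object)
    table.categories["age"] = {
        label: (int((age_binned == label).sum()), percentage(int((age_binned == label).sum()), n))
        for label in age_labels
    }

    occ = demo["occp_cod"].map(lambda c: OCCUPATION_LABELS.get(c, "Unknown")) \
        if not demo.empty else pd.Series(dtype=object)
    reporter_labels = ["Consumer", "Pharmacist", "Physician", "Other Health Professionals", "Lawyer", "Unknown"]
    table.categories["reporter"] = {
        label: (int((occ == label).sum()), percentage(int((occ == label).sum()), n))
        for label in reporter_labels
    }

    country = demo["reporter_country"].map(lambda c: c if c else "Not Specified") \
        if not demo.empty else pd.Series(dtype=object)
    table.categories["country"] = _categorize(country, n)
    if not table.categories["country"]:
        table.categories["country"] = {}

    year = demo["report_year"].map(lambda y: str(y) if y else "Unknown") \
        if not demo.empty else pd.Series(dtype=object)
    table.categories["report_year"] = dict(sorted(_categorize(year, n).items()))

    # outcome rows are not disjoint: one report counts once per distinct code
    outc = bundle.outcomes.loc[bundle.outcomes["primaryid"].isin(cohort)]
    outc = outc.drop_duplicates(["primaryid", "outc_cod"])
    table.categories["outcomes"] = {
        OUTCOME_LABELS[code]: (cnt, percentage(cnt, n))
        for code in ("DE", "DS", "HO", "LT", "CA", "RI", "OT")
        for cnt in (int((outc["outc_cod"] == code).sum()),)
    }

    if query is not None:
        onset = onset_days(bundle, cohort, query)
    else:
        onset = {label: 0 for label, *_ in ONSET_BINS}
        onset["Unknown"] = n
    table.categories["onset_days"] = {
        label: (cnt, percentage(cnt, n)) for label, cnt in onset.items()
    }
    return table
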