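"""Readers and writers for FAERS-style quarterly ASCII files.

The quarterly packages are ``$``-delimited text files with a single header
line: DEMO (one row per report version), DRUG, REAC, OUTC and THER (one row
per mention). Two header dialects are supported: the modern one keyed by
``PRIMARYID``/``CASEID`` and the legacy one keyed by ``ISR``/``CASE``.

Collections are held as :class:`pandas.DataFrame` objects inside a
:class:`QuarterBundle`; typed row views (:class:`DemoRecord` etc.) are
provided for record-level work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger("faersig")

__all__ = [
    "ReportKey",
    "DemoRecord",
    "DrugMention",
    "ReactionMention",
    "OutcomeMention",
    "TherapyRecord",
    "QuarterBundle",
    "VocabularyMap",
    "ParseStats",
    "DialectError",
    "normalize_date",
    "parse_quarter",
    "parse_deleted_list",
    "load_pt_soc_map",
    "write_quarter",
]

SEX_CODES = {"F", "M", "UNK"}
ROLE_CODES = {"PS", "SS", "C", "I"}
OUTCOME_CODES = {"DE", "LT", "HO", "DS", "CA", "RI", "OT"}
AGE_UNITS = {"YR", "DEC", "MON", "WK", "DY", "HR"}
OCCUPATION_CODES = {"CN", "MD", "PH", "OT", "LW", "HP"}

MIN_DATE = 19600101
MAX_DATE = 20991231

# header aliases, legacy -> canonical
_ALIASES = {
    "isr": "primaryid",
    "case": "caseid",
    "gndr_cod": "sex",
    "outc_code": "outc_cod",
    "drug_seq": "drug_seq",
    "lot_nbr": "lot_num",
}

_FIELD_SEP = "$"


class DialectError(ValueError):
    """Raised when a file header matches no known FAERS dialect."""


def normalize_date(raw: str | int | None) -> tuple[int, str]:
    """Normalize a FAERS date field to ``(yyyymmdd, precision)``.

    Accepts full dates (YYYYMMDD), partial dates (YYYYMM or YYYY, padded
    with 01), and anything else (blank, garbled, out of range) which maps
    to ``(0, "missing")``. Precision is one of ``day``, ``month``,
    ``year`` or ``missing``.
    """
    if raw is None:
        return 0, "missing"
    s = str(raw).strip()
    if not s or not s.isdigit():
        return 0, "missing"
    if len(s) == 8:
        value, precision = int(s), "day"
    elif len(s) == 6:
        value, precision = int(s) * 100 + 1, "month"
    elif len(s) == 4:
        value, precision = int(s) * 10000 + 101, "year"
    else:
        return 0, "missing"
    year, month, day = value // 10000, (value // 100) % 100, value % 100
    if not (MIN_DATE <= value <= MAX_DATE and 1 <= month <= 12 and 1 <= day <= 31):
        return 0, "missing"
    return value, precision


@dataclass(frozen=True)
class ReportKey:
    """Identity of one report version."""

    primaryid: str
    caseid: str
    fda_dt: int = 0

    def __post_init__(self) -> None:
        if not self.primaryid:
            raise ValueError("primaryid must be non-empty")
        if self.fda_dt != 0 and not (MIN_DATE <= self.fda_dt <= MAX_DATE):
            raise ValueError(f"fda_dt out of range: {self.fda_dt}")


@dataclass(frozen=True)
class DemoRecord:
    key: ReportKey
    event_dt: int = 0
    sex: str = "UNK"
    age_value: float | None = None
    age_unit: str | None = None
    reporter_occupation: str | None = None
    reporter_country: str | None = None

    @property
    def report_year(self) -> int:
        return self.key.fda_dt // 10000

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODES:
            raise ValueError(f"invalid sex code {self.sex!r}")
        if self.age_value is not None and self.age_value < 0:
            raise ValueError("age_value must be >= 0")
        if self.age_unit is not None and self.age_unit not in AGE_UNITS:
            raise ValueError(f"invalid age unit {self.age_unit!r}")


@dataclass(frozen=True)
class DrugMention:
    report: ReportKey
    drug_seq: int
    role: str
    drugname: str
    active_ingredient: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"invalid role code {self.role!r}")
        if self.drug_seq < 1:
            raise ValueError("drug_seq must be >= 1")


@dataclass(frozen=True)
class ReactionMention:
    report: ReportKey
    pt: str

    def __post_init__(self) -> None:
        if not self.pt.strip():
            raise ValueError("pt must be non-empty")


@dataclass(frozen=True)
class OutcomeMention:
    report: ReportKey
    outcome_code: str

    def __post_init__(self) -> None:
        if self.outcome_code not in OUTCOME_CODES:
            raise ValueError(f"invalid outcome code {self.outcome_code!r}")


@dataclass(frozen=True)
class TherapyRecord:
    report: ReportKey
    dsg_drug_seq: int
    start_dt: int = 0


@dataclass
class ParseStats:
    """Per-file row accounting: rows_in == records_out + skipped."""

    rows_in: dict[str, int] = field(default_factory=dict)
    records_out: dict[str, int] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)
    unknown_codes: dict[str, int] = field(default_factory=dict)
    orphans: dict[str, int] = field(default_factory=dict)


_DEMO_COLS = [
    "primaryid", "caseid", "fda_dt", "event_dt", "event_dt_precision",
    "sex", "age_value", "age_unit", "occp_cod", "reporter_country",
    "report_year",
]
_DRUG_COLS = ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]
_REAC_COLS = ["primaryid", "pt"]
_OUTC_COLS = ["primaryid", "outc_cod"]
_THER_COLS = ["primaryid", "dsg_drug_seq", "start_dt"]


@dataclass
class QuarterBundle:
    """Typed, normalized contents of one quarterly package."""

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    therapies: pd.DataFrame
    quarter_label: str = ""
    stats: ParseStats = field(default_factory=ParseStats)

    def key_for(self, primaryid: str) -> ReportKey:
        row = self.demo.loc[self.demo["primaryid"] == primaryid]
        if row.empty:
            raise KeyError(primaryid)
        r = row.iloc[0]
        return ReportKey(r["primaryid"], r["caseid"], int(r["fda_dt"]))

    def demo_records(self) -> Iterator[DemoRecord]:
        for r in self.demo.itertuples(index=False):
            yield DemoRecord(
                key=ReportKey(r.primaryid, r.caseid, int(r.fda_dt)),
                event_dt=int(r.event_dt),
                sex=r.sex,
                age_value=None if pd.isna(r.age_value) else float(r.age_value),
                age_unit=None if r.age_unit == "" else r.age_unit,
                reporter_occupation=None if r.occp_cod == "" else r.occp_cod,
                reporter_country=None if r.reporter_country == "" else r.reporter_country,
            )

    @staticmethod
    def concat(bundles: Iterable["QuarterBundle"], label: str = "ALL") -> "QuarterBundle":
        bundles = list(bundles)
        if not bundles:
            raise ValueError("no bundles to concatenate")
        return QuarterBundle(
            demo=pd.concat([b.demo for b in bundles], ignore_index=True),
            drugs=pd.concat([b.drugs for b in bundles], ignore_index=True),
            reactions=pd.concat([b.reactions for b in bundles], ignore_index=True),
            outcomes=pd.concat([b.outcomes for b in bundles], ignore_index=True),
            therapies=pd.concat([b.therapies for b in bundles], ignore_index=True),
            quarter_label=label,
        )


def _read_table(path: str | Path, filekind: str, stats: ParseStats) -> tuple[list[str], list[list[str]]]:
    """Read a ``$``-delimited file, returning canonical header + raw rows.

    Rows whose field count differs from the header are skipped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{filekind} file not found: {path}")
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DialectError(f"{path}: empty file (header expected)")
    header = [_ALIASES.get(h.strip().lower(), h.strip().lower()) for h in lines[0].split(_FIELD_SEP)]
    if "primaryid" not in header:
        raise DialectError(f"{path}: unrecognized dialect (no PRIMARYID or ISR column)")
    ncol = len(header)
    rows: list[list[str]] = []
    skipped = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(_FIELD_SEP)
        if len(fields) != ncol:
            skipped += 1
            logger.warning("%s line %d: expected %d fields, got %d — row skipped",
                           path, lineno, ncol, len(fields))
            continue
        rows.append(fields)
    stats.rows_in[filekind] = len(rows) + skipped
    stats.skipped[filekind] = skipped
    return header, rows


def _col(header: list[str], rows: list[list[str]], name: str) -> list[str]:
    if name in header:
        i = header.index(name)
        return [r[i].strip() for r in rows]
    return ["" for _ in rows]


def _count_unknown(stats: ParseStats, key: str, n: int) -> None:
    if n:
        stats.unknown_codes[key] = stats.unknown_codes.get(key, 0) + n
        logger.info("%s: %d unknown codes mapped to missing/UNK", key, n)


def _parse_demo(path: str | Path, stats: ParseStats) -> pd.DataFrame:
    header, rows = _read_table(path, "demo", stats)
    primaryid = _col(header, rows, "primaryid")
    caseid = _col(header, rows, "caseid")
    fda = [normalize_date(v)[0] for v in _col(header, rows, "fda_dt")]
    event = [normalize_date(v) for v in _col(header, rows, "event_dt")]

    sex_raw = [v.upper() for v in _col(header, rows, "sex")]
    sex = [v if v in SEX_CODES else "UNK" for v in sex_raw]
    _count_unknown(stats, "demo.sex", sum(1 for v in sex_raw if v and v not in SEX_CODES))

    age_vals: list[float] = []
    for v in _col(header, rows, "age"):
        try:
            x = float(v)
            age_vals.append(x if x >= 0 else float("nan"))
        except ValueError:
            age_vals.append(float("nan"))
    unit_raw = [v.upper() for v in _col(header, rows, "age_cod")]
    units = [v if v in AGE_UNITS else "" for v in unit_raw]
    _count_unknown(stats, "demo.age_cod", sum(1 for v in unit_raw if v and v not in AGE_UNITS))

    occ_raw = [v.upper() for v in _col(header, rows, "occp_cod")]
    occ = [v if v in OCCUPATION_CODES else "" for v in occ_raw]
    _count_unknown(stats, "demo.occp_cod", sum(1 for v in occ_raw if v and v not in OCCUPATION_CODES))

    country = _col(header, rows, "reporter_country")
    if "occr_country" in header:
        # fall back to occurrence country where the reporter country is blank
        occr = _col(header, rows, "occr_country")
        country = [c if c else o for c, o in zip(country, occr)]

    df = pd.DataFrame({
        "primaryid": primaryid,
        "caseid": caseid,
        "fda_dt": fda,
        "event_dt": [e[0] for e in event],
        "event_dt_precision": [e[1] for e in event],
        "sex": sex,
        "age_value": age_vals,
        "age_unit": units,
        "occp_cod": occ,
        "reporter_country": country,
    })
    df["report_year"] = df["fda_dt"] // 10000
    keep = df["primaryid"] != ""
    stats.skipped["demo"] += int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    stats.records_out["demo"] = len(df)
    return df


def _parse_drug(path: str | Path, stats: ParseStats) -> pd.DataFrame:
    header, rows = _read_table(path, "drug", stats)
    df = pd.DataFrame({
        "primaryid": _col(header, rows, "primaryid"),
        "drug_seq": pd.to_numeric(_col(header, rows, "drug_seq"), errors="coerce"),
        "role_cod": [v.upper() for v in _col(header, rows, "role_cod")],
        "drugname": _col(header, rows, "drugname"),
        "prod_ai": _col(header, rows, "prod_ai"),
    })
    bad = (~df["role_cod"].isin(ROLE_CODES)) | df["drug_seq"].isna() | (df["primaryid"] == "")
    _count_unknown(stats, "drug.role_cod", int((~df["role_cod"].isin(ROLE_CODES)).sum()))
    stats.skipped["drug"] += int(bad.sum())
    df = df.loc[~bad].reset_index(drop=True)
    df["drug_seq"] = df["drug_seq"].astype(int)
    stats.records_out["drug"] = len(df)
    return df


def _parse_reac(path: str | Path, stats: ParseStats) -> pd.DataFrame:
    header, rows = _read_table(path, "reac", stats)
    df = pd.DataFrame({
        "primaryid": _col(header, rows, "primaryid"),
        "pt": [v.strip() for v in _col(header, rows, "pt")],
    })
    bad = (df["pt"] == "") | (df["primaryid"] == "")
    stats.skipped["reac"] += int(bad.sum())
    df = df.loc[~bad].reset_index(drop=True)
    stats.records_out["reac"] = len(df)
    return df


def _parse_outc(path: str | Path, stats: ParseStats) -> pd.DataFrame:
    header, rows = _read_table(path, "outc", stats)
    df = pd.DataFrame({
        "primaryid": _col(header, rows, "primaryid"),
        "outc_cod": [v.upper() for v in _col(header, rows, "outc_cod")],
    })
    bad = (~df["outc_cod"].isin(OUTCOME_CODES)) | (df["primaryid"] == "")
    _count_unknown(stats, "outc.outc_cod", int((~df["outc_cod"].isin(OUTCOME_CODES)).sum()))
    stats.skipped["outc"] += int(bad.sum())
    df = df.loc[~bad].reset_index(drop=True)
    stats.records_out["outc"] = len(df)
    return df


def _parse_ther(path: str | Path, stats: ParseStats) -> pd.DataFrame:
    header, rows = _read_table(path, "ther", stats)
    df = pd.DataFrame({
        "primaryid": _col(header, rows, "primaryid"),
        "dsg_drug_seq": pd.to_numeric(_col(header, rows, "dsg_drug_seq"), errors="coerce"),
        "start_dt": [normalize_date(v)[0] for v in _col(header, rows, "start_dt")],
    })
    bad = df["dsg_drug_seq"].isna() | (df["primaryid"] == "")
    stats.skipped["ther"] += int(bad.sum())
    df = df.loc[~bad].reset_index(drop=True)
    df["dsg_drug_seq"] = df["dsg_drug_seq"].astype(int)
    stats.records_out["ther"] = len(df)
    return df


def parse_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    outc_path: str | Path,
    ther_path: str | Path,
    quarter_label: str = "",
) -> QuarterBundle:
    """Parse one quarterly package into a normalized :class:`QuarterBundle`.

    Mentions whose primaryid does not appear in the DEMO file are orphans:
    they are counted in ``stats.orphans``, logged, and dropped.
    """
    stats = ParseStats()
    demo = _parse_demo(demo_path, stats)
    drugs = _parse_drug(drug_path, stats)
    reac = _parse_reac(reac_path, stats)
    outc = _parse_outc(outc_path, stats)
    ther = _parse_ther(ther_path, stats)

    known = set(demo["primaryid"])
    parts = {}
    for name, df in [("drug", drugs), ("reac", reac), ("outc", outc), ("ther", ther)]:
        mask = df["primaryid"].isin(known)
        n_orphans = int((~mask).sum())
        if n_orphans:
            stats.orphans[name] = n_orphans
            logger.warning("%s: %d orphan mentions dropped (%s)", name, n_orphans, quarter_label)
        parts[name] = df.loc[mask].reset_index(drop=True)

    return QuarterBundle(
        demo=demo,
        drugs=parts["drug"],
        reactions=parts["reac"],
        outcomes=parts["outc"],
        therapies=parts["ther"],
        quarter_label=quarter_label,
        stats=stats,
    )


def parse_deleted_list(path: str | Path) -> set[str]:
    """Read a deleted-case list: one caseid per line, header tolerated.

    A first line whose token is not all digits is treated as a header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"deleted-case list not found: {path}")
    out: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            tok = line.strip().split(_FIELD_SEP)[0].strip()
            if not tok:
                continue
            if i == 0 and not tok.isdigit():
                continue  # header
            out.add(tok)
    return out


class VocabularyMap:
    """Case-insensitive PT -> primary (soc_name, soc_code) lookup."""

    def __init__(self, pt_to_soc: Mapping[str, tuple[str, int]]):
        self._map = {pt.strip().upper(): (name, int(code)) for pt, (name, code) in pt_to_soc.items()}

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, pt: str) -> tuple[str, int] | None:
        """Return ``(soc_name, soc_code)`` or None when unmapped."""
        return self._map.get(pt.strip().upper())

    def __contains__(self, pt: str) -> bool:
        return pt.strip().upper() in self._map


def load_pt_soc_map(path: str | Path) -> VocabularyMap:
    """Load a user-supplied PT->SOC CSV (columns: pt, soc_name, soc_code).

    Duplicate PT rows are tolerated when they agree; conflicting duplicates
    are a fatal error listing the offending PTs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PT->SOC map not found: {path}")
    df = pd.read_csv(path, dtype={"pt": str, "soc_name": str})
    if df.empty:
        return VocabularyMap({})
    missing = {"pt", "soc_name", "soc_code"} - set(df.columns)
    if missing:
        raise ValueError(f"PT->SOC map missing columns: {sorted(missing)}")
    mapping: dict[str, tuple[str, int]] = {}
    conflicts: list[str] = []
    for r in df.itertuples(index=False):
        key = str(r.pt).strip().upper()
        value = (str(r.soc_name), int(r.soc_code))
        if key in mapping and mapping[key] != value:
            conflicts.append(str(r.pt))
        mapping[key] = value
    if conflicts:
        raise ValueError(f"conflicting SOC assignments for PTs: {sorted(set(conflicts))}")
    return VocabularyMap(mapping)


def write_quarter(bundle: QuarterBundle, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write a bundle back to the modern ``$``-delimited dialect.

    Returns the mapping of file kind to path. Inverse of
    :func:`parse_quarter` up to column normalization already applied.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _fmt_date(v: int) -> str:
        return "" if v == 0 else str(v)

    demo = pd.DataFrame({
        "PRIMARYID": bundle.demo["primaryid"],
        "CASEID": bundle.demo["caseid"],
        "FDA_DT": bundle.demo["fda_dt"].map(_fmt_date),
        "EVENT_DT": bundle.demo["event_dt"].map(_fmt_date),
        "SEX": bundle.demo["sex"],
        "AGE": bundle.demo["age_value"].map(lambda v: "" if pd.isna(v) else f"{v:g}"),
        "AGE_COD": bundle.demo["age_unit"],
        "OCCP_COD": bundle.demo["occp_cod"],
        "REPORTER_COUNTRY": bundle.demo["reporter_country"],
    })
    drug = pd.DataFrame({
        "PRIMARYID": bundle.drugs["primaryid"],
        "DRUG_SEQ": bundle.drugs["drug_seq"],
        "ROLE_COD": bundle.drugs["role_cod"],
        "DRUGNAME": bundle.drugs["drugname"],
        "PROD_AI": bundle.drugs["prod_ai"],
    })
    reac = pd.DataFrame({"PRIMARYID": bundle.reactions["primaryid"], "PT": bundle.reactions["pt"]})
    outc = pd.DataFrame({"PRIMARYID": bundle.outcomes["primaryid"], "OUTC_COD": bundle.outcomes["outc_cod"]})
    ther = pd.DataFrame({
        "PRIMARYID": bundle.therapies["primaryid"],
        "DSG_DRUG_SEQ": bundle.therapies["dsg_drug_seq"],
        "START_DT": bundle.therapies["start_dt"].map(_fmt_date),
    })
    for kind, df in [("DEMO", demo), ("DRUG", drug), ("REAC", reac), ("OUTC", outc), ("THER", ther)]:
        p = outdir / f"{prefix}{kind}.txt"
        df.to_csv(p, sep=_FIELD_SEP, index=False, lineterminator="\n")
        paths[kind.lower()] = p
    return paths
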