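"""Generative model emulating FAERS-style quarterly data.

Reports draw a drug multiset (truncated-geometric count, weighted choice),
then one independent Bernoulli per (report, PT) whose probability is the
PT baseline multiplied by a configured rate ratio ``lam`` when that PT's
signal drug is present. Demographics, dates, outcomes and therapy rows
are drawn from categorical marginals; duplicate case versions and a
deleted-case list exercise the dedup stage.

Everything is driven by one :func:`numpy.random.default_rng` stream, so a
given config+seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import QuarterBundle, write_quarter
from .profile import AGE_BINS

__all__ = [
    "TruncatedGeometric",
    "DrugSpec",
    "PtSpec",
    "SignalPair",
    "SynthConfig",
    "TruthTable",
    "generate",
    "expected_ebgm",
]


@dataclass(frozen=True)
class TruncatedGeometric:
    """Geometric distribution on 1..max_value conditioned to its support."""

    mean: float
    max_value: int

    def __post_init__(self) -> None:
        if not (1 <= self.mean < self.max_value):
            raise ValueError("need 1 <= mean < max_value")

    def pmf(self) -> np.ndarray:
        k = np.arange(1, self.max_value + 1)
        if self.mean == 1:
            p = np.zeros(self.max_value)
            p[0] = 1.0
            return p

        def _mean(q: float) -> float:
            w = (1 - q) ** (k - 1) * q
            w /= w.sum()
            return float((k * w).sum())

        q = brentq(lambda q: _mean(q) - self.mean, 1e-9, 1 - 1e-9, xtol=1e-12)
        w = (1 - q) ** (k - 1) * q
        return w / w.sum()

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(np.arange(1, self.max_value + 1), size=size, p=self.pmf())


@dataclass(frozen=True)
class DrugSpec:
    name: str
    weight: float
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class PtSpec:
    pt: str
    soc: str
    baseline: float


@dataclass(frozen=True)
class SignalPair:
    drug: str
    pt: str
    lam: float


_DEFAULT_SEX = {"F": 0.60, "M": 0.30, "UNK": 0.10}
_DEFAULT_AGE = {"<18": 0.05, "18-45": 0.20, "45-65": 0.20, "65-75": 0.07, ">=75": 0.03, "Unknown": 0.45}
_DEFAULT_REPORTER = {"CN": 0.60, "MD": 0.20, "PH": 0.05, "OT": 0.08, "": 0.07}
_DEFAULT_COUNTRY = {"US": 0.95, "": 0.05}
_DEFAULT_YEAR = {str(y): 1 / 6 for y in range(2015, 2021)}
_DEFAULT_OUTCOME = {"HO": 0.05, "DE": 0.01, "DS": 0.01, "LT": 0.01}


@dataclass
class SynthConfig:
    n_reports: int
    drugs: list[DrugSpec]
    pts: list[PtSpec]
    signal_pairs: list[SignalPair] = field(default_factory=list)
    drugs_per_report: TruncatedGeometric = TruncatedGeometric(mean=1.3, max_value=5)
    duplicate_fraction: float = 0.0
    deleted_fraction: float = 0.0
    event_dt_missing: float = 0.2
    therapy_missing: float = 0.2
    sex_marginal: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SEX))
    age_marginal: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_AGE))
    reporter_marginal: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_REPORTER))
    country_marginal: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_COUNTRY))
    year_marginal: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_YEAR))
    outcome_probs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_OUTCOME))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not self.drugs or not self.pts:
            raise ValueError("need at least one drug and one PT")
        if not (0 <= self.duplicate_fraction < 1 and 0 <= self.deleted_fraction < 1):
            raise ValueError("fractions must lie in [0, 1)")
        names = {d.name for d in self.drugs}
        pts = {p.pt: p for p in self.pts}
        seen_pts: set[str] = set()
        for sp in self.signal_pairs:
            if sp.lam < 1:
                raise ValueError("lam must be >= 1")
            if sp.drug not in names or sp.pt not in pts:
                raise ValueError(f"signal pair references unknown drug/PT: {sp}")
            if pts[sp.pt].baseline * sp.lam > 1:
                raise ValueError(f"lam too large for baseline: {sp}")
            if sp.pt in seen_pts:
                raise ValueError(f"PT {sp.pt!r} appears in more than one signal pair")
            seen_pts.add(sp.pt)
        for p in self.pts:
            if not (0 < p.baseline < 1):
                raise ValueError(f"baseline must be in (0,1): {p}")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        """Build a config from plain declarative data (YAML/JSON)."""
        d = dict(d)
        d["drugs"] = [DrugSpec(x["name"], x["weight"], tuple(x.get("synonyms", ()))) for x in d["drugs"]]
        d["pts"] = [PtSpec(x["pt"], x["soc"], x["baseline"]) for x in d["pts"]]
        d["signal_pairs"] = [SignalPair(x["drug"], x["pt"], x["lam"]) for x in d.get("signal_pairs", [])]
        if "drugs_per_report" in d:
            d["drugs_per_report"] = TruncatedGeometric(**d["drugs_per_report"])
        return cls(**d)

    def vocabulary_frame(self) -> pd.DataFrame:
        """PT->SOC map matching the generated PTs (synthetic SOC codes)."""
        socs = {p.soc for p in self.pts}
        codes = {s: 10000000 + i for i, s in enumerate(sorted(socs))}
        return pd.DataFrame(
            [(p.pt, p.soc, codes[p.soc]) for p in self.pts],
            columns=["pt", "soc_name", "soc_code"],
        )


@dataclass
class TruthTable:
    """Design parameters actually used, for parameter-recovery tests."""

    lam: dict[str, float]  # "drug|pt" -> rate ratio
    duplicated_caseids: list[str]
    deleted_caseids: list[str]
    n_reports: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)


def _draw_categorical(rng: np.random.Generator, marginal: dict[str, float], size: int) -> np.ndarray:
    labels = list(marginal)
    p = np.asarray([marginal[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(labels, dtype=object), size=size, p=p)


_AGE_RANGE = {label: (lo, min(hi, 100.0)) for label, lo, hi in AGE_BINS}


def generate(config: SynthConfig, outdir: str | Path | None = None) -> tuple[QuarterBundle, TruthTable]:
    """Draw one synthetic quarter; optionally write the file dialect.

    When ``outdir`` is given, writes DEMO/DRUG/REAC/OUTC/THER plus
    ``DELETED.txt`` and ``truth.json`` into it.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    caseids = np.char.add("1", np.char.zfill(np.arange(n).astype(str), 7))
    primaryids = np.char.add(caseids, "1")

    # drug multiset per report
    weights = np.asarray([d.weight for d in config.drugs], dtype=float)
    wnorm = weights / weights.sum()
    k = config.drugs_per_report.sample(rng, n)
    flat_drug = rng.choice(len(config.drugs), size=int(k.sum()), p=wnorm)
    flat_report = np.repeat(np.arange(n), k)
    mention = pd.DataFrame({"report": flat_report, "drug": flat_drug})
    mention = mention.drop_duplicates().reset_index(drop=True)
    mention["pos"] = mention.groupby("report").cumcount()
    present = np.zeros((n, len(config.drugs)), dtype=bool)
    present[mention["report"], mention["drug"]] = True

    # reaction draws: independent Bernoulli with signal elevation
    lam_by_pt = {sp.pt: sp for sp in config.signal_pairs}
    drug_index = {d.name: i for i, d in enumerate(config.drugs)}
    reac_frames = []
    for j, p in enumerate(config.pts):
        prob = np.full(n, p.baseline)
        sp = lam_by_pt.get(p.pt)
        if sp is not None:
            prob = np.where(present[:, drug_index[sp.drug]], np.minimum(p.baseline * sp.lam, 1.0), prob)
        hits = rng.random(n) < prob
        if hits.any():
            reac_frames.append(pd.DataFrame({"report": np.flatnonzero(hits), "pt_index": j}))
    reac = (
        pd.concat(reac_frames, ignore_index=True).sort_values(["report", "pt_index"], kind="mergesort")
        if reac_frames else pd.DataFrame(columns=["report", "pt_index"])
    )

    # demographics and dates
    sex = _draw_categorical(rng, config.sex_marginal, n)
    age_bin = _draw_categorical(rng, config.age_marginal, n)
    age = np.full(n, np.nan)
    for label, (lo, hi) in _AGE_RANGE.items():
        mask = age_bin == label
        age[mask] = np.round(rng.uniform(lo, hi, size=int(mask.sum())), 1)
    reporter = _draw_categorical(rng, config.reporter_marginal, n)
    country = _draw_categorical(rng, config.country_marginal, n)
    year = _draw_categorical(rng, config.year_marginal, n).astype(int)
    month = rng.integers(1, 13, size=n)
    day = rng.integers(1, 21, size=n)  # headroom so duplicate versions stay in-month
    fda_dt = year * 10000 + month * 100 + day
    event_missing = rng.random(n) < config.event_dt_missing
    event_dt = np.where(event_missing, 0, fda_dt)

    demo = pd.DataFrame({
        "primaryid": primaryids,
        "caseid": caseids,
        "fda_dt": fda_dt,
        "event_dt": event_dt,
        "event_dt_precision": np.where(event_missing, "missing", "day"),
        "sex": sex,
        "age_value": age,
        "age_unit": np.where(np.isnan(age), "", "YR"),
        "occp_cod": reporter,
        "reporter_country": country,
    })
    demo["report_year"] = demo["fda_dt"] // 10000

    roles = np.where(mention["pos"] == 0, "PS", np.where(mention["pos"] % 2 == 1, "SS", "C"))
    drug_names = np.asarray([d.name for d in config.drugs], dtype=object)
    drugs = pd.DataFrame({
        "primaryid": primaryids[mention["report"]],
        "drug_seq": (mention["pos"] + 1).to_numpy(),
        "role_cod": roles,
        "drugname": drug_names[mention["drug"]],
        "prod_ai": drug_names[mention["drug"]],
    })

    pt_names = np.asarray([p.pt for p in config.pts], dtype=object)
    reactions = pd.DataFrame({
        "primaryid": primaryids[reac["report"].to_numpy(dtype=int)] if len(reac) else np.array([], dtype=object),
        "pt": pt_names[reac["pt_index"].to_numpy(dtype=int)] if len(reac) else np.array([], dtype=object),
    })

    outc_frames = []
    for code, p in config.outcome_probs.items():
        hits = rng.random(n) < p
        if hits.any():
            outc_frames.append(pd.DataFrame({"primaryid": primaryids[hits], "outc_cod": code}))
    outcomes = (
        pd.concat(outc_frames, ignore_index=True).sort_values(["primaryid", "outc_cod"], kind="mergesort").reset_index(drop=True)
        if outc_frames else pd.DataFrame(columns=["primaryid", "outc_cod"])
    )

    # one therapy row per PS mention, unless missing; onset mostly short
    ps = mention.loc[mention["pos"] == 0]
    ther_missing = rng.random(len(ps)) < config.therapy_missing
    onset = rng.geometric(1 / 20, size=len(ps))  # days before the event
    ev = pd.to_datetime(
        pd.Series(event_dt[ps["report"].to_numpy()]).astype(str), format="%Y%m%d", errors="coerce"
    )
    start = ev - pd.to_timedelta(onset, unit="D")
    start_int = start.dt.strftime("%Y%m%d").fillna("0").astype(int).to_numpy()
    start_int[ther_missing] = 0
    therapies = pd.DataFrame({
        "primaryid": primaryids[ps["report"]],
        "dsg_drug_seq": 1,
        "start_dt": start_int,
    })

    # duplicate versions: same caseid, larger primaryid and fda_dt
    n_dup = int(config.duplicate_fraction * n)
    dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False)) if n_dup else np.array([], dtype=int)
    if n_dup:
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["primaryid"] = np.char.add(caseids[dup_idx], "2")
        dup_demo["fda_dt"] = dup_demo["fda_dt"] + rng.integers(1, 9, size=n_dup)
        demo = pd.concat([demo, dup_demo], ignore_index=True)
        old_new = dict(zip(primaryids[dup_idx], dup_demo["primaryid"]))

        def _dup(df: pd.DataFrame) -> pd.DataFrame:
            sel = df.loc[df["primaryid"].isin(old_new)].copy()
            sel["primaryid"] = sel["primaryid"].map(old_new)
            return pd.concat([df, sel], ignore_index=True)

        drugs, reactions, outcomes, therapies = map(_dup, (drugs, reactions, outcomes, therapies))

    n_del = int(config.deleted_fraction * n)
    del_idx = np.sort(rng.choice(n, size=n_del, replace=False)) if n_del else np.array([], dtype=int)
    deleted = sorted(caseids[del_idx].tolist())

    bundle = QuarterBundle(
        demo=demo, drugs=drugs, reactions=reactions, outcomes=outcomes,
        therapies=therapies, quarter_label="SYNTH",
    )
    truth = TruthTable(
        lam={f"{sp.drug}|{sp.pt}": sp.lam for sp in config.signal_pairs},
        duplicated_caseids=sorted(caseids[dup_idx].tolist()),
        deleted_caseids=deleted,
        n_reports=n,
        seed=config.seed,
    )

    if outdir is not None:
        outdir = Path(outdir)
        write_quarter(bundle, outdir)
        with open(outdir / "DELETED.txt", "w", encoding="utf-8") as fh:
            fh.write("CASEID\n")
            fh.writelines(f"{cid}\n" for cid in deleted)
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            fh.write(truth.to_json())
        config.vocabulary_frame().to_csv(outdir / "pt_soc_map.csv", index=False, lineterminator="\n")
    return bundle, truth


def _presence_probability(config: SynthConfig, drug: str) -> float:
    """P(report contains the drug) under the with-replacement draw model."""
    weights = np.asarray([d.weight for d in config.drugs], dtype=float)
    w = weights / weights.sum()
    wd = w[[d.name for d in config.drugs].index(drug)]
    pmf = config.drugs_per_report.pmf()
    k = np.arange(1, len(pmf) + 1)
    return float((pmf * (1 - (1 - wd) ** k)).sum())


def expected_ebgm(config: SynthConfig, drug: str, pt: str) -> float:
    """Closed-form expected observed/expected ratio for one (drug, PT) pair.

    Exact for the pair's own signal structure; the contribution of signal
    pairs on *other* drugs to the margins uses the unconditional presence
    probability (the drug-presence correlation is ignored), which is
    negligible when drug weights are small.
    """
    names = [d.name for d in config.drugs]
    if drug not in names or pt not in {p.pt for p in config.pts}:
        raise ValueError("pair not in vocabulary")
    p_d = _presence_probability(config, drug)
    lam_by_pt = {sp.pt: sp for sp in config.signal_pairs}

    def elevated(p: PtSpec, given_drug: str | None) -> float:
        """P(pt drawn), optionally conditioning on given_drug present."""
        sp = lam_by_pt.get(p.pt)
        if sp is None:
            return p.baseline
        hit = min(p.baseline * sp.lam, 1.0)
        if given_drug is not None and sp.drug == given_drug:
            return hit
        p_other = _presence_probability(config, sp.drug)
        return p_other * hit + (1 - p_other) * p.baseline

    target_pt = next(p for p in config.pts if p.pt == pt)
    e_a = p_d * elevated(target_pt, drug)
    e_event = elevated(target_pt, None)
    e_t = p_d * sum(elevated(p, drug) for p in config.pts)
    e_n = sum(elevated(p, None) for p in config.pts)
    return (e_a * e_n) / (e_event * e_t)
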