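"""Recover global denominators from published signal-table rows.

A published PT-level row carries (a, ROR, PRR, chi2, IC, EBGM) to two
decimals but not the underlying 2x2 cells. The Table-1 identities let the
target-drug pair margin T = a+b be recovered per row in closed form:

    R = ROR/PRR  =>  T = a * (R - 1/PRR) / (R - 1)

and the pair-level grand total N is then pinned by the EBGM/PRR gap via
least squares over several rows. With (T, N) fitted, every remaining
statistic of any row follows from (a, PRR) alone, enabling a desk-scale
consistency check of a published analysis without the source database.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .contingency import ContingencyTable
from .stats import BcpnnPriors, DEFAULT_PRIORS, SignalEstimates, compute_estimates

__all__ = [
    "PrintedRow",
    "GlobalsEstimate",
    "load_reference_rows",
    "load_reference_profile",
    "t_from_row",
    "fit_globals",
    "reconstruct_table",
    "predict_row",
    "CALIBRATION_PTS",
]

# rows used to pin (T, N); chosen so no validation-target row calibrates itself
CALIBRATION_PTS = ("Diarrhoea", "Nausea", "Sleep paralysis")


@dataclass(frozen=True)
class PrintedRow:
    """One published PT-level row (values as printed, 2 d.p.)."""

    label: str
    a: int
    ror: float
    prr: float
    chi2: float
    ic: float
    ebgm: float

    def __post_init__(self) -> None:
        if self.a < 3:
            raise ValueError("published rows have a >= 3")
        if min(self.ror, self.prr, self.ebgm) <= 0:
            raise ValueError("published statistics must be positive")


@dataclass(frozen=True)
class GlobalsEstimate:
    """Recovered pair-level denominators and the fit loss."""

    T: float
    N: float
    residual: float

    def __post_init__(self) -> None:
        if not (0 < self.T < self.N):
            raise ValueError(f"need 0 < T < N, got T={self.T}, N={self.N}")


def load_reference_rows() -> pd.DataFrame:
    """Published PT-level rows shipped with the package."""
    with resources.files("faersig.data").joinpath("reference_pt_signals.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_profile() -> pd.DataFrame:
    """Published cohort profile counts shipped with the package."""
    with resources.files("faersig.data").joinpath("reference_profile_counts.csv").open() as fh:
        return pd.read_csv(fh)


def row_from_frame(df: pd.DataFrame, pt: str) -> PrintedRow:
    """Extract one :class:`PrintedRow` by PT label."""
    hit = df.loc[df["pt"].str.upper() == pt.upper()]
    if hit.empty:
        raise KeyError(pt)
    r = hit.iloc[0]
    return PrintedRow(label=str(r["pt"]), a=int(r["a"]), ror=float(r["ror"]),
                      prr=float(r["prr"]), chi2=float(r["chi2"]),
                      ic=float(r["ic"]), ebgm=float(r["ebgm"]))


def t_from_row(row: PrintedRow) -> float:
    """Closed-form target-drug pair margin T = a+b from (a, ROR, PRR)."""
    ratio = row.ror / row.prr
    if ratio <= 1:
        raise ValueError(f"{row.label}: ROR <= PRR, no finite T (R={ratio:.6f})")
    return row.a * (ratio - 1 / row.prr) / (ratio - 1)


def reconstruct_table(a: float, prr_value: float, T: float, N: float) -> ContingencyTable:
    """Cells implied by (a, PRR) under globals (T, N); real-valued."""
    if not (0 < a < T < N):
        raise ValueError("need 0 < a < T < N")
    b = T - a
    c = a * (N - T) / (T * prr_value)
    d = N - T - c
    if c <= 0 or d <= 0:
        raise ValueError("inconsistent inputs: non-positive comparator cells")
    return ContingencyTable(a=a, b=b, c=c, d=d)


def _predicted(a: float, prr_value: float, T: float, N: float) -> tuple[float, float]:
    t = reconstruct_table(a, prr_value, T, N)
    ror_pred = t.a * t.d / (t.b * t.c)
    ebgm_pred = t.a * t.n / ((t.a + t.c) * (t.a + t.b))
    return ror_pred, ebgm_pred


def fit_globals(rows: list[PrintedRow]) -> GlobalsEstimate:
    """Least-squares fit of (T, N) to the rows' printed ROR and EBGM.

    Deterministic for a fixed row set: the optimizer starts at the mean
    closed-form T and the N implied by the row with the widest PRR/EBGM
    gap, and runs to 1e-10 tolerances.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to fit (T, N)")
    t0 = float(np.mean([t_from_row(r) for r in rows]))
    # EBGM = N*PRR / (N + T*(PRR-1))  =>  N = T*EBGM*(PRR-1) / (PRR - EBGM)
    n0 = 0.0
    for r in sorted(rows, key=lambda r: r.prr - r.ebgm, reverse=True):
        if r.prr > r.ebgm:
            n0 = t0 * r.ebgm * (r.prr - 1) / (r.prr - r.ebgm)
            break
    if n0 <= t0:
        n0 = t0 * 1e3

    def residuals(x: np.ndarray) -> np.ndarray:
        T, N = np.exp(x)
        out = []
        for r in rows:
            try:
                ror_pred, ebgm_pred = _predicted(r.a, r.prr, T, N)
            except ValueError:
                return np.full(2 * len(rows), 1e6)
            out.append((ror_pred - r.ror) / r.ror)
            out.append((ebgm_pred - r.ebgm) / r.ebgm)
        return np.asarray(out)

    sol = least_squares(residuals, x0=np.log([t0, n0]), xtol=1e-10, ftol=1e-10, gtol=1e-10)
    if not sol.success:
        raise RuntimeError(f"globals fit did not converge: {sol.message}; residuals={sol.fun}")
    T, N = np.exp(sol.x)
    return GlobalsEstimate(T=float(T), N=float(N), residual=float(np.sum(sol.fun**2)))


def predict_row(
    a: float,
    prr_value: float,
    globals_: GlobalsEstimate,
    priors: BcpnnPriors = DEFAULT_PRIORS,
    yates: bool = False,
) -> SignalEstimates:
    """Full statistics for the table implied by (a, PRR) under the fit."""
    table = reconstruct_table(a, prr_value, globals_.T, globals_.N)
    return compute_estimates(table, priors=priors, yates=yates)


def fit_reference_globals(calibration_pts: tuple[str, ...] = CALIBRATION_PTS) -> GlobalsEstimate:
    """Fit (T, N) on the shipped reference rows."""
    df = load_reference_rows()
    rows = [row_from_frame(df, pt) for pt in calibration_pts]
    return fit_globals(rows)


def validate_reference(
    calibration_pts: tuple[str, ...] = CALIBRATION_PTS,
    rel_tol: float = 0.02,
    ic_tol: float = 0.05,
) -> pd.DataFrame:
    """Reproduce every shipped row's statistics from (a, PRR) and compare.

    Returns a tidy frame with predicted vs printed values and pass flags:
    ROR/chi2/EBGM at ``rel_tol`` relative, IC at ``ic_tol`` absolute.
    """
    df = load_reference_rows()
    globals_ = fit_reference_globals(calibration_pts)
    out = []
    for r in df.itertuples(index=False):
        est = predict_row(float(r.a), float(r.prr), globals_)
        checks = {
            "ror": (est.ror, float(r.ror), abs(est.ror - r.ror) / r.ror <= rel_tol),
            "chi2": (est.chi2, float(r.chi2), abs(est.chi2 - r.chi2) / r.chi2 <= rel_tol),
            "ic": (est.ic, float(r.ic), abs(est.ic - r.ic) <= ic_tol),
            "ebgm": (est.ebgm, float(r.ebgm), abs(est.ebgm - r.ebgm) / r.ebgm <= rel_tol),
        }
        for stat, (pred, printed, ok) in checks.items():
            out.append({"pt": r.pt, "a": r.a, "stat": stat, "predicted": pred,
                        "printed": printed, "pass": ok,
                        "calibration": r.pt in calibration_pts})
    return pd.DataFrame(out)
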