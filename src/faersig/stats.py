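"""Disproportionality statistics for drug-event 2x2 tables.

Implements the reporting odds ratio (ROR), proportional reporting ratio
(PRR), Pearson chi-squared (optionally Yates-corrected), the Bayesian
information component (IC) with its closed-form posterior expectation and
variance, and the observed/expected reporting ratio (EBGM) with a
log-scale confidence interval, together with the standard screening
thresholds:

* ROR: a >= 3 and 95% CI lower bound > 1
* PRR: a >= 3 and 95% CI lower bound > 1
* IC:  IC025 = E(IC) - 2*sqrt(V(IC)) > 0
* EBGM: EBGM05 > 2

No continuity correction is applied anywhere; tables with zero cells are
reported as not evaluable for the ratio estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contingency import ContingencyTable

__all__ = [
    "NotEvaluableError",
    "BcpnnPriors",
    "SignalEstimates",
    "SignalDecision",
    "ror",
    "prr",
    "chi_square",
    "bcpnn_ic",
    "ebgm",
    "compute_estimates",
    "evaluate_signal",
    "evaluate_tables",
]

_Z = 1.96


class NotEvaluableError(ValueError):
    """A statistic cannot be computed for this table (zero cell/margin)."""


@dataclass(frozen=True)
class BcpnnPriors:
    """Hyperparameters of the IC posterior; gamma is derived from these."""

    alpha: float = 2.0
    beta: float = 2.0
    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.alpha1, self.beta1, self.gamma11) <= 0:
            raise ValueError("all priors must be positive")


DEFAULT_PRIORS = BcpnnPriors()


def ror(table: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio ``ad/bc`` with 95% CI.

    Raises :class:`NotEvaluableError` when any cell is zero.
    """
    a, b, c, d = table.as_tuple()
    if min(a, b, c, d) <= 0:
        raise NotEvaluableError("ROR needs all four cells > 0")
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return value, value * math.exp(-_Z * se), value * math.exp(_Z * se)


def prr(table: ContingencyTable) -> tuple[float, float, float]:
    """Proportional reporting ratio ``(a/(a+b)) / (c/(c+d))`` with 95% CI."""
    a, b, c, d = table.as_tuple()
    if a <= 0 or c <= 0:
        raise NotEvaluableError("PRR needs a > 0 and c > 0")
    value = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return value, value * math.exp(-_Z * se), value * math.exp(_Z * se)


def chi_square(table: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-squared on the 2x2; zero when any margin is empty.

    With ``yates`` the continuity correction reduces ``|ad - bc|`` by
    ``N/2`` (floored at zero) before squaring.
    """
    a, b, c, d = (float(x) for x in table.as_tuple())  # avoid int64 overflow
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if n <= 0 or denom == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff * diff / denom


def bcpnn_ic(
    table: ContingencyTable, priors: BcpnnPriors = DEFAULT_PRIORS
) -> tuple[float, float, float]:
    """Posterior expectation, variance and lower bound of the IC.

    Returns ``(e_ic, v_ic, ic025)`` where ``ic025 = e_ic - 2*sqrt(v_ic)``.
    Defined for ``a == 0`` through the priors.
    """
    a, b, c, d = table.as_tuple()
    n = table.n
    if n <= 0:
        raise NotEvaluableError("IC needs N > 0")
    al, be, al1, be1, g11 = priors.alpha, priors.beta, priors.alpha1, priors.beta1, priors.gamma11
    row = a + b  # target-drug margin
    col = a + c  # event margin
    gamma = g11 * (n + al) * (n + be) / ((row + al1) * (col + be1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + gamma) * (row + al1) * (col + be1))
    )
    v_ic = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - row + al - al1) / ((row + al1) * (1 + n + al))
        + (n - col + be - be1) / ((col + be1) * (1 + n + be))
    ) / math.log(2) ** 2
    return e_ic, v_ic, e_ic - 2 * math.sqrt(v_ic)


def ebgm(table: ContingencyTable) -> tuple[float, float, float]:
    """Observed/expected reporting ratio ``aN/((a+c)(a+b))`` with 95% CI.

    The point value needs ``a > 0`` and both margins positive; the CI
    additionally needs all four cells positive, else ``(value, nan, nan)``.
    """
    a, b, c, d = table.as_tuple()
    n = table.n
    if a <= 0 or (a + c) <= 0 or (a + b) <= 0:
        raise NotEvaluableError("EBGM needs a > 0 and positive margins")
    value = a * n / ((a + c) * (a + b))
    if min(a, b, c, d) <= 0:
        return value, float("nan"), float("nan")
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return value, value * math.exp(-_Z * se), value * math.exp(_Z * se)


@dataclass
class SignalEstimates:
    """All statistics for one drug-event pair."""

    table: ContingencyTable
    ror: float = float("nan")
    ror_lo: float = float("nan")
    ror_hi: float = float("nan")
    prr: float = float("nan")
    prr_lo: float = float("nan")
    prr_hi: float = float("nan")
    chi2: float = float("nan")
    ic: float = float("nan")
    v_ic: float = float("nan")
    ic025: float = float("nan")
    ebgm: float = float("nan")
    ebgm_lo: float = float("nan")
    ebgm_hi: float = float("nan")


@dataclass(frozen=True)
class SignalDecision:
    pass_ror: bool
    pass_prr: bool
    pass_bcpnn: bool
    pass_ebgm: bool
    combined: bool
    rule: str = "ALL"


def compute_estimates(
    table: ContingencyTable,
    priors: BcpnnPriors = DEFAULT_PRIORS,
    yates: bool = False,
) -> SignalEstimates:
    """Evaluate every statistic; non-evaluable ones are left NaN."""
    est = SignalEstimates(table=table)
    try:
        est.ror, est.ror_lo, est.ror_hi = ror(table)
    except NotEvaluableError:
        pass
    try:
        est.prr, est.prr_lo, est.prr_hi = prr(table)
    except NotEvaluableError:
        pass
    est.chi2 = chi_square(table, yates=yates)
    try:
        est.ic, est.v_ic, est.ic025 = bcpnn_ic(table, priors)
    except NotEvaluableError:
        pass
    try:
        est.ebgm, est.ebgm_lo, est.ebgm_hi = ebgm(table)
    except NotEvaluableError:
        pass
    return est


def evaluate_signal(
    estimates: SignalEstimates, rule: str = "ALL", min_a: int = 3
) -> SignalDecision:
    """Apply the four screening thresholds and the combination rule."""
    a = estimates.table.a
    pass_ror = bool(a >= min_a and estimates.ror_lo > 1)
    pass_prr = bool(a >= min_a and estimates.prr_lo > 1)
    pass_bcpnn = bool(estimates.ic025 > 0)
    pass_ebgm = bool(estimates.ebgm_lo > 2)
    flags = [pass_ror, pass_prr, pass_bcpnn, pass_ebgm]
    rule_up = rule.upper()
    if rule_up == "ALL":
        combined = all(flags)
    elif rule_up == "ANY":
        combined = any(flags)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return SignalDecision(pass_ror, pass_prr, pass_bcpnn, pass_ebgm, combined, rule_up)


def evaluate_tables(
    tables: list[tuple[str, ContingencyTable]],
    priors: BcpnnPriors = DEFAULT_PRIORS,
    yates: bool = False,
    rule: str = "ALL",
    min_a: int = 3,
) -> pd.DataFrame:
    """Batch evaluation: one row per pair with cells, statistics and flags."""
    rows = []
    for label, table in tables:
        est = compute_estimates(table, priors=priors, yates=yates)
        dec = evaluate_signal(est, rule=rule, min_a=min_a)
        rows.append({
            "event_label": label,
            "a": table.a, "b": table.b, "c": table.c, "d": table.d, "n": table.n,
            "ror": est.ror, "ror_lo": est.ror_lo, "ror_hi": est.ror_hi,
            "prr": est.prr, "prr_lo": est.prr_lo, "prr_hi": est.prr_hi,
            "chi2": est.chi2,
            "ic": est.ic, "v_ic": est.v_ic, "ic025": est.ic025,
            "ebgm": est.ebgm, "ebgm05": est.ebgm_lo, "ebgm_hi": est.ebgm_hi,
            "pass_ror": dec.pass_ror, "pass_prr": dec.pass_prr,
            "pass_bcpnn": dec.pass_bcpnn, "pass_ebgm": dec.pass_ebgm,
            "combined": dec.combined,
        })
    columns = ["event_label", "a", "b", "c", "d", "n",
               "ror", "ror_lo", "ror_hi", "prr", "prr_lo", "prr_hi", "chi2",
               "ic", "v_ic", "ic025", "ebgm", "ebgm05", "ebgm_hi",
               "pass_ror", "pass_prr", "pass_bcpnn", "pass_ebgm", "combined"]
    return pd.DataFrame(rows, columns=columns)
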