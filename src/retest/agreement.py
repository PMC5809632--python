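"""Agreement indices for two-scan test-retest studies.

Four indices are computed from a fitted one-way random-effects model
and/or the raw pairs:

* WSCV  = sigma_e / mu                        (scaled, dimensionless)
* ICC   = sigma_s^2 / (sigma_s^2 + sigma_e^2) (scaled, in [0, 1])
* RC    = sqrt(2) * z_{1-alpha/2} * sigma_e   (unscaled, outcome units;
  also called the smallest detectable difference, SDD)
* PTRT  = mean_i |2 (y_i2 - y_i1) / (y_i2 + y_i1)|  (scaled; the signed
  variant drops the absolute value)

The estimators satisfy the exact identity RC / mu = sqrt(2) z WSCV, so
the RC-to-grand-mean ratio is just WSCV scaled by a constant.

Confidence intervals: ICC uses the exact one-way F interval (Searle
type) for k = 2; WSCV and RC use a chi-square interval on sigma_e^2
with df = n, treating mu as known (a plug-in approximation, exact only
for the sigma_e part).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import (
    DegenerateDesignError,
    TestRetestTable,
    ValidationError,
    VarianceComponents,
    fit_anova,
)

__all__ = [
    "AgreementIndices",
    "wscv",
    "icc",
    "icc_ci",
    "rc",
    "rc_ci",
    "ptrt",
    "wscv_ci",
    "evaluate",
]


class UndefinedRatioError(ValidationError):
    """A ratio-scale index is undefined for the given data (non-positive
    mean or pairwise sum)."""


def wscv(vc: VarianceComponents) -> float:
    """Within-subject coefficient of variation, sigma_e / mu.

    Requires a strictly positive grand mean; the WSCV is meaningless
    for outcomes that are not ratio-scale positive.
    """
    if vc.mu <= 0:
        raise UndefinedRatioError(f"WSCV undefined for mu = {vc.mu} <= 0")
    return vc.sigma_e / vc.mu


def icc(vc: VarianceComponents) -> float:
    """One-way intraclass correlation, sigma_s^2 / (sigma_s^2 + sigma_e^2).

    Measures subject distinguishability: the share of total variance due
    to true between-subject differences.  With the clamped
    (``truncated``) estimator the result is 0; if both variance
    components are zero every observation is identical and the ratio is
    undefined.
    """
    denom = vc.sigma_s**2 + vc.sigma_e**2
    if denom == 0:
        raise DegenerateDesignError(
            "ICC undefined: all observations identical (zero total variance)"
        )
    return vc.sigma_s**2 / denom


def icc_ci(vc: VarianceComponents, alpha: float = 0.05) -> tuple[float, float]:
    """Exact one-way F confidence interval for the ICC (k = 2).

    With F0 = msb/msw on (n-1, n) degrees of freedom:

        lower = (F0/Fu - 1) / (F0/Fu + 1),   Fu = F_{1-a/2; n-1, n}
        upper = (F0*Fv - 1) / (F0*Fv + 1),   Fv = F_{1-a/2; n, n-1}

    both clamped to [0, 1].
    """
    _check_alpha(alpha)
    if vc.msw == 0:
        # no within-subject noise: ICC is exactly 1
        return (1.0, 1.0)
    f0 = vc.msb / vc.msw
    return _icc_interval_from_f(f0, vc.n_subjects, alpha)


def _icc_interval_from_f(f0: float, n: int, alpha: float) -> tuple[float, float]:
    df1, df2 = n - 1, n
    fu = stats.f.ppf(1 - alpha / 2, df1, df2)
    fv = stats.f.ppf(1 - alpha / 2, df2, df1)
    fl = f0 / fu
    fh = f0 * fv
    lower = (fl - 1) / (fl + 1)
    upper = (fh - 1) / (fh + 1)
    return (float(np.clip(lower, 0.0, 1.0)), float(np.clip(upper, 0.0, 1.0)))


def rc(vc: VarianceComponents, alpha: float = 0.05) -> float:
    """Repeatability coefficient, sqrt(2) * z_{1-alpha/2} * sigma_e.

    Interpretable as the smallest detectable difference: the bound
    expected to contain 100(1-alpha)% of test-retest differences.  At
    alpha = 0.05 the multiplier of sigma_e is 2.7719 (z = 1.96).
    """
    _check_alpha(alpha)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(np.sqrt(2.0) * z * vc.sigma_e)


def _sigma_e_interval(msw: float, n: int, alpha: float) -> tuple[float, float]:
    """Chi-square CI for sigma_e given msw on df = n (two scans each)."""
    df = n
    lo_var = df * msw / stats.chi2.ppf(1 - alpha / 2, df)
    hi_var = df * msw / stats.chi2.ppf(alpha / 2, df)
    return (float(np.sqrt(lo_var)), float(np.sqrt(hi_var)))


def wscv_ci(vc: VarianceComponents, alpha: float = 0.05) -> tuple[float, float]:
    """Approximate CI for the WSCV: chi-square interval on sigma_e
    divided by the point estimate of mu (mu's own uncertainty ignored)."""
    _check_alpha(alpha)
    if vc.mu <= 0:
        raise UndefinedRatioError(f"WSCV CI undefined for mu = {vc.mu} <= 0")
    lo, hi = _sigma_e_interval(vc.msw, vc.n_subjects, alpha)
    return (lo / vc.mu, hi / vc.mu)


def rc_ci(vc: VarianceComponents, alpha: float = 0.05) -> tuple[float, float]:
    """Approximate CI for the RC from the chi-square interval on sigma_e."""
    _check_alpha(alpha)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = _sigma_e_interval(vc.msw, vc.n_subjects, alpha)
    return (float(np.sqrt(2.0) * z * lo), float(np.sqrt(2.0) * z * hi))


def ptrt(table: TestRetestTable, signed: bool = False) -> float:
    """Percent test-retest as a fraction (0.20, not 20%).

    Absolute form: mean over subjects of |2 (y2 - y1) / (y2 + y1)|.
    Signed form drops the absolute value (the historical "raw mean
    normalized difference").  Each difference is scaled locally by its
    own pair mean, which is why PTRT reacts less to a single aberrant
    scan than the globally scaled WSCV.
    """
    y = table.values
    sums = y[:, 0] + y[:, 1]
    if np.any(sums <= 0):
        bad = [p.subject_id for p, s in zip(table.pairs, sums) if s <= 0]
        raise UndefinedRatioError(
            f"PTRT undefined: non-positive pair sum for subjects {bad}"
        )
    norm_diff = 2.0 * (y[:, 1] - y[:, 0]) / sums
    if signed:
        return float(norm_diff.mean())
    return float(np.abs(norm_diff).mean())


@dataclass(frozen=True)
class AgreementIndices:
    """All agreement indices for one test-retest table, from one shared fit.

    ``ptrt_abs`` and ``ptrt_signed`` are fractions; rendering as percent
    (x100) belongs to the report layer.  ``ci`` maps index name ->
    (lower, upper) where an interval formula exists.
    """

    wscv: float
    icc: float
    rc: float
    ptrt_abs: float
    ptrt_signed: float
    grand_mean: float
    alpha: float
    n_subjects: int
    truncated: bool
    ci: dict = field(default_factory=dict)
    components: VarianceComponents | None = None


def evaluate(table: TestRetestTable, alpha: float = 0.05) -> AgreementIndices:
    """Compute WSCV, ICC, RC, PTRT (+ grand mean and CIs) from one fit.

    The returned values satisfy ``rc / grand_mean`` =
    ``sqrt(2) * z_{1-alpha/2} * wscv`` exactly, an algebraic identity of
    the estimators.
    """
    _check_alpha(alpha)
    vc = fit_anova(table)
    out = AgreementIndices(
        wscv=wscv(vc),
        icc=icc(vc),
        rc=rc(vc, alpha),
        ptrt_abs=ptrt(table, signed=False),
        ptrt_signed=ptrt(table, signed=True),
        grand_mean=vc.mu,
        alpha=alpha,
        n_subjects=vc.n_subjects,
        truncated=vc.truncated,
        ci={
            "icc": icc_ci(vc, alpha),
            "wscv": wscv_ci(vc, alpha),
            "rc": rc_ci(vc, alpha),
        },
        components=vc,
    )
    # enforce the scaled-WSCV identity as an internal consistency check
    z = stats.norm.ppf(1 - alpha / 2)
    assert abs(out.rc / out.grand_mean - np.sqrt(2.0) * z * out.wscv) < 1e-10
    return out


def _check_alpha(alpha: float) -> None:
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
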