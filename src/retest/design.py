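"""Sample-size planning from test-retest summaries.

Two planning problems are covered:

1. **Precision-based n for ICC / WSCV / RC** — find the smallest number
   of subjects for which the expected confidence-interval width (the
   package's own interval formulas evaluated with the F or chi-square
   statistic set to its population plug-in value under the assumed
   parameters) falls below a target width.  For the one-way ICC with
   k = 2 the plug-in F ratio is (1 + rho) / (1 - rho), the population
   value of MSB/MSW.  PTRT is deliberately excluded: it estimates no
   parameter of the random-effects model, so no interval to invert
   exists.

2. **Paired pre-post n** — the within-subject SD from a test-retest
   experiment feeds the normal-approximation paired formula
   n = ceil((z_{1-a/2} + z_power)^2 * 2 sigma_e^2 / delta^2), the paired
   difference variance 2 sigma_e^2 following from the model with no
   period effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

from scipy import stats

from .agreement import _icc_interval_from_f, _sigma_e_interval
from .model import ValidationError

__all__ = [
    "PrecisionSpec",
    "PrePostSpec",
    "InfeasiblePrecisionError",
    "expected_ci_width",
    "n_for_precision",
    "n_prepost",
]

_METRICS = ("icc", "wscv", "rc")


class InfeasiblePrecisionError(ValueError):
    """The target CI width cannot be reached within the search cap."""

    def __init__(self, target: float, limiting_width: float, n_max: int):
        self.target = target
        self.limiting_width = limiting_width
        self.n_max = n_max
        super().__init__(
            f"target width {target} unreachable: width at n={n_max} "
            f"is {limiting_width:.6g}"
        )


@dataclass(frozen=True)
class PrecisionSpec:
    """Planning assumptions for a precision-based sample size.

    metric : {"icc", "wscv", "rc"}
    assumed_value : planning value — population rho for "icc"; ignored
        for "wscv"/"rc", which are driven by sigma_e (and mu for wscv).
    sigma_e, mu : auxiliary components, required for wscv/rc (mu only
        for wscv).
    target_ci_width : desired full interval width, same scale as the
        metric.
    """

    metric: str
    target_ci_width: float
    assumed_value: float | None = None
    sigma_e: float | None = None
    mu: float | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValidationError(
                f"metric must be one of {_METRICS}, got {self.metric!r}"
            )
        if not self.target_ci_width > 0:
            raise ValidationError("target_ci_width must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.metric == "icc":
            if self.assumed_value is None or not 0 < self.assumed_value < 1:
                raise ValidationError("icc planning needs assumed rho in (0, 1)")
        else:
            if self.sigma_e is None or self.sigma_e <= 0:
                raise ValidationError(f"{self.metric} planning needs sigma_e > 0")
            if self.metric == "wscv" and (self.mu is None or self.mu <= 0):
                raise ValidationError("wscv planning needs mu > 0")


@dataclass(frozen=True)
class PrePostSpec:
    """Assumptions for a paired pre-post design: effect size delta
    (mean pre-post difference, outcome units), within-subject SD, level
    and target power."""

    effect_size: float
    sigma_e: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.effect_size == 0:
            raise ValidationError("effect_size must be nonzero")
        if self.sigma_e <= 0:
            raise ValidationError("sigma_e must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValidationError("power must be in (0, 1)")


def expected_ci_width(spec: PrecisionSpec, n: int) -> float:
    """Expected full CI width at n subjects under the spec's assumptions.

    The interval formulas are the same ones ``retest.agreement`` applies
    to data, evaluated at plug-in population statistics: F0 =
    (1 + rho)/(1 - rho) for the ICC; msw = sigma_e^2 for WSCV and RC.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    if spec.metric == "icc":
        rho = spec.assumed_value
        f0 = (1 + rho) / (1 - rho)
        lo, hi = _icc_interval_from_f(f0, n, spec.alpha)
        return hi - lo
    lo, hi = _sigma_e_interval(spec.sigma_e**2, n, spec.alpha)
    if spec.metric == "wscv":
        return (hi - lo) / spec.mu
    z = stats.norm.ppf(1 - spec.alpha / 2)
    return sqrt(2.0) * z * (hi - lo)


def n_for_precision(spec: PrecisionSpec, n_max: int = 1_000_000) -> int:
    """Smallest n >= 3 whose expected CI width is <= the target.

    Search is increasing doubling followed by bisection, so the result
    satisfies width(n) <= target < width(n - 1) whenever n > 3.
    Raises :class:`InfeasiblePrecisionError` if even ``n_max`` subjects
    cannot reach the target.
    """
    target = spec.target_ci_width
    lo_n = 3
    if expected_ci_width(spec, lo_n) <= target:
        return lo_n
    hi_n = lo_n
    while expected_ci_width(spec, hi_n) > target:
        if hi_n >= n_max:
            raise InfeasiblePrecisionError(
                target, expected_ci_width(spec, n_max), n_max
            )
        hi_n = min(hi_n * 2, n_max)
    # invariant: width(lo_n) > target >= width(hi_n)
    lo_n = hi_n // 2
    while hi_n - lo_n > 1:
        mid = (lo_n + hi_n) // 2
        if expected_ci_width(spec, mid) <= target:
            hi_n = mid
        else:
            lo_n = mid
    return hi_n


def n_prepost(spec: PrePostSpec) -> int:
    """Subjects needed for a paired pre-post comparison.

    Normal approximation: n = ceil((z_{1-a/2} + z_power)^2 * 2 sigma_e^2
    / delta^2), floored at 3 subjects.
    """
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    n = ceil((z_a + z_b) ** 2 * 2.0 * spec.sigma_e**2 / spec.effect_size**2)
    return max(int(n), 3)
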