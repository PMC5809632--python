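"""Bland-Altman agreement diagnostics for test-retest pairs.

For each subject the pair is reduced to (mean, difference); the bias is
the mean difference and the limits of agreement are
bias +/- z_{1-alpha/2} * SD(differences).  Under the one-way
random-effects model the differences have variance 2 sigma_e^2, so
about 95% of them are expected to fall within the alpha = 0.05 limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import DegenerateDesignError, TestRetestTable

__all__ = ["BlandAltmanSummary", "bland_altman"]


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Per-subject (mean, difference) points with bias and limits.

    ``differences`` follow the stated sign convention (default
    retest - test); ``sd_diff`` is the sample SD of the differences
    (ddof = 1).
    """

    means: np.ndarray
    differences: np.ndarray
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    alpha: float
    sign_convention: str = "retest-minus-test"

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (mean, difference) pairs, one row per subject."""
        return np.column_stack([self.means, self.differences])

    @property
    def n_subjects(self) -> int:
        return len(self.means)


def bland_altman(
    table: TestRetestTable,
    alpha: float = 0.05,
    sign: str = "retest-minus-test",
    t_limits: bool = False,
) -> BlandAltmanSummary:
    """Compute a Bland-Altman summary for a two-scan table.

    Parameters
    ----------
    table
        Validated test-retest table (n >= 2 enforced at construction).
    alpha
        Level for the limits of agreement (0.05 -> the familiar
        bias +/- 1.96 SD limits).
    sign
        ``"retest-minus-test"`` (default) or ``"test-minus-retest"``.
        The convention is documented because it is a choice, not a fact
        of the method; flipping it negates the bias and mirrors the
        limits.
    t_limits
        If True, use the t quantile on n - 1 df instead of the normal
        quantile — a small-sample widening, off by default to match the
        conventional 1.96 limits.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sign not in ("retest-minus-test", "test-minus-retest"):
        raise ValueError(f"unknown sign convention {sign!r}")
    y = table.values
    n = table.n_subjects
    if n < 2:  # pragma: no cover - table construction already enforces this
        raise DegenerateDesignError("need >= 2 subjects to estimate sd_diff")
    means = y.mean(axis=1)
    diffs = y[:, 1] - y[:, 0]
    if sign == "test-minus-retest":
        diffs = -diffs
    bias = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    if t_limits:
        q = float(stats.t.ppf(1 - alpha / 2, n - 1))
    else:
        q = float(stats.norm.ppf(1 - alpha / 2))
    return BlandAltmanSummary(
        means=means,
        differences=diffs,
        bias=bias,
        sd_diff=sd_diff,
        loa_lower=bias - q * sd_diff,
        loa_upper=bias + q * sd_diff,
        alpha=alpha,
        sign_convention=sign,
    )
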