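"""One-way random-effects ANOVA model for test-retest data.

A test-retest experiment measures the same quantitative outcome (for
example a PET total volume of distribution, V_T) twice on each of n
subjects under near-identical conditions.  The standard generative model
is the one-way random-effects ANOVA

    y_ij = mu + s_i + e_ij,    s_i ~ N(0, sigma_s^2),  e_ij ~ N(0, sigma_e^2),

with subject effect s_i and measurement error e_ij mutually independent.
``fit_anova`` estimates (mu, sigma_s, sigma_e) by the classical method of
moments from the between- and within-subject mean squares, which is
closed-form for the two-scan design this package standardises on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DegenerateDesignError",
    "ValidationError",
    "GroupLabels",
    "TestRetestPair",
    "TestRetestTable",
    "VarianceComponents",
    "fit_anova",
]


class ValidationError(ValueError):
    """Input data violate a structural requirement (non-finite values,
    duplicate subjects, wrong number of scans)."""


class DegenerateDesignError(ValidationError):
    """The design cannot support estimation (fewer than 2 subjects, or all
    observations identical where a ratio requires spread)."""


@dataclass(frozen=True)
class GroupLabels:
    """Optional grouping tags for a table: which dataset, quantification
    method and region of interest the measurements belong to."""

    dataset_id: str | None = None
    method_id: str | None = None
    region: str | None = None

    def as_tuple(self) -> tuple[str | None, str | None, str | None]:
        return (self.dataset_id, self.method_id, self.region)


@dataclass(frozen=True)
class TestRetestPair:
    """One subject's (test, retest) outcome values.

    ``y1`` is the test scan, ``y2`` the retest scan, in the same outcome
    units.  Ratio-scale indices (WSCV, PTRT) additionally require both
    values to be strictly positive; that is checked where those indices
    are computed, not here.
    """

    subject_id: str
    y1: float
    y2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.y1) and np.isfinite(self.y2)):
            raise ValidationError(
                f"subject {self.subject_id!r}: non-finite value "
                f"(y1={self.y1}, y2={self.y2})"
            )


class TestRetestTable:
    """An ordered collection of test-retest pairs for one analysis group.

    Invariants enforced at construction: at least 2 distinct subjects,
    exactly two scans per subject (pairs), unique subject ids.

    Parameters
    ----------
    pairs
        Iterable of :class:`TestRetestPair` (or ``(subject_id, y1, y2)``
        tuples, which are coerced).
    labels
        Optional :class:`GroupLabels` tagging dataset / method / region.
    """

    def __init__(
        self,
        pairs: Iterable[TestRetestPair | tuple],
        labels: GroupLabels | None = None,
    ) -> None:
        coerced = []
        for p in pairs:
            if not isinstance(p, TestRetestPair):
                p = TestRetestPair(str(p[0]), float(p[1]), float(p[2]))
            coerced.append(p)
        if len(coerced) < 2:
            raise DegenerateDesignError(
                f"need at least 2 subjects, got {len(coerced)}"
            )
        ids = [p.subject_id for p in coerced]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        self.pairs: tuple[TestRetestPair, ...] = tuple(coerced)
        self.labels = labels

    @classmethod
    def from_arrays(
        cls,
        y1: Sequence[float],
        y2: Sequence[float],
        subject_ids: Sequence[str] | None = None,
        labels: GroupLabels | None = None,
    ) -> "TestRetestTable":
        y1 = np.asarray(y1, dtype=float)
        y2 = np.asarray(y2, dtype=float)
        if y1.shape != y2.shape or y1.ndim != 1:
            raise ValidationError("y1 and y2 must be 1-D arrays of equal length")
        if subject_ids is None:
            subject_ids = [f"S{i + 1}" for i in range(len(y1))]
        return cls(
            [TestRetestPair(str(s), a, b) for s, a, b in zip(subject_ids, y1, y2)],
            labels=labels,
        )

    @property
    def n_subjects(self) -> int:
        return len(self.pairs)

    @property
    def subject_ids(self) -> list[str]:
        return [p.subject_id for p in self.pairs]

    @property
    def values(self) -> np.ndarray:
        """(n, 2) array of outcomes; column 0 = test, column 1 = retest."""
        return np.array([[p.y1, p.y2] for p in self.pairs], dtype=float)

    def all_positive(self) -> bool:
        return bool(np.all(self.values > 0))

    def __len__(self) -> int:
        return len(self.pairs)

    def __repr__(self) -> str:
        tag = f", labels={self.labels}" if self.labels else ""
        return f"TestRetestTable(n_subjects={self.n_subjects}{tag})"


@dataclass(frozen=True)
class VarianceComponents:
    """Fitted parameters of the one-way random-effects model.

    Attributes
    ----------
    mu : float
        Grand mean, in outcome units.
    sigma_s : float
        Between-subject standard deviation.
    sigma_e : float
        Within-subject standard deviation, ``sqrt(msw)``; its square is
        the within-subject mean sum of squares (WSMSS).
    msb, msw : float
        Between- and within-subject mean squares.
    n_subjects : int
        Number of subjects n.
    k_replicates : int
        Scans per subject; fixed at 2 throughout the package.
    truncated : bool
        True when the raw moment estimate of sigma_s^2, (msb - msw)/2,
        was negative and clamped to zero.
    """

    mu: float
    sigma_s: float
    sigma_e: float
    msb: float
    msw: float
    n_subjects: int
    k_replicates: int = 2
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.sigma_s < 0 or self.sigma_e < 0 or self.msw < 0:
            raise ValidationError("variance components must be non-negative")


def fit_anova(table: TestRetestTable) -> VarianceComponents:
    """Fit the one-way random-effects ANOVA by method of moments.

    With n subjects and k = 2 scans each:

    * ``msw`` = sum_i sum_j (y_ij - ybar_i)^2 / n      (df = n(k-1) = n)
    * ``msb`` = 2 * sum_i (ybar_i - ybar)^2 / (n - 1)  (df = n - 1)
    * ``sigma_e^2 = msw``; ``sigma_s^2 = max(0, (msb - msw)/2)``.

    A negative raw between-subject variance is clamped to zero and
    flagged via ``truncated``.

    Raises
    ------
    DegenerateDesignError
        If the table has fewer than 2 subjects (enforced at table
        construction).
    """
    y = table.values  # (n, 2)
    n = table.n_subjects
    mu = float(y.mean())
    subj_means = y.mean(axis=1)
    msw = float(((y - subj_means[:, None]) ** 2).sum() / n)
    msb = float(2.0 * ((subj_means - mu) ** 2).sum() / (n - 1))
    sigma_e = float(np.sqrt(msw))
    raw_var_s = (msb - msw) / 2.0
    truncated = raw_var_s < 0.0
    sigma_s = 0.0 if truncated else float(np.sqrt(raw_var_s))
    return VarianceComponents(
        mu=mu,
        sigma_s=sigma_s,
        sigma_e=sigma_e,
        msb=msb,
        msw=msw,
        n_subjects=n,
        k_replicates=2,
        truncated=truncated,
    )
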