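"""Shared fixtures and the independent sums-of-squares oracle.

The oracle computes the one-way ANOVA mean squares with explicit double
loops over deviations — deliberately naive so it cannot share a bug
with the vectorised implementation it checks.
"""

from __future__ import annotations

from math import sqrt

import numpy as np
import pytest
from hypothesis import settings

import retest as rt

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


def anova_oracle(pairs):
    """Brute-force moment estimates for a list of (y1, y2) pairs.

    Returns (mu, msb, msw, sigma_s, sigma_e, truncated).
    """
    n = len(pairs)
    values = []
    for y1, y2 in pairs:
        values.append(y1)
        values.append(y2)
    mu = sum(values) / (2 * n)

    subject_means = []
    for y1, y2 in pairs:
        subject_means.append((y1 + y2) / 2)

    wss = 0.0
    for (y1, y2), m in zip(pairs, subject_means):
        for y in (y1, y2):
            wss += (y - m) ** 2
    msw = wss / n  # df = n(k-1) with k = 2

    bss = 0.0
    for m in subject_means:
        bss += (m - mu) ** 2
    msb = 2.0 * bss / (n - 1)

    sigma_e = sqrt(msw)
    raw = (msb - msw) / 2.0
    truncated = raw < 0
    sigma_s = 0.0 if truncated else sqrt(raw)
    return mu, msb, msw, sigma_s, sigma_e, truncated


@pytest.fixture
def toy_table() -> rt.TestRetestTable:
    """The three-subject worked example used across the suite."""
    return rt.TestRetestTable([("a", 10, 12), ("b", 20, 18), ("c", 30, 33)])


@pytest.fixture
def toy_pairs() -> list[tuple[float, float]]:
    return [(10.0, 12.0), (20.0, 18.0), (30.0, 33.0)]


def simulate_pairs(rng: np.random.Generator, n: int, mu: float, sigma_s: float,
                   sigma_e: float) -> rt.TestRetestTable:
    """Direct draw from the random-effects model, independent of the
    package's own generator."""
    s = rng.normal(0, sigma_s, n)
    y = mu + s[:, None] + rng.normal(0, sigma_e, (n, 2))
    return rt.TestRetestTable.from_arrays(y[:, 0], y[:, 1])
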