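"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive the match counts with plain Python double
loops over every ordered template pair; they share no code with the
implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from keepsampen import SampEnParams, TimeSeries


def brute_force_counts(values, m, r):
    """Enumerate every ordered pair of length-m / length-(m+1) templates.

    Template starts run over i = 0 .. N-m-1 for both lengths; a pair counts
    when its Chebyshev distance is <= r.  Returns (B_total, A_total).
    """
    values = list(values)
    n = len(values)
    nt = n - m
    B = A = 0
    for i in range(nt):
        for j in range(nt):
            if j == i:
                continue
            d_m = max(abs(values[i + k] - values[j + k]) for k in range(m))
            if d_m <= r:
                B += 1
                if max(d_m, abs(values[i + m] - values[j + m])) <= r:
                    A += 1
    return B, A


def brute_force_counts_keep(values, mask, m, r):
    """Missing-aware oracle: only pairs of fully observed length-(m+1)
    windows enter either count.  Returns (B_total, A_total, n_valid)."""
    values = list(values)
    mask = list(mask)
    n = len(values)
    nt = n - m

    def valid(i):
        return all(mask[i + k] for k in range(m + 1))

    starts = [i for i in range(nt) if valid(i)]
    B = A = 0
    for i in starts:
        for j in starts:
            if j == i:
                continue
            d_m = max(abs(values[i + k] - values[j + k]) for k in range(m))
            if d_m <= r:
                B += 1
                if max(d_m, abs(values[i + m] - values[j + m])) <= r:
                    A += 1
    return B, A, len(starts)


def random_series(rng: np.random.Generator, n: int, missing_frac: float = 0.0) -> TimeSeries:
    """A random quantized series (ties at the tolerance boundary are common)."""
    values = rng.integers(0, 10, size=n).astype(float) / 2.0
    mask = np.ones(n, dtype=bool)
    if missing_frac > 0:
        k = int(round(missing_frac * n))
        if k:
            mask[rng.choice(n, size=k, replace=False)] = False
    return TimeSeries(values=values, mask=mask)


@pytest.fixture
def default_params() -> SampEnParams:
    return SampEnParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
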