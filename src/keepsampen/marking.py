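"""Missingness simulation: mark points of a complete series as missing.

Two schemes emulate how gaps arise in continuously monitored physiological
signals:

* **random sample marking** — isolated dropouts (e.g. excluded outlier
  beats): ``C = round(P * N)`` positions masked, chosen uniformly without
  replacement.
* **group-based random marking** — burst dropouts (e.g. transmission
  interruptions): the series is split into ``M = round(P * 10 * I)`` equal
  contiguous segments and one contiguous run of ``L = round(N * P / M)``
  points is masked inside each segment, at a uniformly random in-segment
  start.  The scatter factor ``I`` controls how fragmented the missingness
  is: larger ``I`` gives more, shorter runs at fixed ``P``.

``P`` is a fraction (0.10 means 10% missing); with that reading the segment
formula gives ``M = 1`` single group at 10% missing and ``I = 1``.  All
non-integer counts are resolved by round-half-away-from-zero, which keeps
totals closest to ``P * N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .core import TimeSeries

__all__ = ["MissingSpec", "random_sample_marking", "group_based_marking", "apply_marking"]


def _round_half_away(x: float) -> int:
    """round(2.5) -> 3, not banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class MissingSpec:
    """How to mark values missing: fraction ``P``, scheme, scatter factor ``I``."""

    P: float
    scheme: Literal["random", "group"] = "random"
    I: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.P < 1.0:
            raise ValueError(f"P must be in [0, 1), got {self.P}")
        if self.scheme not in ("random", "group"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "group" and (self.I is None or self.I < 1):
            raise ValueError("group scheme requires an integer factor I >= 1")


def random_sample_marking(series: TimeSeries, P: float, seed: int) -> TimeSeries:
    """Mask exactly ``round(P * N)`` uniformly chosen positions as missing."""
    if not series.is_complete:
        raise ValueError("marking schemes expect a fully observed input series")
    if not 0.0 <= P < 1.0:
        raise ValueError(f"P must be in [0, 1), got {P}")
    n = series.n
    c = _round_half_away(P * n)
    mask = np.ones(n, dtype=bool)
    if c > 0:
        rng = np.random.default_rng(seed)
        mask[rng.choice(n, size=c, replace=False)] = False
    return TimeSeries(values=series.values.copy(), mask=mask)


def group_based_marking(
    series: TimeSeries, P: float, I: int, seed: int
) -> TimeSeries:
    """Mask one contiguous run per segment.

    The series is divided into ``M = round(P * 10 * I)`` contiguous segments
    of equal base length (remainder points assigned to the last segment); in
    each segment a run of ``L = round(N * P / M)`` consecutive points is
    masked, its start uniform over positions that keep the run inside the
    segment.  Total masked = ``M * L``.
    """
    if not series.is_complete:
        raise ValueError("marking schemes expect a fully observed input series")
    if not 0.0 < P < 1.0:
        raise ValueError(f"group scheme requires P in (0, 1), got {P}")
    if I < 1:
        raise ValueError(f"factor I must be >= 1, got {I}")
    n = series.n
    m_segments = _round_half_away(P * 10 * I)
    if m_segments < 1:
        raise ValueError(f"M = round(P*10*I) = {m_segments} < 1 (P={P}, I={I})")
    run_len = _round_half_away(n * P / m_segments)
    if run_len < 1:
        raise ValueError(
            f"run length round(N*P/M) = {run_len} < 1 (N={n}, P={P}, M={m_segments})"
        )
    base_seg = n // m_segments
    if run_len > base_seg:
        raise ValueError(
            f"run length {run_len} exceeds segment length {base_seg} "
            f"(N={n}, P={P}, I={I}, M={m_segments})"
        )
    rng = np.random.default_rng(seed)
    mask = np.ones(n, dtype=bool)
    for s in range(m_segments):
        start = s * base_seg
        end = (s + 1) * base_seg if s < m_segments - 1 else n  # remainder -> last
        run_start = int(rng.integers(start, end - run_len + 1))
        mask[run_start : run_start + run_len] = False
    return TimeSeries(values=series.values.copy(), mask=mask)


def apply_marking(series: TimeSeries, spec: MissingSpec) -> TimeSeries:
    """Apply the scheme described by ``spec``; P = 0 returns the series unchanged."""
    if spec.P == 0.0:
        return series
    if spec.scheme == "random":
        return random_sample_marking(series, spec.P, spec.seed)
    assert spec.I is not None
    return group_based_marking(series, spec.P, spec.I, spec.seed)
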