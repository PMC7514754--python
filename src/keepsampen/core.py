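"""Sample entropy on complete series, tolerance derivation, and multiscale extension.

Sample entropy (SampEn) quantifies the irregularity of a time series as the
negative natural logarithm of the conditional probability that two length-m
template windows matching within a Chebyshev tolerance ``r`` also match when
extended by one point.  This module implements the standard estimator for
fully observed series; handling of missing values lives in
:mod:`keepsampen.methods`.

Conventions
-----------
* Template start indices run over ``1 ... N - m`` (1-based) for BOTH the
  length-m and length-(m+1) counts, the Richman-Moorman convention, which
  guarantees ``A_total <= B_total`` and hence a non-negative entropy.
* A distance exactly equal to ``r`` counts as a match.
* The tolerance default is ``r = 0.15 * sigma`` where ``sigma`` is the
  *population* standard deviation (denominator ``n``) of the observed values.
* Self-pairs (``j == i``) are excluded from all counts.

Internally indices are 0-based; documentation states 1-based positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "InsufficientDataError",
    "TimeSeries",
    "SampEnParams",
    "MatchCounts",
    "SampEnResult",
    "chebyshev_distance",
    "count_matches",
    "tolerance_from_sd",
    "sample_entropy",
    "coarse_grain",
    "multiscale_entropy",
]


class InsufficientDataError(ValueError):
    """Raised when a series has too few (observed) points for the request."""


@dataclass(frozen=True)
class TimeSeries:
    """An ordered real-valued signal with an aligned missingness mask.

    Parameters
    ----------
    values
        Signal samples in signal units.  Entries at masked-out positions are
        placeholders and are never interpreted as data.
    mask
        Boolean array aligned with ``values``; ``True`` marks an observed
        point, ``False`` a missing one.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if self.mask is None:
            mask = np.ones(values.size, dtype=bool)
        else:
            mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError(
                f"mask length {mask.size} != values length {values.size}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "TimeSeries":
        """Build a series from raw values; NaN entries become missing points."""
        arr = np.asarray(values, dtype=float)
        return cls(values=arr, mask=~np.isnan(arr))

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    @property
    def observed_values(self) -> np.ndarray:
        """Observed samples in order, missing positions dropped."""
        return self.values[self.mask]

    def with_nan(self) -> np.ndarray:
        """Values with missing positions replaced by NaN (for I/O, plotting)."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out


ToleranceMode = Literal["absolute", "sd_factor"]


@dataclass(frozen=True)
class SampEnParams:
    """Embedding dimension and tolerance specification.

    ``m`` is the template length (default 2). The tolerance is either an
    absolute value in signal units (``tolerance_mode='absolute'``) or a
    dimensionless factor multiplying the series standard deviation
    (``'sd_factor'``, default factor 0.15).
    """

    m: int = 2
    tolerance_mode: ToleranceMode = "sd_factor"
    r_value: float = 0.15

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.tolerance_mode not in ("absolute", "sd_factor"):
            raise ValueError(f"unknown tolerance_mode {self.tolerance_mode!r}")
        if self.r_value < 0:
            raise ValueError(f"r_value must be >= 0, got {self.r_value}")

    def resolve_tolerance(self, series: TimeSeries) -> tuple[float, Optional[float]]:
        """Return ``(r, sigma)`` in signal units; sigma is None in absolute mode."""
        if self.tolerance_mode == "absolute":
            return float(self.r_value), None
        r, sigma = tolerance_from_sd(series, self.r_value)
        return r, sigma


@dataclass(frozen=True)
class MatchCounts:
    """Ordered template-pair match counts at lengths m and m+1.

    ``B_total`` counts ordered pairs (i, j), i != j, whose length-m templates
    are within ``r`` in Chebyshev distance; ``A_total`` likewise at length
    m+1 over the same index range.  ``n_valid_templates`` is the number of
    template start positions that entered the counts.
    """

    B_total: int
    A_total: int
    n_valid_templates: int

    def __post_init__(self) -> None:
        if self.A_total > self.B_total:
            raise ValueError(
                f"A_total ({self.A_total}) cannot exceed B_total ({self.B_total})"
            )
        if min(self.B_total, self.A_total, self.n_valid_templates) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class SampEnResult:
    """Outcome of a sample-entropy computation.

    ``entropy`` is ``-ln(A_total / B_total)`` in nats, or ``None`` when the
    estimate is undefined (no matched pairs at one of the two lengths).  An
    undefined result is an explicit sentinel, never a silent 0 or infinity.
    """

    entropy: Optional[float]
    counts: Optional[MatchCounts]
    r_used: float
    sigma_used: Optional[float]
    method: str = "sampen"

    @property
    def is_defined(self) -> bool:
        return self.entropy is not None


def chebyshev_distance(v1: Sequence[float], v2: Sequence[float]) -> float:
    """Maximum absolute componentwise difference between two equal-length vectors."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size == 0:
        raise ValueError("inputs must be non-empty 1-D vectors")
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return float(np.max(np.abs(a - b)))


def _match_matrices(
    x: np.ndarray, m: int, r: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean match matrices for length-m and length-(m+1) templates.

    Entry [i, j] of the first matrix is True iff the length-m templates
    starting at i and j (0-based, i, j in 0 .. N-m-1) match within r; the
    second matrix extends the match by one point.  Diagonals are not removed
    here.  O(N^2) time and memory.
    """
    n = x.size
    nt = n - m  # number of template start positions
    # point-level closeness: C[i, j] = |x_i - x_j| <= r
    close = np.abs(x[:, None] - x[None, :]) <= r
    match_m = close[:nt, :nt].copy()
    for k in range(1, m):
        match_m &= close[k : k + nt, k : k + nt]
    match_m1 = match_m & close[m : m + nt, m : m + nt]
    return match_m, match_m1


def count_matches(series: TimeSeries, m: int, r: float) -> MatchCounts:
    """Count matched ordered template pairs at lengths m and m+1.

    Both counts use template start positions 1 .. N-m (1-based) and exclude
    self-pairs.  Equivalent to exhaustive enumeration of all ordered pairs.
    """
    if not series.is_complete:
        raise ValueError("count_matches requires a fully observed series")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    n = series.n
    if n - m < 2:
        raise InsufficientDataError(
            f"need at least m + 2 = {m + 2} points, got {n}"
        )
    match_m, match_m1 = _match_matrices(series.values, m, r)
    nt = n - m
    np.fill_diagonal(match_m, False)
    np.fill_diagonal(match_m1, False)
    return MatchCounts(
        B_total=int(match_m.sum()),
        A_total=int(match_m1.sum()),
        n_valid_templates=nt,
    )


def tolerance_from_sd(series: TimeSeries, factor: float) -> tuple[float, float]:
    """Tolerance ``r = factor * sigma`` from the observed values only.

    ``sigma`` is the population standard deviation (denominator ``n``) of the
    observed points; missing positions are excluded.  A zero-variance series
    yields ``r = 0`` with a logged warning.
    """
    obs = series.observed_values
    if obs.size < 2:
        raise InsufficientDataError(
            f"need at least 2 observed points to estimate sigma, got {obs.size}"
        )
    sigma = float(np.std(obs))  # population convention, ddof=0
    if sigma == 0.0:
        logger.warning(
            "zero-variance series: tolerance r = 0; every identical template matches"
        )
    return factor * sigma, sigma


def sample_entropy(series: TimeSeries, params: SampEnParams) -> SampEnResult:
    """Sample entropy of a fully observed series.

    Returns ``-ln(A_total / B_total)``; the pair-count normalizers of the
    probability definitions cancel in the ratio, so raw counts suffice.  When
    either count is zero the result is flagged undefined and the counts are
    still reported.
    """
    if not series.is_complete:
        raise ValueError(
            "sample_entropy requires a fully observed series; "
            "use a missing-value method from keepsampen.methods"
        )
    r, sigma = params.resolve_tolerance(series)
    counts = count_matches(series, params.m, r)
    return _result_from_counts(counts, r, sigma, method="sampen")


def _result_from_counts(
    counts: MatchCounts, r: float, sigma: Optional[float], method: str
) -> SampEnResult:
    if counts.A_total == 0 or counts.B_total == 0:
        return SampEnResult(
            entropy=None, counts=counts, r_used=r, sigma_used=sigma, method=method
        )
    entropy = -math.log(counts.A_total / counts.B_total) + 0.0  # avoid -0.0
    return SampEnResult(
        entropy=entropy, counts=counts, r_used=r, sigma_used=sigma, method=method
    )


def coarse_grain(series: TimeSeries, scale: int) -> TimeSeries:
    """Block-average a series for multiscale analysis.

    Output element k is the mean of the k-th consecutive non-overlapping block
    of ``scale`` points; a trailing partial block is dropped, so the output
    has ``floor(N / scale)`` points.
    """
    if not series.is_complete:
        raise ValueError("coarse_grain requires a fully observed series")
    if scale < 1:
        raise ValueError(f"scale must be >= 1, got {scale}")
    if scale > series.n:
        raise ValueError(f"scale {scale} exceeds series length {series.n}")
    if scale == 1:
        return series
    n_blocks = series.n // scale
    blocks = series.values[: n_blocks * scale].reshape(n_blocks, scale)
    return TimeSeries(values=blocks.mean(axis=1), mask=np.ones(n_blocks, dtype=bool))


def multiscale_entropy(
    series: TimeSeries,
    params: SampEnParams,
    scales: Sequence[int],
    tolerance_per_scale: bool = False,
) -> list[tuple[int, SampEnResult]]:
    """Sample entropy of coarse-grained versions of the series.

    By default the tolerance is resolved once from the original series
    (sd_factor mode) and reused at every scale, the convention of the
    classical multiscale-entropy implementation; set ``tolerance_per_scale``
    to recompute ``r`` from each coarse-grained series instead.  A scale whose
    coarse-grained series is too short is reported undefined; other scales
    are still computed.
    """
    if not series.is_complete:
        raise ValueError("multiscale_entropy requires a fully observed series")
    r_global, sigma_global = params.resolve_tolerance(series)
    results: list[tuple[int, SampEnResult]] = []
    for scale in scales:
        try:
            grained = coarse_grain(series, scale)
            if tolerance_per_scale:
                r, sigma = params.resolve_tolerance(grained)
            else:
                r, sigma = r_global, sigma_global
            counts = count_matches(grained, params.m, r)
            res = _result_from_counts(counts, r, sigma, method="sampen")
        except (InsufficientDataError, ValueError) as exc:
            logger.warning("scale %d undefined: %s", scale, exc)
            res = SampEnResult(
                entropy=None,
                counts=None,
                r_used=r_global,
                sigma_used=sigma_global,
                method="sampen",
            )
        results.append((int(scale), res))
    return results
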