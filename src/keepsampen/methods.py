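"""Four ways to compute sample entropy on a series with missing values.

* ``keep_sampen`` — the screening method: template pairs enter the match
  counts only when both length-(m+1) windows are fully observed, and the
  tolerance is derived from observed values only.  The input data are never
  modified or imputed.
* ``skip_sampen`` — delete missing points, concatenate the remainder, run
  the standard estimator.
* ``linear_sampen`` — fill gaps by linear interpolation, then standard SampEn.
* ``boot_sampen`` — fill gaps by resampling observed values with replacement;
  average the entropy over several (default 10) reconstructions.

All four agree exactly with :func:`keepsampen.core.sample_entropy` when the
series has no missing values.
"""

from __future__ import annotations

import enum
import logging
import math
from typing import Optional, Sequence

import numpy as np

from .core import (
    InsufficientDataError,
    MatchCounts,
    SampEnParams,
    SampEnResult,
    TimeSeries,
    _match_matrices,
    _result_from_counts,
    sample_entropy,
    tolerance_from_sd,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Method",
    "keep_sampen",
    "skip_sampen",
    "linear_interpolate",
    "linear_sampen",
    "bootstrap_impute",
    "boot_sampen",
    "compute_with_method",
]


class Method(str, enum.Enum):
    """Closed enumeration of the missing-value handling methods."""

    KEEP = "keep"
    SKIP = "skip"
    LINEAR = "linear"
    BOOT = "boot"

    @classmethod
    def parse(cls, name: "str | Method") -> "Method":
        if isinstance(name, Method):
            return name
        try:
            return cls(name.lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown method {name!r}; expected one of: {valid}")


def _valid_template_starts(mask: np.ndarray, m: int) -> np.ndarray:
    """Boolean array over template starts 0..N-m-1: True iff the length-(m+1)
    window x[i..i+m] is fully observed."""
    n = mask.size
    nt = n - m
    valid = mask[:nt].copy()
    for k in range(1, m + 1):
        valid &= mask[k : k + nt]
    return valid


def keep_sampen(series: TimeSeries, params: SampEnParams) -> SampEnResult:
    """Sample entropy with missing-aware template screening.

    A template start i is valid iff the length-(m+1) window starting there
    contains only observed points; both the length-m and length-(m+1) counts
    run over ordered pairs of *valid* starts.  Screening both counts on the
    longer window excludes pairs whose length-m distance exists but whose
    extension does not, keeping the conditional-probability interpretation
    intact.  The tolerance (sd_factor mode) uses observed values only.  The
    input series is never modified.
    """
    if params.m < 1:
        raise ValueError(f"m must be >= 1, got {params.m}")
    n = series.n
    m = params.m
    if n - m < 2:
        raise InsufficientDataError(f"need at least m + 2 = {m + 2} points, got {n}")
    valid = _valid_template_starts(series.mask, m)
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise InsufficientDataError(
            f"only {n_valid} fully observed length-{m + 1} windows; need at least 2"
        )
    r, sigma = params.resolve_tolerance(series)  # sigma from observed values only

    # Placeholder values at masked positions must never influence the result:
    # zero them out, then null every row/column of an invalid template.
    x = np.where(series.mask, series.values, 0.0)
    match_m, match_m1 = _match_matrices(x, m, r)
    pair_ok = valid[:, None] & valid[None, :]
    match_m &= pair_ok
    match_m1 &= pair_ok
    np.fill_diagonal(match_m, False)
    np.fill_diagonal(match_m1, False)
    counts = MatchCounts(
        B_total=int(match_m.sum()),
        A_total=int(match_m1.sum()),
        n_valid_templates=n_valid,
    )
    return _result_from_counts(counts, r, sigma, method="keep")


def skip_sampen(series: TimeSeries, params: SampEnParams) -> SampEnResult:
    """Delete missing points, concatenate the remainder, run standard SampEn.

    The tolerance (sd_factor mode) is computed on the concatenated series,
    which is identical to the observed-value set.
    """
    obs = series.observed_values
    if obs.size < params.m + 2:
        raise InsufficientDataError(
            f"{obs.size} observed points < m + 2 = {params.m + 2}"
        )
    concatenated = TimeSeries(values=obs, mask=np.ones(obs.size, dtype=bool))
    res = sample_entropy(concatenated, params)
    return SampEnResult(
        entropy=res.entropy,
        counts=res.counts,
        r_used=res.r_used,
        sigma_used=res.sigma_used,
        method="skip",
    )


def linear_interpolate(series: TimeSeries) -> TimeSeries:
    """Fill each gap with the straight line between its flanking observed points.

    Leading and trailing gaps, which have only one flanking point, are filled
    with the nearest observed value (constant extrapolation).  Observed values
    are preserved bit-exactly.
    """
    if series.n_observed < 2:
        raise InsufficientDataError(
            f"need at least 2 observed points to interpolate, got {series.n_observed}"
        )
    if series.is_complete:
        return series
    idx = np.arange(series.n)
    obs_idx = idx[series.mask]
    filled = series.values.copy()
    filled[~series.mask] = np.interp(
        idx[~series.mask], obs_idx, series.values[series.mask]
    )
    return TimeSeries(values=filled, mask=np.ones(series.n, dtype=bool))


def linear_sampen(series: TimeSeries, params: SampEnParams) -> SampEnResult:
    """Standard SampEn after linear interpolation of the gaps."""
    filled = linear_interpolate(series)
    res = sample_entropy(filled, params)
    return SampEnResult(
        entropy=res.entropy,
        counts=res.counts,
        r_used=res.r_used,
        sigma_used=res.sigma_used,
        method="linear",
    )


def bootstrap_impute(series: TimeSeries, seed: int) -> TimeSeries:
    """Fill each missing position with an independent draw, with replacement,
    from the multiset of observed values.  Observed positions are unchanged;
    the result is reproducible from ``seed``."""
    obs = series.observed_values
    if obs.size == 0:
        raise InsufficientDataError("cannot impute a series with no observed points")
    if series.is_complete:
        return series
    rng = np.random.default_rng(seed)
    filled = series.values.copy()
    n_missing = series.n - series.n_observed
    filled[~series.mask] = rng.choice(obs, size=n_missing, replace=True)
    return TimeSeries(values=filled, mask=np.ones(series.n, dtype=bool))


def boot_sampen(
    series: TimeSeries,
    params: SampEnParams,
    n_boot: int = 10,
    seed: int = 0,
) -> SampEnResult:
    """Average SampEn over bootstrap-imputed reconstructions.

    ``n_boot`` reconstructions (default 10) are generated, each from the
    sub-seed ``seed + replicate_index``; the reported entropy is the
    arithmetic mean over reconstructions with a defined estimate.  The
    tolerance (sd_factor mode) is recomputed on each reconstruction.
    Reconstructions with an undefined estimate are excluded from the mean
    with a logged count; if all are undefined the result is undefined.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if series.is_complete:
        # every reconstruction is the series itself; the mean of identical
        # estimates is that estimate, bit-exactly
        res = sample_entropy(series, params)
        return SampEnResult(
            entropy=res.entropy,
            counts=res.counts,
            r_used=res.r_used,
            sigma_used=res.sigma_used,
            method="boot",
        )
    entropies: list[float] = []
    last: Optional[SampEnResult] = None
    n_undefined = 0
    for b in range(n_boot):
        reconstruction = bootstrap_impute(series, seed=seed + b)
        last = sample_entropy(reconstruction, params)
        if last.is_defined:
            entropies.append(last.entropy)  # type: ignore[arg-type]
        else:
            n_undefined += 1
    if n_undefined:
        logger.warning(
            "boot_sampen: %d of %d reconstructions had undefined entropy "
            "and were excluded from the mean",
            n_undefined,
            n_boot,
        )
    assert last is not None
    # counts are per-reconstruction and do not aggregate meaningfully; report
    # those of the last reconstruction for diagnostics only
    return SampEnResult(
        entropy=float(np.mean(entropies)) if entropies else None,
        counts=last.counts,
        r_used=last.r_used,
        sigma_used=last.sigma_used,
        method="boot",
    )


def compute_with_method(
    method: "str | Method",
    series: TimeSeries,
    params: SampEnParams,
    seed: int = 0,
    n_boot: int = 10,
) -> SampEnResult:
    """Dispatch to one of the four missing-value methods by name."""
    method = Method.parse(method)
    if method is Method.KEEP:
        return keep_sampen(series, params)
    if method is Method.SKIP:
        return skip_sampen(series, params)
    if method is Method.LINEAR:
        return linear_sampen(series, params)
    return boot_sampen(series, params, n_boot=n_boot, seed=seed)
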