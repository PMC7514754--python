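"""Method-comparison harness: percentage errors, sweeps, summaries, paired tests.

The benchmark design: take a complete series, record its entropy ``x0``,
mark a fraction ``P`` of points missing, recompute entropy ``x`` with each
missing-value method on the *same* masked series, and score each method by

    percentage error = |x - x0| / |x0| * 100.

The paired design (all methods see the identical mask in a cell) is what
makes paired t-tests between methods valid; each record carries a hash of
its mask so pairing can be asserted after the fact.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SampEnParams, TimeSeries, sample_entropy
from .marking import MissingSpec, apply_marking
from .methods import Method, compute_with_method

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorRecord",
    "SummaryCell",
    "PairedTTestResult",
    "percentage_error",
    "run_experiment",
    "paired_t_test",
    "compare_methods",
    "pairwise_method_comparisons",
    "summarize_errors",
    "records_to_frame",
    "relative_runtimes",
]


@dataclass(frozen=True)
class ErrorRecord:
    """One (series, method, P, repeat) evaluation."""

    record_id: str
    method: str
    P: float
    scheme: str
    I: Optional[int]
    repeat: int
    entropy: Optional[float]
    original: float
    percentage_error: Optional[float]
    mask_hash: str
    seed: int


@dataclass(frozen=True)
class SummaryCell:
    """Per-(method, P) summary of percentage errors.

    ``n`` counts defined records only; ``n_undefined`` retains the exclusions.
    ``sd`` uses the sample convention (n-1 denominator); ``se = sd / sqrt(n)``.
    """

    method: str
    P: float
    n: int
    n_undefined: int
    mean: Optional[float]
    sd: Optional[float]
    se: Optional[float]


@dataclass(frozen=True)
class PairedTTestResult:
    """Two-sided paired t-test outcome; ``degenerate`` flags all-zero differences."""

    t: Optional[float]
    p: Optional[float]
    n: int
    degenerate: bool


def percentage_error(x: float, x0: float) -> float:
    """Absolute deviation of ``x`` from the reference ``x0``, in percent."""
    if x0 == 0:
        raise ValueError("reference entropy x0 must be non-zero")
    return abs(x - x0) / abs(x0) * 100.0


def _mask_hash(mask: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(mask).tobytes()).hexdigest()[:12]


def _cell_seed(master_seed: int, series_idx: int, p_idx: int, repeat: int) -> int:
    """Deterministic per-cell seed so any single cell is re-runnable alone."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(series_idx, p_idx, repeat))
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    series_set: Sequence[TimeSeries],
    methods: Sequence["str | Method"],
    P_grid: Sequence[float],
    scheme: str = "random",
    I: Optional[int] = None,
    repeats: int = 10,
    params: Optional[SampEnParams] = None,
    seed: int = 0,
    n_boot: int = 10,
    series_ids: Optional[Sequence[str]] = None,
) -> list[ErrorRecord]:
    """Sweep methods over a P grid with repeated random maskings.

    For each series the baseline entropy ``x0`` is computed once on the
    complete data.  For each (P, repeat) cell ONE masked series is generated
    from a per-cell derived seed and ALL methods are evaluated on it, so
    method comparisons within a cell are paired.  ``P = 0`` cells skip
    masking and every method scores a zero error.  Fully reproducible from
    ``seed``.  A series whose baseline entropy is undefined is skipped with a
    logged reason.
    """
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    params = params or SampEnParams()
    methods = [Method.parse(m) for m in methods]
    if series_ids is None:
        series_ids = [f"series{i:03d}" for i in range(len(series_set))]
    records: list[ErrorRecord] = []
    logger.info("run_experiment: master seed %d", seed)
    for s_idx, (sid, series) in enumerate(zip(series_ids, series_set)):
        base = sample_entropy(series, params)
        if not base.is_defined:
            logger.warning("series %s skipped: baseline entropy undefined", sid)
            continue
        x0 = base.entropy
        assert x0 is not None
        for p_idx, P in enumerate(P_grid):
            for rep in range(1, repeats + 1):
                cell_seed = _cell_seed(seed, s_idx, p_idx, rep)
                spec = MissingSpec(P=P, scheme=scheme, I=I, seed=cell_seed)
                masked = apply_marking(series, spec)
                mh = _mask_hash(masked.mask)
                for method in methods:
                    res = compute_with_method(
                        method, masked, params, seed=cell_seed, n_boot=n_boot
                    )
                    if res.is_defined:
                        err = percentage_error(res.entropy, x0)  # type: ignore[arg-type]
                    else:
                        err = None
                    records.append(
                        ErrorRecord(
                            record_id=sid,
                            method=method.value,
                            P=float(P),
                            scheme=scheme,
                            I=I,
                            repeat=rep,
                            entropy=res.entropy,
                            original=x0,
                            percentage_error=err,
                            mask_hash=mh,
                            seed=cell_seed,
                        )
                    )
    return records


def paired_t_test(
    errors_a: Sequence[float], errors_b: Sequence[float]
) -> PairedTTestResult:
    """Two-sided paired t-test on index-paired error vectors.

    All-zero differences are reported as degenerate rather than fabricating
    a p-value.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if a.size < 2:
        raise ValueError(f"need at least 2 pairs, got {a.size}")
    diffs = a - b
    if np.all(diffs == 0):
        return PairedTTestResult(t=None, p=None, n=a.size, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTTestResult(t=float(t), p=float(p), n=a.size, degenerate=False)


def compare_methods(
    records: Iterable[ErrorRecord],
    method_a: "str | Method",
    method_b: "str | Method",
    P: float,
    average_repeats: bool = True,
) -> PairedTTestResult:
    """Paired t-test between two methods at one missing fraction.

    With ``average_repeats`` (default) the repeat errors of each series are
    first averaged, and the test pairs series; otherwise every
    (series, repeat) cell is a pair.
    """
    ma, mb = Method.parse(method_a).value, Method.parse(method_b).value
    frame = records_to_frame(records)
    frame = frame[(frame["P"] == P) & frame["percentage_error"].notna()]
    if average_repeats:
        cells = frame.groupby(["record_id", "method"])["percentage_error"].mean()
        wide = cells.unstack("method")
    else:
        wide = frame.pivot_table(
            index=["record_id", "repeat"], columns="method",
            values="percentage_error", aggfunc="first",
        )
    wide = wide.dropna(subset=[ma, mb])
    return paired_t_test(wide[ma].to_numpy(), wide[mb].to_numpy())


def pairwise_method_comparisons(
    records: Iterable[ErrorRecord],
    P: float,
    methods: Optional[Sequence["str | Method"]] = None,
    average_repeats: bool = True,
    holm: bool = False,
) -> dict[tuple[str, str], PairedTTestResult]:
    """All pairwise paired t-tests between methods at one missing fraction.

    Raw (uncorrected) p-values by default; ``holm=True`` applies the Holm
    step-down adjustment across the family of pairs.
    """
    records = list(records)
    if methods is None:
        methods = sorted({r.method for r in records})
    names = [Method.parse(m).value for m in methods]
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    results = {
        (a, b): compare_methods(records, a, b, P=P, average_repeats=average_repeats)
        for a, b in pairs
    }
    if holm:
        testable = [(k, v) for k, v in results.items() if not v.degenerate]
        order = sorted(testable, key=lambda kv: kv[1].p)  # type: ignore[arg-type]
        m_tests = len(order)
        adjusted, running_max = {}, 0.0
        for rank, (key, res) in enumerate(order):
            running_max = max(running_max, min(1.0, (m_tests - rank) * res.p))  # type: ignore[operator]
            adjusted[key] = running_max
        results = {
            k: (
                PairedTTestResult(t=v.t, p=adjusted[k], n=v.n, degenerate=False)
                if k in adjusted
                else v
            )
            for k, v in results.items()
        }
    return results


def summarize_errors(records: Iterable[ErrorRecord]) -> list[SummaryCell]:
    """Mean, sample SD and SE of percentage error per (method, P) cell.

    Undefined entropies are excluded from the statistics; their count is
    carried in ``n_undefined``.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    cells: dict[tuple[str, float], list[Optional[float]]] = {}
    for rec in records:
        cells.setdefault((rec.method, rec.P), []).append(rec.percentage_error)
    out: list[SummaryCell] = []
    for (method, P), errs in sorted(cells.items()):
        defined = np.array([e for e in errs if e is not None], dtype=float)
        n = defined.size
        n_undef = len(errs) - n
        if n_undef:
            logger.warning(
                "summary cell (%s, P=%.2f): %d undefined records excluded",
                method, P, n_undef,
            )
        if n == 0:
            out.append(SummaryCell(method, P, 0, n_undef, None, None, None))
            continue
        mean = float(defined.mean())
        sd = float(defined.std(ddof=1)) if n > 1 else None
        se = sd / np.sqrt(n) if sd is not None else None
        out.append(SummaryCell(method, P, n, n_undef, mean, sd, se))
    return out


def records_to_frame(records: Iterable[ErrorRecord]) -> pd.DataFrame:
    """Long-format table of records, stable-ordered so reruns diff cleanly."""
    frame = pd.DataFrame([vars(r) for r in records])
    if frame.empty:
        return frame
    return frame.sort_values(
        ["record_id", "method", "P", "repeat"], kind="stable"
    ).reset_index(drop=True)


def _best_time(fn, repeats: int = 3) -> float:
    best = np.inf
    for _ in range(repeats):
        t0 = time.perf_counter()
        fn()
        best = min(best, time.perf_counter() - t0)
    return best


def relative_runtimes(
    series: TimeSeries,
    masked: TimeSeries,
    params: Optional[SampEnParams] = None,
    n_boot: int = 10,
    seed: int = 0,
    timing_repeats: int = 3,
) -> dict[str, float]:
    """Runtime of each missing-value method relative to complete-series SampEn.

    Hardware-independent diagnostics: each method's best-of-``timing_repeats``
    wall time on ``masked`` divided by the complete-series baseline on
    ``series``.  Expected shape: skip below 1 (fewer points), keep and linear
    near 1, boot near ``n_boot``.
    """
    params = params or SampEnParams()
    base = _best_time(lambda: sample_entropy(series, params), timing_repeats)
    ratios: dict[str, float] = {}
    for method in Method:
        t = _best_time(
            lambda m=method: compute_with_method(
                m, masked, params, seed=seed, n_boot=n_boot
            ),
            timing_repeats,
        )
        ratios[method.value] = t / base
    return ratios
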