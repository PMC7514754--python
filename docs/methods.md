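# Methods

## The estimator

Sample entropy measures irregularity as the negative log of the conditional
probability that two segments of a series which match for `m` consecutive
points (within a Chebyshev tolerance `r`) still match at the next point.
With `B` the count of matched ordered pairs of length-`m` template windows
and `A` the count for their length-`(m+1)` extensions,
`SampEn = −ln(A/B)`. The probability normalizers in the textbook definition
cancel in the ratio, so the implementation works with raw pair counts.

Conventions adopted here, each covered by a test:

- **Template range.** Start positions run over `1 … N−m` for *both* the
  length-`m` and length-`(m+1)` counts. This guarantees `A ≤ B`, hence a
  defined entropy is never negative.
- **Ties.** Distance exactly equal to `r` counts as a match.
- **Self-pairs excluded** (`j ≠ i`); pairs are ordered, so every unordered
  match contributes 2.
- **Tolerance.** Default `r = 0.15·σ`; `σ` is the *population* standard
  deviation (denominator `n`) of the observed values, the convention of the
  classical C implementations this estimator descends from. An absolute `r`
  in signal units can be given instead. A zero-variance series yields
  `r = 0` with a logged warning.
- **Undefined results.** `A = 0` or `B = 0` produces a typed sentinel
  (`entropy=None`, counts still reported), never a silent `0`, `inf` or NaN.
  Downstream summaries exclude undefined records and log how many.

The match counting is vectorized: a boolean point-closeness matrix
`|x_i − x_j| ≤ r` is built once and template matches are formed by AND-ing
its shifted diagonal blocks. Time and memory are O(N²); series up to ~20,000
points are comfortable on a laptop, and the test-suite and benchmark sizes
(≤ 5,000) take fractions of a second per evaluation. The suite verifies the
optimized counts against an independent brute-force double loop on hundreds
of random series.

## Handling missing values

- **keep** — screening: a template start is *valid* iff its length-`(m+1)`
  window is fully observed; both `A` and `B` run over ordered pairs of valid
  starts only. Screening both counts on the longer window (rather than
  validating `B` on length-`m` windows) excludes the asymmetric case where a
  pair's length-`m` distance exists but its extension does not, so `A/B`
  remains a genuine conditional probability. `σ` uses observed values only.
  Placeholder values stored at masked positions are provably never read
  (tested by poisoning them). An `m`-only-valid variant is deliberately not
  offered.
- **skip** — observed values are concatenated in order; `σ` and the counts
  are computed on the concatenated series, since the method presents a
  complete series to the standard algorithm.
- **linear** — interior gaps are filled by the straight line between their
  flanking observed points. Leading/trailing gaps have only one flank; they
  are filled with the nearest observed value (constant extrapolation), which
  avoids inventing a slope.
- **boot** — each missing position is filled with an independent draw, with
  replacement, from the multiset of observed values (iid resampling, not a
  block bootstrap). Ten reconstructions by default (`n_boot`), sub-seeded as
  `seed + replicate_index`; the entropy is the arithmetic mean over
  reconstructions with a defined estimate. A reconstruction with an
  undefined estimate is excluded from the mean with a logged count — a
  choice this package makes explicitly, since no standard pooling rule
  exists for that case. On a complete series the reconstructions are all
  identical and the method short-circuits to the plain estimator, keeping
  the zero-missing identity bit-exact.

All four methods reduce exactly to the standard estimator when nothing is
missing.

### Cost

Baseline SampEn is O(N²). `skip` is cheaper (fewer points, quadratically),
`linear` adds only an O(N) interpolation, `keep` adds a validity mask over
the same O(N²) pair sweep, and `boot` multiplies the baseline by `n_boot`.
The benchmark asserts these as *ratios* (boot ≈ 10× the baseline, keep
within 25% of it, skip below it), never as wall-clock values.

## Missingness simulation

- **Random sample marking**: exactly `round(P·N)` positions masked,
  uniformly without replacement — isolated dropouts such as excluded
  outlier beats.
- **Group-based marking**: the series is divided into
  `M = round(P·10·I)` contiguous equal segments (remainder points assigned
  to the last segment) and one run of `L = round(N·P/M)` consecutive points
  is masked per segment, with the start uniform over positions that keep the
  run inside its segment — burst dropouts such as transmission gaps. `P`
  enters the segment formula as a fraction (0.1, not 10), so 10% missing at
  scatter factor `I = 1` gives a single group. Runs never cross segment
  boundaries, though runs in adjacent segments may touch.

Non-integer counts use round-half-away-from-zero, keeping totals closest to
`P·N`. Masked totals are exact (`round(P·N)` and `M·L` respectively) and
unmasked values are bit-identical to the input — both property-tested.
Mechanisms where missingness depends on the signal amplitude are out of
scope.

## Multiscale extension

Scale `s` replaces the series by the means of consecutive non-overlapping
blocks of `s` points (trailing partial block dropped) and recomputes SampEn.
By default the tolerance is resolved once from the *original* series and
reused at every scale — the convention of the classical multiscale-entropy
code — because re-deriving `r` per scale would absorb the very variance
reduction the curve is meant to show; `tolerance_per_scale=True` switches
to per-scale derivation. A scale that leaves too few points is reported
undefined while other scales still compute.

## Synthetic signals

The generators emulate broad statistical features of physiological signals,
not their physiology:

- `iid_gaussian` — white noise; its SampEn has the closed-form large-`N`
  limit `−ln P(|X−Y| ≤ r) = −ln erf(r/2)` for standard normal data (with
  `m` irrelevant in the limit because consecutive points are independent),
  ≈ 2.4714 at `r = 0.15`. The suite checks the Monte-Carlo mean over 20
  seeds at `N = 5000` against this constant within ±0.15.
- `ar1` — `x_t = φ·x_{t−1} + ε_t`, drawn from a stationary start
  (`x_0 ~ N(0, 1/(1−φ²))`) to avoid transient bias in the entropy; `φ = 0.9`
  is the benchmark default, giving the strong short-range autocorrelation
  typical of slowly varying signals.
- `periodic_noise` — sinusoid plus Gaussian noise. An exactly periodic
  series has entropy exactly 0 only when `r` is below the smallest
  template distance between distinct phases (then the only matches are
  exact periodic copies, which always extend); at the default `r = 0.15·σ`
  near-phase partial matches make the value small but positive.
- `logistic_map` — `x_{t+1} = a·x_t(1−x_t)`, chaotic for `a ∈ (3.57, 4]`,
  with a fixed burn-in of 1000 iterations discarded.

Benchmarks on these signals show how the estimators respond to
missingness under controlled autocorrelation; they cannot certify error
levels on recorded clinical signals, which have nonstationarity, artifacts
and measurement quantization the generators do not model. The harness reads
real recordings from plain one-column text files for that purpose.

## Benchmark design

For each complete series the baseline entropy `x0` is computed once; for
each (missing fraction `P`, repeat) cell a single mask is generated and
*every* method is evaluated on that same masked series. Each record stores a
hash of the mask, so the pairing that justifies paired t-tests is
checkable after the fact. Per-cell seeds derive deterministically from
(master seed, series index, `P` index, repeat), making any cell re-runnable
in isolation. Performance is `|x − x0|/|x0| × 100`; summaries report mean,
sample SD (`n−1`) and SE per (method, `P`).

Paired comparisons default to averaging the repeats of each series first and
pairing series (the repeat average is what a study would report per record);
per-repeat pairing is available. P-values are raw by default, with an
optional Holm step-down adjustment across the method pairs. All-zero
differences (e.g. at `P = 0`) return a degenerate flag instead of a
fabricated p-value.

Default study conditions: series of `N = 4000` points (entropy estimates
stabilize well below this length; it also keeps 2000 points at 50% missing),
20 series per benchmark, missing grid 0–50% in steps of 10, `m = 2`,
`r = 0.15·σ`, 10 bootstrap reconstructions. The acceptance script uses one
mask repeat per series (seed-to-seed variation across 20 series already
averages the masking noise); the qualitative ordering it reports — the
screening method's error a small fraction of the imputation methods' at
every `P` — is stable across seeds.

## Known limitations

- O(N²) memory in the match matrices makes very long series (≫ 50,000
  points) expensive; chunked counting would remove this but is not needed at
  benchmark sizes.
- KeepSampEn needs at least two fully observed length-`(m+1)` windows; under
  extreme or highly clustered missingness it raises an insufficient-data
  error rather than degrading silently.
- The percentage-error metric requires `x0 ≠ 0`; constant (zero-entropy)
  baselines cannot be scored.
- Binary physiological formats are not read directly; convert records to
  one-value-per-row text first (any WFDB-style toolchain can do this).
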