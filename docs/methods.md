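# Methods

## Model and procedure

FCROS treats differential expression as a question about the stability of
fold-change *ranks* rather than about the fold changes themselves. For an
`n`-gene matrix with `m1` control and `m2` test samples:

1. **Pairwise comparisons.** Up to `k = m1·m2` (control, test) sample
   pairs are enumerated in control-major order `(c0,t0), (c0,t1), …`;
   when a smaller `k` is requested the first `k` pairs of this canonical
   order are used, keeping runs reproducible. For each pair the per-gene
   log2 fold change is the difference of log2 values; since ranking is
   invariant under the monotone `2^x` map, no unlogging is needed.
2. **Ranking.** Within each comparison the `n` fold changes are ranked
   ascending. Ties receive midranks — the unique symmetric scheme that
   preserves the column total `n(n+1)/2`, which the tests assert.
3. **Trimmed rank means.** Each gene's `k` ranks are sorted and
   `g = floor(k·trim)` values dropped from each end before averaging
   (so `trim = 0.1` keeps 80% of ranks when `k` is a multiple of 10);
   this shields the mean from outlier samples. The mean is divided by
   `n`, giving `r̄_i ∈ (0, 1]`. Because `g < k/2` whenever
   `trim ∈ [0, 0.5)`, at least one rank always survives; `trim ≥ 0.5` is
   rejected as invalid.
4. **Normal model.** The ordered `r̄` are modeled as an equally spaced
   grid between extremes `a` and `b` with gap `δ̂`, estimated as the mean
   of consecutive sorted differences — which telescopes to
   `(b − a)/(n − 1)` exactly, an identity the tests check to machine
   precision. The closed-form moments of such a grid are `(a+b)/2` and
   `(n²−1)δ²/12`; these are exposed as diagnostics
   (`theoretical_moments`), but the fit itself uses the *sample* mean
   `R̄` and unbiased sample variance `σ̂²` of the `r̄_i`, which remain
   honest when the grid assumption is only approximate.
5. **f-values and calls.** `f_i = Φ((r̄_i − R̄)/σ̂)`; genes with
   `f ≤ α1` are called down-regulated, `f ≥ α2` up-regulated, the rest
   unchanged, with expected selection error `100(α1 + 1 − α2)` percent.
   A single global fit produces every call, so no per-gene
   multiple-testing correction layer is applied (or needed) on top.

**Assumptions.** The normal approximation needs `k` large enough for the
central-limit behaviour of rank averages — tens of comparisons (e.g.
7×7 = 49) work well; with 2–3 samples per group the approximation is
rougher and f-values are better read as ordering scores than calibrated
probabilities. The method assumes each comparison's ranking is
exchangeable across comparisons; systematic per-sample artifacts violate
this and are exactly what the trimmed mean dampens.

**Diagnostics.** `δ = n·δ̂` (reported in the result sidecar and CLI log)
lives in [0, 1]; values near 1 mean genes kept nearly constant ranks
across comparisons and the grid model fits tightly, while values
drifting toward 0.6–0.7 indicate rank churn (as happens when group
labels are randomized).

## Degenerate inputs and numerical choices

- Constant `r̄` (zero sample variance — e.g. a matrix in which every
  comparison ranks genes identically *and* trimming removes all
  variation) raises an explicit error rather than yielding NaN f-values.
- f-values are strictly inside (0, 1) for finite inputs; no clipping is
  applied.
- Exactly zero log fold changes across many genes (common in the
  noise-free limit) produce large midrank ties; all invariants hold in
  that regime and unchanged genes collapse to `f = 0.5`.
- Top-N selections order by the statistic and break ties by gene index,
  so repeated runs on identical data give identical lists.
- Fold change is reported as the ratio of arithmetic means of unlogged
  values (`mean(2^x_test)/mean(2^x_control)`), validated against the
  bundled MACF1/TREM2 example; a geometric variant
  `2^(mean log2 difference)` is available and is used automatically for
  two-color (log2-ratio) data, where absolute intensities do not exist.

## Two-batch analysis

`fcros2` concatenates the within-batch comparison columns
(`k = k1 + k2`) and then proceeds identically. No cross-batch pairs are
formed and no inter-batch normalization is performed: a global additive
batch bias cancels inside each within-batch comparison, which the tests
verify exactly. Design choice: the reported per-gene fold change is the
geometric mean of the two per-batch fold changes — symmetric in the
batches and consistent with the rank-based pooling; batch-specific fold
changes remain available by running each batch alone. When batch 2
duplicates batch 1, results coincide with the single-batch run whenever
`floor(2k·trim) = 2·floor(k·trim)` (the duplicate ranks trim in matched
pairs); otherwise the trim cut falls between duplicates and only the
ordering is preserved.

## Baseline statistics

For benchmarking, the package provides the three formula-level
comparators: the simple fold change with two-sided magnitude
`max(FC, 1/FC)` (so 5-fold repression outranks 4-fold induction in a
joint list); the pooled-variance Student t-test
(`sp² = ((m1−1)s1² + (m2−1)s2²)/(m1+m2−2)`, two-sided p on `m1+m2−2`
df — pooled rather than Welch, matching the pooled-variance formula the
worked example reproduces); and WAD, the average log2 difference
weighted by the gene's min-max-scaled overall mean expression, which
promotes highly expressed genes. The expected false-selection percentage
of a t-type threshold rule, `100·α·n/n2`, is provided alongside the
FCROS error formula.

## Synthetic data generator

`fcros.synthetic` emulates the standard two-condition microarray
simulation setup: baseline log2 expression uniform on [4, 14] (a typical
array dynamic range), a proportion `p_de` of genes (default 0.02)
receiving a signed log2 shift with magnitude uniform on [0.6, 3] — from
~1.5-fold, near the detection edge, to 8-fold — applied to the test
group (up with probability 0.5), and iid additive Gaussian noise of
s.d. `sigma_n` (default 0.2) on every observation. Defaults are
n = 10,000 genes and 7 + 7 samples, giving an expected 200 DE genes.
Generation is bit-reproducible from the mandatory seed.
`generate_two_batches` shares one planted truth between two batches with
independent noise and an optional constant batch offset.

What it does **not** emulate: intensity-dependent noise variance,
probe-level correlation, non-uniform baseline shape, or array-specific
artifacts of real platforms. Passing tests therefore demonstrate the
statistic's behaviour under clean additive noise — rank stability,
noise-robustness ordering, batch-offset immunity — not end-to-end
performance on raw platform data, which additionally depends on
preprocessing outside this package's scope (no RMA/normalization is
included).

## Evaluation protocols

- **Confusion counts / AUC.** Selected-vs-truth 2×2 counts, and a
  Mann–Whitney AUC: the probability that a random true-DE gene outranks
  a random non-DE gene, ties counted half. f-values are folded two-sidedly
  by `|f − 0.5|` before ranking. The midrank formulation equals
  trapezoidal ROC integration, asserted against an independent
  implementation to 1e−10.
- **Subsampling scores.** Repeatedly (default 100 runs) draw a subset of
  samples, rerun a method, select the top-N genes and add 1 to their
  scores; total score mass is exactly `runs × top_n`. The
  randomized-groups variant draws subsets ignoring the true group labels
  and calibrates a score threshold separating reproducible detection
  from chance, whose expectation per gene is `runs·top_n/n` on null
  data. Score thresholds are dataset-derived and therefore exposed as
  user parameters, not constants.
- **Reproducibility counts.** Number of genes with score ≥ threshold,
  e.g. perfect (= runs) and good (≥ 0.9·runs) detection counts.

## Problem sizes used in the test suite

The simulation-based tests run at 2,000 genes with 7 + 7 samples
(`sigma_n ∈ {0.2, 0.4, 0.6}`, 10 seeds each) — the package's chosen
desk-scale study conditions; at this scale the full suite completes in a
few seconds while the noise-robustness ordering and AUC ≥ 0.95 at
`sigma_n = 0.2` are stable across seeds. Determinism contracts
(bit-identical regeneration, seed-fixed resampling) are asserted
directly.

## Known limitations

- f-values from very few comparisons (k < ~10) are coarsely granular;
  thresholds `α1/α2` then act as rank cutoffs rather than error rates.
- The expected-error formula `100(α1 + 1 − α2)` describes the model's
  nominal tail mass, not an empirical FDR; on data violating the normal
  approximation the realized error can differ.
- The simple-FC baseline reports no error statement (`na` by
  construction), matching its usual benchmark role.
- No preprocessing (background correction, normalization, CEL parsing)
  is provided; inputs must already be log2 expression values.
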