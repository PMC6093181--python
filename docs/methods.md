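# Methods

## Model and procedure

`refchip` addresses differential binding between two conditions when the
target factor's genome-wide occupancy may shift globally, so that total read
depth is not a valid normalizer. The working assumption is the existence of
a set of **reference peaks** — binding sites of a parallel-factor control
antibody (e.g. CTCF) or of a species-specific spike-in antibody (e.g.
Drosophila H2Av) — whose biological occupancy is identical in both
conditions. Any systematic difference in their counts between samples is
then attributable to technical efficiency (chromatin recovery, IP
efficiency, library depth) and can be estimated and removed.

Three normalization routes are implemented, in increasing order of
specificity:

1. **RPM baselines** (`normalize_rpm`): columns scaled to reads-per-million
   by reads-in-peaks or library totals. Provided for comparison; these are
   exactly the methods that fail under a global shift.
2. **Reference-peak size factors** (`control_size_factors`): per-sample
   factors computed on the control-peak submatrix only, either proportional
   to control-peak column sums (`sum`) or as the median ratio to the
   per-peak geometric mean (`median_ratio`, the DESeq2 estimator restricted
   to control peaks). Factors are rescaled to geometric mean 1 and applied
   to all peaks.
3. **Normalization coefficient** (`normalization_coefficient`): with
   per-peak replicate means `x` (control condition) and `y` (treated) over
   reference peaks, fit `y = m·x` through the origin by least squares
   (`m = Σxy / Σx²`) and return `c = 1/m`. A single multiplicative
   efficiency bias cannot produce an intercept, hence the through-origin
   form; the fit is in linear count space on replicate means so that every
   read contributes with its weight in the count model (a log-space mean-
   ratio variant, which downweights high-count peaks, is available via
   `fit_space="log"`). Multiplying the treated columns by `c` restores
   gradient 1 identically — `Σx(cy)/Σx² = c·m = 1` — which the test suite
   asserts at 1e-9.

Downstream testing (`nb_wald_test`) models counts as negative binomial,
`K_ij ~ NB(mean s_j μ_g(j), var = mean + α_i mean²)`, log link, with the
log size factors as offsets. For a two-level condition factor the GLM
decomposes into two one-group fits; each group's log-mean is fitted by
vectorised Newton iteration on the score `Σ_j (k_j − s_j μ)/(1 + α s_j μ)`
(tolerance 1e-8, ≤100 iterations), and the Wald statistic uses the Fisher
information `I_g = Σ_j m_j/(1 + α m_j)`:
`z = log2FC / SE`, `SE² = (1/I_ctrl + 1/I_trt)/ln²2`, two-sided normal
p-values, Benjamini–Hochberg FDR. Control peaks are excluded from the
tested set (they are the normalizer, not the hypothesis).

Dispersions are method-of-moments per peak on normalized counts,
`α̂ = max((v − μ)/μ², α_min)` with `v` the within-condition variance pooled
across conditions, stabilised by a least-squares mean-dispersion trend
`α_tr(μ) = a0/μ + a1`; the final value is `max(α̂, α_tr(μ))`. Taking the
maximum is deliberately conservative; empirically it balances the
anti-conservatism of the normal Wald reference at three replicates, and the
pooled null type-I error sits near 0.04 at nominal 0.05 (asserted within
[0.03, 0.07] in the suite).

This test is intentionally simpler than DESeq2: no empirical-Bayes
shrinkage of dispersions or fold-changes, no outlier replacement, no
independent filtering. The package's contribution is the normalization;
the test's contract is calibration and power monotonicity, both of which
are tested directly.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `min_distance` (peak filter) | 500 bp | control peaks within this distance of a target site are dropped; distance is the edge-to-edge gap between half-open intervals (adjacent intervals have gap 0), the conservative reading; a `midpoint` anchor is available |
| `min_mapq` (read counting) | 15 | conventional ChIP-seq mapping-quality floor |
| read→peak rule | strand-aware 5′ end in `[start, end)` | each read lands in at most one position; deterministic and order-independent, unlike any-overlap counting |
| `pseudocount` (MA table) | 0.5 | keeps M and A finite at zero counts; display only, never inside the NB test |
| `rounding` (coefficient application) | `none`; `nearest_int` rounds half away from zero | integer output for count-model compatibility |
| `alpha_min` (dispersion floor) | 1e-8 | lets Poisson-like data be treated as (nearly) Poisson |
| size-factor convention | geometric mean 1 | makes factors comparable across estimation methods |
| LFC correction fit | intercept + slope of M on A over control rows | a constant-only fit is available (`fit="constant"`) |

In `differential_pipeline(mode="coefficient")` the treated columns are
multiplied by `c` (nearest-int) and size factors are then identity: the
coefficient is a single between-condition constant and deliberately does
not re-correct depth differences among replicates of the same condition.

## The synthetic generator

`generate_experiment` draws per-peak expected counts from a lognormal
(default median 100, log-sd 0.5 — a moderate, quarter-to-four-fold spread
typical of a filtered consensus peak set), applies a global treated-library
efficiency `s*` (default 0.8) to every channel, gives a fraction of target
peaks (default 0.5) true effects drawn as `−|Normal(2, 0.5)|` log2 units
(unidirectional loss, the degrader regime), and adds NB noise with
dispersion α (default 0.05, variance = μ + αμ²). Control and spike-in
channels never carry condition effects. `competition_mode` multiplies the
spike-in treated means by `1 + κ(1 − R)`, `R` being the treated/control
ratio of total expected target signal — the antibody-competition artefact
in which spike-in recovery rises as the target is lost. Everything is a
pure function of the config, seed included.

What the generator does **not** emulate: correlated noise between nearby
peaks, GC/mappability biases, fragment-length effects, partial occupancy
changes at control sites, or background reads outside peaks (except in the
BAM fixture writer). Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to every
artefact of real libraries.

`generate_alignment_fixture` writes a sorted, indexed BAM realising exact
per-peak 5′-end counts (plus optional background reads outside peaks) to
exercise the counting path end to end.

## Numerical choices and degenerate inputs

- Through-origin slope requires `Σx² > 0`; all-zero treated means are an
  error rather than a zero coefficient.
- The Newton fit clamps steps to ±10 on the log scale; groups whose counts
  are all zero, and peaks where the iteration does not converge, fall back
  to a moment estimate of the fold-change with a 0.5 pseudocount on group
  means. All-zero peaks report `log2FC = 0, p = 1`.
- Consensus peaks apply per-set interval merging before the occurrence
  sweep (a replicate's internally overlapping peaks count once), and events
  at equal positions are processed together so abutting runs merge, matching
  the per-base coverage definition exactly.
- BH adjustment delegates to `statsmodels`; an exhaustive step-up oracle
  validates it in the tests.
- Subsampling streams are seeded per (fraction value, repetition) from the
  master seed, so reports are independent of the order in which fractions
  are evaluated.
- Median (not mean) summarises the per-peak discrepancy in
  cross-normalization: matched consensus peaks may include residual true
  changes, and the median is equivariant under the applied shift, making
  the post-correction median discrepancy exactly zero.

## Benchmark problem sizes and known limitations

The stability benchmark (`scripts/acceptance.py`) uses 50,000 reference
peaks, 3v3 replicates, treated efficiency 0.8, dispersion 0.05, and 100
draws of 1% subsets; the gradient-restoration benchmark uses 5,000
reference peaks with a 0.7 efficiency bias. Both run in seconds.

A structural point worth knowing when interpreting the stability numbers:
with `n` subsampled reference peaks, `r` replicates and dispersion `α`, the
subsampled coefficient's relative standard error has a floor of
`sqrt(2α/(r·n))` that no depth of coverage removes — at α = 0.05, 3v3 and
500 peaks that is ≈0.8%, so the median |relative error| of a 1% subsample
sits near 1% and the maximum over 100 draws near 3–4% under these
simulation conditions. Tighter figures require lower replicate-level
dispersion or more replicates, not more reads. Relatedly, the linear-space
through-origin estimator carries a small errors-in-variables attenuation
(≈ α/r plus a `1/(rμ)` Poisson term, i.e. ≈1.7% here), which is why the
parameter-recovery tests use deep-coverage reference peaks (median mean
1000) where the Poisson term vanishes; on real data this bias is shared by
any regression of one noisy condition on another and is small relative to
between-sample efficiency differences.

Scope limits: two-condition contrasts only; no IDR, blacklists are
user-supplied; no quantile normalization; no re-implementation of
DESeq2/edgeR-specific behaviours (shrinkage, Cook's filtering).
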