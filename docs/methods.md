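# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind lightchrom, in the spirit of a model-description
document. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Replicate-free differential expression (`lightchrom.de`)

### Model

Read counts for gene *i* in sample *j* are modeled as negative binomial,
`k_ij ~ NB(mu_ij, sigma_ij^2)`. The design has exactly one library per
condition (no replicates), so the per-gene variance cannot be estimated
within condition; it is borrowed from the genome-wide mean–variance
relationship.

### Normalization and filtering

Size factors are median-of-ratios: `s_j = median_i k_ij / g_i` over genes
positive in every sample, with `g_i` the per-gene geometric mean. If no
gene is positive in all samples the function errors and suggests a
pseudo-reference; it does not silently fall back. Genes whose mean
normalized count falls below the 20th percentile of all genes are removed
before testing (`low_expr_quantile = 0.20`).

A note on an algebraic subtlety: rescaling one sample's counts by *c*
changes every per-gene geometric mean by `c^(1/n)`, so the *absolute* size
factor of the scaled sample gains `c^((n-1)/n)` while every other factor
gains `c^(-1/n)`. Only the *relative* factors shift by exactly *c*. Tests
assert the relative form.

### Mean–variance trend

Per-gene means and variances of size-factor-normalized counts are computed
across **all** samples, treated as blind pseudo-replicates (the design
offers nothing better; genuine signal inflates the trend and makes the
test conservative, which we accept). The trend is fit by locally weighted
linear regression (statsmodels `lowess`) of `log s_i^2` on `log m_i` with a
nearest-neighbour span of 0.3 and one robustifying iteration.

The smoother estimates `E[log s^2]`, not `log sigma^2`. Under a chi-square
approximation, `E[log s^2] = log sigma^2 + psi(nu/2) - log(nu/2)` with
`nu = n_samples - 1` degrees of freedom — at four samples the raw smooth
underestimates the variance by a factor of about `e^-0.37 ≈ 0.69` and the
exact test becomes anti-conservative. We therefore subtract the bias term
`psi(nu/2) - log(nu/2)` from the fitted log-variance before exponentiating.
With the correction, a test-suite measurement on 10,000 null NB genes gives
`P(p <= 0.05) ≈ 0.04` (conservative, as intended), and on Poisson-generated
counts the fitted `sigma^2(mu)` lands within 15% of `mu`.

The returned mapping is floored at the Poisson variance
(`sigma^2(mu) >= mu`), made nondecreasing by a running maximum, evaluated
by interpolation on the log-mean axis, and extrapolated flat outside the
fitted range.

### The exact test

For one treatment count `k_t` (size factor `s_t`) and one control count
`k_c` (size factor `s_c`), condition on the total `S = k_t + k_c`:

- common normalized mean `mu0 = (k_t/s_t + k_c/s_c) / 2`;
- dispersion read off the trend at the normalized scale,
  `phi = (sigma^2(mu0) - mu0) / mu0^2`, treated as scale invariant;
- condition means `mu_t = mu0 s_t`, `mu_c = mu0 s_c` with variances
  `mu + phi mu^2` at each condition's scale;
- `f(a, b) = pmf_t(a) · pmf_c(b)` for every split `a + b = S`, with the NB
  pmf parameterized by `r = mu^2/(sigma^2 - mu)` and a Poisson fallback
  when `sigma^2 <= mu (1 + 1e-8)`;
- two-sided p: `p = Σ_{f(a,b) <= f(k_t,k_c)(1+1e-12)} f(a,b) / Σ f(a,b)`,
  the `1e-12` slack making tie inclusion robust under floating point;
  `p = 1` when `S = 0`.

Counts stay raw integers throughout; size factors enter only through the
means, so the pmf is always well defined. Fold changes are ratios of
normalized means with a pseudo-count of 0.5 on both sides.

The implementation is checked against a fully independent enumeration
oracle written on log-gamma arithmetic (criterion-scale: 200 random cases,
sums to 500, agreement to 1e-12 relative) and against the conditional
binomial closed form in the Poisson limit.

### Calling and classification

A gene is light-inducible when any light timepoint (30, 60, 120 min) shows
`p < 0.05` **and** a >= 2-fold increase over dark. Called genes are
classified by their fold profile: *immediate-early* when induction reaches
2-fold within 30 min; otherwise *early* when the profile is maximal at
30 min and non-increasing afterwards; otherwise *late*. The verbal
early/late boundary in the source analysis is operationalized exactly this
way; the three classes partition the called set by construction.

Genotype comparisons rerun the same exact test between genotypes at each
matched light timepoint (size factors and trend refit on the pooled
tables) and flag a gene when any timepoint differs at `p < 0.05` in the
stated direction (lower in a knock-out, higher in an over-expressor).

No multiple-testing correction is applied anywhere in this module — the
method being reimplemented uses raw `p < 0.05` plus the fold gate.

## 2. ChIP-seq peak calling (`lightchrom.peaks`)

Windows of 150 bp advance by 50 bp; a fragment is counted in a window when
its 5′ position lies inside it. Each treatment window is tested against
`lambda = max(k_control, 0.5) · (N_treat/N_control)` under a Poisson upper
tail, `p = P(X >= k_treat)`. The 0.5 floor prevents `lambda = 0`
pathologies in empty control windows. A peak is a maximal run of >= 4
consecutive significant windows (`p < 1e-5`), spanning from the first
window's start to the last window's end; the summit is the position of
maximal per-base treatment coverage inside the peak (first position on
ties). "4 consecutive windows" means 4 overlapping step-50 windows.

The enrichment filter keeps a peak only if its mean per-base coverage is
>= 1.5× the genome-wide mean window coverage **and** >= the 90th
percentile of window coverage. Peak coverage is the mean (not the max)
over the peak; both reference statistics are computed from the same
sliding windows as the scan.

Annotation anchors on the summit. Rule 1: every gene whose strand-aware
promoter window `[TSS-1000, TSS+500]` (inclusive boundaries, mirrored for
minus-strand genes) contains the summit. Rule 2: otherwise the nearest
gene with the summit on its upstream side, unbounded distance, ties broken
by gene id. Rule 3: otherwise unannotated. An independent brute-force
implementation of the three rules agrees on 1,000 random configurations,
including summits exactly at the -1000/+500 boundaries.

Differential binding between dark and light uses OLS of `log2(light+1)` on
`log2(dark+1)` over all sites (log scale keeps count residuals roughly
homoscedastic) and classifies each site against its 80% prediction
interval (residual variance with the leverage term, t quantile at n-2 df;
statsmodels `get_prediction`). Above the band: light-induced; below:
light-reduced; on a collapsed band (zero residual variance) every point is
inside, i.e. unchanged. By construction ~20% of null sites fall outside an
80% band; the test suite measures 0.207 at n = 1000.

## 3. MNase-seq nucleosome mapping (`lightchrom.nucmap`)

Fragments of 100–1000 bp are nucleosomal (the 100 bp boundary is assigned
to the nucleosomal class; the bound is a config knob), fragments under
100 bp are footprint candidates, longer fragments are discarded. Each
nucleosomal fragment contributes +1 over the 50 bp centered on its
midpoint `floor((start+end)/2)`.

Normalization divides by the 90th percentile of mean coverage over
non-overlapping 150 bp tiles with nonzero coverage — window-level rather
than base-level (the source description does not say which; window-level
matches the ChIP window size and makes the operation idempotent and scale
invariant). Smoothing is Gaussian kernel regression with a 30 bp bandwidth
truncated at 4 sd — below half the nucleosome half-width, so dyad positions
are not displaced; constants are preserved and interior mass is conserved
to 0.1%.

The +1 nucleosome is the coverage maximum within ±100 bp of the TSS, ties
broken toward the TSS and then downstream of the gene (a flat window
returns the TSS itself). Metagene profiles average normalized coverage
over ±1500 bp around anchors, strand-aware, with edge-truncated anchors
contributing only their defined offsets. Per-nucleosome occupancy is the
area under the curve over `[dyad-88, dyad+88)` (176 bp).

Repeat length: from ordered dyad calls, the median successive-dyad
distance with a bootstrap percentile CI (200 resamples); from a phased
profile, the lag of the fundamental autocorrelation maximum over lags
50–400 bp, declared undefined when the peak autocorrelation is below 0.1
(white-noise guard). The profile route reports a point estimate without a
CI — the averaged profile no longer carries the anchor-level resampling
units a bootstrap would need; callers who want a CI should use the dyad
route.

Binding-site occupancy is reported as observed/background, where the
observed value is the mean normalized coverage at site summits and the
background redraws site positions at NB-distributed distances from random
TSSs: distances |summit - nearest TSS| are fitted by the method of moments
(`r = m^2/(v-m)`), drawn afresh, and placed strand-aware on the same side
of the TSS as the observed sites. When the moment fit is infeasible
(variance <= mean) the background resamples the observed distances
empirically and logs the fallback. This ratio removes promoter-proximity
bias from the comparison.

Footprint profiles use the **full extent** of sub-nucleosomal fragments
(not a fixed 50 bp midpoint window): footprints are shorter than 100 bp,
so the fragment itself is the natural protection estimate. The profile
around summits is normalized by genome-wide mean sub-nucleosomal coverage,
so 1.0 is background level.

## 4. Motif analytics (`lightchrom.motifs`)

IUPAC patterns are compiled to regular expressions inside a lookahead so
overlapping matches are all reported. With both-strand scanning, a pattern
that equals its own reverse complement (e.g. GATC) is scanned once so each
site appears exactly once. The bipartite GATA-family motif is expressed as
`MGATS NNNNNN MTGY` (14 bp, 6-bp spacer measured edge to edge).

Tandem spacing tallies **all** within-region hit pairs (not only adjacent
ones) by center-to-center distance inside 300 bp summit-centered regions,
up to a configurable maximum. The background applies the same tally to
uniformly random regions (contigs chosen length-weighted) and also reports
the mean hit count per region; on an i.i.d. equal-frequency genome this
converges to `297/256 ≈ 1.16` GATC sites per 300 bp region, which the test
suite verifies to 3 standard errors. Positional density is the histogram
of signed hit-center-to-summit offsets, optionally smoothed with the same
Gaussian kernel as the coverage tracks.

## 5. Synthetic data (`lightchrom.synth`)

Every generator is a pure function of (parameters, seed); identical seeds
give byte-identical outputs through the CLI. Planted features are recorded
in a `TruthRecord` serialized as TSVs plus a flat metadata file, and
pipelines are scored only against it.

**Genomes** are i.i.d. bases at a stated GC fraction — no repeats, no
mappability structure, no sequencing error (the reimplemented pipeline
models none of these).

**Count tables**: per-gene baseline means are log-normal
(`log-mean log(50)`, `log-sd 1`), giving a realistic depth distribution
with a median around 50 reads per gene. The variance function is
`v(m) = m + phi(m) m^2` with `phi(m) = phi0 + phi1/m`, decreasing in the
mean as empirical trends are. Defaults `phi0 = 0.01`, `phi1 = 0.5`
represent single-library (technical, near-Poisson) overdispersion — the
appropriate regime for a design in which every condition is one library;
`phi0 = phi1 = 0` recovers the exact Poisson limit. Planted induced genes
follow one of two profiles over DD/30/60/120 min: *early* genes peak at
8-fold at 30 min and decay (8, 4, 2), *late* genes rise monotonically
(1.5, 3, 6). A configurable fraction of induced genes is
genotype-dependent: their light folds are multiplied by the genotype's
factor (default 0.5 in the knock-out, 2.0 in the over-expressor, floored
at 1).

**ChIP fragments**: control midpoints are uniform; treatment midpoints are
drawn with relative rate `fold` within ±fragment_mean/2 of each planted
summit and 1 elsewhere; lengths are normal(200, 40) truncated at 50 bp.
The enrichment multiplier acts on fragment **midpoints** so that per-base
coverage peaks at the planted summit — a start-position multiplier would
displace the coverage maximum by about half a fragment length and make
summit positions unrecoverable to ±50 bp by any caller.

**MNase fragments**: nucleosomal fragments are centered on planted dyads
with normal(0, 10) jitter and lengths normal(150, 10) truncated to
[100, 1000]; each dyad emits Poisson(depth · occupancy) fragments.
The jitter and length spread are package choices (the emulated experiment
reports observed lengths of ~140–150 bp but no noise model); 10 bp was
chosen so planted dyads are recoverable but not trivially exact. Footprint
fragments are normal(60, 10) in length (truncated to [20, 99]) centered on
the planted footprint with normal(0, 5) jitter. A uniform background adds
both fragment classes at a low per-kb rate so null profiles are defined.

What the generators deliberately do **not** emulate: GC bias, mappability,
duplicated reads, MNase sequence preference, digestion-degree variation,
and biological replicate structure. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under their own model
assumptions — not robustness to these real-data artifacts.

## 6. Problem sizes and determinism

The validation suite runs at the sizes the analyses are specified at:
10,000 genes for calibration and recovery, a 1 Mb genome with 20 planted
sites at 30× depth (and 20 null re-simulations at 20×) for the peak
caller, 80 arrays × 10 nucleosomes for spacing recovery, 1,000 sites for
prediction-interval coverage, and 2,000 random 300 bp regions for motif
background statistics. `scripts/acceptance.py` recomputes all of it from
one seed in well under a minute on a single CPU.

All file writers are deterministic; every randomized operation takes an
explicit seed, and the CLI logs the seed and effective parameters of each
stage to stderr so runs can be reproduced exactly.

## 7. Known limitations

- The exact test's conservativeness depends on the blind trend fit; with
  many strongly induced genes the trend inflates and power drops. This
  mirrors the no-replicate design it reimplements and is not corrected.
- The dispersion floor (`sigma^2 >= mu`) means genuinely under-dispersed
  data are tested as Poisson.
- The peak caller has no duplicate collapsing, mappability correction, or
  control-free mode; peaks on opposite strands are not distinguished
  (ChIP fragments are unstranded).
- `estimate_spacing` assumes a single dominant periodicity; mixtures of
  repeat lengths return the dominant one without a mixture decomposition.
- The NB background for site occupancy conditions only on distance to the
  nearest TSS; other covariates (gene length, expression) are not matched.
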