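# Methods

## Statistical model

Each phenotype (metabolite, transcript or clinical trait, z-scored at the
strain level) is scanned one marker at a time under

    y = mu + x beta + u + e,   Var(u) = sigma_g^2 K,   Var(e) = sigma_e^2 I.

`K` is the identity-by-state kinship: the mean over SNPs, nonmissing in
both strains, of `1 - |g_i - g_j|/2` with dosages in {0, 1, 2}; the
diagonal is exactly 1 and a heterozygous (interpolated recombinant-inbred)
call counts as half-matching. If the smallest eigenvalue of `K` falls
below 1e-8, 1e-6 is added to the diagonal before factorization.

REML is profiled to the ratio `delta = sigma_e^2 / sigma_g^2`. With
`S` the residual-maker of the fixed design `X`, the spectrum `(xi_i,
eta_i)` of `S K S` reduces the restricted log-likelihood to a smooth
scalar function of `delta`, evaluated on a 100-point log-spaced grid over
[1e-5, 1e5]; every local maximum bracket (including the grid ends) is
refined by bounded scalar optimization to |d log10 delta| < 1e-6. The
variance components follow in closed form; a grid-end optimum is flagged
`at_boundary` but still reported as converged (for a null phenotype the
genetic variance legitimately sits at the boundary). Given `delta`, each
marker is tested by generalized least squares under `Sigma ~ K + delta I`
(whitening through the eigendecomposition of the full `K`) with an F-test
of the SNP coefficient on (1, n-2) degrees of freedom: one tested
coefficient, intercept absorbed. P-values are floored at 1e-300 so logs
stay finite.

Two scan modes:

* `exact` (default) — `delta` re-estimated per SNP with `X = [1, g]`, the
  exact per-marker REML.
* `null_approx` — `delta` estimated once under `X = [1]` and reused. This
  is much faster and agrees with `exact` within 15% on the −log10 p scale
  for significant SNPs **when no single marker carries a large effect**;
  for markers explaining ≥ about half the phenotype variance the
  null-model `delta` absorbs part of the signal and the approximation
  loses significance relative to the exact refit (it is conservative,
  never anti-conservative, in our checks). The calibration and
  replicate-heavy diagnostics therefore use `null_approx`; anything
  effect-size-sensitive uses `exact`.

Missing phenotypes are dropped once per phenotype; missing genotypes are
dropped per SNP (casewise deletion, kinship subset from the full-panel
matrix rather than recomputed). SNPs monomorphic after deletion are
skipped with a log entry. The MAF filter (> 5%) is applied to the
genotype matrix before scanning.

Percent variance explained of a fitted marker is
`1 - var(y - X beta_hat) / var(y)` with residuals from the **fixed
effects only** (intercept + SNP, GLS coefficients). Including the random-
effect BLUP in the residuals would conflate kinship signal with the SNP
effect; the fixed-only choice makes PVE the marker's own share. Values
may be negative for null markers and are returned unclamped.

## Preprocessing

Fixed stage order, recorded in a provenance sidecar:

1. **Missingness filter** — drop variables with strictly more than 20% of
   sample cells missing (computed over samples, before any averaging).
2. **Run-day registration** — divide every cell of a run-day by that
   run-day's pooled median (all nonmissing cells of all variables), making
   each run-day's median exactly 1. This exactly inverts a multiplicative
   batch effect. The pooled (not per-variable) median is used because the
   batch factor is an instrument-scale property shared by the whole run.
3. **Replicate averaging** — one row per strain, mean over nonmissing
   replicate samples; a cell is missing only if all replicates are.
4. **Standardization** — per-variable z-score with the sample standard
   deviation (n−1). Standardizing after averaging makes the strain, not
   the mouse, the unit of analysis; z-scoring before averaging would
   differ only by the (small) replicate-noise share of the variance.

Stages 2–4 are idempotent on their own output. No imputation anywhere;
downstream analyses use casewise deletion.

## Multiple testing

Storey q-values over the pooled set of all phenotype × SNP p-values of a
scan (one genome-wide p-value cutoff for all metabolites; a per-phenotype
option exists). pi0 is estimated on the lambda-grid 0.05 … 0.95 (step
0.05) with a cubic smoothing spline read off at lambda = 0.95 and clamped
to (0, 1]; inputs under 100 tests, or a failed spline fit, fall back to
the conservative pi0 = 1, where the q-values coincide exactly with
Benjamini–Hochberg adjusted p-values. The FDR-equivalent p-value
threshold is the largest p whose q is at or below the level. Bonferroni
helpers cover the fixed-family cases (loci examined, metabolite pairs).

## Loci and co-localization

Significant SNPs of one phenotype are ranked by ascending p (ties by
chromosome, position, then SNP id — a convention; ties are measure-zero
with continuous statistics). The best unabsorbed SNP becomes a peak and
absorbs every remaining **same-chromosome** SNP with R² > 0.5 against it;
the rule repeats until all SNPs are assigned, so the member sets partition
the input. Cross-chromosome correlation in an inbred panel reflects strain
structure, which the mixed model already handles, hence the restriction.
Greedy collapsing can split a chained LD group that single-linkage
components would merge; the tests enumerate 5-SNP fixtures and check
agreement wherever the two definitions coincide.

A locus is the peak ± 1 Mb (inclusive; 1-based coordinates throughout). A
transcript's eQTL is *local* when its peak SNP lies within 2 Mb of the
gene span on the gene's chromosome; candidates for a metabolite locus are
genes whose local-eQTL peak lies within 1 Mb of the metabolite peak, and
pathway co-annotation (a user-supplied metabolite–gene pair table) flags
mechanistically supported candidates. Distinct loci are deduplicated by
exact peak-SNP identity; window-overlap deduplication is available behind
a flag.

## Correlation

Biweight midcorrelation: `u = (x - med) / (9 mad)` with the **unscaled**
MAD (no 1.4826 consistency factor — variants exist; this follows the
biweight construction), weights `(1 - u^2)^2` inside |u| < 1, correlation
of the weighted median-centred vectors. A zero-MAD variable falls back to
mean/sd standardization with a warning. No outlier-fraction cap is
applied. P-values use the t approximation `t = r sqrt((n-2)/(1-r^2))` on
n−2 df (the permutation alternative was not adopted; the t approximation
is standard for these sample sizes). Pair screens use per-pair casewise
deletion; within/between-class accounting assigns each variable its single
class, and the between percentage is 100 minus the rounded within
percentage so the split always sums to 100.

## Synteny replication

Synteny is consumed, never computed: a 6-column blockwise map is an input.
A mouse locus (peak ± 1 Mb) maps to the whole human interval of every
overlapping block (whole-block mapping is a convention; the map's
granularity sets the resolution). The human summary, filtered to the same
metabolite through an explicit id map, replicates the locus when its
minimum p inside any mapped interval is at or below `alpha / n_loci` in at
least one population. Metabolite-ratio phenotypes (log-ratio of two
z-scored metabolites, i.e. their difference, re-standardized) can be
appended for ratio mapping; symmetry motivated the log form.

## Synthetic panel generator

The generator emulates the study design at desk scale and is the ground
truth for every recovery test. Defaults: 100 strains in 8 discrete
families, 2,000 SNPs in 10-SNP LD blocks across 19 autosomes (100 kb
spacing; scaled down from ~1e5 SNPs), 60 metabolites in the eight standard
classes over 6 run-days, one strain with five replicates where
configured, 2% missing cells.

* **Genotypes** — per block, each strain copies its family's founder
  allele with probability `family_mixing` (default 0.4) or draws
  independently; SNPs inside a block copy the strain's founder with flip
  probability `(1 - ld_block_r)/2` (default r = 0.9). SNPs failing MAF
  > 5% are removed. This discrete-family-plus-block model is the simplest
  mechanism that makes the naive no-kinship scan measurably
  anti-conservative (lambda_GC ≈ 1.6 at the defaults) while the mixed
  model stays calibrated — exactly the property the calibration tests
  demonstrate.
* **Phenotypes** — strain core = planted SNP effect + family random
  effect (sd 0.7) + residual noise (sd 0.7); samples add intra-strain
  measurement noise (sd 0.35), a positive baseline (10), and a
  multiplicative run-day factor `exp(0.3 N(0,1))`. The planted effect
  size is chosen so the causal SNP explains the target PVE of the
  **measured-sample** variance budget (family + residual + intra-strain
  noise) in expectation; the realized (finite-draw) PVE is recorded in
  the ground truth. Because the run-day effect is multiplicative, median
  registration is the exactly correct correction, and the batch/no-batch
  twins of a seed normalize to identical tables.
* **Traits** — built as `rho * z(metabolite) + sqrt(1-rho^2) * noise` at
  the strain level from the run-day-registered metabolite (traits track
  the biological level, not the batch artifact).
* **Human summary** — a configured fraction of mouse loci receive a
  sub-threshold p inside their syntenically mapped human interval; the
  rest and the background records draw uniform p.

All generators are pure functions of (config, seed); each draws from its
own purpose-labelled stream spawned from the master seed, so adding a
generator never shifts another's draws.

What the generator does **not** emulate: realistic recombination maps or
coalescent LD decay, sex or diet effects, assay detection limits and
missing-not-at-random patterns, heavy-tailed metabolite distributions, or
trans-eQTL networks. Passing tests therefore certify the statistical
machinery under a faithful but idealized structure model, not performance
on any particular real panel.

## Problem sizes used by the diagnostics

Calibration: 100 strains × 2,000 SNPs × 50 null metabolites (one seed).
Empirical FDR: 20 replicate panels of 100 strains × 500 SNPs with 10
planted (PVE 0.5) and 10 null metabolites each. PVE recovery: 5 replicate
panels of 100 strains × 600 SNPs with QTLs planted at PVE 0.3/0.5/0.7;
estimates are compared as means over replicates against a ±0.15 envelope
(the single-draw spread at n = 100 is itself of that order). Oracle
checks run on 5–40-variable fixtures. These sizes keep the whole
diagnostic set in the minutes range on one CPU while leaving each check
statistically meaningful.

## Known limitations

* The null-delta approximation's conservativeness for very large effects
  (above) is inherent to reusing one variance ratio; the exact mode is
  the remedy and the default.
* PVE estimates at n ≈ 100 carry sampling spread of roughly ±0.1 and a
  mild upward pull when the causal SNP is itself correlated with family
  structure (the fixed effect absorbs aligned family variance); the
  recovery tests average over replicate panels for this reason.
* Greedy peak collapsing is order-dependent by design (strongest first);
  it matches best-per-component deduplication except under LD chaining.
* Storey's pi0 smoother is unstable below ~100 tests; the conservative
  pi0 = 1 fallback applies there.
* The t approximation for bicor p-values is asymptotic; at very small n
  with heavy weighting it is approximate (the screens here use n ≥ ~30).
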