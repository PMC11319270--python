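# Methods

This note records the models the package implements, the parameter choices
that matter, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer would want to know about.

## The scientific setting

Autotetraploid crops such as potato are genotyped from reduced-
representation sequencing (GBS) read counts. Dosage callers conventionally
assume every locus carries four copies, but phase deletions make gene copy
number vary along the genome (1–4 copies, averaging ~3.2 in elite
material, with roughly half of loci truly tetraploid). The package
quantifies the consequences of that misspecification for genomic
prediction (GBLUP) and single-marker mixed-model GWAS by running two
encodings of the same read counts — the raw alternative-allele read
fraction, and forced tetraploid dosage calls — through one shared
pipeline.

## Synthetic panel

`simulate_population` draws a diallel-cross breeding panel: default 18
parents and 762 offspring assigned round-robin over the 153 unordered
parent pairs, at 31,000 biallelic loci on 12 chromosomes plus an
unanchored bin ("chromosome 0", 3% of loci by default).

**Copy-number model.** Each parent × locus receives an independent copy
number from a mixture over {1, 2, 3, 4}. The default mixture
{1: 0.08, 2: 0.18, 3: 0.20, 4: 0.54} has mean 3.20 and 54% tetraploid
loci, matching the published genome-assembly summary for elite material
while keeping most mass on 3 and 4 copies. Alternative-allele copies are
binomial in the copy number at a per-locus ancestral allele frequency,
uniform on (0.05, 0.95) by default.

**Gamete model.** A parent's copies are imagined to sit on `copy_number`
of its four homologous phases (the remaining phases carry deletions); a
gamete samples two phases without replacement and transmits the copies and
alleles found there. A gamete therefore carries `copy_number / 2` copies
*in expectation*, so the copy-number distribution is stable across
generations — the panel mean stays at the parental 3.2. The obvious
alternative (transmit exactly `floor(copy_number / 2)` copies) was
rejected because it deterministically halves odd copy numbers: two
triploid-locus parents would always produce a diploid locus, and the panel
would drift to mean ~2.9, contradicting the design it is meant to emulate.
Recombination, double reduction and segregation distortion are not
modelled; how copy-number variants actually segregate through tetrasomic
meiosis is an open empirical question, and this generator makes the
simplest choice that preserves the marginal copy-number distribution.
In the rare event that both gametes carry zero copies (possible only when
both parents have ≤ 3 copies), the locus is restored to one copy with an
ancestral-frequency allele, keeping copy number in {1, …, 4}.

**Read counts.** Depth per sample × locus is negative binomial (dispersion
6) truncated to the configured window, with the untruncated mean tuned by
bisection so the conditional mean hits the target; defaults 5–60× with
mean 19×, the realized depth profile of the GBS design being emulated.
The alternative read count is binomial at
`q = af·(1−ε) + (1−af)·ε` with sequencing error ε = 0.01 pushing
fractions toward the interior. A configurable fraction of loci (5% by
default) is paired into duplicate groups whose counts are summed into one
observed locus, emulating paralogous regions co-mapping to a single
reference position; pooled loci show composite heterozygous ratios
(m / total copies) and roughly doubled depth.

**Traits.** Additive genetic values combine up to `n_qtl` major loci
(`1 − polygenic_share` of genetic variance) with a polygenic background
(small effects at every polymorphic locus, computed on true allele
fractions). Noise is residualized against the genetic value and rescaled
so the realized variance ratio equals h² exactly; traits are standardized
to mean 0, variance 1 (harmless for correlation and slope metrics, which
are scale-free). Missing phenotypes are masked completely at random at a
configurable rate (the real design had up to ~30% missing for one trait,
mechanism unreported).

What the generator does **not** emulate: linkage disequilibrium and
genetic maps (loci segregate independently given parents; "chromosomes"
matter only for LOCO bookkeeping), dominance/epistasis, genotyping error
beyond binomial sampling + symmetric base error, and ascertainment of the
SNP set. Passing tests therefore demonstrate correctness of the statistical
machinery and the encoding comparison under the stated generative model,
not performance on real linkage structures.

## Genotyping and filters

Continuous genotypes are `alt / (ref + alt)` where depth strictly exceeds
`min_depth` (default 5; a genotype at exactly 5 reads is missing). The
tetraploid caller maximizes the binomial likelihood of the alt count over
class means {ε, 0.25, 0.5, 0.75, 1−ε} (ε default 0.01 — a stand-in for
the error handling embedded in production variant callers), recodes the
winning dosage d to d/4, and breaks exact likelihood ties toward the lower
dosage so calls are deterministic.

The filter cascade applies, in order: per-genotype depth masking; locus
mean-depth window (inclusive, default 5–60); MAF bounds computed from
**pooled read counts** across samples (strictly inside (0.01, 0.99) —
pooled counts rather than mean called genotypes, since the frequency is
determined from read coverage before any calling); locus missing rate
≤ 0.5; sample missing rate < 0.7; and removal from *both* matrices of any
locus monomorphic in *either* — the step that guarantees the two encodings
are compared on identical sample and locus sets. Each step's surviving
counts are recorded in a report that tests reproduce with an independent
brute-force re-scan.

## Relationship matrices

With `p_k` the mean genotype at locus k over non-missing samples:
per-sample missing-data weights
`w_i = Σ_k p_k(1−p_k) / Σ_{k obs in i} p_k(1−p_k)` compensate samples
typed at fewer loci; `Z_ik = (X_ik − p_k)·w_i` with missing entries set to
0 after centering (mean imputation); `G = ZZᵀ / (0.25 Σ_k p_k(1−p_k))`.
The 0.25 factor is the tetraploid scaling: under tetraploid random mating
the allele-fraction variance at locus k is `p_k(1−p_k)/4`, so the scaling
constant equals the expected `ZZᵀ` diagonal and the mean diagonal of G is
~1 (0.96 on a simulated no-missing tetraploid panel; the small deficit is
the finite-parent relatedness of a diallel). On *mixed-ploidy* data the
diagonal exceeds 1 (~1.5 at mean copy number 3.2), because lower-copy loci
have allele-fraction variance `p(1−p)/c > p(1−p)/4`; this is a property of
the data, not a bug, and is why heritability is reported on the
mean-diagonal scale (below). Loci monomorphic within a LOCO subset
contribute zero to numerator and denominator alike; no blending toward the
identity is applied.

LOCO matrices are rebuilt per chromosome — weights and centering
recomputed on the retained loci — with the unanchored bin treated as its
own exclusion group. Whether the weight sums should span all genotyped or
only post-filter loci is not fully pinned down by the source description;
post-filter loci are used, consistent with the pipeline order.

## GBLUP

The default fit profiles the restricted likelihood over
`δ = σ²_e / σ²_g` on the eigendecomposition of the phenotyped-sample block
of G (49-point log-grid bracket + bounded Brent refinement, `xatol` 1e-8),
then returns BLUP values `E[g | y] = σ²_g G[:, obs] V⁻¹ (y_obs − μ̂)` for
all samples, phenotyped or not. Variance components are floored at
1e-8 · var(y) to avoid exact-boundary failures. The optional Gibbs sampler
(default 12,000 sweeps, 2,000 burn-in, matching the sampler settings of
the original Bayesian fit) works in the same rotated basis with weakly
informative scaled-inverse-χ² priors (df 5, prior mode at half the
phenotypic variance per component); its posterior-mean GEBVs correlate
> 0.99 with REML on a 300-sample panel, which is why the deterministic
REML path is the default.

**Heritability scale.** The reported estimate is
`h² = σ²_g·mean(diag G_obs) / (σ²_g·mean(diag G_obs) + σ²_e)`. The raw
ratio `σ²_g/(σ²_g+σ²_e)` equals this only when the G diagonal averages 1;
on mixed-ploidy panels (diagonal ~1.5) the raw ratio would understate a
true h² of 0.5 as ~0.38 purely through the scale convention.

Cross-validation shuffles phenotyped samples into 8 folds, 10 repeats,
refitting per fold; the per-repeat accuracy pools the eight out-of-fold
GEBV vectors before correlating (one coefficient per repeat, as implied by
reporting exactly ten coefficients per trait). Fold assignments depend
only on the seed, so two encodings evaluated with the same seed are paired
by identical groupings; the encoding comparison is then a paired t-test on
Fisher z-transformed per-repeat correlations, with guards for zero
difference variance and |r| = 1. Prediction bias is the OLS slope of
observed on predicted (1 = calibrated). Unphenotyped samples are excluded
from folds but still receive GEBVs.

## GWAS

Per chromosome, variance components are estimated once under the null
model with that chromosome's LOCO G and then held fixed for every marker
on it; each marker's effect and Wald χ²(1) come from GLS with
`V = σ²_g G + σ²_e I`, computed by whitening in the eigenbasis (the
per-marker cost is a pair of dot products). This
fixed-components approximation replaces per-marker REML refits; it is the
standard efficient mixed-model shortcut and the acceptance suite verifies
its calibration (λ_gc within [0.9, 1.1] and nominal type-I error on a
structured null). Missing marker genotypes are mean-imputed, mirroring the
GRM convention; markers with zero variance after imputation are flagged
and reported at p = 1 rather than erroring.

Genomic control recovers χ² from each p-value through the inverse
χ²(1) upper tail, computes `λ_gc = median(χ²)/0.4549364231`, and — only
when λ_gc exceeds 1 (by more than 1e-8, tolerance for the truncated
constant) — divides every χ² by λ_gc before converting back. The source
description's trigger "for χ² > 1" is read as λ_gc > 1, the only
dimensionally consistent interpretation. λ_gc is reported either way;
all-p = 1 degeneracy reports λ_gc = 0 with no correction. Significance is
Bonferroni, α / N.

## Depth-discrimination simulation

For each depth N on a grid (default 3–1,000), 2,500 binomial(N, p) counts
per state are converted to ratios; empirical percentiles use linear
interpolation (no estimator was prescribed). The discrimination depth is
the first grid depth at which the lower-mean state's `confidence`
percentile falls below the higher-mean state's `1 − confidence`
percentile; orientation is normalized automatically, so the answer is
invariant to swapping the two states or expressing ratios as A- or
B-fractions. The two per-state one-sided 95% envelopes are compared as
stated, without re-deriving a joint coverage level. A closed-form check,
`N* = (z·(√(p₁q₁) + √(p₂q₂)) / |p₁−p₂|)²`, gives 318.7 for the
0.25-vs-1/3 pair at 95%; simulation yields 316–320 depending on seed.
The approximation is asymptotic: for state pairs whose crossing depth is
below ~100 the binomial skew and the 1/N discreteness of ratios can move
the simulated crossing more than 10% from the formula, so property tests
compare the two only in the large-N regime.

**Histogram peaks.** Heterozygous ratios (strictly inside (0.1, 0.9), bin
width 0.01) pile up at exact rationals m/c — 0.25/0.5/0.75 for tetraploid,
1/3 and 2/3 for triploid loci, composite fractions for co-mapped pairs —
on top of a dense binomial-sampling baseline. Peaks are local maxima with
topographic prominence at least 0.15× the median bin count. A threshold
expressed as a *multiple* of the median cannot work here: prominence is
height above the enclosing saddle, and the class spikes rise only
0.3–1.7 medians above the baseline even when they are unmistakable to the
eye, so a 2× rule detects nothing. The 0.15 default recovers all five
mixed-ploidy class peaks across seeds at depth 20–60 while remaining a
parameter the caller can tighten.

## Numerical and interface conventions

* All randomness flows through `numpy` Generators seeded from explicit
  integers; every simulation stage derives its stream from
  `(config.seed, stage_index)`, so regeneration is bit-identical.
* Genotype matrices interchange as TSV (samples × loci, `NA` missing);
  GRMs as TSV with sample-id headers; read counts as VCF with AD FORMAT
  fields (1-based positions, chromosome labels "0"–"12"). VCF ingest
  skips non-biallelic records with a count, treats missing AD as zero
  depth, and errors on records lacking AD entirely.
* The pipeline writes every artifact under one run directory with a
  manifest carrying the seed and a hash of the scientific configuration
  (output paths excluded), and reruns with the same seed are byte-identical.
* Problem sizes in the test suite (panels of 100–500 samples, 200–5,300
  loci) are chosen so each check exercises the full pipeline at a scale
  where its statistical assertion has power; the full 762 × 31k default
  remains the generator's reference configuration.

## Known limitations

* No linkage: QTL mapping resolution and LD-decay arguments cannot be
  studied with this generator.
* The fixed-components GWAS approximation can differ from per-marker REML
  for borderline minor signals; major-QTL conclusions are unaffected.
* The Gibbs sampler targets the same additive model as REML, not any
  particular Bayesian software's prior family; agreement is asserted at
  the GEBV level only.
* The encoding comparison inherits the generator's assumption that
  continuous allele fractions are unbiased measurements of the underlying
  dosage; reference-mapping bias, which would distort both encodings, is
  out of scope.
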