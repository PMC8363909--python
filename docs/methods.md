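# Methods

This note documents the models, defaults and numerical choices behind
`plasmafrac`, and what the synthetic test bed does and does not establish.

## Fraction accounting

A fractionation run holds per-fraction amounts `a_f` of each analyte
(NTA-visible particles, bulk protein, named markers) together with the
whole-input reference totals. Recovery over a fraction set `F` is
`R = Σ_{f∈F} a_f / a_total`; enrichment of analyte X over Y is
`E = R_X / R_Y`, which equals the X:Y ratio in the pooled fractions divided
by the same ratio in the input because the pooled volumes cancel. Factors
are kept at full precision; only presentation rounds to "n-fold" integers
(`EnrichmentReport.rounded_factor`). Because two co-reported recoveries are
themselves typically rounded to 2–3 significant digits, a factor recomputed
from them can differ from an independently computed factor by a few
percent; e.g. recoveries printed as 34 % and 1.40 % give 24.3-fold, and
34 % and 1.1 % give 30.9-fold, even when the underlying unrounded data
rounds to 25- and 32-fold. The package therefore treats factor values
recomputed from rounded recoveries as approximations with a rounded-input
tolerance rather than exact targets.

Measurement noise can push a recovery slightly above 1; it is clamped for
reporting and a warning is emitted. Zero reference totals raise
`UndefinedRecoveryError` instead of returning infinities.

## Synthetic plasma and fractionation

The generator is a study-condition emulator, not a physical
chromatography/ultracentrifugation model (no diffusion, no sedimentation
coefficients).

**Plasma.** Default composition: EV at 1e10 particles/ml (log-normal sizes,
median 120 nm, GSD 1.5; buoyant density N(1.095, 0.007) g/ml) carrying CD9
and FLOT1; HDL at 1.5e16/ml (10 nm; N(1.055, 0.010)) carrying APOA1;
APOB-carrying lipoproteins at 1e15/ml (median 25 nm, LDL-dominated;
N(1.052, 0.007)) carrying APOB; and a soluble-protein background of
70 mg/ml (55 % albumin, effective size 5 nm, density ~1.015). Total LPP:EV
concentration ratio ≈ 1.6e6, consistent with the six-orders-of-magnitude
excess the workflow has to defeat. HDL is flagged invisible to
nanoparticle tracking (below its detection range), so "particles" counts
EV plus APOB-LPP.

**SEC.** Elution of a species of size `s` (nm) is a Gaussian over the
fraction index, discretized on unit windows and renormalized over the 16
fractions to sum to `1 − loss_fraction` (default 0):

    mean(s)  = 13.2065 − 3.7065 · log10(s)
    sd(s)    = max(1.6706 − 0.3706 · log10(s), 0.35)

The log-linear size→fraction map is the simplest monotone choice that
reproduces the observed elution order (large particles first, soluble
protein late). The two lines are anchored so that, noise-free, CD9
(120 nm) pools 73.4 % into fractions 5–6, APOA1 (10 nm) 1.0 %, and APOB
(25 nm) 9.2 % — matching the marginal recoveries this kind of column
achieves (73.0 %, 1.40 %, 9.67 %). These are calibration targets for the
shipped defaults, not claims about any specific plasma sample.

**Density gradient.** Fraction densities default to a fixed monotone
ladder (1.01…1.27 g/ml with 0.01 steps through the analytic windows). A
class with density N(μ, σ) distributes proportionally to the normal pdf
evaluated at the fraction densities, renormalized — a Gaussian banding
approximation to 18 h of isopycnic centrifugation. Defaults put ≥96 % of
APOA1 and ≥99 % of APOB (noise-free) into the 1.04–1.07 g/ml window and
make 1.09 or 1.10 g/ml the modal CD9 fraction with ≈44 % of the signal,
emulating the published behaviour of this gradient (≥85 %, ≥95 %, 44.6 %).

**Measurement noise.** Each recorded cell is multiplied by a unit-mean
log-normal with CV `noise_cv` (default 0.10; assay CVs are rarely
reported, 10 % is a realistic immunoassay/NTA figure). Conservation
(fraction sums equal input totals to 1e-9 relative) holds exactly in the
noise-free, lossless configuration, which is what the conservation tests
assert. Because single noisy recoveries have ~5 % spread, the calibration
tests average over 10 seeds: the envelope is a statement about the default
parameters' expected behaviour, not about one draw.

## LFQ generator and differential testing

**Generator.** Feature baselines ~ N(26, 2) on the log2 scale, replicate
noise sd 0.5, planted per-group log2 shifts added on top. Dropout is
missing-not-at-random: P(missing | x) = logistic((L − x)/s) with location
L = 22 (≈ 2 sd below the baseline mean) and scale 0.8, giving ~5 % overall
missingness that concentrates in low-abundance features. What this does
*not* emulate: peptide-level effects, shared-peptide ambiguity,
normalization artefacts, batch effects, or correlated features — so
passing tests show correct statistics under a clean MNAR Gaussian world,
not robustness to real acquisition pathologies.

**Filter.** A feature is kept when some group has valid values in at least
66.67 % of its replicates, with a 1e-9 slack so 4/6 = 0.6667 passes.

**Imputation.** Missing values are drawn per sample column from
N(m − 1.8·σ, (0.3·σ)²) where m, σ are the column's observed moments — the
conventional down-shifted-normal model for abundance-dependent dropout;
width/downshift are configurable, and a whole-matrix variant is available
by flag. Draws are seeded; observed values are never touched.

**Statistic and FDR.** t_S0 = (x̄₁ − x̄₂)/(S0 + SE_pooled) with pooled
(not Welch) standard error — the designs here are equal-n — and S0 = 0.1
by default. The permutation null permutes group labels; all C(n, n₁)
distinct splits are enumerated when there are at most 10,000 (or no more
than the requested permutation count — a sampling request that exceeds the
number of distinct splits falls back to enumeration, which also makes such
runs seed-free), otherwise splits are sampled with the configured seed.
The q-value of feature i is

    q_i = min(1, mean_perm #{|t_perm| ≥ |t_i|} / #{|t_obs| ≥ |t_i|})

with the counts pooled across features, then made monotone by a cumulative
minimum walking from the least to the most significant feature. Exceedance
counting slackens the threshold by a relative 1e-9 so float jitter cannot
flip a statistic's self-count (this is what makes label-swap symmetry hold
bitwise). Fewer than 10 distinct splits triggers a warning and exact
enumeration. Tests are two-sided throughout. Z-scoring before clustering
is available via the API but not applied by default; both orders are
legitimate and neither is asserted as canonical.

**Descriptives.** PCA centres features (sklearn); correlation matrices use
pairwise-complete observations with pairs under 3 shared features flagged
NaN; 1−Pearson distances for constant items are set to the maximum (2.0)
with a warning; kernel densities use Gaussian KDE with Scott's bandwidth
on a grid extending 4 bandwidths past the data; z-scores use the ddof=1
standard deviation and return zeros (with a warning) for constant series.

## Catalogues

"Identified in the crude extract" is operationalized as valid
(non-imputed) values in ≥ 66.67 % of crude replicates — the same threshold
as the filter, reused for coherence since presence is otherwise
undefined. Direction of enrichment comes from the sign of the group-mean
difference; significance from the permutation q at α = 0.05 (interpreted
on the multiple-testing-corrected scale). Non-EV-associated: in crude AND
LPP-direction q < α. Corona candidate: in crude AND EV-direction q < α
AND secreted AND valid in ≥ 66.67 % of EV replicates ("consistently
identified"). The two categories are mutually exclusive by construction
(opposite-direction significance). Proteins without annotation are
treated as not secreted and logged. The enrichment criterion is a
two-sided test plus a direction check; a one-sided variant would halve the
p-values but is not implemented as the default. The Spearman correlation
of corona abundance with plasma concentration enumerates all n! rank
orders for n ≤ 10 (chunked matrix products) and uses the t approximation
above.

## Small-RNA statistics

**Generator.** Counts are negative binomial with var = μ + α·μ² (α = 0.1
default; α = 0 falls back to Poisson, documented limiting case). Means are
`library_size × biotype share × within-biotype weight`, with the tRNA
share further split by per-group amino-acid isotype proportions; weights
are a skewed Dirichlet draw fixed by the seed. Default compositions: EV
extracts at miRNA 7.18 %, tRNA 7.79 %, piRNA 0.358 %, lncRNA 16.1 % of
non-ribosomal reads with a flat 19-isotype tRNA pool; total plasma with a
Gly-dominated pool (45 %, then Glu 15 % and Val 9 %) and planted 4× HDL-
and platelet-signature miRNAs. This reproduces the qualitative signature
that most non-Gly isotypes appear relatively EV-enriched (16 of 19 with
the defaults). A decay multiplier (`decay_factor ** t` across ordered
samples) emulates a therapy-tracking miRNA time course. Trp fragments are
omitted from the isotype list as too rare to quantify.

**Filter.** Keep a feature iff some group has count ≥ 1 in at least
⌈group size / 2⌉ of its samples (all-zero features always removed). The
stricter every-group reading is available via `any_group=False`.

**Normalization.** Median-of-ratios to per-feature geometric means over
features nonzero in all samples (verified in tests against an independent
reference implementation); when no such feature exists, library-size
scaling with geometric mean 1 is used with a warning.

**DE test.** The paper-grade tool for this step is a full NB shrinkage
model; this package ships a documented simplified stand-in: per-feature
method-of-moments dispersion (pooled across the two groups, clipped at 0),
log2 fold change of normalized group means with pseudo-count 0.5, a
delta-method Wald SE, normal two-sided p, BH adjustment, and the standard
call criteria |log2FC| ≥ 1 AND adjusted p ≤ 0.05. It is well calibrated in
the generator's clean NB world (power ≥ 0.8 at 4-fold, n = 6/6,
α_disp = 0.1) but lacks dispersion shrinkage, so expect it to be anticonservative
for very low counts on real data.

**GSEA.** "Classic" is the unweighted running sum: +1/N_h at hits,
−1/(N−N_h) at misses, ES the signed maximum deviation (∈ [−1, 1]). The
null permutes which positions are hits (gene-label permutation — the only
permutation available on a single ranked list), default 1000 permutations,
seeded. NES divides ES by the mean |ES| of same-sign permutations; p is
the same-sign exceedance fraction with add-one smoothing. Ranking uses
log2 fold change, ties broken by mean normalized count then feature id.

**Mann–Whitney.** For n₁+n₂ ≤ 20 the U null is enumerated over all
C(n₁+n₂, n₁) assignments of the tie-averaged pooled ranks; the two-sided p
is P(|U − n₁n₂/2| ≥ observed). Complete separation at 6 vs 6 gives
p = 2/924 = 0.0022. Larger samples use the tie-corrected normal
approximation. All-tied input returns p = 1 with a warning.

## Pipeline

One global seed; per-stage seeds are `crc32(stage) XOR (seed ·
2654435761) mod 2³¹`, so toggling a stage never shifts another stage's
randomness. Reports contain no timestamps and are serialized with sorted
keys: identical configuration ⇒ byte-identical reports (asserted in
tests). Dependency violations (e.g. catalogues without proteomics) fail
fast with the stage named. Configuration is YAML, schema-checked with
unknown keys rejected.

## Problem sizes

Defaults were chosen so the whole suite runs in seconds: 16-fraction
stages; 600-protein LFQ matrices with 6 replicates per extract (83 planted
lipoprotein-only, 20 corona, 30 EV-marker features); ~170 small-RNA
features with 4 replicates per group; exhaustive permutation nulls at
these group sizes (924 splits at 6 vs 6, 20 at 3 vs 3); 200-replicate
null-calibration simulations at 1000 features; 1000 GSEA permutations.

## Known limitations

- The fractionation simulator is phenomenological; it cannot answer
  questions about column chemistry, gradient deformation or spin time.
- The LFQ generator's features are independent; correlation-structure
  effects on the pooled permutation null are untested.
- The NB Wald test has no dispersion shrinkage (see above).
- Catalogue accuracy on synthetic data says nothing about the biological
  identity of real contaminant or corona proteins; annotations are
  user-supplied and not fetched from any database.
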