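# Methods

## Model

All analyses assume the additive single-trait model

    y = 1 μ + Z g + e,      g ~ N(0, G σ²ₐ),   e ~ N(0, I σ²ₑ)

for a herd of n genotyped animals, or its marker-effect form
yᵢ = μ + Σⱼ z_ij gⱼ + eᵢ with dosages z_ij ∈ {0, 1, 2}.  Only an intercept
is fitted as a fixed effect; the two forms are linked by G = W Wᵀ / c with
W the centered dosage matrix and c = 2 Σ pⱼ(1−pⱼ), which makes GBLUP
identical to ridge regression on markers at matched shrinkage
(σ²_marker = σ²ₐ/c) — a property the test suite checks to 10⁻⁶.

## Quality control

Filters run in a fixed, logged order: marker call rate (remove ≤ 0.90),
Hardy–Weinberg (remove p < 10⁻⁶), minor allele frequency (remove < 0.01),
then sample call rate (retain > 0.90).  The order matters for the
bookkeeping — each marker is charged to the first filter that removes it —
and is deliberately fixed because the counts are otherwise ambiguous.  The
HWE statistic is the 1-df Pearson chi-square against expectations at the
sample allele frequency (the conventional chip-QC default at this
threshold); a conditional exact test is available behind a flag.
Monomorphic markers test at p = 1 by convention but are always removed at
the MAF stage, because they carry no information and break the VanRaden
denominator.  Missing calls are excluded from MAF/HWE counts at QC time and
mean-imputed (2pⱼ) only when G is built.

## Genomic relationships

VanRaden's first method with observed-sample frequencies (the only
frequencies a single-herd study has).  Observed-frequency centering forces
G·1 = 0, so raw G is always singular; REML handles this because the null
direction coincides with the intercept, while the inverse-based
mixed-model-equation routes require the identity blend
G* = (1−w)G + wI (default w = 0.05, exposed and logged; weights above 0.25
are rejected as a change of model rather than a numerical fix).

## REML

Average-information REML on the eigen-rotated model: with G = U D Uᵀ the
rotated covariance is diagonal, so each iteration costs O(n) after one
O(n³) decomposition.  AI steps are damped by halving until they stay inside
the parameter space; if no damped step is valid an EM step is taken.
Convergence is declared at relative parameter change < 10⁻⁸, at a
restricted-likelihood change below 10⁻⁹·(1+|ℓ|) (the EM crawl near a
boundary moves parameters long after the likelihood is flat), or after
three consecutive iterations pinned at the σ²ₐ floor; boundary fits are
reported with a flag, never raised.  The standard error of h² comes from
the inverse AI matrix by the delta method.  Against a Nelder–Mead and a
dense-grid oracle of the same restricted likelihood the fit agrees to
better than 10⁻³ in each component.

At the emulated design (a few hundred nominally unrelated animals,
chip-derived G) the h² information content is low: single-fit standard
errors are ≈ 0.15, so per-herd estimates scatter widely even though the
mean over replicates recovers the target to within 0.05 across
h² ∈ {0.07, 0.25, 0.35, 0.57} (n=400, m=2000).  Published "±" values of
0.01–0.04 for comparable designs are not reproducible from this model; no
check is tied to them.

## Bayesian samplers

One numba-compiled single-site Gibbs kernel serves all four priors; a fixed
seed gives bit-identical chains.  Dosages are centered at 2p inside the
sampler; μ is sampled, not profiled.  Per marker the right-hand side
rⱼ = wⱼᵀe + wⱼᵀwⱼ gⱼ is formed once; Bayes B/C draw the indicator from the
marginal odds with the effect integrated out (the joint update; a naive
conditional update is reducible because gⱼ = 0 has zero density under the
slab), then the effect from its conjugate normal.  Marker variances update
from scaled-inv-χ²(ν+1, ·) conditionals (or the prior when excluded); the
Lasso uses the inverse-Gaussian conditional for 1/τ²ⱼ and a Gamma update
for λ².  σ²ₑ uses a weak scaled-inv-χ² prior (ν = 4.2) centered at the REML
residual variance when available.

Hyperparameter defaults: ν = 4.2; S solved so the prior mean marker
variance equals σ²ₐ/((1−π)·c) from a REML pre-fit (half the phenotypic
variance if none); Bayes B π = 0.95; Lasso a = b = 0.1; chains
20,000/5,000/5 (length/burn-in/thin) by default, with a reduced
2,000/500/2 profile used inside cross-validation.  All are configuration,
not estimates.  Convergence is monitored by a split-chain R̂ on saved
scalar chains, and a chain-halves proxy for the Monte-Carlo SE of each
fitted genetic value supports the chain-doubling stability check in the
tests.  Degenerate modes (fixed variances, fixed π, no intercept) exist so
each sampler can be compared to conjugate closed forms.

## Cross-validation and summaries

`make_folds` draws, per repeat, a uniform random partition into k folds
with sizes differing by at most one; all methods share partitions.  GBLUP
predicts masked animals from the training-block equations through the
genomic covariances (two algebraically identical routes, joint and
projection, kept as an internal cross-check); Bayesian methods refit on
each training set and accumulate marker effects for the validation
animals using training-time centering.  Ability cells are averaged over
all repeat × fold cells ("mean of the correlation values"); pooling
predictions before correlating is available but off by default.  Accuracy
divides by √h² from the whole-data REML fit — per-fold h² estimates would
add noise without changing the expectation, and the shipped reference
tables only reconcile under the whole-data convention.  Animals missing a
trait are dropped per trait, not imputed.

## Synthetic herd

The generator emulates the motivating study population: 354 animals,
post-QC-like panel with MAF ~ Uniform(0.06, 0.5) over 29 autosomes,
trait scale ≈ 84 ± 10 kg at weaning, heritability targets spanning
0.07–0.57.  Haplotype alleles are Bernoulli(pⱼ) indicators driven by
latent uniforms; with probability `ld_decay` (default 0.5 — the study
panel's empirical LD is unpublished, so this is a choice, not an
inference) a marker reuses its left neighbour's uniform, inducing positive
adjacent-marker correlation without touching any marginal frequency.
Architecture: 20 QTL carry half the genetic variance (configurable), the
rest is polygenic; effects are rescaled so the sample additive variance
equals h²σ²_P exactly, which leaves realized h² fluctuating only through
the residual draw (mean within ±0.03 of target at herd sizes ≥ 300).

The later-age trait mixes the early additive value with an independent
polygenic value at genetic correlation 0.9 and heritability 0.5, and a
quarter of animals lack the later record.  The calibration comes from the
chain r(GEBV₆, y₃₀) ≈ r(GEBV₆, a₆) · r_g · √h²₃₀ with the measured
in-sample GBLUP accuracy ≈ 0.62 at this design: 0.62 · 0.9 · √0.5 ≈ 0.39,
matching the ≈ 0.4 early-to-later correlation regime the workflow is meant
to exhibit.  Both values sit inside the range reported for weight traits
in cattle (age–age genetic correlations 0.8–0.95, adult-weight h²
0.3–0.5).

What the generator does *not* emulate: family/pedigree structure (animals
are unrelated beyond chance sharing, so realized relationships are much
weaker than in half-sib designs — h² SEs and prediction abilities are
correspondingly conservative), long-range LD from bottlenecks or
admixture, dominance/epistasis, genotyping error, and non-uniform marker
density.  Passing tests therefore certify the statistical machinery, not
field performance on a structured herd.

## Problem sizes

Recovery and cross-validation checks run at n = 300–400 animals and
m = 1,000–2,000 markers with 2–10 CV repeats and reduced Gibbs chains;
these sizes keep every property of interest measurable (the statistics
above are all herd-size-explicit) while a full suite run stays in the
minutes range on one CPU.

## Known limitations

* Single trait, intercept-only fixed effects, additive variance only.
* The exact test for HWE is conditional-exact but two-sided by
  probability mass, the common convention; mid-p is not offered.
* The Monte-Carlo SE proxy (chain halves) underestimates for very short
  chains; the convergence R̂ is reported so users can lengthen chains.
* No LD pruning, relatedness-based exclusion, or sex checks at QC; no
  pedigree or single-step matrices.
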