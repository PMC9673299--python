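# Methods

## The model

`fullgen` fits one trait at a time with the mixed linear full genetic
model. For line *k* in environment *h*,

y_hk = μ + c_hk + Σᵢ aᵢ x_Aᵢₖ + Σᵢ dᵢ x_Dᵢₖ
     + Σᵢ<ⱼ aaᵢⱼ x_AAᵢⱼₖ + adᵢⱼ x_ADᵢⱼₖ + daᵢⱼ x_DAᵢⱼₖ + ddᵢⱼ x_DDᵢⱼₖ
     + e_h + Σᵢ aeᵢₕ u_AEᵢₕₖ + deᵢₕ u_DEᵢₕₖ
     + Σᵢ<ⱼ (aae, ade, dae, dde)ᵢⱼₕ u-terms + ε_hk.

Coefficients: x_A is 1 for QQ, 0 for Qq, −1 for qq with Q the non-B73
allele (so a is half the homozygote difference); x_D is 1 for Qq only
(d is the heterozygote's deviation from the homozygote midpoint); the four
digenic epistasis coefficients are the products of the constituent
contrasts, which yields the conventional ±1/0 tables (e.g. x_AA = 1 for
QQ×QQ and qq×qq, −1 for QQ×qq and qq×QQ, 0 otherwise; x_DD = 1 only for
Qq×Qq). Incidence columns u equal the matching x on records of their
environment and 0 elsewhere. c_hk are optional principal-component
cofactors of the centered x_A matrix (base model: none; adjusted model:
top k, default 10 when used; the PC sign is fixed by making each
component's largest-magnitude loading positive).

Main and epistasis effects are fixed. Environment and each of the six G×E
families (ae, de, aae, ade, dae, dde) are random, one iid variance
component per family. The dde family is constructed and estimated even
though it is often reported as ~0; its slot exists in every output table.

### Estimation

Variance components are estimated by REML. With q random columns and
diagonal prior covariance D, V = σ²_ε I + Z D Zᵀ is inverted through the
Woodbury identity, so each likelihood evaluation costs O(q³) after a
single pass over the data; the profile REML criterion is minimized over
log-variances with L-BFGS-B, polished by a Nelder-Mead pass when the
gradient method stalls. Fixed effects are then BLUE and realized random
effects BLUP.

Effect uncertainty comes from a Gibbs sampler (defaults: 20 000
iterations, burn-in 2000, thinning 5, seeded): flat priors on fixed
effects, inverse-gamma(0.001, 0.001) on every variance component, blocked
normal updates for the fixed vector and each random family using
precomputed cross-products (each sweep is O((p+q)²), independent of n).
A split-half mean-drift diagnostic is computed per parameter and a warning
logged beyond 0.5 posterior SD. If the residual variance is numerically
zero the posterior is degenerate and the exact REML/BLUE solution is
returned with zero spread (logged).

### Testing

Henderson's method III: every term (each fixed column; each random term's
per-environment column group) is tested in the all-effects-fixed
representation. The design is pruned to full column rank (pruned columns
logged; a term whose columns are all pruned gets F = 0), and the F
statistic is the reduction-in-SS difference between the full model and the
model without that term's columns, over the full-model residual mean
square. On balanced fixed-only designs this reproduces classical ANOVA F
exactly, which the tests assert to 1e-10.

Experiment-wise thresholds: phenotypes are permuted within environment
(preserving e_h while breaking the genotype-phenotype link), the maximum F
over a term family is recorded per permutation, and the critical F is the
(1 − α) upper empirical quantile. The default family is a single
*experiment-wise* family over all tested terms, which is what controls the
probability that any term rejects at α — splitting into {main, epistasis,
interaction} families (available via `families="reported"`, matching how
results tables are usually grouped) controls each family separately and
inflates the any-term rate to roughly 1 − (1 − α)^3. P_EW per term is the
rank-based tail probability (1 + #{max-F ≥ F_obs}) / (n_perm + 1). Small
designs can enumerate all within-environment permutations exactly
(`exhaustive=True`); fewer than 100 sampled permutations is refused unless
forced. A "highly significant" label (−log10 P > 5) is attached in the
pipeline's effect table as a reporting convention.

### Heritability

Each component share is the variance across observed records of that term
family's predicted contribution (fixed columns × estimates, or incidence
columns × realized random effects) divided by the observed phenotypic
variance, reported in percent. The observed (post-QC) variance is the
denominator — the convention is stated here because raw-versus-QC'd
denominators differ slightly and the choice is otherwise invisible.
Aggregates: h²_T is the sum of all 12 components, h²_D+ sums every
dominance-containing component (D, AD, DA, DD, DE, ADE, DAE, DDE), h²_GE
sums every environment-interaction component (AE, DE, AAE, ADE, DAE,
DDE). These identities are exercised against published four-trait rows in
the acceptance tests. Because estimates carry sampling noise, estimated
shares are slightly inflated relative to truth; recovery is calibrated to
±3 percent points at n = 8000 records.

## Quality control

SNPs: minor allele frequency (heterozygote contributes one allele of
each, computed on integer counts so boundaries are exact) and call rate;
strictly-below thresholds are removed, boundary values kept — mirroring
the quoted inequalities "MAF < 0.05" and "call rate < 90%". Phenotypes:
first IQR fences per trait × environment (quartiles by linear
interpolation between order statistics, the numpy default — the
convention is pinned by oracle tests), values strictly outside
Q1 − k·IQR / Q3 + k·IQR removed (k = 1.5); groups under 4 values are
skipped with a warning. Then residual outliers: residuals from the
trait × environment mean (the simplest defensible baseline), pooled per
trait, removed when |ε − μ_ε|/σ_ε > k (k = 3; σ_ε = 0 removes nothing).
On Gaussian data the k = 3 rule removes ≈ 0.27%, which the tests verify.
SNP and phenotype filters act on independent axes, so their order is
immaterial; the SNP filter is exactly idempotent, the fence-based
phenotype filters are idempotent on the fixtures tested but not by
construction (fences move slightly after removal).

Missing genotype calls that survive QC are handled at the coefficient
level: the x_A / x_D entries are imputed by the within-family mean
coefficient (column mean, then 0, as fallbacks), keeping every phenotype
record in the design.

## GMDR prescreen

The score statistic for a quantitative trait is the residual from a
mean + environment model. For a 1-, 2- or 3-locus tuple, records fall
into 3^d genotype cells; a cell is high-risk when its training-fold mean
residual exceeds the overall training mean. The tuple's score is the
cross-validated (5-fold, pooled counts) balanced accuracy of that
labeling: ~0.5 for a null tuple, 1.0 under perfect separation, invariant
to affine transformations of the phenotype. Records missing a call at a
tuple locus are excluded from that tuple's scoring. The 1D scan is
exhaustive; 2D/3D scans run over the top 1D survivors (configurable,
default 50) — a desk-scale trade against the original exhaustive
GPU-style scan. Ranking ties break by (chromosome, position). Selected
triples expand to their three constituent pairs before the association
stage, since the fitted model is digenic.

## Breeding prediction

Total genotypic value of a genotype vector over the significant loci is
the fixed-effect sum (plus that environment's realized ae/de/aae/ade/dae/
dde effects when an environment is specified); μ is reported separately,
and the "overall" column uses main + epistasis effects only. The best
existing line is the argmax over observed lines (ties by line id). The
superior line is the optimum over {QQ, qq}; the superior hybrid over
{QQ, Qq, qq}. Up to 15 loci the optimum is exact enumeration (vectorized,
chunked); beyond that, stepwise tuning sweeps loci in descending
|a| + |d| order, accepting strictly improving single-locus changes —
monotone, deterministic given its start, and run from the marginal
per-locus optimum, the three uniform vectors and 8 seeded random restarts
(epistatic landscapes are multimodal; single-start coordinate descent
stalls on ~25% of random instances, multi-start matches exhaustive
enumeration on all tested ones and can never exceed it). The hybrid
search is seeded with the superior line, so hybrid ≥ line always; line ≥
best existing line holds whenever the population is homozygous at the
effect loci (heterozygous existing lines can beat every homozygote when
dominance is strong — the same reversal printed tables sometimes show).

## Synthetic data

The generator emulates a NAM population: `n_families` half-sib RIL
families share the common parent B73; at each (family, SNP) cell the
founder carries the non-B73 allele with probability 0.5 (configurable),
making the SNP segregate 1:1 QQ:qq among that family's inbred lines, and
otherwise the family is fixed qq. Residual heterozygosity from selfing is
a per-cell Bernoulli overwrite (default rate 0.03 — the population's
residual heterozygosity is not published, so this is a stated modeling
choice), and missing calls likewise. Loci are drawn independently within
family: there is **no linkage map and no LD**, so nothing here can test
LD-dependent behaviour (fine-mapping resolution, clumping) — every
formula the package implements operates on coefficient columns, which the
generator does populate faithfully. Environment effects are drawn once
per run from N(0, σ_e²) or supplied as a fixed list.

`make_architecture` turns a target heritability profile into concrete
effects: raw effects are drawn N(0, 1) per component, G×E blocks are
centered across environments per locus (so interaction contributions are
orthogonal to main-effect contributions on a balanced layout), and each
component block is rescaled so its realized contribution variance on a
reference population equals exactly target × total variance, with total =
σ_ε²/(1 − Σ targets). On an independent population the realized shares
match targets to Monte-Carlo error. Components are calibrated marginally;
cross-component covariances are near zero by construction but not exactly
zero.

Every stochastic function takes an explicit seed; the pipeline fans a
single run seed out through `numpy.random.SeedSequence.spawn` in a fixed
order (simulation, prescreen, permutation, Gibbs).

## Calibration experiments and problem sizes

The null type-I experiment uses 200 replicate datasets of 500 lines × 2
environments × 50 candidate SNPs with 200 permutations each — sizes at
which the whole experiment completes in about half a minute while the
binomial standard error (0.015) still resolves miscalibration. The
parameter-recovery experiment uses 2000 lines × 4 environments, 6 loci,
2 epistatic pairs and G×E on 2 loci; its reference population uses a 0.2
heterozygote rate because with NAM-level heterozygosity (0.03) the
Qq × Qq cells behind dd terms are essentially empty at n = 2000 and the
dominance-related effects would be unidentifiable by construction rather
than by any fault of the estimator. Coverage is assessed as |posterior
mean − truth| ≤ 3 posterior SD over the a, d, aa, dd and ae terms.

## Known limitations

- No linkage map, LD, selection or multi-allelic SNPs in the simulator.
- The fitted epistasis is digenic only; 3D GMDR hits enter as their
  constituent pairs.
- One trait per model fit; multi-trait runs loop the pipeline.
- The Gibbs sampler assumes the REML-chosen random-effect structure;
  variance components with very few informative records (e.g. dde under
  low heterozygosity) shrink toward their prior.
- Heritability shares use point estimates of effects, so very noisy
  effects inflate their component slightly.
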