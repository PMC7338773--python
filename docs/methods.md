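# Methods

## Model

For one reproductive trait and one environmental covariate, record *n* of
sow *l* (parity class *j*, birth year *i*, permanent-environment level
*m*, covariate value *k*) is modelled as

    y_ijklmn = α φ0 + β φ1(x_k) + CG_i + Par_j
               + a0_l φ0 + a1_l φ1(x_k) + p_m + e_ijklmn

with the **normalized** first-order Legendre basis φ0 = √(1/2),
φ1(x) = √(3/2)·x on the standardized covariate x ∈ [−1, 1]. The
normalized basis (rather than the raw pair (1, x)) is used for both the
fixed and the random regression: derived across-environment genetic
correlations depend on this convention, and only the normalized form
reproduces the correlation anchors the package is validated against.
The overall intercept α rides on φ0, so it is the performance at the
covariate midpoint up to the constant √½.

Distributional assumptions:

* (a0, a1) over all pedigree animals ~ N(0, **H** ⊗ **G**), **G** the
  2×2 intercept/slope covariance. **H** combines pedigree and genomic
  information (below); with no genotypes it reduces to **A**.
* p ~ N(0, I σ²_pe), one level per sow, shared across her parities.
* e ~ N(0, σ²_et), five residual classes t assigned from the covariate's
  quintiles (boundaries at the 20/40/60/80th percentiles, linear
  interpolation, ties to the lower class) so class sizes are balanced up
  to ties. Allocating classes on the covariate (not the phenotype)
  makes the residual variance a function of the environment, which is
  what produces the broken-line heritability profile across the gradient.
* Contemporary group is the sow birth year only — a coarser grouping
  than farm-year-season, chosen to avoid collinearity with the
  environmental covariate itself.

Fixed effects use reference (drop-first) dummy coding, keeping the model
full rank with a flat prior.

## Relationship matrices

* **A**: tabular method with inbreeding; ancestors deeper than 10
  generations (counted from the youngest animals) are treated as unknown
  founders. **A**⁻¹ is assembled sparsely by Henderson's rules using
  the inbreeding coefficients from the tabular pass, and matches the
  dense inverse to 1e−10.
* **G** (VanRaden method 2): Z = M − 2p with sample allele frequencies,
  G = ZDZ′, D_ii = 1/[m·2p_i(1−p_i)]. Missing dosages are mean-imputed
  (zero in Z). Under Hardy–Weinberg data the mean diagonal is ≈ 1.
* Blending: G* = ωG + (1−ω)A22 with ω = 0.95 by default — G alone is
  singular (centered Z), blending guarantees invertibility with
  negligible distortion.
* **H**⁻¹ = **A**⁻¹ + [[0, 0], [0, G*⁻¹ − A22⁻¹]] in the
  (non-genotyped, genotyped) ordering. Printed versions of this formula
  sometimes show A11⁻¹ in place of **A**⁻¹; the standard corrected form
  is implemented and verified against a brute-force construction of
  **H** from the joint distribution on a toy pedigree.

## Gibbs sampler

Location effects are updated with scalar draws for fixed effects and
per-animal blocks for the genetic effects; a recorded sow's
(a0, a1, pe) triple is drawn jointly from its 3×3 conditional. The
joint sow-level block matters: a0 and pe are confounded at the sow level
and mix poorly under scalar updates. Sweeps run in a numba-compiled
kernel; one sweep is O(records + q²) with q pedigree animals (the q²
term is the dense H⁻¹ row product in the genetic conditionals and the
quadratic form for the **G** update).

Variance conditionals: **G** | a ~ IW(ν_g + q, S_g + A′H⁻¹A) with
A = [a0 a1]; σ²_pe and each σ²_et from scaled inverse-χ² conditionals on
their sums of squares (each residual class uses only its own records).
The sampler's location draws were validated against the exact joint
posterior (mixed-model-equation mean and marginal variances) at fixed
variance components.

**Priors.** Flat for fixed effects; IW(ν_g = 4, S_g) for **G**; scaled
inverse-χ²(ν = 4) for the scalar variances. The default scale is set to
0.1·Var(y) per component rather than 1. This matters: the likelihood is
nearly flat along the direction that trades φ0²σ0² against σ²_pe
(a REML profile on simulated data moves only ~2 log-units between
σ0² = 0.5 and σ0² = 9 at n ≈ 2000), and a unit-scale IW prior — whose
prior mean is **G** = I — silently decides that direction, collapsing
the genetic intercept variance. Scaling the prior mean to a fraction of
the phenotypic variance (the convention popularized by MCMCglmm-style
animal models) keeps the prior proper and mild at any measurement scale.
Posterior intervals for σ0² remain wide; that is the honest width of a
weakly-identified component, not a sampler artifact.

**Chains.** Stored draws follow (iterations − burn-in)/thinning; chains
are bit-reproducible under a fixed seed (one seed stream drives the
compiled kernel, a second the variance draws). Convergence is checked
with Geweke z-scores (first 10% vs last 50% of stored draws, spectral
variance at frequency zero via a Bartlett-windowed autocovariance sum
with lag cutoff √n).

**Two-step covariate screening.** Step 1 fits every candidate covariate
with a reduced chain (default 30,000 iterations) and, by default, only
sire genotypes in **H** — cheaper per fit, and sufficient to rank
covariates by the posterior mean slope variance σ1². Step 2 refits the
winning covariate with the full chain and all genotypes. Because the
relationship structure does not depend on the covariate, **H**⁻¹ is
built once and shared across all screening fits.

## Derived parameters

Γ = Φ′**G**Φ over a grid of standardized covariate values (default 201
equally spaced points on [−1, 1]). For first-order norms the minimum
off-diagonal correlation sits at the grid extremes and is insensitive to
grid resolution; the median is grid-dependent and is always reported
together with the grid used. Environment-specific heritability
h²(x) = Γ_kk/(Γ_kk + σ²_pe + σ²_et) is computed per posterior draw and
summarized as mean with a 95% credible band. Reaction norms are
r(x) = αφ0 + βφ1(x) at the population level, with (a0_l, a1_l) added for
individuals.

Sire selection for the tolerant/susceptible extremes requires ≥ 50
recorded daughters whose records are not concentrated under comfortable
gradients: the daughters' covariate values must span ≥ 60% of the
observed range with records in ≥ 4 of the 5 residual classes (both
thresholds configurable). Eligible sires are ranked by total slope
β + a1; the top and bottom k (default 4) are returned.

## Window-based ssGWAS

SNP effects are back-solved per term as û = DZ′(ZDZ′)⁺â. The
pseudoinverse is used because ZDZ′ with sample frequencies is always
rank-deficient (centered Z annihilates the ones vector); the solution is
exact for â in the range of ZDZ′ and a least-squares projection
otherwise. Direct genomic values of 10-SNP windows sliding by one SNP
(never across chromosomes) are computed across genotyped animals; each
window's DGV variance (population variance, divisor n) is expressed as a
percentage of the whole-genome DGV variance. The top ceil(1%·W) windows
per term are selected, ties broken by (share, chromosome, position).

**Bootstrap test.** The null distribution of the *maximum* window share
is built from B random permutations of the SNP-effect vector: the
multiset of effect sizes is preserved while genomic clustering is
broken. A selected window is significant if its share exceeds the
(1 − α) quantile of that null. Under a global null the permutation group
makes the observed maximum exchangeable with the null draws, so the
family-wise false-positive rate is ≈ α (measured 5.5% at α = 5% over 200
null datasets). A circular-shift null was rejected at design time: a
shift keeps a contiguous block of large effects contiguous, making the
null equal the observed statistic and destroying power. Gene overlap
uses half-open intervals ([start, end); GFF3 coordinates are converted
from 1-based inclusive).

## Synthetic-data generator

The generator emulates the study's data structure so recovery is
testable: a sire-structured pedigree (founders, then each generation's
sires drawn from the previous generation's males, with configurable
daughter counts so the ≥ 50-daughter selection rule can be exercised);
founder genotypes at Hardy–Weinberg proportions with MAF uniform on a
configurable range, dropped through the pedigree by per-locus Mendelian
sampling (no linkage disequilibrium — a stated non-goal); weather as a
seasonal sinusoid (temperature amplitude 12 °C around 15 °C, relative
humidity 70 ± 15% a quarter-period out of phase, daily noise SD 3,
diurnal spread 8 °C — temperate North-American magnitudes) with RH
clipped to [0, 100]; and phenotypes assembled exactly from the model
equation through the same interval/standardization/basis code used at
fitting time.

Breeding values are drawn by the pedigree-recursive rule
bv = ½(bv_s + bv_d) + m with Var(m) = **G**(½ − ¼(F_s + F_d)) — the
exact N(0, **A** ⊗ **G**) distribution at linear cost. Conception dates
are uniform over the calendar so all covariate quintiles are populated;
gestation is fixed at 114 days. Default truth sits at litter-trait
magnitudes on a percent-of-phenotypic-variance scale: **G** =
[[9.0, 0.6], [0.6, 6.5]], σ²_pe = 15, σ²_e = (30, 32, 34, 36, 38), fixed
slope β = −1.5 (performance declines with heat load). The default
population (120 founders, two offspring generations of 25 sires × 10
daughters, 8–12 parities per sow) yields ≈ 500 recorded sows in 50 sire
families with ≈ 5,000 records and 2,000 SNPs. Litters per sow are set
above the commercial average (~2) to give the permanent-environment
variance repeated records to bind against within a small population.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: linkage disequilibrium and realistic
haplotype structure, selection across generations, farm/climate
heterogeneity (one weather series per dataset by default), within-barn
microclimate, missing weather, litter-level piglet variation, and the
very unbalanced sow/parity structures of commercial data. Secondary
trait columns (beyond the focal trait) carry only plausible marginals,
not the full generative structure.

## Problem sizes used in validation

Stochastic guarantees are exercised at sizes chosen for tight,
repeatable tests: parameter recovery at the default ≈ 500 sows / 5,000
records / 2,000 SNPs with a 20,000-iteration chain (4,000 burn-in);
covariate-screen ranking at ≈ 300 sows / 1,500 records over five
candidate covariates chosen from different variables and well-separated
intervals (weekly climate covariates are strongly autocorrelated, so
near-neighbour intervals genuinely share the GxE signal — ranking among
near-duplicates is not a well-posed recovery target); bootstrap
calibration over 100 null genomes of 309 SNPs × 100 animals at B = 200.

## Known limitations

* σ0² (genetic intercept variance) is weakly identified whenever sow-level
  genetic and permanent-environment effects must be separated mainly
  through family structure; its posterior is prior-sensitive (see
  Priors) and honest intervals are wide.
* The Gibbs kernel stores **H**⁻¹ dense; practical up to a few thousand
  pedigree animals, not at national-evaluation scale.
* The back-solve assumes the VanRaden-2 construction used for fitting;
  alternative weighting schemes (iterated SNP weights) are not
  implemented.
* The covariate screen refits one model per covariate; at the full 95 ×
  traits × populations grid this is embarrassingly parallel but serial
  here.
* Medians of the Γ correlation distribution depend on the grid and on
  the distribution of observed covariate values; only the minimum is
  grid-insensitive and used as a validation anchor.
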