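# Methods

This note documents the statistical models implemented in `canegps`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Trial model and BLUEs

Phenotypic records from a multi-environment clonal trial are described by

    y_ijkl = μ + E_i + R_ij + C_k + EC_ik + G_l + GC_kl + GE_il + GCE_ikl + ε_ijkl

with environment (location–year) E, replicate-within-environment R, crop
type C (plant cane, first and second ratoon), genotype G, their
interactions, and a plot residual. For adjusted genotype means (BLUEs),
genotype is fitted as fixed in cell-means form (no intercept, one
coefficient per genotype) and every other term as random — the standard
two-stage genomic-prediction workflow. Terms whose factor has fewer than
two levels in a data subset are dropped automatically, which handles
unreplicated second-line-style trials (no R term) and single-crop strata
(no C, EC, GC, GCE terms) without special cases.

The REML engine handles arbitrary known covariance structures
`u_k ~ N(0, K_k σ²_k)`. It iterates average-information (AI) updates with
step-halving, falling back to the EM step — which is a guaranteed ascent
direction — whenever an AI proposal fails or decreases the restricted
likelihood; the first two iterations are always EM for stability. Variance
components are floored at 1e-8 × var(y); convergence is declared at a
relative parameter change below 1e-6 (default), capped at 200 iterations
with `converged=False` reported otherwise. Rank-deficient fixed designs
are resolved by QR column pruning (first level = reference). A separate
single-kernel solver (`spectral_reml`) profiles the restricted likelihood
over the variance ratio on the eigenbasis of K with Brent's method; it is
exact, fast, and deliberately kept independent of the general solver so
the two can cross-check each other (and so rrBLUP is a genuinely distinct
route from GBLUP in the equivalence test).

## Heritability

Broad-sense heritability uses the entry-mean form with harmonic means of
the per-genotype counts of environments (ñE), crops (ñC), environment ×
crop cells (ñEC) and plot records (ñECr):

    H² = σ²_G / (σ²_G + σ²_GE/ñE + σ²_GC/ñC + σ²_GEC/ñEC + σ²_e/ñECr)

Harmonic means downweight genotypes observed in few environments, which
matters in a selection funnel where late entries are thinly replicated.
Narrow-sense h² = σ²_A/(σ²_A + σ²_e) is fitted with genotype random under
either the pedigree A matrix or the VanRaden G; with one record per
genotype the spectral path is used.

## Relationship matrices

* Pedigree A: Henderson's tabular method; exact, and verified against
  gene-dropping Monte Carlo in the tests.
* Additive G (VanRaden): dosages centered by 2p and scaled by Σ2p(1−p),
  with allele frequencies taken from the observed panel after mean
  imputation. Monomorphic markers are excluded with a warning.
* Dominance G_D (Vitezica): per-marker coding (−2p², 2pq, −2q²) for
  dosages (0, 1, 2), scaled by Σ(2pq)²; fractional (imputed) dosages are
  interpolated piecewise-linearly between the three codings.
* Epistatic kernels: Hadamard products G_A∘G_A and G_A∘G_D, PSD by the
  Schur product theorem, rescaled to mean diagonal 1 so variance
  components are comparable across kernels (switchable).
* Single-step H (Legarra): G* = (1−τ)G + τA₂₂ blended with τ = 0.05 by
  default for invertibility (τ exposed; the limiting cases τ=0 with all /
  none genotyped collapse to G / A exactly).

Genotype QC follows the usual panel rules: markers with missing fraction
> 0.2 or MAF < 0.1 are dropped; markers in complete LD (r² = 1 on imputed
dosages, sign-invariant) are deduplicated keeping the first in map order.
LD pruning for the density sweep is a greedy in-map-order pass (a marker
is kept iff its r² with every previously kept marker on the chromosome
within a 100-marker window is below the threshold) — deterministic, and
monotone in the threshold by construction. r² is composite LD on dosages;
genotypes are unphased.

## Prediction models

Extended GBLUP fits one REML variance component per kernel; the GEBV is
the sum of all kernel BLUPs plus any fixed-covariate contribution
(genome-wide heterozygosity — the per-genotype fraction of heterozygous
calls, centered — and/or GWAS-selected SNP dosages). Unphenotyped
genotypes are predicted through their kernel covariance with the training
set: û = σ̂²_k K[:, train] P y.

rrBLUP estimates the shrinkage level by spectral REML and recovers marker
effects as β̂ = σ²_β W′V⁻¹(y − Xb̂); GBLUP(G_A) and rrBLUP GEBVs are
mathematically identical, which the suite asserts at r ≥ 0.999.

The Bayesian alphabet is a single-site Gibbs sampler with in-place
residual updates. Priors follow the common R²-split convention: scaled
inverse-χ² with df 5 for all variances, scales set so the prior mode
assigns R² = 0.5 of the phenotypic variance to markers and the rest to the
residual; BayesB/C use a spike-and-slab with π ~ Beta(5,5) (prior mean
0.5); the Bayesian Lasso uses the Park–Casella inverse-Gaussian scale
mixture with λ² ~ Gamma. Defaults are 12,000 iterations, 2,000 burn-in,
thinning 5 → exactly 2,000 retained draws. RKHS builds
K = exp(−h·D²) on squared-Euclidean marker distance scaled to mean 1
(default h = 1), eigendecomposes it and samples the regression on scaled
eigenvectors exactly like Bayesian ridge; h → 0 is flagged degenerate.

The GWAS scan is an uncompressed single-locus mixed linear model in the
EMMA style: the polygenic variance ratio is estimated once under the null
on the kinship spectrum, then each marker is Wald-tested by GLS in the
rotated basis (P3D approximation). Monomorphic markers get p = 1. The G+S
model appends the selected SNP dosages (p < 0.001, capped at the 50
smallest p, QR-pruned if collinear) as fixed effects; an empty selection
falls back to plain GBLUP with a notice. Scans are computed inside the
fold loop on training phenotypes only; a `allow_full_data_scan` switch
exists solely to demonstrate how leakage inflates apparent accuracy.

Random-forest and radial-SVR adapters (scikit-learn) train on centered
dosages; RF is seed-deterministic.

## Multi-trait model

For t traits, `y = μ + Zα + ε` with α ~ MVN(0, Σ⊗K), unstructured t×t
genetic covariance Σ, and ε ~ MVN(0, R⊗I) with R diagonal (residual
covariances are not estimated, matching the standard practice for
compound-trait prediction). Traits are standardized internally and
back-transformed on output. Two fitting routes:

* **EM REML**: the E-step computes the exact posterior of the n·t genetic
  values given the observed cells through the projection matrix P (fixed
  effects absorbed, so the fixed point is the REML optimum — the t=1 case
  matches the spectral solver to 1e-6); the M-step updates Σ from
  E[A′K⁻¹A]/n with a nearest-PSD repair (eigenvalue clipping, counted and
  reported) and the residuals from the standard component-wise form.
* **Gibbs (BMTM)**: inverse-Wishart prior on Σ (df t+2, prior mode 0.5·I
  on the standardized scale), scaled inverse-χ² residuals, data
  augmentation for missing cells. The genetic values are sampled in the
  eigenbasis of K, where their full conditional factorises into n
  independent t×t Gaussians — the sampler is O(n·t³) per sweep. The
  sampler was cross-validated against an independent MCMC on the
  marginal (genetic-values-integrated-out) likelihood. Note the posterior
  mean of a genetic correlation is attenuated relative to the REML mode
  in small or noisy samples (skewed posterior); the recovery test uses an
  informative design for that reason.

Hidden-trait prediction masks the target on the validation ids, keeps the
secondary traits observed there, and reports the single-trait GBLUP
baseline alongside. Sugar yield is the motivating target: it is computed
as SY = CY·TRS (CY = NS·SW) rather than measured, so its phenotype shares
the components' measurement noise, and observing the components in the
validation set is strongly informative — the synthetic compound-trait
experiments build SY the same way.

## Validation

Fivefold CV partitions genotypes into seed-deterministic folds (sizes
within 1); metrics are computed per fold and averaged (pooled-prediction
mode is not the default). Cross-stage validation trains on an early-stage
subset's BLUEs and predicts a later stage from genomic data alone;
genotypes present in both stages are kept in training only (leakage
guard, switchable to reproduce designs with overlapping entries).
Predictive ability is the Pearson correlation between GEBVs and BLUEs.
Coincidence indices select the top (or bottom) ⌈n·0.2⌉ genotypes by each
ranking, breaking ties by stable id order, and report the overlap
fraction; under random ranking the expectation equals the selection
fraction, verified by permutation. The marker-density sweep re-runs a
scheme after LD pruning at the threshold ladder
{0.1, 0.15, 0.2, 0.3, 0.4, 0.6, 0.8, 0.99}; pruning uses genotype data
only, so it is computed once per threshold (not per fold) without leaking
phenotype information.

## Synthetic data generator

The generator emulates the structure the models assume, at configurable
scale (defaults: 567 genotypes, funnel fractions 1.0/0.5/0.25/0.1 over
stages 2–5, 2–6 environments per stage, up to 3 crop types, 1–3 reps,
alternating heavy/light soils):

* Genotypes: diploid dosages {0,1,2}; each gamete is a thresholded
  Gaussian liability mixing a per-block latent haplotype signal (weight
  0.85) with marker noise, giving high within-block r² decaying to ~0
  across blocks; MAF uniform in (0.1, 0.5); optional MCAR missingness.
* Pedigree: founders plus random biparental crosses, topologically
  ordered, with a genotyped flag for single-step tests.
* Traits: four latent traits (TRS, NS, SW, Fiber) built from correlated
  marker effects — additive on centered dosages, dominance on centered
  heterozygosity codes, epistasis on random marker-pair products — with
  components rescaled so the configured variance fractions (default
  0.7/0.2/0.1) are realised exactly; natural-scale means and genetic CVs
  are set to realistic sugarcane values (e.g. TRS 110 kg Mg⁻¹, CY ≈ 66 Mg
  ha⁻¹). CY = NS·SW and SY = CY·TRS hold exactly at the genotypic level;
  the additive part of a compound trait is its first-order (delta-method)
  approximation and the nonlinear remainder is booked as epistatic.
* Trials: one record per genotype × environment × crop × rep with
  independent Gaussian effects for every trial-model term, each sized as
  a multiple of the trait's genotypic variance; stage-to-stage selection
  is truncation on the previous stage's phenotypic mean of one trait
  (default CY).

Not emulated: coalescent-accurate LD, polyploid dosages, spatial field
trend, check-based augmented-design adjustment, and multi-trait visual
selection between stages. Passing tests therefore demonstrate the
estimators' internal correctness and the direction of the main effects
(multi-trait information, marker density, GWAS fixed effects) under a
clean generative model — not performance on aneuploid sugarcane data,
where dosage miscalls, population structure and genotype-by-management
effects add noise the generator does not contain.

## Problem sizes and numerics

The test suite and the acceptance script run everything at desk scale,
chosen so each experiment finishes in seconds to a couple of minutes on
one core: panels of 100–500 genotypes and 100–5,000 markers, 6–30 seed
replicates per stochastic claim, full-length (12,000-iteration) chains
only where the sampler itself is the object under test. Degenerate inputs
are handled explicitly: empty marker panels raise, entirely-missing
markers raise before imputation, monomorphic markers are excluded from
GRMs and get p = 1 in scans, constant response vectors are rejected where
a correlation would be undefined, and singular A₂₂ in the single-step
construction raises with a pointer to blending.
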