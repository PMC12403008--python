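# Methods

This note documents the models implemented in `spatid`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Genomic inbreeding and genotype summaries

`compute_fgrm` implements the per-locus-standardized GRM diagonal

F_grm = (1/L) Σ_i [x_i² − (1+2p_i)x_i + 2p_i²] / (2p_i(1−p_i)),

whose per-locus terms have expectation zero under Hardy–Weinberg proportions
at the reference frequencies. Three consequences drive the implementation:

* **Reference sample matters.** F_grm measures departure from *a stated
  reference*; `fgrm_per_site` scores each individual against its own deme's
  frequencies (the within-population convention), while validation against
  pedigree expectations (e.g. full-sib offspring ≈ 0.25) requires founder
  frequencies. The reference is always an explicit argument.
* **Monomorphic loci** (p = 0 or 1) have an undefined denominator and are
  excluded per individual; L is the per-individual count of loci actually
  summed, reported alongside the estimate.
* The statistic is exactly invariant to allele-label swaps
  (x → 2−x, p → 1−p), which the tests assert to 1e-12.

Filtering runs in a fixed order — locus missingness (≤10%), individual
missingness (≤20%), one-sided exact heterozygote-excess test (α = 0.05,
pooled across demes by default; a per-site flag exists because either
convention is defensible), MAF (≥0.05), then spacing thinning that keeps one
randomly selected locus per ≥100 kbp window (single seeded draw, so the
filter is idempotent and reproducible). The heterozygote-excess test uses
the exact conditional distribution of heterozygote counts given the minor
allele count.

Pairwise π is the probability that one allele drawn from each of two
individuals differs, averaged over loci called in both; the diagonal is left
undefined. PCA mean-imputes missing calls per locus, centers, and fixes each
component's sign by making its largest-magnitude loading positive, making
repeated runs identical. F_ST is Weir & Cockerham's two-population
variance-components estimator as a multi-locus ratio of sums.

LD-based Ne uses squared Pearson correlations of 012 dosages (composite LD —
the data are unphased) over locus pairs on different chromosomes or ≥100 kbp
apart, subtracts the sample-size expectation (1/S + 3.19/S² for S ≥ 30,
0.0018 + 0.907/S + 4.44/S² below), and inverts the random-mating
drift-LD relation; a non-positive drift component reports Ne = ∞, and the CI
is a leave-one-individual-out jackknife. At S = 50 with a few hundred
unlinked loci the estimator's median lands within ~25–30% of truth in
forward Wright–Fisher simulations — the known precision class of this
method at such sample sizes, asserted as such in the tests.

## Pedigree kinship and reproductive success

Kinship is computed by the tabular recursion in a parents-before-offspring
order (cycles are detected and named at construction). Pedigree inbreeding
is *defined* as the kinship of the parents, so the identity
F(child) = k(dam, sire) is exact rather than approximate; gene-dropping
Monte Carlo serves as an independent oracle in the tests.

Reproductive success counts pedigree children with the captive-birth
correction applied to mothers: a lab-born child counts only if it was
encountered in the field after its birth year or has descendants of its own.
`years_contributing` is the number of calendar years in the study window
between an individual's maturity (birth year + 3 by default, the maturation
age of the study species, configurable) and the last year it was known
alive (latest of last capture and last offspring's birth year). Dummy
(unsampled, inferred) parents participate in kinship paths exactly like
genotyped ones, and dummy children count as offspring by default — a dummy
child is evidence of reproduction; both behaviors sit behind flags because
field pedigrees differ in convention.

## Growth

The Fabens formulation of von Bertalanffy growth needs no ages:
ΔL = (L∞ − L₁)(1 − e^(−KΔt)) over first/last capture pairs separated by at
least one winter, fit by least squares with a multi-start K grid
(0.1–1.0) and L∞ started at 1.1× the largest observed length. Candidate
parameterizations (shared / per-site / per-sex / site×sex, independently
for L∞ and K) are compared by AICc under a Gaussian increment likelihood.
Lengths are projected forward or backward exactly along the fitted curve;
ages back-calculated as −(1/K)·ln((L∞−L)/(L∞−L₀)) with birth-year bounds of
±2 years. Size at birth defaults to 19 cm (configurable; neonate size for
the study system). A length at or beyond the asymptote is never shrunk
forward and maps to a configurable maximum age in back-calculation.

## Cormack–Jolly–Seber survival

The likelihood conditions on first capture:

L_i = Π φ_t · Π p_t^y (1−p_t)^(1−y) · χ_last,  χ_T = 1,
χ_t = (1−φ_t) + φ_t(1−p_{t+1})χ_{t+1},

with logit links on both φ and p. Implementation decisions:

* **Unsurveyed site-years** are dummy occasions with p forced to exactly 0,
  keeping all intervals annual; the tests prove this equals the brute-force
  treatment.
* **Covariates** are standardized as (x − mean)/(2·SD) so continuous and
  binary coefficients are comparable. Occasion-varying body size comes from
  the growth module (observed where measured, model-predicted elsewhere);
  the trap-response indicator AFpriorcap2 flags a detection two years
  earlier at adult size (≥45 cm).
* **Optimization** is multi-start BFGS (null start plus jittered starts);
  variance is the inverse observed information via a central-difference
  Hessian; a singular information matrix flags (never drops) the affected
  parameters.
* **AICc effective sample size** defaults to total releases (detections that
  could be followed by a re-observation); the per-individual convention is
  available since the field tools disagree and the difference is small.
* Model selection reports ΔAICc, Akaike weights, k, −2lnL, and flags
  survival coefficients whose 85% CI covers zero (the "uninformative
  parameter" convention) without auto-dropping models.
* The likelihood is verified against exhaustive latent-state enumeration for
  every nonzero history at T ≤ 5 with random covariates (|Δ| ≤ 1e−10).

Calibration experiments (`simulate_histories`) default to staggered entry —
first captures spread uniformly over occasions — matching a field program
that marks animals every year; a single release cohort leaves late occasions
nearly uninformative and degrades Wald calibration.

## Reproductive-output models

The inbreeding load B is minus the F_grm slope of an OLS fit of
ln(offspring+1) on F_grm + site + years contributing. The ZINB mixture is

P(0) = π + (1−π)(θ/(θ+μ))^θ,  P(k>0) = (1−π)·NB2(k; μ, θ),

log link on μ, logit link on π, identical designs in both components (the
a-priori expectation that the same factors drive both), numeric predictors
scaled by their SD. Fitting is direct maximum likelihood on (β, γ, lnθ)
with multi-start BFGS; Wald CIs at 85% and 95%. A dispersion running to the
boundary (θ > 10⁶, i.e. Poisson-like) is flagged rather than hidden. The
mixture pmf is tested to normalize to 1 (cutoff y ≤ 10,000) and the fit is
cross-checked against an independent ZINB implementation's log-likelihood.
Fixed effects only: the candidate set contains no random terms, so a
mixed-model formulation is not needed. `odds_change` converts a logit
coefficient per SD-scaled unit into a percent odds change per raw increment;
the zero-inflation component models the odds of *no* offspring, so the
caller negates the coefficient to speak about the odds of any offspring.

## Spatial structure

Individuals are reduced to capture centroids (single captures keep their
location). Pair classes are assigned with priority dam–offspring >
sire–offspring > parent-pair > unrelated-without-offspring, where
"unrelated" means pedigree kinship exactly zero and neither member has
offspring; the classes partition the analyzed pairs. Distance distributions
are compared by two-sample KS tests with Bonferroni correction (the number
of comparisons defaults to those actually run and is configurable).
Isolation by distance is the Spearman correlation of pairwise π with
centroid distance; significance comes from permuting individual locations
(seeded, 999 permutations by default). The nearby-pair tests build unordered
pairs within 25 m and report pooled-df and Welch variants of each t test,
since either convention is defensible for field data.

## The simulator: what it emulates, what it does not

Defaults describe one study-scale deme and stay fixed: 200 founders, 1,500
unlinked biallelic SNPs at Beta(1.5, 1.5) founder frequencies, a 1,500 m
square arena, 40 m natal dispersal SD, 250 m mating radius with
exp(−d²/2r²) mate weighting, 12 annual occasions, maturity at 3 years,
biennial female reproduction, NB2 litters (mean 4, dispersion 2), baseline
survival logit 1.1 with slopes −3 (true F) and +0.5 (standardized SVL),
baseline no-offspring logit 0.4 with slope +3 on F, detection probability
0.35 with a −0.8 logit trap-shy shift for adult females captured as adults
two years prior, and von Bertalanffy growth (L∞ 66 cm, K 0.5/yr, 19 cm at
birth, 1 cm measurement noise). Under these conditions a run yields
roughly 500–600 sampled individuals with about 7–11% of them above
F_grm = 0.05 and maximum pedigree F of 0.25 — the regime the analysis is
designed for. Two-deme datasets are two independent runs concatenated with
site labels (no migration).

Choices worth knowing:

* The *causal* inbreeding in the fitness functions is pedigree-path F,
  maintained exactly by the kinship recursion as individuals are born, so
  F_grm can be validated as an estimator of it rather than baked in.
* Survival standardizes body size against a fixed reference (45 ± 15 cm),
  not the current cohort, keeping draws reproducible and independent of
  population composition.
* Individuals occupy their birth location for life; the analysis collapses
  recaptures to centroids anyway, so within-life movement would add noise
  the estimators never see.
* Dispersal SD at or above the arena side switches to uniform resettlement:
  clipping an arena-sized Gaussian to the boundary piles offspring in
  corners and corrupts the global-mating null the regime exists to provide.
* True death years are recorded, letting null experiments condition on
  uncensored lifespans (inbred individuals are born late by construction,
  so end-of-study censoring otherwise masquerades as inbreeding depression).
* Within-year event order: births → survey → survival; a newborn can be
  captured in its birth year and can die before the next.

Not emulated: linkage and recombination (loci are unlinked, so LD reflects
drift and family structure only), selection at individual loci and purging,
migration between demes, within-life movement, genotyping error (added
explicitly by perturbation where tests need it), and unsequenced "dummy"
parents — the simulator's pedigree is complete and error-free. Passing
recovery tests therefore demonstrate estimator correctness under the
generative model, not robustness to pedigree-reconstruction error or
real-data artifacts.

## Problem sizes and numerical choices

Test and acceptance experiments run at sizes chosen to make Monte-Carlo
error small relative to the asserted tolerances while keeping the default
suite quick: estimator-calibration experiments use 100–200 replicates at
n = 500–2,000; spatial-emergence checks use 12 replicates of ~70-founder
arenas; the end-to-end determinism check uses two ~55-founder demes with 200
loci. Optimizer tolerances: BFGS gradient tolerance 1e−7 (CJS) / 1e−6
(ZINB), least-squares x/f tolerances 1e−12 (growth); likelihood
probabilities are floored at 1e−300 before logs; pipeline reports serialize
with sorted keys and no timestamps so identical inputs yield identical
bytes.
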