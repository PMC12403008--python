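# spatid

Inbreeding-depression analysis for small, spatially structured wildlife
populations, built around long-term capture–mark–recapture monitoring plus
SNP genotyping — the data situation typical of threatened, hard-to-observe
species such as the eastern massasauga rattlesnake. The package estimates
individual inbreeding genomically and from a pedigree, links inbreeding to
the two fitness components such studies can actually measure (annual
apparent survival and reproductive output in a reconstructed pedigree), and
quantifies the fine-scale spatial kinship clustering that generates
nonrandom mating in the first place. A forward, spatially explicit
population simulator produces every input the pipeline consumes, so each
estimator is validated by parameter recovery against known truth.

## What it computes

**Genomic inbreeding (F_grm).** For individual genotypes
x<sub>i</sub> ∈ {0, 1, 2} and reference allele frequencies p<sub>i</sub>,

    F_grm = (1/L) Σ_i [x_i² − (1 + 2p_i) x_i + 2p_i²] / (2 p_i (1 − p_i))

the diagonal of a per-locus-standardized genomic relationship matrix: zero
expectation under Hardy–Weinberg proportions, positive for homozygosity
excess (weighted toward minor-allele homozygotes), negative for
heterozygosity excess. Supporting genotype machinery: missingness/MAF/
heterozygote-excess/spacing filters, pairwise π, PCA, Weir–Cockerham
F<sub>ST</sub>, replicate-based genotyping-error rates, and the
bias-corrected LD (r²) effective-population-size estimator, all with
jackknife intervals where a CI is standard.

**Pedigree inbreeding and kinship.** The classical recursion
k(i,i) = (1 + F<sub>i</sub>)/2, k(i,j) = [k(dam<sub>i</sub>,j) +
k(sire<sub>i</sub>,j)]/2 with unrelated founders; F of an individual is the
kinship of its parents. Reproductive success is extracted from the pedigree
with the captive-born correction (a lab-born offspring counts toward its
mother only if re-encountered after birth or leaving descendants).

**Survival.** A from-scratch Cormack–Jolly–Seber likelihood with group
factors (site, sex), a static F_grm covariate, an occasion-varying body-size
covariate predicted by a Fabens-fit von Bertalanffy growth model, dummy
occasions for unsurveyed site-years (p forced to 0), and a trap-response
indicator for adult females captured as adults two years earlier. Candidate
models are ranked by AICc with Akaike weights; survival is predicted with
delta-method CIs across the observed inbreeding range at fixed body size.

**Reproduction.** The inbreeding load B (minus the slope of ln(offspring+1)
on F_grm, controlling for site and opportunity years) and zero-inflated
negative binomial regression — log-link NB2 counts plus a logit-link
excess-zero component on the same design — separating "fewer offspring among
parents" from "no offspring at all", with 85% and 95% Wald intervals.

**Spatial structure.** Capture centroids, pair classification
(dam–offspring / sire–offspring / parent pairs / unrelated without
offspring), Kolmogorov–Smirnov distance-distribution tests with Bonferroni
correction, isolation by distance (Spearman π-vs-distance with permutation
p), and the within-25-m t tests that control spatial confounding of the
inbreeding–reproduction association.

**Simulator.** Overlapping generations on a continuous arena: Beta-drawn
founder allele frequencies, Gaussian natal dispersal, proximity-weighted
mate choice within a mating radius, negative-binomial litters with a
logit-linear excess-zero draw, Mendelian transmission at unlinked SNPs,
logit-linear inbreeding depression on survival, von Bertalanffy growth, and
imperfect detection with the biennial adult-female trap response. True
pedigree inbreeding is maintained exactly via the kinship recursion as
individuals are born.

## Worked example

```python
import spatid

cfg = spatid.SimulationConfig(seed=7)          # one study-scale deme
ds = spatid.simulate_population(cfg)
sampled = sorted(ds.captures["id"].unique())

est = spatid.fgrm_per_site(ds.genotypes.subset_ids(sampled))
f = est.as_series()
r, df, p = spatid.fgrm_vs_pedigree_f(f, spatid.pedigree_inbreeding(ds.pedigree))

rec = spatid.reproductive_success(ds.pedigree, captures=ds.captures)
rec = rec.merge(f.rename("fgrm"), left_on="id", right_index=True)
load = spatid.inbreeding_load(rec)

cent = spatid.capture_centroids(ds.captures)
ks = spatid.ks_compare(spatid.classify_pairs(ds.pedigree, cent, rec))
```

Output of the full script (printed values, seed 7):

```
simulated 817 snakes over 12 years; 522 sampled in 1005 captures
F_grm range: -0.077 to 0.302; 11.1% of individuals above 0.05
genomic vs pedigree inbreeding: r(520) = 0.924, p = 1.12e-218
inbreeding load B = 0.89 (SE 0.45, n = 522)
dam-offspring vs unrelated distances: KS D = 0.98, Bonferroni p = 0.00e+00
```

Reading it: a minority (~11%) of individuals carry elevated inbreeding, the
genomic estimator tracks the true pedigree coefficient tightly, log
reproductive output declines with F_grm (the load B, here generated with
depression acting through both survival and the chance of breeding at all),
and offspring settle much closer to their mothers than unrelated animals
live to each other — the spatial clustering that sustains nonrandom mating.
`spatid.run_pipeline` chains all stages (filtering → F_grm → pedigree
metrics → growth → CJS model selection → load/ZINB → spatial tests) into a
single deterministic JSON report.

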