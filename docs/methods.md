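# Methods

This note records the models implemented in `geoffset`, the assumptions
behind the synthetic landscape that drives them, the numerical choices
that were genuinely open, and what the passing tests do and do not show
about real data.

## Synthetic landscape

The generator (`geoffset.synthetic`) produces the dataset a range-wide
resequencing study of a wind-dispersed temperate tree would yield, at
desk scale. Defaults are the study conditions and are not tuned per run.

**Space and populations.** 24 populations are placed uniformly in a
10° × 13° lon/lat box, half south and half north of a fixed split
latitude; the two halves are the ancestry groups. Each population
contributes 10 diploid individuals.

**Climate.** All climate surfaces are deterministic functions of
(lon, lat) built from random Fourier features (random-cosine expansions
approximating a squared-exponential Gaussian field), so populations and
any grid lattice see the same fields and every output is bit-reproducible
from the seed. Nineteen variables (BIO1–BIO19 naming; the first ten
temperature-like, the rest precipitation-like in their units) load on six
latent fields, each latent being a random linear gradient plus smooth
noise. The first variable of each latent group is the designated causal
variable (loading 0.95); the others are noisier correlates (loadings
0.55–0.85), which makes pairwise correlations span both sides of the 0.6
pruning threshold. Future surfaces add, per climate model and variable, a
shared directional shift (warming for temperature, mixed-sign for
precipitation) plus a model-specific smooth field, all multiplied by the
scenario scale (SSP126 = 1, SSP370 = 2). The scenario ordering is
hard-wired so "higher emissions → larger offsets" is a testable property
rather than an accident of one draw.

**Genetics.** Neutral loci: ancestral frequency ~ U(0.1, 0.9), then a
hierarchical Balding–Nichols cascade — ancestral → ancestry group
(F = drift_F/5) → population (F = drift_F, default 0.05). The
between-group F is deliberately a small fraction of the within-population
drift: the emulated system shows weak north/south divergence relative to
local drift, and the hierarchical cascade is what makes both the PC1
group split and positive isolation by distance emerge. Adaptive loci
(100 of 5100): logit(p_pop) = α + β·z(e_causal) with |β| ~ U(0.5, 1.5),
random sign, causal variables assigned round-robin, plus logit-scale
noise (SD 0.25, a free design choice fixed once). Genotypes are
Binomial(2, p_pop) with 2% missingness. Variant classes (SNP 89%, indel
10%, SV 1% as symbolic `<DEL>` alleles) and functional categories
(noncoding 90%, synonymous 5%, tolerated 3%, deleterious 1.5%, LOF 0.5%)
are annotation labels only — they do not alter the frequency model. The
ancestral allele is REF throughout, so derived = ALT.

**What the generator does not emulate** — linkage disequilibrium (loci
are exchangeable and independent; the LD-pruning operation is exercised
on data where it should remove almost nothing), recombination and
demography through time, selection dynamics, genotype imputation, and
real BIOCLIM covariance structure. Passing tests therefore certify the
statistical machinery and its calibration, not robustness to LD
structure, call-rate artefacts or model misspecification in real data.

## GEA scans

**Latent-factor scan.** The scan is the deterministic least-squares
latent-factor estimator: K = 3 factors are the leading left singular
vectors of the genotype matrix *residualized on the full environmental
design* (the ridge limit of the joint estimator). Estimating factors on
the raw matrix lets them absorb the shared clinal signal of the adaptive
loci and destroys power; the residualized form keeps factors orthogonal
to the tested predictors while still capturing structure. Per variable,
OLS of mean-imputed dosage on [1, z(e), U] gives z = β/SE; the genomic
inflation factor λ = median(z²)/median(χ²₁) recalibrates the scan
(λ ≈ 2–3 on the default landscape, driven by population-level drift that
three factors cannot fully absorb), and BH q-values are computed per
variable with hits unioned across variables. Individuals inherit their
population's climate, so the effective replication is the 24 populations,
not the 240 individuals — λ-calibration is what keeps the null uniform
despite that.

**RDA outliers.** Population frequencies (centered, mean-imputed) are
constrained on the standardized kept variables; axes come from the SVD of
the fitted values. Loadings are the **right singular vectors** (raw
species scores), not variant–axis correlations: a variant's score folds
in its frequency variance, and with the 3 SD outlier rule this is the
only workable choice — correlation-loadings give a cutoff larger than 1
whenever neutral structure correlates with the constrained axes. Axis
signs are fixed by making the largest-magnitude site score positive.
The first 3 axes are scanned by default (configurable).

**Variable pruning.** Greedy walk in descending turnover-importance
order, keeping a variable iff |Spearman r| < 0.6 with everything already
kept. The ranking model is fit on the LFMM hit set (100 trees); the
pruned set typically mixes causal variables with close proxies, which is
inherent when causal and proxy variables correlate at r ≈ 0.8.

**Known power limit.** On the default landscape the core set recovers
~75% of planted loci at ~5% FDR. The missing quarter is the weak-effect
tail: loci with |β| ≤ 0.75 have clinal variance comparable to the
binomial sampling noise of 20 alleles per population and are not 3 SD
species-score outliers on any axis (41% flagged in that band vs 100% for
|β| > 1.25). This is a property of the stated conditions, not of the
implementation — the ceiling is unchanged under oracle variable
selection, all 19 variables, or all constrained axes.

## Turnover model and offsets

Per core locus, 500 fully grown CART regression trees (scikit-learn,
`max_features = ⌈P/3⌉`) are fit to population frequencies with
populations bootstrapped as the sampling unit. Every split's variance
reduction is logged at its threshold; within a locus the split weights
are normalized to sum to the locus's out-of-bag R² (loci with R² ≤ 0 are
dropped), aggregated across loci, and globally normalized so the
cumulative-importance functions sum to 1 at +∞. Functions are
right-continuous step functions, clamped to their boundary values outside
the fitted range. Conditional (extended-forest) permutation importance is
deliberately simplified to impurity-decrease importance: deterministic,
testable, and yielding the same monotone turnover object. One visible
consequence of variance-reduction split placement: a single locus with a
linear response produces an S-shaped rather than linear cumulative curve
(splits concentrate mid-range); aggregation over many loci softens this.

Offsets are Euclidean distances in transformed-climate space as defined
in the README. Forward offsets search grid cells (not continuous space)
with great-circle distances (haversine, R = 6371.0088 km) between cell
centers; an empty reachable set under a small cap yields NaN with a
warning rather than an error. RGB composites min–max scale each metric
over the grid to [0, 255], rounding half-up, with constant channels
mapped to 0 (the stretch is recorded here because no canonical choice
exists).

**RONA** uses the fitted value at current climate as the baseline
(RONA = |b|·|Δe| after clipping fitted frequencies to [0, 1]): the
quantity is the regression-implied shift, which makes the closed form
exact; an observed-frequency baseline is available via the per-locus
regression table. Regressions are fit once on current climate and
projected into each model's future, then averaged across models
(mean ± SE); per-variable values are reported without cross-variable
aggregation.

## Supporting statistics

* **F_ST** — Weir–Cockerham per-site a/b/c components; multi-site
  estimate is the ratio of sums ("weighted" convention, matching the
  common VCF tooling default). Negative pairwise θ is kept in
  `FstResult` and clamped at 0 only when linearizing to θ/(1−θ) for
  distance matrices; θ = 1 maps to a large sentinel with a warning.
  Sites where any population has no called individuals are skipped.
* **π** — per population, Σ_sites c_ref·c_alt/C(n, 2) divided by a
  caller-supplied total callable-site count (the synthetic default is
  the number of simulated sites, so values are per variant site, not
  per bp).
* **LD pruning** — plink-style sliding window (50 variants, step 10,
  r² > 0.2 removes the later variant), deterministic in input order.
* **PCA** — SVD of the column-centered, mean-imputed dosage matrix;
  population scores are means over members. Mean imputation is used for
  PCA and the scans only; counting statistics use observed alleles.
* **Mantel / partial Mantel** — Pearson r on strictly-lower-triangle
  entries; one-sided upper p from joint row/column permutations,
  p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm). The partial test uses the
  residual method (residualize both matrices on the control by OLS) with
  raw-matrix permutation of the first matrix; the controlled matrix is
  recorded in the result.
* **Variance partitioning** — multivariate redundancy R² for the 7
  nested models of {climate, geography (lon/lat), structure (3 PCs)},
  each Ezekiel-adjusted (1 − (1−R²)(n−1)/(n−p−1)); exclusive and shared
  fractions by inclusion–exclusion, so fractions sum to the full-model
  adjusted R² exactly (individual fractions may be negative).
* **Load** — derived-allele counts per functional category relative to
  synonymous; the default numerator is dosage-weighted allele counts
  (sample-size robust, invariant to duplicating individuals), with a
  segregating-variant mode available because "number of derived
  mutations" is ambiguous between the two. SV burden excludes
  individuals with no heterozygous SNPs (with a warning). Spearman
  correlations use average ranks and the two-sided t approximation.

## Problem sizes and determinism

The default analysis uses 24 × 10 individuals, 5100 loci, a 20 × 20
offset grid, 999 Mantel permutations, 1000 random draws in the F_ST
contrast, 500 trees per locus in the final turnover fit (100 for the
ranking fit inside the GEA stage), and 500 replicates in the type-I
calibration checks — sizes chosen so the full suite and the acceptance
script each complete in minutes on one CPU while keeping Monte-Carlo
error well inside the asserted tolerances. Every stochastic component
takes an explicit seed; the pipeline writes a manifest of parameters and
artifact checksums, and reruns with the same config are bit-identical.

## Known limitations

Beyond the generator's non-goals listed above: the Bayesian MCMC variant
of the latent-factor scan (run-averaged p-values) is out of scope; RDA
significance is the SD-cutoff rule, not permutation ANOVA; windowed
genome scans are omitted because the synthetic loci carry no LD
structure; and genotype imputation is not performed — all statistics use
observed alleles and must tolerate missing cells.
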