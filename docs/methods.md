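# Methods

`gxepred` implements an enviromics-aided genomic prediction pipeline for
wheat quality traits in multi-environment trials: relationship matrices
from pedigree and markers, an enviromic relationship matrix from monthly
weather and soil covariates, Bayesian kernel reaction-norm models fitted
by Gibbs sampling, leave-one-year-out validation, climate-ensemble bias
correction and trait projection, and downstream stability, risk and
covariate-attribution analyses.  Everything runs on synthetic data whose
statistical structure mirrors a national variety-testing series, so every
stage is testable offline.

## Relationship matrices

**Pedigree kinship (A).** Recursive tabular kinship,
phi(i,j) = (phi(p1,j) + phi(p2,j))/2, with unrelated founders at zero.
All lines are inbred: with `g` extra selfing generations (default 6) a
line's inbreeding coefficient is F = 1 − (1 − phi(p1,p2))·2^−g, so the
self-kinship (1+F)/2 approaches one (0.9921875 at g = 6 for a line from
unrelated parents).  Founders are treated as fully developed inbred lines
too — this is what makes full sibs of unrelated parents come out near
0.5, the value expected for inbred sib lines.

**Marker QC.** Markers with more than 10% missing calls or minor-allele
frequency below 0.05 are removed (both boundaries retained at equality).
Remaining gaps are filled by iterative per-column random-forest
imputation (column-mode initialisation, at most 5 rounds, 30 trees,
seeded).  Redundant markers are pruned by a greedy left-to-right scan
dropping any marker whose absolute Pearson correlation with an
already-kept marker exceeds 0.8; absolute correlation is used because the
sign of a marker's coding is arbitrary.

**Genomic kinship (G) and blending (H).** G = MM′/p with each marker
column centred and scaled to unit population standard deviation, so
mean(diag G) = 1 exactly.  G is put on A's scale by the affine map
Gs = a + b·G solving two moment equations (matching A's mean diagonal and
mean off-diagonal over shared genotypes), then blended as
H = ω·A + (1−ω)·Gs with ω = 0.2; pairs involving an ungenotyped line keep
their plain A value.  The two-moment match is one of several published
ways to rescale G; it is exact, deterministic, and invariant to affine
transformations of G.

For fully inbred lines the VanRaden off-diagonal estimates the kinship
coefficient itself (each line carries one allele per locus and G is a
correlation-scale matrix), so the gene-dropping consistency check
regresses G's off-diagonals on A's and expects a slope near one.

## Enviromic relationship matrix

Each trial environment (harvest-year × location) is characterised by 7
monthly weather variables over the October–August season (rainfall, mean/
min/max temperature, relative humidity, sea-level pressure, wind speed)
plus 7 static soil properties (sand/clay/silt, organic carbon, nitrogen,
pH, cation-exchange capacity): 84 covariates.  Season months October–
December belong to the preceding autumn of the same harvest year.  The
EC matrix is column-centred and scaled (sample sd; zero-variance columns
dropped), and the kernel is

    Omega = exp(−h · D / theta)

with D the squared-Euclidean distance matrix between environment rows,
theta the mean of all q² entries of D (zero diagonal included) and
bandwidth h = 1.  Squared distances in both numerator and scale give the
exact two-environment closed form exp(−2) and make Omega invariant to any
uniform rescaling of the ECs.  All covariates enter the kernel — no
feature selection.

## Kernel models

All models have the form y = μ1 + Σ_k u_k + ε with u_k ~ N(0, σ²_k K_k)
and independent residuals, over observation-level kernels built from the
trial design:

| model | components | kernels |
|---|---|---|
| MM    | E, g          | KE = ZE ZE′, Kg = Zg H Zg′ |
| MDs   | E, g, gE      | + KgE = Kg ⊙ KE |
| RNMM  | E, W, g, gW   | + KW = ZE Ω ZE′, KgW = Kg ⊙ KW |
| RNMDs | E, W, g, gE, gW | all of the above |

E is the iid environment effect; W is the enviromic main effect — the
part of environmental variation predictable from the covariates — and gW
is the genotype-specific reaction norm.  E and W have strongly
overlapping kernel spans (Ω has a near-unit diagonal), so their separate
variances are weakly identified; their sum, the total environment main
effect, is the well-identified quantity and is what parameter-recovery
checks compare.  W and gW are the only components with non-zero
cross-covariance to unseen environments, which is why only the
reaction-norm models give environment-specific predictions in new years.

**Sampler.** Blocked Gibbs in each kernel's eigenbasis: writing
K = VΛV′ and u = Vα, the full conditional of α given the partial
residual is diagonal, giving O(n·rank) updates per sweep.  The bases
exploit kernel structure — KE and KgE are block-diagonal over
environments, Kg and KW have rank at most the number of genotypes/
environments (their orthonormal eigenvectors come from count-weighted
group-level problems); only KgW needs a dense decomposition.
Eigenvalues below max(1e−8, 1e−10·λmax) are truncated; a kernel with an
eigenvalue below −1e−6·λmax is rejected as non-PSD.  Variances carry
scaled-inverse-chi-square priors with df = 5 and scale set so each
term's prior mean is var(y)/(number of variance terms); the intercept is
flat.  Default run length 10,000 iterations, 2,000 burn-in, thinning 2;
chains are reproducible under seed.  Constant responses are handled by
flooring the prior variance scale at 1e−6.

**Prediction.** New genotype × environment rows are predicted by the
conditional mean at the posterior-mean variance components (plug-in
BLUP): each component contributes σ̂²_k K_cross,k C⁻¹(y − μ̂) with
C = Σ σ̂²_k K_k + σ̂²_ε I over the training rows.  This form never
inverts a singular component kernel on its own, so it is stable under
Monte Carlo noise in the effect chains.  E and gE have zero
cross-covariance with unseen environments and contribute nothing there;
for training environments (or exact training pairs) they contribute
their in-sample conditional means.  Grid projections factorise the same
formula through per-genotype and per-pair coefficient sums, so a
68,280-record genotype × grid-cell × scenario block never materialises
an observation-level kernel.

**Bivariate trait model.** Trait pairs are fitted jointly on complete
cases (rows holding both traits): matrix-variate genetic effects with row
covariance Zg H Zg′ and 2×2 column covariance Ug, iid environment-level
effects with column covariance UE, and unstructured 2×2 residual
covariance.  Inverse-Wishart priors are weakly informative (minimal
proper df, prior mean var(y)/20 per component) so the data dominate;
correlations are computed from posterior-mean covariances.  Defaults:
10,000 iterations, 5,000 burn-in, thinning 2.

## Cross-validation

Leave-one-year-out for untested genotypes in untested years: each year's
observations form the test set and every genotype occurring in that year
is also removed from training, so test genotypes connect to training only
through H.  Year-mean accuracy correlates year-pooled observed and
predicted means across years (observations weighted equally); within-
trial accuracy correlates observed and predicted values across genotypes
per trial, skipping trials with fewer than three test genotypes or
constant values.  Models are compared by two-sided paired t-tests over
the common trial set.

## Climate projection

Ensemble members are bias-corrected per location × variable × calendar
month × member:

    Xbc(t) = O̅_B − X̅_B + X̅_fut + (σ_O / σ_XB) · (X(t) − X̅_fut)

over a 2000–2019 baseline and 2050–2069 future window by default.
Rainfall and wind are handled on the natural-log scale and relative
humidity as the log saturation deficit log(100 − RH), so corrected values
respect physical bounds structurally; the correction's two moment
identities (corrected mean = O̅ + change signal; corrected sd =
σ_O·σ_fut/σ_XB) hold exactly in transformed space.  Corrected series feed
two environment sets: a climatological pair per grid cell (observed
average vs future average, for mean climate-change maps) and year samples
(one environment per member × year × location, for year-to-year
variability).  Missing soil cells are imputed with column medians.

## Stability, risk, attribution

Finlay–Wilkinson joint regression fits each genotype's predictions
against the mean of all genotypes per environment; on any balanced
matrix the slopes average exactly to one.  The risk index is the
percentage of projected year environments failing the milling-quality
rule (protein within [11, 13]%; HFN > 250 s; specific weight > 76 kg/hl;
Chopin W > 170; Chopin P/L < 0.9; Zeleny > 30 — one-sided rules strict,
the protein window closed).  Covariate attribution fits one random
forest per trait × location (500 trees, a third of features per split,
minimum leaf 5) to the environment-mean predictions, reporting
impurity-based importance max-scaled per panel, alongside signed Pearson
correlations for direction.

## Synthetic data

The generator emulates a two-decade national variety-testing series:

* **Pedigree/markers.** Founder lines crossed in later generations;
  biallelic markers gene-dropped with full selfing to homozygosity
  (calls 0/2), founder frequencies uniform in a configurable range, so A
  and G agree by construction.
* **Trial network.** Per year, a uniform number of single-location
  trials in the configured range (default 15–29); each genotype is
  tested during a contiguous window of years (geometric length, mean 4),
  reproducing variety turnover and the train/test confounding the CV
  must survive.
* **Weather.** Monthly values follow seasonal sinusoids plus persistent
  location anomalies, a year anomaly shared across locations, and
  residual monthly noise.  Anomalies at every level load on two latent
  factors (thermal, moisture) plus variable-own noise: the three
  temperature variables are nearly collinear, humidity co-varies with
  moisture (+) and temperature (−), and rainfall and wind live on the
  log scale.  The location contrasts are set to realistic regional
  gradients (≈1.8 °C in temperature, a 2–4× rainfall range); without
  both the gradients and the factor couplings, the 84-column EC space
  has such a high effective dimensionality that pairwise distances
  concentrate and the Gaussian kernel loses the between-environment
  contrast that real trial networks show — and with it any transferable
  enviromic signal.  Ensemble members add a per-member mean bias and a
  log-normal variance inflation so bias correction is a non-trivial
  step; future years add a configurable mean shift and variance scaling.
* **Soil.** Seven per-location constants (texture from a Dirichlet,
  chemistry log-normal/normal).
* **Phenotypes.** y = μ + E + W + g + gE + gW + ε with E iid per
  environment, W ~ MVN(0, σ²_W Ω), g ~ MVN(0, σ²_g H), gE independent
  MVN(0, σ²_gE H) per environment, gW matrix-normal with row covariance
  H and column covariance Ω, and iid noise.  Component variances are the
  configured fractions of the squared trait sd divided by mean kernel
  diagonals, so realised variances hit the fractions.  Trait intercepts
  and sds default to quality-criteria midpoints with field-realistic
  dispersions (e.g. HFN 280 ± 45 s).  The W fraction defaults to zero;
  analyses that emulate weather-driven seasons set it explicitly.

**What the generator does not emulate:** daily weather and its temporal
autocorrelation, spatial correlation between neighbouring grid cells,
genotype-by-management effects, selection/attrition bias in which
genotypes stay in trials, non-Gaussian trait distributions (e.g. the
hard floor of HFN at 62 s), and CO₂ trends.  Passing tests therefore
show that every algorithmic stage behaves correctly under the assumed
covariance structure — not that the models would reach any particular
accuracy on real trial data.

## Problem sizes in tests and analyses

Test fixtures use networks of 30–240 genotypes over 4–12 years (up to
~2,300 observations), full-length chains (10,000 iterations) only where
a check needs converged variance estimates, and reduced chains
(2,000/500) for the model-comparison replicates, matching the reduced
setting used for cross-validation experiments.  The bundled analyses run
a 120-genotype, 10-year study with a 6-member ensemble and a 150-cell
grid.  Design-count checks run the full UK-scale design (1,707 12-km
grid cells, 12 members × 20 years × 3 locations) because those counts
are structural and cost little beyond memory-friendly chunking.

## Known limitations

* E and W variance components are reported separately but only their sum
  is well identified; interpret the split cautiously.
* The bivariate model analyses complete cases; under informative
  missingness across traits its correlations would be biased.
* Variance components for a null reaction-norm term do not shrink fully
  to zero at small n (a few percent of total variance remains at
  n ≈ 1,000; below 5% needs n ≈ 2,000).
* The greedy pruning and two-moment G-scaling are deterministic
  conventions; other published choices would give slightly different H
  matrices.
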