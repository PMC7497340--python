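# Methods

This note documents the models, the numerical choices behind the REML
engine, what the synthetic-trial generator does and does not emulate, and
the sizes at which the simulation studies run.

## Vegetation indices

Indices are computed from plot-level *mean* band reflectances expressed as
fractions in [0, 1]. The pure band ratios (NDVI, GNDVI, NDRE, Ratio) are
invariant to a common rescaling of all bands; SAVI and EVI are not, because
their soil/aerosol terms (`L = 0.5`, the `+1` in EVI) are additive
constants on the reflectance scale — inputs scaled 0–100 would silently
change them, which is why the readers validate fractions. EVI is not
clamped to [−1, 1]; the formula can legitimately leave that interval.
Batch computation keeps rows with zero denominators as flagged missing
records so a handful of bad plots cannot abort a season's pipeline, while
the single-record API raises. A log10 transform is available; these
bounded, negatively skewed indices gave indistinguishable mixed-model
results with and without it, so the pipeline default is untransformed.

## Genomic relationships for single-cross hybrids

Parental inbred panels are screened per marker (missingness > 0.15,
MAF < 0.01, heterozygosity > 0.01 — the last being an inbred-specific
genotyping-error filter), with each removed marker attributed to the first
failing filter in that order. Missing calls are imputed with the marker
mode; ties break toward the lower genotype code so imputation is
deterministic. Each panel then yields a VanRaden method-1 GRM with allele
frequencies computed *within* the panel (centering by 2p, denominator
2Σp(1−p)); method 1 is that citation's primary formula and the default
choice when no variant is named. With the maternal and paternal pools
assumed unrelated, hybrid relationships average the corresponding parental
relationships, including on the diagonal. Hybrids sharing both parents
make this matrix exactly singular, so a diagonal ridge of 1e−6 is added
and, if needed, the spectrum floored, purely for numerical invertibility
in the mixed-model equations; the fitting engine itself never inverts a
relationship matrix (see below), so even a barely regularized G is safe.
One scale consequence worth knowing: fully inbred parental panels have
VanRaden diagonals ≈ 1 + f ≈ 2, so the hybrid GRM diagonal is also ≈ 2 and
the GBLUP σ²_a (defined per unit of relationship) is about half the
plot-level genetic variance. Heritabilities computed as
σ²_a/(σ²_a + σ²_e) inherit that scale; genetic correlations, BLUP rankings
and prediction accuracies do not, because the factor cancels.

## The REML engine

Every model here has marginal covariance linear in its parameters,
V(θ) = Σ_c Z_c(Σ_c ⊗ K_c)Z_c′, where each random term owns a known
structure K (a GRM, or the identity) and an unknown d × d covariance Σ
among its effect blocks. Residuals are represented the same way — a
selector design with K = I — which is what lets one engine serve all three
models:

- ST-GBLUP: a genetic scalar (K = G) plus a residual scalar.
- Bivariate GBLUP: a d = 2 genetic term (Σ_g ⊗ G) plus a d = 2 residual
  term over plots. A record of trait t on plot j loads residual column
  (t, j), so jointly recorded plots get the full 2 × 2 residual covariance
  and single-trait plots contribute only their marginal variance — the
  standard unbalanced multi-trait treatment, and exactly what fold-masked
  cross-validation needs.
- Random regression: a d = m genetic term (Σ_a ⊗ G, spline covariables in
  Z), a d = m permanent-environment term per plot, and one residual scalar
  per flight.

Fitting is EM with average-information (AI) acceleration. The first three
iterations are EM; afterwards an AI step is attempted and accepted only if
it does not decrease the restricted log-likelihood. When the full Newton
step fails — typical once an estimate reaches the PSD boundary, where the
Newton direction points outside the cone — the step is retried under
escalating Levenberg damping (λ·diag(AI) added to the AI matrix), which
keeps making progress in the interior directions; failing that, an EM step
is taken and then amplified along its own direction as far as the
likelihood keeps improving (monotone EM extrapolation). EM steps use the
matrix update
Σ ← Σ + (1/q)·Σ(W − T̃)Σ with W[t,s] = g_t′K g_s, T̃[t,s] = tr(K(Z′PZ)[t,s])
and g = Z′Py, which needs no K⁻¹ — this is why singular relationship
matrices and PSD-boundary covariances are handled without special cases.
The likelihood history of every fit is therefore monotone by construction,
and the test suite asserts it per iteration.

Numerical choices:

- **Convergence**: |Δ restricted log-likelihood| < 1e−8 *and* relative
  parameter change < 1e−6 (both configurable). Estimates pinned at a
  boundary (a variance → 0, a correlation → 1) keep creeping in parameter
  space long after the likelihood is flat, so five consecutive
  sub-tolerance likelihood changes also declare convergence. The
  Monte-Carlo studies use tol = 1e−6, far below their measurement noise.
  On permanent-environment/residual ridges the stopping point can sit a
  fraction of a log-likelihood unit below the exact optimum; refitting at
  tol = 1e−8 moves Σ_a by well under 1% there, which is why the looser
  tolerance is acceptable for the studies.
- **Starting values**: half the phenotypic variance per component;
  bivariate covariances start at 0.5·√(σ₁₁σ₂₂)·0.1.
- **Bending**: any interim Σ that is not positive definite has its
  eigenvalues floored at 1e−6 × trace and is reconstructed; bendings are
  counted on the fit.
- **Trait scaling**: the bivariate model standardizes each trait
  internally and back-transforms Σ_g, Σ_e and the BLUPs. Grain yield
  (variance ~10³) next to NDVI (variance ~10⁻³) otherwise puts the
  trace-based bending floor on the order of the smaller trait's entire
  variance.
- **Fixed effects**: intercept + replicate for single/multi-trait models;
  saturated replicate × flight cell means for the random regression. No
  other covariates.
- Non-convergence is flagged on the result, never raised; standard errors
  come from the inverse AI matrix at the optimum.

## Thermal time and the spline basis

Daily GDD is (Tmax + Tmin)/2 − 10 °C with each temperature first floored
at 10 °C and capped at 30 °C, so daily values lie in [0, 20]. Accumulation
includes both the planting day and the flight day (the convention is
otherwise arbitrary; it only shifts all cumulative values together).
Covariables are the linear-spline weights of the two flanking knots;
observations outside the knot range raise rather than extrapolate. Knot
placement is configuration — by default the first, middle and last flight,
or the first two plus last two when four knots are wanted; with only 4–6
flights per season there is no meaningful scope for knot optimization.
Permanent-environment coefficients are indexed by plot and absorb the
correlation of repeated records on the same plot, which is why the
residual structure can stay diagonal with one variance per flight. The
fitted Σ_a is a covariance function: cov(t, s) = z(t)′Σ_a z(s), exact at
knot pairs and piecewise bilinear between them.

## The synthetic-trial generator

The generator is the package's study system: one site-year of a hybrid
trial. Parents are near-homozygous inbreds at independent biallelic
markers with uniform allele frequencies in [0.05, 0.5]; hybrids are random
distinct (mother, father) crosses; the layout is an RCBD with two
replicates; weather is a sinusoidal temperate season (≈17 °C at planting,
≈25 °C mid-season mean, ±7 °C diurnal spread) that exercises both GDD
clamps. VI trajectories follow the spline model exactly: hybrid
coefficient vectors with covariance Σ_a ⊗ G (drawn through PSD square
roots, negative eigenvalues floored at zero), iid plot
permanent-environment vectors, per-flight residuals, on a logistic mean
curve in (0.2, 0.95) that saturates the way canopy NDVI does. Default
true parameters put per-flight VI phenotypic variance at a few thousandths
with heritabilities rising through the season (≈0.45–0.65), inside the
range real trials report. Flights sit at 524, 759, 816, 1157 and 1501
cumulative GDD — values taken from a real flight schedule — with knots at
524/816/1501. End-of-season traits are built from the VI genetic value at
a chosen flight: r·(standardized VI genetic value) + √(1−r²)·(independent
G-structured deviate), with the independent part orthogonalized in sample
and the genetic/residual scales set empirically, so the *realized* genetic
correlation and heritability hit their targets rather than merely their
expectations. Defaults are h² = 0.3 and r_g = 0.9 on a grain-yield-like
scale (mean 150, phenotypic variance 1650).

What the generator does **not** emulate: linkage disequilibrium (markers
are independent), genotype-by-environment interaction (each dataset is one
site-year), spatial field trend beyond the replicate effect, band-level
reflectance (VI values are generated directly), and selection structure in
the hybrid set (crosses are random). Passing tests therefore demonstrate
correctness of the estimators under the models' own assumptions, not
robustness to violations of them.

## Simulation studies and their sizes

The studies in `vigblup.studies` (run by both the test suite and
`scripts/acceptance.py`) use sizes chosen as the smallest at which the
checked property is comfortably identified:

- **ST recovery**: 400 hybrids × 2 replicates, σ²_a = 500, σ²_e = 850
  (grain-yield scale, h² = 0.37), 20 seeds; the mean ĥ² must sit within
  ±0.04 of truth and every likelihood history must be monotone.
- **MT recovery**: 300 hybrids, both traits h² = 0.3, true r_g ∈ {0, 0.8},
  20 seeds each; mean r̂_g within ±0.1 (null) and ±0.15 (strong).
- **RR fidelity**: 300 unrelated hybrids, 5 flights, 3 knots. The genetic
  correlation matrix across flights reconstructed from Σ̂_a is compared
  with the correlations from all 10 pairwise bivariate fits (max absolute
  deviation ≤ 0.1), and RR genetic effects at each knot are correlated
  with per-time genetic BLUPs averaged over the pairwise fits containing
  that flight (≥ 0.9). Unrelated hybrids are used here so the comparison
  measures the covariance function rather than GRM shrinkage; relatedness
  is exercised end-to-end by the CV study. Since only bivariate models are
  in scope, pairwise fits stand in for a single all-flights multi-trait
  model.
- **CV gain**: full pipeline (parents → GRM → VI → trait) at 150 hybrids
  from 15 × 15 parents, 10 seeds per scenario. With r_g = 0.9 and trait
  h² = 0.3 the bivariate model must beat the single-trait model on
  identical folds in ≥ 8/10 seeds; with r_g = 0 the mean gain must be
  indistinguishable from zero. Accuracy is fold-averaged Pearson
  correlation between masked plot phenotypes and predicted genetic values
  (pooling predictions before correlating is a documented alternative the
  functions could adopt, but fold-averaging matches how such results are
  usually reported). Variance components are re-estimated within every
  training fold to avoid leakage; masked hybrids stay in G and their
  records are deleted, not zeroed.

## Known limitations

- Multi-trait models are bivariate only; more traits (e.g. all flights
  jointly) are served by the random-regression model instead.
- Linear splines only; smoother bases (Legendre polynomials) and knot
  optimization are out of scope.
- No spatial adjustment, no multi-environment G×E modeling, no dominance
  or epistatic relationship matrices.
- The dense-covariance REML engine scales comfortably to a few thousand
  records per fit — ample for single site-year trials — but is not meant
  for national-evaluation scale.
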