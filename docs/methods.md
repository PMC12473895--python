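# Methods

This note documents the statistical models, the numerical choices behind
them, and what the synthetic-data generator does and does not emulate.

## Observation model

A complete factorial (NC-II) mating design crosses every female parent to
every male parent; the resulting hybrids are evaluated in randomized
complete blocks across environments.  Plot observations follow

    y = µ + f + m + fm + s + fs + ms + fms + r(s) + e

with independent zero-mean Gaussian random effects: female GCA `f`, male
GCA `m`, SCA `fm` (the deviation of a specific cross from its parents'
GCAs), environment `s`, the three genotype-by-environment interactions,
replicate nested in environment `r(s)`, and the plot residual `e`.  The
single-environment model keeps `f, m, fm, r, e`.  All effects are i.i.d.
within a term (covariance σ²I); kernel-structured covariances enter only
in the prediction models, not in the variance-component fits.

## REML

Variance components are estimated by restricted maximum likelihood under
non-negativity bounds (L-BFGS-B on the component scale, analytic
gradients, multi-start).  Two routes share one surface:

* **Spectral route (balanced designs).**  For a complete factorial with a
  constant replicate count, every term's covariance is a tensor product of
  identity and all-ones blocks over the (female, male, environment,
  replicate) grid.  All such matrices diagonalize in one fixed orthogonal
  basis, so the restricted likelihood factorizes over eigen-classes
  (mean-vs-contrast per axis): each likelihood evaluation needs only the
  per-class projection sums of squares, computed once.  This is exact
  REML, not an approximation, and it makes a full 10 × 10 × 8 × 2 fit run
  in tens of milliseconds — per-band spectral decompositions and
  simulation studies are cheap.
* **Dense route (general data).**  Unbalanced data fall back to the
  generic Gaussian REML with the full n × n covariance.  The two routes
  are cross-checked against each other in the tests (same estimates and
  restricted log-likelihood on balanced inputs).

A response with zero variance short-circuits to all-zero components.  The
restricted log-likelihoods of the two routes share one normalization so
that likelihood-ratio statistics may mix routes.

**LRT.**  Each random term is tested by refitting without it and
referring `−2 Δ log L_R` to χ²₁, the conventional reference for this
procedure.  Because the null value lies on the boundary of the parameter
space, the test is conservative (the asymptotic null is a 50:50 mixture of
χ²₀ and χ²₁); the plain χ²₁ reference is used deliberately for
comparability, and the type-I behavior is verified in the tests.

**Known limitation — boundary truncation.**  Components whose sampling
spread reaches the zero bound (notably a replicate term with one contrast
degree of freedom) are truncated at zero; this inflates their mean
estimate and deflects coupled components (the residual) by a percent or
two.  This is inherent to bounded REML, not an optimizer artifact.

## Heritability

Entry-mean heritabilities across `t` environments with `r` replicates:

    H²  = σ²_g* / D,   h² = (σ²_f + σ²_m) / D,
    h²_f = σ²_f / D,   h²_m = σ²_m / D,
    D = σ²_g* + σ²_g×e*/t + σ²_e/(t·r)

where σ²_g* = σ²_f + σ²_m + σ²_fm and σ²_g×e* = σ²_fs + σ²_ms + σ²_fms.
Single-environment forms use D = σ²_g + σ²_e/r.  `heritability_combined`
also accepts aggregated components (total hybrid, total hybrid-by-
environment, residual) so report-level tables can be fed directly.  The
residual coefficient of variation is `CVe = 100 · √σ²_e / x̄`.  `r = 2` is
the default in report workflows (replicate counts that differ by year make
`r` a modeling choice; it is exposed as a parameter everywhere).

## BLUEs

Per-environment hybrid means are extracted from a fixed-hybrid,
random-replicate mixed model: replicate and residual variances by REML,
then the GLS solve for the hybrid cell means.  For balanced data this
reduces to plot means.  Hybrid-by-environment BLUE tables are the record
layout that the prediction models and cross-validation consume.

## Kernels

* Genomic: `G = X_c X_c' / n` with marker-centered dosages.  The division
  by marker count follows the working definition used with this pipeline;
  the classical `2 Σ p_j(1−p_j)` denominator is available via
  `denominator="2pq"` and differs only by a scalar, which the prediction
  models absorb into the kernel variance.
* SCA: the Kronecker product of the female and male GCA kernels restricted
  to realized crosses.
* Phenomic: `P = D D' / q` where `D` is the scaled window-11 polynomial-
  order-2 Savitzky-Golay first derivative of the reflectance spectra
  (edges dropped: 4200 bands → 4190).  "Scaled around zero" is read as
  center-and-unit-SD per band; centering-only is exposed as an option.
* Interactions: record-expanded kernels are multiplied element-wise with
  the environment-sharing indicator `Z_E Z_E'` (Schur products of PSD
  matrices, hence PSD).  Small negative eigenvalues from roundoff
  (> −1e−8) are clipped to zero before sampling decompositions.

## Multi-kernel Gibbs sampler

GP, PP, and GP+PP models are Bayesian RKHS regressions

    y = 1µ + Σ_j u_j + e,   u_j ~ N(0, σ²_j K_j),   e ~ N(0, σ²_e I)

fitted by Gibbs sampling.  Each kernel is eigendecomposed once; writing
`u_j = U_j D_j^{1/2} b_j` makes the full conditional of `b_j` Gaussian
with **diagonal** precision `D_j/σ²_e + I/σ²_j`, so one sweep costs
O(n · rank) per kernel.  Variances get scaled-inverse-χ² conditionals with
degrees of freedom df₀ = 5 and scales set so the prior mode splits R² = 0.5
of the response variance equally among kernels (both exposed in
`ModelSpec`).  Environment main effects are a Gaussian ridge on
environment indicators — algebraically an identity kernel over environment
levels, handled as one more kernel term.  Missing responses are imputed
each sweep (data augmentation), which yields predictions for masked
records directly.  The default chain is 5000 iterations, 1000 burn-in,
thinning 10; a split-chain potential-scale-reduction diagnostic on the
variance draws is reported and a warning is logged above 1.1.  With
variances fixed, posterior-mean fitted values converge to the
mixed-model-equation BLUP solution; the tests verify correlation ≥ 0.995
on toys against a from-scratch oracle.

Model composition: GP = {f-GCA, m-GCA, SCA}; PP = {phenomic}; combined
scope adds the environment block and the matching interaction kernels
(f×E, m×E, SCA×E, NIR×E).  The combined GP+PP stack has nine variance
terms plus the residual.

## Cross-validation

Records are hybrid-by-environment BLUE cells.  Per repeat, hybrids split
70:30 into training and test sets:

* CV1 masks test-hybrid records everywhere; accuracy is the
  per-environment Pearson correlation over the 30 test hybrids.
* CV2 additionally masks an entire held-out environment and scores the 70
  *training* hybrids there (tested hybrids, uncharacterized environment).
* CV3 masks identically and scores the 30 *test* hybrids there.

With 100 hybrids and 8 environments: 560 training / 240 masked records
(CV1) and 490 / 310 (CV2–CV3); with 4 environments: 280/120 and 210/190.
Per-environment accuracies are averaged (unweighted) within repeat, then
summarized across repeats (SE over repeats).  Model comparison applies
Tukey's HSD to the repeat-level accuracies with model as the only factor;
the compact letter display uses insert-and-absorb.  The default protocol
is 50 repeats.

## Synthetic data

The generator draws inbred parents (homozygous dosages, per-marker allele
frequencies uniform on the MAF range), derives hybrids as the parental
mean (the deterministic F1 of inbred parents), and simulates plot records
term by term.  Two effect modes:

* **i.i.d. mode** draws every term i.i.d. normal — exactly the
  variance-component model above.  Used for estimator-recovery studies.
* **genomic mode** (default) ties genetic terms to the simulated
  genotypes: GCA effects are marker-effect sums, SCA and per-environment
  interaction effects are multivariate-normal draws from the corresponding
  kernels.  Draws are scaled so the expected across-level (ddof = 1)
  sample variance equals the configured component; relationship matrices
  on centered dosages are sum-to-zero, so their support is exactly the
  contrast space a variance-component fit measures.  Because
  kernel-correlated draws violate the i.i.d. working covariance, REML on
  genomic-mode data shows small (few-percent) systematic deflections in
  the interaction components — a property of the data-generating process,
  not the estimator, and the reason recovery studies use i.i.d. mode.

Spectra are smooth curves on a row-normalized cubic B-spline basis
(~40 knots) plus white residual noise; per-band variance decomposes into
female / male / hybrid / environment / G×E / replicate / residual shares
that sum to one.  The default shares put ~49% of band variance in the
hybrid total and give band-wise H² near 0.97 under 8 environments × 2
replicates, matching the highly heritable character of grain NIR spectra.
The wavelength grid is half-open ([400, 2500) nm at 0.5 nm → 4200 bands)
so the band count matches the conventional 100 × 4200 layout.  Not
emulated: chemistry-based forward models of reflectance, scatter effects,
linkage/LD structure among markers, and selection dynamics — so passing
tests show the *pipeline* is correct under the assumed variance structure,
not that real spectra behave this way.

`trait_from_spectra` builds a trait whose signal is a band-window
functional of each record's spectrum (including its environment and G×E
parts); it provides the spectra-loaded condition under which phenomic
prediction must beat genomic prediction, the constructive check used in
the pipeline-sanity tests.

## Problem sizes and defaults

Desk-scale defaults chosen for minutes-scale runs while preserving all
structure: 2000 markers, 10 × 10 factorial, 8 environments × 2 replicates.
The pipeline-sanity studies use 4 environments, 20 CV repeats, and
shortened chains (1000/250/5); variance-recovery studies use 200 simulated
datasets through the spectral REML route.  All sampling is seeded through
`numpy.random.SeedSequence`, and identical seeds reproduce outputs
bit-for-bit.

## Design choices that were genuinely open

* Savitzky-Golay polynomial order: 2 (window 11 ≫ order; the standard
  first-derivative pretreatment).
* Edge handling: drop the window−1 edge bands rather than pad, keeping the
  4200 → 4190 band count contract.
* Band scaling after the derivative, before the kernel; center+unit-SD
  with centering-only as config.
* Hybrid dosage as parental mean rather than gamete sampling: parents are
  inbred lines, so the F1 is deterministic.
* Gibbs hyperpriors (df₀ = 5, equal R² = 0.5 split) follow the defaults of
  the sampler family this implementation mirrors; they are package
  defaults, not assertions about any external analysis.
* LRT without the boundary mixture (see above), mixture available.
* Missing-genotype handling on ingestion: markers with > 5% missing calls
  removed, the rest mean-imputed; the threshold and method are config.
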