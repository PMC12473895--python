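# phenopred

Genomic and NIR-phenomic prediction for factorial hybrid trials.

`phenopred` implements the full analysis pipeline for multi-environment
trials of hybrids from a complete factorial (NC-II) mating design, where
both parental SNP genotypes and near-infrared reflectance spectra of the
harvested grain are available:

* **Kernels** — the marker-based relationship matrix `G = X_c X_c' / n` on
  centered dosages for each parent pool, the SCA kernel over hybrids as the
  Kronecker product `H[(f1,m1),(f2,m2)] = G_f[f1,f2] * G_m[m1,m2]`, the
  phenomic relationship `P = D D' / q` from the scaled Savitzky-Golay first
  derivative of the spectra, and genotype-by-environment interaction
  kernels as Hadamard products `(Z K Z') ⊙ (Z_E Z_E')`.
* **Variance components** — REML for the combined-environment model

  `y = µ + f + m + fm + s + fs + ms + fms + r(s) + e`

  (female GCA, male GCA, SCA, environment, the three G×E interactions,
  replicate-within-environment, residual), likelihood-ratio tests per
  term, and entry-mean heritabilities

  `H² = σ²_g* / (σ²_g* + σ²_g×e*/t + σ²_e/(t·r))`

  with `σ²_g* = σ²_f + σ²_m + σ²_fm` and the additive, female, and male
  narrow-sense variants sharing the denominator.
* **Prediction** — a from-scratch multi-kernel Bayesian RKHS regression
  fitted by Gibbs sampling (effects sampled in each kernel's eigenbasis,
  scaled-inverse-χ² variance conditionals, missing responses imputed by
  data augmentation), composing GP (GCA + SCA kernels), PP (phenomic
  kernel), and GP+PP models in single- and combined-environment scope.
* **Evaluation** — CV1 (untested hybrids, characterized environments),
  CV2 (tested hybrids, uncharacterized environment), CV3 (untested hybrids,
  uncharacterized environment) with repeated 70:30 hybrid splits,
  per-environment Pearson accuracies, and Tukey-HSD model comparison with
  compact letter displays.
* **Synthetic data** — a seeded generator for the whole study design
  (inbred parent genotypes, expected-F1 hybrid dosages, plot records drawn
  from configurable variance components, smooth per-plot reflectance
  spectra with per-band variance shares), so every stage is testable at
  desk scale without field data.

The fittable pieces follow scikit-learn conventions
(`SavitzkyGolayDerivative` and `BandScaler` transformers, the
`FactorialREML` estimator, the `MultiKernelGibbs` regressor), with plain
functions (`reml_combined`, `gibbs_fit`, `run_scheme`, ...) as thin
wrappers.

## Worked example

Simulate a 10 × 10 factorial evaluated in 8 environments with 2 replicates
(grain-yield-scale variance components), estimate the variance components,
and compute heritability:

```python
from phenopred import (DesignSpec, FactorialSimulator, reml_combined,
                       heritability_combined, cve)

sim = FactorialSimulator(
    design=DesignSpec(10, 10, {f"E{i+1}": 2 for i in range(8)}),
    n_markers=2000,
)
data = sim.simulate(seed=1)
records = data["records"]

vc = reml_combined(records, "trait")
for term, est in vc.estimates.items():
    print(f"  {term:4s} {est:7.3f}  ({vc.percents[term]:5.1f} %)")
hr = heritability_combined(vc, t=8, r=2)
print(f"H2 = {hr.H2:.2f}  h2 = {hr.h2:.2f}  h2_f = {hr.h2_f:.2f}  h2_m = {hr.h2_m:.2f}")
print(f"CVe = {cve(vc, records.frame['trait'].mean()):.2f} %")
```

prints

```
  f      0.050  (  3.5 %)
  m      0.240  ( 16.6 %)
  fm     0.025  (  1.8 %)
  s      0.316  ( 21.9 %)
  fs     0.070  (  4.8 %)
  ms     0.043  (  3.0 %)
  fms    0.110  (  7.6 %)
  r_s    0.013  (  0.9 %)
  e      0.577  ( 39.9 %)
H2 = 0.83  h2 = 0.76  h2_f = 0.13  h2_m = 0.63
CVe = 12.18 %
```

The rows are the REML estimates for each random term (female GCA `f`, male
GCA `m`, SCA `fm`, environment `s`, the three G×E interactions, replicate
within environment, residual) with their percent of total variance.  A
single dataset gives noisy estimates for terms with few levels — the
environment component here is one draw of 8 environment effects, and the
two GCA components are draws of 10 parental effects each, so their spread
around the generating values is large; averaged over repeated simulations
the estimates converge to the generating components (the test suite checks
this).  `H2` is the entry-mean broad-sense heritability across
environments, `h2` the additive (GCA) fraction, `h2_f`/`h2_m` its female
and male parts, and `CVe` the residual coefficient of variation.

The same pipeline runs from the shell:

```bash
phenopred simulate --seed 1 --out simdata
phenopred varcomp --phenotypes simdata/phenotypes.csv --trait trait
phenopred spectra --spectra simdata/spectra.csv --out prep
phenopred cv --data-dir simdata --scheme CV1 --repeats 50 --seed 1
```

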