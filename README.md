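# sevsem

Structural equation modeling of alcohol use disorder (AUD) severity.

Clinically, AUD has long been diagnosed as a yes/no category, yet the
disorder spans a continuum of withdrawal, craving, consequences and
diagnostic symptoms. `sevsem` implements, as a reusable and tested
library, the covariance-structure analysis behind a dimensional AUD
severity construct: a four-latent-factor model in which five clinical
indices (ADS, PACS, COUNT, DRINC, CIWA) measure a **Severity** factor
that is regressed on three validation constructs — **Alcohol Use**
(DPDD, BINGE%), **Affective Symptoms** (BAI, BDI) and **Motivation to
change** (SOCRATES STEPS/RECOG/AMBIV) — with free covariances among the
three exogenous factors.

## What the package does

* **Model syntax & bookkeeping** (`sevsem.model_spec`) — a lavaan-like
  text grammar (`Severity =~ 1*ADS + PACS + ...`), identification
  checks, free-parameter counting and model degrees of freedom.
* **ML estimation** (`sevsem.sem_core`) — RAM-matrix implied
  covariances Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ, the ML discrepancy
  F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p minimized by Fisher scoring with
  analytic derivatives, χ² = (n−1)·F, standardized solutions and latent
  R².
* **Fit indices** (`sevsem.fit_indices`) — relative χ², the
  independence baseline (closed form F_b = −ln|R|), CFI and RMSEA.
* **Robust statistics** (`sevsem.robust_stats`) — the asymptotic
  fourth-moment matrix Γ of sample covariances, Satorra–Bentler scaling
  c = tr(UΓ)/df with T_SB = T_ML/c, sandwich standard errors, robust
  CFI/RMSEA.
* **Multi-group invariance** (`sevsem.multigroup`) — simultaneous
  fitting with cross-group equality constraints and univariate
  Lagrange-multiplier release tests.
* **Synthetic data** (`sevsem.synthetic`) — Fleishman-polynomial
  margins combined by the Vale–Maurelli method, so raw samples with a
  target correlation structure and right-skewed, leptokurtic margins
  (like real alcohol scores) can be generated from one seed, including
  a two-group gender design.
* **Study pipeline** (`sevsem.study`) — one-command reproduction of the
  published analyses from the bundled printed moment table (12
  variables, n = 283), plus BDI-II/BAI clinical-range binning.

## Worked example

```python
from sevsem import fit_ml, fit_report, latent_rsquared
from sevsem.study import load_study_moments, model_a_spec

moments = load_study_moments()          # bundled table: 12 vars, n = 283
fit = fit_ml(model_a_spec(), moments)   # ML fit of the four-factor model
report = fit_report(fit)

print(f"chi2({fit.df}) = {fit.t_ml:.2f}, CFI = {report.cfi:.3f}, "
      f"RMSEA = {report.rmsea:.3f}")
print(f"R2(Severity) = {latent_rsquared(fit, 'Severity'):.3f}")
print({e.pid: round(e.standardized, 3)
       for e in fit.params.entries if e.pid.startswith('Severity=~')})
```

prints

```
chi2(48) = 123.42, CFI = 0.953, RMSEA = 0.075
R2(Severity) = 0.684
{'Severity=~ADS': 0.738, 'Severity=~PACS': 0.629, 'Severity=~COUNT': 0.638,
 'Severity=~DRINC': 0.861, 'Severity=~CIWA': 0.319}
```

i.e. all five severity indices load strongly on one factor, and the
three validation constructs jointly explain 68% of the severity
variance. (The χ² here is the plain ML statistic computed from the
printed, rounded correlation table; the published statistic is the
smaller Satorra–Bentler scaled value obtained from the raw data, which
is why the descriptive indices differ slightly.)

The same analyses run from a shell:

```bash
sevsem reproduce-paper --out reproduction/        # all four analyses
sevsem fit --moments table1.csv --model modelA.txt
sevsem simulate --n 283 --seed 1 --out synthetic.csv
sevsem invariance --raw grouped.csv --model modelA.txt --group-column gender
```

`reproduce-paper` writes per-model TSV comparison tables (printed value,
reproduced value, |Δ|) and a JSON summary; `--strict` exits nonzero when
any comparison exceeds its documented tolerance.

## Data

No raw subject-level data were ever published for this study; the
package bundles only the printed summary table (means, SDs,
correlations, n = 283). Every raw-data-dependent stage (robust
statistics, subset refits, gender invariance) is exercised on synthetic
samples generated by `sevsem.synthetic`, which is first-class, tested
code — see `docs/methods.md` for what those simulations do and do not
establish.
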