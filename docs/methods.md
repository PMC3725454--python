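# Methods

## Model

The severity model is a recursive latent-variable system over p = 12
observed clinical scores. Four latent factors: an endogenous AUD
**Severity** factor measured by ADS, PACS, COUNT, DRINC and CIWA, and
three exogenous factors — **Alcohol Use** (DPDD, BINGE%), **Affective
Symptoms** (BAI, BDI), **Motivation** (STEPS, RECOG, AMBIV) — that
predict Severity and covary freely with one another.

Identification follows the original analysis: each exogenous factor has
variance fixed to 1 with all loadings free; Severity is scaled by
fixing the ADS loading to 1, with its disturbance variance free. "The
variance of the severity construct freely estimated" is read as the
*disturbance* variance, since the total variance of an endogenous
factor is determined by its predictors — the only reading consistent
with 30 free parameters and df = 78 − 30 = 48. All 12 residual
variances are free. Mean structure is not modeled (the analysis is
covariance-only); missing data are handled upstream by listwise
deletion.

Internally the model is held in RAM form — path matrix A, symmetric S,
filter F = [I_p 0] — so the implied covariance is
Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ. This is fully general for the recursive
model class used here and keeps derivatives simple: every free
parameter occupies one or more slots of A or S (equality constraints
share a slot list), and ∂Σ/∂θ has a closed form in B = (I−A)⁻¹.

## Estimation

ML estimation minimizes F(θ) = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p. The
optimizer is Fisher scoring (Gauss–Newton with the expected information
ΔᵀWΔ, W the normal-theory weight), which is affine-invariant and hence
indifferent to the wildly different scales of the clinical scores (SDs
from 0.30 to 22.12). Numerical choices:

* Jacobi-preconditioned solves and a trust-region cap (step length ≤ 10
  in the information metric) — large early steps can otherwise hop into
  degenerate basins in which a two-indicator factor collapses onto one
  indicator;
* Levenberg ridging plus step halving when a step fails;
* convergence when the scale-invariant score norm max_k |g_k|/√I_kk
  drops below 1e−6 (a raw-gradient norm would be scale-dependent);
  up to six restarts alternate between perturbed start values and an
  L-BFGS-B escape in a normalized parameterization;
* start values: residual variances at half the sample variance,
  loadings at half the indicator SD on the factor's scale with signs
  taken from the correlation with the factor's anchor indicator,
  factor variances at half the marker variance, paths at 0;
* χ² = (n−1)·F_ML — the convention of classical SEM programs,
  confirmed by back-solving the published (χ², df, n, RMSEA) triples;
* Heywood cases (negative variance estimates) are flagged in the
  result, never silently truncated, since truncation would mask misfit.

The standardized solution rescales each coefficient by the implied SDs
of its endpoints from the full covariance (I−A)⁻¹S(I−A)⁻ᵀ; latent R² is
one minus the standardized disturbance.

## Fit indices

Relative χ² = T/df; RMSEA = √(max(0, (T−df)/(df(n−1)))); CFI uses the
independence baseline with free variances, whose ML solution is closed
form (F_b = −ln|R|, df_b = p(p−1)/2) — the universal convention, which
the source analysis does not spell out. Saturated models (df = 0) raise
rather than return relative χ²/RMSEA.

The published CFI/RMSEA are *robust* versions computed from the
Satorra–Bentler scaled χ² of the raw data. From the printed summary
table only the ML versions are reproducible; the documented comparison
tolerances (±0.03 standardized estimates and R², ±0.02 CFI, ±0.01
RMSEA) reflect both the 2-dp rounding of the published correlations and
that substitution. In practice the ML RMSEA on the reconstructed matrix
(0.075) sits just outside ±0.01 of the published robust 0.064 — the ML
χ² (123.4) is necessarily larger than the scaled 103.73 — and the
package reports the discrepancy rather than hiding it.

## Robust statistics

With raw data, Γ estimates the asymptotic covariance of sample
covariances from centered fourth moments (biased 1/n moments, chosen
for simplicity and stability; the difference is O(1/n)). The
Satorra–Bentler factor is c = tr(UΓ)/df with
U = W − WΔ(ΔᵀWΔ)⁻¹ΔᵀW and W = ½Dᵀ(Σ̂⁻¹⊗Σ̂⁻¹)D evaluated at θ̂
(duplication matrix D; vech is column-major lower-triangular
everywhere). Under normality Γ = W⁻¹ and UW⁻¹ is a rank-df projection,
so c = 1 exactly — asserted to 1e−8 in tests. Robust standard errors
are the sandwich (ΔᵀWΔ)⁻¹ΔᵀWΓWΔ(ΔᵀWΔ)⁻¹/(n−1). The robust CFI scales
the independence baseline on the same Γ; this matches the behavior
family of classical implementations but is flagged approximate in
reports. Full ADF (Γ-weighted) estimation is out of scope.

## Multi-group analysis

Groups share one spec; the joint discrepancy is Σ_g (n_g−1)F_g, its
minimum the total χ² on Σ_g p(p+1)/2 − q_joint df. The "all paths
equal" constraint set comprises free loadings, structural paths and
factor covariances — residual and factor variances stay group-specific
(configurable). Releasing a constraint is scored without refitting by
the univariate LM statistic sᵀI⁻¹s in the released parameterization at
the constrained optimum (score s, expected information I, both weighted
by n_g−1); it is asymptotically χ²(G−1) and agrees with the explicit
refit LR drop within 15% on test fixtures.

A caution established by the package's own power simulations: with one
standardized loading differing by 0.3 between groups at n = 500/group,
the targeted LM test flags the right constraint essentially always,
but the omnibus total χ² (113 df for this model) dilutes that single-
constraint signal to ~30–50% rejection. Localized release tests, not
the omnibus statistic, carry the group-difference inference.

## Synthetic data

The generator produces raw samples whose population correlation matrix
is the model-implied structure of the published standardized solution
(the printed loadings/paths/factor correlations, residuals completing
unit variances — these generating values reproduce the published 68%
severity R² exactly) and whose margins match the printed means and SDs.
Non-normality uses Fleishman cubic transforms Y = a + bZ + cZ² + dZ³
solved for requested (skew, excess kurtosis) — feasible when kurtosis ≥
skew² − 2 — combined by the Vale–Maurelli intermediate-correlation
cubic so that target correlations survive the transform.

Default margins: the seven alcohol-related scores (ADS, PACS, COUNT,
DRINC, CIWA, DPDD, BINGE%) get skew 1.0 and excess kurtosis 1.5 —
plainly right-skewed yet comfortably Fleishman-feasible — while affect
and motivation margins stay normal; the true higher moments of the
study variables were never published, so these are study-plausible
defaults, configurable per variable. Scores are continuous; COUNT is
not integer-rounded by default (rounding would perturb the target
moments), with discretization available for realism experiments. The
two-group gender design defaults to the study's 75 women / 205 men and
can offset chosen standardized loadings in the second group; offsets
must keep loadings inside the unit interval (the +0.2 direction on BAI
or BDI would imply negative residual variance and is rejected).

What the simulations establish — and what they do not: passing tests
show the estimator, the SB correction and the LM machinery behave
correctly *on data generated by this mechanism* (polynomial margins,
exact target structure, no measurement floor/ceiling effects, no
item-level discreteness, no missingness). They cannot certify the
published raw-data statistics (SB χ² magnitudes, robust SEs, the gender
LM values 8.26/5.07), which are checked only qualitatively: synthetic
gender data with depressed BAI/BDI loadings put exactly those two
constraints atop the LM release list in ≥ 80% of replicates.

For the SB calibration study the margins are skew 1.5 / excess kurtosis
6: symmetric kurtosis alone leaves the residual directions of a factor
model nearly normal-theory (asymptotic c ≈ 1.03), whereas the skewed
leptokurtic margins give c ≈ 1.14, a cleaner probe of the correction;
mean T_SB/df stays within [0.9, 1.1] in both regimes.

## Reproduction pipeline and problem sizes

`reproduce-paper` runs: (1) the full model on the bundled table; (2)
the model without COUNT — mechanical removal yields df = 38 while the
published table prints df = 35, and since the three extra freed
parameters are not identified in print, the discrepancy is surfaced,
not resolved; (3) a subset-sensitivity refit dropping 12 flagged rows
of a synthetic n = 283 sample (typical maximum standardized shift ≈
0.02, median over a 20-seed grid; occasional near-Heywood replicates
can exceed 0.05); (4) the constrained gender analysis with LM release
recommendations. BDI-II/BAI totals are also binned into the standard
clinical ranges (0–13/14–19/20–28/29–63 and 0–7/8–15/16–25/26–63).

Simulation sizes used by the test suite — 500 null replicates for the
χ² calibration, 200 for the SB calibration, 100 two-group replicates
for LM power, n = 10⁵–10⁶ for moment-fidelity checks — were chosen so
the whole suite runs comfortably on a laptop-class single core while
keeping Monte Carlo error well below the asserted tolerances.

## Known limitations

* Covariance structure only: no mean/intercept structure, ordinal
  indicators, formative measurement or FIML for missing data.
* GLS/WLS/full-ADF estimators, bootstrap SEs, RMSEA confidence
  intervals, SRMR/TLI are not implemented.
* Published robust χ² magnitudes and standard errors are not
  recoverable without the raw data; the package substitutes exact
  algebraic identities and calibration simulations, as documented
  above.
* The LM release test is univariate (one constraint at a time), not a
  forward-stepping multivariate procedure.
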