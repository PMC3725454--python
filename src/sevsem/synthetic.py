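"""Simulation of raw samples with a target correlation structure and
non-normal margins (Fleishman polynomials combined by the Vale-Maurelli
method), including a two-group design mirroring the study's gender
analysis.

Each margin is the cubic transform Y = a + bZ + cZ^2 + dZ^3 of a
standard normal Z, with (a, b, c, d) solved so that Y has mean 0,
variance 1 and the requested skew and excess kurtosis (a = -c).  To hit
a target correlation r between two transformed margins, the underlying
normals are correlated at the intermediate value rho solving

    r = rho (b_i b_j + 3 b_i d_j + 3 d_i b_j + 9 d_i d_j)
        + rho^2 (2 c_i c_j) + rho^3 (6 d_i d_j).

All randomness flows through a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.optimize as sopt

from .exceptions import InfeasibleMomentsError, NotPositiveDefiniteError, SpecificationError

__all__ = [
    "MarginSpec",
    "SyntheticSpec",
    "fleishman_coefficients",
    "intermediate_correlation",
    "generate_sample",
    "generate_study_like_groups",
    "study_implied_correlation",
    "STUDY_VARIABLES",
    "STUDY_MEANS",
    "STUDY_SDS",
    "STUDY_TRUE_STANDARDIZED",
    "ALCOHOL_VARIABLES",
]


# ---------------------------------------------------------------------------
# Fleishman margins


def fleishman_coefficients(skew: float, excess_kurtosis: float) -> tuple[float, float, float, float]:
    """Solve the Fleishman moment system for (a, b, c, d).

    Feasibility requires excess_kurtosis >= skew^2 - 2 (the boundary of
    the attainable (skew, kurtosis) region for cubic transforms of a
    normal is slightly inside that bound; the solver reports failures).
    """
    g1, g2 = float(skew), float(excess_kurtosis)
    if g2 < g1**2 - 2:
        raise InfeasibleMomentsError(
            f"(skew={g1}, excess kurtosis={g2}) violates kurtosis >= skew^2 - 2"
        )
    if g1 == 0.0 and g2 == 0.0:
        return (0.0, 1.0, 0.0, 0.0)

    def system(x):
        b, c, d = x
        f1 = b**2 + 6 * b * d + 2 * c**2 + 15 * d**2 - 1
        f2 = 2 * c * (b**2 + 24 * b * d + 105 * d**2 + 2) - g1
        f3 = 24 * (
            b * d
            + c**2 * (1 + b**2 + 28 * b * d)
            + d**2 * (12 + 48 * b * d + 141 * c**2 + 225 * d**2)
        ) - g2
        return [f1, f2, f3]

    starts = [
        (0.95, 0.1 * np.sign(g1) if g1 else 0.0, 0.03),
        (0.9, g1 / 6.0, 0.05),
        (1.0, 0.0, 0.0),
        (0.8, 0.3 * np.sign(g1) if g1 else 0.1, 0.1),
    ]
    for x0 in starts:
        sol = sopt.root(system, x0, method="hybr", tol=1e-13)
        if sol.success and np.max(np.abs(system(sol.x))) < 1e-9:
            b, c, d = sol.x
            if b < 0:  # sign convention: keep b > 0 so Y increases with Z
                b, c, d = -b, c, -d
            return (-c, b, c, d)
    raise InfeasibleMomentsError(
        f"no Fleishman solution found for (skew={g1}, excess kurtosis={g2}); "
        "the pair lies outside the attainable region of cubic transforms"
    )


def intermediate_correlation(target_r: float, coeffs_i, coeffs_j) -> float:
    """Normal-scale correlation rho reproducing target_r after transforms."""
    if not -1 < target_r < 1:
        raise SpecificationError("target correlation must lie strictly in (-1, 1)")
    _, bi, ci, di = coeffs_i
    _, bj, cj, dj = coeffs_j
    k1 = bi * bj + 3 * bi * dj + 3 * di * bj + 9 * di * dj
    k2 = 2 * ci * cj
    k3 = 6 * di * dj
    if target_r == 0.0 and k2 == 0.0:
        return 0.0
    roots = np.roots([k3, k2, k1, -target_r]) if (k3 or k2) else np.array([target_r / k1])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-10 and -1 < r.real < 1]
    if not real:
        raise InfeasibleMomentsError(
            f"target correlation {target_r} unattainable for the given margins"
        )
    # the admissible root closest to the target (the relation is near-linear)
    return min(real, key=lambda r: abs(r - target_r))


# ---------------------------------------------------------------------------
# sample generation


@dataclass
class MarginSpec:
    mean: float = 0.0
    sd: float = 1.0
    skew: float = 0.0
    excess_kurtosis: float = 0.0

    def __post_init__(self):
        if self.sd <= 0:
            raise SpecificationError("margin SD must be positive")
        if self.excess_kurtosis < self.skew**2 - 2:
            raise InfeasibleMomentsError(
                f"margin (skew={self.skew}, kurtosis={self.excess_kurtosis}) infeasible"
            )


@dataclass
class SyntheticSpec:
    target_correlation: np.ndarray
    margins: list[MarginSpec]
    n: int
    names: Optional[list[str]] = None
    seed: int = 0
    strict: bool = False  # error instead of repairing a non-PD intermediate matrix
    # optional realism step: round the named columns to integers after
    # generation (perturbs the target moments slightly, hence off by default)
    integer_columns: Optional[list[str]] = None

    def __post_init__(self):
        R = np.asarray(self.target_correlation, dtype=float)
        p = R.shape[0]
        if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
            raise SpecificationError("target correlation must be square symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise SpecificationError("target correlation must have unit diagonal")
        if len(self.margins) != p:
            raise SpecificationError("one margin spec per variable is required")
        self.target_correlation = 0.5 * (R + R.T)
        if self.names is None:
            self.names = [f"x{i + 1}" for i in range(p)]


def _nearest_pd_correlation(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    w = np.clip(w, eps, None)
    M = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(M))
    return M / np.outer(d, d)


def generate_sample(spec: SyntheticSpec, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw an n x p raw score table matching the synthetic spec.

    Reproducible given the spec's seed; sample moments converge to the
    targets as n grows.
    """
    rng = rng or np.random.default_rng(spec.seed)
    R = spec.target_correlation
    p = R.shape[0]
    coeffs = [fleishman_coefficients(m.skew, m.excess_kurtosis) for m in spec.margins]
    rho = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if R[i, j] != 0 or any(c[2] for c in (coeffs[i], coeffs[j])):
                rho[i, j] = rho[j, i] = intermediate_correlation(R[i, j], coeffs[i], coeffs[j])
    w = np.linalg.eigvalsh(rho)
    if w.min() <= 1e-10:
        if spec.strict:
            raise NotPositiveDefiniteError(
                "intermediate normal correlation matrix is not positive definite"
            )
        warnings.warn("intermediate correlation matrix repaired to nearest PD", stacklevel=2)
        rho = _nearest_pd_correlation(rho)
    L = np.linalg.cholesky(rho)
    Z = rng.standard_normal((spec.n, p)) @ L.T
    X = np.empty_like(Z)
    for j, (m, (a, b, c, d)) in enumerate(zip(spec.margins, coeffs)):
        z = Z[:, j]
        X[:, j] = m.mean + m.sd * (a + z * (b + z * (c + z * d)))
    out = pd.DataFrame(X, columns=spec.names)
    for col in spec.integer_columns or []:
        out[col] = np.round(out[col])
    return out


# ---------------------------------------------------------------------------
# study-like data: the four-factor AUD severity model

STUDY_VARIABLES = [
    "ADS", "PACS", "COUNT", "DRINC", "CIWA",
    "STEPS", "RECOG", "AMBIV", "BAI", "BDI", "DPDD", "BINGE_PCT",
]
STUDY_MEANS = dict(zip(STUDY_VARIABLES, [
    40.25, 17.92, 5.23, 40.9, 5.66, 2.8, 2.72, 3.09, 18.82, 20.56, 7.08, 0.66,
]))
STUDY_SDS = dict(zip(STUDY_VARIABLES, [
    7.31, 6.61, 2.81, 22.12, 6.92, 0.93, 0.92, 0.92, 12.99, 12.04, 4.66, 0.3,
]))
# right-skewed alcohol-related scores; affect and motivation margins normal
ALCOHOL_VARIABLES = ["ADS", "PACS", "COUNT", "DRINC", "CIWA", "DPDD", "BINGE_PCT"]
DEFAULT_ALCOHOL_SKEW = 1.0
DEFAULT_ALCOHOL_KURTOSIS = 1.5

# standardized generating values of the four-factor severity model
STUDY_TRUE_STANDARDIZED = {
    "loadings": {
        ("Severity", "ADS"): 0.737,
        ("Severity", "PACS"): 0.639,
        ("Severity", "COUNT"): 0.647,
        ("Severity", "DRINC"): 0.860,
        ("Severity", "CIWA"): 0.313,
        ("AlcoholUse", "DPDD"): 0.648,
        ("AlcoholUse", "BINGE_PCT"): 0.967,
        ("Affective", "BAI"): 0.902,
        ("Affective", "BDI"): 0.923,
        ("Motivation", "STEPS"): 0.614,
        ("Motivation", "RECOG"): 0.941,
        ("Motivation", "AMBIV"): 0.860,
    },
    "paths": {
        ("AlcoholUse", "Severity"): 0.206,
        ("Affective", "Severity"): 0.167,
        ("Motivation", "Severity"): 0.674,
    },
    "factor_correlations": {
        ("AlcoholUse", "Affective"): 0.020,
        ("AlcoholUse", "Motivation"): 0.335,
        ("Affective", "Motivation"): 0.257,
    },
}

_EXOG = ["AlcoholUse", "Affective", "Motivation"]


def study_implied_correlation(
    loading_overrides: Optional[dict] = None,
) -> tuple[np.ndarray, list[str]]:
    """Model-implied correlation matrix of the 12 indicators under the
    standardized four-factor severity model (optionally with per-indicator
    loading overrides, e.g. for group-difference scenarios)."""
    tv = STUDY_TRUE_STANDARDIZED
    loadings = dict(tv["loadings"])
    if loading_overrides:
        loadings.update(loading_overrides)
    beta = np.array([tv["paths"][(f, "Severity")] for f in _EXOG])
    Phi = np.eye(3)
    for (a, b), r in tv["factor_correlations"].items():
        i, j = _EXOG.index(a), _EXOG.index(b)
        Phi[i, j] = Phi[j, i] = r
    sev_var = float(beta @ Phi @ beta)
    if sev_var >= 1:
        raise SpecificationError("structural paths imply Severity variance above 1")
    # factor covariance matrix in order [Severity, AlcoholUse, Affective, Motivation]
    C = np.empty((4, 4))
    C[1:, 1:] = Phi
    C[0, 0] = 1.0  # disturbance sized so the Severity variance is 1
    C[0, 1:] = C[1:, 0] = Phi @ beta
    factors = ["Severity"] + _EXOG
    Lam = np.zeros((len(STUDY_VARIABLES), 4))
    for (f, v), lam in loadings.items():
        Lam[STUDY_VARIABLES.index(v), factors.index(f)] = lam
    R = Lam @ C @ Lam.T
    resid = 1.0 - np.diag(R)
    if np.any(resid <= 0):
        raise SpecificationError("loadings imply non-positive residual variances")
    np.fill_diagonal(R, 1.0)
    return R, list(STUDY_VARIABLES)


def _study_margins(nonnormal: bool) -> list[MarginSpec]:
    out = []
    for v in STUDY_VARIABLES:
        skew = DEFAULT_ALCOHOL_SKEW if (nonnormal and v in ALCOHOL_VARIABLES) else 0.0
        kurt = DEFAULT_ALCOHOL_KURTOSIS if (nonnormal and v in ALCOHOL_VARIABLES) else 0.0
        out.append(MarginSpec(STUDY_MEANS[v], STUDY_SDS[v], skew, kurt))
    return out


def generate_study_sample(
    n: int, seed: int = 0, nonnormal: bool = True,
    loading_overrides: Optional[dict] = None,
) -> pd.DataFrame:
    """One raw sample from the model-implied study correlation structure."""
    R, names = study_implied_correlation(loading_overrides)
    spec = SyntheticSpec(R, _study_margins(nonnormal), n, names, seed=seed)
    return generate_sample(spec)


def generate_study_like_groups(
    n_women: int = 75,
    n_men: int = 205,
    loading_offsets: Optional[dict] = None,
    seed: int = 0,
    nonnormal: bool = True,
    group_column: str = "gender",
) -> pd.DataFrame:
    """Two-group raw table from the study model, the second (male) group
    with optional additive offsets on specified standardized loadings,
    e.g. ``{("Affective", "BAI"): 0.2}``."""
    p = len(STUDY_VARIABLES)
    if min(n_women, n_men) <= p:
        raise SpecificationError("each group needs more rows than observed variables")
    rng = np.random.default_rng(seed)
    R_w, names = study_implied_correlation()
    overrides = None
    if loading_offsets:
        overrides = {
            key: STUDY_TRUE_STANDARDIZED["loadings"][key] + off
            for key, off in loading_offsets.items()
        }
    R_m, _ = study_implied_correlation(overrides)
    margins = _study_margins(nonnormal)
    women = generate_sample(SyntheticSpec(R_w, margins, n_women, names, seed=seed), rng)
    men = generate_sample(SyntheticSpec(R_m, margins, n_men, names, seed=seed), rng)
    women[group_column] = "female"
    men[group_column] = "male"
    return pd.concat([women, men], ignore_index=True)
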