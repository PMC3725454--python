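"""Distribution-robust test statistics from raw data.

Sample covariances of non-normal data have an asymptotic covariance
matrix Gamma driven by fourth-order moments.  The Satorra-Bentler
correction rescales the normal-theory chi-square by

    c = tr(U Gamma) / df,      T_SB = T_ML / c,

where U = W - W Delta (Delta' W Delta)^-1 Delta' W is the residual
weight built from the normal-theory weight W = 0.5 D'(Sigma^-1 (x)
Sigma^-1) D (duplication matrix D, column-major lower-triangle vech
order shared with :mod:`sevsem.sem_core`) and Delta the Jacobian of
vech(Sigma(theta)) at the ML solution.  Under multivariate normality
Gamma = W^-1 and c = 1 exactly, because U W^-1 is a rank-df projection.

Robust (sandwich) standard errors and robust CFI/RMSEA (the chi-square
formulas applied to scaled statistics, with the independence baseline
scaled on the same Gamma) round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .exceptions import SevsemError, SpecificationError
from .fit_indices import FitIndexReport, cfi, relative_chi_square, rmsea
from .sem_core import (
    FitResult,
    SampleMoments,
    duplication_matrix,
    vech_indices,
)

__all__ = [
    "RobustWorkspace",
    "adf_gamma",
    "normal_theory_weight",
    "build_workspace",
    "satorra_bentler_scale",
    "robust_standard_errors",
    "robust_fit_indices",
    "robust_baseline_scale",
]


def adf_gamma(raw) -> np.ndarray:
    """Asymptotic covariance of sample covariances from fourth moments.

    Element ((i,j),(k,l)) estimates Cov(s_ij, s_kl) as the (biased, 1/n)
    sample covariance of the centered cross products x_i x_j and x_k x_l.
    Rows with missing values must have been removed upstream.
    """
    X = raw.to_numpy(dtype=float) if isinstance(raw, pd.DataFrame) else np.asarray(raw, dtype=float)
    n, p = X.shape
    ps = p * (p + 1) // 2
    if n <= ps:
        raise SpecificationError(
            f"n={n} raw rows cannot support the {ps}x{ps} fourth-moment matrix"
        )
    Xc = X - X.mean(axis=0)
    r, c = vech_indices(p)
    Y = Xc[:, r] * Xc[:, c]  # n x p* matrix of centered cross products
    Yc = Y - Y.mean(axis=0)
    return (Yc.T @ Yc) / n


def normal_theory_weight(sigma: np.ndarray) -> np.ndarray:
    """W = 0.5 D'(Sigma^-1 kron Sigma^-1) D in the shared vech order."""
    p = sigma.shape[0]
    sig_inv = sla.inv(sigma)
    D = duplication_matrix(p)
    return 0.5 * D.T @ np.kron(sig_inv, sig_inv) @ D


@dataclass
class RobustWorkspace:
    """All pieces of the robust correction for one converged fit."""

    gamma: np.ndarray
    w: np.ndarray
    delta: np.ndarray
    u: np.ndarray
    c: float
    t_sb: float
    df: int
    n: int


def _residual_weight(w: np.ndarray, delta: np.ndarray) -> np.ndarray:
    wd = w @ delta
    bread = sla.inv(delta.T @ wd)
    return w - wd @ bread @ wd.T


def build_workspace(fit: FitResult, raw=None, gamma: np.ndarray | None = None) -> RobustWorkspace:
    """Assemble the robust workspace from a converged fit and raw data
    (or a precomputed Gamma)."""
    if not fit.converged:
        raise SevsemError("robust statistics require a converged fit")
    if gamma is None:
        if raw is None:
            raise SpecificationError("either raw data or a Gamma matrix is required")
        cols = list(raw.columns) if isinstance(raw, pd.DataFrame) else None
        if cols is not None and cols != fit.moments.names:
            raw = raw[fit.moments.names]
        gamma = adf_gamma(raw)
    sigma = fit.implied_sigma
    w = normal_theory_weight(sigma)
    delta = fit.ram.delta_matrix(fit.theta)
    u = _residual_weight(w, delta)
    c, t_sb = satorra_bentler_scale(fit.t_ml, gamma=gamma, u=u, df=fit.df)
    return RobustWorkspace(
        gamma=gamma, w=w, delta=delta, u=u, c=c, t_sb=t_sb, df=fit.df, n=fit.n
    )


def satorra_bentler_scale(t_ml, workspace: RobustWorkspace | None = None, df: int | None = None,
                          *, gamma=None, u=None):
    """Scaling factor c = tr(U Gamma)/df and scaled statistic T_SB = T_ML/c."""
    if workspace is not None:
        gamma, u = workspace.gamma, workspace.u
        df = workspace.df if df is None else df
    if df is None or df <= 0:
        raise SpecificationError("Satorra-Bentler scaling requires df > 0")
    c = float(np.trace(u @ gamma)) / df
    if c <= 0:
        raise SevsemError(f"non-positive scaling factor c = {c:.3e}")
    return c, float(t_ml) / c


def robust_standard_errors(workspace: RobustWorkspace, moments: SampleMoments | None = None) -> np.ndarray:
    """Sandwich standard errors, (A^-1 D'W Gamma W D A^-1)/(n-1) with
    A = Delta' W Delta, diagonal square-rooted; order matches the fit's
    free-parameter ids."""
    w, delta, gamma = workspace.w, workspace.delta, workspace.gamma
    wd = w @ delta
    try:
        bread = sla.inv(delta.T @ wd)
    except sla.LinAlgError:
        raise SevsemError("singular information matrix: model not identified at theta-hat")
    n = moments.n if moments is not None else workspace.n
    meat = wd.T @ gamma @ wd
    cov = bread @ meat @ bread / (n - 1)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def robust_baseline_scale(moments: SampleMoments, gamma: np.ndarray):
    """SB-scale the closed-form independence baseline on the same Gamma.

    The baseline's Delta columns are the vech positions of the p free
    variances; its implied covariance is diag(S).
    """
    p = moments.p
    sigma_b = np.diag(np.diag(moments.S))
    w = normal_theory_weight(sigma_b)
    r, c = vech_indices(p)
    ps = len(r)
    delta = np.zeros((ps, p))
    for k, (i, j) in enumerate(zip(r, c)):
        if i == j:
            delta[k, i] = 1.0
    u = _residual_weight(w, delta)
    df_b = p * (p - 1) // 2
    return float(np.trace(u @ gamma)) / df_b


def robust_fit_indices(t_sb, df, t_sb_baseline, df_b, n) -> FitIndexReport:
    """CFI/RMSEA formulas applied to SB-scaled statistics."""
    return FitIndexReport(
        t_stat=t_sb,
        df=df,
        n=n,
        relative_chi_square=relative_chi_square(t_sb, df),
        cfi=cfi(t_sb, df, t_sb_baseline, df_b),
        rmsea=rmsea(t_sb, df, n),
        baseline_t=t_sb_baseline,
        baseline_df=df_b,
    )
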