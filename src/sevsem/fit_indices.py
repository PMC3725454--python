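"""Chi-square based fit statistics: relative chi-square, independence
baseline, CFI and RMSEA.

The baseline (null) model is the independence model with free variances,
whose ML solution has a closed form: the fitted variances equal the
sample variances, so F_baseline = -ln|R| with R the sample correlation
matrix, on df = p(p-1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NotPositiveDefiniteError, SaturatedModelError
from .sem_core import FitResult, SampleMoments

__all__ = [
    "FitIndexReport",
    "relative_chi_square",
    "baseline_independence_fit",
    "cfi",
    "rmsea",
    "fit_report",
]


@dataclass
class BaselineFit:
    """Closed-form independence-model fit (diagonal covariance, free variances)."""

    f_ml: float
    t_ml: float
    df: int
    n: int


@dataclass
class FitIndexReport:
    t_stat: float
    df: int
    n: int
    relative_chi_square: float
    cfi: float
    rmsea: float
    baseline_t: float
    baseline_df: int


def relative_chi_square(t: float, df: int) -> float:
    """t/df; the study reads values below 2 as adequate fit."""
    if df <= 0:
        raise SaturatedModelError("relative chi-square undefined for a saturated model (df = 0)")
    return t / df


def baseline_independence_fit(moments: SampleMoments) -> BaselineFit:
    """Fit the independence model in closed form: F = -ln|R|, df = p(p-1)/2."""
    sd = np.sqrt(np.diag(moments.S))
    R = moments.S / np.outer(sd, sd)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise NotPositiveDefiniteError("sample correlation matrix is singular")
    f = max(-logdet, 0.0)
    p = moments.p
    return BaselineFit(f_ml=f, t_ml=(moments.n - 1) * f, df=p * (p - 1) // 2, n=moments.n)


def cfi(t: float, df: int, t_b: float, df_b: int) -> float:
    """Comparative fit index, 1 - max(t-df,0)/max(t-df, t_b-df_b, 0)."""
    num = max(t - df, 0.0)
    den = max(t - df, t_b - df_b, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def rmsea(t: float, df: int, n: int) -> float:
    """Root mean square error of approximation, sqrt(max(0,(t-df)/(df (n-1))))."""
    if df <= 0:
        raise SaturatedModelError("RMSEA undefined for a saturated model (df = 0)")
    if n <= 1:
        raise SaturatedModelError("RMSEA requires n > 1")
    return float(np.sqrt(max(0.0, (t - df) / (df * (n - 1)))))


def fit_report(fit: FitResult, moments: SampleMoments | None = None) -> FitIndexReport:
    """Assemble the full fit-index report for a converged model fit."""
    mom = moments or fit.moments
    base = baseline_independence_fit(mom)
    return FitIndexReport(
        t_stat=fit.t_ml,
        df=fit.df,
        n=mom.n,
        relative_chi_square=relative_chi_square(fit.t_ml, fit.df) if fit.df > 0 else float("nan"),
        cfi=cfi(fit.t_ml, fit.df, base.t_ml, base.df),
        rmsea=rmsea(fit.t_ml, fit.df, mom.n) if fit.df > 0 else float("nan"),
        baseline_t=base.t_ml,
        baseline_df=base.df,
    )
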