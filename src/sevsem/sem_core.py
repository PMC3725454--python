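"""Maximum-likelihood covariance-structure estimation.

The engine works on the RAM representation of a model: with ``t`` total
variables (``p`` observed followed by ``m`` latent), an asymmetric path
matrix ``A`` (``A[i, j]`` = coefficient of ``j`` in the equation for
``i``), a symmetric matrix ``S`` of variances/covariances of exogenous
shocks, and the selection matrix ``F = [I_p 0]``.  The model-implied
covariance is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T

and the maximum-likelihood discrepancy between a sample covariance ``S0``
and ``Sigma`` is

    F_ML = ln|Sigma| + tr(S0 Sigma^-1) - ln|S0| - p,

minimized over the free parameters.  The chi-square statistic is
``T = (n - 1) F_ML`` (the convention of classical SEM software).

Optimization runs Fisher scoring (Gauss-Newton with the expected
information) on analytic derivatives, with L-BFGS-B escapes from
perturbed starts when scoring stalls; convergence is judged by a
scale-invariant score norm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt

from .exceptions import (
    ConvergenceError,
    IdentificationError,
    NotPositiveDefiniteError,
    SevsemError,
    SpecificationError,
)
from .model_spec import ModelSpec

__all__ = [
    "SampleMoments",
    "FitResult",
    "ParameterTable",
    "OptimizerOptions",
    "RAMModel",
    "covariance_from_correlation",
    "fml_discrepancy",
    "fit_ml",
    "standardize",
    "latent_rsquared",
]


# ---------------------------------------------------------------------------
# sample moments


def covariance_from_correlation(R: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Rescale a correlation matrix to a covariance matrix, diag(sd) R diag(sd)."""
    R = np.asarray(R, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise SpecificationError("correlation matrix must be square")
    if sd.shape != (R.shape[0],):
        raise SpecificationError("sd length does not match correlation dimension")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise SpecificationError("correlation matrix must have unit diagonal")
    if np.abs(R).max() > 1 + 1e-12:
        raise SpecificationError("correlation entries must lie in [-1, 1]")
    if np.any(sd <= 0):
        raise SpecificationError("standard deviations must be strictly positive")
    S = sd[:, None] * R * sd[None, :]
    return 0.5 * (S + S.T)


@dataclass
class SampleMoments:
    """Observed covariance matrix with sample size (and optional means)."""

    S: np.ndarray
    n: int
    names: list[str]
    means: Optional[np.ndarray] = None
    source: str = "raw"

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        p = self.S.shape[0]
        if self.S.shape != (p, p):
            raise SpecificationError("covariance matrix must be square")
        if len(self.names) != p:
            raise SpecificationError("variable names do not match matrix dimension")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise SpecificationError("covariance matrix is not symmetric")
        self.S = 0.5 * (self.S + self.S.T)
        if self.n < p + 1:
            raise SpecificationError(f"n={self.n} too small for p={p} variables")
        try:
            sla.cholesky(self.S, lower=True)
        except sla.LinAlgError:
            raise NotPositiveDefiniteError("sample covariance matrix is not positive definite")
        if self.means is not None:
            self.means = np.asarray(self.means, dtype=float)
            if self.means.shape != (p,):
                raise SpecificationError("means length does not match matrix dimension")

    @property
    def p(self) -> int:
        return self.S.shape[0]

    @classmethod
    def from_correlation(cls, R, sd, n, names, means=None) -> "SampleMoments":
        return cls(covariance_from_correlation(R, sd), n, list(names), means, source="correlation+sd")

    @classmethod
    def from_raw(cls, data: pd.DataFrame, n: Optional[int] = None) -> "SampleMoments":
        X = data.to_numpy(dtype=float)
        return cls(
            np.cov(X, rowvar=False, ddof=1),
            n if n is not None else X.shape[0],
            list(data.columns),
            means=X.mean(axis=0),
            source="raw",
        )

    def subset(self, names: list[str]) -> "SampleMoments":
        idx = [self.names.index(v) for v in names]
        return SampleMoments(
            self.S[np.ix_(idx, idx)],
            self.n,
            list(names),
            None if self.means is None else self.means[idx],
            source=self.source,
        )


# ---------------------------------------------------------------------------
# vech helpers (column-major lower triangle, used consistently everywhere)


def vech_indices(p: int):
    rows, cols = [], []
    for j in range(p):
        for i in range(j, p):
            rows.append(i)
            cols.append(j)
    return np.array(rows), np.array(cols)


def vech(M: np.ndarray) -> np.ndarray:
    r, c = vech_indices(M.shape[0])
    return M[r, c]


def duplication_matrix(p: int) -> np.ndarray:
    """D with vec(M) = D vech(M) for symmetric M."""
    ps = p * (p + 1) // 2
    D = np.zeros((p * p, ps))
    r, c = vech_indices(p)
    for k, (i, j) in enumerate(zip(r, c)):
        D[j * p + i, k] = 1.0
        if i != j:
            D[i * p + j, k] = 1.0
    return D


# ---------------------------------------------------------------------------
# RAM machinery


class RAMModel:
    """Numeric RAM realization of a :class:`ModelSpec`.

    Maps the free-parameter vector ``theta`` onto slots of A and S and
    provides the implied covariance and its analytic derivatives.
    """

    def __init__(self, spec: ModelSpec):
        spec.validate()
        self.spec = spec
        self.obs = list(spec.observed_vars)
        self.lat = list(spec.latent_vars)
        self.names = self.obs + self.lat
        self.p = len(self.obs)
        self.m = len(self.lat)
        self.t = self.p + self.m
        ix = {v: i for i, v in enumerate(self.names)}

        self.A0 = np.zeros((self.t, self.t))
        self.S0 = np.zeros((self.t, self.t))
        # slots[pid] = list of ("A"|"S", i, j)
        slots: dict[str, list[tuple[str, int, int]]] = {}

        def add(entry_pid, fixed, mat, i, j):
            if fixed is not None:
                if mat == "A":
                    self.A0[i, j] = fixed
                else:
                    self.S0[i, j] = fixed
                    self.S0[j, i] = fixed
            else:
                slots.setdefault(entry_pid, []).append((mat, i, j))

        for ld in spec.loadings:
            add(ld.pid, ld.fixed, "A", ix[ld.indicator], ix[ld.factor])
        for pa in spec.structural_paths:
            add(pa.pid, pa.fixed, "A", ix[pa.target], ix[pa.source])
        for cv in spec.factor_covariances + spec.residual_variances:
            add(cv.pid, cv.fixed, "S", ix[cv.var1], ix[cv.var2])

        # merge equality classes
        rep = {}
        for cls in spec.constraints:
            for pid in cls:
                rep[pid] = cls[0]
        merged: dict[str, list[tuple[str, int, int]]] = {}
        for pid, sl in slots.items():
            merged.setdefault(rep.get(pid, pid), []).extend(sl)
        self.param_ids = list(merged)
        self.slots = [merged[pid] for pid in self.param_ids]
        self.q = len(self.param_ids)
        self._vr, self._vc = vech_indices(self.p)

    # -- theta -> matrices ------------------------------------------------

    def matrices(self, theta: np.ndarray):
        A = self.A0.copy()
        S = self.S0.copy()
        for val, sl in zip(theta, self.slots):
            for mat, i, j in sl:
                if mat == "A":
                    A[i, j] = val
                else:
                    S[i, j] = val
                    S[j, i] = val
        return A, S

    def total_covariance(self, theta: np.ndarray) -> np.ndarray:
        """Implied covariance of all t variables, (I-A)^-1 S (I-A)^-T."""
        A, S = self.matrices(theta)
        I = np.eye(self.t)
        try:
            B = sla.solve(I - A, I)
        except sla.LinAlgError:
            raise SevsemError("singular (I - A): non-recursive or degenerate model")
        return B @ S @ B.T

    def implied(self, theta: np.ndarray) -> np.ndarray:
        C = self.total_covariance(theta)
        Sig = C[: self.p, : self.p]
        return 0.5 * (Sig + Sig.T)

    def _core(self, theta):
        A, S = self.matrices(theta)
        I = np.eye(self.t)
        B = sla.solve(I - A, I)
        C = B @ S @ B.T
        return A, S, B, C

    def dsigma_slots(self, theta: np.ndarray):
        """Yield (per-parameter) derivative matrices dSigma/dtheta_k (p x p)."""
        _, S, B, C = self._core(theta)
        P = B[: self.p, :]  # F B
        Cop = C[:, : self.p]  # C F^T
        out = []
        for sl in self.slots:
            dS = np.zeros((self.p, self.p))
            for mat, i, j in sl:
                if mat == "A":
                    u = P[:, i]
                    v = Cop[j, :]
                    dS += np.outer(u, v) + np.outer(v, u)
                else:
                    u = P[:, i]
                    v = P[:, j]
                    if i == j:
                        dS += np.outer(u, u)
                    else:
                        dS += np.outer(u, v) + np.outer(v, u)
            out.append(dS)
        return out

    def delta_matrix(self, theta: np.ndarray) -> np.ndarray:
        """Jacobian of vech(Sigma(theta)), shape p(p+1)/2 x q."""
        dmats = self.dsigma_slots(theta)
        return np.column_stack([d[self._vr, self._vc] for d in dmats])

    # -- start values ------------------------------------------------------

    def start_values(self, moments: SampleMoments) -> np.ndarray:
        """Scale-aware defaults: residuals at half the sample variance,
        loadings at half the indicator SD (sign from the correlation with
        the factor's first indicator), variances 1, paths 0."""
        ix = {v: i for i, v in enumerate(moments.names)}
        sd = np.sqrt(np.diag(moments.S))
        R = moments.S / np.outer(sd, sd)
        # scale of each factor: marker's sd if a marker is fixed, else 1
        fac_scale = {}
        fac_anchor = {}
        for f in self.lat:
            lds = [ld for ld in self.spec.loadings if ld.factor == f]
            marker = next((ld for ld in lds if ld.fixed is not None), None)
            if marker is not None and marker.indicator in ix:
                fac_scale[f] = sd[ix[marker.indicator]] / abs(marker.fixed or 1.0)
                fac_anchor[f] = marker.indicator
            else:
                fac_scale[f] = 1.0
                fac_anchor[f] = lds[0].indicator if lds else None
        theta = np.zeros(self.q)
        by_pid = {pid: k for k, pid in enumerate(self.param_ids)}
        for ld in self.spec.loadings:
            if ld.pid in by_pid and ld.indicator in ix:
                anchor = fac_anchor.get(ld.factor)
                sign = 1.0
                if anchor in ix and anchor != ld.indicator:
                    sign = np.sign(R[ix[ld.indicator], ix[anchor]]) or 1.0
                theta[by_pid[ld.pid]] = 0.5 * sign * sd[ix[ld.indicator]] / fac_scale[ld.factor]
        for cv in self.spec.residual_variances:
            if cv.pid in by_pid and cv.var1 in ix:
                theta[by_pid[cv.pid]] = 0.5 * moments.S[ix[cv.var1], ix[cv.var1]]
        for cv in self.spec.factor_covariances:
            if cv.pid in by_pid:
                if cv.var1 == cv.var2:
                    theta[by_pid[cv.pid]] = 0.5 * fac_scale[cv.var1] ** 2
                else:
                    theta[by_pid[cv.pid]] = 0.0
        return theta


# ---------------------------------------------------------------------------
# discrepancy


def _logdet_pd(M: np.ndarray) -> float:
    L = sla.cholesky(M, lower=True)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def fml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """ML discrepancy ln|Sigma| + tr(S Sigma^-1) - ln|S| - p (>= 0)."""
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = S.shape[0]
    if sigma.shape != (p, p):
        raise SpecificationError("dimension mismatch between S and Sigma")
    try:
        ld_s = _logdet_pd(S)
        c, low = sla.cho_factor(sigma, lower=True)
        ld_sig = 2.0 * float(np.sum(np.log(np.diag(c))))
        tr = float(np.trace(sla.cho_solve((c, low), S)))
    except sla.LinAlgError:
        raise NotPositiveDefiniteError("S and Sigma must both be positive definite")
    return max(ld_sig + tr - ld_s - p, 0.0)


# ---------------------------------------------------------------------------
# results


@dataclass
class ParameterEstimate:
    pid: str
    kind: str  # loading | path | covariance | variance
    estimate: float
    se: Optional[float] = None
    z: Optional[float] = None
    standardized: Optional[float] = None


@dataclass
class ParameterTable:
    entries: list[ParameterEstimate]
    rsquared: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, pid: str) -> ParameterEstimate:
        for e in self.entries:
            if e.pid == pid:
                return e
        raise KeyError(pid)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": e.pid,
                    "kind": e.kind,
                    "estimate": e.estimate,
                    "se": e.se,
                    "z": e.z,
                    "standardized": e.standardized,
                }
                for e in self.entries
            ]
        )


@dataclass
class FitResult:
    spec: ModelSpec
    ram: RAMModel
    moments: SampleMoments
    theta: np.ndarray
    f_ml: float
    t_ml: float
    df: int
    converged: bool
    n_iter: int
    grad_norm: float
    heywood: list[str] = field(default_factory=list)
    params: Optional[ParameterTable] = None

    @property
    def n(self) -> int:
        return self.moments.n

    @property
    def implied_sigma(self) -> np.ndarray:
        return self.ram.implied(self.theta)

    def theta_dict(self) -> dict[str, float]:
        return dict(zip(self.ram.param_ids, self.theta.tolist()))

    def to_json(self) -> str:
        d = {
            "f_ml": self.f_ml,
            "t_ml": self.t_ml,
            "df": self.df,
            "n": self.n,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "heywood": self.heywood,
            "theta": self.theta_dict(),
            "implied_sigma": self.implied_sigma.tolist(),
            "rsquared": self.params.rsquared if self.params else {},
            "parameters": [
                {
                    "parameter": e.pid,
                    "kind": e.kind,
                    "estimate": e.estimate,
                    "se": e.se,
                    "z": e.z,
                    "standardized": e.standardized,
                }
                for e in (self.params.entries if self.params else [])
            ],
        }
        return json.dumps(d, indent=2)


@dataclass
class OptimizerOptions:
    max_iter: int = 10_000
    gtol: float = 1e-6
    ftol: float = 1e-10
    n_restarts: int = 6


# ---------------------------------------------------------------------------
# fitting


_BIG = 1e12


def _objective(ram: RAMModel, S: np.ndarray):
    p = ram.p

    def fun(theta):
        try:
            Sig = ram.implied(theta)
            c, low = sla.cho_factor(Sig, lower=True)
        except (sla.LinAlgError, SevsemError, FloatingPointError):
            return _BIG, np.zeros(ram.q)
        ld_sig = 2.0 * np.sum(np.log(np.diag(c)))
        Sig_inv = sla.cho_solve((c, low), np.eye(p))
        f = ld_sig + float(np.sum(Sig_inv * S)) - _logdet_pd(S) - p
        G = Sig_inv - Sig_inv @ S @ Sig_inv  # dF/dSigma (x2 off-diagonal via symmetry)
        grad = np.array([float(np.sum(G * d)) for d in ram.dsigma_slots(theta)])
        return f, grad

    return fun


def expected_information(ram: RAMModel, theta: np.ndarray) -> np.ndarray:
    """Delta' W Delta with W the normal-theory weight, via the trace form
    0.5 tr(Sigma^-1 dSigma_j Sigma^-1 dSigma_k)."""
    Sig = ram.implied(theta)
    Sig_inv = sla.inv(Sig)
    M = [Sig_inv @ d for d in ram.dsigma_slots(theta)]
    q = ram.q
    info = np.empty((q, q))
    for j in range(q):
        for k in range(j, q):
            info[j, k] = info[k, j] = 0.5 * float(np.sum(M[j] * M[k].T))
    return info


def _score_vector(ram: RAMModel, theta: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Gradient of F_ML (equals 2 Delta' W vech(Sigma - S))."""
    Sig = ram.implied(theta)
    Sig_inv = sla.inv(Sig)
    G = Sig_inv - Sig_inv @ S @ Sig_inv
    return np.array([float(np.sum(G * d)) for d in ram.dsigma_slots(theta)])


def _scaled_gnorm(grad, info):
    """Scale-invariant gradient norm: each score component divided by the
    square root of its information diagonal (a score-to-SE ratio)."""
    d = np.sqrt(np.clip(np.diag(info), 1e-300, None))
    return float(np.max(np.abs(grad) / d))


def _fisher_scoring(fun, info_fun, theta0, options, max_steps=300):
    """Gauss-Newton/Fisher-scoring minimization of F_ML with Levenberg
    ridging and step halving.  Affine-invariant, so indifferent to the
    wildly different scales of loading and variance parameters."""
    theta = np.asarray(theta0, dtype=float).copy()
    q = theta.size
    f_val, grad = fun(theta)
    n_iter = 0
    ridge = 0.0
    gnorm = np.inf
    for _ in range(max_steps):
        if f_val >= _BIG:
            break
        try:
            info = info_fun(theta)
            # Jacobi preconditioning: parameters live on wildly different
            # scales, which makes the raw information ill-conditioned
            d = np.sqrt(np.clip(np.diag(info), 1e-300, None))
            gnorm = float(np.max(np.abs(grad) / d))
            if gnorm < options.gtol:
                break
            info_n = info / np.outer(d, d)
            if ridge:
                info_n = info_n + ridge * np.eye(q)
            with warnings.catch_warnings():
                # near-singular iterates are recovered by ridge + line search
                warnings.simplefilter("ignore", sla.LinAlgWarning)
                step = sla.solve(info_n, -0.5 * grad / d, assume_a="sym") / d
            # trust-region cap in the information metric: huge early steps
            # can hop into degenerate basins (e.g. a collapsed factor)
            slen = float(np.linalg.norm(d * step))
            if slen > 10.0:
                step *= 10.0 / slen
        except (sla.LinAlgError, FloatingPointError):
            ridge = max(ridge * 10, 1e-6)
            n_iter += 1
            continue
        t, improved = 1.0, False
        for _ in range(40):
            f_new, g_new = fun(theta + t * step)
            if f_new < f_val - 1e-15 or (
                f_new < _BIG and f_new <= f_val + 1e-15 and np.max(np.abs(g_new)) < np.max(np.abs(grad))
            ):
                theta, f_val, grad = theta + t * step, f_new, g_new
                improved = True
                break
            t *= 0.5
        n_iter += 1
        if improved:
            ridge /= 10
        else:
            if ridge > 1e6:
                break
            ridge = max(ridge * 10, 1e-6)
    if f_val < _BIG:
        try:
            gnorm = _scaled_gnorm(grad, info_fun(theta))
        except (sla.LinAlgError, FloatingPointError):
            gnorm = np.inf
    return theta, f_val, grad, gnorm, n_iter


def _minimize_fml(fun, info_fun, start, options):
    """Shared minimization driver: Fisher scoring, then scaled L-BFGS-B
    escapes from perturbed points when the (scale-invariant) gradient
    tolerance is not met."""
    theta, f_val, grad, gnorm, n_iter = _fisher_scoring(fun, info_fun, start, options, max_steps=500)
    rng = np.random.default_rng(0)
    attempt = 0
    while gnorm >= options.gtol and attempt < options.n_restarts:
        attempt += 1
        # alternate between re-entering from the original start (fresh
        # basin) and polishing the current best with an L-BFGS escape
        if attempt % 2 == 1:
            th0 = start * (1 + 0.2 * rng.standard_normal(start.size)) + 0.02 * rng.standard_normal(start.size)
            th1, f1, g1, gn1, it1 = _fisher_scoring(fun, info_fun, th0, options, max_steps=500)
            n_iter += it1
        else:
            th0 = theta if f_val < _BIG else start
            th0 = th0 * (1 + 0.1 * rng.standard_normal(th0.size)) + 0.01 * rng.standard_normal(th0.size)
            scale = np.maximum(np.abs(th0), 0.1)

            def scaled(u):
                f, g = fun(u * scale)
                return f, g * scale

            res = sopt.minimize(
                scaled, th0 / scale, jac=True, method="L-BFGS-B",
                options={"maxiter": options.max_iter, "ftol": options.ftol},
            )
            th1, f1, g1, gn1, it1 = _fisher_scoring(fun, info_fun, res.x * scale, options, max_steps=500)
            n_iter += int(res.nit) + it1
        if f1 < f_val or (gn1 < gnorm and f1 < _BIG and f1 <= f_val + 1e-12):
            theta, f_val, grad, gnorm = th1, f1, g1, gn1
    return theta, f_val, grad, gnorm, n_iter


def fit_ml(
    spec: ModelSpec,
    moments: SampleMoments,
    options: Optional[OptimizerOptions] = None,
    theta0: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit a model by maximum likelihood to sample moments.

    Fisher scoring from scale-aware start values, with scaled L-BFGS-B
    fallbacks from perturbed starts.  Raises :class:`ConvergenceError`
    when the gradient tolerance is never reached, and flags (never
    truncates) Heywood cases.
    """
    options = options or OptimizerOptions()
    spec.validate()
    missing = [v for v in spec.observed_vars if v not in moments.names]
    if missing:
        raise SpecificationError(f"moments lack model variables: {missing}")
    mom = moments if moments.names == spec.observed_vars else moments.subset(spec.observed_vars)
    ram = RAMModel(spec)
    df = ram.p * (ram.p + 1) // 2 - ram.q
    if df < 0:
        raise IdentificationError("negative degrees of freedom")
    fun = _objective(ram, mom.S)
    info_fun = lambda th: expected_information(ram, th)
    start = ram.start_values(mom) if theta0 is None else np.asarray(theta0, dtype=float)

    theta, f_val, grad, grad_norm, n_iter = _minimize_fml(fun, info_fun, start, options)
    converged = f_val < _BIG and grad_norm < options.gtol * 10
    if not converged:
        raise ConvergenceError(
            f"no convergence after {n_iter} iterations (grad inf-norm {grad_norm:.2e})",
            trace={"theta": theta, "f": f_val},
        )

    heywood = []
    th_map = dict(zip(ram.param_ids, theta))
    for cv in spec.residual_variances + spec.factor_covariances:
        if cv.var1 == cv.var2 and cv.pid in th_map and th_map[cv.pid] < 0:
            heywood.append(cv.pid)

    fit = FitResult(
        spec=spec,
        ram=ram,
        moments=mom,
        theta=theta,
        f_ml=float(f_val),
        t_ml=float((mom.n - 1) * f_val),
        df=df,
        converged=converged,
        n_iter=n_iter,
        grad_norm=grad_norm,
        heywood=heywood,
    )
    fit.params = standardize(fit, spec)
    return fit


# ---------------------------------------------------------------------------
# standardized solution


def standardize(fit: FitResult, spec: Optional[ModelSpec] = None) -> ParameterTable:
    """Standardized solution: every loading/path rescaled by the implied
    SDs of its endpoints, covariances turned into correlations, and R^2
    for each endogenous latent (1 minus the standardized disturbance)."""
    spec = spec or fit.spec
    ram = fit.ram
    if not fit.converged:
        raise ConvergenceError("cannot standardize a non-converged fit")
    C = ram.total_covariance(fit.theta)
    sd = np.sqrt(np.abs(np.diag(C)))
    if np.any(sd == 0):
        raise SevsemError("zero implied variance; standardization undefined")
    ix = {v: i for i, v in enumerate(ram.names)}
    th = dict(zip(ram.param_ids, fit.theta))
    # normal-theory SEs
    se_map: dict[str, float] = {}
    try:
        info = expected_information(ram, fit.theta)
        cov_theta = sla.inv(info) / (fit.n - 1)
        ses = np.sqrt(np.clip(np.diag(cov_theta), 0, None))
        se_map = dict(zip(ram.param_ids, ses))
    except sla.LinAlgError:
        pass

    def entry(pid, kind, raw, std):
        se = se_map.get(pid)
        z = raw / se if se not in (None, 0) and se is not None and se > 0 else None
        return ParameterEstimate(pid, kind, float(raw), se, z, float(std))

    rep = {}
    for cls in spec.constraints:
        for pid in cls:
            rep[pid] = cls[0]

    entries = []
    for ld in spec.loadings:
        raw = ld.fixed if ld.fixed is not None else th[rep.get(ld.pid, ld.pid)]
        std = raw * sd[ix[ld.factor]] / sd[ix[ld.indicator]]
        entries.append(entry(ld.pid, "loading", raw, std))
    for pa in spec.structural_paths:
        raw = pa.fixed if pa.fixed is not None else th[rep.get(pa.pid, pa.pid)]
        std = raw * sd[ix[pa.source]] / sd[ix[pa.target]]
        entries.append(entry(pa.pid, "path", raw, std))
    for cv in spec.factor_covariances + spec.residual_variances:
        raw = cv.fixed if cv.fixed is not None else th[rep.get(cv.pid, cv.pid)]
        i, j = ix[cv.var1], ix[cv.var2]
        if cv.var1 == cv.var2:
            std = raw / C[i, i] if C[i, i] != 0 else np.nan
            entries.append(entry(cv.pid, "variance", raw, std))
        else:
            std = C[i, j] / (sd[i] * sd[j])
            entries.append(entry(cv.pid, "covariance", raw, std))

    rsq = {}
    for f, endo in spec.latent_vars.items():
        if endo:
            dist = next(
                (cv for cv in spec.factor_covariances if cv.var1 == f and cv.var2 == f), None
            )
            if dist is not None:
                raw = dist.fixed if dist.fixed is not None else th[rep.get(dist.pid, dist.pid)]
                rsq[f] = float(1.0 - raw / C[ix[f], ix[f]])
    return ParameterTable(entries, rsq)


def latent_rsquared(fit: FitResult, latent: str) -> float:
    """Proportion of an endogenous factor's variance explained by its predictors."""
    if latent not in fit.spec.latent_vars:
        raise SpecificationError(f"unknown latent factor {latent!r}")
    if not fit.spec.latent_vars[latent]:
        raise SpecificationError(f"factor {latent!r} is exogenous; R^2 undefined")
    table = fit.params or standardize(fit)
    return table.rsquared[latent]
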