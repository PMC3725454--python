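"""Multi-group estimation with cross-group equality constraints and
Lagrange-multiplier release tests.

The same model is fitted simultaneously in G groups by minimizing the
weighted discrepancy sum

    T(theta) = sum_g (n_g - 1) F_ML(S_g, Sigma(theta_g)),

where each group's parameter vector theta_g is a selection from one
joint vector: parameters named in the constraint set share a single
estimate across groups, all others are group-specific.  At the optimum
T is the likelihood-ratio chi-square on G p(p+1)/2 - q_joint degrees of
freedom.

Releasing one equality constraint is scored without refitting by the
univariate Lagrange-multiplier (score) statistic s' I^-1 s evaluated at
the constrained optimum in the released parametrization; it is
asymptotically chi-square with G-1 degrees of freedom and equal to the
likelihood-ratio drop from actually refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg as sla
import scipy.stats as sstats

from .exceptions import SevsemError, SpecificationError
from .model_spec import ModelSpec
from .sem_core import (
    FitResult,
    OptimizerOptions,
    RAMModel,
    SampleMoments,
    _BIG,
    _minimize_fml,
    _objective,
    expected_information,
    standardize,
)

__all__ = [
    "MultiGroupFit",
    "LMResult",
    "default_invariance_constraints",
    "fit_multigroup",
    "lm_release_test",
    "invariance_report",
]


def default_invariance_constraints(spec: ModelSpec) -> list[str]:
    """All free loadings, structural paths, and factor covariances —
    the 'all paths equal' constraint set; residual and factor variances
    stay group-specific."""
    pids = []
    for ld in spec.loadings:
        if ld.fixed is None:
            pids.append(ld.pid)
    for pa in spec.structural_paths:
        if pa.fixed is None:
            pids.append(pa.pid)
    for cv in spec.factor_covariances:
        if cv.fixed is None and cv.var1 != cv.var2:
            pids.append(cv.pid)
    return pids


@dataclass
class LMResult:
    constraint: str
    statistic: float
    df: int
    p_value: float
    released: bool = False


@dataclass
class MultiGroupFit:
    spec: ModelSpec
    labels: list[str]
    groups: list[SampleMoments]
    constraints: list[str]
    param_ids: list[str]
    theta: np.ndarray
    t_ml_total: float
    df: int
    converged: bool
    n_iter: int
    grad_norm: float
    ram: RAMModel
    group_index: list[np.ndarray]  # theta_g = theta[group_index[g]]
    lm_results: list[LMResult] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return sum(m.n for m in self.groups)

    def theta_dict(self) -> dict[str, float]:
        return dict(zip(self.param_ids, self.theta.tolist()))

    def group_theta(self, g: int) -> np.ndarray:
        return self.theta[self.group_index[g]]

    def group_fit(self, g: int) -> FitResult:
        """Single-group view of the joint solution (for standardization)."""
        mom = self.groups[g]
        th = self.group_theta(g)
        sig = self.ram.implied(th)
        from .sem_core import fml_discrepancy

        f = fml_discrepancy(mom.S, sig)
        fit = FitResult(
            spec=self.spec,
            ram=self.ram,
            moments=mom,
            theta=th,
            f_ml=f,
            t_ml=(mom.n - 1) * f,
            df=self.df,
            converged=self.converged,
            n_iter=self.n_iter,
            grad_norm=self.grad_norm,
        )
        fit.params = standardize(fit, self.spec)
        return fit


def _joint_maps(ram: RAMModel, labels: Sequence[str], constraints: Sequence[str]):
    """Joint parameter ids and per-group index arrays into the joint vector."""
    con = set(constraints)
    unknown = con - set(ram.param_ids)
    if unknown:
        raise SpecificationError(f"constraints on unknown/fixed parameters: {sorted(unknown)}")
    joint: dict[str, int] = {}
    group_index = []
    for lab in labels:
        idx = []
        for pid in ram.param_ids:
            jid = pid if pid in con else f"{pid}@{lab}"
            if jid not in joint:
                joint[jid] = len(joint)
            idx.append(joint[jid])
        group_index.append(np.array(idx))
    return list(joint), group_index


def _joint_objective(ram, moments_list, weights, group_index, q_joint):
    funs = [_objective(ram, m.S) for m in moments_list]

    def fun(theta):
        total = 0.0
        grad = np.zeros(q_joint)
        for f_g, w, idx in zip(funs, weights, group_index):
            fv, gv = f_g(theta[idx])
            if fv >= _BIG:
                return _BIG, np.zeros(q_joint)
            total += w * fv
            np.add.at(grad, idx, w * gv)
        return total, grad

    def info_fun(theta):
        info = np.zeros((q_joint, q_joint))
        for w, idx in zip(weights, group_index):
            ig = expected_information(ram, theta[idx])
            info[np.ix_(idx, idx)] += w * ig
        return info

    return fun, info_fun


def fit_multigroup(
    spec: ModelSpec,
    groups,
    constraints: Optional[Sequence[str]] = None,
    options: Optional[OptimizerOptions] = None,
    compute_lm: bool = False,
    alpha: float = 0.05,
) -> MultiGroupFit:
    """Fit one spec simultaneously in several groups.

    ``groups`` is a list of (label, SampleMoments) pairs (or a dict).
    ``constraints`` lists parameter ids held equal across groups; the
    default is no cross-group constraints.
    """
    options = options or OptimizerOptions()
    if isinstance(groups, dict):
        groups = list(groups.items())
    labels = [str(lab) for lab, _ in groups]
    moments_list = []
    for _, m in groups:
        mm = m if m.names == spec.observed_vars else m.subset(spec.observed_vars)
        if mm.n <= mm.p:
            raise SpecificationError(f"group with n={mm.n} <= p={mm.p} cannot be fitted")
        moments_list.append(mm)
    if len(moments_list) < 1:
        raise SpecificationError("at least one group is required")
    constraints = list(constraints or [])
    ram = RAMModel(spec)
    joint_ids, group_index = _joint_maps(ram, labels, constraints)
    q_joint = len(joint_ids)
    weights = [m.n - 1 for m in moments_list]
    fun, info_fun = _joint_objective(ram, moments_list, weights, group_index, q_joint)

    start = np.zeros(q_joint)
    counts = np.zeros(q_joint)
    for m, idx in zip(moments_list, group_index):
        s = ram.start_values(m)
        np.add.at(start, idx, s)
        np.add.at(counts, idx, 1.0)
    start /= counts

    theta, t_val, grad, grad_norm, n_iter = _minimize_fml(fun, info_fun, start, options)
    converged = t_val < _BIG and grad_norm < options.gtol * 10
    if not converged:
        raise SevsemError(
            f"multi-group fit did not converge (scaled grad inf-norm {grad_norm:.2e})"
        )

    p = ram.p
    df = len(moments_list) * p * (p + 1) // 2 - q_joint
    fit = MultiGroupFit(
        spec=spec,
        labels=labels,
        groups=moments_list,
        constraints=constraints,
        param_ids=joint_ids,
        theta=theta,
        t_ml_total=float(t_val),
        df=df,
        converged=converged,
        n_iter=n_iter,
        grad_norm=grad_norm,
        ram=ram,
        group_index=group_index,
    )
    if compute_lm:
        fit.lm_results = [lm_release_test(fit, c) for c in constraints]
        for r in fit.lm_results:
            r.released = r.p_value < alpha
    return fit


def lm_release_test(fit: MultiGroupFit, constraint: str) -> LMResult:
    """Score (LM) test for releasing one cross-group equality constraint.

    The released parametrization splits the shared parameter into one
    per group; the statistic is s' I^-1 s with score s and expected
    information I of the released model, both evaluated at the
    constrained optimum.
    """
    if constraint not in fit.constraints:
        raise SpecificationError(f"{constraint!r} is not an active constraint of this fit")
    ram = fit.ram
    G = len(fit.groups)
    joint_ids, rel_index = _joint_maps(
        ram, fit.labels, [c for c in fit.constraints if c != constraint]
    )
    q_rel = len(joint_ids)
    # embed the constrained solution into the released space
    con_map = {pid: k for k, pid in enumerate(fit.param_ids)}
    theta_rel = np.zeros(q_rel)
    for g, lab in enumerate(fit.labels):
        for k, pid in enumerate(ram.param_ids):
            jid_con = pid if pid in fit.constraints else f"{pid}@{lab}"
            theta_rel[rel_index[g][k]] = fit.theta[con_map[jid_con]]

    score = np.zeros(q_rel)
    info = np.zeros((q_rel, q_rel))
    for g, mom in enumerate(fit.groups):
        idx = rel_index[g]
        th_g = theta_rel[idx]
        w = mom.n - 1
        fg = _objective(ram, mom.S)
        _, grad_g = fg(th_g)
        np.add.at(score, idx, -0.5 * w * grad_g)  # score of the log-likelihood
        info[np.ix_(idx, idx)] += w * expected_information(ram, th_g)
    d = np.sqrt(np.clip(np.diag(info), 1e-300, None))
    try:
        lm = float(score / d @ sla.solve(info / np.outer(d, d), score / d, assume_a="sym"))
    except sla.LinAlgError:
        raise SevsemError("singular released-model information in LM test")
    lm = max(lm, 0.0)
    df = G - 1
    return LMResult(constraint, lm, df, float(sstats.chi2.sf(lm, df)))


def invariance_report(fit: MultiGroupFit, alpha: float = 0.05) -> list[LMResult]:
    """LM statistics for every active constraint, sorted descending;
    constraints with p < alpha are flagged for release."""
    results = fit.lm_results or [lm_release_test(fit, c) for c in fit.constraints]
    out = sorted(results, key=lambda r: -r.statistic)
    for r in out:
        r.released = bool(alpha > 0 and r.p_value < alpha)
    return out
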