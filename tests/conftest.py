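"""Shared fixtures, including the session-scoped simulation studies that
several test modules assert against."""

from __future__ import annotations

import numpy as np
import pytest

from sevsem import SampleMoments, fit_ml
from sevsem.multigroup import (
    default_invariance_constraints,
    fit_multigroup,
    invariance_report,
)
from sevsem.model_spec import parse_model_syntax
from sevsem.robust_stats import build_workspace
from sevsem.study import load_study_moments, model_a_spec, run_model_a
from sevsem.synthetic import (
    MarginSpec,
    SyntheticSpec,
    generate_sample,
    generate_study_like_groups,
    generate_study_sample,
)

# --- a small two-factor model used for the calibration simulations --------

SMALL_MODEL = """\
F1 =~ x1 + x2 + x3
F2 =~ x4 + x5 + x6
F1 ~~ F2
"""
SMALL_LOADINGS = np.array([0.7, 0.8, 0.6, 0.7, 0.6, 0.8])
SMALL_FACTOR_R = 0.3


def small_model_sigma() -> np.ndarray:
    """Population covariance of the small model, built directly from
    factor algebra (Lambda Phi Lambda' + Theta), independent of the RAM
    machinery under test."""
    lam = np.zeros((6, 2))
    lam[:3, 0] = SMALL_LOADINGS[:3]
    lam[3:, 1] = SMALL_LOADINGS[3:]
    phi = np.array([[1.0, SMALL_FACTOR_R], [SMALL_FACTOR_R, 1.0]])
    theta = np.diag(1.0 - SMALL_LOADINGS**2)
    return lam @ phi @ lam.T + theta


SMALL_NAMES = [f"x{i}" for i in range(1, 7)]


@pytest.fixture(scope="session")
def small_spec():
    return parse_model_syntax(SMALL_MODEL)


@pytest.fixture(scope="session")
def table1_moments():
    return load_study_moments()


@pytest.fixture(scope="session")
def model_a_fit(table1_moments):
    return fit_ml(model_a_spec(), table1_moments)


@pytest.fixture(scope="session")
def model_a_report():
    return run_model_a()


# --- simulation studies ----------------------------------------------------


@pytest.fixture(scope="session")
def tml_null_sim(small_spec):
    """Null distribution of T_ML: 500 normal-data replicates of the
    correctly specified small model at n = 500."""
    sigma = small_model_sigma()
    L = np.linalg.cholesky(sigma)
    rng = np.random.default_rng(20240501)
    ts = []
    for _ in range(500):
        X = rng.standard_normal((500, 6)) @ L.T
        mom = SampleMoments(np.cov(X, rowvar=False), 500, SMALL_NAMES)
        ts.append(fit_ml(small_spec, mom).t_ml)
    return np.array(ts), 8  # df = 21 - 13


@pytest.fixture(scope="session")
def sb_leptokurtic_sim(small_spec):
    """Satorra-Bentler calibration: 200 replicates of the correctly
    specified small model with strongly non-normal margins (skew 1.5,
    excess kurtosis 6 — right-skewed and leptokurtic like the alcohol
    scores) at n = 500."""
    sigma = small_model_sigma()
    margins = [MarginSpec(0.0, 1.0, 1.5, 6.0) for _ in range(6)]
    out = {"t_ml": [], "t_sb": [], "c": []}
    for rep in range(200):
        spec = SyntheticSpec(sigma, margins, 500, SMALL_NAMES, seed=30_000 + rep)
        raw = generate_sample(spec)
        fit = fit_ml(small_spec, SampleMoments.from_raw(raw))
        ws = build_workspace(fit, raw)
        out["t_ml"].append(fit.t_ml)
        out["t_sb"].append(ws.t_sb)
        out["c"].append(ws.c)
    return {k: np.array(v) for k, v in out.items()} | {"df": 8}


@pytest.fixture(scope="session")
def recovery_fit():
    """Parameter recovery at n = 100 000 from the study-model structure
    with normal margins."""
    raw = generate_study_sample(n=100_000, seed=77, nonnormal=False)
    return fit_ml(model_a_spec(), SampleMoments.from_raw(raw))


@pytest.fixture(scope="session")
def lm_power_sim():
    """100 two-group replicates with the BAI and BDI loadings offset by
    -0.2 in the second group; records the top-2 and released constraints."""
    spec = model_a_spec()
    cons = default_invariance_constraints(spec)
    offsets = {("Affective", "BAI"): -0.2, ("Affective", "BDI"): -0.2}
    results = []
    for rep in range(100):
        g = generate_study_like_groups(
            500, 500, loading_offsets=offsets, seed=40_000 + rep, nonnormal=False
        )
        data, groups = g.drop(columns="gender"), g["gender"]
        moms = [
            (lab, SampleMoments.from_raw(data.loc[groups == lab, spec.observed_vars]))
            for lab in sorted(groups.unique())
        ]
        fit = fit_multigroup(spec, moms, cons)
        rep_list = invariance_report(fit, alpha=0.05)
        results.append(
            {
                "top2": {rep_list[0].constraint, rep_list[1].constraint},
                "released": {r.constraint for r in rep_list if r.released},
            }
        )
    return results
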