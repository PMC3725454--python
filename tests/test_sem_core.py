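"""The ML estimation engine: moment construction, implied covariance
against an independent path-accumulation oracle, the discrepancy
function, fitting, standardization and latent R-squared."""

import numpy as np
import pytest

from conftest import SMALL_NAMES, small_model_sigma

from sevsem import (
    SampleMoments,
    covariance_from_correlation,
    fit_ml,
    fml_discrepancy,
    latent_rsquared,
)
from sevsem.exceptions import NotPositiveDefiniteError, SpecificationError
from sevsem.model_spec import parse_model_syntax
from sevsem.sem_core import RAMModel


def path_accumulation_covariance(ram, theta):
    """Independent oracle for recursive models: expand each variable's
    equation by repeated back-substitution (total effects M = I + A +
    A^2 + ... , requiring nilpotent A), then M S M'."""
    A, S = ram.matrices(theta)
    t = A.shape[0]
    M = np.eye(t)
    power = np.eye(t)
    for _ in range(t):
        power = power @ A
        M += power
    assert np.allclose(power @ A, 0), "fixture must be recursive (nilpotent A)"
    C = M @ S @ M.T
    return C[: ram.p, : ram.p]


class TestSampleMoments:
    def test_identity_correlation_gives_diagonal_sd_squared(self):
        sd = np.array([2.0, 3.0, 0.5])
        assert np.allclose(covariance_from_correlation(np.eye(3), sd), np.diag(sd**2))

    def test_study_table_rescaling(self, table1_moments):
        S = table1_moments.S
        i = table1_moments.names.index("ADS")
        j = table1_moments.names.index("PACS")
        assert S[i, i] == pytest.approx(7.31**2)  # 53.4361
        assert S[i, j] == pytest.approx(0.50 * 7.31 * 6.61, abs=5e-3)  # 24.16

    def test_non_unit_diagonal_rejected(self):
        R = np.array([[1.0, 0.2], [0.2, 0.9]])
        with pytest.raises(SpecificationError):
            covariance_from_correlation(R, np.ones(2))

    def test_non_positive_definite_rejected(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(NotPositiveDefiniteError):
            SampleMoments(S, 50, ["a", "b"])

    def test_n_too_small_rejected(self):
        with pytest.raises(SpecificationError):
            SampleMoments(np.eye(3), 3, ["a", "b", "c"])


class TestDiscrepancy:
    def test_zero_at_equality(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = rng.standard_normal((4, 4))
            S = A @ A.T + 4 * np.eye(4)
            assert fml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_closed_form(self):
        # p=1, S=2, Sigma=1: ln 1 + 2 - ln 2 - 1 = 0.3069
        assert fml_discrepancy([[2.0]], [[1.0]]) == pytest.approx(1 - np.log(2), abs=1e-12)
        assert round(fml_discrepancy([[2.0]], [[1.0]]), 4) == 0.3069

    def test_positive_whenever_matrices_differ(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            A = rng.standard_normal((3, 3))
            B = rng.standard_normal((3, 3))
            S = A @ A.T + 3 * np.eye(3)
            Sig = B @ B.T + 3 * np.eye(3)
            assert fml_discrepancy(S, Sig) > 0


class TestImpliedCovariance:
    def test_zero_loadings_give_diagonal_residuals(self):
        spec = parse_model_syntax("F =~ x1 + x2 + x3\n")
        ram = RAMModel(spec)
        # loadings zero, residual variances 1
        theta = np.array([0.0 if "=~" in pid else 1.0 for pid in ram.param_ids])
        assert np.allclose(ram.implied(theta), np.eye(3))

    def test_two_indicator_product_rule(self):
        spec = parse_model_syntax("F =~ x1 + x2\n")
        ram = RAMModel(spec)
        vals = {"F=~x1": 0.6, "F=~x2": 0.8, "x1~~x1": 0.64, "x2~~x2": 0.36}
        theta = np.array([vals[pid] for pid in ram.param_ids])
        sig = ram.implied(theta)
        assert sig[0, 1] == pytest.approx(0.48, abs=1e-12)
        assert np.allclose(np.diag(sig), 1.0)

    @pytest.mark.parametrize(
        "text",
        [
            "F =~ x1 + x2 + x3\n",
            "F1 =~ x1 + x2 + x3\nF2 =~ x4 + x5\nF1 ~~ F2\n",
            # structural chain with an endogenous factor
            "F1 =~ 1*x1 + x2\nF2 =~ 1*x3 + x4\nF2 ~ F1\n",
            # observed-only covariance model
            "x1 ~~ x2\nx2 ~~ x3\n",
        ],
    )
    def test_matches_path_accumulation_oracle(self, text):
        spec = parse_model_syntax(text)
        ram = RAMModel(spec)
        rng = np.random.default_rng(42)
        theta = np.array(
            [
                rng.uniform(0.4, 0.9) if ("=~" in pid or "~~" not in pid) else
                (rng.uniform(0.5, 1.5) if pid.split("~~")[0] == pid.split("~~")[1] else rng.uniform(-0.2, 0.2))
                for pid in ram.param_ids
            ]
        )
        assert np.allclose(ram.implied(theta), path_accumulation_covariance(ram, theta), atol=1e-10)

    def test_model_a_implied_matches_oracle_at_solution(self, model_a_fit):
        ram, theta = model_a_fit.ram, model_a_fit.theta
        assert np.allclose(ram.implied(theta), path_accumulation_covariance(ram, theta), atol=1e-10)

    def test_model_a_implied_ads_pacs_correlation(self, model_a_fit):
        # path tracing with the standardized loadings: ~0.737 * 0.639 = 0.471,
        # under-reproducing the sample 0.50 (absorbed by the residual misfit)
        sig = model_a_fit.implied_sigma
        names = model_a_fit.moments.names
        i, j = names.index("ADS"), names.index("PACS")
        r = sig[i, j] / np.sqrt(sig[i, i] * sig[j, j])
        std = {e.pid: e.standardized for e in model_a_fit.params.entries}
        assert r == pytest.approx(std["Severity=~ADS"] * std["Severity=~PACS"], abs=1e-10)
        assert r == pytest.approx(0.471, abs=0.02)


class TestFitML:
    def test_saturated_model_fits_perfectly(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((3, 3))
        S = A @ A.T + 3 * np.eye(3)
        spec = parse_model_syntax("x1 ~~ x2\nx1 ~~ x3\nx2 ~~ x3\n")
        fit = fit_ml(spec, SampleMoments(S, 100, ["x1", "x2", "x3"]))
        assert fit.df == 0
        assert fit.f_ml == pytest.approx(0.0, abs=1e-10)
        assert fit.t_ml == pytest.approx(0.0, abs=1e-8)

    def test_population_moments_recovered_exactly(self, small_spec):
        # fitting the population covariance returns the generating values
        mom = SampleMoments(small_model_sigma(), 10_000, SMALL_NAMES)
        fit = fit_ml(small_spec, mom)
        assert fit.f_ml == pytest.approx(0.0, abs=1e-10)
        std = {e.pid: e.standardized for e in fit.params.entries if e.kind == "loading"}
        for i, pid in enumerate(["F1=~x1", "F1=~x2", "F1=~x3", "F2=~x4", "F2=~x5", "F2=~x6"]):
            assert std[pid] == pytest.approx([0.7, 0.8, 0.6, 0.7, 0.6, 0.8][i], abs=1e-7)
        corr = next(e for e in fit.params.entries if e.pid == "F1~~F2")
        assert corr.standardized == pytest.approx(0.3, abs=1e-7)

    def test_chi_square_uses_n_minus_one(self, small_spec):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 6)) @ np.linalg.cholesky(small_model_sigma()).T
        mom = SampleMoments(np.cov(X, rowvar=False), 200, SMALL_NAMES)
        fit = fit_ml(small_spec, mom)
        assert fit.t_ml == pytest.approx(199 * fit.f_ml, rel=1e-12)

    def test_scale_invariance_of_fit_and_standardized_solution(self, table1_moments):
        from sevsem.study import model_a_spec

        spec = model_a_spec()
        fit1 = fit_ml(spec, table1_moments)
        scale = np.ones(table1_moments.p)
        scale[table1_moments.names.index("DRINC")] = 10.0
        S2 = table1_moments.S * np.outer(scale, scale)
        fit2 = fit_ml(spec, SampleMoments(S2, table1_moments.n, table1_moments.names))
        assert fit2.f_ml == pytest.approx(fit1.f_ml, abs=1e-8)
        std1 = {e.pid: e.standardized for e in fit1.params.entries}
        std2 = {e.pid: e.standardized for e in fit2.params.entries}
        for pid in std1:
            assert std2[pid] == pytest.approx(std1[pid], abs=1e-6)

    def test_null_chi_square_calibration(self, tml_null_sim):
        ts, df = tml_null_sim
        assert abs(ts.mean() - df) / df < 0.05

    def test_parameter_recovery_large_n(self, recovery_fit):
        from sevsem.synthetic import STUDY_TRUE_STANDARDIZED

        std = {e.pid: e.standardized for e in recovery_fit.params.entries}
        for (f, v), lam in STUDY_TRUE_STANDARDIZED["loadings"].items():
            assert std[f"{f}=~{v}"] == pytest.approx(lam, abs=0.02)
        for (f, t), b in STUDY_TRUE_STANDARDIZED["paths"].items():
            assert std[f"{t}~{f}"] == pytest.approx(b, abs=0.02)

    def test_heywood_case_flagged_not_truncated(self):
        # lambda1*lambda2=.8, lambda1*lambda3=.8, lambda2*lambda3=.5
        # implies lambda1^2 = 1.28 and a negative residual for x1
        R = np.array([[1.0, 0.8, 0.8], [0.8, 1.0, 0.5], [0.8, 0.5, 1.0]])
        spec = parse_model_syntax("F =~ x1 + x2 + x3\n")
        fit = fit_ml(spec, SampleMoments(R, 200, ["x1", "x2", "x3"]))
        assert "x1~~x1" in fit.heywood
        assert fit.theta_dict()["x1~~x1"] < 0  # reported, not clamped


class TestStandardize:
    def test_sign_flip_indeterminacy(self, small_spec):
        sigma = small_model_sigma()
        flip = np.diag([1, 1, 1, -1, -1, -1]).astype(float)
        fit1 = fit_ml(small_spec, SampleMoments(sigma, 1000, SMALL_NAMES))
        fit2 = fit_ml(small_spec, SampleMoments(flip @ sigma @ flip, 1000, SMALL_NAMES))
        std1 = {e.pid: e.standardized for e in fit1.params.entries if e.kind != "variance"}
        std2 = {e.pid: e.standardized for e in fit2.params.entries if e.kind != "variance"}
        assert all(abs(abs(std1[p]) - abs(std2[p])) < 1e-6 for p in std1)

    def test_rsquared_from_single_standardized_path(self):
        # population model: F2 = 0.5 F1 + d, all factors standardized
        text = "F1 =~ x1 + x2 + x3\nF2 =~ 1*x4 + x5 + x6\nF2 ~ F1\n"
        spec = parse_model_syntax(text)
        lam = np.zeros((6, 2))
        lam[:3, 0] = [0.7, 0.8, 0.6]
        lam[3:, 1] = [0.7, 0.6, 0.8]
        phi = np.array([[1.0, 0.5], [0.5, 1.0]])  # corr(F1, F2) = path = 0.5
        sigma = lam @ phi @ lam.T + np.diag(1 - np.array([0.7, 0.8, 0.6, 0.7, 0.6, 0.8]) ** 2)
        fit = fit_ml(spec, SampleMoments(sigma, 1000, SMALL_NAMES))
        assert latent_rsquared(fit, "F2") == pytest.approx(0.25, abs=1e-6)

    def test_rsquared_rejects_exogenous_factor(self, model_a_fit):
        with pytest.raises(SpecificationError):
            latent_rsquared(model_a_fit, "Motivation")
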