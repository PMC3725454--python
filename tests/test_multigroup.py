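"""Multi-group equality-constrained fitting and Lagrange-multiplier
release tests."""

import numpy as np
import pytest

from conftest import SMALL_NAMES, small_model_sigma

from sevsem import SampleMoments, fit_ml
from sevsem.exceptions import SpecificationError
from sevsem.multigroup import (
    default_invariance_constraints,
    fit_multigroup,
    invariance_report,
    lm_release_test,
)
from sevsem.study import model_a_spec
from sevsem.synthetic import generate_study_like_groups


def _two_group_moments(spec, seed, n=500, offsets=None):
    g = generate_study_like_groups(n, n, loading_offsets=offsets, seed=seed, nonnormal=False)
    data, groups = g.drop(columns="gender"), g["gender"]
    return [
        (lab, SampleMoments.from_raw(data.loc[groups == lab, spec.observed_vars]))
        for lab in sorted(groups.unique())
    ]


class TestFitMultigroup:
    def test_single_group_reduces_to_fit_ml(self, small_spec):
        from sevsem import OptimizerOptions

        tight = OptimizerOptions(gtol=1e-10)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((400, 6)) @ np.linalg.cholesky(small_model_sigma()).T
        mom = SampleMoments(np.cov(X, rowvar=False), 400, SMALL_NAMES)
        single = fit_ml(small_spec, mom, options=tight)
        multi = fit_multigroup(small_spec, [("all", mom)], options=tight)
        th = multi.theta_dict()
        for pid, val in single.theta_dict().items():
            assert th[f"{pid}@all"] == pytest.approx(val, abs=1e-8)
        assert multi.t_ml_total == pytest.approx(single.t_ml, abs=1e-8)

    def test_identical_groups_fully_constrained_match_pooled_fit(self, small_spec):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 6)) @ np.linalg.cholesky(small_model_sigma()).T
        mom = SampleMoments(np.cov(X, rowvar=False), 300, SMALL_NAMES)
        from sevsem import OptimizerOptions

        tight = OptimizerOptions(gtol=1e-10)
        pooled = fit_ml(small_spec, mom, options=tight)
        ram_ids = pooled.ram.param_ids
        multi = fit_multigroup(small_spec, [("a", mom), ("b", mom)], constraints=ram_ids,
                               options=tight)
        th = multi.theta_dict()
        for pid, val in pooled.theta_dict().items():
            assert th[pid] == pytest.approx(val, abs=1e-7)

    def test_total_df_accounting(self, small_spec):
        mom = SampleMoments(small_model_sigma(), 500, SMALL_NAMES)
        cons = default_invariance_constraints(small_spec)  # 6 loadings + 1 covariance
        multi = fit_multigroup(small_spec, [("a", mom), ("b", mom)], constraints=cons)
        # q_joint = 7 shared + 2 x 6 residuals; total moments 2 x 21
        assert multi.df == 42 - (7 + 12)

    def test_group_smaller_than_p_rejected(self, small_spec):
        mom = SampleMoments(small_model_sigma(), 500, SMALL_NAMES)
        small = SampleMoments(small_model_sigma(), 500, SMALL_NAMES)
        small.n = 5
        with pytest.raises(SpecificationError):
            fit_multigroup(small_spec, [("a", mom), ("b", small)])

    def test_null_total_chi_square_calibration(self, small_spec):
        # two independent groups from the same parameters, all shared
        sigma = small_model_sigma()
        L = np.linalg.cholesky(sigma)
        cons = default_invariance_constraints(small_spec)
        rng = np.random.default_rng(8)
        ts = []
        for _ in range(200):
            moms = []
            for lab in ("a", "b"):
                X = rng.standard_normal((500, 6)) @ L.T
                moms.append((lab, SampleMoments(np.cov(X, rowvar=False), 500, SMALL_NAMES)))
            fit = fit_multigroup(small_spec, moms, constraints=cons)
            ts.append(fit.t_ml_total)
        df = fit.df
        assert abs(np.mean(ts) - df) / df < 0.1

    def test_power_against_a_shifted_bai_loading(self):
        # one group's standardized BAI loading differs by 0.3; the
        # targeted LM test localizes it almost surely, while the omnibus
        # total chi-square (113 df) dilutes the single-loading signal to
        # moderate - but clearly above-nominal - rejection rates
        import scipy.stats as sstats

        spec = model_a_spec()
        cons = default_invariance_constraints(spec)
        omnibus = lm_hits = 0
        reps = 20
        for s in range(reps):
            moms = _two_group_moments(
                spec, seed=60_000 + s, n=500, offsets={("Affective", "BAI"): -0.3}
            )
            fit = fit_multigroup(spec, moms, constraints=cons)
            crit = sstats.chi2.ppf(0.95, fit.df)
            omnibus += fit.t_ml_total > crit
            lm_hits += lm_release_test(fit, "Affective=~BAI").p_value < 0.05
        assert lm_hits / reps >= 0.9
        assert omnibus / reps >= 0.15  # well above the 5% null rate


class TestLMTest:
    def test_lm_zero_when_constraint_already_binds(self, small_spec):
        mom = SampleMoments(small_model_sigma(), 500, SMALL_NAMES)
        cons = default_invariance_constraints(small_spec)
        fit = fit_multigroup(small_spec, [("a", mom), ("b", mom)], constraints=cons)
        for c in cons:
            assert lm_release_test(fit, c).statistic < 1e-4

    def test_lm_agrees_with_refit_lr_drop(self, small_spec):
        spec = model_a_spec()
        moms = _two_group_moments(spec, seed=7, n=400, offsets={("Affective", "BAI"): -0.15})
        cons = default_invariance_constraints(spec)
        fit = fit_multigroup(spec, moms, cons)
        lm = lm_release_test(fit, "Affective=~BAI")
        released = fit_multigroup(spec, moms, [c for c in cons if c != "Affective=~BAI"])
        lr = fit.t_ml_total - released.t_ml_total
        assert abs(lm.statistic - lr) / lr < 0.15

    def test_group_relabeling_invariance(self, small_spec):
        rng = np.random.default_rng(12)
        L = np.linalg.cholesky(small_model_sigma())
        moms = []
        for lab in ("a", "b"):
            X = rng.standard_normal((400, 6)) @ L.T
            moms.append((lab, SampleMoments(np.cov(X, rowvar=False), 400, SMALL_NAMES)))
        cons = default_invariance_constraints(small_spec)
        f1 = fit_multigroup(small_spec, moms, cons)
        f2 = fit_multigroup(small_spec, moms[::-1], cons)
        for c in cons:
            assert lm_release_test(f1, c).statistic == pytest.approx(
                lm_release_test(f2, c).statistic, rel=1e-5, abs=1e-8
            )

    def test_inactive_constraint_rejected(self, small_spec):
        mom = SampleMoments(small_model_sigma(), 500, SMALL_NAMES)
        fit = fit_multigroup(small_spec, [("a", mom), ("b", mom)],
                             constraints=["F1=~x1"])
        with pytest.raises(SpecificationError):
            lm_release_test(fit, "F1=~x2")

    def test_chi1_calibration_under_true_constraint(self, small_spec):
        # one truly-equal loading constrained; LM ~ chi2(1), mean ~ 1
        rng = np.random.default_rng(14)
        L = np.linalg.cholesky(small_model_sigma())
        stats = []
        for _ in range(500):
            moms = []
            for lab in ("a", "b"):
                X = rng.standard_normal((500, 6)) @ L.T
                moms.append((lab, SampleMoments(np.cov(X, rowvar=False), 500, SMALL_NAMES)))
            fit = fit_multigroup(small_spec, moms, constraints=["F1=~x2"])
            stats.append(lm_release_test(fit, "F1=~x2").statistic)
        assert abs(np.mean(stats) - 1.0) < 0.15


class TestInvarianceReport:
    def test_power_to_flag_offset_loadings(self, lm_power_sim):
        target = {"Affective=~BAI", "Affective=~BDI"}
        top2 = np.mean([r["top2"] == target for r in lm_power_sim])
        flagged = np.mean([target <= r["released"] for r in lm_power_sim])
        assert top2 >= 0.8
        assert flagged >= 0.8

    def test_identical_group_data_yields_no_releases(self):
        spec = model_a_spec()
        cons = default_invariance_constraints(spec)
        for seed in range(5):
            g = generate_study_like_groups(300, 300, seed=seed, nonnormal=False)
            data = g.drop(columns="gender")
            mom = SampleMoments.from_raw(data[spec.observed_vars])
            fit = fit_multigroup(spec, [("a", mom), ("b", mom)], constraints=cons)
            assert [r for r in invariance_report(fit, alpha=0.05) if r.released] == []

    def test_alpha_zero_releases_nothing(self, small_spec):
        rng = np.random.default_rng(15)
        L = np.linalg.cholesky(small_model_sigma())
        moms = []
        for lab in ("a", "b"):
            X = rng.standard_normal((300, 6)) @ L.T
            moms.append((lab, SampleMoments(np.cov(X, rowvar=False), 300, SMALL_NAMES)))
        fit = fit_multigroup(small_spec, moms, default_invariance_constraints(small_spec))
        assert all(not r.released for r in invariance_report(fit, alpha=0.0))
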