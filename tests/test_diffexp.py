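"""Moderated-t differential expression: group stats, empirical Bayes,
multiple testing and status calls."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from evmir.cq_io import SampleSheet
from evmir.detection import EXCLUSIVE_A, ExclusivityCall
from evmir.diffexp import (
    ModerationParams,
    bh_adjust,
    call_de,
    estimate_moderation,
    fit_group_stats,
    moderated_t_arrays,
    moderated_t_contrast,
    run_contrast,
    trigamma_inverse,
)
from evmir.normalization import NormalizedMatrix
from conftest import two_group_sheet


def norm_from(x, n=3):
    x = np.asarray(x, dtype=float)
    ids = [f"a{i}" for i in range(x.shape[0])]
    samples = [f"F{i}" for i in range(n)] + [f"N{i}" for i in range(n)]
    expr = pd.DataFrame(x, index=ids, columns=samples)
    return NormalizedMatrix(expr=expr, normalizer_set=set(),
                            sample_means=expr.mean())


class TestGroupStats:
    def test_hand_means_and_log2fc(self):
        gs = fit_group_stats(norm_from([[1, 2, 3, 0, 1, 2]]),
                             two_group_sheet(), "FPP:IN", "NSC:IN")
        row = gs.table.loc["a0"]
        assert row["mean_a"] == pytest.approx(2.0)
        assert row["mean_b"] == pytest.approx(1.0)
        assert row["log2fc"] == pytest.approx(1.0)
        assert gs.residual_df == 4

    def test_pooled_variance_formula(self):
        gs = fit_group_stats(norm_from([[1, 2, 3, 0, 2, 4]]),
                             two_group_sheet(), "FPP:IN", "NSC:IN")
        expected = (2 * 1.0 + 2 * 4.0) / 4
        assert gs.table.loc["a0", "s2"] == pytest.approx(expected)

    def test_incomplete_assays_routed_out_of_the_test(self):
        x = [[1, 2, 3, 0, 1, 2], [1, 2, np.nan, 0, 1, 2]]
        gs = fit_group_stats(norm_from(x), two_group_sheet(), "FPP:IN", "NSC:IN")
        assert gs.tested == ["a0"]
        assert gs.untested == ["a1"]

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            fit_group_stats(norm_from([[1, 2]], n=1), two_group_sheet(1),
                            "FPP:IN", "NSC:IN")


class TestModeration:
    def test_recovers_planted_hyperparameters(self):
        rng = np.random.default_rng(42)
        d0_true, s0_true, dg = 4.0, 0.05, 4
        s2 = s0_true * rng.f(dg, d0_true, size=5000)
        mod = estimate_moderation(s2, dg)
        assert abs(mod.d0 - d0_true) / d0_true < 0.25
        assert abs(mod.s0_sq - s0_true) / s0_true < 0.10

    def test_identical_variances_hit_infinite_prior_branch(self):
        mod = estimate_moderation(np.full(50, 0.2), 4)
        assert math.isinf(mod.d0)
        assert mod.s0_sq == pytest.approx(0.2)

    def test_all_zero_variances_is_hard_error(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_moderation(np.zeros(50), 4)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for y in (1e-5, 0.01, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert float(polygamma(1, x)) == pytest.approx(y, rel=1e-6)


class TestModeratedT:
    def test_d0_zero_equals_classical_pooled_t(self, rng):
        x = rng.normal(0, 0.5, size=(40, 6))
        x[:5, :3] += 1.0
        gs = fit_group_stats(norm_from(x), two_group_sheet(), "FPP:IN", "NSC:IN")
        res = moderated_t_contrast(gs, ModerationParams(d0=0.0, s0_sq=1.0))
        oracle = sps.ttest_ind(x[:, :3], x[:, 3:], axis=1, equal_var=True)
        assert np.allclose(res.table["t"].to_numpy(), oracle.statistic,
                           atol=1e-10)
        assert np.allclose(res.table["p"].to_numpy(), oracle.pvalue, atol=1e-10)

    def test_null_point_gives_t_zero_p_one(self):
        t, p, _ = moderated_t_arrays([0.0], [0.04], 3, 3,
                                     ModerationParams(d0=4, s0_sq=0.05))
        assert t[0] == 0.0 and p[0] == pytest.approx(1.0)

    def test_doubling_deviations_doubles_t_at_fixed_variance(self):
        mod = ModerationParams(d0=4, s0_sq=0.05)
        t1, _, _ = moderated_t_arrays([0.7], [0.04], 3, 3, mod)
        t2, _, _ = moderated_t_arrays([1.4], [0.04], 3, 3, mod)
        assert t2[0] == pytest.approx(2 * t1[0])

    def test_zero_posterior_variance_flags_not_evaluable(self):
        res_tab = norm_from([[1, 1, 1, 0, 0, 0]])
        gs = fit_group_stats(res_tab, two_group_sheet(), "FPP:IN", "NSC:IN")
        res = moderated_t_contrast(gs, ModerationParams(d0=0.0, s0_sq=1.0))
        res = call_de(res)
        assert res.table.loc["a0", "status"] == "not_evaluable"


class TestBHAdjust:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_singleton_and_saturated(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_statsmodels_on_random_input(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(200)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), adj, atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(100) ** 2
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDe:
    def base_result(self, log2fc, adj_p):
        tab = pd.DataFrame({
            "log2fc": [log2fc], "fc_linear": [2 ** abs(log2fc)],
            "t": [3.0], "df": [10.0], "p": [adj_p / 2], "adj_p": [adj_p],
            "status": [pd.NA],
        }, index=["a0"])
        from evmir.diffexp import ContrastResult
        return ContrastResult("FPP:IN", "NSC:IN", tab)

    def test_joint_threshold_rule(self):
        up = call_de(self.base_result(math.log2(1.6), 0.04))
        assert up.table.loc["a0", "status"] == "up_A"
        ns = call_de(self.base_result(math.log2(1.4), 0.04))
        assert ns.table.loc["a0", "status"] == "ns"
        ns2 = call_de(self.base_result(math.log2(1.6), 0.06))
        assert ns2.table.loc["a0", "status"] == "ns"

    def test_exclusivity_overrides_and_clears_statistics(self):
        res = call_de(self.base_result(2.0, 0.01),
                      [ExclusivityCall("a0", "FPP:IN", "NSC:IN", EXCLUSIVE_A)])
        assert res.table.loc["a0", "status"] == EXCLUSIVE_A
        assert np.isnan(res.table.loc["a0", "p"])

    def test_group_swap_symmetry(self, rng):
        x = rng.normal(0, 0.4, size=(30, 6))
        x[:6, :3] += 1.2
        norm = norm_from(x)
        sheet = two_group_sheet()
        mod = ModerationParams(d0=4.0, s0_sq=0.08)
        fwd = run_contrast(norm, sheet, "FPP:IN", "NSC:IN", moderation=mod)
        rev = run_contrast(norm, sheet, "NSC:IN", "FPP:IN", moderation=mod)
        assert np.allclose(fwd.table["log2fc"], -rev.table["log2fc"])
        assert np.allclose(fwd.table["p"], rev.table["p"], atol=1e-12)
        swap = {"up_A": "up_B", "up_B": "up_A", "ns": "ns",
                "not_evaluable": "not_evaluable"}
        assert list(rev.table["status"]) == [swap[s] for s in fwd.table["status"]]
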