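"""Detection window, group completeness and exclusivity rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evmir.cq_io import cq_matrix_from_arrays
from evmir.detection import (
    BOTH_EVALUABLE,
    EXCLUSIVE_A,
    EXCLUSIVE_B,
    NEITHER,
    detected_in_all,
    detection_call,
    exclusivity_call,
    group_complete,
)
from conftest import two_group_sheet


def matrix(rows: dict[str, list[float]], samples=None):
    samples = samples or ["F0", "F1", "F2", "N0", "N1", "N2"]
    return cq_matrix_from_arrays(list(rows), samples, list(rows.values()))


class TestDetectionCall:
    @pytest.mark.parametrize(
        "cq,expect",
        [
            (24.3, True),  # well inside the window
            (33.4, False),  # above the window (numeric but unreliable)
            (30.0, True),  # inclusive upper boundary
            (30.01, False),
            (15.0, True),  # inclusive lower boundary
            (14.99, False),
            (np.nan, False),  # sentinel
        ],
    )
    def test_window_boundaries(self, cq, expect):
        det = detection_call(cq_matrix_from_arrays(["a"], ["s"], [[cq]]))
        assert bool(det.detected.loc["a", "s"]) is expect

    def test_invalid_bounds_rejected(self):
        m = cq_matrix_from_arrays(["a"], ["s"], [[20.0]])
        with pytest.raises(ValueError):
            detection_call(m, lower_cq=30, upper_cq=15)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(16, 40), min_size=6, max_size=6),
           st.floats(25, 32), st.floats(32, 39))
    def test_raising_upper_cq_never_shrinks_detected_set(self, vals, lo_up, hi_up):
        m = matrix({"a": vals[:3] + vals[3:]})
        d1 = detection_call(m, upper_cq=min(lo_up, 40)).detected
        d2 = detection_call(m, upper_cq=min(max(lo_up, hi_up), 40)).detected
        assert (d2 | ~d1).all().all()  # d1 subset of d2


class TestGroupComplete:
    def test_complete_group_mean_is_arithmetic_mean(self):
        m = matrix({"a": [24, 25, 26, 27, 28, 29]})
        det = group_complete(detection_call(m), two_group_sheet())
        assert det.complete.loc["a", "FPP:IN"]
        assert det.group_mean.loc["a", "FPP:IN"] == pytest.approx(25.0)
        assert det.n_detected.loc["a", "FPP:IN"] == 3

    def test_one_failed_read_discards_the_group_mean(self):
        m = matrix({"a": [24, 25, np.nan, 27, 28, 29]})
        det = group_complete(detection_call(m), two_group_sheet())
        assert not det.complete.loc["a", "FPP:IN"]
        assert np.isnan(det.group_mean.loc["a", "FPP:IN"])
        assert det.n_detected.loc["a", "FPP:IN"] == 2

    def test_all_sentinel_group_has_zero_detected(self):
        m = matrix({"a": [np.nan] * 6})
        det = group_complete(detection_call(m), two_group_sheet())
        assert det.n_detected.loc["a", "FPP:IN"] == 0
        assert not det.complete.loc["a", "FPP:IN"]


class TestExclusivity:
    def prepared(self, rows):
        det = detection_call(matrix(rows))
        return group_complete(det, two_group_sheet())

    def test_strongly_expressed_vs_undetected_is_exclusive(self):
        # one compartment amplifies in the low twenties, the other never does
        det = self.prepared({"miR-622": [24.2, 24.3, 24.4, 33.3, 33.4, 33.5]})
        (call,) = exclusivity_call(det, "FPP:IN", "NSC:IN")
        assert call.status == EXCLUSIVE_A

    def test_gap_zone_above_expressed_cutoff_is_neither(self):
        det = self.prepared({"a": [28.9, 29.0, 29.1, np.nan, np.nan, np.nan]})
        (call,) = exclusivity_call(det, "FPP:IN", "NSC:IN")
        assert call.status == NEITHER

    def test_identical_complete_groups_are_both_evaluable(self):
        det = self.prepared({"a": [24, 25, 26, 24, 25, 26]})
        (call,) = exclusivity_call(det, "FPP:IN", "NSC:IN")
        assert call.status == BOTH_EVALUABLE

    def test_single_detected_replicate_blocks_exclusivity(self):
        det = self.prepared({"a": [24, 25, 26, 29.5, np.nan, np.nan]})
        (call,) = exclusivity_call(det, "FPP:IN", "NSC:IN")
        assert call.status == NEITHER

    def test_antisymmetry_under_group_swap(self):
        det = self.prepared({
            "x": [24, 25, 26, np.nan, np.nan, np.nan],
            "y": [np.nan, np.nan, np.nan, 24, 25, 26],
            "z": [24, 25, 26, 24, 25, 26],
        })
        fwd = {c.assay_id: c.status
               for c in exclusivity_call(det, "FPP:IN", "NSC:IN")}
        rev = {c.assay_id: c.status
               for c in exclusivity_call(det, "NSC:IN", "FPP:IN")}
        swap = {EXCLUSIVE_A: EXCLUSIVE_B, EXCLUSIVE_B: EXCLUSIVE_A,
                BOTH_EVALUABLE: BOTH_EVALUABLE, NEITHER: NEITHER}
        assert rev == {a: swap[s] for a, s in fwd.items()}

    def test_group_mean_variant_uses_means_not_replicates(self):
        # replicates straddle 28 but the mean is below it
        det = self.prepared({"a": [27.0, 27.5, 28.5, np.nan, np.nan, np.nan]})
        (per_rep,) = exclusivity_call(det, "FPP:IN", "NSC:IN")
        (per_mean,) = exclusivity_call(det, "FPP:IN", "NSC:IN",
                                       per_replicate=False)
        assert per_rep.status == NEITHER
        assert per_mean.status == EXCLUSIVE_A

    def test_raising_expressed_cq_never_shrinks_exclusive_set(self, rng):
        vals = np.where(rng.random((40, 6)) < 0.3, np.nan,
                        rng.uniform(20, 30, size=(40, 6)))
        det = detection_call(
            cq_matrix_from_arrays([f"a{i}" for i in range(40)],
                                  ["F0", "F1", "F2", "N0", "N1", "N2"], vals))
        det = group_complete(det, two_group_sheet())
        exc = {}
        for cutoff in (24.0, 26.0, 28.0):
            calls = exclusivity_call(det, "FPP:IN", "NSC:IN", expressed_cq=cutoff)
            exc[cutoff] = {c.assay_id for c in calls
                           if c.status in (EXCLUSIVE_A, EXCLUSIVE_B)}
        assert exc[24.0] <= exc[26.0] <= exc[28.0]


class TestDetectedInAll:
    def test_matches_brute_force_intersection(self, rng):
        vals = np.where(rng.random((30, 6)) < 0.4, np.nan,
                        rng.uniform(16, 30, size=(30, 6)))
        m = cq_matrix_from_arrays([f"a{i}" for i in range(30)],
                                  [f"s{j}" for j in range(6)], vals)
        det = detection_call(m)
        brute = set(m.assay_ids)
        for s in m.sample_ids:
            brute &= {a for a in m.assay_ids if det.detected.loc[a, s]}
        assert detected_in_all(det) == brute

    def test_seventeen_of_eighteen_is_excluded(self):
        vals = np.full((1, 18), 25.0)
        vals[0, 7] = np.nan
        m = cq_matrix_from_arrays(["a"], [f"s{j}" for j in range(18)], vals)
        assert detected_in_all(detection_call(m)) == set()
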