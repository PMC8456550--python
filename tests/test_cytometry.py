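import itertools

import numpy as np
import pandas as pd
import pytest

from transmut import (
    CalibrationCurve,
    ConfigurationError,
    DataError,
    call_expression_change,
    correct_position_effects,
    mad_filter,
    normalize_to_reference,
    summarize_well,
    transform_to_expression,
    two_level_permutation_test,
)


class TestSummarizeWell:
    def test_identical_cells_return_their_fluorescence(self):
        events = np.tile([2.0, 7.0], (150, 1))
        with pytest.warns(UserWarning):
            assert summarize_well(events) == pytest.approx(7.0)

    def test_size_proportional_fluorescence_collapses_to_geometric_mean(self, rng):
        size = rng.lognormal(0, 0.3, 500)
        c = 4.0
        events = np.column_stack([size, c * size])
        expected = c * np.exp(np.mean(np.log(size)))
        assert summarize_well(events) == pytest.approx(expected, rel=1e-9)

    def test_scale_equivariance(self, rng):
        size = rng.lognormal(0, 0.2, 300)
        fl = rng.lognormal(1, 0.1, 300)
        events = np.column_stack([size, fl])
        doubled = np.column_stack([size, 2 * fl])
        assert summarize_well(doubled) == pytest.approx(2 * summarize_well(events))

    def test_too_few_events_rejected(self):
        with pytest.raises(DataError):
            summarize_well(np.ones((50, 2)))


class TestPositionCorrection:
    @staticmethod
    def _plate(truth, gradient_row=0.0, gradient_col=0.0):
        rows = []
        idx = 0
        for r in range(1, 9):
            for c in range(1, 13):
                is_control = idx < 20
                true_val = 1.0 if is_control else truth.get((r, c), 1.0)
                rows.append(
                    {
                        "plate_id": "p1",
                        "row": r,
                        "col": c,
                        "value": true_val + gradient_row * r + gradient_col * c,
                        "is_control": is_control,
                    }
                )
                idx += 1
        return pd.DataFrame(rows)

    def test_no_gradient_leaves_values_unchanged(self):
        wells = self._plate({}, 0.0, 0.0)
        out = correct_position_effects(wells)
        assert np.allclose(out["corrected"], out["value"])

    def test_linear_gradient_exactly_inverted(self):
        truth = {(5, 5): 1.4, (8, 12): 0.7}
        wells = self._plate(truth, gradient_row=0.02, gradient_col=0.01)
        out = correct_position_effects(wells)
        # corrected = truth + constant offset shared by all wells
        offsets = out["corrected"] - [
            truth.get((r.row, r.col), 1.0) for r in wells.itertuples()
        ]
        assert np.std(offsets) < 1e-10

    def test_control_mean_preserved(self):
        wells = self._plate({(4, 4): 2.0}, 0.03, -0.01)
        out = correct_position_effects(wells)
        ctrl = out[out["is_control"]]
        assert ctrl["corrected"].mean() == pytest.approx(ctrl["value"].mean())

    def test_too_few_controls_warns_and_skips(self):
        wells = self._plate({}, 0.02, 0.0)
        wells["is_control"] = [i < 2 for i in range(len(wells))]
        with pytest.warns(UserWarning):
            out = correct_position_effects(wells)
        assert np.allclose(out["corrected"], out["value"])


class TestCalibration:
    def test_identity_without_curve(self):
        v = np.array([0.5, 1.0, 2.0])
        assert np.allclose(transform_to_expression(v), v)

    def test_log_log_slope_three(self):
        # slope-3 curve: a 1% fluorescence change ~ 3% expression change
        curve = CalibrationCurve([1.0, 2.0], [1.0, 8.0])
        lo, hi = transform_to_expression(np.array([1.0, 1.01]), curve)
        assert hi / lo == pytest.approx(1.01**3, rel=1e-9)

    def test_anchor_maps_exactly(self):
        curve = CalibrationCurve([1.0, 2.0, 4.0], [1.0, 3.0, 10.0])
        out = transform_to_expression(np.array([2.0]), curve)
        assert out[0] == pytest.approx(3.0, rel=1e-12)

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ConfigurationError):
            CalibrationCurve([1.0, 2.0], [2.0, 1.0])


class TestRelativeExpression:
    def test_reference_maps_to_one_autofl_to_zero(self):
        assert normalize_to_reference(np.array([10.0]), 2.0, 10.0)[0] == 1.0
        assert normalize_to_reference(np.array([2.0]), 2.0, 10.0)[0] == 0.0
        assert normalize_to_reference(np.array([6.0]), 2.0, 10.0)[0] == 0.5

    def test_bad_denominator_rejected(self):
        with pytest.raises(DataError):
            normalize_to_reference(np.array([1.0]), 5.0, 5.0)


class TestMadFilter:
    def test_tight_replicates_all_kept(self):
        v = np.array([1.00, 1.01, 0.99, 1.02])
        assert len(mad_filter(v)) == 4

    def test_outlier_dropped(self):
        v = np.array([1.00, 1.01, 0.99, 2.00])
        kept = mad_filter(v)
        assert 2.00 not in kept and len(kept) == 3

    def test_zero_mad_keeps_everything(self):
        v = np.array([1.0, 1.0, 1.0, 5.0])
        assert len(mad_filter(v)) == 4


def _exhaustive_p(test, position):
    """Enumeration oracle over all C(8,4)=70 splits of the pooled values."""
    pool = np.concatenate([test, position])
    d_obs = abs(np.mean(test) - np.mean(position))
    ds = []
    for combo in itertools.combinations(range(8), 4):
        first = pool[list(combo)]
        second = pool[[i for i in range(8) if i not in combo]]
        ds.append(d_obs - abs(first.mean() - second.mean()))
    ds = np.array(ds)
    nonzero = np.count_nonzero(ds)
    return 1.0 if nonzero == 0 else np.sum(ds < 0) / nonzero


class TestTwoLevelPermutation:
    def test_all_equal_values_give_p_one(self):
        panel = np.ones((5, 4))
        assert two_level_permutation_test(np.ones(4), panel, seed=0) == 1.0

    def test_single_position_matches_enumeration(self, rng):
        test = rng.normal(1.0, 0.02, 4)
        position = rng.normal(1.0, 0.02, 4)
        exact = _exhaustive_p(test, position)
        p = two_level_permutation_test(test, position[None, :], n_iter=10_000, seed=5)
        assert p == pytest.approx(exact, abs=0.025)

    def test_seed_reproducibility(self, rng):
        panel = rng.normal(1, 0.02, (20, 4))
        test = rng.normal(1.03, 0.02, 4)
        p1 = two_level_permutation_test(test, panel, seed=9)
        p2 = two_level_permutation_test(test, panel, seed=9)
        assert p1 == p2

    def test_affine_invariance(self, rng):
        panel = rng.normal(1, 0.02, (20, 4))
        test = rng.normal(1.05, 0.02, 4)
        p = two_level_permutation_test(test, panel, seed=3)
        p_shift = two_level_permutation_test(test + 5, panel + 5, seed=3)
        p_scale = two_level_permutation_test(test * 7, panel * 7, seed=3)
        assert p == p_shift == p_scale

    def test_larger_shifts_do_not_raise_p(self, rng):
        panel = rng.normal(1, 0.01, (40, 4))
        mean_ps = []
        for shift in (0.0, 0.03, 0.10):
            ps = [
                two_level_permutation_test(
                    rng.normal(1 + shift, 0.01, 4), panel, n_iter=2000, seed=k
                )
                for k in range(20)
            ]
            mean_ps.append(np.mean(ps))
        assert mean_ps[0] >= mean_ps[1] >= mean_ps[2]

    def test_requires_four_replicates(self):
        with pytest.raises(ConfigurationError):
            two_level_permutation_test(np.ones(3), np.ones((5, 4)))
        with pytest.raises(ConfigurationError):
            two_level_permutation_test(np.ones(4), np.empty((0, 4)))


class TestCallExpressionChange:
    def test_small_effect_never_called(self, rng):
        panel = rng.normal(1, 0.01, (30, 4))
        test = rng.normal(1.005, 0.001, 4)
        assert not call_expression_change(test, panel, seed=0)

    def test_large_shift_called(self, rng):
        panel = rng.normal(1, 0.01, (30, 4))
        test = rng.normal(0.90, 0.005, 4)
        assert call_expression_change(test, panel, seed=0)
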