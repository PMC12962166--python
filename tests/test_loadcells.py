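"""Leg-load biomechanics: fractions, CoS, formulas, exponential fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limbcoord import loadcells as lc
from limbcoord.synthetic import CohortConfig, LoadTrial, generate_load_trial


def _trial(means, n=800, sr=100.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sr
    ch = {c: np.full(n, m) + rng.normal(0, noise, n) for c, m in zip(lc.CHANNELS, means)}
    return LoadTrial(time=t, channels=ch, metadata={"weight_g": sum(means), "slope_deg": 0.0})


class TestWeightFractions:
    def test_equal_channels(self):
        w, _ = lc.weight_fractions(_trial([5, 5, 5, 5]))
        assert all(w[c] == pytest.approx(0.25) for c in lc.CHANNELS)

    def test_two_two_one_one(self):
        w, _ = lc.weight_fractions(_trial([2, 2, 1, 1]))
        assert w["RF"] == pytest.approx(1 / 3)
        assert w["LF"] == pytest.approx(1 / 3)
        assert w["RH"] == pytest.approx(1 / 6)
        assert w["LH"] == pytest.approx(1 / 6)

    def test_four_second_standstill_rejected(self):
        with pytest.raises(lc.StandstillError):
            lc.weight_fractions(_trial([5, 5, 5, 5], n=400))  # 4 s at 100 Hz

    def test_standstill_found_after_movement(self):
        cfg = CohortConfig(seed=5)
        trial, _ = generate_load_trial(cfg, (44.0, 0.0), 24.0)
        w, (i0, i1) = lc.weight_fractions(trial)
        assert (i1 - i0) / trial.sample_rate >= 5.0
        assert i0 >= cfg.movement_lead_s * cfg.load_sample_rate * 0.5
        assert sum(w.values()) == pytest.approx(1.0)


fractions4 = st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=4, max_size=4
).map(lambda v: dict(zip(lc.CHANNELS, (np.array(v) / np.sum(v)).tolist())))


class TestCenterOfSupport:
    def test_equal_fractions_centered(self):
        assert lc.center_of_support_index(dict(zip(lc.CHANNELS, [0.25] * 4))) == (0.0, 0.0)

    def test_fore_biased(self):
        w = {"RF": 0.4, "LF": 0.4, "RH": 0.1, "LH": 0.1}
        ap, ml = lc.center_of_support_index(w)
        assert ap == pytest.approx(0.6)
        assert ml == pytest.approx(0.0)

    def test_extreme_fore(self):
        w = {"RF": 0.5, "LF": 0.5, "RH": 0.0, "LH": 0.0}
        assert lc.center_of_support_index(w)[0] == pytest.approx(1.0)

    @given(fractions4)
    @settings(deadline=None, max_examples=100)
    def test_antisymmetry_under_fore_hind_swap(self, w):
        swapped = {"RF": w["RH"], "LF": w["LH"], "RH": w["RF"], "LH": w["LF"]}
        assert lc.center_of_support_index(w)[0] == pytest.approx(
            -lc.center_of_support_index(swapped)[0]
        )

    def test_position_symmetric_square(self):
        pos = {"RF": (1, 1), "LF": (1, -1), "RH": (-1, 1), "LH": (-1, -1)}
        w = dict(zip(lc.CHANNELS, [0.25] * 4))
        assert lc.center_of_support_position(w, pos) == (0.0, 0.0)

    def test_position_all_load_one_foot(self):
        pos = {"RF": (2.5, 1.0), "LF": (2.5, -1.0), "RH": (-2.5, 1.0), "LH": (-2.5, -1.0)}
        w = {"RF": 1.0, "LF": 0.0, "RH": 0.0, "LH": 0.0}
        assert lc.center_of_support_position(w, pos) == (2.5, 1.0)

    def test_position_weighted_mean(self):
        pos = {"RF": (2, 0), "LF": (2, 0), "RH": (-2, 0), "LH": (-2, 0)}
        w = {"RF": 0.3, "LF": 0.3, "RH": 0.2, "LH": 0.2}
        assert lc.center_of_support_position(w, pos)[0] == pytest.approx(0.4)

    @given(fractions4, st.floats(-5, 5), st.floats(-5, 5))
    @settings(deadline=None, max_examples=50)
    def test_position_translation_equivariance(self, w, tx, ty):
        pos = {"RF": (2.5, 1.0), "LF": (2.5, -1.0), "RH": (-2.5, 1.0), "LH": (-2.5, -1.0)}
        shifted = {c: (p[0] + tx, p[1] + ty) for c, p in pos.items()}
        a = lc.center_of_support_position(w, pos)
        b = lc.center_of_support_position(w, shifted)
        assert b[0] == pytest.approx(a[0] + tx, abs=1e-9)
        assert b[1] == pytest.approx(a[1] + ty, abs=1e-9)

    def test_missing_position_rejected(self):
        w = dict(zip(lc.CHANNELS, [0.25] * 4))
        with pytest.raises(ValueError, match="LH"):
            lc.center_of_support_position(w, {"RF": (1, 1), "LF": (1, -1), "RH": (-1, 1)})


class TestSlopeAndHeadHeight:
    def test_flat_surface_unchanged(self):
        assert lc.slope_detectable_weight(25.0, 0.0) == pytest.approx(25.0)

    def test_sixty_degrees_halves(self):
        assert lc.slope_detectable_weight(30.0, 60.0) == pytest.approx(15.0)

    def test_vertical_rejected(self):
        with pytest.raises(ValueError):
            lc.slope_detectable_weight(30.0, 90.0)

    def test_offload_zero_when_all_detected(self):
        assert lc.offload_fraction(15.0, 30.0, 60.0) == pytest.approx(0.0)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(deadline=None, max_examples=25)
    def test_offload_invariant_to_uniform_rescaling(self, c):
        a = lc.offload_fraction(20.0, 25.0, 10.0)
        b = lc.offload_fraction(20.0 * c, 25.0 * c, 10.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_max_comfortable_height_values(self):
        assert lc.max_comfortable_height(22.0) == pytest.approx(52.0)
        assert lc.max_comfortable_height(24.0) == pytest.approx(54.5)

    def test_weight_adjusted_values(self):
        assert lc.weight_adjusted_head_height(52.0, 22.0) == pytest.approx(1.0)
        assert lc.weight_adjusted_head_height(24.5, 17.0) == pytest.approx(0.0)
        assert lc.weight_adjusted_head_height(44.0, 24.0) == pytest.approx(0.65)

    @given(st.floats(min_value=5.0, max_value=60.0))
    @settings(deadline=None, max_examples=50)
    def test_identity_at_max_comfortable_height(self, w):
        assert lc.weight_adjusted_head_height(lc.max_comfortable_height(w), w) == pytest.approx(1.0)


class TestExponentialDecay:
    def test_exact_recovery_zero_noise(self):
        x = np.linspace(0, 60, 20)
        y = 180.0 - 40.0 * np.exp(-0.1 * x)
        fit = lc.fit_exponential_decay(x, y)
        assert fit.converged
        assert fit.A == pytest.approx(180.0, rel=1e-6)
        assert fit.B == pytest.approx(40.0, rel=1e-6)
        assert fit.k == pytest.approx(0.1, rel=1e-6)

    def test_constant_data_flagged(self):
        fit = lc.fit_exponential_decay(np.arange(6.0), np.full(6, 3.0))
        assert not fit.converged
        assert fit.A == pytest.approx(3.0)
        assert fit.B == pytest.approx(0.0)

    def test_generator_rate_recovered_within_20_percent(self):
        """k recovered from 8 generated head heights at 1% load noise."""
        cfg = CohortConfig(
            seed=31,
            forelimb_frac_A=0.7,
            forelimb_frac_B=0.4,
            forelimb_frac_k=0.08,
            slope_load_rate=0.0,
            offload_rate=0.0,
            load_noise_frac=0.01,
        )
        heights = np.linspace(20.0, 60.0, 8)
        fracs = []
        for i, h in enumerate(heights):
            trial, _ = generate_load_trial(cfg, (h, 0.0), 24.0, trial=i)
            w, _ = lc.weight_fractions(trial)
            fracs.append(w["RF"] + w["LF"])
        fit = lc.fit_exponential_decay(heights, np.array(fracs))
        assert fit.converged
        assert fit.k == pytest.approx(0.08, rel=0.2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            lc.fit_exponential_decay([1, 2, 3], [1, 2, 3])


class TestSummary:
    def test_summary_consistency(self):
        cfg = CohortConfig(seed=41)
        trial, truth = generate_load_trial(cfg, (47.0, 10.0), 26.0)
        s = lc.summarize_load_trial(trial)
        assert s.w_RF + s.w_LF + s.w_RH + s.w_LH == pytest.approx(1.0)
        assert -1 <= s.cos_ap_index <= 1
        assert s.offload_fraction == pytest.approx(truth.offload_fraction, abs=0.02)
        assert s.cos_ap_cm == pytest.approx(truth.cos_ap_cm, abs=0.05)
        assert s.weight_adjusted_head_height == pytest.approx(
            lc.weight_adjusted_head_height(47.0, 26.0)
        )
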