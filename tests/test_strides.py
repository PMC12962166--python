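"""Stride segmentation, phase estimation, filters, and the stride table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limbcoord import kinematics, strides
from limbcoord.circstats import circ_dist, wrap_angle
from limbcoord.synthetic import CohortConfig, generate_trajectory_trial


def _sawtooth(n_periods, period, rise_frac, amp=10.0):
    """Sawtooth with a slow rising (stance) segment of ``rise_frac`` of the cycle.

    Phase-shifted by half a period so peaks are interior to the series
    (one peak per period, at t = period/2 + k*period).
    """
    t = np.arange(n_periods * period)
    f = ((t + period // 2) % period) / period
    fall = 1.0 - rise_frac
    return amp * np.where(f < fall, 1.0 - f / fall, (f - fall) / rise_frac)


class TestSegmentation:
    def test_constant_series_zero_strides(self):
        seg = strides.segment_strides(np.full(500, 3.0), 400.0)
        assert seg.n_strides == 0

    def test_ten_period_sawtooth_gives_nine_strides(self):
        x = _sawtooth(10, 100, 0.6)
        seg = strides.segment_strides(x, 400.0)
        assert seg.n_strides == 9
        np.testing.assert_array_equal(np.diff(seg.swing_onsets), 100)

    def test_two_peaks_one_stride(self):
        x = _sawtooth(2, 100, 0.6)
        seg = strides.segment_strides(x, 400.0)
        assert seg.n_strides == 1


class TestRelativePhase:
    def test_identical_series_zero_phase(self):
        x = _sawtooth(6, 100, 0.6)
        assert strides.relative_phase(x, x, (200, 300)) == 0.0

    def test_half_period_shift_is_alternation(self):
        x = _sawtooth(6, 100, 0.6)
        other = np.roll(x, 50)
        ph = strides.relative_phase(x, other, (200, 300))
        assert abs(ph) == pytest.approx(np.pi, abs=2 * np.pi / 100)

    def test_quarter_period_earlier_shift_gives_minus_half_pi(self):
        """other(t) = ref(t + d/4): the other limb leads by a quarter cycle."""
        x = _sawtooth(6, 100, 0.6)
        other = np.roll(x, -25)  # shifted earlier
        ph = strides.relative_phase(x, other, (200, 300))
        assert ph == pytest.approx(-np.pi / 2, abs=2 * np.pi / 100)

    def test_quarter_period_delay_gives_plus_half_pi(self):
        x = _sawtooth(6, 100, 0.6)
        other = np.roll(x, 25)  # delayed: other lags reference
        ph = strides.relative_phase(x, other, (200, 300))
        assert ph == pytest.approx(np.pi / 2, abs=2 * np.pi / 100)

    def test_zero_variance_window_flagged(self):
        x = _sawtooth(6, 100, 0.6)
        with pytest.raises(strides.UndefinedPhaseError):
            strides.relative_phase(x, np.zeros_like(x), (200, 300))


class TestConsistencyFilter:
    def test_distance_above_tolerance_drops(self):
        assert not strides.consistency_filter(0.30 * np.pi, 0.44 * np.pi)

    def test_wrap_aware_distance_keeps(self):
        assert strides.consistency_filter(0.98 * np.pi, -0.98 * np.pi)

    @given(st.floats(min_value=-np.pi, max_value=np.pi - 1e-9))
    @settings(deadline=None, max_examples=50)
    def test_identical_phases_always_kept(self, x):
        assert strides.consistency_filter(x, x)

    def test_keeping_monotone_in_tolerance(self):
        """A larger tolerance never drops a stride a smaller one kept."""
        rng = np.random.default_rng(1)
        a, b = rng.uniform(-np.pi, np.pi, (2, 300))
        kept_small = np.array([strides.consistency_filter(x, y, 0.05 * np.pi) for x, y in zip(a, b)])
        kept_large = np.array([strides.consistency_filter(x, y, 0.1 * np.pi) for x, y in zip(a, b)])
        assert np.all(kept_large[kept_small])


class TestDutyFactor:
    def test_symmetric_triangle_half(self):
        x = _sawtooth(6, 100, 0.5)
        seg = strides.segment_strides(x, 400.0)
        assert strides.duty_factor(seg, seg.strides[1]) == pytest.approx(0.5, abs=0.02)

    def test_seventy_percent_stance_sawtooth(self):
        """Stance (trough -> next peak) occupies 70% of the cycle."""
        x = _sawtooth(6, 100, 0.7)
        seg = strides.segment_strides(x, 400.0)
        assert strides.duty_factor(seg, seg.strides[1]) == pytest.approx(0.7, abs=0.02)

    def test_missing_stance_onset_flagged(self):
        seg = strides.StrideSegmentation(np.array([0, 100]), np.array([], dtype=int), [(0, 100)])
        with pytest.raises(ValueError):
            strides.duty_factor(seg, (0, 100))


class TestCategorize:
    @pytest.mark.parametrize(
        "phase,expected",
        [
            (0.95 * np.pi, strides.CATEGORY_ALTERNATING),
            (-0.85 * np.pi, strides.CATEGORY_ALTERNATING),
            (0.1 * np.pi, strides.CATEGORY_SYNCHRONIZED),
            (-0.15 * np.pi, strides.CATEGORY_SYNCHRONIZED),
            (0.5 * np.pi, strides.CATEGORY_ASYM_LEFT),
            (-0.5 * np.pi, strides.CATEGORY_ASYM_RIGHT),
        ],
    )
    def test_band_classification(self, phase, expected):
        assert strides.categorize_hindlimb_phase(phase) == expected

    @given(st.floats(min_value=-np.pi, max_value=np.pi - 1e-9))
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_2pi(self, phase):
        assert strides.categorize_hindlimb_phase(phase) == strides.categorize_hindlimb_phase(
            phase + 2 * np.pi
        )


class TestStrideTable:
    def test_noise_free_alternating_trial_all_alternating(self, noise_free_trial):
        rec, truth = noise_free_trial
        posture = kinematics.compute_posture(rec)
        table, drops = strides.build_stride_table(rec, posture)
        assert len(table) > 0
        assert (table["hindlimb_category"] == strides.CATEGORY_ALTERNATING).all()
        assert drops["consistency"] == 0

    def test_phase_recovery_within_one_lag(self, noise_free_trial):
        rec, truth = noise_free_trial
        posture = kinematics.compute_posture(rec)
        table, _ = strides.build_stride_table(rec, posture)
        d = rec.frame_rate * 0.25
        for pair in ("left_fore", "right_hind", "right_fore"):
            err = np.abs(circ_dist(table[f"phase_{pair}"].to_numpy(), truth.true_mu[pair]))
            assert err.max() <= 2 * np.pi / d + 1e-9

    def test_inflated_landmark_jitter_drops_match_recount(self):
        """Stride drops from the 0.1 pi rule match an independent recount."""
        cfg = CohortConfig(
            seed=21, landmark_jitter_sd=0.5, tracking_noise_sd=0.0, dropout_frac=0.0
        )
        rec, _ = generate_trajectory_trial(cfg, 0, (44.0, 0.0, 20.0), n_strides=30)
        posture = kinematics.compute_posture(rec)
        table, drops = strides.build_stride_table(rec, posture)

        # independent recount: re-apply the rule per stride, per limb pair
        from limbcoord.kinematics import locomotor_bouts

        recount_dropped = 0
        rows = 0
        (b0, b1) = locomotor_bouts(posture.locomotion_mask)[0]
        ref_mean = 0.5 * (
            rec.data["left_hind_toe"]["x"][b0:b1] + rec.data["left_hind_heel"]["x"][b0:b1]
        )
        seg = strides.segment_strides(ref_mean, rec.frame_rate)
        for stride in seg.strides:
            kept = True
            for limb in ("left_fore", "right_fore", "right_hind"):
                ph = [
                    strides.relative_phase(
                        rec.data[f"left_hind_{m}"]["x"][b0:b1],
                        rec.data[f"{limb}_{m}"]["x"][b0:b1],
                        stride,
                    )
                    for m in ("toe", "heel")
                ]
                if abs(circ_dist(ph[0], ph[1])) > 0.1 * np.pi:
                    kept = False
                    break
            if kept:
                rows += 1
            else:
                recount_dropped += 1
        assert drops["consistency"] == recount_dropped
        assert len(table) == rows
        assert recount_dropped > 0  # the inflated jitter must actually bite

    def test_ten_peak_bout_gives_nine_rows(self, noise_free_config):
        rec, truth = generate_trajectory_trial(
            noise_free_config, 0, (44.0, 0.0, 20.0), n_strides=8
        )
        posture = kinematics.compute_posture(rec)
        table, _ = strides.build_stride_table(rec, posture)
        # 8 requested strides -> 9 ground-truth swing onsets; detected peaks
        # may include the margin peak, so compare against the segmentation
        from limbcoord.kinematics import locomotor_bouts

        b0, b1 = locomotor_bouts(posture.locomotion_mask)[0]
        ref = 0.5 * (
            rec.data["left_hind_toe"]["x"][b0:b1] + rec.data["left_hind_heel"]["x"][b0:b1]
        )
        seg = strides.segment_strides(ref, rec.frame_rate)
        assert len(table) == seg.swing_onsets.size - 1

    def test_table_deterministic(self, noise_free_trial):
        rec, _ = noise_free_trial
        posture = kinematics.compute_posture(rec)
        t1, _ = strides.build_stride_table(rec, posture)
        t2, _ = strides.build_stride_table(rec, posture)
        assert t1.equals(t2)

    def test_emitted_phases_wrapped(self, noisy_config):
        rec, _ = generate_trajectory_trial(noisy_config, 1, (37.0, 0.0, 20.0), n_strides=25)
        posture = kinematics.compute_posture(rec)
        table, _ = strides.build_stride_table(rec, posture)
        for pair in ("left_fore", "right_hind", "right_fore"):
            ph = table[f"phase_{pair}"].to_numpy()
            assert np.all(ph >= -np.pi) and np.all(ph < np.pi)
            assert np.array_equal(ph, wrap_angle(ph))
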