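"""Responsiveness, intensity, dynamics, tuning: closed forms and recovery."""

import numpy as np
import pytest

from odoresp import preprocess as pre
from odoresp import respmetrics as rm
from odoresp import synthgen as sg


class TestResponsivenessMap:
    def test_perfect_correlation(self, rng):
        stim = np.tile([0.0, 1.0], 50)
        values = np.stack([stim, -stim + 3.0, rng.normal(size=100)])
        out = rm.responsiveness_map(values, stim)
        assert out.values[0] == pytest.approx(1.0)
        assert out.values[1] == pytest.approx(-1.0)
        assert out.mask[0] and out.mask[1]

    def test_zero_variance_voxel_masked_not_error(self):
        stim = np.tile([0.0, 1.0], 20)
        values = np.vstack([np.full(40, 2.0), stim])
        out = rm.responsiveness_map(values, stim)
        assert not out.mask[0]
        assert out.mask[1]

    def test_constant_stimulus_rejected(self):
        with pytest.raises(ValueError):
            rm.responsiveness_map(np.ones((2, 10)), np.ones(10))

    def test_false_positive_rate_near_alpha(self):
        # independent noise voxels: ≈5% should pass at alpha=0.05
        r = np.random.default_rng(99)
        stim = np.tile([0.0, 1.0], 5000)
        values = r.normal(size=(2000, 10_000))
        out = rm.responsiveness_map(values, stim, alpha=0.05)
        rate = out.mask.mean()
        # binomial 3-sigma band around 0.05 at n=2000
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_agrees_with_scipy_pearsonr(self, rng):
        from scipy.stats import pearsonr

        stim = rng.normal(size=200)
        values = rng.normal(size=(5, 200))
        out = rm.responsiveness_map(values, stim, alpha=1.0)
        for v in range(5):
            r_ref, p_ref = pearsonr(values[v], stim)
            assert out.values[v] == pytest.approx(r_ref, abs=1e-12)


class TestRegionResponsiveness:
    def test_top20_of_ten(self):
        values = np.arange(0.1, 1.05, 0.1)
        m = rm.MetricMap(values, np.ones(10, bool), "r")
        out = rm.region_responsiveness(m, np.ones(10, int), top_fraction=0.2)
        assert out[1] == pytest.approx(0.95)

    def test_single_voxel_and_all_equal(self):
        m = rm.MetricMap(np.array([0.7, 0.4, 0.4]), np.ones(3, bool), "r")
        out = rm.region_responsiveness(m, np.array([1, 2, 2]))
        assert out[1] == pytest.approx(0.7)
        assert out[2] == pytest.approx(0.4)

    def test_region_without_valid_voxels_absent(self):
        m = rm.MetricMap(np.array([0.5, 0.5]), np.array([True, False]), "r")
        out = rm.region_responsiveness(m, np.array([1, 2]))
        assert 2 not in out


def _tensor(values, odors, rate=2.0):
    values = np.asarray(values, dtype=float)
    n_trials, n_vox, n_frames = values.shape
    return pre.TrialTensor(
        values=values,
        window_offsets=np.arange(n_frames),
        odor_labels=np.asarray(odors, dtype=object),
        session_ids=np.zeros(n_trials, int),
        frame_rate=rate,
    )


class TestResponseIntensity:
    def test_zero_tensor(self):
        tt = _tensor(np.zeros((4, 3, 10)), ["A"] * 4)
        out = rm.response_intensity(tt, "sd")
        np.testing.assert_array_equal(out.values, 0.0)

    def test_square_pulse_sd_closed_form(self):
        # amplitude a over half the window: sd of two-level vector = a/2
        a = 0.8
        frames = np.concatenate([np.full(5, a), np.zeros(5)])
        tt = _tensor(frames[None, None, :], ["A"])
        out = rm.response_intensity(tt, "sd")
        assert out.values[0] == pytest.approx(a / 2)

    def test_auc_constant(self):
        # constant a for T seconds -> a*T
        tt = _tensor(np.full((1, 1, 10), 0.3), ["A"], rate=2.0)
        out = rm.response_intensity(tt, "auc")
        assert out.values[0] == pytest.approx(0.3 * 5.0)

    def test_unknown_statistic(self):
        with pytest.raises(ValueError):
            rm.response_intensity(_tensor(np.zeros((1, 1, 2)), ["A"]), "median")


class TestResponseDynamics:
    def test_triangular_pulse_delay(self):
        y = np.concatenate([np.zeros(2), [0.5, 1.0, 0.5], np.zeros(5)])
        delay, _ = rm.response_dynamics(y, frame_rate=2.3, onset_index=0)
        assert delay == pytest.approx(3 / 2.3)

    def test_gaussian_fwhm(self):
        t = np.arange(0, 20, 0.05)
        y = np.exp(-0.5 * ((t - 10) / 1.0) ** 2)
        _, width = rm.response_dynamics(y, frame_rate=20.0)
        assert width == pytest.approx(2.3548, abs=0.01)

    def test_rectangular_pulse_width_within_frame(self):
        rate = 4.0
        y = np.zeros(80)
        y[20:40] = 1.0  # 5 s wide at 4 Hz
        _, width = rm.response_dynamics(y, frame_rate=rate)
        assert abs(width - 5.0) <= 1 / rate

    def test_nonpositive_peak_flagged(self):
        delay, width = rm.response_dynamics(-np.ones(10), 2.0)
        assert np.isnan(delay) and np.isnan(width)

    def test_kernel_recovery_within_one_frame(self, noiseless_exp):
        # parameter recovery on noiseless synthetic data
        cfg = noiseless_exp.config
        p = cfg.channel_params["calcium"]
        dff = pre.dff_from_experiment(noiseless_exp, "calcium")
        tt = pre.extract_trials(dff, noiseless_exp.trial_table, 0, 30)
        tuned = np.flatnonzero(
            noiseless_exp.ground_truth.ensemble_membership["calcium"][:, 0]
        )
        sel = np.asarray(tt.odor_labels) == cfg.odors[0]
        avg = tt.values[sel][:, tuned[0], :].mean(axis=0)
        delay, width = rm.response_dynamics(avg, cfg.frame_rate)
        frame = 1 / cfg.frame_rate
        assert abs(delay - sg.kernel_peak_time(p.delay, p.rise_tau, p.decay_tau)) <= frame
        assert abs(width - sg.kernel_fwhm(p.delay, p.rise_tau, p.decay_tau)) <= frame


class TestOdorTuning:
    def test_exclusive_responder_tuning_equals_auc(self):
        # voxel responds only to OCT with per-trial AUC a
        rate = 2.0
        values = np.zeros((12, 1, 8))
        odors = np.array(["OCT", "MCH", "EA"] * 4, dtype=object)
        values[odors == "OCT", 0, :] = 1.0  # AUC = 8/2 = 4
        tt = _tensor(values, odors, rate=rate)
        out = rm.odor_tuning(tt, "OCT")
        assert out.values[0] == pytest.approx(4.0)
        assert out.mask[0]

    def test_tunings_sum_to_zero_with_equal_counts(self, rng):
        values = rng.normal(size=(18, 6, 5))
        odors = np.array(["A", "B", "C"] * 6, dtype=object)
        tt = _tensor(values, odors)
        total = sum(rm.odor_tuning(tt, o).values for o in "ABC")
        np.testing.assert_allclose(total, 0.0, atol=1e-10)

    def test_odorless_voxel_masked(self):
        r = np.random.default_rng(5)
        values = r.normal(size=(60, 40, 6))
        odors = np.array(["A", "B", "C"] * 20, dtype=object)
        out = rm.odor_tuning(_tensor(values, odors), "A")
        assert out.mask.mean() < 0.2  # BH at 5% on null data: few rejections

    def test_missing_odor_class_rejected(self):
        tt = _tensor(np.zeros((4, 1, 3)), ["A", "B", "A", "B"])
        with pytest.raises(ValueError):
            rm.odor_tuning(tt, "C")

    def test_planted_ensemble_recovery(self, small_exp, small_trials):
        # amplitude 0.5 = 5× noise sd: ≥95% planted voxels found with
        # positive tuning; ≤5% of never-tuned voxels flagged.  (Voxels
        # planted for a different odor legitimately show significant
        # negative tuning for the probed odor, so they are excluded from
        # the false-positive set.)
        gt = small_exp.ground_truth.ensemble_membership["calcium"]
        tt = small_trials["calcium"]
        odor_idx = {o: i for i, o in enumerate(small_exp.config.odors)}
        untuned = ~(gt > 0).any(axis=1)
        for odor in small_exp.config.odors:
            out = rm.odor_tuning(tt, odor)
            planted = gt[:, odor_idx[odor]] > 0
            detected = out.mask & (out.values > 0)
            assert detected[planted].mean() >= 0.95
            assert out.mask[untuned].mean() <= 0.05


class TestStandardizedTunedRatio:
    def test_equal_fractions_all_zero(self):
        m = rm.MetricMap(np.zeros(8), np.array([True] * 8), "t")
        atlas = np.repeat([1, 2], 4)
        out = rm.standardized_tuned_ratio(m, atlas, [1, 2])
        assert out == {1: 0.0, 2: 0.0}

    def test_single_hot_region_zscore(self):
        mask = np.concatenate([np.ones(4, bool), np.zeros(16, bool)])
        m = rm.MetricMap(np.zeros(20), mask, "t")
        atlas = np.repeat([1, 2, 3, 4, 5], 4)
        out = rm.standardized_tuned_ratio(m, atlas, [1, 2, 3, 4, 5])
        fractions = np.array([1.0, 0, 0, 0, 0])
        expected = (1.0 - 0.2) / fractions.std(ddof=1)
        assert out[1] == pytest.approx(expected)

    def test_empty_region_excluded(self):
        m = rm.MetricMap(np.zeros(4), np.ones(4, bool), "t")
        atlas = np.array([1, 1, 2, 2])
        out = rm.standardized_tuned_ratio(m, atlas, [1, 2, 9])
        assert set(out) == {1, 2}

    def test_fewer_than_two_regions_undefined(self):
        m = rm.MetricMap(np.zeros(4), np.ones(4, bool), "t")
        with pytest.raises(ValueError):
            rm.standardized_tuned_ratio(m, np.ones(4, int), [1])
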