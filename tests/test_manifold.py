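"""Manifold geometry: Procrustes alignment, distance metrics, invariances,
crossing-time oracles, and stage-wise drift recovery."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from odoresp import decoding as dec
from odoresp import manifold as man
from odoresp import preprocess as pre
from odoresp import synthgen as sg


def _traces(coords, odors, sessions=None, t0=-2.0, rate=1.0):
    coords = np.asarray(coords, float)
    n, f, _ = coords.shape
    return man.ManifoldTraces(
        coords=coords,
        time_axis=t0 + np.arange(f) / rate,
        odor_labels=np.asarray(odors, dtype=object),
        session_ids=np.zeros(n, int) if sessions is None else np.asarray(sessions),
        fold_ids=np.zeros(n, int),
    )


class TestAlignFolds:
    def test_identical_folds_identity(self, rng):
        coords = rng.normal(size=(6, 10, 2))
        odors = ["A", "B"] * 3
        a = _traces(coords, odors)
        b = _traces(coords.copy(), odors)
        merged = man.align_folds([a, b])
        assert merged.alignment_residuals[1] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(merged.coords[:6], merged.coords[6:], atol=1e-10)

    def test_sign_flip_recovered(self, rng):
        coords = rng.normal(size=(6, 10, 2))
        odors = ["A", "B"] * 3
        flipped = coords * np.array([1.0, -1.0])
        merged = man.align_folds([_traces(coords, odors), _traces(flipped, odors)])
        assert merged.alignment_residuals[1] == pytest.approx(0.0, abs=1e-8)

    def test_random_rotations_recovered(self, rng):
        # Procrustes oracle: rotated copies align to numerical precision
        coords = rng.normal(size=(9, 12, 3))
        odors = ["A", "B", "C"] * 3
        folds = [_traces(coords, odors)]
        for seed in range(2):
            r = ortho_group.rvs(3, random_state=seed)
            folds.append(_traces(coords @ r, odors))
        merged = man.align_folds(folds)
        np.testing.assert_allclose(merged.alignment_residuals, 0.0, atol=1e-8)
        for k in (1, 2):
            np.testing.assert_allclose(
                merged.coords[9 * k : 9 * (k + 1)], coords, atol=1e-8
            )

    def test_degenerate_means_warn_identity(self):
        coords = np.zeros((4, 5, 2))
        odors = ["A", "B"] * 2
        with pytest.warns(UserWarning, match="degenerate"):
            merged = man.align_folds([_traces(coords, odors), _traces(coords, odors)])
        assert merged.coords.shape == (8, 5, 2)


class TestManifoldMetrics:
    def test_identical_trajectories_zero_intra(self, rng):
        traj = rng.normal(size=(1, 8, 2))
        coords = np.repeat(traj, 6, axis=0)
        m = man.manifold_metrics(_traces(coords, ["A", "B"] * 3))
        for o in m.odors:
            np.testing.assert_allclose(m.intra_class[o], 0.0, atol=1e-12)

    def test_two_static_classes_constant_inter(self):
        coords = np.zeros((4, 6, 2))
        coords[2:, :, 0] = 3.0  # class B offset by 3
        m = man.manifold_metrics(_traces(coords, ["A", "A", "B", "B"]))
        np.testing.assert_allclose(m.inter_class[("A", "B")], 3.0, atol=1e-12)

    def test_homogeneity_under_scaling(self, rng):
        coords = rng.normal(size=(9, 15, 2)) + 1.0
        t = _traces(coords, ["A", "B", "C"] * 3)
        t5 = _traces(5.0 * coords, ["A", "B", "C"] * 3)
        m1, m5 = man.manifold_metrics(t), man.manifold_metrics(t5)
        for o in m1.odors:
            np.testing.assert_allclose(
                5.0 * m1.dist_to_origin[o], m5.dist_to_origin[o], atol=1e-10
            )
        assert m5.mean_intra_class_0_12s == pytest.approx(
            5.0 * m1.mean_intra_class_0_12s
        )

    def test_rotation_invariance(self, rng):
        coords = rng.normal(size=(9, 15, 3))
        r = ortho_group.rvs(3, random_state=1)
        m1 = man.manifold_metrics(_traces(coords, ["A", "B", "C"] * 3))
        m2 = man.manifold_metrics(_traces(coords @ r, ["A", "B", "C"] * 3))
        for o in m1.odors:
            np.testing.assert_allclose(
                m1.dist_to_origin[o], m2.dist_to_origin[o], atol=1e-10
            )

    def test_t_fifth_matches_dense_grid_crossing(self):
        # kernel-shaped planted trajectory: analytic crossing vs metric
        rate = 1.15
        t = -2.0 + np.arange(41) / rate
        kern = np.asarray(sg.response_kernel(np.maximum(t, 0), 0.2, 0.5, 4.0, 2.0))
        coords = np.zeros((2, 41, 2))
        coords[:, :, 0] = kern
        coords[1, :, 1] = 1e-9  # break exact class degeneracy
        m = man.manifold_metrics(_traces(coords, ["A", "B"], rate=rate, t0=-2.0))
        dense_t = np.linspace(0, 38, 2_000_000)
        dense = np.asarray(sg.response_kernel(dense_t, 0.2, 0.5, 4.0, 2.0))
        peak_i = dense.argmax()
        target = dense.max() / 5
        cross = dense_t[peak_i + np.argmax(dense[peak_i:] <= target)]
        # sampled trace: crossing within one frame interval of the dense oracle
        assert m.t_fifth["A"] == pytest.approx(cross, abs=1 / rate)


class TestStageAnalysis:
    def _drifting_traces(self, stage_values, n_sessions=12, noise=0.0, seed=0):
        r = np.random.default_rng(seed)
        drift = sg.stage_drift(stage_values, n_sessions)
        rate, f = 1.15, 41
        t = -2.0 + np.arange(f) / rate
        kern = np.asarray(sg.response_kernel(np.maximum(t, 0), 0.2, 0.5, 4.0, 1.0))
        coords, odors, sessions = [], [], []
        for s in range(n_sessions):
            for oi, o in enumerate(("A", "B", "C")):
                direction = np.zeros(2)
                direction[oi % 2] = 1.0 if oi < 2 else -1.0
                c = np.outer(kern * drift[s], direction)
                coords.append(c + noise * r.normal(size=c.shape))
                odors.append(o)
                sessions.append(s)
        return _traces(np.array(coords), odors, sessions, rate=rate)

    def test_planted_decay_strictly_decreasing(self):
        tr = self._drifting_traces((1.0, 0.85, 0.7, 0.55), noise=0.01)
        res = man.stage_analysis(tr)
        assert np.all(np.diff(res.stage_max_dist) < 0)
        # relative amplitude ratios recovered within 15% on near-noiseless data
        ratios = res.stage_max_dist / res.stage_max_dist[0]
        np.testing.assert_allclose(ratios, [1.0, 0.85, 0.7, 0.55], rtol=0.15)

    def test_flat_schedule_no_trend(self):
        tr = self._drifting_traces((1.0, 1.0, 1.0, 1.0), noise=0.05, seed=3)
        res = man.stage_analysis(tr)
        spread = res.stage_max_dist.max() - res.stage_max_dist.min()
        assert spread < 0.1 * res.stage_max_dist.mean()

    def test_return_locations_shape(self):
        tr = self._drifting_traces((1.0, 1.0, 1.0, 1.0))
        res = man.stage_analysis(tr)
        assert set(res.return_locations) == set(range(12))
        for s, (x, y) in res.return_xy.items():
            assert np.isfinite(x) and np.isfinite(y)

    def test_too_few_sessions_rejected(self):
        tr = self._drifting_traces((1.0, 1.0, 1.0, 1.0), n_sessions=12)
        sub = tr.select_trials(np.flatnonzero(tr.session_ids < 2))
        with pytest.raises(ValueError):
            man.stage_analysis(sub, n_stages=4)


class TestTraceIO:
    def test_hdf5_roundtrip(self, tmp_path, rng):
        tr = _traces(rng.normal(size=(6, 10, 2)), ["A", "B"] * 3)
        man.write_traces(tr, tmp_path / "traces.h5")
        back = man.read_traces(tmp_path / "traces.h5")
        np.testing.assert_array_equal(back.coords, tr.coords)
        assert list(back.odor_labels) == list(tr.odor_labels)
        np.testing.assert_array_equal(back.time_axis, tr.time_axis)


class TestProjectManifold:
    def test_planted_signal_separates_classes(self, small_exp, small_dff, small_trials):
        tt = small_trials["calcium"]
        res = dec.multiregion_classify(tt, dec.DecoderSpec(seed=0))
        rate = small_exp.config.frame_rate
        full = pre.extract_trials(
            small_dff["calcium"], small_exp.trial_table,
            int(round(2 * rate)), int(round(33 * rate)),
        )
        traces = man.project_manifold(res, full)
        assert traces.coords.shape[0] == tt.n_trials
        m = man.manifold_metrics(traces)
        stim_sel = (m.time_axis >= 0) & (m.time_axis <= 8)
        base_sel = m.time_axis < 0
        for pair, d in m.inter_class.items():
            assert d[stim_sel].max() > 3 * d[base_sel].mean()

    def test_null_signal_trajectories_stay_near_origin(self, rng):
        n_trials, v, f_feat = 60, 30, 14
        odors = np.array(list("ABC") * 20, dtype=object)
        sessions = np.repeat(np.arange(20), 3)
        coords3 = np.column_stack([np.arange(v) % 5, np.arange(v) // 5,
                                   np.zeros(v, int)])
        feat = pre.TrialTensor(rng.normal(size=(n_trials, v, f_feat)),
                               np.arange(f_feat), odors, sessions, 2.3,
                               voxel_coords=coords3, region_id=np.ones(v, int))
        full_vals = rng.normal(size=(n_trials, v, 30))
        full = pre.TrialTensor(full_vals, np.arange(-3, 27), odors, sessions, 2.3,
                               voxel_coords=coords3, region_id=np.ones(v, int))
        res = dec.multiregion_classify(feat, dec.DecoderSpec(seed=0))
        traces = man.project_manifold(res, full)
        m = man.manifold_metrics(traces)
        # class separation comparable to baseline fluctuation, not above it
        for pair, d in m.inter_class.items():
            assert d.max() < 3 * np.mean([m.intra_class[o].mean() for o in m.odors])
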