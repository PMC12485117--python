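"""Low-dimensional manifold trajectories and their geometry.

Applying each cross-validation fold's fitted PCA and LDA maps to every
frame of a wide trial window (−2 s before odor onset to +33 s after)
turns each held-out trial into a trajectory in discriminant (LDA) space.
Folds are aligned by orthogonal Procrustes on their class-mean
trajectory matrices and concatenated; the combined manifold is
summarized by distance-to-origin, inter-class and intra-class distance
time courses, return times (to one-fifth of the maximum and to the
29–30 s "random" level), and per-session return locations.  Splitting
the sessions into four equal stages turns these into temporal-stability
metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .decoding import DecodeResult, _as_channel_list, _apply_frames

__all__ = [
    "ManifoldTraces",
    "ManifoldMetrics",
    "StageResult",
    "project_manifold",
    "align_folds",
    "manifold_metrics",
    "stage_analysis",
]


@dataclass
class ManifoldTraces:
    """Trial trajectories in LDA space: trials × frames × dims."""

    coords: np.ndarray  # (n_trials, F, d)
    time_axis: np.ndarray  # (F,) s relative to odor onset, strictly increasing
    odor_labels: np.ndarray
    session_ids: np.ndarray
    fold_ids: np.ndarray
    alignment_residuals: np.ndarray | None = None  # per fold, Frobenius residual

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_axis) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.coords.shape[1] != self.time_axis.size:
            raise ValueError("time axis must match the frame axis")

    def select_trials(self, idx: np.ndarray) -> "ManifoldTraces":
        return ManifoldTraces(
            coords=self.coords[idx],
            time_axis=self.time_axis,
            odor_labels=self.odor_labels[idx],
            session_ids=self.session_ids[idx],
            fold_ids=self.fold_ids[idx],
            alignment_residuals=self.alignment_residuals,
        )


@dataclass
class ManifoldMetrics:
    """Geometry of one (combined) manifold."""

    origin: np.ndarray  # (d,) mean location at the start time point
    odors: list
    dist_to_origin: dict  # odor -> (F,) distance of the odor-mean trace
    inter_class: dict  # (odor_a, odor_b) -> (F,)
    intra_class: dict  # odor -> (F,) mean pairwise same-odor distance
    max_dist_to_origin: dict  # odor -> float
    max_inter_class: dict  # pair -> float
    t_fifth: dict  # odor -> s (nan if never reached)
    t_random: dict  # odor -> s (nan if never reached)
    mean_intra_class_0_12s: float
    time_axis: np.ndarray

    @property
    def mean_max_dist_to_origin(self) -> float:
        return float(np.mean(list(self.max_dist_to_origin.values())))

    @property
    def mean_max_inter_class(self) -> float:
        return float(np.mean(list(self.max_inter_class.values())))


def write_traces(traces: ManifoldTraces, path) -> None:
    """Write manifold traces to HDF5 (coords, time axis, per-trial labels)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=traces.coords, track_times=False)
        f.create_dataset("time_axis", data=traces.time_axis, track_times=False)
        f.create_dataset(
            "odor_labels",
            data=np.asarray(traces.odor_labels, dtype="S"),
            track_times=False,
        )
        f.create_dataset("session_ids", data=traces.session_ids, track_times=False)
        f.create_dataset("fold_ids", data=traces.fold_ids, track_times=False)


def read_traces(path) -> ManifoldTraces:
    """Read manifold traces written by :func:`write_traces`."""
    import h5py

    with h5py.File(path, "r") as f:
        return ManifoldTraces(
            coords=f["coords"][()],
            time_axis=f["time_axis"][()],
            odor_labels=f["odor_labels"][()].astype(str),
            session_ids=f["session_ids"][()],
            fold_ids=f["fold_ids"][()],
        )


def project_manifold(result: DecodeResult, full_trials) -> ManifoldTraces:
    """Project wide-window trials through each fold's fitted transforms.

    ``full_trials`` is a TrialTensor (or list per channel, matching the
    decode) whose window spans −2 s to +33 s around odor onset.  Each
    trial is projected by the transforms of the fold in which it was held
    out, then folds are aligned (:func:`align_folds`) and concatenated.
    """
    tensors = _as_channel_list(full_trials)
    if result.channel_masks is not None:
        tensors = [
            t if m is None else t.select_voxels(np.asarray(m))
            for t, m in zip(tensors, result.channel_masks)
        ]
    time_axis = tensors[0].time_axis
    frames = [t.values.transpose(0, 2, 1) for t in tensors]  # (n, F, V)
    n_folds = len(result.transforms)
    per_fold = []
    for fold in range(n_folds):
        test = np.flatnonzero(result.fold_assignment == fold)
        if test.size == 0:
            raise ValueError(f"fold {fold} has no held-out trials")
        coords = result.transforms[fold].project([f[test] for f in frames])
        per_fold.append(
            ManifoldTraces(
                coords=coords,
                time_axis=time_axis,
                odor_labels=np.asarray(result.odor_labels)[test],
                session_ids=np.asarray(result.session_ids)[test],
                fold_ids=np.full(test.size, fold),
            )
        )
    return align_folds(per_fold)


def align_folds(folds: list[ManifoldTraces]) -> ManifoldTraces:
    """Align per-fold manifolds by orthogonal Procrustes and concatenate.

    Each fold's class-mean trajectory matrix (classes × frames stacked,
    d columns) is mapped onto the first fold's by rotation/reflection
    only (no scaling).  Residuals are recorded so misalignment is
    detectable.  Degenerate (near-zero) class means fall back to the
    identity with a warning.
    """
    if len(folds) < 2:
        return folds[0] if folds else None
    classes = sorted(set().union(*(set(f.odor_labels) for f in folds)))

    def class_means(f: ManifoldTraces) -> np.ndarray:
        rows = []
        for c in classes:
            sel = f.odor_labels == c
            rows.append(
                f.coords[sel].mean(axis=0)
                if sel.any()
                else np.zeros(f.coords.shape[1:])
            )
        return np.concatenate(rows, axis=0)  # (classes*F, d)

    ref = class_means(folds[0])
    aligned = [folds[0]]
    residuals = [0.0]
    for f in folds[1:]:
        a = class_means(f)
        if np.linalg.norm(a) < 1e-12 or np.linalg.norm(ref) < 1e-12:
            warnings.warn("degenerate class means: identity alignment used")
            r = np.eye(a.shape[1])
        else:
            r, _ = orthogonal_procrustes(a, ref)
        residuals.append(float(np.linalg.norm(a @ r - ref)))
        aligned.append(
            ManifoldTraces(
                coords=f.coords @ r,
                time_axis=f.time_axis,
                odor_labels=f.odor_labels,
                session_ids=f.session_ids,
                fold_ids=f.fold_ids,
            )
        )
    return ManifoldTraces(
        coords=np.concatenate([f.coords for f in aligned]),
        time_axis=folds[0].time_axis,
        odor_labels=np.concatenate([f.odor_labels for f in aligned]),
        session_ids=np.concatenate([f.session_ids for f in aligned]),
        fold_ids=np.concatenate([f.fold_ids for f in aligned]),
        alignment_residuals=np.array(residuals),
    )


def _first_crossing_after(
    t: np.ndarray, y: np.ndarray, start_idx: int, level: float
) -> float:
    """First time at/after ``start_idx`` where y falls to ``level``, with
    linear interpolation between samples.  NaN if never reached."""
    for i in range(start_idx, y.size):
        if y[i] <= level:
            if i == start_idx or y[i - 1] <= level:
                return float(t[i])
            frac = (y[i - 1] - level) / (y[i - 1] - y[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return float("nan")


def manifold_metrics(
    traces: ManifoldTraces,
    random_window: tuple[float, float] = (29.0, 30.0),
    intra_window: tuple[float, float] = (0.0, 12.0),
) -> ManifoldMetrics:
    """Distance metrics of a combined manifold.

    The origin is the mean location over all trials at the first time
    point (−2 s).  Distances (Euclidean in LDA space) are computed on
    per-odor mean traces (to origin and between odor pairs) and across
    same-odor trials (intra-class).  Return times: ``t_fifth`` is the
    first post-peak time the origin distance falls to max/5; ``t_random``
    the first post-peak time it falls to the 29–30 s average level.
    """
    t = traces.time_axis
    coords = traces.coords
    odors = sorted(set(traces.odor_labels))
    origin = coords[:, 0, :].mean(axis=0)
    centered = coords - origin

    means = {
        o: centered[traces.odor_labels == o].mean(axis=0) for o in odors
    }  # (F, d) each
    dist_to_origin = {o: np.linalg.norm(means[o], axis=1) for o in odors}
    inter = {
        (a, b): np.linalg.norm(means[a] - means[b], axis=1)
        for a, b in combinations(odors, 2)
    }
    intra = {}
    for o in odors:
        grp = centered[traces.odor_labels == o]
        n = grp.shape[0]
        if n < 2:
            intra[o] = np.zeros(t.size)
            continue
        acc = np.zeros(t.size)
        for i, j in combinations(range(n), 2):
            acc += np.linalg.norm(grp[i] - grp[j], axis=1)
        intra[o] = acc / (n * (n - 1) / 2)

    onset_idx = int(np.searchsorted(t, 0.0))
    rand_sel = (t >= random_window[0]) & (t <= random_window[1])
    t_fifth = {}
    t_random = {}
    max_d = {}
    for o in odors:
        d = dist_to_origin[o]
        post = d[onset_idx:]
        peak_rel = int(np.argmax(post))
        peak_idx = onset_idx + peak_rel
        max_d[o] = float(post[peak_rel])
        t_fifth[o] = _first_crossing_after(t, d, peak_idx, max_d[o] / 5.0)
        rand_level = float(d[rand_sel].mean()) if rand_sel.any() else float("nan")
        t_random[o] = _first_crossing_after(t, d, peak_idx, rand_level)

    intra_sel = (t >= intra_window[0]) & (t <= intra_window[1])
    mean_intra = float(
        np.mean([intra[o][intra_sel].mean() for o in odors])
    ) if intra_sel.any() else float("nan")

    return ManifoldMetrics(
        origin=origin,
        odors=odors,
        dist_to_origin=dist_to_origin,
        inter_class=inter,
        intra_class=intra,
        max_dist_to_origin=max_d,
        max_inter_class={k: float(v.max()) for k, v in inter.items()},
        t_fifth=t_fifth,
        t_random=t_random,
        mean_intra_class_0_12s=mean_intra,
        time_axis=t,
    )


@dataclass
class StageResult:
    """Per-stage manifold metrics and per-session return locations."""

    stage_metrics: list[ManifoldMetrics]  # one per stage
    stage_sessions: list[np.ndarray]  # sessions in each stage
    return_locations: dict  # session -> (d,) mean location over 29-30 s
    return_xy: dict  # session -> (x, y) on the first two discriminant axes
    return_distance: dict  # session -> distance to the global origin
    stage_max_dist: np.ndarray  # (n_stages,) mean over odors of max origin distance
    stage_max_inter: np.ndarray
    stage_intra: np.ndarray


def stage_analysis(
    traces: ManifoldTraces,
    n_stages: int = 4,
    random_window: tuple[float, float] = (29.0, 30.0),
) -> StageResult:
    """Temporal-stability analysis: metrics per stage of the session axis.

    Sessions are split evenly into ``n_stages`` contiguous stages (the
    default four-stage split of 60 sessions is S1: 1–15 … S4: 46–60).
    Return locations (mean manifold location over 29–30 s) are computed
    per session; their x/y coordinates are the first two discriminant
    axes.
    """
    sessions = np.unique(traces.session_ids)
    if sessions.size < n_stages:
        raise ValueError("fewer sessions than stages")
    edges = np.linspace(0, sessions.size, n_stages + 1).astype(int)
    stage_sessions = [sessions[edges[i] : edges[i + 1]] for i in range(n_stages)]

    origin = traces.coords[:, 0, :].mean(axis=0)
    t = traces.time_axis
    rand_sel = (t >= random_window[0]) & (t <= random_window[1])

    return_locations = {}
    return_xy = {}
    return_distance = {}
    for s in sessions:
        sel = traces.session_ids == s
        loc = traces.coords[sel][:, rand_sel, :].mean(axis=(0, 1)) - origin
        return_locations[int(s)] = loc
        return_xy[int(s)] = (float(loc[0]), float(loc[1]) if loc.size > 1 else 0.0)
        return_distance[int(s)] = float(np.linalg.norm(loc))

    metrics = []
    for stage in stage_sessions:
        sel = np.isin(traces.session_ids, stage)
        metrics.append(manifold_metrics(traces.select_trials(np.flatnonzero(sel))))
    return StageResult(
        stage_metrics=metrics,
        stage_sessions=stage_sessions,
        return_locations=return_locations,
        return_xy=return_xy,
        return_distance=return_distance,
        stage_max_dist=np.array([m.mean_max_dist_to_origin for m in metrics]),
        stage_max_inter=np.array([m.mean_max_inter_class for m in metrics]),
        stage_intra=np.array([m.mean_intra_class_0_12s for m in metrics]),
    )
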