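"""ΔF/F extraction, trial windowing, and region averaging.

The baseline convention is a causal sliding window: for each frame the
baseline F₀ is the mean of the lowest 30% of intensities among the
previous 200 frames, and ΔF/F = (F − F₀)/F₀.  Early frames with fewer
than 200 preceding frames use all available preceding frames (warm-up);
frame 0, with no history, is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "DffTensor",
    "TrialTensor",
    "RegionTraces",
    "compute_dff",
    "extract_trials",
    "region_average",
    "downsample",
    "dff_from_experiment",
    "read_volumes",
    "read_trial_table",
]


@dataclass
class DffTensor:
    """Voxels × frames ΔF/F with voxel geometry.

    Voxel order is the C-order raveling of the (x, y, z) grid and is stable
    across the pipeline.
    """

    values: np.ndarray  # (V, T) ΔF/F, dimensionless
    voxel_coords: np.ndarray  # (V, 3) int
    region_id: np.ndarray  # (V,) 0 = unassigned
    frame_rate: float  # Hz

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be voxels × frames")
        if len(self.voxel_coords) != len(self.values) or len(self.region_id) != len(
            self.values
        ):
            raise ValueError("voxel metadata length mismatch")
        if np.any(self.region_id < 0):
            raise ValueError("region ids must be >= 0")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class TrialTensor:
    """Trial-windowed ΔF/F: trials × voxels × frames."""

    values: np.ndarray  # (n_trials, V, F)
    window_offsets: np.ndarray  # (F,) frame offsets relative to odor onset
    odor_labels: np.ndarray  # (n_trials,) str
    session_ids: np.ndarray  # (n_trials,) int
    frame_rate: float
    voxel_coords: np.ndarray | None = None  # (V, 3)
    region_id: np.ndarray | None = None  # (V,)

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be trials × voxels × frames")
        if self.values.shape[2] != len(self.window_offsets):
            raise ValueError("window_offsets length must match frame axis")
        if len(self.odor_labels) != self.values.shape[0] or len(self.session_ids) != (
            self.values.shape[0]
        ):
            raise ValueError("per-trial metadata length mismatch")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def time_axis(self) -> np.ndarray:
        """Seconds relative to odor onset."""
        return self.window_offsets / self.frame_rate

    def select_voxels(self, idx: np.ndarray) -> "TrialTensor":
        return TrialTensor(
            values=self.values[:, idx, :],
            window_offsets=self.window_offsets,
            odor_labels=self.odor_labels,
            session_ids=self.session_ids,
            frame_rate=self.frame_rate,
            voxel_coords=None if self.voxel_coords is None else self.voxel_coords[idx],
            region_id=None if self.region_id is None else self.region_id[idx],
        )

    def select_trials(self, idx: np.ndarray) -> "TrialTensor":
        return TrialTensor(
            values=self.values[idx],
            window_offsets=self.window_offsets,
            odor_labels=self.odor_labels[idx],
            session_ids=self.session_ids[idx],
            frame_rate=self.frame_rate,
            voxel_coords=self.voxel_coords,
            region_id=self.region_id,
        )


@dataclass
class RegionTraces:
    """Region-averaged traces; empty regions are absent, never zero-filled."""

    region_ids: np.ndarray  # (R,) present regions, sorted
    values: np.ndarray  # (R, T)
    frame_rate: float


def compute_dff(
    trace: np.ndarray, window: int = 200, fraction: float = 0.3
) -> np.ndarray:
    """Sliding-window ΔF/F of a fluorescence trace (1-D) or stack (V × T).

    For frame i the baseline F₀ is the mean of the lowest
    ``ceil(fraction × w)`` values among the previous ``w = min(window, i)``
    frames; ΔF/F = (F − F₀)/F₀.  Frame 0 returns 0 by convention.

    Raises if any baseline is non-positive (input must be positive
    fluorescence, not already-normalized data).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(trace, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("trace must be 1-D or 2-D (voxels × frames)")
    n_vox, n_frames = x.shape
    if n_frames < 1:
        raise ValueError("trace must have at least one frame")

    f0 = np.empty_like(x)
    f0[:, 0] = x[:, 0]  # frame 0: no history, ΔF/F defined as 0
    warm_end = min(window, n_frames - 1)
    for i in range(1, warm_end + 1):
        w = i
        k = ceil(fraction * w)
        win = np.partition(x[:, :i], k - 1, axis=1) if k < w else x[:, :i]
        f0[:, i] = win[:, :k].mean(axis=1)
    if n_frames - 1 > window:
        k = ceil(fraction * window)
        from numpy.lib.stride_tricks import sliding_window_view

        # windows ending just before frame i = window..n_frames-1
        chunk = max(1, int(1e7 / (max(n_frames - window, 1) * window)))
        for v0 in range(0, n_vox, chunk):
            v1 = min(v0 + chunk, n_vox)
            wins = sliding_window_view(x[v0:v1, : n_frames - 1], window, axis=1)
            part = np.partition(wins, k - 1, axis=-1)[..., :k]
            f0[v0:v1, window:] = part.mean(axis=-1)
    # frame 0's self-baseline is excluded: its output is 0 by definition
    if np.any(f0[:, 1:] <= 0):
        raise ValueError("non-positive baseline F0: input must be positive fluorescence")
    f0[:, 0] = 1.0
    out = (x - f0) / f0
    out[:, 0] = 0.0
    return out[0] if squeeze else out


def dff_from_experiment(exp, channel: str, window: int = 200, fraction: float = 0.3) -> DffTensor:
    """Convenience: ΔF/F tensor of one channel of a synthetic experiment."""
    values = compute_dff(exp.fluorescence[channel], window=window, fraction=fraction)
    return DffTensor(
        values=values,
        voxel_coords=exp.voxel_coords,
        region_id=exp.region_id,
        frame_rate=exp.config.frame_rate,
    )


def extract_trials(
    dff: DffTensor,
    trials: pd.DataFrame,
    pre_frames: int,
    post_frames: int,
) -> TrialTensor:
    """Window ΔF/F around each odor onset.

    Trial t, frame k holds ΔF/F at ``onset_frame(t) − pre_frames + k``;
    trial order is preserved.  Raises naming the offending trial if a
    window leaves the recording.
    """
    if pre_frames < 0 or post_frames < 1:
        raise ValueError("need pre_frames >= 0 and post_frames >= 1")
    n_frames = dff.n_frames
    onsets = trials["onset_frame"].to_numpy()
    starts = onsets - pre_frames
    stops = onsets + post_frames
    bad = np.flatnonzero((starts < 0) | (stops > n_frames))
    if bad.size:
        t = int(trials["trial"].iloc[bad[0]])
        raise ValueError(
            f"trial {t}: window [{starts[bad[0]]}, {stops[bad[0]]}) exceeds "
            f"recording bounds [0, {n_frames})"
        )
    width = pre_frames + post_frames
    idx = starts[:, None] + np.arange(width)[None, :]
    values = dff.values[:, idx].transpose(1, 0, 2)  # (trials, V, F)
    return TrialTensor(
        values=values,
        window_offsets=np.arange(-pre_frames, post_frames),
        odor_labels=trials["odor"].to_numpy(dtype=object),
        session_ids=trials["session"].to_numpy(),
        frame_rate=dff.frame_rate,
        voxel_coords=dff.voxel_coords,
        region_id=dff.region_id,
    )


def region_average(dff: DffTensor, atlas: np.ndarray | None = None) -> RegionTraces:
    """Unweighted mean ΔF/F over member voxels per region.

    Label 0 means unassigned and is excluded.  Regions with no voxels are
    simply absent from the result.
    """
    labels = atlas.reshape(-1) if atlas is not None else dff.region_id
    if len(labels) != dff.n_voxels:
        raise ValueError("atlas shape does not match the voxel set")
    present = np.unique(labels)
    present = present[present > 0]
    out = np.empty((present.size, dff.n_frames))
    for i, r in enumerate(present):
        out[i] = dff.values[labels == r].mean(axis=0)
    return RegionTraces(region_ids=present, values=out, frame_rate=dff.frame_rate)


def region_trial_tensor(trials: TrialTensor) -> TrialTensor:
    """Average a voxel-level TrialTensor into a region-level one."""
    if trials.region_id is None:
        raise ValueError("TrialTensor lacks region ids")
    present = np.unique(trials.region_id)
    present = present[present > 0]
    values = np.stack(
        [trials.values[:, trials.region_id == r, :].mean(axis=1) for r in present],
        axis=1,
    )
    return TrialTensor(
        values=values,
        window_offsets=trials.window_offsets,
        odor_labels=trials.odor_labels,
        session_ids=trials.session_ids,
        frame_rate=trials.frame_rate,
        voxel_coords=None,
        region_id=present,
    )


def downsample(trace: np.ndarray, factor: int) -> np.ndarray:
    """Block mean over non-overlapping groups of ``factor`` frames (last axis).

    A trailing partial block is dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = np.asarray(trace)
    if factor == 1:
        return x.copy()
    n = (x.shape[-1] // factor) * factor
    shape = x.shape[:-1] + (n // factor, factor)
    return x[..., :n].reshape(shape).mean(axis=-1)


def read_volumes(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-channel 4-D volumes from the generator's HDF5 layout."""
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        for name in f:
            out[name] = f[name][()]
    return out


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"trial", "session", "odor", "onset_frame"}
    if not required <= set(table.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    return table
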