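"""Motion-confound analysis.

Motion energy is the mean absolute difference between consecutive
behavior-video frames.  Trial-windowed motion is reduced to behavioral
principal components; an SVM decodes stimulus period vs interval and
odor identity from them (with a label-shuffle control); ridge regression
partitions the variance of the first neural PCs into behavior-explained
and residual parts, both of which can be fed back into odor
classification; and lagged cross-correlation profiles quantify
motion–neural coupling within ±1 s at 0.1 s steps (positive lag =
neural delayed relative to motion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "MotionTrace",
    "motion_energy",
    "trial_motion_windows",
    "behavior_features",
    "behavior_decoding",
    "ridge_partition",
    "lagged_correlation",
]


@dataclass
class MotionTrace:
    """Per-frame motion energy (intensity units per frame pair)."""

    energy: np.ndarray  # (n_video_frames - 1,)
    frame_rate: float

    def __post_init__(self) -> None:
        if np.any(self.energy < 0):
            raise ValueError("motion energy must be non-negative")


def motion_energy(video: np.ndarray, frame_rate: float) -> MotionTrace:
    """Mean over pixels of |f_{t+1} − f_t| for each consecutive frame pair."""
    v = np.asarray(video, dtype=float)
    if v.ndim != 3 or v.shape[0] < 2:
        raise ValueError("video must be (frames, h, w) with >= 2 frames")
    energy = np.abs(np.diff(v, axis=0)).mean(axis=(1, 2))
    return MotionTrace(energy=energy, frame_rate=frame_rate)


def trial_motion_windows(
    motion: MotionTrace,
    onset_frames: np.ndarray,
    pre_frames: int,
    post_frames: int,
) -> np.ndarray:
    """Window the motion-energy trace around odor onsets: (trials, F)."""
    onsets = np.asarray(onset_frames)
    starts = onsets - pre_frames
    stops = onsets + post_frames
    if np.any(starts < 0) or np.any(stops > motion.energy.size):
        raise ValueError("motion window exceeds the video extent")
    idx = starts[:, None] + np.arange(pre_frames + post_frames)[None, :]
    return motion.energy[idx]


def behavior_features(
    trial_motion: np.ndarray, n_pcs: int = 30, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Behavioral PCs of per-trial motion windows.

    Returns (features, explained variance ratio).  The sign convention is
    deterministic: each PC's largest-magnitude loading is positive.
    """
    x = np.asarray(trial_motion, dtype=float)
    if x.ndim != 2:
        raise ValueError("trial motion must be trials × frames")
    n_pcs = min(n_pcs, *x.shape)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    feats = pca.fit_transform(x)
    # deterministic sign: flip so each component's extreme loading is positive
    for k in range(n_pcs):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            feats[:, k] *= -1
    return feats, pca.explained_variance_ratio_


def behavior_decoding(
    features: np.ndarray,
    labels: np.ndarray,
    shuffle_control: bool = False,
    seed: int = 0,
    cv_folds: int = 5,
    svm_c: float = 1.0,
) -> float:
    """SVM decoding of labels from behavioral features, 5-fold CV accuracy.

    ``labels`` may be stimulus period vs interval or odor identity.  With
    ``shuffle_control`` the labels are permuted (seeded) first — the
    negative control.  Features are used as-is: behavioral PCs are already
    centered and variance-ordered, and rescaling them would amplify the
    low-variance noise components.
    """
    y = np.asarray(labels)
    x = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    if shuffle_control:
        y = y[rng.permutation(y.size)]
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(x, y):
        svm = SVC(kernel="linear", C=svm_c)
        svm.fit(x[train], y[train])
        accs.append(float((svm.predict(x[test]) == y[test]).mean()))
    return float(np.mean(accs))


@dataclass
class RidgePartition:
    """Variance partition of neural PCs by predictor set."""

    r2: dict  # predictor set -> mean CV R² across neural PCs
    behavior_explained: np.ndarray  # (trials, n_pcs) fitted from behavior
    residual: np.ndarray  # neural PCs minus the behavior-explained part


def _stimulus_design(labels: np.ndarray, neural_pcs: np.ndarray) -> np.ndarray:
    """Trial-averaged response per odor identity as the stimulus predictor."""
    classes = np.unique(labels)
    means = {c: neural_pcs[labels == c].mean(axis=0) for c in classes}
    return np.stack([means[c] for c in labels])


def ridge_partition(
    neural_pcs: np.ndarray,
    behavior: np.ndarray,
    stimulus_labels: np.ndarray | None = None,
    alpha: float = 1.0,
    cv_folds: int = 5,
    seed: int = 0,
) -> RidgePartition:
    """Ridge variance partitioning of neural PCs.

    Predicts each neural PC from behavior features, the stimulus design
    (trial-averaged responses per odor identity), or both; R² by 5-fold
    CV.  The behavior-explained component is the fitted values of the
    behavior-only model (fit on all trials), the residual its exact
    complement — the two reconstruct the neural PCs identically.
    Zero regularization is forbidden.
    """
    if alpha <= 0:
        raise ValueError("ridge penalty must be positive (singular designs otherwise)")
    y = np.asarray(neural_pcs, dtype=float)
    xb = StandardScaler().fit_transform(np.asarray(behavior, dtype=float))
    designs: dict[str, np.ndarray] = {"behavior": xb}
    if stimulus_labels is not None:
        xs = _stimulus_design(np.asarray(stimulus_labels), y)
        designs["stimulus"] = xs
        designs["both"] = np.concatenate([xb, xs], axis=1)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    r2: dict[str, float] = {}
    for name, x in designs.items():
        scores = []
        for train, test in kf.split(x):
            model = Ridge(alpha=alpha).fit(x[train], y[train])
            pred = model.predict(x[test])
            ss_res = ((y[test] - pred) ** 2).sum(axis=0)
            ss_tot = ((y[test] - y[train].mean(axis=0)) ** 2).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                scores.append(np.nanmean(1 - ss_res / ss_tot))
        r2[name] = float(np.mean(scores))

    behavior_model = Ridge(alpha=alpha).fit(xb, y)
    explained = behavior_model.predict(xb)
    return RidgePartition(r2=r2, behavior_explained=explained, residual=y - explained)


def lagged_correlation(
    neural: np.ndarray,
    motion: np.ndarray,
    frame_rate: float,
    max_lag: float = 1.0,
    step: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Lagged Pearson correlation between neural traces and motion.

    ``neural`` is (V, T) on the same time base as ``motion`` (T,).
    Positive lag = neural delayed relative to motion.  Sub-frame shifts
    use linear interpolation of the motion trace.  Returns (lags,
    profiles (V, n_lags), summary) where the summary carries the mean
    profile, the per-lag fraction of voxels above the mean correlation,
    and the per-voxel peak lag.
    """
    x = np.asarray(neural, dtype=float)
    m = np.asarray(motion, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != m.size:
        raise ValueError("neural and motion must share a time base")
    lags = np.round(np.arange(-max_lag, max_lag + step / 2, step), 10)
    t = np.arange(m.size) / frame_rate
    margin = int(np.ceil(max_lag * frame_rate)) + 1
    sl = slice(margin, m.size - margin)
    profiles = np.empty((x.shape[0], lags.size))
    xs = x[:, sl]
    xc = xs - xs.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    for li, lag in enumerate(lags):
        # neural delayed by `lag` => compare neural(t) with motion(t - lag)
        m_shift = np.interp(t[sl] - lag, t, m)
        mc = m_shift - m_shift.mean()
        denom = xn * np.linalg.norm(mc)
        with np.errstate(invalid="ignore", divide="ignore"):
            profiles[:, li] = (xc @ mc) / denom
    mean_profile = np.nanmean(profiles, axis=0)
    overall_mean = np.nanmean(profiles)
    frac_above = np.nanmean(profiles > overall_mean, axis=0)
    peak_lag = lags[np.nanargmax(profiles, axis=1)]
    summary = {
        "mean_per_lag": mean_profile,
        "fraction_above_mean": frac_above,
        "peak_lag": peak_lag,
    }
    return lags, profiles, summary
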