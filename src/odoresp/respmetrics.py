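"""Per-voxel and per-region response characterization.

Covers the "maps" of the analysis: responsiveness (significance-gated
Pearson correlation with the binary stimulus sequence), response
intensity (per-trial sd or AUC of ΔF/F in the response window), response
dynamics (phase delay to peak and full width at half maximum), and odor
tuning (AUC difference against the pooled other odors, significance by
Mann–Whitney U with Benjamini–Hochberg correction across voxels).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import stats as sps

from .preprocess import TrialTensor
from .stats import bh_correct

__all__ = [
    "MetricMap",
    "responsiveness_map",
    "region_responsiveness",
    "response_intensity",
    "response_dynamics",
    "odor_tuning",
    "standardized_tuned_ratio",
]


@dataclass
class MetricMap:
    """Per-voxel scalar map with a validity mask."""

    values: np.ndarray  # (V,) metric-specific units
    mask: np.ndarray  # (V,) bool, True = valid
    metric_name: str

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must align")

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of x (V × T) against y (T,) with two-sided p.

    p-values follow the exact t distribution with T − 2 df (the same null
    model scipy.stats.pearsonr uses).  Zero-variance rows give r = nan.
    """
    n = y.size
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * sps.t.sf(np.abs(t), n - 2)
    p[np.isnan(r)] = np.nan
    # |r| == 1 exactly -> p = 0
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def responsiveness_map(
    dff_values: np.ndarray, stimulus: np.ndarray, alpha: float = 0.05
) -> MetricMap:
    """Correlation of each voxel's ΔF/F with the binary stimulus sequence.

    Only significant correlations (two-sided p < alpha) are kept; the rest
    (and zero-variance voxels) are masked invalid.  ``dff_values`` is the
    voxels × frames ΔF/F concatenated over the analysis window.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.std() == 0:
        raise ValueError("stimulus sequence must not be constant")
    if dff_values.shape[1] != stimulus.size:
        raise ValueError("stimulus must align with the concatenated frames")
    r, p = _pearson_with_p(np.asarray(dff_values, dtype=float), stimulus)
    mask = np.isfinite(r) & np.isfinite(p) & (p < alpha)
    return MetricMap(values=np.where(np.isfinite(r), r, 0.0), mask=mask, metric_name="responsiveness")


def region_responsiveness(
    metric: MetricMap, atlas: np.ndarray, top_fraction: float = 0.2
) -> dict[int, float]:
    """Mean of the top-``top_fraction`` valid values per region.

    Regions with zero valid voxels are absent from the result.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    labels = atlas.reshape(-1)
    out: dict[int, float] = {}
    for r in np.unique(labels):
        if r <= 0:
            continue
        vals = metric.values[(labels == r) & metric.mask]
        if vals.size == 0:
            continue
        k = ceil(top_fraction * vals.size)
        out[int(r)] = float(np.sort(vals)[-k:].mean())
    return out


def response_intensity(trials: TrialTensor, statistic: str = "sd") -> MetricMap:
    """Per-voxel response intensity averaged across trials.

    ``sd``: standard deviation of ΔF/F within the response window per trial.
    ``auc``: area under the curve (frame sum × frame interval, s·ΔF/F).
    """
    if trials.values.shape[2] == 0:
        raise ValueError("empty response window")
    if statistic == "sd":
        per_trial = trials.values.std(axis=2)
    elif statistic == "auc":
        per_trial = trials.values.sum(axis=2) / trials.frame_rate
    else:
        raise ValueError("statistic must be 'sd' or 'auc'")
    values = per_trial.mean(axis=0)
    return MetricMap(
        values=values,
        mask=np.ones_like(values, dtype=bool),
        metric_name=f"intensity_{statistic}",
    )


def response_dynamics(
    trial_avg: np.ndarray, frame_rate: float, onset_index: int = 0
) -> tuple[float, float]:
    """Phase delay and pulse width of a trial-averaged response trace.

    Phase delay is the time from odor onset to the response peak; pulse
    width is the full width at half maximum, with linear interpolation
    between samples at the half-max crossings.  Returns (nan, nan) for a
    trace with no positive peak.
    """
    y = np.asarray(trial_avg, dtype=float)
    if y.ndim != 1:
        raise ValueError("trial_avg must be a single trace")
    post = y[onset_index:]
    peak_rel = int(np.argmax(post))
    peak = post[peak_rel]
    if peak <= 0:
        return float("nan"), float("nan")
    phase_delay = peak_rel / frame_rate
    half = peak / 2.0
    ipk = onset_index + peak_rel

    # walk left from the peak to the last sample below half-max
    left = ipk
    while left > 0 and y[left - 1] >= half:
        left -= 1
    if left == 0 and y[0] >= half:
        t_left = 0.0
    else:
        frac = (half - y[left - 1]) / (y[left] - y[left - 1])
        t_left = (left - 1 + frac) / frame_rate

    right = ipk
    n = y.size
    while right < n - 1 and y[right + 1] >= half:
        right += 1
    if right == n - 1 and y[right] >= half:
        t_right = (n - 1) / frame_rate
    else:
        frac = (y[right] - half) / (y[right] - y[right + 1])
        t_right = (right + frac) / frame_rate
    return phase_delay, t_right - t_left


def odor_tuning(
    trials: TrialTensor, odor: str, alpha: float = 0.05
) -> MetricMap:
    """Odor tuning: AUC difference for ``odor`` against the pooled others.

    Tuning = mean per-trial AUC on trials of ``odor`` minus the mean over
    all other trials pooled.  Significance per voxel by two-sided
    Mann–Whitney U between the two trial groups, Benjamini–Hochberg
    corrected across voxels; non-significant voxels are masked.
    """
    labels = np.asarray(trials.odor_labels)
    in_class = labels == odor
    if in_class.sum() < 2 or (~in_class).sum() < 2:
        raise ValueError(f"need at least 2 trials of {odor!r} and 2 of the rest")
    auc = trials.values.sum(axis=2) / trials.frame_rate  # (trials, V)
    a = auc[in_class]
    b = auc[~in_class]
    tuning = a.mean(axis=0) - b.mean(axis=0)
    res = sps.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    p_adj, reject = bh_correct(res.pvalue, alpha=alpha)
    return MetricMap(values=tuning, mask=reject, metric_name=f"tuning_{odor}")


def standardized_tuned_ratio(
    tuning: MetricMap, atlas: np.ndarray, regions: list[int] | tuple[int, ...]
) -> dict[int, float]:
    """Fraction of significantly tuned voxels per region, z-scored.

    ``regions`` is the subset to standardize across (typically the
    community containing most olfactory regions).  Empty regions are
    excluded; fewer than 2 populated regions is undefined.
    """
    labels = atlas.reshape(-1)
    fractions: dict[int, float] = {}
    for r in regions:
        member = labels == r
        if member.sum() == 0:
            continue
        fractions[int(r)] = float(tuning.mask[member].mean())
    if len(fractions) < 2:
        raise ValueError("need at least 2 populated regions to standardize")
    vals = np.array(list(fractions.values()))
    sd = vals.std(ddof=1)
    if sd == 0:
        return {r: 0.0 for r in fractions}
    mean = vals.mean()
    return {r: float((v - mean) / sd) for r, v in fractions.items()}
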