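"""Ground-truth synthetic generator for dual-channel volumetric odor recordings.

Emulates the statistical structure of denoised, motion-corrected,
atlas-aligned volumetric fluorescence recordings during repeated odor
stimulation: odor-tuned voxel ensembles localized to labeled brain
regions, channel-specific response kinetics (fast calcium/ACh, slow
5-HT), session-wise multiplicative amplitude drift, shared latent
couplings between voxel groups, motion-coupled variance, and additive
noise.  Every planted parameter is returned as :class:`GroundTruth` so
downstream analyses can be validated against known answers.

The default trial structure is 3 odors × 60 sessions (180 trials), 5 s
stimuli with 30 s inter-trial intervals, presented in pseudo-random
order with no immediate repeats and each session containing each odor
exactly once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ChannelParams",
    "EnsembleEntry",
    "CouplingGroup",
    "SynthConfig",
    "GroundTruth",
    "Experiment",
    "generate_trial_order",
    "response_kernel",
    "kernel_peak_time",
    "kernel_fwhm",
    "stage_drift",
    "make_atlas",
    "generate_experiment",
    "write_experiment",
]

KERNEL_SUPPORT_S = 60.0  # kernels truncated past this lag; tails are < 1e-3 of peak for defaults


@dataclass(frozen=True)
class ChannelParams:
    """Response kinetics of one indicator channel.

    delay, rise_tau, decay_tau in seconds; amplitude_scale multiplies all
    planted ensemble amplitudes of the channel (ΔF/F units).
    """

    delay: float = 0.2
    rise_tau: float = 0.3
    decay_tau: float = 3.0
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.rise_tau >= self.decay_tau:
            raise ValueError("rise_tau must be smaller than decay_tau")


@dataclass(frozen=True)
class EnsembleEntry:
    """One planted odor-tuned ensemble: a voxel subset of a region.

    Entries with the same ``group`` key (default: the odor label), region
    and fraction share one voxel draw — across odors and channels — which
    lets a scenario plant, e.g., two odors driving identical voxels in one
    channel (indistinguishable there) while another channel separates them.
    """

    channel: str
    odor: str
    region: int
    member_fraction: float
    amplitude: float  # ΔF/F at response peak
    group: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.member_fraction <= 1:
            raise ValueError("member_fraction must be in [0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class CouplingGroup:
    """Voxels sharing a latent fluctuation (creates correlated activity).

    ``voxels`` are flat voxel indices; ``strength`` is the ΔF/F standard
    deviation of the shared latent added to every member.
    """

    channel: str
    voxels: tuple[int, ...]
    strength: float


def _default_channels() -> dict[str, ChannelParams]:
    return {
        "calcium": ChannelParams(delay=0.2, rise_tau=0.3, decay_tau=3.0),
        "ach": ChannelParams(delay=0.2, rise_tau=0.4, decay_tau=3.5),
    }


def _default_drift(channels: tuple[str, ...], n_sessions: int) -> dict[str, np.ndarray]:
    """Qualitative per-channel drift defaults: calcium decays gradually across
    the four stages, ACh stays flat through the first three, 5-HT drops only
    from stage 1 to stage 2.  Config-driven, not a claim about any dataset."""
    presets = {
        "calcium": (1.0, 0.85, 0.7, 0.55),
        "ach": (1.0, 1.0, 1.0, 0.9),
        "serotonin": (1.0, 0.7, 0.7, 0.7),
    }
    return {
        ch: stage_drift(presets.get(ch, (1.0, 1.0, 1.0, 1.0)), n_sessions)
        for ch in channels
    }


def stage_drift(stage_values: tuple[float, ...] | list[float], n_sessions: int) -> np.ndarray:
    """Expand per-stage multipliers into a per-session drift schedule.

    Sessions are split into ``len(stage_values)`` contiguous stages (the
    default four-stage split of 60 sessions is S1: 1–15 … S4: 46–60).
    """
    vals = np.asarray(stage_values, dtype=float)
    if np.any(vals <= 0):
        raise ValueError("drift multipliers must be positive")
    edges = np.linspace(0, n_sessions, len(vals) + 1).astype(int)
    out = np.empty(n_sessions, dtype=float)
    for i, v in enumerate(vals):
        out[edges[i] : edges[i + 1]] = v
    return out


@dataclass
class SynthConfig:
    """Full specification of one synthetic experiment."""

    grid_shape: tuple[int, int, int] = (24, 24, 8)
    n_regions: int = 8
    olfactory_regions: tuple[int, ...] = (1, 2, 3, 4)
    odors: tuple[str, ...] = ("OCT", "MCH", "EA")
    n_sessions: int = 60
    trials_per_session: int | None = None  # defaults to len(odors)
    frame_rate: float = 2.3  # Hz
    stim_duration: float = 5.0  # s
    inter_trial_interval: float = 30.0  # s
    rest_duration: float = 600.0  # s of pre-stimulation resting state
    channel_params: dict[str, ChannelParams] = field(default_factory=_default_channels)
    ensemble_spec: list[EnsembleEntry] | None = None  # None -> default layout
    coupling_groups: list[CouplingGroup] = field(default_factory=list)
    drift_schedule: dict[str, np.ndarray] | None = None  # None -> qualitative defaults
    motion_sd: float = 0.0  # ΔF/F-equivalent sd of the baseline motion latent
    motion_coupling: dict[str, float] | None = None  # per-channel gain on motion
    motion_stim_amplitude: float = 0.0  # stimulus-locked motion, any odor
    motion_odor_amplitudes: dict[str, float] | None = None  # odor-specific motion
    noise_sd: float = 0.05  # ΔF/F units, i.i.d. Gaussian
    baseline_F: float = 100.0  # arbitrary fluorescence units
    video_shape: tuple[int, int] = (16, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_session is None:
            self.trials_per_session = len(self.odors)
        if self.trials_per_session != len(self.odors):
            raise ValueError(
                "each session must contain each odor exactly once: "
                "trials_per_session must equal len(odors)"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.noise_sd < 0 or self.motion_sd < 0:
            raise ValueError("noise/motion sd must be non-negative")
        if self.baseline_F <= 0:
            raise ValueError("baseline_F must be positive")
        if self.n_sessions < 1:
            raise ValueError("need at least one session")
        if not set(self.olfactory_regions) <= set(range(1, self.n_regions + 1)):
            raise ValueError("olfactory_regions must be valid region ids (1-based)")

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session

    @property
    def trial_period(self) -> float:
        return self.stim_duration + self.inter_trial_interval

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.channel_params)


@dataclass
class GroundTruth:
    """Planted parameters of a generated experiment."""

    ensemble_membership: dict[str, np.ndarray]  # channel -> (V, n_odors) peak ΔF/F
    kernel_params: dict[str, ChannelParams]
    drift_schedule: dict[str, np.ndarray]  # channel -> (n_sessions,)
    motion_trace: np.ndarray  # (T,), motion_trace[0] == 0
    trial_order: list[str]
    coupling_groups: list[CouplingGroup]

    def to_json(self) -> str:
        payload = {
            "ensemble_membership": {
                ch: m.tolist() for ch, m in self.ensemble_membership.items()
            },
            "kernel_params": {
                ch: vars(p) for ch, p in self.kernel_params.items()
            },
            "drift_schedule": {ch: d.tolist() for ch, d in self.drift_schedule.items()},
            "motion_trace": self.motion_trace.tolist(),
            "trial_order": self.trial_order,
            "coupling_groups": [
                {"channel": g.channel, "voxels": list(g.voxels), "strength": g.strength}
                for g in self.coupling_groups
            ],
        }
        return json.dumps(payload)


@dataclass
class Experiment:
    """In-memory result of :func:`generate_experiment`.

    Fluorescence is stored voxels × frames; ``voxel_coords`` maps rows to
    grid positions (C-order raveling of the grid).
    """

    fluorescence: dict[str, np.ndarray]  # channel -> (V, T) float32
    trial_table: pd.DataFrame  # columns: trial, session, odor, onset_frame
    atlas: np.ndarray  # (x, y, z) int labels, 1-based; 0 = unassigned
    voxel_coords: np.ndarray  # (V, 3) int
    ground_truth: GroundTruth
    video: np.ndarray  # (T, H, W) float32 behavior frames
    config: SynthConfig

    @property
    def region_id(self) -> np.ndarray:
        return self.atlas.reshape(-1)

    def volume(self, channel: str) -> np.ndarray:
        """Return channel data as a 4-D (x, y, z, t) volume view."""
        v = self.fluorescence[channel]
        return v.reshape(*self.config.grid_shape, v.shape[1])


def generate_trial_order(
    n_sessions: int,
    odors: tuple[str, ...] | list[str],
    seed: int,
    *,
    frame_rate: float = 2.3,
    stim_duration: float = 5.0,
    inter_trial_interval: float = 30.0,
    rest_duration: float = 0.0,
) -> pd.DataFrame:
    """Pseudo-random balanced trial order with no immediate odor repeats.

    Each session is a permutation of the odor set; no two consecutive trials
    (including across session boundaries) share an odor.  Onsets are spaced
    by ``stim_duration + inter_trial_interval`` seconds, starting after the
    resting segment.
    """
    odors = tuple(odors)
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if len(odors) < 2:
        raise ValueError(
            "cannot avoid consecutive repeats with a single odor per session"
        )
    rng = np.random.default_rng(seed)
    order: list[str] = []
    prev: str | None = None
    for _ in range(n_sessions):
        while True:
            perm = list(rng.permutation(len(odors)))
            labels = [odors[i] for i in perm]
            if labels[0] != prev:
                break
        order.extend(labels)
        prev = labels[-1]
    period = stim_duration + inter_trial_interval
    onset_times = rest_duration + np.arange(len(order)) * period
    table = pd.DataFrame(
        {
            "trial": np.arange(len(order)),
            "session": np.repeat(np.arange(n_sessions), len(odors)),
            "odor": order,
            "onset_frame": np.rint(onset_times * frame_rate).astype(int),
        }
    )
    return table


def kernel_peak_time(delay: float, rise_tau: float, decay_tau: float) -> float:
    """Time of the kernel peak relative to stimulus onset (analytic)."""
    return delay + (
        rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    )


def response_kernel(
    t: np.ndarray | float,
    delay: float,
    rise_tau: float,
    decay_tau: float,
    amplitude: float,
) -> np.ndarray | float:
    """Difference-of-exponentials response kernel, unit peak × amplitude.

    Zero before ``delay``; rises with ``rise_tau`` and decays with
    ``decay_tau``; internally normalized so the peak equals ``amplitude``.
    """
    if rise_tau <= 0 or decay_tau <= 0:
        raise ValueError("time constants must be positive")
    if rise_tau >= decay_tau:
        raise ValueError("rise_tau must be smaller than decay_tau")
    t = np.asarray(t, dtype=float)
    s = t - delay
    raw = np.where(
        s > 0, np.exp(-np.maximum(s, 0) / decay_tau) - np.exp(-np.maximum(s, 0) / rise_tau), 0.0
    )
    s_peak = kernel_peak_time(delay, rise_tau, decay_tau) - delay
    peak = np.exp(-s_peak / decay_tau) - np.exp(-s_peak / rise_tau)
    out = amplitude * raw / peak
    return out if out.ndim else float(out)


def kernel_fwhm(delay: float, rise_tau: float, decay_tau: float) -> float:
    """Full width at half maximum of the unit-peak kernel (numeric, brentq)."""
    from scipy.optimize import brentq

    t_peak = kernel_peak_time(delay, rise_tau, decay_tau)

    def f(t: float) -> float:
        return float(response_kernel(t, delay, rise_tau, decay_tau, 1.0)) - 0.5

    left = brentq(f, delay + 1e-12, t_peak)
    hi = t_peak
    while f(hi + decay_tau) > 0:  # pragma: no cover - bounded by decay
        hi += decay_tau
    right = brentq(f, t_peak, hi + 20 * decay_tau)
    return right - left


def make_atlas(grid_shape: tuple[int, int, int], n_regions: int) -> np.ndarray:
    """Partition the voxel grid into ``n_regions`` contiguous boxes.

    Region ids are 1-based; the factorization of ``n_regions`` along the
    three axes is chosen as close to a cube as the grid allows.
    """
    best = None
    for nx in range(1, n_regions + 1):
        if n_regions % nx:
            continue
        for ny in range(1, n_regions // nx + 1):
            if (n_regions // nx) % ny:
                continue
            nz = n_regions // (nx * ny)
            if nx > grid_shape[0] or ny > grid_shape[1] or nz > grid_shape[2]:
                continue
            score = max(nx, ny, nz) - min(nx, ny, nz)
            if best is None or score < best[0]:
                best = (score, (nx, ny, nz))
    if best is None:
        raise ValueError("grid too small to host the requested number of regions")
    nx, ny, nz = best[1]
    atlas = np.zeros(grid_shape, dtype=np.int32)
    xe = np.linspace(0, grid_shape[0], nx + 1).astype(int)
    ye = np.linspace(0, grid_shape[1], ny + 1).astype(int)
    ze = np.linspace(0, grid_shape[2], nz + 1).astype(int)
    label = 1
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                atlas[xe[i] : xe[i + 1], ye[j] : ye[j + 1], ze[k] : ze[k + 1]] = label
                label += 1
    return atlas


def _default_ensembles(config: SynthConfig) -> list[EnsembleEntry]:
    """Each odor drives a slice of every olfactory region in every channel
    (peak ΔF/F 0.5).  Member fractions cycle over 0.10/0.15/0.20 with the
    odor-region pairing, so different odors recruit regions unevenly —
    region-mean traces then carry odor information, as in real recordings
    where odors engage olfactory neuropils with different strengths."""
    fractions = (0.10, 0.15, 0.20)
    entries = []
    for ch in config.channels:
        for oi, odor in enumerate(config.odors):
            for ri, region in enumerate(config.olfactory_regions):
                entries.append(
                    EnsembleEntry(
                        channel=ch,
                        odor=odor,
                        region=region,
                        member_fraction=fractions[(oi + ri) % len(fractions)],
                        amplitude=0.5,
                    )
                )
    return entries


def _smooth_noise(rng: np.random.Generator, n: int, sigma_frames: float) -> np.ndarray:
    """Unit-variance low-pass Gaussian noise (Gaussian-kernel smoothing)."""
    from scipy.ndimage import gaussian_filter1d

    x = gaussian_filter1d(rng.standard_normal(n), sigma_frames, mode="reflect")
    sd = x.std()
    return x / sd if sd > 0 else x


def _plant_memberships(
    config: SynthConfig,
    ensembles: list[EnsembleEntry],
    region_id: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw member voxels per (channel, odor, region) entry.

    The same (odor, region, fraction) tuple maps to the same voxel subset in
    every channel, so channels share ensembles unless their specs differ."""
    n_vox = region_id.size
    odor_index = {o: i for i, o in enumerate(config.odors)}
    membership = {
        ch: np.zeros((n_vox, len(config.odors)), dtype=float) for ch in config.channels
    }
    # deterministic member draw keyed by (odor, region, fraction), shared across channels
    draw_cache: dict[tuple, np.ndarray] = {}
    for e in ensembles:
        if e.channel not in membership:
            raise ValueError(f"unknown channel {e.channel!r} in ensemble spec")
        if e.odor not in odor_index:
            raise ValueError(f"unknown odor {e.odor!r} in ensemble spec")
        pool = np.flatnonzero(region_id == e.region)
        n_members = int(np.ceil(e.member_fraction * pool.size))
        if n_members > pool.size or (e.member_fraction > 0 and pool.size == 0):
            raise ValueError(
                f"region {e.region} has {pool.size} voxels; cannot host "
                f"{n_members} ensemble members (grid too small)"
            )
        key = (e.group or e.odor, e.region, round(e.member_fraction, 9))
        if key not in draw_cache:
            draw_cache[key] = rng.choice(pool, size=n_members, replace=False)
        scale = config.channel_params[e.channel].amplitude_scale
        membership[e.channel][draw_cache[key], odor_index[e.odor]] += e.amplitude * scale
    return membership


def complementary_channel_config(
    seed: int,
    *,
    grid_shape: tuple[int, int, int] = (8, 8, 4),
    n_sessions: int = 20,
    amplitude: float = 0.5,
    noise_sd: float = 0.1,
    **overrides,
) -> SynthConfig:
    """Scenario: the second channel carries signal absent from the first.

    In the calcium channel the first odor has its own ensemble while the
    other two odors drive one *shared* ensemble (identical voxels and
    amplitude — indistinguishable in calcium beyond noise).  The ACh
    channel adds an ensemble specific to the second odor, so dual-channel
    decoding can separate all three odors while calcium alone cannot.
    """
    base = SynthConfig(grid_shape=grid_shape, n_sessions=n_sessions, seed=seed)
    odors = base.odors
    spec = [
        EnsembleEntry("calcium", odors[0], 1, 0.4, amplitude),
        EnsembleEntry("calcium", odors[1], 2, 0.4, amplitude, group="shared"),
        EnsembleEntry("calcium", odors[2], 2, 0.4, amplitude, group="shared"),
        EnsembleEntry("ach", odors[1], 3, 0.4, amplitude),
    ]
    return SynthConfig(
        grid_shape=grid_shape,
        n_sessions=n_sessions,
        ensemble_spec=spec,
        noise_sd=noise_sd,
        rest_duration=overrides.pop("rest_duration", 30.0),
        drift_schedule={"calcium": np.ones(n_sessions), "ach": np.ones(n_sessions)},
        seed=seed,
        **overrides,
    )


def coupled_clusters_config(
    seed: int,
    *,
    cross_cluster: bool,
    grid_shape: tuple[int, int, int] = (8, 8, 4),
    n_sessions: int = 12,
    strength: float = 0.15,
    extra_strength: float = 0.12,
    noise_sd: float = 0.05,
    **overrides,
) -> SynthConfig:
    """Scenario: shared calcium/ACh clusters plus extra ACh coupling.

    Two voxel groups in the first region share latent fluctuations in both
    channels (the calcium clusters).  The ACh channel gets one extra
    coupled set: spanning the two clusters (``cross_cluster=True``, the
    complementation case) or inside the first cluster (the
    within-cluster emphasis control).  The deflation-ratio difference
    metric Δ_w⁺ − Δ_b⁺ should be smaller in the cross-cluster case.
    """
    atlas = make_atlas(grid_shape, 8)
    vox = np.flatnonzero(atlas.reshape(-1) == 1)
    half = vox.size // 2
    g1 = tuple(int(v) for v in vox[:half])
    g2 = tuple(int(v) for v in vox[half:])
    q = half // 2
    if cross_cluster:
        extra = g1[:q] + g2[:q]
    else:
        extra = g1[: 2 * q]
    groups = [
        CouplingGroup("calcium", g1, strength),
        CouplingGroup("calcium", g2, strength),
        CouplingGroup("ach", g1, strength),
        CouplingGroup("ach", g2, strength),
        CouplingGroup("ach", tuple(extra), extra_strength),
    ]
    return SynthConfig(
        grid_shape=grid_shape,
        n_sessions=n_sessions,
        ensemble_spec=[],
        coupling_groups=groups,
        noise_sd=noise_sd,
        rest_duration=overrides.pop("rest_duration", 30.0),
        drift_schedule={"calcium": np.ones(n_sessions), "ach": np.ones(n_sessions)},
        seed=seed,
        **overrides,
    )


def generate_experiment(config: SynthConfig) -> Experiment:
    """Generate the full synthetic experiment.

    Fluorescence per channel is
    ``baseline_F × (1 + Σ planted kernels × drift + motion_coupling × motion + noise)``
    clipped at zero.  Identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    atlas = make_atlas(config.grid_shape, config.n_regions)
    region_id = atlas.reshape(-1)
    n_vox = region_id.size
    coords = np.indices(config.grid_shape).reshape(3, -1).T.astype(np.int32)

    table = generate_trial_order(
        config.n_sessions,
        config.odors,
        int(rng.integers(0, 2**31 - 1)),
        frame_rate=config.frame_rate,
        stim_duration=config.stim_duration,
        inter_trial_interval=config.inter_trial_interval,
        rest_duration=config.rest_duration,
    )
    # recording extends one full trial period past the last onset
    total_s = (
        config.rest_duration + config.n_trials * config.trial_period
    )
    n_frames = int(np.ceil(total_s * config.frame_rate))
    t_axis = np.arange(n_frames) / config.frame_rate

    ensembles = (
        config.ensemble_spec if config.ensemble_spec is not None else _default_ensembles(config)
    )
    membership = _plant_memberships(config, ensembles, region_id, rng)
    drift = (
        {ch: np.asarray(config.drift_schedule[ch], dtype=float) for ch in config.channels}
        if config.drift_schedule is not None
        else _default_drift(config.channels, config.n_sessions)
    )
    for ch, d in drift.items():
        if d.shape != (config.n_sessions,):
            raise ValueError(f"drift schedule for {ch!r} must have one entry per session")

    # --- motion latent -------------------------------------------------
    motion = np.zeros(n_frames)
    if config.motion_sd > 0:
        motion += config.motion_sd * np.abs(_smooth_noise(rng, n_frames, sigma_frames=5.0))
    odor_amp = dict(config.motion_odor_amplitudes or {})
    kernel_support = int(np.ceil(KERNEL_SUPPORT_S * config.frame_rate))
    if config.motion_stim_amplitude > 0 or odor_amp:
        lag = np.arange(kernel_support) / config.frame_rate
        mk = response_kernel(lag, 0.1, 0.2, 1.5, 1.0)
        for _, row in table.iterrows():
            a = config.motion_stim_amplitude + odor_amp.get(row.odor, 0.0)
            if a == 0:
                continue
            i0 = int(row.onset_frame)
            i1 = min(i0 + kernel_support, n_frames)
            motion[i0:i1] += a * mk[: i1 - i0]
    motion[0] = 0.0

    # --- per-channel odor drive time courses ---------------------------
    odor_courses: dict[str, np.ndarray] = {}
    for ch in config.channels:
        p = config.channel_params[ch]
        lag = np.arange(kernel_support) / config.frame_rate
        kern = np.asarray(response_kernel(lag, p.delay, p.rise_tau, p.decay_tau, 1.0))
        courses = np.zeros((len(config.odors), n_frames))
        for _, row in table.iterrows():
            oi = config.odors.index(row.odor)
            i0 = int(row.onset_frame)
            i1 = min(i0 + kernel_support, n_frames)
            courses[oi, i0:i1] += drift[ch][int(row.session)] * kern[: i1 - i0]
        odor_courses[ch] = courses

    coupling = config.coupling_groups
    gains = dict(config.motion_coupling or {})

    fluorescence: dict[str, np.ndarray] = {}
    for ch in config.channels:
        signal = membership[ch] @ odor_courses[ch]  # (V, T)
        for g in coupling:
            if g.channel != ch:
                continue
            latent = g.strength * _smooth_noise(rng, n_frames, sigma_frames=2.0)
            signal[np.asarray(g.voxels, dtype=int)] += latent
        g_motion = gains.get(ch, 0.0)
        if g_motion:
            signal = signal + g_motion * motion
        noise = (
            rng.standard_normal((n_vox, n_frames)) * config.noise_sd
            if config.noise_sd > 0
            else 0.0
        )
        f = config.baseline_F * (1.0 + signal + noise)
        fluorescence[ch] = np.clip(f, 0.0, None).astype(np.float32)

    # --- behavior video: frame-difference energy == motion by construction
    h, w = config.video_shape
    levels = np.zeros(n_frames)
    cap = max(float(np.abs(motion).max()) * 4.0, 1.0)
    for i in range(1, n_frames):
        step = motion[i]
        if levels[i - 1] + step <= cap:
            levels[i] = levels[i - 1] + step
        else:
            levels[i] = levels[i - 1] - step
    video = np.repeat(levels, h * w).reshape(n_frames, h, w).astype(np.float32)

    gt = GroundTruth(
        ensemble_membership=membership,
        kernel_params=dict(config.channel_params),
        drift_schedule=drift,
        motion_trace=motion,
        trial_order=list(table["odor"]),
        coupling_groups=list(coupling),
    )
    return Experiment(
        fluorescence=fluorescence,
        trial_table=table,
        atlas=atlas,
        voxel_coords=coords,
        ground_truth=gt,
        video=video,
        config=config,
    )


def write_experiment(exp: Experiment, outdir: str | Path, *, video: bool = True) -> dict[str, Path]:
    """Write an experiment to disk in the pipeline's interchange formats.

    Volumes and the atlas go to HDF5 (datasets dims x, y, z, t), the trial
    table to TSV, the ground truth to JSON, and the behavior video to a
    multi-page TIFF.
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    vol_path = outdir / "volumes.h5"
    with h5py.File(vol_path, "w", track_order=True) as f:
        for ch, data in exp.fluorescence.items():
            dset = f.create_dataset(
                ch, data=data.reshape(*exp.config.grid_shape, -1), track_times=False
            )
            dset.attrs["dims"] = "x,y,z,t"
            dset.attrs["frame_rate"] = exp.config.frame_rate
    paths["volumes"] = vol_path

    atlas_path = outdir / "atlas.h5"
    with h5py.File(atlas_path, "w") as f:
        f.create_dataset("labels", data=exp.atlas, track_times=False)
    paths["atlas"] = atlas_path

    trials_path = outdir / "trials.tsv"
    exp.trial_table.to_csv(trials_path, sep="\t", index=False)
    paths["trials"] = trials_path

    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(exp.ground_truth.to_json())
    paths["ground_truth"] = gt_path

    if video:
        video_path = outdir / "behavior.tiff"
        tifffile.imwrite(video_path, exp.video)
        paths["video"] = video_path
    return paths
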