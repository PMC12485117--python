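"""Staged pipeline tying the analysis modules into end-to-end workflows.

Each stage reads its upstream artifacts from a run directory, verifies
their recorded hashes, writes its outputs, and appends a manifest entry
(config hash, input hashes, output hashes).  Identical inputs and seed
give identical manifests, so reruns are idempotent and corruption is
detected before a stage runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior as beh
from . import connectivity as con
from . import decoding as dec
from . import manifold as man
from . import preprocess as pre
from . import respmetrics as rm
from . import synthgen as sg

__all__ = ["PipelineConfig", "run_stage", "STAGES"]

log = logging.getLogger("odoresp")

STAGES = (
    "simulate",
    "preprocess",
    "metrics",
    "connectivity",
    "decode",
    "manifold",
    "behavior",
    "report",
)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    synth: sg.SynthConfig = field(default_factory=sg.SynthConfig)
    decoder: dec.DecoderSpec = field(default_factory=dec.DecoderSpec)
    dff_window: int = 200
    dff_fraction: float = 0.3
    response_frames: int = 20  # response window per channel, frames at frame_rate
    manifold_pre_s: float = 2.0
    manifold_post_s: float = 33.0
    fc_top_fraction: float = 0.30
    behavior_n_pcs: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_raw = raw.pop("synth", {})
        if "channel_params" in synth_raw:
            synth_raw["channel_params"] = {
                k: sg.ChannelParams(**v) for k, v in synth_raw["channel_params"].items()
            }
        for key in ("grid_shape", "olfactory_regions", "odors"):
            if key in synth_raw and isinstance(synth_raw[key], list):
                synth_raw[key] = tuple(synth_raw[key])
        decoder_raw = raw.pop("decoder", {})
        for key in ("feature_frames", "block_shape", "multiregion_block"):
            if key in decoder_raw and isinstance(decoder_raw[key], list):
                decoder_raw[key] = tuple(decoder_raw[key])
        return cls(
            synth=sg.SynthConfig(**synth_raw),
            decoder=dec.DecoderSpec(**decoder_raw),
            **raw,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["channel_params"] = {
            k: vars(v) for k, v in self.synth.channel_params.items()
        }
        return _jsonable(d)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()


def _load_manifest(run_dir: Path) -> dict:
    path = run_dir / "manifest.json"
    return json.loads(path.read_text()) if path.exists() else {}


def _save_manifest(run_dir: Path, manifest: dict) -> None:
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(run_dir: Path, manifest: dict, stage: str, names: list[str]) -> dict[str, Path]:
    """Check upstream artifacts exist and match their recorded hashes."""
    if stage not in manifest:
        raise RuntimeError(
            f"missing upstream artifacts: run the '{stage}' stage first"
        )
    out = {}
    for name in names:
        rec = manifest[stage]["outputs"].get(name)
        if rec is None:
            raise RuntimeError(f"stage '{stage}' did not record output '{name}'")
        path = run_dir / rec["path"]
        if not path.exists():
            raise RuntimeError(f"artifact {path} missing: rerun stage '{stage}'")
        digest = _sha256(path)
        if digest != rec["sha256"]:
            raise RuntimeError(
                f"artifact {path} hash mismatch (expected {rec['sha256'][:12]}…, "
                f"got {digest[:12]}…): rerun stage '{stage}'"
            )
        out[name] = path
    return out


def _record(
    run_dir: Path, manifest: dict, stage: str, config: PipelineConfig,
    outputs: dict[str, Path], inputs: dict[str, Path] | None = None,
) -> None:
    manifest[stage] = {
        "config_hash": _config_hash(config),
        "inputs": {k: {"path": str(p.relative_to(run_dir)), "sha256": _sha256(p)}
                   for k, p in (inputs or {}).items()},
        "outputs": {k: {"path": str(p.relative_to(run_dir)), "sha256": _sha256(p)}
                    for k, p in outputs.items()},
    }
    _save_manifest(run_dir, manifest)


def _write_json(path: Path, payload) -> Path:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
    return path


def _load_experiment(run_dir: Path, config: PipelineConfig) -> sg.Experiment:
    # regenerating from config is cheaper and exact; files on disk are the
    # interchange record, verified by hash in _require
    import dataclasses

    synth = dataclasses.replace(config.synth, seed=config.seed)
    return sg.generate_experiment(synth)


def run_stage(stage: str, config: PipelineConfig, run_dir: str | Path) -> dict:
    """Run one pipeline stage; returns a summary dict of what it produced."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(run_dir)
    t0 = time.time()
    handler = globals()[f"_stage_{stage}"]
    summary = handler(config, run_dir, manifest)
    log.info("stage %s finished in %.1f s", stage, time.time() - t0)
    return summary


def _stage_simulate(config: PipelineConfig, run_dir: Path, manifest: dict) -> dict:
    import dataclasses

    synth = dataclasses.replace(config.synth, seed=config.seed)
    exp = sg.generate_experiment(synth)
    paths = sg.write_experiment(exp, run_dir / "data")
    cfg_path = _write_json(run_dir / "data" / "config.json", config.to_dict())
    paths["config"] = cfg_path
    _record(run_dir, manifest, "simulate", config, paths)
    return {"n_trials": exp.config.n_trials, "channels": list(exp.fluorescence)}


def _stage_preprocess(config: PipelineConfig, run_dir: Path, manifest: dict) -> dict:
    inputs = _require(run_dir, manifest, "simulate", ["volumes", "trials", "atlas"])
    exp = _load_experiment(run_dir, config)
    out_dir = run_dir / "dff"
    out_dir.mkdir(exist_ok=True)
    import h5py

    path = out_dir / "dff.h5"
    with h5py.File(path, "w") as f:
        for ch in exp.fluorescence:
            dff = pre.dff_from_experiment(
                exp, ch, window=config.dff_window, fraction=config.dff_fraction
            )
            d = f.create_dataset(ch, data=dff.values.astype(np.float32), track_times=False)
            d.attrs["frame_rate"] = dff.frame_rate
    sidecar = _write_json(
        out_dir / "provenance.json",
        {"window": config.dff_window, "fraction": config.dff_fraction,
         "frame_rate": exp.config.frame_rate},
    )
    _record(run_dir, manifest, "preprocess", config,
            {"dff": path, "provenance": sidecar}, inputs)
    return {"channels": list(exp.fluorescence)}


def _trial_tensors(exp: sg.Experiment, config: PipelineConfig, post_frames: int,
                   pre_frames: int = 0) -> dict[str, pre.TrialTensor]:
    out = {}
    for ch in exp.fluorescence:
        dff = pre.dff_from_experiment(
            exp, ch, window=config.dff_window, fraction=config.dff_fraction
        )
        out[ch] = pre.extract_trials(dff, exp.trial_table, pre_frames, post_frames)
    return out


def _stage_metrics(config: PipelineConfig, run_dir: Path, manifest: dict) -> dict:
    inputs = _require(run_dir, manifest, "preprocess", ["dff"])
    exp = _load_experiment(run_dir, config)
    tensors = _trial_tensors(exp, config, config.response_frames)
    n_frames = exp.fluorescence[next(iter(exp.fluorescence))].shape[1]
    stim = np.zeros(n_frames)
    stim_frames = int(round(exp.config.stim_duration * exp.config.frame_rate))
    for onset in exp.trial_table["onset_frame"]:
        stim[onset : onset + stim_frames] = 1.0
    summary: dict = {}
    out_dir = run_dir / "metrics"
    out_dir.mkdir(exist_ok=True)
    for ch in exp.fluorescence:
        dff = pre.dff_from_experiment(exp, ch, window=config.dff_window,
                                      fraction=config.dff_fraction)
        resp = rm.responsiveness_map(dff.values, stim)
        region_resp = rm.region_responsiveness(resp, exp.atlas)
        intensity = rm.response_intensity(tensors[ch], "sd")
        regions = pre.region_average(dff)
        trial_region = pre.extract_trials(
            pre.DffTensor(regions.values, np.zeros((len(regions.region_ids), 3), int),
                          regions.region_ids, regions.frame_rate),
            exp.trial_table, 0, config.response_frames)
        dynamics = {}
        for i, r in enumerate(regions.region_ids):
            avg = trial_region.values[:, i, :].mean(axis=0)
            delay, width = rm.response_dynamics(avg, regions.frame_rate)
            dynamics[int(r)] = {"phase_delay_s": delay, "pulse_width_s": width}
        tuning_frac = {}
        for odor in exp.config.odors:
            tuned = rm.odor_tuning(tensors[ch], odor)
            tuning_frac[odor] = float(tuned.mask.mean())
        summary[ch] = {
            "n_responsive": int(resp.mask.sum()),
            "region_responsiveness": region_resp,
            "mean_intensity": float(intensity.values.mean()),
            "region_dynamics": dynamics,
            "tuned_fraction": tuning_frac,
        }
    path = _write_json(out_dir / "metrics.json", summary)
    _record(run_dir, manifest, "metrics", config, {"metrics": path}, inputs)
    return summary


def _stage_connectivity(config: PipelineConfig, run_dir: Path, manifest: dict) -> dict:
    inputs = _require(run_dir, manifest, "preprocess", ["dff"])
    exp = _load_experiment(run_dir, config)
    tensors = _trial_tensors(exp, config, config.response_frames)
    out_dir = run_dir / "connectivity"
    out_dir.mkdir(exist_ok=True)
    summary: dict = {}
    olf = set(int(r) for r in exp.config.olfactory_regions)
    for ch, tens in tensors.items():
        reg = pre.region_trial_tensor(tens)
        spliced = reg.values.transpose(1, 0, 2).reshape(reg.values.shape[1], -1)
        fc = con.build_fc(spliced, node_ids=reg.region_id)
        graph = con.fc_graph(fc, "all")
        part = con.detect_communities(graph, "louvain", seed=config.seed)
        greedy = con.detect_communities(graph, "greedy")
        ratio = con.community_ratio(graph, part, olf)
        _, avg_deg, dist = con.node_degrees(graph)
        summary[ch] = {
            "community_ratio": ratio,
            "methods_agreement_ari": con.compare_partitions(part, greedy),
            "average_degree": avg_deg,
            "modularity": part.modularity,
        }
        np.savetxt(out_dir / f"fc_{ch}.tsv", fc.corr, delimiter="\t")
    channels = list(tensors)
    if len(channels) >= 2:
        # voxel-level complementation within the first olfactory region
        region = exp.config.olfactory_regions[0]
        vox = np.flatnonzero(exp.region_id == region)
        mats = {}
        for ch in channels[:2]:
            sub = tensors[ch].select_voxels(vox)
            spliced = sub.values.transpose(1, 0, 2).reshape(vox.size, -1)
            mats[ch] = con.build_fc(spliced, node_ids=vox)
        diff = con.difference_matrix(mats[channels[1]], mats[channels[0]],
                                     seed=config.seed,
                                     edge_rule=config.fc_top_fraction)
        summary["complementation"] = {
            "region": int(region),
            "delta_w_minus_b": con.complementation_metric(diff),
        }
    path = _write_json(out_dir / "connectivity.json", summary)
    _record(run_dir, manifest, "connectivity", config, {"connectivity": path}, inputs)
    return summary


def _decode_frames(config: PipelineConfig) -> int:
    return int(config.decoder.feature_frames[1])


def _stage_decode(config: PipelineConfig, run_dir: Path, manifest: dict) -> dict:
    inputs = _require(run_dir, manifest, "preprocess", ["dff"])
    exp = _load_experiment(run_dir, config)
    tensors = _trial_tensors(exp, config, _decode_frames(config))
    channels = list(tensors)
    out_dir = run_dir / "decode"
    out_dir.mkdir(exist_ok=True)
    spec = dec.DecoderSpec(**{**asdict(config.decoder), "seed": config.seed})
    summary: dict = {}
    for ch in channels:
        res = dec.multiregion_classify(tensors[ch], spec)
        reg = pre.region_trial_tensor(tensors[ch])
        res_region = dec.brainregion_level_classify(reg, spec)
        summary[ch] = {
            "multiregion_accuracy": res.accuracy,
            "multiregion_fold_accuracies": res.fold_accuracies,
            "region_average_accuracy": res_region.accuracy,
        }
    if len(channels) >= 2:
        res_dual = dec.multiregion_classify([tensors[c] for c in channels[:2]], spec)
        summary["dual"] = {
            "multiregion_accuracy": res_dual.accuracy,
            "gain_over_first_channel": res_dual.accuracy
            - summary[channels[0]]["multiregion_accuracy"],
        }
    path = _write_json(out_dir / "decode.json", summary)
    _record(run_dir, manifest, "decode", config, {"decode": path}, inputs)
    return summary


def _stage_manifold(config: PipelineConfig, run_dir: Path, manifest: dict) -> dict:
    inputs = _require(run_dir, manifest, "preprocess", ["dff"])
    exp = _load_experiment(run_dir, config)
    rate = exp.config.frame_rate
    pre_frames = int(round(config.manifold_pre_s * rate))
    post_frames = int(round(config.manifold_post_s * rate))
    tensors = _trial_tensors(exp, config, _decode_frames(config))
    full = _trial_tensors(exp, config, post_frames, pre_frames=pre_frames)
    spec = dec.DecoderSpec(**{**asdict(config.decoder), "seed": config.seed})
    out_dir = run_dir / "manifold"
    out_dir.mkdir(exist_ok=True)
    summary: dict = {}
    for ch in tensors:
        res = dec.multiregion_classify(tensors[ch], spec)
        traces = man.project_manifold(res, full[ch])
        metrics = man.manifold_metrics(traces)
        stages = man.stage_analysis(traces)
        summary[ch] = {
            "max_dist_to_origin": metrics.mean_max_dist_to_origin,
            "max_inter_class": metrics.mean_max_inter_class,
            "mean_intra_class_0_12s": metrics.mean_intra_class_0_12s,
            "stage_max_dist": stages.stage_max_dist,
            "stage_max_inter": stages.stage_max_inter,
            "alignment_residuals": traces.alignment_residuals,
        }
    path = _write_json(out_dir / "manifold.json", summary)
    _record(run_dir, manifest, "manifold", config, {"manifold": path}, inputs)
    return summary


def _stage_behavior(config: PipelineConfig, run_dir: Path, manifest: dict) -> dict:
    inputs = _require(run_dir, manifest, "simulate", ["video"])
    exp = _load_experiment(run_dir, config)
    rate = exp.config.frame_rate
    motion = beh.motion_energy(exp.video, rate)
    win = int(round(12.0 * rate))
    onsets = exp.trial_table["onset_frame"].to_numpy()
    trial_motion = beh.trial_motion_windows(motion, onsets - 1, 0, win)
    feats, evr = beh.behavior_features(trial_motion, config.behavior_n_pcs,
                                       seed=config.seed)
    odor_acc = beh.behavior_decoding(feats, exp.trial_table["odor"].to_numpy(),
                                     seed=config.seed)
    shuffle_acc = beh.behavior_decoding(feats, exp.trial_table["odor"].to_numpy(),
                                        shuffle_control=True, seed=config.seed)
    out_dir = run_dir / "behavior"
    out_dir.mkdir(exist_ok=True)
    summary = {
        "odor_accuracy_from_behavior": odor_acc,
        "odor_accuracy_shuffled": shuffle_acc,
        "variance_explained_first_pc": float(evr[0]) if len(evr) else 0.0,
    }
    path = _write_json(out_dir / "behavior.json", summary)
    _record(run_dir, manifest, "behavior", config, {"behavior": path}, inputs)
    return summary


def _stage_report(config: PipelineConfig, run_dir: Path, manifest: dict) -> dict:
    collected = {}
    for stage, names in [
        ("metrics", ["metrics"]), ("connectivity", ["connectivity"]),
        ("decode", ["decode"]), ("manifold", ["manifold"]),
        ("behavior", ["behavior"]),
    ]:
        if stage in manifest:
            paths = _require(run_dir, manifest, stage, names)
            collected[stage] = json.loads(paths[names[0]].read_text())
    path = _write_json(run_dir / "report.json", collected)
    _record(run_dir, manifest, "report", config, {"report": path})
    return collected
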