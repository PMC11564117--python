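"""End-to-end pipeline: images -> per-bead measurements -> QC ->
control normalization -> group statistics, with reproducible outputs.

A run is described by a :class:`RunConfig` plus a condition manifest
mapping condition names to image files and naming the control condition.
All stages are deterministic, so identical config and seed reproduce
byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (ConditionResult, NormalizationError, StatsReport,
                       anova_dunnett, normalize_to_control, qc_filter,
                       summarize_condition)
from .io import (dump_yaml, load_yaml, read_multichannel_image, to_uint16,
                 write_labels_tiff, write_scene)
from .profiling import (DegenerateROIError, ProfileConfig,
                        sample_radial_profiles, summarize_bead)
from .segmentation import (SegmentationParams, build_exclusion_mask,
                           fit_circular_rois, segment_beads)
from .synthetic import (SceneConfig, SyntheticScene, generate_multichannel_scene,
                        scene_config_from_dict)

__all__ = [
    "ImageEntry",
    "ConditionSpec",
    "Manifest",
    "RunConfig",
    "RunRecord",
    "PipelineResult",
    "PipelineStageError",
    "load_manifest",
    "load_run_config",
    "run_pipeline",
    "simulate_experiment",
    "default_simulation_config",
]

logger = logging.getLogger("beadrim")

BEADS_COLUMNS = [
    "condition", "replicate", "image", "bead_label", "center_row",
    "center_col", "radius", "area_px", "n_valid_lines", "mean_amplitude",
    "sd_amplitude", "normalized", "qc_pass", "qc_reason",
]


class PipelineStageError(RuntimeError):
    """Stage failure carrying the stage name and offending file."""

    def __init__(self, stage: str, file: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {file!r}: {cause}")
        self.stage = stage
        self.file = file
        self.cause = cause


@dataclass(frozen=True)
class ImageEntry:
    path: Path
    replicate: str


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    images: tuple[ImageEntry, ...]
    channel: str                     # measurement channel
    channels: tuple[str, ...]        # channel names present in each TIFF


@dataclass(frozen=True)
class Manifest:
    conditions: tuple[ConditionSpec, ...]
    control: str


@dataclass
class RunConfig:
    """Full description of a quantification run."""

    manifest: Manifest
    output_dir: Path | None = None
    qc_ratio: float = 0.5
    seed: int = 0
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    segmentation_channel: str = "max"   # "max" = per-pixel max over channels
    exclude_edge_beads: bool = True
    normalize_per_replicate: bool = False
    write_profiles: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.qc_ratio <= 1:
            raise ValueError("qc_ratio must be in (0, 1]")


@dataclass
class RunRecord:
    """Provenance of one run: config snapshot, software version, and the
    per-condition count ledger (found = passed + qc_excluded +
    edge_excluded + unmeasurable)."""

    config: dict
    version: str
    started: str
    finished: str = ""
    images_read: int = 0
    counts: dict = field(default_factory=dict)

    def add_condition(self, name: str) -> None:
        self.counts.setdefault(name, {
            "beads_found": 0, "passed": 0, "qc_excluded": 0,
            "edge_excluded": 0, "unmeasurable": 0,
        })

    def balanced(self) -> bool:
        return all(
            c["beads_found"] == c["passed"] + c["qc_excluded"]
            + c["edge_excluded"] + c["unmeasurable"]
            for c in self.counts.values()
        )


@dataclass
class PipelineResult:
    beads: pd.DataFrame
    conditions: pd.DataFrame
    condition_results: list[ConditionResult]
    stats: StatsReport | None
    record: RunRecord
    profiles: pd.DataFrame | None = None


def _parse_images(raw: Sequence) -> tuple[ImageEntry, ...]:
    entries = []
    for i, item in enumerate(raw):
        if isinstance(item, Mapping):
            entries.append(ImageEntry(Path(item["path"]),
                                      str(item.get("replicate", i + 1))))
        else:
            entries.append(ImageEntry(Path(item), str(i + 1)))
    return tuple(entries)


def load_manifest(data: Mapping | str | Path,
                  base_dir: Path | None = None) -> Manifest:
    """Load a condition manifest from YAML (path) or an equivalent dict.

    Relative image paths are resolved against ``base_dir`` (defaults to
    the manifest's own directory)."""
    if isinstance(data, (str, Path)):
        path = Path(data)
        base_dir = base_dir or path.parent
        data = load_yaml(path)
    base_dir = base_dir or Path(".")
    conditions = []
    for name, spec in data["conditions"].items():
        images = _parse_images(spec["images"])
        images = tuple(
            ImageEntry(base_dir / e.path if not e.path.is_absolute() else e.path,
                       e.replicate)
            for e in images
        )
        channel = spec["channel"]
        channels = tuple(spec.get("channels", [channel]))
        if channel not in channels:
            raise ValueError(f"condition {name!r}: measurement channel "
                             f"{channel!r} not in channels {channels}")
        conditions.append(ConditionSpec(name=str(name), images=images,
                                        channel=channel, channels=channels))
    control = data["control"]
    if control not in {c.name for c in conditions}:
        raise ValueError(f"control {control!r} not among manifest conditions")
    return Manifest(conditions=tuple(conditions), control=control)


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Load a run configuration YAML; the manifest may be inline (under
    ``manifest:``) or referenced by path (``manifest: runs/manifest.yaml``).
    Keyword overrides (e.g. from CLI flags) replace file values."""
    path = Path(path)
    data = load_yaml(path)
    mdata = data["manifest"]
    if isinstance(mdata, str):
        mpath = Path(mdata)
        if not mpath.is_absolute():
            mpath = path.parent / mpath
        manifest = load_manifest(mpath)
    else:
        manifest = load_manifest(mdata, base_dir=path.parent)
    if overrides.get("control"):
        manifest = replace(manifest, control=overrides.pop("control"))
    else:
        overrides.pop("control", None)
    kwargs: dict = {"manifest": manifest}
    if "output_dir" in data:
        kwargs["output_dir"] = path.parent / data["output_dir"]
    for key in ("qc_ratio", "seed", "segmentation_channel",
                "exclude_edge_beads", "normalize_per_replicate",
                "write_profiles", "log_level"):
        if key in data:
            kwargs[key] = data[key]
    if "profile" in data:
        kwargs["profile"] = ProfileConfig(**data["profile"])
    if "segmentation" in data:
        kwargs["segmentation"] = SegmentationParams(**data["segmentation"])
    for key, val in overrides.items():
        if val is not None:
            kwargs[key] = val
    return RunConfig(**kwargs)


def _config_snapshot(config: RunConfig) -> dict:
    snap = {
        "qc_ratio": config.qc_ratio,
        "seed": config.seed,
        "segmentation_channel": config.segmentation_channel,
        "exclude_edge_beads": config.exclude_edge_beads,
        "normalize_per_replicate": config.normalize_per_replicate,
        "profile": dataclasses.asdict(config.profile),
        "segmentation": dataclasses.asdict(config.segmentation),
        "control": config.manifest.control,
        "conditions": {
            c.name: {"channel": c.channel,
                     "channels": list(c.channels),
                     "images": [str(e.path) for e in c.images]}
            for c in config.manifest.conditions
        },
    }
    if config.output_dir is not None:
        snap["output_dir"] = str(config.output_dir)
    return snap


def _measure_image(image_path: Path, cond: ConditionSpec, config: RunConfig,
                   record: RunRecord):
    """Segment one image and measure every bead; returns per-bead rows."""
    try:
        channels = read_multichannel_image(image_path, cond.channels)
    except Exception as exc:
        raise PipelineStageError("read", str(image_path), exc) from exc
    record.images_read += 1
    meas = np.asarray(channels[cond.channel], dtype=float)
    if config.segmentation_channel == "max":
        seg_img = np.max(np.stack([np.asarray(c, float)
                                   for c in channels.values()]), axis=0)
    else:
        if config.segmentation_channel not in channels:
            raise PipelineStageError(
                "segment", str(image_path),
                KeyError(f"segmentation channel "
                         f"{config.segmentation_channel!r} not in file"))
        seg_img = np.asarray(channels[config.segmentation_channel], float)
    try:
        labelmap = segment_beads(seg_img, config.segmentation,
                                 source_channel=cond.channel)
        rois = fit_circular_rois(labelmap, config.segmentation.min_area_px)
        mask = build_exclusion_mask(rois, meas.shape,
                                    config.segmentation.mask_margin_px)
    except Exception as exc:
        raise PipelineStageError("segment", str(image_path), exc) from exc
    counts = record.counts[cond.name]
    counts["beads_found"] += len(rois)
    roi_table = pd.DataFrame(
        [{"label": r.label, "center_row": round(r.center_rc[0], 3),
          "center_col": round(r.center_rc[1], 3),
          "radius": round(r.radius, 3), "area_px": r.area_px,
          "touches_edge": r.touches_edge} for r in rois],
        columns=["label", "center_row", "center_col", "radius", "area_px",
                 "touches_edge"])
    rows = []
    profile_rows = []
    for roi in rois:
        if config.exclude_edge_beads and roi.touches_edge:
            counts["edge_excluded"] += 1
            continue
        try:
            profiles = sample_radial_profiles(meas, roi, mask, config.profile)
            m = summarize_bead(profiles)
        except DegenerateROIError:
            counts["unmeasurable"] += 1
            continue
        except Exception as exc:
            raise PipelineStageError("profile", str(image_path), exc) from exc
        rows.append((roi, m))
        if config.write_profiles:
            for p in profiles:
                for d, v in zip(p.distances, p.intensities):
                    profile_rows.append({
                        "condition": cond.name, "image": image_path.name,
                        "bead_label": p.bead_label,
                        "angle_rad": p.angle_rad, "distance": d,
                        "intensity": v,
                    })
    return labelmap, roi_table, rows, profile_rows


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute segment -> ROI fit -> exclusion mask -> profiles ->
    per-bead summary on every image, then QC -> control normalization ->
    one-way ANOVA with Dunnett comparisons; write result tables if
    ``config.output_dir`` is set."""
    started = datetime.datetime.now().isoformat(timespec="seconds")
    record = RunRecord(config=_config_snapshot(config), version=__version__,
                       started=started)
    out_dir = config.output_dir
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    try:
        result = _run(config, record, out_dir)
    except Exception:
        if out_dir is not None:
            (out_dir / "FAILED").write_text(
                "pipeline aborted; partial outputs may be present\n")
        raise
    return result


def _run(config: RunConfig, record: RunRecord,
         out_dir: Path | None) -> PipelineResult:
    manifest = config.manifest
    per_bead: list[dict] = []
    measurements_by_cond: dict[str, list] = {}
    all_profiles: list[dict] = []
    for cond in manifest.conditions:
        record.add_condition(cond.name)
        measurements_by_cond[cond.name] = []
        for entry in cond.images:
            labelmap, roi_table, rows, profile_rows = _measure_image(
                entry.path, cond, config, record)
            all_profiles.extend(profile_rows)
            if out_dir is not None:
                write_labels_tiff(
                    out_dir / f"labels_{entry.path.stem}.tif",
                    labelmap.labels)
                roi_table.to_csv(
                    out_dir / f"rois_{entry.path.stem}.csv", index=False)
            for roi, m in rows:
                measurements_by_cond[cond.name].append(
                    (cond.name, entry.replicate, entry.path.name, roi, m))

    # QC (pooled per condition; verdict depends only on each bead)
    bead_means: dict[str, list[float]] = {}
    for cond in manifest.conditions:
        items = measurements_by_cond[cond.name]
        passed, excluded = qc_filter([m for *_, m in items],
                                     ratio=config.qc_ratio)
        counts = record.counts[cond.name]
        for *_, m in items:
            if m.qc_reason == "no_valid_lines":
                counts["unmeasurable"] += 1
            elif m.qc_pass:
                counts["passed"] += 1
            else:
                counts["qc_excluded"] += 1
        bead_means[cond.name] = [m.mean_amplitude for m in passed]

    # control normalization (pooled across replicates by default)
    if config.normalize_per_replicate:
        normalized_lookup = _per_replicate_normalization(
            measurements_by_cond, manifest.control)
    else:
        normalize_to_control(bead_means, manifest.control)  # validates control
        denom = float(np.mean(bead_means[manifest.control]))
        normalized_lookup = {name: denom for name in bead_means}

    # assemble tidy per-bead table
    norm_values: dict[str, list[float]] = {c.name: [] for c in manifest.conditions}
    for cond in manifest.conditions:
        for cname, rep, img, roi, m in measurements_by_cond[cond.name]:
            if m.qc_pass:
                if config.normalize_per_replicate:
                    denom = normalized_lookup[(cname, rep)]
                else:
                    denom = normalized_lookup[cname]
                norm = m.mean_amplitude / denom
                norm_values[cname].append(norm)
            else:
                norm = float("nan")
            per_bead.append({
                "condition": cname, "replicate": rep, "image": img,
                "bead_label": roi.label,
                "center_row": round(roi.center_rc[0], 3),
                "center_col": round(roi.center_rc[1], 3),
                "radius": round(roi.radius, 3), "area_px": roi.area_px,
                "n_valid_lines": m.n_valid_lines,
                "mean_amplitude": m.mean_amplitude,
                "sd_amplitude": m.sd_amplitude,
                "normalized": norm,
                "qc_pass": bool(m.qc_pass), "qc_reason": m.qc_reason,
            })

    condition_results = []
    for cond in manifest.conditions:
        counts = record.counts[cond.name]
        n_excl = (counts["qc_excluded"] + counts["edge_excluded"]
                  + counts["unmeasurable"])
        condition_results.append(summarize_condition(
            cond.name, bead_means[cond.name], norm_values[cond.name], n_excl))

    # statistics vs control over conditions with enough passing beads
    stats_groups = {name: vals for name, vals in norm_values.items()
                    if len(vals) >= 2}
    for name, vals in norm_values.items():
        if len(vals) < 2:
            logger.warning("condition %r has %d QC-passing bead(s); "
                           "excluded from statistics", name, len(vals))
    stats = None
    if manifest.control in stats_groups and len(stats_groups) >= 2:
        stats = anova_dunnett(stats_groups, control=manifest.control)

    beads_df = pd.DataFrame(per_bead, columns=BEADS_COLUMNS)
    conditions_df = pd.DataFrame([
        {"condition": r.condition, "n_beads_pass": r.n_beads_pass,
         "n_beads_excluded": r.n_beads_excluded,
         "mean_normalized": r.mean_normalized,
         "sd_normalized": r.sd_normalized}
        for r in condition_results
    ])
    profiles_df = (pd.DataFrame(all_profiles) if config.write_profiles
                   else None)
    record.finished = datetime.datetime.now().isoformat(timespec="seconds")
    if not record.balanced():
        raise RuntimeError("internal error: bead count ledger does not "
                           f"balance: {record.counts}")
    if out_dir is not None:
        _write_outputs(out_dir, beads_df, conditions_df, stats, record,
                       profiles_df)
    return PipelineResult(beads=beads_df, conditions=conditions_df,
                          condition_results=condition_results, stats=stats,
                          record=record, profiles=profiles_df)


def _per_replicate_normalization(measurements_by_cond, control):
    """Control mean per replicate; replicates missing a control fall back
    to the pooled control mean."""
    ctrl_by_rep: dict[str, list[float]] = {}
    pooled: list[float] = []
    for cname, rep, img, roi, m in measurements_by_cond[control]:
        if m.qc_pass:
            ctrl_by_rep.setdefault(rep, []).append(m.mean_amplitude)
            pooled.append(m.mean_amplitude)
    if not pooled:
        raise NormalizationError(
            f"control condition {control!r} has no QC-passing beads")
    pooled_mean = float(np.mean(pooled))
    lookup: dict[tuple[str, str], float] = {}
    for cname, items in measurements_by_cond.items():
        for _, rep, *_ in items:
            reps = ctrl_by_rep.get(rep)
            lookup[(cname, rep)] = (float(np.mean(reps)) if reps
                                    else pooled_mean)
    return lookup


def stats_table(stats: StatsReport | None) -> pd.DataFrame:
    cols = ["test", "control", "group", "n_group", "n_control", "estimate",
            "statistic", "p_adjusted", "stars"]
    if stats is None:
        return pd.DataFrame(columns=cols)
    rows = [{
        "test": stats.test_name, "control": stats.control, "group": c.group,
        "n_group": stats.group_sizes[c.group],
        "n_control": stats.group_sizes.get(stats.control, ""),
        "estimate": c.estimate, "statistic": c.statistic,
        "p_adjusted": c.p_adjusted, "stars": c.stars,
    } for c in stats.comparisons]
    return pd.DataFrame(rows, columns=cols)


def _write_outputs(out_dir: Path, beads_df, conditions_df, stats, record,
                   profiles_df) -> None:
    beads_df.to_csv(out_dir / "beads.csv", index=False)
    conditions_df.to_csv(out_dir / "conditions.csv", index=False)
    stats_table(stats).to_csv(out_dir / "stats.csv", index=False)
    if profiles_df is not None:
        profiles_df.to_csv(out_dir / "profiles.csv", index=False)
    dump_yaml(out_dir / "run_record.yaml", {
        "version": record.version, "started": record.started,
        "finished": record.finished, "images_read": record.images_read,
        "counts": record.counts, "config": record.config,
    })


# ---------------------------------------------------------------------------
# simulation front-end

def default_simulation_config() -> dict:
    """A four-condition demo: a control plus a three-point competitor
    titration whose rim amplitude follows the hyperbolic surrogate
    (max 100 gray values, IC50 1 uM, doses 0.1-10 uM)."""
    return {
        "seed": 0,
        "scene": {"image_shape": [512, 512], "n_beads": 12,
                  "background_level": 100.0, "gaussian_noise_sd": 5.0,
                  "poisson_scale": 0.5, "min_separation": 70.0,
                  "radius_distribution": [20.0, 3.0], "rim_sigma": 2.0,
                  "interior_level": 10.0},
        "channels": {"measurement": "GFP", "bait": "mCherry"},
        "bait_amplitude": 80.0,
        "n_images_per_condition": 3,
        "control": "dose_0.1uM",
        "conditions": [
            {"name": "dose_0.1uM", "dose": 0.1},
            {"name": "dose_1uM", "dose": 1.0},
            {"name": "dose_3.2uM", "dose": 3.2},
            {"name": "dose_10uM", "dose": 10.0},
        ],
        "amplitude_model": {"max_amplitude": 100.0, "ic50": 1.0},
    }


def simulate_experiment(sim_config: Mapping, out_dir: str | Path,
                        seed: int | None = None) -> Path:
    """Render a multi-condition synthetic experiment to disk.

    Writes, per condition, multichannel TIFFs with ground-truth sidecars,
    plus a ``manifest.yaml`` and ``run.yaml`` ready for quantification.
    Returns the path of the run configuration file.  Conditions carry
    either an explicit ``rim_amplitude`` or a ``dose`` evaluated through
    the hyperbolic ``amplitude_model``.
    """
    from .synthetic import dose_response_amplitude  # local to avoid cycle

    sim = dict(sim_config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_seed = int(sim.get("seed", 0) if seed is None else seed)
    scene_cfg = scene_config_from_dict(sim.get("scene", {}))
    chan = sim.get("channels", {"measurement": "GFP", "bait": "mCherry"})
    meas_name = chan["measurement"]
    bait_name = chan.get("bait")
    bait_amp = float(sim.get("bait_amplitude", 80.0))
    n_images = int(sim.get("n_images_per_condition", 3))
    model = sim.get("amplitude_model", {})
    manifest_conditions: dict = {}
    for i, cond in enumerate(sim["conditions"]):
        name = cond["name"]
        if "rim_amplitude" in cond:
            amp = float(cond["rim_amplitude"])
        else:
            amp = dose_response_amplitude(float(cond["dose"]),
                                          float(model["max_amplitude"]),
                                          float(model["ic50"]))
        cond_dir = out_dir / name
        images = []
        for j in range(n_images):
            cfg = replace(scene_cfg, rim_amplitude=amp,
                          seed=base_seed + 1009 * i + j)
            amplitudes = {meas_name: amp}
            if bait_name:
                amplitudes[bait_name] = bait_amp
            channels, beads, labels = generate_multichannel_scene(
                cfg, amplitudes)
            scene = SyntheticScene(config=cfg, beads=beads,
                                   image=channels[meas_name],
                                   truth_labels=labels)
            paths = write_scene(
                scene, cond_dir, f"{name}_rep{j + 1}",
                extra_channels={k: to_uint16(v)
                                for k, v in channels.items()})
            images.append({"path": str(paths["image"].relative_to(out_dir)),
                           "replicate": str(j + 1)})
        manifest_conditions[name] = {
            "channel": meas_name,
            "channels": ([meas_name, bait_name] if bait_name
                         else [meas_name]),
            "images": images,
        }
    control = sim.get("control", sim["conditions"][0]["name"])
    manifest = {"control": control, "conditions": manifest_conditions}
    dump_yaml(out_dir / "manifest.yaml", manifest)
    run_cfg = {"manifest": "manifest.yaml", "output_dir": "results",
               "seed": base_seed}
    dump_yaml(out_dir / "run.yaml", run_cfg)
    return out_dir / "run.yaml"
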