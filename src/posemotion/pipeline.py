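"""End-to-end workflow: convert → clean → velocity → acceleration → norms → plots.

The pipeline mirrors the intended analysis of a stimulus clip: aggregate
the pose-estimator's per-frame JSON into one table, impute tracking
dropouts, differentiate, reduce to the MF1 motion series, and render the
diagnostic plots. Each stage writes files with the conventional suffix
(``_body25``, ``_cleaned``, ``_velocity_x``/``_y``, ``_en_velocity``, ...)
and every artifact is recorded in a JSON manifest with its stage,
parameters, and an input content hash, so a run is auditable and re-runs
are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import cleaning, io, kinematics, viz
from .laterality import det_hand
from .models import get_model

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("posemotion")

STAGES = ("convert", "clean", "velocity", "acceleration", "en", "plot")


class PipelineError(RuntimeError):
    """A stage failed; the manifest records what completed before it."""


@dataclass
class RunConfig:
    """Validated parameters of a pipeline run.

    ``input_dir`` holds one clip's frame JSON files, or — with
    ``batch=True`` — one subdirectory per clip. ``stages`` must be a
    prefix of the chain ``convert → clean → velocity → acceleration →
    en → plot``; ``last_stage`` is a convenience for choosing that prefix.
    """

    input_dir: Path
    output_dir: Path | None = None
    model: str = "body25"
    fps: float = 25.0
    cutoff: float = cleaning.DEFAULT_CUTOFF
    overwrite: bool = False
    pattern: str = "*.json"
    person_policy: str = "first"
    last_stage: str = "plot"
    batch: bool = False
    continue_on_error: bool = False
    laterality: bool = False
    log_level: str = "INFO"
    seed: int = 0

    stages: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)
        get_model(self.model)  # raises on unknown model
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError(f"cutoff must be in [0, 1], got {self.cutoff}")
        if self.person_policy not in io.PERSON_POLICIES:
            raise ValueError(f"unknown person_policy {self.person_policy!r}")
        if self.last_stage not in STAGES:
            raise ValueError(
                f"last_stage must be one of {STAGES}, got {self.last_stage!r}"
            )
        self.stages = STAGES[: STAGES.index(self.last_stage) + 1]
        if not self.input_dir.is_dir():
            raise NotADirectoryError(self.input_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _run_clip(config: RunConfig, clip_dir: Path, out_dir: Path) -> dict:
    """Run the stage chain for one clip directory; returns its manifest entry."""
    model = get_model(config.model)
    entry: dict = {"clip": clip_dir.name, "stages": [], "artifacts": []}

    def record(stage: str, paths: list[Path], source: Path, **params) -> None:
        entry["stages"].append(stage)
        for p in paths:
            entry["artifacts"].append(
                {
                    "stage": stage,
                    "path": str(p),
                    "input": str(source),
                    "input_sha256": _sha256(source) if source.is_file() else None,
                    "params": params,
                }
            )
        log.info("%s: %s -> %s", stage, clip_dir.name,
                 ", ".join(p.name for p in paths))

    table = io.convert_clip(
        clip_dir, model, output_dir=out_dir, fps=config.fps,
        pattern=config.pattern, person_policy=config.person_policy,
    )
    record("convert", [table], clip_dir, model=model.name, fps=config.fps)
    if "clean" not in config.stages:
        return entry

    cleaned_path = cleaning.clean_file(
        table, cutoff=config.cutoff, overwrite=config.overwrite
    )
    record("clean", [cleaned_path], table, cutoff=config.cutoff,
           overwrite=config.overwrite)
    seq = io.read_table(cleaned_path)
    stem = cleaned_path.parent / cleaned_path.stem
    if "velocity" not in config.stages:
        return entry

    vel = kinematics.velocity(seq)
    vel_paths = io.write_field(vel, stem)
    record("velocity", list(vel_paths), cleaned_path, fps=config.fps)
    if "acceleration" in config.stages:
        acc = kinematics.acceleration(seq)
        acc_paths = io.write_field(acc, stem)
        record("acceleration", list(acc_paths), cleaned_path, fps=config.fps)
    if "en" not in config.stages:
        return entry

    en_vel = kinematics.euclidean_norm_of_sums(vel)
    en_vel_path = io.write_series(en_vel, Path(f"{stem}_en_velocity.csv"))
    paths = [en_vel_path]
    if "acceleration" in config.stages:
        en_acc = kinematics.euclidean_norm_of_sums(acc)
        paths.append(
            io.write_series(en_acc, Path(f"{stem}_en_acceleration.csv"))
        )
    record("en", paths, cleaned_path)

    if config.laterality and model.name == "body25":
        side = det_hand(seq)
        entry["laterality"] = {
            "label": side.label,
            "left_motion": side.left_motion,
            "right_motion": side.right_motion,
            "ratio": side.ratio,
        }
    if "plot" not in config.stages:
        return entry

    frontal_path = Path(f"{stem}_frontal.png")
    viz.plot_frontal(seq, cutoff=config.cutoff, out=frontal_path)
    ts_path = Path(f"{stem}_en_velocity.png")
    segments = kinematics.detect_motion_segments(en_vel) if en_vel.values.max() > 0 else []
    viz.plot_timeseries(en_vel, segments=segments, out=ts_path)
    record("plot", [frontal_path, ts_path], cleaned_path)
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage chain and write ``manifest.json``.

    Returns the manifest. In batch mode each clip subdirectory is
    processed independently; a failure stops the run unless
    ``continue_on_error`` is set, in which case it is recorded and the
    remaining clips still run.
    """
    logging.basicConfig(level=config.log_level)
    out_root = config.output_dir or config.input_dir
    out_root.mkdir(parents=True, exist_ok=True)

    if config.batch:
        clip_dirs = sorted(d for d in config.input_dir.iterdir() if d.is_dir())
    else:
        clip_dirs = [config.input_dir]

    manifest: dict = {
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in vars(config).items()
        },
        "clips": [],
        "failures": [],
    }
    for clip_dir in clip_dirs:
        has_frames = any(clip_dir.glob(config.pattern))
        if not has_frames:
            log.warning("no frame files matching %r in %s; skipping",
                        config.pattern, clip_dir)
            continue
        out_dir = out_root if not config.batch else out_root / clip_dir.name
        try:
            manifest["clips"].append(_run_clip(config, clip_dir, out_dir))
        except Exception as exc:
            failure = {"clip": clip_dir.name, "error": str(exc)}
            manifest["failures"].append(failure)
            log.error("clip %s failed: %s", clip_dir.name, exc)
            if not config.continue_on_error:
                _write_manifest(manifest, out_root)
                raise PipelineError(
                    f"clip {clip_dir.name!r} failed: {exc}"
                ) from exc
    _write_manifest(manifest, out_root)
    return manifest


def _write_manifest(manifest: dict, out_root: Path) -> Path:
    path = out_root / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    manifest["manifest_path"] = str(path)
    return path
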