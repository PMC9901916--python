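"""End-to-end pipeline: simulate -> extract -> calibrate -> encode -> classify.

`PipelineConfig` is the single on-disk configuration object (JSON); it
nests the per-stage configs, rejects unknown keys and round-trips
losslessly.  `run_pipeline` executes the stages in order under one output
directory, logs one structured line per stage, and records a
`RunManifest` (config hash, package version, per-stage artifacts, seeds)
so a rerun with the same config reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import io as bio
from .classify import cross_validate, evaluate_predictions
from .labeler import DEFAULT_TAU_GRID, select_tau, sweep_threshold
from .orb import OrbFeatureExtractor
from .simulator import HIT, MISS, SimConfig, generate_dataset

logger = logging.getLogger("braggveto")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _dataclass_from_dict(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        if f.name == "anomaly_flags":
            v = frozenset(v)
        coerced[f.name] = v
    return cls(**coerced)


@dataclass(frozen=True)
class PipelineConfig:
    """Nested stage configuration with a single global seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    orb: dict = field(default_factory=dict)
    tau: int | None = None
    tau_grid: tuple[int, ...] = DEFAULT_TAU_GRID
    model: str = "mlp"
    k_folds: int = 5
    normalize: bool = True
    seed: int = 0
    out_dir: str = "braggveto_run"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = _dataclass_from_dict(SimConfig, data.pop("sim", {}), "sim")
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown keys in pipeline config: {sorted(unknown)}")
        if "tau_grid" in data:
            data["tau_grid"] = tuple(data["tau_grid"])
        if "orb" in data:
            valid = {
                "fast_threshold", "fast_min_count", "patch_size", "n_bits",
                "smoothing_sigma", "n_pyramid_levels", "pyramid_scale",
                "max_keypoints", "nms_window", "contiguous_arc", "pattern_seed",
            }
            bad = set(data["orb"]) - valid
            if bad:
                raise ValueError(f"unknown keys in orb: {sorted(bad)}")
        return cls(sim=sim, **data)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(json.load(f))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["anomaly_flags"] = sorted(self.sim.anomaly_flags)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: list = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, "time": time.time(), **info})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, default=str)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage on simulator data and write all artifacts.

    Stage order: simulate, extract, calibrate tau (against simulation
    truth), label, cross-validated classification on the auto labels.
    Any failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__, seed=config.seed
    )

    def _stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return result

    # -- simulate ----------------------------------------------------------
    sim = config.sim.with_(seed=config.sim.seed or config.seed)
    frames = _stage("simulate", lambda: generate_dataset(sim))
    frames_path = out / "frames.h5"
    bio.write_frames(frames_path, frames)
    truth = np.array([f.truth_label for f in frames])
    logger.info("simulate: %d frames (%d hits) -> %s",
                len(frames), int((truth == HIT).sum()), frames_path)
    manifest.add("simulate", frames=len(frames), path=str(frames_path))

    # -- extract -----------------------------------------------------------
    extractor = OrbFeatureExtractor(**config.orb).fit()
    def _extract():
        kps, descs = [], []
        for fr in frames:
            k, d = extractor.extract_frame(fr)
            kps.append(k)
            descs.append(d)
        return kps, descs

    keypoints, descriptors = _stage("extract", _extract)
    bio.write_descriptors(out / "descriptors.bvds", descriptors)
    bio.write_keypoints_csv(out / "keypoints.csv", keypoints)
    counts = np.array([len(k) for k in keypoints])
    logger.info("extract: %d keypoints over %d frames", int(counts.sum()), len(frames))
    manifest.add("extract", keypoints=int(counts.sum()))

    # -- calibrate tau -----------------------------------------------------
    if config.tau is None:
        sweep = _stage("calibrate-tau",
                       lambda: sweep_threshold(counts, truth, config.tau_grid))
        sweep.to_csv(out / "tau_sweep.csv", index=False)
        tau = select_tau(sweep)
    else:
        tau = config.tau
    logger.info("calibrate-tau: tau = %d", tau)
    manifest.add("calibrate-tau", tau=int(tau))

    # -- label -------------------------------------------------------------
    auto_labels = np.where(counts >= tau, HIT, MISS)
    bio.write_labels_csv(out / "labels.csv", auto_labels, counts)
    agreement = float((auto_labels == truth).mean())
    logger.info("label: agreement with truth %.4f", agreement)
    manifest.add("label", agreement=agreement)

    # -- classify (cross-validated, codebook refit per fold) ---------------
    cv = _stage(
        "classify",
        lambda: cross_validate(
            descriptors, auto_labels, model=config.model,
            k_folds=config.k_folds, random_state=config.seed,
        ),
    )
    report = {k: v for k, v in cv.items() if k != "reports"}
    report["label_agreement_with_truth"] = agreement
    with open(out / "evaluation.json", "w") as f:
        json.dump(report, f, indent=2)
    logger.info("classify: %s mean accuracy %.2f%%", config.model,
                cv["accuracy_mean"])
    manifest.add("classify", model=config.model,
                 accuracy_mean=cv["accuracy_mean"])

    manifest.write(out / "manifest.json")
    return manifest
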