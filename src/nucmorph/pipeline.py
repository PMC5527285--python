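"""End-to-end orchestration: simulate, analyse, report.

``run_pipeline`` executes the staged workflow described by a
:class:`RunConfig`: generate synthetic assays (``simulate``), analyse
existing inputs (``analyze``), or both in one pass (``full``).  Every stage
writes its tabular output (CSV) and summary (JSON) into the output
directory, and a top-level ``report.json`` collects cohort fractions, the
rupture-event summary, trajectory-variance statistics, damage tables and a
provenance block (seed, config hash, package version).  Outputs are
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from . import rupture, segmentation, shape, stats, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

MODES = ("simulate", "analyze", "full")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Parameter blocks mirror the module surfaces: ``image``/``traces``/
    ``trajectories`` feed the generators, ``segmentation``/``classifier``/
    ``detection``/``damage`` feed the analysis stages.  In ``analyze`` mode
    the input paths must exist.
    """

    mode: str = "full"
    output_dir: str = "nucmorph_out"
    seed: int = 0
    pixel_size: float = 0.25
    image: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)
    trajectories: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    input_image: str | None = None
    input_traces: str | None = None
    input_trajectories: str | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML config file; keyword overrides win over file keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return RunConfig(**data)


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _simulate(cfg: RunConfig, out: Path) -> dict:
    img_kw = dict(cfg.image)
    img_kw.setdefault("seed", cfg.seed)
    img_kw.setdefault("pixel_size", cfg.pixel_size)
    spec = synthetic.ImageSpec(**img_kw)
    sim = synthetic.generate_nucleus_image(spec)
    tifffile.imwrite(out / "image.tif", sim.channels.astype(np.float32))
    tifffile.imwrite(out / "labels.tif", sim.labels.astype(np.int32))
    sim.ground_truth.to_csv(out / "image_ground_truth.csv", index=False)

    tr_kw = dict(cfg.traces)
    tr_kw.setdefault("seed", cfg.seed)
    tspec = synthetic.TraceSpec(**tr_kw)
    traces, trace_gt = synthetic.generate_reporter_traces(tspec)
    pd.concat([t.to_dataframe() for t in traces], ignore_index=True).to_csv(
        out / "traces.csv", index=False
    )
    trace_gt.to_csv(out / "trace_ground_truth.csv", index=False)

    tj_kw = dict(cfg.trajectories)
    tj_kw.setdefault("seed", cfg.seed)
    tj_kw.setdefault("n_cells", 40)
    traj, traj_gt = synthetic.generate_shape_trajectories(**tj_kw)
    traj.to_csv(out / "trajectories.csv", index=False)
    traj_gt.to_csv(out / "trajectory_ground_truth.csv", index=False)

    return {
        "image": sim,
        "traces": traces,
        "trajectories": traj,
        "n_nuclei": int(sim.ground_truth.shape[0]),
        "n_traces": len(traces),
    }


def _analyze(cfg: RunConfig, out: Path, sim: dict | None) -> dict:
    report: dict[str, Any] = {}

    # --- images -> segmentation -> classification -> cohort ---------------
    if sim is not None:
        channels = sim["image"].channels
        pixel_size = sim["image"].pixel_size
    else:
        path = Path(cfg.input_image) if cfg.input_image else None
        if path is None or not path.exists():
            raise FileNotFoundError(f"input image not found: {path}")
        channels = tifffile.imread(path)
        pixel_size = cfg.pixel_size
    seg_params = segmentation.SegmentationParams(**cfg.segmentation)
    labels, records = segmentation.segment_nuclei(channels[0], pixel_size, seg_params)
    logger.info("stage segmentation: %d nuclei", len(records))
    if len(channels) > 1 and records:
        segmentation.assess_envelope_coverage(
            labels, channels[1], pixel_size, records=records
        )
        thresholds = segmentation.ClassifierThresholds(**cfg.classifier)
        segmentation.classify_records(records, thresholds)
        summary = segmentation.score_cohort(records, group_label=cfg.mode)
        report["cohort"] = {
            "n_cells": summary.n_cells,
            "fraction_deformed": summary.fraction_deformed,
            "fraction_ruptured": summary.fraction_ruptured,
            "class_fractions": summary.class_fractions,
        }
        _write_json(out / "cohort_summary.json", report["cohort"])
    tifffile.imwrite(out / "segmentation_labels.tif", labels.astype(np.int32))
    segmentation.records_to_dataframe(records).to_csv(out / "nuclei.csv", index=False)

    # --- traces -> rupture events -----------------------------------------
    if sim is not None:
        traces = sim["traces"]
    else:
        path = Path(cfg.input_traces) if cfg.input_traces else None
        if path is None or not path.exists():
            raise FileNotFoundError(f"input traces not found: {path}")
        traces = rupture.traces_from_dataframe(pd.read_csv(path))
    det = rupture.DetectionParams(**cfg.detection)
    events = [ev for t in traces for ev in rupture.detect_rupture_events(t, det)]
    ev_summary = rupture.cohort_event_summary(traces, events)
    logger.info("stage rupture: %d events in %d traces", len(events), len(traces))
    rupture.events_to_dataframe(events).to_csv(out / "rupture_events.csv", index=False)
    report["events"] = {
        "n_cells": ev_summary.n_cells,
        "observation_time_h": ev_summary.observation_time_h,
        "n_events": ev_summary.n_events,
        "events_per_cell_hour": ev_summary.events_per_cell_hour,
        "mean_duration_min": ev_summary.mean_duration_min,
        "n_truncated": ev_summary.n_truncated,
    }
    _write_json(out / "event_summary.json", report["events"])

    # --- trajectories -> variance statistics -------------------------------
    if sim is not None:
        traj = sim["trajectories"]
    else:
        path = Path(cfg.input_trajectories) if cfg.input_trajectories else None
        if path is None or not path.exists():
            raise FileNotFoundError(f"input trajectories not found: {path}")
        traj = pd.read_csv(path)
    tstats = shape.trajectory_stats_table(traj)
    tstats.to_csv(out / "trajectory_stats.csv", index=False)
    report["trajectories"] = {
        "n_cells": int(tstats.shape[0]),
        "variance_divisor": "k-1 (sample variance)",
        "mean_var_circularity": float(tstats["var_circularity"].mean()),
        "mean_var_perimeter": float(tstats["var_perimeter"].mean()),
        "mean_var_aspect_ratio": float(tstats["var_aspect_ratio"].mean()),
    }
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Raises with the failing stage named; returns the report dict.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {
            "version": __version__,
            "seed": cfg.seed,
            "mode": cfg.mode,
            "config_hash": cfg.config_hash(),
        }
    }
    sim = None
    if cfg.mode in ("simulate", "full"):
        try:
            sim = _simulate(cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
        report["simulate"] = {"n_nuclei": sim["n_nuclei"], "n_traces": sim["n_traces"]}
    if cfg.mode in ("analyze", "full"):
        try:
            report.update(_analyze(cfg, out, sim))
        except Exception as exc:
            raise RuntimeError(f"stage 'analyze' failed: {exc}") from exc
    _write_json(out / "report.json", report)
    return report
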