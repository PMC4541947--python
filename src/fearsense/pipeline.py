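"""End-to-end orchestration of the fear-evaluation protocol.

The measurement protocol runs, per subject: a subjective questionnaire, one
minute of eye video (blink rate), five minutes of eyes-closed facial
temperature and EEG, then the fear stimulus, then the same measurements again
(blink rate from the last minute of the stimulus).  ``run_pipeline`` executes
the computational counterpart on synthetic data: a camera-calibration stage,
a per-subject cohort of the four modality measurements, and the reliability
statistics that rank the modalities.  Every run writes a manifest (config,
seeds, version) so identical configurations reproduce identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import (
    BilinearTransform,
    Point2D,
    calibration_report,
    detect_calibration_blobs,
    fit_bilinear_transform,
)
from .reliability import ReliabilityReport, build_report
from .synthetic import CohortSpec, SceneSpec, gen_calibration_scene, gen_cohort

__all__ = [
    "ProtocolConfig",
    "PipelineStageError",
    "subjective_score",
    "run_pipeline",
    "report_to_dict",
]


class PipelineStageError(RuntimeError):
    """A stage failure carrying the stage name (and subject where relevant)."""

    def __init__(self, stage: str, message: str, subject=None):
        self.stage = stage
        self.subject = subject
        where = f"stage {stage!r}" + (f", subject {subject!r}" if subject is not None else "")
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol timing, cohort size and seeds for a synthetic run.

    Durations mirror the measurement schedule (5 min physiological
    measurement blocks, 1 min blink windows, 23 min stimulus) and are
    recorded in the manifest; the cohort statistics depend only on
    ``n_subjects``, ``condition``, ``compensate`` and ``seed``.
    """

    n_subjects: int = 16
    condition: str = "horror"
    compensate: bool = False
    seed: int = 0
    premeasure_minutes: float = 5.0
    stimulus_minutes: float = 23.0
    blink_window_seconds: float = 60.0
    subjective_aggregate: str = "mean"  # or "sum"


def subjective_score(answers, aggregate: str = "mean") -> float:
    """Collapse the five questionnaire answers (each 1-10) into one score.

    The default subject score is the arithmetic mean of the five answers;
    ``aggregate="sum"`` gives the summed-items alternative.
    """
    arr = np.asarray(answers, dtype=float)
    if arr.shape != (5,):
        raise ValueError(f"exactly 5 answers are required, got shape {arr.shape}")
    if arr.min() < 1 or arr.max() > 10:
        raise ValueError("answers must lie in [1, 10]")
    if aggregate == "mean":
        return float(arr.mean())
    if aggregate == "sum":
        return float(arr.sum())
    raise ValueError(f"unknown aggregate {aggregate!r}")


def _calibration_stage(seed: int) -> dict:
    """Synthetic dual-camera calibration: render, detect blobs, fit, score."""
    spec = SceneSpec(
        transform=BilinearTransform(1.02, 0.015, 1e-5, 4.0, -0.01, 0.98, -8e-6, 2.5),
        blob_centers=(
            Point2D(40.0, 40.0),
            Point2D(270.0, 45.0),
            Point2D(45.0, 195.0),
            Point2D(265.0, 190.0),
        ),
        noise_sd=0.5,
        seed=seed,
    )
    try:
        vis, th, true_pairs = gen_calibration_scene(spec)
        vis_pts = detect_calibration_blobs(vis, 4)
        th_pts = detect_calibration_blobs(th, 4)
        from .geometry import CorrespondencePair

        fitted = fit_bilinear_transform(
            [CorrespondencePair(v, t) for v, t in zip(vis_pts, th_pts)]
        )
        from .geometry import apply_transform

        report = calibration_report(
            [(p.thermal, apply_transform(fitted, p.visible)) for p in true_pairs]
        )
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineStageError("calibration", str(exc)) from exc
    return {
        "transform": dict(zip("abcdefgh", fitted.coefficients())),
        "mean_error_px": report.mean_error,
    }


def run_pipeline(config: ProtocolConfig = ProtocolConfig()):
    """Run calibration plus the cohort-level reliability analysis.

    Returns ``(report, manifest)``: the :class:`ReliabilityReport` of the
    synthetic cohort and a manifest dict (config hash, seeds, version,
    calibration accuracy) that makes runs auditable and reproducible.
    """
    conditions = ("horror", "neutral") if config.compensate else (config.condition,)
    try:
        cohort = gen_cohort(
            CohortSpec(
                n_subjects=config.n_subjects,
                conditions=conditions,
                seed=config.seed,
            )
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("simulate_cohort", str(exc)) from exc
    calibration = _calibration_stage(config.seed)
    try:
        report = build_report(
            cohort,
            condition=conditions[0],
            neutral_condition="neutral" if config.compensate else None,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("reliability_stats", str(exc)) from exc
    cfg = dataclasses.asdict(config)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "calibration": calibration,
        "n_rows": int(len(cohort)),
    }
    return report, manifest


def report_to_dict(report: ReliabilityReport) -> dict:
    """JSON-serializable view of a reliability report."""
    return {
        "welch": {
            m: {"t": r.t, "df": r.df, "p": r.p} for m, r in report.welch.items()
        },
        "effect_sizes": {
            m: {"d": e.d, "label": e.label} for m, e in report.effect_sizes.items()
        },
        "correlation": {
            "modalities": list(report.correlation.index),
            "matrix": report.correlation.to_numpy().tolist(),
        },
        "correlation_sums": dict(report.correlation_sums),
        "ranking": {
            "by_effect_size": list(report.ranking.by_effect_size),
            "by_correlation_sum": list(report.ranking.by_correlation_sum),
            "top2_consensus": list(report.ranking.top2_consensus),
            "tied": report.ranking.tied,
        },
    }


def write_report(report: ReliabilityReport, manifest: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report_to_dict(report), indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    pd.DataFrame(
        [
            {
                "modality": m,
                "d": e.d,
                "label": e.label,
                "p": report.welch[m].p,
                "correlation_sum": report.correlation_sums[m],
            }
            for m, e in report.effect_sizes.items()
        ]
    ).to_csv(out / "summary.csv", index=False)
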