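"""Synthetic inputs with known ground truth for every pipeline stage.

The original study's sensor recordings were never deposited, so each stage is
exercised on generated data carrying the statistical structure the stage
assumes:

* a visible/thermal calibration scene — four Gaussian blobs whose thermal
  positions are the bilinear image of their visible positions,
* a face scene — dark nostril blobs in the visible frame and commanded
  constant thermal levels inside each measurement region,
* an eye-video sequence — dark elliptical pupils with bright corneal glints,
  occluded by a flat eyelid fill during scheduled blinks,
* an EEG recording — sums of in-band sinusoids whose analytic delta/beta
  power ratio (amplitude-squared ratio) is returned alongside the signal,
* a pre/post cohort — independent Gaussian draws per subject, modality,
  phase and condition, defaulting to the published group parameters.

All generators are pure functions of their spec: randomness comes from
numpy's PCG64 generator seeded from the spec, so identical specs produce
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import fixtures
from .eeg_bands import BETA, CHANNEL_NAMES_14, DELTA, EEGRecording
from .eyeblink import CLOSED, OPEN, EyeFrame
from .geometry import BilinearTransform, CorrespondencePair, Point2D, apply_transform
from .thermal_face import (
    ROIConfig,
    FacialFeatureSet,
    Rect,
    ThermalFrame,
    define_rois,
)

__all__ = [
    "SceneSpec",
    "EyeSequenceSpec",
    "EEGSpec",
    "EEGComponent",
    "CohortSpec",
    "gen_calibration_scene",
    "gen_face_scene",
    "gen_eye_sequence",
    "gen_eeg",
    "gen_cohort",
    "default_face_features",
    "eeg_spec_for_ratio",
]


# ---------------------------------------------------------------------------
# Calibration scene

@dataclass(frozen=True)
class SceneSpec:
    """A visible/thermal calibration scene related by a known transform."""

    transform: BilinearTransform
    blob_centers: tuple[Point2D, Point2D, Point2D, Point2D]
    visible_shape: tuple[int, int] = (240, 320)  # (rows, cols)
    thermal_shape: tuple[int, int] = (240, 320)
    blob_sigma: float = 2.5
    blob_amplitude: float = 200.0
    background: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0


def _add_gaussian_blob(
    img: np.ndarray, center: Point2D, sigma: float, amplitude: float
) -> None:
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    img += amplitude * np.exp(
        -((xx - center.x) ** 2 + (yy - center.y) ** 2) / (2.0 * sigma**2)
    )


def gen_calibration_scene(
    spec: SceneSpec,
) -> tuple[np.ndarray, np.ndarray, list[CorrespondencePair]]:
    """Render the calibration scene and return its exact correspondences.

    The visible image holds four bright Gaussian blobs at the spec centres;
    the thermal image holds the same blobs at their transform-mapped
    positions.  Raises if any blob (visible or mapped) leaves its image.
    """
    rng = np.random.default_rng(spec.seed)
    vis = np.full(spec.visible_shape, spec.background, dtype=float)
    th = np.full(spec.thermal_shape, spec.background, dtype=float)
    pairs: list[CorrespondencePair] = []
    for center in spec.blob_centers:
        mapped = apply_transform(spec.transform, center)
        for p, shape, name in (
            (center, spec.visible_shape, "visible"),
            (mapped, spec.thermal_shape, "thermal"),
        ):
            if not (0 <= p.x < shape[1] and 0 <= p.y < shape[0]):
                raise ValueError(f"blob at {p} falls outside the {name} image {shape}")
        _add_gaussian_blob(vis, center, spec.blob_sigma, spec.blob_amplitude)
        _add_gaussian_blob(th, mapped, spec.blob_sigma, spec.blob_amplitude)
        pairs.append(CorrespondencePair(visible=center, thermal=mapped))
    if spec.noise_sd > 0:
        vis += rng.normal(0.0, spec.noise_sd, vis.shape)
        th += rng.normal(0.0, spec.noise_sd, th.shape)
    return vis, th, pairs


# ---------------------------------------------------------------------------
# Face scene

def default_face_features(shape: tuple[int, int] = (240, 320)) -> FacialFeatureSet:
    """A frontal synthetic face layout filling a 320x240 frame."""
    h, w = shape
    cx, eye_y = w / 2.0, 0.42 * h
    iod = 0.25 * w
    return FacialFeatureSet(
        face_box=Rect(cx - 0.35 * w, 0.1 * h, cx + 0.35 * w, 0.95 * h),
        left_eye=Point2D(cx - iod / 2.0, eye_y),
        right_eye=Point2D(cx + iod / 2.0, eye_y),
        nose_box=Rect(cx - 0.08 * w, eye_y + 0.12 * h, cx + 0.08 * w, eye_y + 0.28 * h),
        nostrils=(
            Point2D(cx - 0.03 * w, eye_y + 0.22 * h),
            Point2D(cx + 0.03 * w, eye_y + 0.22 * h),
        ),
    )


def gen_face_scene(
    features: FacialFeatureSet,
    roi_levels: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    visible_shape: tuple[int, int] = (240, 320),
    thermal_shape: tuple[int, int] = (240, 320),
    background_level: float = 14500.0,
    skin_intensity: float = 180.0,
    nostril_intensity: float = 30.0,
    roi_config: ROIConfig = ROIConfig(),
) -> tuple[np.ndarray, ThermalFrame, dict]:
    """Render a face scene with commanded thermal levels per measurement region.

    The visible frame is uniform skin with two dark nostril ellipses at the
    feature positions; the thermal frame holds ``roi_levels[name]`` raw counts
    over each region footprint (plus optional Gaussian noise).  Regions must
    not overlap so levels stay unambiguous.  Returns the ground truth
    (per-region levels and the region set) alongside the images.
    """
    rng = np.random.default_rng(seed)
    rois = define_rois(features, roi_config)
    rects = [rois[name] for name in roi_levels]
    for i, r1 in enumerate(rects):
        for r2 in rects[i + 1 :]:
            if r1.x0 < r2.x1 and r2.x0 < r1.x1 and r1.y0 < r2.y1 and r2.y0 < r1.y1:
                raise ValueError("overlapping regions: commanded levels are ambiguous")
    vis = np.full(visible_shape, skin_intensity, dtype=float)
    if features.nostrils is not None:
        yy, xx = np.mgrid[0 : visible_shape[0], 0 : visible_shape[1]]
        for nostril in features.nostrils:
            mask = ((xx - nostril.x) / 3.0) ** 2 + ((yy - nostril.y) / 2.0) ** 2 <= 1.0
            vis[mask] = nostril_intensity
    th = np.full(thermal_shape, background_level, dtype=float)
    for name, level in roi_levels.items():
        rows, cols = rois[name].clip(thermal_shape[1], thermal_shape[0]).to_slices()
        th[rows, cols] = level
    if noise_sd > 0:
        th += rng.normal(0.0, noise_sd, th.shape)
    th = np.clip(th, 0, 16383)
    ground_truth = {"roi_levels": dict(roi_levels), "rois": rois}
    return vis, ThermalFrame(counts=th), ground_truth


# ---------------------------------------------------------------------------
# Eye-video sequence

@dataclass(frozen=True)
class EyeSequenceSpec:
    """An eye-video sequence with scheduled blink (occlusion) events.

    The frame holds two eyes; each open frame shows a dark elliptical pupil
    with a bright corneal glint per eye, and frames inside a blink window are
    a flat eyelid fill at skin intensity (the simplest stimulus that defeats
    both glint detection and ellipse fitting).
    """

    n_frames: int = 300
    frame_rate: float = 5.0
    blink_times: tuple[float, ...] = ()
    blink_duration: float = 0.6
    frame_shape: tuple[int, int] = (96, 384)  # (rows, cols), 4:1 like the eye crop
    pupil_centers: tuple[Point2D, Point2D] = (Point2D(96.0, 48.0), Point2D(288.0, 48.0))
    pupil_radii: tuple[float, float] = (15.0, 12.0)  # (horizontal, vertical semi-axis)
    sr_offset: tuple[float, float] = (5.0, -4.0)
    skin_intensity: float = 120.0
    pupil_intensity: float = 20.0
    glint_intensity: float = 255.0
    glint_radius: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0


def _merge_blinks(spec: EyeSequenceSpec) -> list[tuple[float, float]]:
    intervals = sorted((t, t + spec.blink_duration) for t in spec.blink_times)
    merged: list[tuple[float, float]] = []
    for start, end in intervals:
        if merged and start < merged[-1][1]:
            warnings.warn("overlapping blink events merged", stacklevel=3)
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    duration = spec.n_frames / spec.frame_rate
    for start, end in merged:
        if start < 0 or end > duration:
            raise ValueError(f"blink [{start}, {end}) outside the {duration} s sequence")
    return merged


def gen_eye_sequence(
    spec: EyeSequenceSpec,
) -> tuple[list[EyeFrame], list[str]]:
    """Render the eye sequence and return per-frame ground-truth labels."""
    rng = np.random.default_rng(spec.seed)
    blinks = _merge_blinks(spec)
    h, w = spec.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    open_frame = np.full(spec.frame_shape, spec.skin_intensity, dtype=float)
    for center in spec.pupil_centers:
        rx, ry = spec.pupil_radii
        pupil = ((xx - center.x) / rx) ** 2 + ((yy - center.y) / ry) ** 2 <= 1.0
        open_frame[pupil] = spec.pupil_intensity
        gx, gy = center.x + spec.sr_offset[0], center.y + spec.sr_offset[1]
        glint = (xx - gx) ** 2 + (yy - gy) ** 2 <= spec.glint_radius**2
        open_frame[glint] = spec.glint_intensity
    closed_frame = np.full(spec.frame_shape, spec.skin_intensity, dtype=float)
    frames: list[EyeFrame] = []
    labels: list[str] = []
    for i in range(spec.n_frames):
        t = i / spec.frame_rate
        is_closed = any(start <= t < end for start, end in blinks)
        img = closed_frame if is_closed else open_frame
        if spec.noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0, 255)
        frames.append(EyeFrame(intensity=img.copy(), timestamp=t))
        labels.append(CLOSED if is_closed else OPEN)
    return frames, labels


def blink_schedule(k: int, duration: float = 60.0) -> tuple[float, ...]:
    """Evenly spaced blink onsets: k blinks over ``duration`` seconds."""
    if k == 0:
        return ()
    return tuple((i + 0.5) * duration / k for i in range(k))


# ---------------------------------------------------------------------------
# EEG

@dataclass(frozen=True)
class EEGComponent:
    """One sinusoidal component: amplitude * sin(2*pi*frequency*t + phase)."""

    frequency: float
    amplitude: float
    phase: float = 0.0


@dataclass(frozen=True)
class EEGSpec:
    """Band-limited EEG: a sum of sinusoids plus white noise on every channel."""

    components: tuple[EEGComponent, ...]
    duration: float = 60.0
    sampling_rate: float = 128.0
    channel_names: tuple[str, ...] = CHANNEL_NAMES_14
    noise_sd: float = 0.0
    seed: int = 0


def eeg_spec_for_ratio(
    target_ratio: float,
    delta_freq: float = 2.0,
    beta_freq: float = 20.0,
    beta_amplitude: float = 1.0,
    **kwargs,
) -> EEGSpec:
    """Two-tone spec whose analytic delta/beta power ratio equals ``target_ratio``.

    Sinusoid power scales with amplitude squared, so the delta amplitude is
    sqrt(target_ratio) times the beta amplitude.  The default tones sit on
    exact 1 Hz analysis bins.
    """
    if target_ratio < 0:
        raise ValueError("target_ratio must be non-negative")
    return EEGSpec(
        components=(
            EEGComponent(delta_freq, beta_amplitude * float(np.sqrt(target_ratio))),
            EEGComponent(beta_freq, beta_amplitude),
        ),
        **kwargs,
    )


def analytic_band_ratio(spec: EEGSpec) -> float:
    """Delta/beta power ratio implied by the spec's component amplitudes."""
    delta_p = sum(
        c.amplitude**2 for c in spec.components if DELTA.low <= c.frequency < DELTA.high
    )
    beta_p = sum(
        c.amplitude**2 for c in spec.components if BETA.low <= c.frequency < BETA.high
    )
    if beta_p == 0:
        raise ValueError("spec has no beta-band component: analytic ratio undefined")
    return delta_p / beta_p


def gen_eeg(spec: EEGSpec) -> tuple[EEGRecording, float]:
    """Synthesize the recording and return it with its analytic delta/beta ratio.

    Every channel carries the same deterministic component sum with
    independent Gaussian noise per channel.  Component frequencies must stay
    below the Nyquist rate.
    """
    nyquist = spec.sampling_rate / 2.0
    for c in spec.components:
        if c.frequency >= nyquist:
            raise ValueError(f"component at {c.frequency} Hz >= Nyquist ({nyquist} Hz)")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    base = np.zeros(n)
    for c in spec.components:
        base += c.amplitude * np.sin(2.0 * np.pi * c.frequency * t + c.phase)
    samples = np.tile(base, (len(spec.channel_names), 1))
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, samples.shape)
    recording = EEGRecording(
        samples=samples,
        channel_names=spec.channel_names,
        sampling_rate=spec.sampling_rate,
    )
    return recording, analytic_band_ratio(spec)


# ---------------------------------------------------------------------------
# Cohort

def _default_cohort_parameters() -> dict:
    """Published group parameters: fear condition from the summary tables,
    neutral condition from the reported neutral means with the matching
    fear-condition SDs (neutral SDs were not published)."""
    params: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    for modality, phases in fixtures.COHORT_SUMMARIES.items():
        params[modality] = {
            "horror": {
                "pre": (phases["pre"].mean, phases["pre"].sd),
                "post": (phases["post"].mean, phases["post"].sd),
            },
            "neutral": {
                "pre": (fixtures.NEUTRAL_MEANS[modality]["pre"], phases["pre"].sd),
                "post": (fixtures.NEUTRAL_MEANS[modality]["post"], phases["post"].sd),
            },
        }
    return params


@dataclass(frozen=True)
class CohortSpec:
    """A pre/post cohort of independent Gaussian measurements.

    ``parameters[modality][condition][phase] = (mean, sd)``; the defaults are
    the published 16-subject group parameters.  Cells are drawn independently
    — the published tables give no within-subject correlation structure, so
    none is imposed by default.  ``correlation`` optionally induces a common
    latent factor across modalities (non-physiological; stress-testing only).
    """

    n_subjects: int = 16
    parameters: Mapping = field(default_factory=_default_cohort_parameters)
    conditions: tuple[str, ...] = ("horror",)
    correlation: float = 0.0
    seed: int = 0


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the cohort as a long table (subject, modality, condition, phase, value)."""
    if not 0.0 <= spec.correlation < 1.0:
        raise ValueError("correlation must lie in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for condition in spec.conditions:
        # optional shared latent factor per subject (z-scored), off by default
        latent = rng.standard_normal(spec.n_subjects) if spec.correlation > 0 else None
        for modality, by_condition in spec.parameters.items():
            for phase, (mean, sd) in by_condition[condition].items():
                if sd < 0:
                    raise ValueError(f"negative sd for {modality}/{condition}/{phase}")
                z = rng.standard_normal(spec.n_subjects)
                if latent is not None:
                    z = (
                        np.sqrt(spec.correlation) * latent
                        + np.sqrt(1.0 - spec.correlation) * z
                    )
                values = mean + sd * z
                for subject, value in enumerate(values, start=1):
                    rows.append(
                        {
                            "subject": subject,
                            "modality": modality,
                            "condition": condition,
                            "phase": phase,
                            "value": float(value),
                        }
                    )
    return pd.DataFrame(rows)
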