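"""EEG band powers and the delta/beta ratio used as a fear index.

A 14-channel consumer EEG headset samples at 128 Hz.  Each channel is
min-max scaled to [-1, 1] over the session (adjusting DC level and gain),
cut into non-overlapping rectangular windows of 128 samples (1 s, giving a
1 Hz bin spacing), and transformed with a discrete Fourier transform.  The
fear index for an electrode is the per-window ratio of delta-band power
(0.5-4 Hz) to beta-band power (above 13 Hz; bounded at 30 Hz by default so
line noise and high-frequency artifacts are not absorbed), averaged over
windows.  A fear response lowers the ratio: slow delta activity drops while
fast beta activity rises.

The periodogram is normalized so that the band powers of one window sum to
the window's mean squared amplitude (Parseval), making band power directly
interpretable as a share of signal variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNEL_NAMES_14",
    "DELTA",
    "THETA",
    "ALPHA",
    "BETA",
    "EEGRecording",
    "BandDefinition",
    "BandRatioSeries",
    "minmax_normalize",
    "window_spectra",
    "band_power",
    "delta_beta_ratio",
    "read_eeg_text",
    "write_eeg_text",
]

#: electrode montage of the 14-channel headset (10-20 system positions)
CHANNEL_NAMES_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"invalid band {self.name}: [{self.low}, {self.high})")


DELTA = BandDefinition("delta", 0.5, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)


@dataclass(frozen=True)
class EEGRecording:
    """A channels x time array of dimensionless EEG amplitudes."""

    samples: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES_14
    sampling_rate: float = 128.0

    def __post_init__(self) -> None:
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{samples.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("EEG samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ValueError(
                f"electrode {name!r} not in montage {self.channel_names}"
            ) from None
        return self.samples[idx]


@dataclass(frozen=True)
class BandRatioSeries:
    """Per-window delta/beta power ratios and their session mean."""

    per_window_ratio: np.ndarray
    session_value: float
    n_windows_skipped: int = 0


def minmax_normalize(channel: np.ndarray) -> np.ndarray:
    """Scale a channel to [-1, 1] over the whole session: y = 2(x-min)/(max-min) - 1.

    A constant channel carries no usable signal; it is returned as all zeros
    with a warning rather than dividing by zero.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("minmax_normalize expects a 1-D signal of length >= 2")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant channel: min-max normalization returns zeros", stacklevel=2)
        return np.zeros_like(x)
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def window_spectra(
    channel: np.ndarray, window_len: int = 128, sampling_rate: float = 128.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window periodogram power on non-overlapping rectangular windows.

    Returns ``(freqs, powers)`` where ``powers[w, k]`` is the power of window
    ``w`` in the bin at ``freqs[k] = k * sampling_rate / window_len``; at the
    default 128-sample window and 128 Hz rate the bins fall on integer hertz.
    Powers are one-sided and scaled so ``powers[w].sum()`` equals the mean
    squared amplitude of window ``w`` (Parseval).  A trailing partial window
    is discarded.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1:
        raise ValueError("window_spectra expects a 1-D signal")
    if x.size < window_len:
        raise ValueError(f"signal of length {x.size} shorter than window ({window_len})")
    n_windows = x.size // window_len
    frames = x[: n_windows * window_len].reshape(n_windows, window_len)
    spectrum = np.fft.rfft(frames, axis=1)
    power = np.abs(spectrum) ** 2 / window_len**2
    # one-sided doubling for all bins except DC (and Nyquist when present)
    if window_len % 2 == 0:
        power[:, 1:-1] *= 2.0
    else:
        power[:, 1:] *= 2.0
    freqs = np.fft.rfftfreq(window_len, d=1.0 / sampling_rate)
    return freqs, power


def band_power(
    spectrum: np.ndarray, band: BandDefinition, freqs: np.ndarray
) -> np.ndarray:
    """Sum of periodogram power over bins with band.low <= f < band.high.

    Works on a single window (1-D) or a stack of windows (2-D, bins last).
    The DC bin can never fall inside a band because bands start above 0 Hz.
    """
    freqs = np.asarray(freqs, dtype=float)
    mask = (freqs >= band.low) & (freqs < band.high) & (freqs > 0)
    if not mask.any():
        raise ValueError(
            f"band {band.name} [{band.low}, {band.high}) contains no frequency bins"
        )
    return np.asarray(spectrum)[..., mask].sum(axis=-1)


def delta_beta_ratio(
    recording: EEGRecording,
    electrode: str,
    delta: BandDefinition = DELTA,
    beta: BandDefinition = BETA,
    window_len: int = 128,
    normalize: bool = True,
    aggregate: str = "mean_of_ratios",
    beta_floor: float = 1e-12,
) -> BandRatioSeries:
    """Session delta/beta power ratio for one electrode.

    The channel is min-max normalized (the ratio itself is scale invariant,
    but normalization matches the acquisition pipeline), windowed, and the
    delta/beta power ratio formed per window.  Windows whose beta power falls
    below ``beta_floor`` are skipped and counted.  ``aggregate`` selects the
    session statistic: ``"mean_of_ratios"`` (default) or ``"ratio_of_means"``
    (ratio of window-mean band powers) for sensitivity analysis.
    """
    x = recording.channel(electrode)
    if normalize:
        x = minmax_normalize(x)
    freqs, powers = window_spectra(x, window_len, recording.sampling_rate)
    delta_p = band_power(powers, delta, freqs)
    beta_p = band_power(powers, beta, freqs)
    valid = beta_p > beta_floor
    n_skipped = int((~valid).sum())
    if not valid.any():
        raise ValueError(
            f"all {len(beta_p)} windows have beta power below {beta_floor}"
        )
    ratios = delta_p[valid] / beta_p[valid]
    if aggregate == "mean_of_ratios":
        session = float(ratios.mean())
    elif aggregate == "ratio_of_means":
        session = float(delta_p[valid].mean() / beta_p[valid].mean())
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return BandRatioSeries(
        per_window_ratio=ratios, session_value=session, n_windows_skipped=n_skipped
    )


# ---------------------------------------------------------------------------
# Delimited-text ingestion (header row of channel names, one row per sample)

def read_eeg_text(path: str | Path, sampling_rate: float = 128.0) -> EEGRecording:
    df = pd.read_csv(path)
    return EEGRecording(
        samples=df.to_numpy(dtype=float).T,
        channel_names=tuple(df.columns),
        sampling_rate=sampling_rate,
    )


def write_eeg_text(path: str | Path, recording: EEGRecording) -> None:
    pd.DataFrame(
        recording.samples.T, columns=list(recording.channel_names)
    ).to_csv(path, index=False)


def write_ratio_table(
    path: str | Path, rows: Sequence[tuple[str, str, float]]
) -> None:
    """Write (electrode, phase, session ratio) rows as delimited text."""
    df = pd.DataFrame(rows, columns=["electrode", "phase", "ratio"])
    df.to_csv(path, index=False)
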