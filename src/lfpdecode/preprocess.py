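"""Raw LFP -> lagged feature tensors and aligned kinematic targets.

The feature chain mirrors the offline analysis it reimplements: notch
filtering of the 50/100/150 Hz lines, a six-band Butterworth band-pass bank,
band envelopes (full-wave rectification, 4 Hz low-pass, resampling to 10 Hz),
the windowed mean LFP amplitude (200 ms windows, 100 ms step), and lagged
feature tensors of shape channel x lag x feature (8 x 10 x 7 by default)
with a 100 ms lag step.  All filters run zero-phase (forward-backward).

Every derived series lives on a single shared 10 Hz grid whose first sample
sits at t = 100 ms (the centre of the first 200 ms amplitude window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .bands import BandSpec, CANONICAL_BANDS, FEATURE_NAMES

__all__ = [
    "FEATURE_RATE",
    "EnvelopeSeries",
    "ALFPSeries",
    "FeatureTensorSeries",
    "FeatureNormalizer",
    "remove_line_noise",
    "bandpass_bank",
    "envelope",
    "compute_alfp",
    "build_feature_tensor",
    "align_targets",
    "preprocess_session",
]

FEATURE_RATE = 10.0  # Hz
LAG_STEP = 0.1  # seconds

LINE_FREQS = (50.0, 100.0, 150.0)
NOTCH_HALF_WIDTH = 2.0  # Hz, stop band is f0 +/- 2 Hz
ENVELOPE_CUTOFF = 4.0  # Hz


@dataclass
class EnvelopeSeries:
    """Band envelopes at 10 Hz: ``values[t, channel, band]``."""

    values: np.ndarray
    times: np.ndarray
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS


@dataclass
class ALFPSeries:
    """Windowed mean LFP amplitude at 10 Hz: ``values[t, channel]``."""

    values: np.ndarray
    times: np.ndarray


@dataclass
class FeatureTensorSeries:
    """Lagged feature tensors: ``tensors[t, channel, lag, feature]``.

    ``tensors[i, c, l, f]`` holds feature ``f`` of channel ``c`` at time
    ``times[i] - l * 100 ms``.  Feature ordering follows
    :data:`~lfpdecode.bands.FEATURE_NAMES` (six band envelopes then ALFP).
    """

    tensors: np.ndarray
    times: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n_channels(self) -> int:
        return self.tensors.shape[1]

    @property
    def n_lags(self) -> int:
        return self.tensors.shape[2]

    @property
    def n_features(self) -> int:
        return self.tensors.shape[3]

    def flattened(self) -> np.ndarray:
        """Per-time-point feature vectors for the linear baselines."""
        return self.tensors.reshape(len(self.times), -1)


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim != 2:
        raise ValueError("signal must be 1-D or 2-D (channels x samples)")
    return x, False


def remove_line_noise(
    x: np.ndarray, fs: float, line_freqs: Sequence[float] = LINE_FREQS
) -> np.ndarray:
    """Suppress power-line interference with 4th-order Butterworth notches.

    Each notch is a band-stop with a +/-2 Hz stop band around the line
    frequency, applied forward-backward (zero phase).
    """
    x2d, was_1d = _as_2d(x)
    out = x2d
    for f0 in line_freqs:
        if f0 + NOTCH_HALF_WIDTH >= fs / 2:
            raise ValueError(
                f"cannot notch {f0} Hz at fs={fs} Hz: stop band reaches Nyquist"
            )
        sos = signal.butter(
            4,
            [f0 - NOTCH_HALF_WIDTH, f0 + NOTCH_HALF_WIDTH],
            btype="bandstop",
            fs=fs,
            output="sos",
        )
        out = signal.sosfiltfilt(sos, out, axis=-1)
    return out[0] if was_1d else out


def design_bandpass(band: BandSpec, fs: float) -> np.ndarray:
    """4th-order Butterworth band-pass for one band, as second-order sections."""
    band.validate_against(fs)
    return signal.butter(
        4, [band.low, band.high], btype="bandpass", fs=fs, output="sos"
    )


def bandpass_bank(
    x: np.ndarray, bands: Sequence[BandSpec] = CANONICAL_BANDS, fs: float = 500.0
) -> np.ndarray:
    """Split the signal into band-limited components.

    Returns an array of shape ``(n_bands, n_channels, n_samples)`` (the
    leading axis is dropped-in order of ``bands``); filtering is zero-phase.
    """
    x2d, was_1d = _as_2d(x)
    out = np.empty((len(bands),) + x2d.shape)
    for i, band in enumerate(bands):
        sos = design_bandpass(band, fs)
        out[i] = signal.sosfiltfilt(sos, x2d, axis=-1)
    return out[:, 0, :] if was_1d else out


def _feature_grid(n_samples: int, fs: float) -> np.ndarray:
    """Shared 10 Hz grid: t = 0.1, 0.2, ... (window centres of the ALFP)."""
    n_out = int(n_samples / fs * FEATURE_RATE) - 1
    if n_out < 1:
        raise ValueError("signal too short for the 10 Hz feature grid")
    return (np.arange(n_out) + 1) / FEATURE_RATE


def envelope(band_signal: np.ndarray, fs: float) -> np.ndarray:
    """Envelope of a band-limited signal on the shared 10 Hz grid.

    Full-wave rectification, 4th-order Butterworth low-pass at 4 Hz
    (zero-phase), then anti-aliased polyphase resampling to 10 Hz.  Output
    shape matches the input with the time axis on the 10 Hz grid.
    """
    x2d, was_1d = _as_2d(band_signal)
    sos = signal.butter(4, ENVELOPE_CUTOFF, btype="lowpass", fs=fs, output="sos")
    smooth = signal.sosfiltfilt(sos, np.abs(x2d), axis=-1)
    decim = fs / FEATURE_RATE
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of 10 Hz")
    env = signal.resample_poly(smooth, up=1, down=int(round(decim)), axis=-1)
    n_out = _feature_grid(x2d.shape[-1], fs).size
    env = env[..., 1 : n_out + 1]  # drop the t=0 sample to land on the grid
    env = np.clip(env, 0.0, None)  # low-pass ringing may dip below zero
    return env[0] if was_1d else env


def compute_envelopes(
    band_signals: np.ndarray, fs: float, bands: Sequence[BandSpec] = CANONICAL_BANDS
) -> EnvelopeSeries:
    """Envelopes for a full band bank: ``(band, channel, time)`` input."""
    env = envelope(band_signals.reshape(-1, band_signals.shape[-1]), fs)
    env = env.reshape(band_signals.shape[0], band_signals.shape[1], -1)
    times = _feature_grid(band_signals.shape[-1], fs)
    return EnvelopeSeries(
        values=np.moveaxis(env, (0, 1, 2), (2, 1, 0)), times=times, bands=tuple(bands)
    )


def compute_alfp(x: np.ndarray, fs: float) -> ALFPSeries:
    """Mean rectified LFP amplitude in 200 ms windows stepped every 100 ms.

    The raw LFP is near zero-mean, so the window mean is taken over the
    absolute signal.
    """
    x2d, was_1d = _as_2d(x)
    win = int(round(0.2 * fs))
    step = int(round(0.1 * fs))
    if x2d.shape[-1] < win:
        raise ValueError("signal shorter than one 200 ms window")
    windows = np.lib.stride_tricks.sliding_window_view(np.abs(x2d), win, axis=-1)
    vals = windows[:, ::step, :].mean(axis=-1)
    times = (np.arange(vals.shape[-1]) * step + win / 2) / fs
    values = vals[0] if was_1d else vals.T  # (time, channel) for 2-D input
    return ALFPSeries(values=values, times=times)


def build_feature_tensor(
    envelopes: EnvelopeSeries, alfp: ALFPSeries, n_lags: int = 10
) -> FeatureTensorSeries:
    """Stack band envelopes and ALFP into lagged 3-D feature tensors.

    Times lacking a full lag history (the first ``n_lags - 1`` grid points)
    are dropped, so the first tensor sits >= 900 ms after series start.
    """
    n = min(len(envelopes.times), len(alfp.times))
    if n < len(envelopes.times) or n < len(alfp.times):
        envelopes = EnvelopeSeries(envelopes.values[:n], envelopes.times[:n], envelopes.bands)
        alfp = ALFPSeries(alfp.values[:n], alfp.times[:n])
    if not np.allclose(envelopes.times, alfp.times, atol=1e-9):
        raise ValueError("envelope and ALFP series are not on the same 10 Hz grid")
    feats = np.concatenate([envelopes.values, alfp.values[:, :, None]], axis=2)
    n_t, n_ch, n_feat = feats.shape
    if n_t < n_lags:
        raise ValueError("series shorter than the lag history")
    # windows[i, c, f, l] = feats[i + l, c, f]; lag l counts backwards from
    # the tensor time stamp at index i + n_lags - 1.
    windows = np.lib.stride_tricks.sliding_window_view(feats, n_lags, axis=0)
    tensors = np.moveaxis(windows[:, :, :, ::-1], (1, 3, 2), (1, 2, 3)).copy()
    times = envelopes.times[n_lags - 1 :]
    return FeatureTensorSeries(tensors=tensors, times=times)


def align_targets(
    kinematics: np.ndarray, kinematic_fs: float, feature_times: np.ndarray
) -> np.ndarray:
    """Resample joint angles onto the feature grid.

    Anti-alias low-pass (4th-order Butterworth at 4 Hz, zero-phase) then
    sample at the feature time stamps by linear interpolation.
    """
    kin = np.atleast_2d(np.asarray(kinematics, dtype=float))
    t_kin = np.arange(kin.shape[-1]) / kinematic_fs
    ft = np.asarray(feature_times, dtype=float)
    if ft.min() < t_kin[0] - 1e-9 or ft.max() > t_kin[-1] + 1e-9:
        raise ValueError("feature times fall outside the kinematic record")
    sos = signal.butter(4, ENVELOPE_CUTOFF, btype="lowpass", fs=kinematic_fs, output="sos")
    smooth = signal.sosfiltfilt(sos, kin, axis=-1)
    out = np.vstack([np.interp(ft, t_kin, row) for row in smooth])
    return out if np.asarray(kinematics).ndim == 2 else out[0]


class FeatureNormalizer:
    """Z-score each (channel, feature) pair using training statistics only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, tensors: np.ndarray) -> "FeatureNormalizer":
        # Pool over time and lag: a lagged copy is the same physical feature.
        self.mean_ = tensors.mean(axis=(0, 2), keepdims=True)
        sd = tensors.std(axis=(0, 2), keepdims=True)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, tensors: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("normalizer is not fitted")
        return (tensors - self.mean_) / self.sd_


def preprocess_session(
    session, bands: Sequence[BandSpec] = CANONICAL_BANDS, n_lags: int = 10
):
    """Full chain from a session to (feature tensors, aligned targets).

    Returns
    -------
    features : FeatureTensorSeries
    targets : ndarray, shape (6, n_times)
        Joint angles (degrees) aligned to ``features.times``.
    """
    clean = remove_line_noise(session.neural, session.neural_fs)
    band_sig = bandpass_bank(clean, bands, session.neural_fs)
    envs = compute_envelopes(band_sig, session.neural_fs, bands)
    alfp = compute_alfp(clean, session.neural_fs)
    features = build_feature_tensor(envs, alfp, n_lags=n_lags)
    targets = align_targets(session.kinematics, session.kinematic_fs, features.times)
    return features, targets
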