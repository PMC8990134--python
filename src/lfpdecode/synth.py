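"""Synthetic session generator.

Produces sessions with known ground truth: gait-periodic joint angles at a
configurable cadence, and multichannel LFP whose band-limited components are
amplitude-modulated by gait phase with per-channel/per-band coupling depth
and phase.  Line interference at 50/100/150 Hz, pink (1/f) noise and white
noise are added on top.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import signal

from .bands import CANONICAL_BANDS, BandSpec
from .session import DEFAULT_CHANNEL_MAP, JOINT_NAMES, Session

__all__ = [
    "GaitModel",
    "CouplingSpec",
    "NoiseSpec",
    "SynthConfig",
    "ConfigurationError",
    "generate_kinematics",
    "generate_lfp",
    "generate_session",
    "cadence_group",
    "LOW_CADENCE_THRESHOLD",
    "HIGH_CADENCE_THRESHOLD",
]

#: Sessions slower than this (steps/s) belong to the "lower" cadence group.
LOW_CADENCE_THRESHOLD = 0.67
#: Sessions faster than this belong to the "higher" cadence group.
HIGH_CADENCE_THRESHOLD = 0.73

N_BANDS = len(CANONICAL_BANDS)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


def cadence_group(cadence: float) -> str:
    """Classify a cadence as 'lower', 'higher' or 'excluded' (in between)."""
    if cadence < LOW_CADENCE_THRESHOLD:
        return "lower"
    if cadence > HIGH_CADENCE_THRESHOLD:
        return "higher"
    return "excluded"


@dataclass
class GaitModel:
    """Harmonic model of the six hindlimb joint angles.

    Each joint angle is ``baseline + sum_h amp[h] * cos(h*(phi + lag) +
    phase[h])`` where ``phi = 2*pi*cadence*t`` and ``lag`` is 0 for the left
    leg and ``-left_right_lag`` for the right leg (default pi: alternating
    gait).  ``amplitudes[j]`` lists the harmonic amplitudes of joint ``j`` in
    degrees (index 0 = fundamental); ``phases[j]`` the matching phase
    offsets in radians.
    """

    cadence: float = 0.7
    amplitudes: Sequence[Sequence[float]] = (
        (20.0, 5.0),
        (15.0, 6.0),
        (25.0, 7.0),
        (20.0, 5.0),
        (15.0, 6.0),
        (25.0, 7.0),
    )
    phases: Sequence[Sequence[float]] = (
        (0.0, 0.6),
        (1.1, 2.0),
        (2.3, 3.1),
        (0.0, 0.6),
        (1.1, 2.0),
        (2.3, 3.1),
    )
    baselines: Sequence[float] = (100.0, 90.0, 110.0, 100.0, 90.0, 110.0)
    left_right_lag: float = np.pi

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ConfigurationError("cadence must be positive")
        if not (
            len(self.amplitudes) == len(self.phases) == len(self.baselines) == 6
        ):
            raise ConfigurationError("gait model needs 6 joints")
        for a, p in zip(self.amplitudes, self.phases):
            if len(a) < 1 or len(a) != len(p):
                raise ConfigurationError(
                    "each joint needs >= 1 harmonic with matching phases"
                )


@dataclass
class CouplingSpec:
    """Gait-phase coupling of the band-limited LFP components.

    The instantaneous gain of band ``b`` on channel ``c`` is
    ``a[c, b] * (1 + m[c, b] * cos(phi - psi[c, b]))``; ``0 <= m < 1`` keeps
    the gain positive.
    """

    depth: np.ndarray | None = None  # m[channel, band] in [0, 1)
    phase: np.ndarray | None = None  # psi[channel, band], radians
    amplitude: np.ndarray | None = None  # a[channel, band] > 0

    def resolved(self, n_channels: int) -> "CouplingSpec":
        shape = (n_channels, N_BANDS)
        m = np.full(shape, 0.5) if self.depth is None else np.broadcast_to(
            np.asarray(self.depth, dtype=float), shape
        ).copy()
        if self.phase is None:
            # Spread modulation phases over channels and bands so that the
            # population carries both sine and cosine components of the gait.
            c = np.arange(n_channels)[:, None]
            b = np.arange(N_BANDS)[None, :]
            psi = (2 * np.pi * (c / n_channels + b / (2 * N_BANDS))) % (2 * np.pi)
        else:
            psi = np.broadcast_to(np.asarray(self.phase, dtype=float), shape).copy()
        a = np.ones(shape) if self.amplitude is None else np.broadcast_to(
            np.asarray(self.amplitude, dtype=float), shape
        ).copy()
        if np.any(m < 0) or np.any(m >= 1):
            raise ConfigurationError("modulation depth must lie in [0, 1)")
        if np.any(a < 0):
            raise ConfigurationError("base band amplitudes must be >= 0")
        return CouplingSpec(depth=m, phase=psi, amplitude=a)


@dataclass
class NoiseSpec:
    """Additive disturbances: 50/100/150 Hz lines, white and pink noise."""

    line_amplitudes: Sequence[float] = (1.0, 0.5, 0.25)
    line_freqs: Sequence[float] = (50.0, 100.0, 150.0)
    white_sd: float = 0.5
    pink_amplitude: float = 0.5

    def __post_init__(self) -> None:
        if (
            any(a < 0 for a in self.line_amplitudes)
            or self.white_sd < 0
            or self.pink_amplitude < 0
        ):
            raise ConfigurationError("noise amplitudes must be non-negative")
        if len(self.line_amplitudes) != len(self.line_freqs):
            raise ConfigurationError("one amplitude per line frequency")


@dataclass
class SynthConfig:
    """Full configuration of one synthetic session."""

    duration: float = 60.0
    neural_fs: float = 500.0
    kinematic_fs: float = 50.0
    n_channels: int = 8
    seed: int = 0
    gait: GaitModel = field(default_factory=GaitModel)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    #: When set, the theta-band base amplitude is multiplied by
    #: ``1 + slope * (cadence - 0.70) / 0.70`` so that faster sessions carry
    #: more theta power (the cadence analysis is expected to recover this).
    cadence_theta_slope: float | None = 1.5

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.neural_fs <= 0 or self.kinematic_fs <= 0:
            raise ConfigurationError("sampling rates must be positive")
        ratio = self.neural_fs / self.kinematic_fs
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "neural rate must be an integer multiple of the kinematic rate"
            )


def generate_kinematics(config: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate the six joint-angle trajectories and the ground-truth phase.

    Returns
    -------
    angles : ndarray, shape (6, n_kin)
        Joint angles in degrees at the kinematic rate.
    phase : ndarray, shape (n_kin,)
        Ground-truth gait phase ``phi(t) = 2*pi*cadence*t`` (unwrapped,
        radians) on the kinematic grid.
    t : ndarray, shape (n_kin,)
        Time stamps in seconds.
    """
    gait = config.gait
    n = int(round(config.duration * config.kinematic_fs))
    t = np.arange(n) / config.kinematic_fs
    phi = 2 * np.pi * gait.cadence * t
    angles = np.empty((6, n))
    for j in range(6):
        lag = 0.0 if JOINT_NAMES[j].startswith("left") else -gait.left_right_lag
        a = np.full(n, float(gait.baselines[j]))
        for h, (amp, ph) in enumerate(zip(gait.amplitudes[j], gait.phases[j]), start=1):
            a += amp * np.cos(h * (phi + lag) + ph)
        angles[j] = a
    return angles, phi, t


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, band: BandSpec
) -> np.ndarray:
    """White noise band-passed to ``band`` and scaled to unit variance."""
    sos = signal.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def theta_amplitude_multiplier(config: SynthConfig) -> float:
    """Cadence-power linkage factor applied to the theta base amplitude."""
    if config.cadence_theta_slope is None:
        return 1.0
    return 1.0 + config.cadence_theta_slope * (config.gait.cadence - 0.70) / 0.70


def generate_lfp(config: SynthConfig, phase: np.ndarray) -> np.ndarray:
    """Generate multichannel LFP given the ground-truth phase track.

    ``phase`` is the unwrapped gait phase on the kinematic grid; it is
    upsampled to the neural grid by linear interpolation.  Each channel is a
    sum over the six canonical bands of band-limited Gaussian noise whose
    envelope is multiplied by ``a*(1 + m*cos(phi - psi))``, plus line
    sinusoids, pink noise and white noise.
    """
    n_neural = int(round(config.duration * config.neural_fs))
    t_neural = np.arange(n_neural) / config.neural_fs
    t_kin = np.arange(len(phase)) / config.kinematic_fs
    phi = np.interp(t_neural, t_kin, phase)

    coupling = config.coupling.resolved(config.n_channels)
    theta_mult = theta_amplitude_multiplier(config)
    theta_idx = next(i for i, b in enumerate(CANONICAL_BANDS) if b.name == "theta")

    rng = np.random.default_rng(config.seed)
    lfp = np.zeros((config.n_channels, n_neural))
    for c in range(config.n_channels):
        for b, band in enumerate(CANONICAL_BANDS):
            carrier = _band_noise(rng, n_neural, config.neural_fs, band)
            a = coupling.amplitude[c, b]
            if b == theta_idx:
                a = a * theta_mult
            gain = a * (1.0 + coupling.depth[c, b] * np.cos(phi - coupling.phase[c, b]))
            lfp[c] += gain * carrier
        noise = config.noise
        for amp, f0 in zip(noise.line_amplitudes, noise.line_freqs):
            if amp > 0:
                lfp[c] += amp * np.sin(2 * np.pi * f0 * t_neural)
        if noise.pink_amplitude > 0:
            lfp[c] += noise.pink_amplitude * _pink_noise(rng, n_neural)
        if noise.white_sd > 0:
            lfp[c] += noise.white_sd * rng.standard_normal(n_neural)
    return lfp


def generate_session(config: SynthConfig) -> Session:
    """Generate a complete synthetic :class:`~lfpdecode.session.Session`.

    The session metadata records the cadence, its group label under the
    0.67/0.73 steps/s thresholds, the seed, and the resolved ground-truth
    coupling parameters.
    """
    angles, phase, _ = generate_kinematics(config)
    lfp = generate_lfp(config, phase)
    coupling = config.coupling.resolved(config.n_channels)
    meta = {
        "cadence": config.gait.cadence,
        "cadence_group": cadence_group(config.gait.cadence),
        "seed": config.seed,
        "synthetic": True,
        "ground_truth": {
            "phase_start": 0.0,
            "coupling_depth": coupling.depth.tolist(),
            "coupling_phase": coupling.phase.tolist(),
            "coupling_amplitude": coupling.amplitude.tolist(),
            "gait": {
                "cadence": config.gait.cadence,
                "amplitudes": [list(a) for a in config.gait.amplitudes],
                "phases": [list(p) for p in config.gait.phases],
                "baselines": list(config.gait.baselines),
                "left_right_lag": config.gait.left_right_lag,
            },
            "theta_amplitude_multiplier": theta_amplitude_multiplier(config),
        },
    }
    channel_map = {k: dict(v) for k, v in DEFAULT_CHANNEL_MAP.items()}
    if config.n_channels != 8:
        # Fall back to a cyclic assignment for non-default channel counts.
        keys = sorted(DEFAULT_CHANNEL_MAP)
        channel_map = {
            i + 1: dict(DEFAULT_CHANNEL_MAP[keys[i % 8]])
            for i in range(config.n_channels)
        }
    return Session(
        neural=lfp,
        neural_fs=config.neural_fs,
        kinematics=angles,
        kinematic_fs=config.kinematic_fs,
        channel_map=channel_map,
        meta=meta,
    )
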