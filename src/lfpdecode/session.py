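"""Session container and HDF5 persistence.

A :class:`Session` bundles a multichannel neural recording with synchronously
captured joint-angle trajectories, the electrode map (dorsal/lateral column,
left/right side) and free-form metadata.  Sessions are stored as HDF5 files
with the layout::

    /neural/data        float array, channels x samples
    /neural/fs          scalar sampling rate (Hz)
    /kinematics/data    float array, 6 joints x samples
    /kinematics/fs      scalar sampling rate (Hz)
    attrs["channel_map"]  JSON mapping electrode index -> {column, side}
    attrs["meta"]         JSON metadata (cadence, seed, ground truth, notes)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import h5py
import numpy as np

__all__ = [
    "JOINT_NAMES",
    "DEFAULT_CHANNEL_MAP",
    "Session",
    "SchemaError",
    "read_session",
    "write_session",
]

#: Joint ordering used by every array in the package.
JOINT_NAMES = (
    "left_hip",
    "left_knee",
    "left_ankle",
    "right_hip",
    "right_knee",
    "right_ankle",
)

#: Electrode layout: electrodes 1,4,5,8 sit in the lateral columns and
#: 2,3,6,7 in the dorsal columns; 3,4,7,8 are on the left side of the cord,
#: 1,2,5,6 on the right.  Keys are 1-based electrode numbers.
DEFAULT_CHANNEL_MAP: dict[int, dict[str, str]] = {
    1: {"column": "lateral", "side": "right"},
    2: {"column": "dorsal", "side": "right"},
    3: {"column": "dorsal", "side": "left"},
    4: {"column": "lateral", "side": "left"},
    5: {"column": "lateral", "side": "right"},
    6: {"column": "dorsal", "side": "right"},
    7: {"column": "dorsal", "side": "left"},
    8: {"column": "lateral", "side": "left"},
}


class SchemaError(ValueError):
    """Raised when a session file does not follow the documented layout."""


@dataclass
class Session:
    """One recording session: neural data, kinematics, channel map, metadata.

    Parameters
    ----------
    neural : ndarray, shape (n_channels, n_samples)
        Broadband neural signal in amplitude units.
    neural_fs : float
        Neural sampling rate in Hz.
    kinematics : ndarray, shape (6, n_samples_kin)
        Joint angles in degrees, ordered as :data:`JOINT_NAMES`.
    kinematic_fs : float
        Kinematic sampling rate in Hz.
    channel_map : dict
        Electrode number (1-based) -> ``{"column": ..., "side": ...}``.
    meta : dict
        Free-form metadata; synthetic sessions store cadence, seed and the
        ground-truth generator parameters here.
    """

    neural: np.ndarray
    neural_fs: float
    kinematics: np.ndarray
    kinematic_fs: float
    channel_map: dict[int, dict[str, str]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHANNEL_MAP.items()}
    )
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.neural = np.asarray(self.neural, dtype=float)
        self.kinematics = np.asarray(self.kinematics, dtype=float)
        if self.neural.ndim != 2:
            raise SchemaError("neural array must be 2-D (channels x samples)")
        if self.kinematics.ndim != 2:
            raise SchemaError("kinematic array must be 2-D (joints x samples)")
        if self.neural_fs <= 0 or self.kinematic_fs <= 0:
            raise SchemaError("sampling rates must be positive")
        if len(self.channel_map) != self.n_channels:
            raise SchemaError(
                f"channel map has {len(self.channel_map)} entries for "
                f"{self.n_channels} channels"
            )
        # Both streams must span the same wall-clock duration (within one
        # sample at the slower rate).
        d_n = self.neural.shape[1] / self.neural_fs
        d_k = self.kinematics.shape[1] / self.kinematic_fs
        if abs(d_n - d_k) > 1.0 / min(self.neural_fs, self.kinematic_fs) + 1e-9:
            raise SchemaError(
                f"neural ({d_n:.3f} s) and kinematic ({d_k:.3f} s) records "
                "span different durations"
            )

    @property
    def n_channels(self) -> int:
        return self.neural.shape[0]

    @property
    def duration(self) -> float:
        """Duration of the neural record in seconds."""
        return self.neural.shape[1] / self.neural_fs

    @property
    def cadence(self) -> float | None:
        return self.meta.get("cadence")

    def channels_in(self, *, column: str | None = None, side: str | None = None) -> list[int]:
        """Return 0-based channel indices matching a column and/or side label."""
        out = []
        for elec in sorted(self.channel_map):
            info = self.channel_map[elec]
            if column is not None and info["column"] != column:
                continue
            if side is not None and info["side"] != side:
                continue
            out.append(elec - 1)
        return out


def write_session(session: Session, path) -> None:
    """Write a :class:`Session` to an HDF5 file (bitwise round-trip)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("neural")
        g.create_dataset("data", data=session.neural)
        g.create_dataset("fs", data=float(session.neural_fs))
        g = f.create_group("kinematics")
        g.create_dataset("data", data=session.kinematics)
        g.create_dataset("fs", data=float(session.kinematic_fs))
        f.attrs["channel_map"] = json.dumps(
            {str(k): v for k, v in session.channel_map.items()}
        )
        f.attrs["meta"] = json.dumps(session.meta)


def read_session(path) -> Session:
    """Read a session file, validating the documented layout."""
    with h5py.File(path, "r") as f:
        for group in ("neural", "kinematics"):
            if group not in f:
                raise SchemaError(f"session file is missing the '{group}' group")
            for ds in ("data", "fs"):
                if ds not in f[group]:
                    raise SchemaError(f"session file is missing '/{group}/{ds}'")
        for attr in ("channel_map", "meta"):
            if attr not in f.attrs:
                raise SchemaError(f"session file is missing the '{attr}' attribute")
        neural = f["neural/data"][()]
        neural_fs = float(f["neural/fs"][()])
        kin = f["kinematics/data"][()]
        kin_fs = float(f["kinematics/fs"][()])
        channel_map = {
            int(k): v for k, v in json.loads(f.attrs["channel_map"]).items()
        }
        meta = json.loads(f.attrs["meta"])
    return Session(
        neural=neural,
        neural_fs=neural_fs,
        kinematics=kin,
        kinematic_fs=kin_fs,
        channel_map=channel_map,
        meta=meta,
    )
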