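"""In-memory containers for the two measurement streams.

A :class:`KinematicStream` holds 3-D positions (mm) of a fixed sensor set on a
shared, uniformly sampled clock; a :class:`ManikinStream` holds the manikin's
compression-depth signal (mm) on its own clock.  Long-form interchange
(``time_s,sensor_id,x_mm,y_mm,z_mm``) is handled by :mod:`cprkinemat.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Sensor channels exported by the simulator (MVN-style joint centres bounding
#: each modeled segment, plus the right-palm contact marker).
KNOWN_SENSORS = (
    "pelvis",
    "c7_th1",
    "l_hip",
    "r_hip",
    "l_knee",
    "r_knee",
    "l_ankle",
    "r_ankle",
    "l_shoulder",
    "r_shoulder",
    "l_elbow",
    "r_elbow",
    "l_wrist",
    "r_wrist",
    "r_palm",
)


@dataclass
class KinematicStream:
    time_s: np.ndarray
    positions: Dict[str, np.ndarray]  # sensor -> (n, 3) array, mm
    sample_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        n = self.time_s.size
        for sensor, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (n, 3):
                raise ValidationError(
                    f"sensor {sensor!r}: expected shape ({n}, 3), got {pos.shape}"
                )
            self.positions[sensor] = pos

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    @property
    def sensors(self) -> list[str]:
        return list(self.positions)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if self.n_frames else 0.0

    def require(self, *sensors: str) -> None:
        missing = [s for s in sensors if s not in self.positions]
        if missing:
            raise ValidationError(f"kinematic stream missing sensors: {missing}")

    def to_frame(self) -> pd.DataFrame:
        """Long-form DataFrame ``time_s,sensor_id,x_mm,y_mm,z_mm``."""
        blocks = []
        for sensor in self.positions:
            pos = self.positions[sensor]
            blocks.append(
                pd.DataFrame(
                    {
                        "time_s": self.time_s,
                        "sensor_id": sensor,
                        "x_mm": pos[:, 0],
                        "y_mm": pos[:, 1],
                        "z_mm": pos[:, 2],
                    }
                )
            )
        out = pd.concat(blocks, ignore_index=True)
        return out.sort_values(["time_s", "sensor_id"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, sample_hz: float | None = None, meta: dict | None = None
    ) -> "KinematicStream":
        """Build from a long-form table; every sensor must share the clock."""
        sensors = list(dict.fromkeys(df["sensor_id"]))
        first = df[df["sensor_id"] == sensors[0]]
        time_s = first["time_s"].to_numpy(dtype=float)
        positions: Dict[str, np.ndarray] = {}
        for sensor in sensors:
            sub = df[df["sensor_id"] == sensor]
            if sub.shape[0] != time_s.size or not np.array_equal(
                sub["time_s"].to_numpy(dtype=float), time_s
            ):
                raise ValidationError(
                    f"sensor {sensor!r} does not share the common time base"
                )
            positions[sensor] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        if sample_hz is None:
            if time_s.size < 2:
                raise ValidationError("cannot infer sample rate from < 2 frames")
            sample_hz = 1.0 / float(np.median(np.diff(time_s)))
        return cls(time_s=time_s, positions=positions, sample_hz=sample_hz,
                   meta=meta or {})


@dataclass
class ManikinStream:
    time_s: np.ndarray
    depth_mm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        if self.time_s.shape != self.depth_mm.shape:
            raise ValidationError("time_s and depth_mm must have equal length")
        if np.any(self.depth_mm < 0):
            raise ValidationError("negative compression depth in manikin stream")

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if self.n_samples else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "depth_mm": self.depth_mm})

    def shifted(self, lag_s: float) -> "ManikinStream":
        """Return a copy with ``lag_s`` subtracted from the clock (aligned)."""
        return ManikinStream(
            time_s=self.time_s - lag_s, depth_mm=self.depth_mm.copy(),
            meta=dict(self.meta),
        )
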