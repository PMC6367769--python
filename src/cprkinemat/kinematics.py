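"""Angular features of the rescuer and the force-decomposition model.

Joint flexion is the angle between adjacent segment axes (0° = straight
limb); trunk inclination is measured above the horizontal plane; the
compression-axis deviation α is the angle between the palm→C7-Th1 line and
the vertical.  The vertical component of a compression force F applied at
deviation α is F·cos(α), so a deviation of 25° already costs ~10% of the
force and reducing it to ~10° restores ~98% of the maximum.

The coordinate frame is manikin-centred: x along the manikin's longitudinal
axis, y lateral, z vertical (up through the sternum compression point).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .streams import KinematicStream

_EPS = 1e-12

#: Maps each segment axis to the (proximal, distal) sensors that bound it,
#: plus the two point sensors used for the compression axis.
DEFAULT_SENSOR_MAP: dict[str, Union[Tuple[str, str], str]] = {
    "l_thigh": ("l_hip", "l_knee"),
    "l_shank": ("l_knee", "l_ankle"),
    "r_thigh": ("r_hip", "r_knee"),
    "r_shank": ("r_knee", "r_ankle"),
    "l_upper_arm": ("l_shoulder", "l_elbow"),
    "l_forearm": ("l_elbow", "l_wrist"),
    "r_upper_arm": ("r_shoulder", "r_elbow"),
    "r_forearm": ("r_elbow", "r_wrist"),
    "trunk": ("pelvis", "c7_th1"),
    "palm": "r_palm",
    "c7": "c7_th1",
}


def _as_vec(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise ValidationError(f"expected 3-vector(s), got shape {v.shape}")
    return v


def flexion_angle(proximal_dir, distal_dir) -> float:
    """Flexion angle, degrees, between a proximal segment axis (proximal→joint)
    and the distal axis (joint→distal).

    Collinear axes (a straight limb) give 0; a right-angle bend gives 90.
    Invariant to rigid rotation of both vectors and positive rescaling of
    either.  Accepts stacked (..., 3) arrays.
    """
    p, d = _as_vec(proximal_dir), _as_vec(distal_dir)
    np_, nd = np.linalg.norm(p, axis=-1), np.linalg.norm(d, axis=-1)
    if np.any(np_ < _EPS) or np.any(nd < _EPS):
        raise ValidationError("flexion_angle: zero-length segment axis")
    cosang = np.clip(np.sum(p * d, axis=-1) / (np_ * nd), -1.0, 1.0)
    out = np.degrees(np.arccos(cosang))
    return float(out) if out.ndim == 0 else out


def trunk_inclination(trunk_axis) -> float:
    """Angle, degrees in [0, 90], between the trunk axis and the horizontal
    (x–y) plane."""
    v = _as_vec(trunk_axis)
    n = np.linalg.norm(v, axis=-1)
    if np.any(n < _EPS):
        raise ValidationError("trunk_inclination: zero-length axis")
    out = np.degrees(np.arcsin(np.clip(np.abs(v[..., 2]) / n, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def compression_axis_deviation(palm_pos, c7_pos) -> float:
    """Deviation α, degrees in [0, 90], of the palm→C7-Th1 line from vertical."""
    p, c = _as_vec(palm_pos), _as_vec(c7_pos)
    d = c - p
    n = np.linalg.norm(d, axis=-1)
    if np.any(n < _EPS):
        raise ValidationError("compression_axis_deviation: coincident points")
    out = np.degrees(np.arccos(np.clip(np.abs(d[..., 2]) / n, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def vertical_force_fraction(alpha) -> float:
    """cos(α): the fraction of a compression force delivered vertically when
    the compression axis deviates α degrees from vertical.  α in [0, 90]."""
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a > 90):
        raise ValidationError("alpha must lie in [0, 90] degrees")
    out = np.cos(np.radians(a))
    return float(out) if out.ndim == 0 else out


@dataclass
class PoseSeries:
    """Per-frame angular features.

    ``frame`` columns: time_s, lkfa, rkfa, lefa, refa, trunk_incl, alpha_dev
    (degrees) plus a boolean ``valid`` flag — frames with undefined geometry
    (a zero-length segment axis) carry NaN angles and valid=False; they are
    flagged, never dropped.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    ANGLE_COLUMNS = ("lkfa", "rkfa", "lefa", "refa", "trunk_incl", "alpha_dev")

    @property
    def n_frames(self) -> int:
        return self.frame.shape[0]

    def window_means(self, t0: float, t1: float) -> dict[str, float]:
        """Mean of each angle over valid frames with time in [t0, t1)."""
        m = (self.frame["time_s"] >= t0) & (self.frame["time_s"] < t1)
        sub = self.frame[m & self.frame["valid"]]
        return {c: float(sub[c].mean()) for c in self.ANGLE_COLUMNS}

    def to_tsv(self, path) -> None:
        cols = ["time_s", *self.ANGLE_COLUMNS]
        self.frame[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def _axis(pos: Mapping[str, np.ndarray], pair: Tuple[str, str]) -> np.ndarray:
    a, b = pair
    return pos[b] - pos[a]


def _angle_between(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized flexion angle with validity mask (no raise on zero axes)."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    ok = (nu > _EPS) & (nv > _EPS)
    cosang = np.full(nu.shape, np.nan)
    np.divide(np.sum(u * v, axis=-1), nu * nv, out=cosang, where=ok)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang, ok


def extract_pose_series(
    stream: KinematicStream,
    sensor_map: Mapping[str, Union[Tuple[str, str], str]] = DEFAULT_SENSOR_MAP,
) -> PoseSeries:
    """Build segment axes from sensor positions and emit all six angles per
    frame.  Raises :class:`ValidationError` naming any sensor the map demands
    but the stream lacks."""
    needed: set[str] = set()
    for spec in sensor_map.values():
        if isinstance(spec, str):
            needed.add(spec)
        else:
            needed.update(spec)
    stream.require(*sorted(needed))
    pos = stream.positions

    valid = np.ones(stream.n_frames, dtype=bool)
    angles: dict[str, np.ndarray] = {}

    for name, prox, dist in (
        ("lkfa", "l_thigh", "l_shank"),
        ("rkfa", "r_thigh", "r_shank"),
        ("lefa", "l_upper_arm", "l_forearm"),
        ("refa", "r_upper_arm", "r_forearm"),
    ):
        ang, ok = _angle_between(
            _axis(pos, sensor_map[prox]), _axis(pos, sensor_map[dist])
        )
        angles[name], valid = ang, valid & ok

    trunk = _axis(pos, sensor_map["trunk"])
    n = np.linalg.norm(trunk, axis=-1)
    ok = n > _EPS
    incl = np.full(n.shape, np.nan)
    np.divide(np.abs(trunk[:, 2]), n, out=incl, where=ok)
    angles["trunk_incl"] = np.degrees(np.arcsin(np.clip(incl, 0.0, 1.0)))
    valid &= ok

    axis = pos[sensor_map["c7"]] - pos[sensor_map["palm"]]
    n = np.linalg.norm(axis, axis=-1)
    ok = n > _EPS
    dev = np.full(n.shape, np.nan)
    np.divide(np.abs(axis[:, 2]), n, out=dev, where=ok)
    angles["alpha_dev"] = np.degrees(np.arccos(np.clip(dev, 0.0, 1.0)))
    valid &= ok

    frame = pd.DataFrame({"time_s": stream.time_s, **angles, "valid": valid})
    return PoseSeries(frame=frame, meta={"sample_hz": stream.sample_hz})
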