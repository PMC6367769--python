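"""Stream synchronization, compression-cycle detection and the per-minute
feature table.

The two devices observe the same physical cycle, so their unknown clock
offset is estimated by maximizing the normalized cross-correlation between
the manikin depth signal and the negated vertical excursion of the palm
sensor.  Features are then windowed per minute: angular/sway features on the
first 30 s of each minute, depth and rate on the full 60 s.  Windows are
half-open [start, end).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import SynchronizationError, ValidationError
from .kinematics import DEFAULT_SENSOR_MAP, extract_pose_series
from .streams import KinematicStream, ManikinStream
from .sway_metrics import (
    ellipse_area_95,
    path_length,
    project_trajectory,
    smooth_trajectory,
)
from .errors import DegenerateTrajectoryError

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = (
    "minute_idx",
    "depth_mm",
    "rate_cpm",
    "pl_mm",
    "ea_mm2",
    "lkfa",
    "rkfa",
    "lefa",
    "refa",
    "trunk_incl",
    "alpha_dev",
    "group",
)


@dataclass
class CompressionCycles:
    """Per-compression peak times (s, aligned clock) and maximum depths (mm)."""

    peak_times_s: np.ndarray
    depths_mm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        if np.any(np.diff(self.peak_times_s) <= 0):
            raise ValidationError("peak times must be strictly increasing")
        if np.any(self.depths_mm < 0):
            raise ValidationError("cycle depths must be non-negative")

    @property
    def n_cycles(self) -> int:
        return self.peak_times_s.size

    def in_window(self, t0: float, t1: float) -> tuple[float, float]:
        """(mean depth, rate in cpm) for peaks in [t0, t1); rate is NaN
        (flagged) when the window holds fewer than two peaks."""
        m = (self.peak_times_s >= t0) & (self.peak_times_s < t1)
        times = self.peak_times_s[m]
        if times.size == 0:
            return float("nan"), float("nan")
        depth = float(self.depths_mm[m].mean())
        if times.size < 2:
            logger.warning("window [%s, %s): <2 peaks, rate undefined", t0, t1)
            return depth, float("nan")
        rate = 60.0 * (times.size - 1) / (times[-1] - times[0])
        return depth, float(rate)


def synchronize(
    kin: KinematicStream,
    man: ManikinStream,
    max_lag_s: float = 5.0,
    min_corr: float = 0.5,
    sensor_map: Mapping = DEFAULT_SENSOR_MAP,
) -> float:
    """Estimate the manikin clock offset (s).

    Returns the lag maximizing the normalized cross-correlation between the
    manikin depth and the negated vertical palm excursion, searched on the
    kinematic sample grid over ±``max_lag_s``.  Subtracting the returned lag
    from the manikin clock aligns the two streams.
    """
    if kin.duration_s < 10.0 or man.duration_s < 10.0:
        raise ValidationError("synchronization needs >= 10 s in both streams")
    palm = sensor_map["palm"]
    kin.require(palm)
    z = kin.positions[palm][:, 2]
    sig = np.max(z) - z  # downward excursion, positive at full compression
    t = kin.time_s
    if np.std(sig) < 1e-9 or np.std(man.depth_mm) < 1e-9:
        raise SynchronizationError("streams do not co-vary; cannot synchronize")

    dt = 1.0 / kin.sample_hz
    n_lag = int(round(max_lag_s / dt))
    lags = np.arange(-n_lag, n_lag + 1) * dt
    best_corr, best_lag = -np.inf, 0.0
    for lag in lags:
        tau = t + lag
        m = (tau >= man.time_s[0]) & (tau <= man.time_s[-1])
        if m.sum() < 2:
            continue
        d = np.interp(tau[m], man.time_s, man.depth_mm)
        s = sig[m]
        sd_d, sd_s = d.std(), s.std()
        if sd_d < 1e-9 or sd_s < 1e-9:
            continue
        corr = float(np.mean((d - d.mean()) * (s - s.mean())) / (sd_d * sd_s))
        if corr > best_corr:
            best_corr, best_lag = corr, float(lag)
    if best_corr < min_corr:
        raise SynchronizationError(
            f"streams do not co-vary; cannot synchronize "
            f"(peak correlation {best_corr:.3f} < {min_corr})"
        )
    logger.info("synchronize: lag %.4f s (corr %.3f)", best_lag, best_corr)
    return best_lag


def detect_cycles(
    man: ManikinStream,
    min_prominence_mm: float = 10.0,
    min_separation_s: float = 0.25,
) -> CompressionCycles:
    """Find compression peaks in the depth signal.

    Peaks need at least ``min_prominence_mm`` prominence and
    ``min_separation_s`` separation; per-peak depth is the local maximum.
    """
    if man.n_samples < 3:
        raise ValidationError("manikin stream too short for cycle detection")
    fs = 1.0 / float(np.median(np.diff(man.time_s)))
    idx, _ = find_peaks(
        man.depth_mm,
        prominence=min_prominence_mm,
        distance=max(1, int(round(min_separation_s * fs))),
    )
    if idx.size == 0:
        logger.warning("detect_cycles: no compression cycles found (flat signal?)")
    return CompressionCycles(
        peak_times_s=man.time_s[idx],
        depths_mm=man.depth_mm[idx],
        meta={"sample_hz": fs, "n_cycles": int(idx.size)},
    )


def group_by_depth(table: pd.DataFrame, threshold_mm: float = 40.0) -> pd.DataFrame:
    """Label every row ``deep`` iff depth_mm >= threshold (boundary inclusive),
    else ``shallow``.  Returns a copy; the labels partition the table."""
    if "depth_mm" not in table.columns:
        raise ValidationError("feature table has no depth_mm column")
    out = table.copy()
    out["group"] = np.where(out["depth_mm"] >= threshold_mm, "deep", "shallow")
    return out


def build_feature_table(
    kin: KinematicStream,
    man: ManikinStream,
    lag_s: Optional[float] = None,
    threshold_mm: float = 40.0,
    kin_window_s: float = 30.0,
    depth_window_s: float = 60.0,
    smooth_window: Optional[int] = None,
    ellipse_method: str = "chi2",
    sensor_map: Mapping = DEFAULT_SENSOR_MAP,
) -> pd.DataFrame:
    """One row per complete minute: sway and angle features over the first
    ``kin_window_s`` seconds of the minute, depth and rate over the full
    minute, plus the depth-threshold group label.

    Incomplete trailing minutes are dropped, never padded.  ``lag_s`` (the
    manikin clock offset) is estimated by :func:`synchronize` when not given.
    """
    if lag_s is None:
        lag_s = synchronize(kin, man, sensor_map=sensor_map)
    aligned = man.shifted(lag_s)
    cycles = detect_cycles(aligned)
    pose = extract_pose_series(kin, sensor_map=sensor_map)
    c7 = kin.positions[sensor_map["c7"]]

    t0 = float(kin.time_s[0])
    # samples are half-open: a stream sampled on [0, T) covers T seconds
    dt_kin = 1.0 / kin.sample_hz
    dt_man = float(np.median(np.diff(aligned.time_s)))
    duration = (
        min(float(kin.time_s[-1]) + dt_kin, float(aligned.time_s[-1]) + dt_man) - t0
    )
    n_minutes = int(np.floor(duration / 60.0 + 1e-9))
    if n_minutes < 1:
        raise ValidationError("streams cover less than one full minute")

    rows = []
    for m in range(n_minutes):
        w0 = t0 + 60.0 * m
        kin_mask = (kin.time_s >= w0) & (kin.time_s < w0 + kin_window_s)
        traj = project_trajectory(c7[kin_mask], plane="horizontal")
        if smooth_window:
            traj = smooth_trajectory(traj, smooth_window)
        pl = path_length(traj)
        try:
            ea = ellipse_area_95(traj, method=ellipse_method).area_mm2
        except DegenerateTrajectoryError:
            logger.warning("minute %d: degenerate C7 trajectory, EA set to NaN", m + 1)
            ea = float("nan")
        depth, rate = cycles.in_window(w0, w0 + depth_window_s)
        angles = pose.window_means(w0, w0 + kin_window_s)
        rows.append(
            {
                "minute_idx": m + 1,
                "depth_mm": depth,
                "rate_cpm": rate,
                "pl_mm": pl,
                "ea_mm2": ea,
                **angles,
            }
        )
    table = pd.DataFrame(rows)
    table = group_by_depth(table, threshold_mm=threshold_mm)
    return table[list(FEATURE_COLUMNS)]
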