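"""Synthetic-data generator.

Two generators live here:

* :func:`generate_trial` — a forward-kinematics simulation of a kneeling
  rescuer compressing a manikin chest.  The nine-segment chain (hands,
  forearms, upper arms, trunk, upper legs — with the lower legs as ground
  contacts) is posed from the configured joint angles; a raised-cosine
  compression cycle, an elliptical C7-Th1 sway, per-minute fatigue drift and
  i.i.d. Gaussian sensor noise are superimposed.  The manikin depth signal is
  the palm's vertical excursion on a clock shifted by the configured offset.

* :func:`generate_feature_table` — a feature-level statistical generator:
  four equicorrelated standardized predictors (rate, PL, LKFA, LEFA) with a
  linear effect on compression depth, the equicorrelation solved so that the
  population explained variance matches the requested R².
"""
from __future__ import annotations

import logging
import math
from dataclasses import replace
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .config import (
    MANIKIN_RESISTANCE_N_PER_CM2,
    PREDICTOR_COLUMNS,
    PosturePose,
    StatsGenConfig,
    TrialConfig,
)
from .errors import GeometryError, ValidationError
from .streams import KinematicStream, ManikinStream

logger = logging.getLogger(__name__)

#: Fixed body-frame offsets, mm.
KNEE_HALF_WIDTH = 100.0
SHOULDER_HALF_WIDTH = 170.0
SHOULDER_DROP = 50.0  # shoulders sit below the C7-Th1 marker
CHEST_HEIGHT = 200.0  # uncompressed sternum height above the floor
HAND_STACK = 30.0  # the left hand rests on top of the right

#: Eccentricity of the C7-Th1 sway ellipse (minor/major axis ratio).
SWAY_AXIS_RATIO = 0.6

_PRESETS = ("correct", "shallow")


def reference_posture(preset: str = "correct") -> PosturePose:
    """Reference postures.

    ``correct`` is the posture reported for rescuers achieving adequate
    compression depth: knee flexion 109° (left) / 97° (right), elbow flexion
    14.1° (left) / 3.7° (right), trunk inclined 23.4° above the horizontal.
    ``shallow`` reduces both knee flexion angles by 8°, the direction
    consistent with the positive LKFA regression coefficient and with keeping
    knee flexion above 90° for effective compressions.
    """
    if preset not in _PRESETS:
        raise ValidationError(
            f"unknown posture preset {preset!r}; valid presets: {_PRESETS}"
        )
    thigh = 450.0  # default upper-leg length, mm
    if preset == "correct":
        lkfa, rkfa = 109.0, 97.0
    else:
        lkfa, rkfa = 101.0, 89.0
    hip_height = thigh * (math.sin(math.radians(lkfa)) + math.sin(math.radians(rkfa))) / 2
    return PosturePose(
        lkfa=lkfa,
        rkfa=rkfa,
        lefa=14.1,
        refa=3.7,
        trunk_incl=23.4,
        hip_height=round(hip_height, 1),
    )


def _two_link_span(l1: float, l2: float, flexion_deg: float) -> float:
    """Shoulder-to-palm distance of a two-link arm bent by ``flexion_deg``."""
    c = math.cos(math.radians(flexion_deg))
    return math.sqrt(l1 * l1 + l2 * l2 + 2.0 * l1 * l2 * c)


def _bend_elbow(shoulder, palm, l1, l2, lateral_sign):
    """Place the elbow of a two-link arm whose ends are given; the elbow
    flares laterally (sign ±1 for left/right)."""
    s = np.asarray(shoulder, dtype=float)
    p = np.asarray(palm, dtype=float)
    w = p - s
    d = np.linalg.norm(w)
    w_hat = w / d
    cos_g = np.clip((l1 * l1 + d * d - l2 * l2) / (2.0 * l1 * d), -1.0, 1.0)
    sin_g = math.sqrt(max(0.0, 1.0 - cos_g * cos_g))
    ref = np.array([lateral_sign, 0.0, 0.0])
    n = ref - np.dot(ref, w_hat) * w_hat
    if np.linalg.norm(n) < 1e-9:
        ref = np.array([0.0, 1.0, 0.0])
        n = ref - np.dot(ref, w_hat) * w_hat
    n /= np.linalg.norm(n)
    return s + l1 * (cos_g * w_hat + sin_g * n)


def solve_chain(
    pose: PosturePose, segment_lengths: Mapping[str, float]
) -> Dict[str, np.ndarray]:
    """Solve the static kneeling chain for all sensor positions (palm at the
    uncompressed chest).

    Geometry: the manikin's sternum compression point is the origin; the
    rescuer kneels on the +y side facing −y, shanks flat on the floor pointing
    away from the manikin.  The body's horizontal placement is the unique
    position at which both shoulder-to-palm distances equal the spans implied
    by the configured elbow flexion angles; if no such placement exists the
    chain cannot reach floor and chest simultaneously.
    """
    seg = segment_lengths
    thigh, shank, trunk = seg["upper_leg"], seg["lower_leg"], seg["trunk"]
    l1, l2 = seg["upper_arm"], seg["forearm"] + seg["hand"]

    lk, rk = math.radians(pose.lkfa), math.radians(pose.rkfa)
    incl = math.radians(pose.trunk_incl)

    # hips relative to knees (shank direction knee→ankle is +y, flat on floor)
    hip_dy = {"l": -thigh * math.cos(lk), "r": -thigh * math.cos(rk)}
    hip_dz = {"l": thigh * math.sin(lk), "r": thigh * math.sin(rk)}
    pelvis_dy = (hip_dy["l"] + hip_dy["r"]) / 2.0
    pelvis_dz = (hip_dz["l"] + hip_dz["r"]) / 2.0
    c7_z = pelvis_dz + trunk * math.sin(incl)
    shoulder_z = c7_z - SHOULDER_DROP

    palm_z = {"r": CHEST_HEIGHT, "l": CHEST_HEIGHT + HAND_STACK}
    span = {"r": _two_link_span(l1, l2, pose.refa),
            "l": _two_link_span(l1, l2, pose.lefa)}
    h2 = {}
    for side in ("l", "r"):
        v = shoulder_z - palm_z[side]
        h2[side] = span[side] ** 2 - v * v
        if h2[side] <= 0.0:
            raise GeometryError(
                "segment chain cannot reach floor and chest simultaneously: "
                f"{side} arm span {span[side]:.1f} mm is shorter than the "
                f"vertical shoulder-to-palm drop {abs(v):.1f} mm"
            )

    # Solve the horizontal body placement: shoulders at x0 ± half-width must
    # sit at the two required horizontal distances from the stacked palms.
    sw = SHOULDER_HALF_WIDTH
    x0 = (h2["l"] - h2["r"]) / (4.0 * sw)  # left shoulder at x0 + sw
    y2 = h2["r"] - (x0 - sw) ** 2
    if y2 <= 0.0:
        raise GeometryError(
            "segment chain cannot reach floor and chest simultaneously: "
            "the two arm spans admit no common shoulder placement"
        )
    shoulder_y = math.sqrt(y2)  # rescuer on the +y side

    c7 = np.array([x0, shoulder_y, c7_z])
    pelvis = c7 + np.array([0.0, trunk * math.cos(incl), 0.0])
    pelvis[2] = pelvis_dz
    knee_y = pelvis[1] - pelvis_dy

    pos: Dict[str, np.ndarray] = {"pelvis": pelvis, "c7_th1": c7}
    for side, sign in (("l", +1.0), ("r", -1.0)):
        knee = np.array([x0 + sign * KNEE_HALF_WIDTH, knee_y, 0.0])
        ankle = knee + np.array([0.0, shank, 0.0])
        hip = knee + np.array([0.0, hip_dy[side], hip_dz[side]])
        shoulder = c7 + np.array([sign * sw, 0.0, -SHOULDER_DROP])
        palm = np.array([0.0, 0.0, palm_z[side]])
        elbow = _bend_elbow(shoulder, palm, l1, l2, lateral_sign=sign)
        fore = palm - elbow
        wrist = elbow + seg["forearm"] * fore / np.linalg.norm(fore)
        pos[f"{side}_knee"] = knee
        pos[f"{side}_ankle"] = ankle
        pos[f"{side}_hip"] = hip
        pos[f"{side}_shoulder"] = shoulder
        pos[f"{side}_elbow"] = elbow
        pos[f"{side}_wrist"] = wrist
        if side == "r":
            pos["r_palm"] = palm
    return pos


def _drifted_pose(pose: PosturePose, drift, minute: int) -> PosturePose:
    if not drift.pose_deg_per_min:
        return pose
    return pose.replace_angles(
        **{k: v * minute for k, v in drift.pose_deg_per_min.items()}
    )


def generate_trial(cfg: TrialConfig) -> tuple[KinematicStream, ManikinStream]:
    """Simulate one trial; identical configs (including seed) give
    bit-identical streams.

    The chain is posed statically (re-posed each minute if pose drift is
    configured); the compression excursion is carried by the palm marker and
    the sway by the C7-Th1 marker, so every configured angle is exactly
    recoverable from noiseless output.
    """
    fs = cfg.sample_hz
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    minute = np.floor(t / 60.0).astype(int)
    f_hz = cfg.rate_cpm / 60.0

    rng = np.random.default_rng(cfg.seed)
    amp = np.clip(cfg.depth_mm + cfg.drift.depth_mm_per_min * minute, 0.0, None)
    # compression-to-compression depth variability (humans are not metronomes;
    # it also makes the clock-offset estimate well-posed for periodic cycles)
    cycle_idx = np.floor(f_hz * t).astype(int)
    n_cycles = int(cycle_idx[-1]) + 1
    jitter = np.clip(
        1.0 + cfg.cycle_jitter_frac * rng.standard_normal(n_cycles), 0.0, None
    )
    excursion = amp * jitter[cycle_idx] * 0.5 * (1.0 - np.cos(2.0 * np.pi * f_hz * t))

    # static chain, re-solved per minute when the pose drifts
    base: Dict[str, np.ndarray] = {}
    if cfg.drift.pose_deg_per_min:
        chains = {
            m: solve_chain(_drifted_pose(cfg.pose, cfg.drift, m), cfg.segment_lengths)
            for m in np.unique(minute)
        }
        sensors = list(next(iter(chains.values())))
        for s in sensors:
            per_min = np.stack([chains[m][s] for m in np.unique(minute)])
            base[s] = per_min[minute]
    else:
        chain = solve_chain(cfg.pose, cfg.segment_lengths)
        for s, p in chain.items():
            base[s] = np.broadcast_to(p, (n, 3)).copy()

    # elliptical C7-Th1 sway at the compression frequency (trunk rocking)
    phase = 2.0 * np.pi * f_hz * t
    base["c7_th1"][:, 0] += cfg.sway_amp_mm * np.sin(phase)
    base["c7_th1"][:, 1] += SWAY_AXIS_RATIO * cfg.sway_amp_mm * np.cos(phase)

    base["r_palm"][:, 2] -= excursion

    if cfg.noise_sd_mm > 0:
        noise = rng.normal(0.0, cfg.noise_sd_mm, size=(len(base), n, 3))
        for i, s in enumerate(base):
            base[s] = base[s] + noise[i]

    meta = {
        "resistance_n_per_cm2": MANIKIN_RESISTANCE_N_PER_CM2,
        "sample_hz": fs,
        "seed": cfg.seed,
        "rate_cpm": cfg.rate_cpm,
        "depth_mm": cfg.depth_mm,
        "noise_sd_mm": cfg.noise_sd_mm,
        "clock_offset_s": cfg.clock_offset_s,
    }
    logger.info(
        "generate_trial: %d frames at %.0f Hz, noise SD %.2f mm, seed %d",
        n, fs, cfg.noise_sd_mm, cfg.seed,
    )
    kin = KinematicStream(time_s=t, positions=base, sample_hz=fs, meta=dict(meta))
    man = ManikinStream(
        time_s=t + cfg.clock_offset_s,
        depth_mm=np.clip(excursion, 0.0, None),
        meta=dict(meta),
    )
    return kin, man


# ---------------------------------------------------------------------------
# feature-level statistical generator


def solve_equicorrelation(beta, r2_target: float) -> float:
    """Solve for the scalar predictor equicorrelation ρ at which the
    population explained variance βᵀRβ = Σβᵢ² + 2ρ·Σ_{i<j}βᵢβⱼ equals the
    target R².  Raises with the attainable R² range when no ρ in (−1/3, 1)
    works (−1/3 is the positive-definiteness bound for four predictors)."""
    b = np.asarray(beta, dtype=float)
    ssq = float(b @ b)
    cross = float((b.sum() ** 2 - ssq) / 2.0)
    if abs(cross) < 1e-12:
        if abs(r2_target - ssq) < 1e-9:
            return 0.0
        raise ValidationError(
            f"predictor cross-terms vanish: attainable R² is exactly {ssq:.4f}"
        )
    rho = (r2_target - ssq) / (2.0 * cross)
    if not -1.0 / 3.0 < rho < 1.0:
        lo, hi = sorted((ssq + 2.0 * (-1.0 / 3.0) * cross, ssq + 2.0 * cross))
        raise ValidationError(
            f"no equicorrelation in (-1/3, 1) yields R²={r2_target}; "
            f"attainable range is ({lo:.4f}, {hi:.4f})"
        )
    return float(rho)


def generate_feature_table(cfg: StatsGenConfig) -> pd.DataFrame:
    """Draw a feature table with known population regression structure.

    Standardized predictors are 4-variate normal with equicorrelation ρ;
    standardized depth = βᵀx + ε with ε ~ N(0, 1 − βᵀRβ), so the population
    standardized coefficients equal cfg.beta and the population R² equals the
    target.  Physical units come from the configured means/SDs.  Columns:
    rate_cpm, pl_mm, lkfa, lefa, depth_mm.
    """
    beta = np.asarray(cfg.beta, dtype=float)
    if cfg.pred_rho is None:
        rho = solve_equicorrelation(beta, cfg.r2_target)
    else:
        rho = float(cfg.pred_rho)
    R = np.full((4, 4), rho)
    np.fill_diagonal(R, 1.0)
    pop_r2 = float(beta @ R @ beta)
    if not 0.0 < pop_r2 < 1.0:
        raise ValidationError(
            f"population R²={pop_r2:.4f} implied by beta and rho is not in (0, 1)"
        )
    logger.info(
        "generate_feature_table: n=%d, solved rho=%.5f, population R2=%.4f, "
        "residual SD (std units)=%.4f",
        cfg.n_rows, rho, pop_r2, math.sqrt(1.0 - pop_r2),
    )
    rng = np.random.default_rng(cfg.seed)
    chol = np.linalg.cholesky(R)
    z = rng.standard_normal((cfg.n_rows, 4)) @ chol.T
    depth_std = z @ beta + rng.normal(0.0, math.sqrt(1.0 - pop_r2), cfg.n_rows)

    table = pd.DataFrame(
        {
            col: cfg.pred_means[j] + cfg.pred_sds[j] * z[:, j]
            for j, col in enumerate(PREDICTOR_COLUMNS)
        }
    )
    table["depth_mm"] = cfg.depth_mean_mm + cfg.depth_sd * depth_std
    table.attrs["solved_rho"] = rho
    table.attrs["population_r2"] = pop_r2
    return table
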