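"""Configuration objects for the simulator, the feature-level generator and runs.

Units are millimetres, degrees, seconds and compressions per minute throughout.
Flexion angles follow the 0° = fully-extended convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Tuple

from .errors import ValidationError

#: Default body-segment lengths, mm.  Chosen for an average adult; the hand is
#: modeled collinear with the forearm (flat on the chest).
DEFAULT_SEGMENT_LENGTHS: dict[str, float] = {
    "hand": 80.0,
    "forearm": 260.0,
    "upper_arm": 300.0,
    "trunk": 500.0,
    "upper_leg": 450.0,
    "lower_leg": 400.0,
}

#: Manikin compression resistance, N/cm^2 (recorded as stream metadata).
MANIKIN_RESISTANCE_N_PER_CM2 = 9.0

_POSE_ANGLE_FIELDS = ("lkfa", "rkfa", "lefa", "refa", "trunk_incl")


@dataclass(frozen=True)
class PosturePose:
    """A kneeling rescuer's static posture.

    lkfa/rkfa: left/right knee flexion, degrees (0 = straight leg).
    lefa/refa: left/right elbow flexion, degrees (0 = straight arm).
    trunk_incl: trunk inclination above the horizontal plane, degrees.
    hip_height: vertical hip-joint height above the floor, mm.  Descriptive:
        the chain solver derives hip height from the leg geometry; this field
        records the value implied by the default segment lengths.
    """

    lkfa: float
    rkfa: float
    lefa: float
    refa: float
    trunk_incl: float
    hip_height: float

    def __post_init__(self) -> None:
        for name in ("lkfa", "rkfa", "lefa", "refa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise ValidationError(f"{name}={v!r} outside [0, 180] degrees")
        if not 0.0 <= self.trunk_incl <= 90.0:
            raise ValidationError(
                f"trunk_incl={self.trunk_incl!r} outside [0, 90] degrees"
            )
        if not self.hip_height > 0:
            raise ValidationError(f"hip_height={self.hip_height!r} must be > 0")

    def replace_angles(self, **deltas: float) -> "PosturePose":
        """Return a copy with additive changes applied to the named angles."""
        values = asdict(self)
        for name, d in deltas.items():
            if name not in _POSE_ANGLE_FIELDS:
                raise ValidationError(f"unknown pose angle {name!r}")
            values[name] += d
        return PosturePose(**values)


@dataclass(frozen=True)
class DriftConfig:
    """Linear per-minute fatigue drift applied by the simulator.

    depth_mm_per_min shifts the nominal compression depth each minute;
    pose_deg_per_min maps pose-angle names to additive degrees per minute.
    """

    depth_mm_per_min: float = 0.0
    pose_deg_per_min: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.pose_deg_per_min:
            if name not in _POSE_ANGLE_FIELDS:
                raise ValidationError(f"unknown pose angle in drift: {name!r}")

    @property
    def is_zero(self) -> bool:
        return self.depth_mm_per_min == 0.0 and not any(
            v != 0.0 for v in self.pose_deg_per_min.values()
        )


@dataclass(frozen=True)
class TrialConfig:
    """Everything that defines one simulated chest-compression trial."""

    pose: PosturePose
    segment_lengths: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_LENGTHS)
    )
    rate_cpm: float = 110.0
    depth_mm: float = 50.0
    duration_s: float = 600.0
    sample_hz: float = 60.0
    noise_sd_mm: float = 2.0
    cycle_jitter_frac: float = 0.05
    sway_amp_mm: float = 10.0
    drift: DriftConfig = field(default_factory=DriftConfig)
    clock_offset_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_cpm <= 0:
            raise ValidationError("rate_cpm must be > 0")
        if self.depth_mm < 0:
            raise ValidationError("depth_mm must be >= 0")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if self.sample_hz < 20:
            raise ValidationError("sample_hz must be >= 20")
        if self.noise_sd_mm < 0:
            raise ValidationError("noise_sd_mm must be >= 0")
        if self.cycle_jitter_frac < 0:
            raise ValidationError("cycle_jitter_frac must be >= 0")
        missing = set(DEFAULT_SEGMENT_LENGTHS) - set(self.segment_lengths)
        if missing:
            raise ValidationError(f"segment_lengths missing {sorted(missing)}")


#: Standardized regression coefficients the feature-level generator is
#: calibrated to, in predictor order (rate, PL, LKFA, LEFA).
TABLE_BETA: Tuple[float, float, float, float] = (
    0.363932,
    -0.293873,
    0.290902,
    -0.239073,
)

#: Column names of the four regression predictors, in calibration order.
PREDICTOR_COLUMNS = ("rate_cpm", "pl_mm", "lkfa", "lefa")


@dataclass(frozen=True)
class StatsGenConfig:
    """Feature-level generator: four equicorrelated predictors with a linear
    effect on depth and residual noise set by the target explained variance.

    If ``pred_rho`` is None the equicorrelation is solved from ``r2_target``;
    an explicit ``pred_rho`` overrides it (the implied R² is then βᵀRβ).
    Physical-unit means/SDs are reporting conventions, not fitted quantities.
    """

    n_rows: int = 10_000
    beta: Tuple[float, float, float, float] = TABLE_BETA
    pred_rho: Optional[float] = None
    r2_target: float = 0.418
    pred_means: Tuple[float, float, float, float] = (110.0, 2600.0, 103.0, 9.0)
    pred_sds: Tuple[float, float, float, float] = (10.0, 700.0, 7.0, 6.0)
    depth_mean_mm: float = 42.0
    depth_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValidationError("n_rows must be >= 1")
        if len(self.beta) != 4:
            raise ValidationError("beta must have exactly four entries")
        if not 0.0 < self.r2_target < 1.0:
            raise ValidationError("r2_target must lie in (0, 1)")
        if self.pred_rho is not None and not -1.0 / 3.0 < self.pred_rho < 1.0:
            raise ValidationError(
                "pred_rho must lie in (-1/3, 1) for a positive-definite "
                "4x4 equicorrelation matrix"
            )
        if any(s <= 0 for s in self.pred_sds) or self.depth_sd <= 0:
            raise ValidationError("all SDs must be > 0")


@dataclass
class RunConfig:
    """End-to-end pipeline run: simulate -> synchronize -> features -> analyze."""

    out_dir: str
    preset: str = "correct"
    duration_s: float = 600.0
    threshold_mm: float = 40.0
    sample_hz: float = 60.0
    noise_sd_mm: float = 2.0
    depth_mm: float = 50.0
    rate_cpm: float = 110.0
    clock_offset_s: float = 0.0
    smooth_window: Optional[int] = None
    ellipse_method: str = "chi2"
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.threshold_mm <= 0:
            raise ValidationError("threshold_mm must be > 0")
        if self.ellipse_method not in ("chi2", "quantile"):
            raise ValidationError("ellipse_method must be 'chi2' or 'quantile'")
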