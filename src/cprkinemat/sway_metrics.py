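"""Postural-sway metrics of the C7-Th1 trajectory, borrowed from
centre-of-pressure posturography: path length (PL) and the area of the 95%
prediction ellipse (EA).

PL is the summed Euclidean length of the projected trajectory; EA is the area
of the ellipse expected to contain 95% of positions under a bivariate-normal
model — semi-axes sqrt(chi2_{0.95,2} * lambda_i) along the eigenvectors of the
sample covariance, area = pi * chi2_{0.95,2} * sqrt(lambda_1 * lambda_2).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateTrajectoryError, ValidationError

PLANES = ("horizontal", "sagittal")

#: chi-square quantile defining the 95% prediction ellipse in 2-D.
CHI2_95_2 = float(stats.chi2.ppf(0.95, df=2))  # 5.991...


@dataclass(frozen=True)
class Trajectory2D:
    """An ordered 2-D trajectory (mm) in a named projection plane."""

    points: np.ndarray  # (n, 2)
    plane: str = "horizontal"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValidationError(
                f"Trajectory2D needs an (n>=1, 2) array, got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError("Trajectory2D: non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class Ellipse95:
    """The 95% prediction ellipse: centre (mm), semi-axes a >= b (mm),
    major-axis orientation (degrees from the u-axis), area (mm^2)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation_deg: float
    area_mm2: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points fall inside (or on) the ellipse."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.center)
        th = np.radians(self.orientation_deg)
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        uv = pts @ rot.T
        a, b = self.semi_axes
        return (uv[:, 0] / a) ** 2 + (uv[:, 1] / b) ** 2 <= 1.0

    def to_dict(self) -> dict:
        return {
            "center_mm": list(self.center),
            "semi_axes_mm": list(self.semi_axes),
            "orientation_deg": self.orientation_deg,
            "area_mm2": self.area_mm2,
        }


def project_trajectory(positions, plane: str = "horizontal") -> Trajectory2D:
    """Project a 3-D point sequence into the manikin's horizontal (x, y) or
    sagittal (x, z) plane, preserving order."""
    if plane not in PLANES:
        raise ValidationError(f"unknown plane {plane!r}; expected one of {PLANES}")
    pts = np.asarray(positions, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] != 3:
        raise ValidationError(f"expected (n, 3) positions, got {pts.shape}")
    cols = (0, 1) if plane == "horizontal" else (0, 2)
    return Trajectory2D(points=pts[:, cols], plane=plane)


def path_length(traj: Trajectory2D) -> float:
    """Total length (mm) of the segments joining consecutive points; 0 for a
    single point.  Additive under concatenation, invariant to rigid motion."""
    if traj.n_points < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(traj.points, axis=0), axis=1)))


def smooth_trajectory(traj: Trajectory2D, window: int) -> Trajectory2D:
    """Centred moving-average smoother (odd window); noise inflates PL, so the
    pipeline can optionally smooth before measuring it."""
    if window < 1 or window % 2 == 0:
        raise ValidationError("smoothing window must be a positive odd integer")
    if window == 1 or traj.n_points < window:
        return traj
    kernel = np.ones(window) / window
    sm = np.column_stack(
        [np.convolve(traj.points[:, j], kernel, mode="valid") for j in range(2)]
    )
    return Trajectory2D(points=sm, plane=traj.plane)


def ellipse_area_95(traj: Trajectory2D, method: str = "chi2") -> Ellipse95:
    """Fit the 95% ellipse of a trajectory's point cloud.

    method='chi2' (default): prediction ellipse scaled by chi2_{0.95,2};
    method='quantile': scaled by the empirical 95th percentile of squared
    Mahalanobis distances, so exactly ~95% of the sample falls inside.
    """
    if method not in ("chi2", "quantile"):
        raise ValidationError(f"unknown ellipse method {method!r}")
    pts = traj.points
    if pts.shape[0] < 3:
        raise DegenerateTrajectoryError("degenerate trajectory: fewer than 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    lam, vec = np.linalg.eigh(cov)
    if lam[0] <= max(1e-12, 1e-12 * lam[1]):
        raise DegenerateTrajectoryError(
            "degenerate trajectory: rank-deficient covariance"
        )
    if method == "chi2":
        scale = CHI2_95_2
    else:
        d = pts - center
        maha = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
        scale = float(np.quantile(maha, 0.95))
    # eigh returns ascending eigenvalues: lam[1] is the major axis.
    a, b = float(np.sqrt(scale * lam[1])), float(np.sqrt(scale * lam[0]))
    major = vec[:, 1]
    orientation = float(np.degrees(np.arctan2(major[1], major[0])))
    return Ellipse95(
        center=(float(center[0]), float(center[1])),
        semi_axes=(a, b),
        orientation_deg=orientation,
        area_mm2=float(np.pi * a * b),
    )
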