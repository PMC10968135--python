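"""Landmark superposition, ascending-aorta region of interest, and growth.

Paired CT exams of one patient are expressed in a common coordinate system by
a rigid (Kabsch) least-squares fit on anatomical correspondences: the aortic
annulus point, the brachiocephalic-trunk centroid, and the right coronary
ostium.  The region of interest (ROI) is the ascending segment between the
annulus (inflow) plane and the plane through the brachiocephalic centroid
oriented along the local centerline tangent; growth is a >= 5 % increase of
the ROI volume between exams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path as FilePath

import numpy as np

from .geometry import (MM3_PER_CM3, Centerline, Plane, TriSurface,
                       clip_by_plane, enclosed_volume)

__all__ = [
    "LandmarkSet",
    "RigidTransform",
    "RoiResult",
    "GrowthCall",
    "fit_rigid_transform",
    "register_landmarks",
    "define_roi",
    "percent_volume_change",
    "classify_growth",
    "GROWTH_THRESHOLD_PCT",
]

#: growth criterion: ROI volume increase of at least this percentage.
GROWTH_THRESHOLD_PCT = 5.0


@dataclass(frozen=True)
class LandmarkSet:
    """Anatomical anchors of one exam, in that exam's frame (mm)."""

    annulus: Plane
    brachiocephalic: np.ndarray
    left_main: np.ndarray
    right_coronary: np.ndarray

    def __post_init__(self):
        for name in ("brachiocephalic", "left_main", "right_coronary"):
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark '{name}' is not finite")
            object.__setattr__(self, name, p)
        if self.annulus.signed_distance(self.brachiocephalic)[0] <= 0:
            raise ValueError("brachiocephalic centroid must lie on the "
                             "positive (distal) side of the annulus plane")

    def correspondence_points(self) -> np.ndarray:
        """The three points used for rigid superposition."""
        return np.vstack([self.annulus.point, self.brachiocephalic,
                          self.right_coronary])

    def transformed(self, transform: "RigidTransform") -> "LandmarkSet":
        r, t = transform.rotation, transform.translation
        return LandmarkSet(self.annulus.transformed(r, t),
                           r @ self.brachiocephalic + t,
                           r @ self.left_main + t,
                           r @ self.right_coronary + t)

    def to_dict(self) -> dict:
        return {"annulus": self.annulus.to_dict(),
                "brachiocephalic": self.brachiocephalic.tolist(),
                "left_main": self.left_main.tolist(),
                "right_coronary": self.right_coronary.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(Plane.from_dict(d["annulus"]),
                   np.asarray(d["brachiocephalic"]),
                   np.asarray(d["left_main"]),
                   np.asarray(d["right_coronary"]))

    def save_json(self, path) -> None:
        FilePath(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path) -> "LandmarkSet":
        return cls.from_dict(json.loads(FilePath(path).read_text()))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("reflections are not rigid motions")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def fit_rigid_transform(src: np.ndarray, dst: np.ndarray
                        ) -> tuple[RigidTransform, float]:
    """Least-squares rigid motion mapping ``src`` onto ``dst`` (Kabsch).

    Returns the transform and the RMS residual in mm.  Requires at least
    three non-collinear correspondence pairs; otherwise the rotation is
    underdetermined and a ``ValueError`` is raised.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    if len(src) < 3:
        raise ValueError("need >= 3 landmark pairs for a rigid fit")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    a, b = src - cs, dst - cd
    scale = max(np.abs(a).max(), 1e-30)
    if np.linalg.matrix_rank(a, tol=1e-9 * scale) < 2:
        raise ValueError("landmarks are collinear or coincident; "
                         "rotation underdetermined")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cd - r @ cs
    transform = RigidTransform(r, t)
    rms = float(np.sqrt(np.mean(np.sum((transform.apply(src) - dst) ** 2,
                                       axis=1))))
    return transform, rms


def register_landmarks(moving: LandmarkSet, fixed: LandmarkSet
                       ) -> tuple[RigidTransform, float]:
    """Rigid transform superposing a moving exam onto the fixed exam."""
    return fit_rigid_transform(moving.correspondence_points(),
                               fixed.correspondence_points())


@dataclass(frozen=True)
class RoiResult:
    roi_mesh: TriSurface
    volume_cm3: float
    theta_deg: float

    def __post_init__(self):
        if not self.volume_cm3 > 0:
            raise ValueError("ROI volume must be positive")
        if not 0.0 < self.theta_deg < 180.0:
            raise ValueError("theta must lie in (0, 180) degrees")


def plane_line_angle_deg(plane: Plane, direction: np.ndarray) -> float:
    """Angle between a plane and a line direction, degrees in (0, 90]."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    return float(np.degrees(np.arcsin(np.clip(abs(u @ plane.normal), 0.0, 1.0))))


def define_roi(mesh: TriSurface, landmarks: LandmarkSet,
               centerline: Centerline) -> RoiResult:
    """Extract the ascending-aorta ROI and its volume.

    Clips by the annulus plane (keeping the distal side, toward the
    brachiocephalic trunk) and then by the plane anchored at the
    brachiocephalic centroid with normal along the centerline tangent at the
    nearest centerline point (keeping the proximal side).  Also reports the
    angle theta between the annulus plane and the line joining the
    brachiocephalic and left-main-coronary centroids.
    """
    proximal = clip_by_plane(mesh, landmarks.annulus, keep="positive")
    s_bct = centerline.nearest_arclength(landmarks.brachiocephalic)
    distal_plane = Plane(landmarks.brachiocephalic, centerline.tangent_at(s_bct))
    if distal_plane.signed_distance(landmarks.annulus.point)[0] > 0:
        # tangent pointing backwards: flip so "negative" is the proximal side
        distal_plane = Plane(distal_plane.point, -distal_plane.normal)
    roi = clip_by_plane(proximal, distal_plane, keep="negative")
    volume = enclosed_volume(roi) / MM3_PER_CM3
    theta = plane_line_angle_deg(landmarks.annulus,
                                 landmarks.brachiocephalic - landmarks.left_main)
    return RoiResult(roi, volume, theta)


def percent_volume_change(v1: float, v2: float) -> float:
    """Percent change of the ROI volume between exams, ``100 (v2-v1)/v1``."""
    if not v1 > 0:
        raise ValueError("baseline volume must be positive")
    return 100.0 * (v2 - v1) / v1


@dataclass(frozen=True)
class GrowthCall:
    v1_cm3: float
    v2_cm3: float
    pct_change: float
    grew: bool
    dt_years: float

    def __post_init__(self):
        if not self.dt_years > 0:
            raise ValueError("dt_years must be positive")


def classify_growth(v1: float, v2: float, dt_years: float,
                    threshold_pct: float = GROWTH_THRESHOLD_PCT) -> GrowthCall:
    """Call aneurysm growth: volume increase of at least ``threshold_pct``.

    The comparison is inclusive: a change of exactly the threshold counts as
    growth.
    """
    if not threshold_pct > 0:
        raise ValueError("threshold_pct must be positive")
    pct = percent_volume_change(v1, v2)
    return GrowthCall(v1, v2, pct, pct >= threshold_pct, dt_years)
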