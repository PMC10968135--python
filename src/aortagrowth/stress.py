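"""Thresholded wall-pressure / wall-shear-stress region statistics.

The hemodynamic predictors of aneurysm growth are area statistics of the
wall fields on the ascending-aorta surface at the first exam:

* the high-pressure region, faces with relative wall pressure >= 100 Pa
  (pressure is reported relative to the inlet ventricular pressure);
* high-shear regions at two literature-derived cutoffs, tau_s >= 5 Pa and
  >= 7 Pa;
* the intersections of each high-shear region with the high-pressure region.

For each region we report the area-weighted mean and the maximum of the
relevant field.  Empty regions yield *missing* values (not zeros), and the
missingness propagates into the cohort statistics with per-metric n, as
happens in real cohorts where some patients have no high-stress overlap.
Thresholds are inclusive (``>=``).  Artificial cap faces produced by ROI
clipping are excluded from every region.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from typing import Optional

import numpy as np

from .geometry import TriSurface

__all__ = [
    "WallFieldSurface",
    "RegionMask",
    "MetricRecord",
    "METRIC_NAMES",
    "threshold_mask",
    "intersect_masks",
    "region_stats",
    "compute_metric_record",
    "stress_load",
    "DEFAULT_PRESSURE_CUT",
    "DEFAULT_WSS_CUTS",
]

DEFAULT_PRESSURE_CUT = 100.0  # Pa
DEFAULT_WSS_CUTS = (5.0, 7.0)  # Pa

#: the ten per-exam stress metrics, in reporting order.
METRIC_NAMES = (
    "P100_mean", "P_max",
    "tau5_mean", "tau7_mean", "tau5_max", "tau7_max",
    "tau5_100_mean", "tau7_100_mean", "tau5_100_max", "tau7_100_max",
)


class WallFieldSurface:
    """A closed wall surface carrying per-face pressure and WSS fields [Pa]."""

    def __init__(self, surface: TriSurface, pressure=None, wss=None):
        p = surface.face_fields.get("pressure") if pressure is None else pressure
        w = surface.face_fields.get("wss") if wss is None else wss
        if p is None or w is None:
            raise ValueError("WallFieldSurface needs 'pressure' and 'wss' fields")
        p = np.asarray(p, dtype=float)
        w = np.asarray(w, dtype=float)
        if len(p) != surface.n_faces or len(w) != surface.n_faces:
            raise ValueError("field length must equal the face count")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(w))):
            raise ValueError("wall fields must be finite")
        if np.any(w < 0):
            raise ValueError("wall shear stress magnitude must be >= 0")
        self.surface = surface
        self.pressure = p
        self.wss = w

    @property
    def wall_faces(self) -> np.ndarray:
        """Indices of genuine wall faces (cut caps excluded)."""
        return np.flatnonzero(~self.surface.cap_mask())


@dataclass(frozen=True)
class RegionMask:
    """A subset of wall faces of one parent surface, with its total area."""

    surface: TriSurface
    indices: np.ndarray
    area_mm2: float

    @classmethod
    def from_indices(cls, surface: TriSurface, indices) -> "RegionMask":
        idx = np.unique(np.asarray(indices, dtype=np.int64))
        if idx.size and (idx[0] < 0 or idx[-1] >= surface.n_faces):
            raise ValueError("mask indices out of range")
        return cls(surface, idx, float(surface.face_areas[idx].sum()))

    @property
    def is_empty(self) -> bool:
        return self.indices.size == 0


def threshold_mask(wfs: WallFieldSurface, field: np.ndarray,
                   cutoff: float) -> RegionMask:
    """Faces whose field value is at or above ``cutoff`` (inclusive)."""
    field = np.asarray(field, dtype=float)
    keep = wfs.wall_faces
    return RegionMask.from_indices(wfs.surface, keep[field[keep] >= cutoff])


def intersect_masks(a: RegionMask, b: RegionMask) -> RegionMask:
    if a.surface is not b.surface:
        raise ValueError("masks belong to different surfaces")
    return RegionMask.from_indices(a.surface,
                                   np.intersect1d(a.indices, b.indices))


def region_stats(field: np.ndarray, mask: RegionMask
                 ) -> tuple[Optional[float], Optional[float]]:
    """Area-weighted mean and maximum of ``field`` over the region.

    Returns ``(None, None)`` for an empty region: an absent region carries no
    value, and the distinction matters downstream (per-metric n).
    """
    if mask.is_empty:
        return None, None
    values = np.asarray(field, dtype=float)[mask.indices]
    areas = mask.surface.face_areas[mask.indices]
    return float(np.sum(areas * values) / np.sum(areas)), float(values.max())


@dataclass(frozen=True)
class MetricRecord:
    """The ten stress metrics of one exam; ``None`` marks an empty region."""

    P100_mean: Optional[float] = None
    P_max: Optional[float] = None
    tau5_mean: Optional[float] = None
    tau7_mean: Optional[float] = None
    tau5_max: Optional[float] = None
    tau7_max: Optional[float] = None
    tau5_100_mean: Optional[float] = None
    tau7_100_mean: Optional[float] = None
    tau5_100_max: Optional[float] = None
    tau7_100_max: Optional[float] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


def compute_metric_record(wfs: WallFieldSurface,
                          p_cut: float = DEFAULT_PRESSURE_CUT,
                          wss_cuts: tuple[float, float] = DEFAULT_WSS_CUTS
                          ) -> MetricRecord:
    """All ten thresholded-region statistics of one field-carrying surface."""
    lo_cut, hi_cut = wss_cuts
    if not lo_cut <= hi_cut:
        raise ValueError("wss_cuts must be (lower, higher)")
    p_mask = threshold_mask(wfs, wfs.pressure, p_cut)
    t_lo = threshold_mask(wfs, wfs.wss, lo_cut)
    t_hi = threshold_mask(wfs, wfs.wss, hi_cut)
    p_mean, p_max = region_stats(wfs.pressure, p_mask)
    lo_mean, lo_max = region_stats(wfs.wss, t_lo)
    hi_mean, hi_max = region_stats(wfs.wss, t_hi)
    lo_i_mean, lo_i_max = region_stats(wfs.wss, intersect_masks(t_lo, p_mask))
    hi_i_mean, hi_i_max = region_stats(wfs.wss, intersect_masks(t_hi, p_mask))
    return MetricRecord(
        P100_mean=p_mean, P_max=p_max,
        tau5_mean=lo_mean, tau7_mean=hi_mean,
        tau5_max=lo_max, tau7_max=hi_max,
        tau5_100_mean=lo_i_mean, tau7_100_mean=hi_i_mean,
        tau5_100_max=lo_i_max, tau7_100_max=hi_i_max,
    )


def stress_load(metric: Optional[float], dt_years: float) -> Optional[float]:
    """Stress load over time: a wall-stress metric times the exam interval.

    Units Pa*years.  A missing metric stays missing.
    """
    if not dt_years > 0:
        raise ValueError("dt_years must be positive")
    if metric is None or (isinstance(metric, float) and np.isnan(metric)):
        return None
    return float(metric) * dt_years
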