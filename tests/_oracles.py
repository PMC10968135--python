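"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the column-sampling
volume oracle rasterizes z-parallel rays on a regular grid instead of using
the closed-form divergence sum, and the per-face metric oracle is an
explicit Python loop instead of vectorized masking.
"""

import numpy as np


def column_volume(vertices: np.ndarray, faces: np.ndarray,
                  pitch: float = 0.1) -> float:
    """Volume of a watertight mesh by z-column sampling at ``pitch``.

    For every (x, y) grid-cell centre, the signed z-heights of all facet
    crossings are accumulated (equivalent to summing the inside z-extents of
    the parity intervals), each weighted by the cell footprint ``pitch^2``.
    Accurate to O(surface_area * pitch).
    """
    tri = vertices[faces]
    lo = vertices.min(axis=0)[:2] - pitch
    hi = vertices.max(axis=0)[:2] + pitch
    nx = int(np.ceil((hi[0] - lo[0]) / pitch))
    ny = int(np.ceil((hi[1] - lo[1]) / pitch))
    xs = lo[0] + (np.arange(nx) + 0.5) * pitch
    ys = lo[1] + (np.arange(ny) + 0.5) * pitch

    total = 0.0
    for t in tri:
        a, b, c = t
        n = np.cross(b - a, c - a)
        if n[2] == 0.0:  # vertical facet: no z-column crossing
            continue
        sign = 1.0 if n[2] > 0 else -1.0
        t2 = t[:, :2]
        ix = np.searchsorted(xs, [t2[:, 0].min(), t2[:, 0].max()])
        iy = np.searchsorted(ys, [t2[:, 1].min(), t2[:, 1].max()])
        gx, gy = np.meshgrid(xs[ix[0]:ix[1]], ys[iy[0]:iy[1]], indexing="ij")
        if gx.size == 0:
            continue
        p = np.stack([gx.ravel(), gy.ravel()], axis=1)
        # barycentric containment in the xy-projection
        d = t2[1:] - t2[0]
        det = d[0, 0] * d[1, 1] - d[0, 1] * d[1, 0]
        rel = p - t2[0]
        u = (rel[:, 0] * d[1, 1] - rel[:, 1] * d[1, 0]) / det
        v = (rel[:, 1] * d[0, 0] - rel[:, 0] * d[0, 1]) / det
        inside = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not inside.any():
            continue
        z = a[2] + u[inside] * (b[2] - a[2]) + v[inside] * (c[2] - a[2])
        total += sign * z.sum()
    return float(total * pitch * pitch)


def naive_metric_record(surface, pressure, wss, p_cut=100.0,
                        wss_cuts=(5.0, 7.0)) -> dict:
    """Loop-over-faces recomputation of the ten stress metrics."""
    areas = surface.face_areas
    cap = surface.cap_mask()

    def region(pred):
        vals, ars = [], []
        for i in range(surface.n_faces):
            if not cap[i] and pred(i):
                vals.append(i)
                ars.append(areas[i])
        return vals

    def stat(field, idx):
        if not idx:
            return None, None
        vals = np.array([field[i] for i in idx])
        ars = np.array([areas[i] for i in idx])
        return float(np.sum(ars * vals) / np.sum(ars)), float(max(vals))

    lo, hi = wss_cuts
    p_idx = region(lambda i: pressure[i] >= p_cut)
    lo_idx = region(lambda i: wss[i] >= lo)
    hi_idx = region(lambda i: wss[i] >= hi)
    lo_i = [i for i in lo_idx if i in set(p_idx)]
    hi_i = [i for i in hi_idx if i in set(p_idx)]
    out = {}
    out["P100_mean"], out["P_max"] = stat(pressure, p_idx)
    out["tau5_mean"], out["tau5_max"] = stat(wss, lo_idx)
    out["tau7_mean"], out["tau7_max"] = stat(wss, hi_idx)
    out["tau5_100_mean"], out["tau5_100_max"] = stat(wss, lo_i)
    out["tau7_100_mean"], out["tau7_100_max"] = stat(wss, hi_i)
    return out
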