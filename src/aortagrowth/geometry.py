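"""Triangulated-surface geometry for aortic volumetry.

The growth analysis rests on a small set of exact mesh operations: enclosed
volume of a closed, outward-oriented triangle surface (divergence theorem),
clipping a closed surface by a plane with planar-fan capping so the result is
again closed, and cross-section "equivalent-area" diameters along a
centerline.  Coordinates are millimetres throughout; volumes are mm^3
internally and converted to cm^3 only at reporting boundaries.

Per-face scalar fields (wall pressure, wall shear stress) travel with the
surface: clipping assigns each child triangle the value of its parent, and
cap triangles are tagged in a dedicated ``"cap"`` field so downstream region
statistics can exclude the artificial cut planes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import numpy as np
import trimesh

__all__ = [
    "Plane",
    "Centerline",
    "TriSurface",
    "CAP_FIELD",
    "enclosed_volume",
    "clip_by_plane",
    "max_diameter",
    "read_surface",
    "write_surface",
]

#: name of the per-face flag marking artificial cap triangles created by
#: plane clipping (1 = cap, 0 = original wall).
CAP_FIELD = "cap"

MM3_PER_CM3 = 1000.0


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point on it and a unit normal (mm)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0.0:
            raise ValueError("plane normal must be a nonzero finite vector")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of ``points`` (positive on the normal side)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Plane":
        return Plane(rotation @ self.point + translation, rotation @ self.normal)

    def to_dict(self) -> dict:
        return {"point": self.point.tolist(), "normal": self.normal.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Plane":
        return cls(np.asarray(d["point"]), np.asarray(d["normal"]))


class Centerline:
    """Ordered vessel-axis polyline with cumulative arclength (mm).

    Points run from the aortic annulus toward the arch.  Tangents are central
    finite differences of the polyline; queries by arclength interpolate
    linearly between samples.
    """

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("centerline needs >= 2 points of dimension 3")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline arclength must be strictly increasing")
        self.points = pts
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: float) -> np.ndarray:
        s = float(np.clip(s, 0.0, self.length))
        out = np.empty(3)
        for k in range(3):
            out[k] = np.interp(s, self.arclength, self.points[:, k])
        return out

    def tangent_at(self, s: float) -> np.ndarray:
        i = int(np.searchsorted(self.arclength, np.clip(s, 0, self.length)))
        lo, hi = max(i - 1, 0), min(i + 1, len(self.points) - 1)
        t = self.points[hi] - self.points[lo]
        return t / np.linalg.norm(t)

    def nearest_arclength(self, point: np.ndarray) -> float:
        """Arclength of the polyline sample closest to ``point``."""
        d = np.linalg.norm(self.points - np.asarray(point, dtype=float), axis=1)
        return float(self.arclength[int(np.argmin(d))])

    def transformed(self, rotation, translation) -> "Centerline":
        return Centerline(self.points @ np.asarray(rotation).T + translation)

    def to_dict(self) -> dict:
        return {"points": self.points.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Centerline":
        return cls(np.asarray(d["points"]))

    def save_json(self, path):
        FilePath(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path) -> "Centerline":
        return cls.from_dict(json.loads(FilePath(path).read_text()))


class TriSurface:
    """Oriented triangulated surface with optional per-face scalar fields.

    Degenerate (zero-area) faces are removed on construction, together with
    their field entries.  ``is_closed`` requires every undirected edge to be
    shared by exactly two faces with opposite directed orientations, i.e. a
    watertight, consistently wound 2-manifold.
    """

    def __init__(self, vertices, faces, face_fields: dict | None = None,
                 area_tol: float = 1e-12):
        v = np.ascontiguousarray(np.asarray(vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.size == 0:
            f = f.reshape(0, 3)
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        fields = {k: np.asarray(a) for k, a in (face_fields or {}).items()}
        for name, arr in fields.items():
            if len(arr) != len(f):
                raise ValueError(
                    f"field '{name}' has {len(arr)} entries for {len(f)} faces")
        # drop degenerate faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        areas = 0.5 * np.linalg.norm(cross, axis=1)
        good = areas > area_tol
        self.vertices = v
        self.faces = f[good]
        self.face_fields = {k: a[good] for k, a in fields.items()}
        self._face_normals_raw = cross[good]
        self._face_areas = areas[good]

    # -- derived quantities -------------------------------------------------

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def face_areas(self) -> np.ndarray:
        """Triangle areas, mm^2."""
        return self._face_areas

    @property
    def face_normals(self) -> np.ndarray:
        """Unit normals following the face winding."""
        return self._face_normals_raw / (2.0 * self._face_areas)[:, None]

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def total_area(self) -> float:
        return float(self._face_areas.sum())

    @property
    def is_closed(self) -> bool:
        if self.n_faces == 0:
            return False
        e = self._directed_edges()
        # every directed edge must appear exactly once and have its reverse
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        if np.any(counts != 1):
            return False
        rev = uniq[:, ::-1]
        order = np.lexsort((uniq[:, 1], uniq[:, 0]))
        rev_order = np.lexsort((rev[:, 1], rev[:, 0]))
        return bool(np.array_equal(uniq[order], rev[rev_order]))

    def _directed_edges(self) -> np.ndarray:
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def signed_volume(self) -> float:
        """Divergence-theorem volume (mm^3); positive for outward winding."""
        v = self.vertices
        t = v[self.faces]
        return float(np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0)

    def oriented(self) -> "TriSurface":
        """Return a copy with outward orientation (signed volume > 0)."""
        if self.signed_volume() < 0:
            return TriSurface(self.vertices, self.faces[:, ::-1], self.face_fields)
        return self

    def transformed(self, rotation, translation) -> "TriSurface":
        r = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return TriSurface(self.vertices @ r.T + t, self.faces, self.face_fields)

    def cap_mask(self) -> np.ndarray:
        """Boolean mask of artificial cap faces (all-False if never clipped)."""
        if CAP_FIELD in self.face_fields:
            return self.face_fields[CAP_FIELD].astype(bool)
        return np.zeros(self.n_faces, dtype=bool)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


def enclosed_volume(mesh: TriSurface) -> float:
    """Volume enclosed by a closed outward-oriented surface, mm^3.

    Uses the divergence theorem: the sum of signed tetrahedra spanned by each
    face and the origin.  Translation/rotation invariant because the surface
    is closed.  Raises on open meshes — cap them (e.g. via
    :func:`clip_by_plane`) first.
    """
    if not mesh.is_closed:
        raise ValueError(
            "enclosed_volume requires a closed surface; cap open boundaries "
            "(clip_by_plane caps its cuts) before measuring volume")
    return mesh.signed_volume()


# -- plane clipping ---------------------------------------------------------


class NonManifoldCutError(ValueError):
    """Raised when the plane cut produces boundary loops that cannot be
    chained (a vertex with more than one outgoing boundary edge)."""


def clip_by_plane(mesh: TriSurface, plane: Plane, keep: str = "negative",
                  atol: float | None = None) -> TriSurface:
    """Clip a closed surface by a plane and cap the cut with planar fans.

    Triangles crossing the plane are split exactly on it; each open boundary
    loop left by the cut is capped with a triangle fan anchored at the loop
    centroid, so the result is closed again.  Child faces inherit their
    parent's per-face field values; cap faces get 0 and are flagged in the
    ``"cap"`` field.

    Parameters
    ----------
    keep:
        ``"positive"`` keeps the half-space the normal points into,
        ``"negative"`` the other one.
    """
    if keep not in ("positive", "negative"):
        raise ValueError("keep must be 'positive' or 'negative'")
    if not mesh.is_closed:
        raise ValueError("clip_by_plane requires a closed surface")
    sign = 1.0 if keep == "positive" else -1.0
    scale = float(np.abs(mesh.vertices).max()) if len(mesh.vertices) else 1.0
    if atol is None:
        atol = 1e-9 * max(1.0, scale)
    d = sign * plane.signed_distance(mesh.vertices)
    d[np.abs(d) < atol] = 0.0

    if np.all(d >= 0):  # wholly kept
        return TriSurface(mesh.vertices, mesh.faces, mesh.face_fields)
    if np.all(d <= 0):
        raise ValueError("plane clips the entire mesh away on the kept side")

    verts = [tuple(p) for p in mesh.vertices]
    cut_cache: dict[tuple[int, int], int] = {}

    def cut_point(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = cut_cache.get(key)
        if idx is None:
            a, b = key
            t = d[a] / (d[a] - d[b])
            p = mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a])
            idx = len(verts)
            verts.append(tuple(p))
            cut_cache[key] = idx
        return idx

    new_faces: list[tuple[int, int, int]] = []
    parents: list[int] = []

    for fi, (a, b, c) in enumerate(mesh.faces):
        dv = (d[a], d[b], d[c])
        if min(dv) >= 0:
            new_faces.append((a, b, c))
            parents.append(fi)
            continue
        if max(dv) <= 0:
            continue
        # Sutherland–Hodgman clip of the triangle against d >= 0
        poly = []
        tri = (a, b, c)
        for k in range(3):
            i, j = tri[k], tri[(k + 1) % 3]
            di, dj = d[i], d[j]
            if di >= 0:
                poly.append(i)
            if (di > 0 and dj < 0) or (di < 0 and dj > 0):
                poly.append(cut_point(i, j))
        if len(poly) < 3:
            continue
        for k in range(1, len(poly) - 1):  # fan triangulation (3 or 4 verts)
            new_faces.append((poly[0], poly[k], poly[k + 1]))
            parents.append(fi)

    clipped = _finalize_clip(mesh, np.asarray(verts), new_faces, parents)
    return clipped


def _finalize_clip(mesh: TriSurface, verts: np.ndarray, faces: list,
                   parents: list) -> TriSurface:
    """Cap boundary loops of the kept sub-surface and assemble fields."""
    faces = np.asarray(faces, dtype=np.int64)
    parents = np.asarray(parents, dtype=np.int64)
    # drop degenerate children before boundary detection
    cross = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                     verts[faces[:, 2]] - verts[faces[:, 0]])
    ok = 0.5 * np.linalg.norm(cross, axis=1) > 1e-12
    faces, parents = faces[ok], parents[ok]

    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    eset = set(map(tuple, edges))
    boundary = [e for e in eset if (e[1], e[0]) not in eset]

    cap_faces: list[tuple[int, int, int]] = []
    verts = list(map(tuple, verts))
    if boundary:
        nxt: dict[int, int] = {}
        for u, vtx in boundary:
            if u in nxt:
                raise NonManifoldCutError(
                    f"non-manifold cut: vertex {u} starts multiple boundary "
                    f"edges ({nxt[u]} and {vtx})")
            nxt[u] = vtx
        seen: set[int] = set()
        for start in list(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = nxt[start]
            while cur != start:
                if cur in seen or cur not in nxt:
                    raise NonManifoldCutError(
                        f"boundary loop through vertex {start} does not close "
                        f"(stuck at vertex {cur})")
                loop.append(cur)
                seen.add(cur)
                cur = nxt[cur]
            centroid = np.mean([verts[i] for i in loop], axis=0)
            ci = len(verts)
            verts.append(tuple(centroid))
            for k in range(len(loop)):
                u, w = loop[k], loop[(k + 1) % len(loop)]
                # reversed so the cap matches the surface winding
                cap_faces.append((ci, w, u))

    all_faces = np.concatenate([faces, np.asarray(cap_faces, dtype=np.int64)
                                .reshape(-1, 3)])
    n_child, n_cap = len(faces), len(cap_faces)

    fields: dict[str, np.ndarray] = {}
    for name, arr in mesh.face_fields.items():
        pad = np.zeros(n_cap, dtype=arr.dtype)
        fields[name] = np.concatenate([arr[parents], pad])
    cap_flag = np.concatenate([
        mesh.face_fields[CAP_FIELD][parents].astype(np.uint8)
        if CAP_FIELD in mesh.face_fields else np.zeros(n_child, dtype=np.uint8),
        np.ones(n_cap, dtype=np.uint8)])
    fields[CAP_FIELD] = cap_flag

    # compact unreferenced vertices
    verts = np.asarray(verts)
    used = np.unique(all_faces)
    remap = np.full(len(verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriSurface(verts[used], remap[all_faces], fields)


# -- cross-section diameters ------------------------------------------------


def max_diameter(mesh: TriSurface, centerline: Centerline,
                 n_stations: int = 50) -> tuple[float, float]:
    """Maximum equivalent-area cross-section diameter along a centerline.

    At each of ``n_stations`` arclength stations the surface is sectioned by
    the plane normal to the local centerline tangent; the diameter is
    ``2*sqrt(A/pi)`` of the section polygon containing the station point.
    Returns ``(diameter_mm, arclength_mm_of_max)``.

    Stations whose plane yields no section enclosing the station point are
    skipped with a warning; if all are skipped an error is raised.
    """
    from shapely.geometry import Point as ShapelyPoint

    if n_stations < 2:
        raise ValueError("n_stations must be >= 2")
    tm = mesh.as_trimesh()
    L = centerline.length
    inset = 1e-3 * L
    stations = np.clip(np.linspace(0.0, L, n_stations), inset, L - inset)
    best = (-np.inf, np.nan)
    n_ok = 0
    for s in stations:
        origin = centerline.point_at(s)
        normal = centerline.tangent_at(s)
        section = tm.section(plane_origin=origin, plane_normal=normal)
        area = np.nan
        if section is not None:
            try:
                planar, to_3d = section.to_2D()
                p2 = np.linalg.inv(to_3d) @ np.append(origin, 1.0)
                pt = ShapelyPoint(p2[:2])
                for poly in planar.polygons_full:
                    if poly.contains(pt):
                        area = poly.area
                        break
            except Exception:  # degenerate section geometry
                area = np.nan
        if not np.isfinite(area):
            warnings.warn(f"station s={s:.2f} mm: no closed section contains "
                          "the centerline point; skipped", stacklevel=2)
            continue
        n_ok += 1
        dia = 2.0 * np.sqrt(area / np.pi)
        if dia > best[0]:
            best = (dia, float(s))
    if n_ok == 0:
        raise ValueError("no station produced a valid cross-section")
    return best


# -- I/O --------------------------------------------------------------------


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = FilePath(path).suffix.lower()
    if suffix == ".stl":
        return "stl"
    if suffix == ".vtk":
        return "vtk"
    raise ValueError(f"cannot infer surface format from '{path}'")


def read_surface(path, fmt: str | None = None) -> TriSurface:
    """Read a surface from STL (ASCII or binary) or legacy VTK polydata.

    VTK ``CELL_DATA`` scalar arrays are attached as per-face fields;
    ``POINT_DATA`` scalars are averaged onto faces.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "stl":
        tm = trimesh.load_mesh(str(path), file_type="stl")
        tm.merge_vertices()
        return TriSurface(tm.vertices, tm.faces)
    if fmt == "vtk":
        from . import vtkio
        return vtkio.read_polydata(path)
    raise ValueError(f"unknown surface format '{fmt}'")


def write_surface(mesh: TriSurface, path, fmt: str | None = None,
                  binary: bool = False) -> None:
    """Write STL (fields dropped) or legacy VTK polydata (fields kept)."""
    fmt = _infer_format(path, fmt)
    if fmt == "stl":
        tm = mesh.as_trimesh()
        tm.export(str(path), file_type="stl" if binary else "stl_ascii")
        return
    if fmt == "vtk":
        from . import vtkio
        vtkio.write_polydata(mesh, path)
        return
    raise ValueError(f"unknown surface format '{fmt}'")
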