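"""Minimal legacy-VTK (ASCII) polydata reader/writer.

Covers exactly the dialect the pipeline exchanges: ``DATASET POLYDATA`` with
``POINTS``, triangle ``POLYGONS``, and named ``SCALARS`` arrays under
``CELL_DATA`` (per-face) or ``POINT_DATA`` (averaged onto faces on read,
matching the per-face field convention of the rest of the package).
Unknown sections raise a parse error naming the offending line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import TriSurface


class VtkParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


class _Tokens:
    """Whitespace tokenizer that remembers the current line number."""

    def __init__(self, path):
        self.path = path
        self.items: list[tuple[str, int]] = []
        with open(path, "r") as fh:
            for lineno, line in enumerate(fh, 1):
                for tok in line.split():
                    self.items.append((tok, lineno))
        self.pos = 0
        self.lineno = 1

    def __bool__(self):
        return self.pos < len(self.items)

    def next(self, expect: str | None = None) -> str:
        if self.pos >= len(self.items):
            raise VtkParseError(self.path, self.lineno, "unexpected end of file")
        tok, self.lineno = self.items[self.pos]
        self.pos += 1
        if expect is not None and tok.upper() != expect:
            raise VtkParseError(self.path, self.lineno,
                                f"expected '{expect}', found '{tok}'")
        return tok

    def next_int(self) -> int:
        tok = self.next()
        try:
            return int(tok)
        except ValueError:
            raise VtkParseError(self.path, self.lineno,
                                f"expected integer, found '{tok}'") from None

    def next_floats(self, n: int) -> np.ndarray:
        out = np.empty(n)
        for i in range(n):
            tok = self.next()
            try:
                out[i] = float(tok)
            except ValueError:
                raise VtkParseError(self.path, self.lineno,
                                    f"expected number, found '{tok}'") from None
        return out


def _read_scalar_block(toks: _Tokens, n: int) -> tuple[str, np.ndarray]:
    name = toks.next()
    toks.next()  # data type (float/double)
    # optional numComponents before LOOKUP_TABLE
    nxt, _ = toks.items[toks.pos]
    if nxt.upper() != "LOOKUP_TABLE":
        toks.next_int()
    toks.next(expect="LOOKUP_TABLE")
    toks.next()  # table name
    return name, toks.next_floats(n)


def read_polydata(path) -> TriSurface:
    """Read triangles plus named scalar fields from legacy ASCII polydata."""
    path = Path(path)
    with open(path, "r") as fh:
        header = fh.readline()
        if not header.startswith("# vtk DataFile"):
            raise VtkParseError(path, 1, "missing '# vtk DataFile' header")
        fh.readline()  # title
        fmt = fh.readline().strip().upper()
        if fmt != "ASCII":
            raise VtkParseError(path, 3, f"only ASCII supported, found '{fmt}'")
        body_start = fh.tell()

    toks = _Tokens(path)
    # skip the three header lines' tokens
    while toks and toks.items[toks.pos][1] <= 3:
        toks.pos += 1
    del body_start

    toks.next(expect="DATASET")
    kind = toks.next()
    if kind.upper() != "POLYDATA":
        raise VtkParseError(path, toks.lineno, f"expected POLYDATA, found '{kind}'")

    vertices = None
    faces = None
    cell_fields: dict[str, np.ndarray] = {}
    point_fields: dict[str, np.ndarray] = {}
    mode = None  # None | ("cell", n) | ("point", n)

    while toks:
        key = toks.next().upper()
        if key == "POINTS":
            n = toks.next_int()
            toks.next()  # dtype
            vertices = toks.next_floats(3 * n).reshape(n, 3)
        elif key == "POLYGONS":
            m = toks.next_int()
            size = toks.next_int()
            flat = np.empty(size, dtype=np.int64)
            for i in range(size):
                flat[i] = toks.next_int()
            faces = []
            i = 0
            while i < size:
                k = flat[i]
                if k != 3:
                    raise VtkParseError(path, toks.lineno,
                                        f"only triangles supported, got {k}-gon")
                faces.append(flat[i + 1:i + 4])
                i += k + 1
            faces = np.asarray(faces)
            if len(faces) != m:
                raise VtkParseError(path, toks.lineno,
                                    f"POLYGONS declares {m} cells, found {len(faces)}")
        elif key == "CELL_DATA":
            mode = ("cell", toks.next_int())
        elif key == "POINT_DATA":
            mode = ("point", toks.next_int())
        elif key == "SCALARS":
            if mode is None:
                raise VtkParseError(path, toks.lineno,
                                    "SCALARS outside CELL_DATA/POINT_DATA")
            name, values = _read_scalar_block(toks, mode[1])
            (cell_fields if mode[0] == "cell" else point_fields)[name] = values
        else:
            raise VtkParseError(path, toks.lineno, f"unsupported section '{key}'")

    if vertices is None or faces is None:
        raise VtkParseError(path, toks.lineno, "missing POINTS or POLYGONS")
    for name, arr in cell_fields.items():
        if len(arr) != len(faces):
            raise VtkParseError(
                path, 0, f"cell field '{name}' has {len(arr)} values for "
                         f"{len(faces)} faces")
    for name, arr in point_fields.items():
        if len(arr) != len(vertices):
            raise VtkParseError(
                path, 0, f"point field '{name}' has {len(arr)} values for "
                         f"{len(vertices)} points")
        cell_fields[name] = arr[faces].mean(axis=1)
    return TriSurface(vertices, faces, cell_fields)


def write_polydata(mesh: TriSurface, path) -> None:
    """Write triangles and per-face scalar fields as legacy ASCII polydata."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("aortagrowth surface\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        m = len(mesh.faces)
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if mesh.face_fields:
            fh.write(f"CELL_DATA {m}\n")
            for name, arr in mesh.face_fields.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{x:.17g}" for x in np.asarray(arr, float)))
                fh.write("\n")
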