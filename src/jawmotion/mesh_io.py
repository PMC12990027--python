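"""Triangle-mesh I/O in the STL standard (binary and ASCII dialects).

STL is the only geometry format the pipeline consumes or produces.
Coordinates are interpreted as millimetres throughout; STL itself carries no
unit metadata, so this is a documented convention of the package.

Reading merges the per-facet vertex triples of the STL "triangle soup" into a
shared vertex table by *exact* coordinate equality, preserving first-occurrence
order.  That exactness matters: duplicated scanner exports of the same arch in
different occlusal positions keep identical vertex ordering, which is what the
corresponded registration fast path relies on.  Facet normals found in the file
are never trusted; they are recomputed from the vertex winding.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np

from .errors import StlFormatError

__all__ = [
    "Correspondence",
    "PoseLabel",
    "TriangleMesh",
    "check_correspondence",
    "read_stl",
    "write_stl",
]

_BINARY_HEADER_BYTES = 80
_BINARY_FACET_BYTES = 50
_BINARY_DTYPE = np.dtype(
    [("normal", "<f4", (3,)), ("corners", "<f4", (3, 3)), ("attr", "<u2")]
)
assert _BINARY_DTYPE.itemsize == _BINARY_FACET_BYTES

PathLike = Union[str, Path]


class PoseLabel(str, Enum):
    """The four static occlusal records the workflow operates on.

    ``MIP`` (maximum intercuspation) doubles as the centric-occlusion record
    for edentulous inputs; the pipeline does not distinguish the two.
    """

    MIP = "MIP"
    RIGHT_LATEROTRUSIVE = "RIGHT_LATEROTRUSIVE"
    LEFT_LATEROTRUSIVE = "LEFT_LATEROTRUSIVE"
    PROTRUSIVE = "PROTRUSIVE"


class Correspondence(str, Enum):
    """Verdict on whether two meshes share vertex ordering and topology."""

    CORRESPONDED = "corresponded"
    UNCORRESPONDED = "uncorresponded"


@dataclass(frozen=True, eq=False)
class TriangleMesh:
    """An indexed triangle mesh: shared vertex table plus facet index triples.

    Parameters
    ----------
    vertices
        ``(n, 3)`` float64 array of point coordinates in millimetres.
    facets
        ``(m, 3)`` integer array of vertex indices, one row per triangle.
    facet_normals
        Optional ``(m, 3)`` array of per-facet unit normals (zero rows are
        allowed, mirroring STL practice for degenerate facets).
    """

    vertices: np.ndarray
    facets: np.ndarray
    facet_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        vertices = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        facets = np.ascontiguousarray(np.asarray(self.facets, dtype=np.int64))
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise ValueError(f"vertices must have shape (n, 3), got {vertices.shape}")
        if facets.ndim != 2 or facets.shape[1] != 3:
            raise ValueError(f"facets must have shape (m, 3), got {facets.shape}")
        if not np.all(np.isfinite(vertices)):
            raise ValueError("vertices contain non-finite coordinates")
        if facets.size and (facets.min() < 0 or facets.max() >= len(vertices)):
            raise ValueError("facet indices out of range of the vertex table")
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "facets", facets)
        if self.facet_normals is not None:
            normals = np.ascontiguousarray(np.asarray(self.facet_normals, dtype=np.float64))
            if normals.shape != (len(facets), 3):
                raise ValueError("facet_normals shape must match facet count")
            norms = np.linalg.norm(normals, axis=1)
            ok = (np.abs(norms - 1.0) <= 1e-6) | (norms == 0.0)
            if not np.all(ok):
                raise ValueError("facet normals must be unit length or zero")
            object.__setattr__(self, "facet_normals", normals)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_facets(self) -> int:
        return len(self.facets)

    def require_usable(self) -> None:
        """Raise unless the mesh is large enough to register (>= 3 vertices, >= 1 facet)."""
        if self.n_vertices < 3 or self.n_facets < 1:
            raise ValueError(
                f"mesh too small to use: {self.n_vertices} vertices, {self.n_facets} facets"
            )

    def computed_normals(self) -> np.ndarray:
        """Per-facet unit normals from vertex winding; zero rows for degenerate facets."""
        tri = self.vertices[self.facets]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        lengths = np.linalg.norm(n, axis=1)
        nz = lengths > 0
        n[nz] /= lengths[nz, None]
        n[~nz] = 0.0
        return n


def _merge_soup(corners: np.ndarray) -> TriangleMesh:
    """Collapse an (m, 3, 3) triangle soup into an indexed mesh.

    Vertices are merged by exact coordinate equality; the shared table keeps
    first-occurrence order so that identical soups produce identical meshes.
    """
    flat = corners.reshape(-1, 3)
    _, first, inverse = np.unique(flat, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first, kind="stable")
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    vertices = flat[np.sort(first)]
    facets = rank[inverse].reshape(-1, 3)
    return TriangleMesh(vertices=vertices, facets=facets)


def _parse_binary(data: bytes) -> TriangleMesh:
    if len(data) < _BINARY_HEADER_BYTES + 4:
        raise StlFormatError(
            f"binary STL too short: {len(data)} bytes, need at least 84"
        )
    (count,) = struct.unpack_from("<I", data, _BINARY_HEADER_BYTES)
    expected = _BINARY_HEADER_BYTES + 4 + _BINARY_FACET_BYTES * count
    if len(data) != expected:
        raise StlFormatError(
            f"binary STL length mismatch: header declares {count} facets "
            f"({expected} bytes) but file has {len(data)} bytes"
        )
    if count == 0:
        raise StlFormatError("binary STL declares zero facets")
    records = np.frombuffer(data, dtype=_BINARY_DTYPE, count=count, offset=84)
    corners = records["corners"].astype(np.float64)
    if not np.all(np.isfinite(corners)):
        raise StlFormatError("binary STL contains non-finite vertex coordinates")
    return _merge_soup(corners)


def _parse_ascii(text: str) -> TriangleMesh:
    # Token-per-line state machine; accepts arbitrary solid names, blank lines
    # and scientific notation.  Errors report the 1-based line number.
    lines = text.splitlines()
    corners: list[list[float]] = []
    state = "solid"
    triangle: list[list[float]] = []

    def fail(lineno: int, msg: str) -> StlFormatError:
        return StlFormatError(f"ASCII STL parse error at line {lineno}: {msg}")

    for lineno, raw in enumerate(lines, start=1):
        tokens = raw.split()
        if not tokens:
            continue
        keyword = tokens[0].lower()
        if state == "solid":
            if keyword != "solid":
                raise fail(lineno, f"expected 'solid', got {tokens[0]!r}")
            state = "facet"
        elif state == "facet":
            if keyword == "facet":
                if len(tokens) < 2 or tokens[1].lower() != "normal":
                    raise fail(lineno, "expected 'facet normal nx ny nz'")
                state = "loop"
            elif keyword == "endsolid":
                state = "done"
            else:
                raise fail(lineno, f"expected 'facet' or 'endsolid', got {tokens[0]!r}")
        elif state == "loop":
            if keyword != "outer" or len(tokens) < 2 or tokens[1].lower() != "loop":
                raise fail(lineno, "expected 'outer loop'")
            triangle = []
            state = "vertex"
        elif state == "vertex":
            if keyword == "vertex":
                if len(tokens) != 4:
                    raise fail(lineno, "vertex needs exactly 3 coordinates")
                try:
                    triangle.append([float(t) for t in tokens[1:]])
                except ValueError as exc:
                    raise fail(lineno, f"bad coordinate: {exc}") from None
                if len(triangle) > 3:
                    raise fail(lineno, "more than 3 vertices in a facet")
            elif keyword == "endloop":
                if len(triangle) != 3:
                    raise fail(lineno, f"facet has {len(triangle)} vertices, expected 3")
                corners.append(triangle)
                state = "endfacet"
            else:
                raise fail(lineno, f"expected 'vertex' or 'endloop', got {tokens[0]!r}")
        elif state == "endfacet":
            if keyword != "endfacet":
                raise fail(lineno, f"expected 'endfacet', got {tokens[0]!r}")
            state = "facet"
        elif state == "done":
            raise fail(lineno, "content after 'endsolid'")
    if state != "done":
        raise StlFormatError(
            f"ASCII STL parse error at line {len(lines)}: unexpected end of file "
            f"(parser state {state!r})"
        )
    if not corners:
        raise StlFormatError("ASCII STL contains no facets")
    # quantize through float32 so both dialects read back bit-identically
    soup = np.asarray(corners, dtype=np.float64).astype(np.float32).astype(np.float64)
    return _merge_soup(soup)


def read_stl(path: PathLike) -> TriangleMesh:
    """Read an STL file, auto-detecting the ASCII vs binary dialect.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    StlFormatError
        On an empty file, a truncated binary payload, or an ASCII parse
        failure (the message carries the offending line number).
    """
    data = Path(path).read_bytes()
    if len(data) == 0:
        raise StlFormatError(f"{path}: empty file is not a valid STL")
    if data[:5].lower() == b"solid":
        text = data.decode("utf-8", errors="replace")
        try:
            return _parse_ascii(text)
        except StlFormatError as ascii_err:
            # A binary file may legitimately start with "solid" in its header;
            # if neither dialect parses, the ASCII diagnosis is the useful one.
            try:
                return _parse_binary(data)
            except StlFormatError:
                raise ascii_err from None
    return _parse_binary(data)


def write_stl(mesh: TriangleMesh, path: PathLike, dialect: str = "binary") -> None:
    """Write ``mesh`` to ``path`` in the requested STL dialect.

    Both dialects quantize coordinates to float32 (the binary dialect's native
    precision) so that the same mesh written either way reads back identically.
    Normals are recomputed from winding, never taken from ``facet_normals``.
    """
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    mesh.require_usable()
    corners32 = mesh.vertices[mesh.facets].astype(np.float32)
    normals32 = mesh.computed_normals().astype(np.float32)
    path = Path(path)
    if dialect == "binary":
        records = np.zeros(mesh.n_facets, dtype=_BINARY_DTYPE)
        records["normal"] = normals32
        records["corners"] = corners32
        header = b"jawmotion binary STL".ljust(_BINARY_HEADER_BYTES, b" ")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", mesh.n_facets))
            fh.write(records.tobytes())
    else:
        # {:.9g} round-trips float32 exactly.
        def fmt(v: np.ndarray) -> str:
            return " ".join(f"{float(c):.9g}" for c in v)

        out = ["solid jawmotion"]
        for normal, tri in zip(normals32, corners32):
            out.append(f"  facet normal {fmt(normal)}")
            out.append("    outer loop")
            for corner in tri:
                out.append(f"      vertex {fmt(corner)}")
            out.append("    endloop")
            out.append("  endfacet")
        out.append("endsolid jawmotion")
        path.write_text("\n".join(out) + "\n", encoding="ascii")


def check_correspondence(a: TriangleMesh, b: TriangleMesh) -> Correspondence:
    """Decide whether two meshes share per-vertex correspondence.

    Corresponded means equal vertex and facet counts *and* identical facet
    index triples — the topology is untouched, so vertex ``i`` in one mesh is
    the same physical point as vertex ``i`` in the other.  Rigid motion
    preserves this; remeshing or decimation breaks it.
    """
    if a.n_vertices != b.n_vertices or a.n_facets != b.n_facets:
        return Correspondence.UNCORRESPONDED
    if not np.array_equal(a.facets, b.facets):
        return Correspondence.UNCORRESPONDED
    return Correspondence.CORRESPONDED
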