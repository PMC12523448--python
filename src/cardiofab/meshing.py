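"""Label map -> watertight surface meshes, and STL input/output.

Surfaces are extracted per substructure by marching cubes at iso-level
0.5 on the binary mask, with vertices scaled to millimetres (the only
unit in mesh space; the voxel->mm conversion happens exactly once,
here).  Optional Laplacian smoothing rescales the result about its
centroid so the enclosed volume is preserved.

STL is written and read at byte level: the binary dialect is the
standard 80-byte header + uint32 facet count + 50-byte facet records
(little-endian); parse failures report the offending byte offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh

from .anatomy import SubstructureID, substructure
from .phantom import LabeledVolume

__all__ = ["SurfaceMesh", "STLParseError", "extract_mesh", "write_stl", "read_stl"]

log = logging.getLogger(__name__)


class STLParseError(ValueError):
    """Corrupt or truncated STL file; message carries the byte offset."""


@dataclass
class SurfaceMesh:
    """A triangulated surface in millimetres.

    Invariants for meshes produced by :func:`extract_mesh`: watertight
    (every edge shared by exactly two faces), outward orientation
    (signed volume > 0), no degenerate faces.
    """

    vertices: np.ndarray
    faces: np.ndarray
    substructure: SubstructureID | None = None
    units: str = "mm"

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, sub=None) -> "SurfaceMesh":
        return cls(vertices=np.asarray(tm.vertices, dtype=np.float64),
                   faces=np.asarray(tm.faces, dtype=np.int64),
                   substructure=sub)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @property
    def volume(self) -> float:
        """Signed enclosed volume, mm^3 (positive when outward-oriented)."""
        v = self.vertices
        t = v[self.faces]
        return float(np.einsum("ij,ij->i", t[:, 0],
                               np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    @property
    def area(self) -> float:
        t = self.vertices[self.faces]
        return float(np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1).sum() / 2.0)

    @property
    def is_watertight(self) -> bool:
        return self.to_trimesh().is_watertight

    @property
    def euler_number(self) -> int:
        return int(self.to_trimesh().euler_number)


def _laplacian_smooth(vertices: np.ndarray, faces: np.ndarray,
                      iterations: int, lam: float = 0.5) -> np.ndarray:
    """Umbrella-operator smoothing with volume restoration.

    After the requested iterations the mesh is rescaled about its
    centroid so the enclosed volume matches the input exactly, which
    bounds the volume drift of the overall operation at zero while the
    surface area still decreases on convex shapes.
    """
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    n = len(vertices)
    deg = np.bincount(edges.reshape(-1), minlength=n).astype(np.float64)

    def vol(v):
        t = v[faces]
        return np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0

    v0 = vol(vertices)
    v = vertices.copy()
    for _ in range(iterations):
        acc = np.zeros_like(v)
        np.add.at(acc, edges[:, 0], v[edges[:, 1]])
        np.add.at(acc, edges[:, 1], v[edges[:, 0]])
        v += lam * (acc / deg[:, None] - v)
    c = v.mean(axis=0)
    v1 = vol(v)
    if v1 > 0 and v0 > 0:
        v = c + (v - c) * (v0 / v1) ** (1.0 / 3.0)
    return v


def extract_mesh(volume: LabeledVolume, key, smoothing_iters: int = 10) -> SurfaceMesh:
    """Extract the watertight surface of one substructure, in mm.

    The binary mask is padded by one voxel on every side (masks touching
    the grid boundary are thereby closed; this is logged), marching
    cubes runs at iso-level 0.5, vertices are scaled by the voxel
    spacing, and optional volume-preserving Laplacian smoothing is
    applied.
    """
    from skimage import measure

    sub = substructure(key)
    mask = volume.labels == sub.code
    if not mask.any():
        raise ValueError(f"label {sub.abbrev} (code {sub.code}) absent from volume")
    touches = (mask[0].any() or mask[-1].any() or mask[:, 0].any()
               or mask[:, -1].any() or mask[:, :, 0].any() or mask[:, :, -1].any())
    if touches:
        log.info("%s mask touches the grid boundary; padding before extraction",
                 sub.abbrev)
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=volume.spacing)
    verts = verts - np.asarray(volume.spacing)  # undo the pad offset
    verts = verts[:, ::-1]  # volume axes are (z, y, x); meshes use (x, y, z)
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if tm.volume < 0:
        tm.invert()
    verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    if smoothing_iters > 0:
        verts = _laplacian_smooth(verts, faces, smoothing_iters)
    return SurfaceMesh(vertices=verts, faces=faces, substructure=sub)


_BIN_FACET = np.dtype([
    ("normal", "<f4", (3,)),
    ("v", "<f4", (3, 3)),
    ("attr", "<u2"),
])


def write_stl(mesh: SurfaceMesh, path, mode: str = "binary") -> None:
    """Write an STL file (binary: 80-byte header, uint32 count, 50-byte
    facet records; ascii: the ``solid``/``facet`` dialect)."""
    if mode not in ("binary", "ascii"):
        raise ValueError("mode must be 'binary' or 'ascii'")
    tris = mesh.vertices[mesh.faces].astype(np.float32)
    n = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    name = mesh.substructure.abbrev if mesh.substructure else "mesh"
    if mode == "binary":
        rec = np.zeros(len(tris), dtype=_BIN_FACET)
        rec["normal"] = n
        rec["v"] = tris
        header = f"cardiofab {name} (units: mm)".encode().ljust(80, b"\0")[:80]
        with open(path, "wb") as f:
            f.write(header)
            f.write(np.uint32(len(tris)).tobytes())
            f.write(rec.tobytes())
    else:
        lines = [f"solid {name}"]
        for ni, ti in zip(n, tris):
            lines.append(f"  facet normal {ni[0]:.9e} {ni[1]:.9e} {ni[2]:.9e}")
            lines.append("    outer loop")
            for v in ti:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {name}")
        with open(path, "w") as f:
            f.write("\n".join(lines) + "\n")


def read_stl(path, sub=None) -> SurfaceMesh:
    """Read a binary or ASCII STL file back into a :class:`SurfaceMesh`.

    Duplicate vertices are merged so the topology (watertightness,
    Euler characteristic) is recovered.  Corrupt files raise
    :class:`STLParseError` with the byte offset of the failure.
    """
    with open(path, "rb") as f:
        data = f.read()
    if len(data) >= 5 and data[:5] == b"solid":
        try:
            text = data.decode("ascii")
            if "facet" in text or text.strip().splitlines()[-1].startswith("endsolid"):
                return _read_ascii(text, sub)
        except UnicodeDecodeError:
            pass
    if len(data) < 84:
        raise STLParseError(
            f"binary STL needs 84 header bytes, file ends at offset {len(data)}")
    count = int(np.frombuffer(data[80:84], dtype="<u4")[0])
    expected = 84 + 50 * count
    if len(data) < expected:
        raise STLParseError(
            f"facet count {count} implies {expected} bytes, "
            f"file truncated at offset {len(data)}")
    rec = np.frombuffer(data[84:expected], dtype=_BIN_FACET)
    tris = rec["v"].astype(np.float64)
    return _from_triangle_soup(tris, sub)


def _read_ascii(text: str, sub) -> SurfaceMesh:
    tris = []
    cur = []
    for lineno, line in enumerate(text.splitlines(), 1):
        parts = line.split()
        if parts and parts[0] == "vertex":
            if len(parts) != 4:
                raise STLParseError(f"malformed vertex on line {lineno}")
            cur.append([float(x) for x in parts[1:]])
            if len(cur) == 3:
                tris.append(cur)
                cur = []
    if cur:
        raise STLParseError("dangling vertices at end of ascii STL")
    return _from_triangle_soup(np.asarray(tris, dtype=np.float64), sub)


def _from_triangle_soup(tris: np.ndarray, sub) -> SurfaceMesh:
    flat = tris.reshape(-1, 3)
    tm = trimesh.Trimesh(vertices=flat,
                         faces=np.arange(len(flat)).reshape(-1, 3),
                         process=True)  # merges duplicate vertices
    return SurfaceMesh.from_trimesh(tm, sub)
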