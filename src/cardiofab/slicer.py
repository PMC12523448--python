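"""STL -> embedded-printing G-code.

Planar slicing at mid-layer heights, concentric (inward-offset) infill,
deterministic path ordering, and catalyst-ink extrusion accounting.  In
embedded printing the deposit is held by the support matrix, so no
support structures, brims or retractions are ever generated; the
preamble lifts the platform to a clearance height so the needle cannot
collide with the matrix container while homing, and the postamble
restores it.

Ink accounting: a track of length L has volume L x line_width x
layer_height; the dispensed catalyst ink is ``extrusion_rate`` times the
track volume (4% by default), so the construct:ink volumetric ratio is
the reciprocal of the extrusion rate (25:1 at 4%).  The G-code E axis
carries cumulative ink volume in mm^3 (declared in the header comment).

All emitted coordinates are quantized to the printed precision before
any totals are accumulated, so re-simulating the program text
reproduces the totals exactly.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

__all__ = ["SliceParams", "SliceLayer", "GCodeProgram", "slice_mesh",
           "concentric_infill", "emit_gcode", "resimulate"]

#: default ink reservoir capacity, mm^3 (0.1 L; syringe reservoirs in
#: embedded printing are typically below 100 mL)
RESERVOIR_CAPACITY_MM3 = 100_000.0


@dataclass(frozen=True)
class SliceParams:
    """Printing parameters (defaults follow the study's settings)."""

    layer_height: float = 0.4
    line_width: float = 0.3
    infill_density: float = 1.0
    extrusion_rate: float = 0.04
    print_speed: float = 15.0
    infill_pattern: str = "concentric"
    clearance_z: float = 80.0
    container_height: float = 60.0

    def __post_init__(self):
        if min(self.layer_height, self.line_width, self.print_speed,
               self.clearance_z) <= 0:
            raise ValueError("layer_height, line_width, print_speed and "
                             "clearance_z must be positive")
        if not 0.0 < self.infill_density <= 1.0:
            raise ValueError("infill_density must be in (0, 1]")
        if not 0.0 < self.extrusion_rate < 1.0:
            raise ValueError("extrusion_rate must be in (0, 1)")
        if self.infill_pattern != "concentric":
            raise ValueError("only concentric infill is implemented")


@dataclass
class SliceLayer:
    """One layer: perimeter polygons (with hole nesting) and infill loops.

    Perimeter exteriors are counter-clockwise, holes clockwise; every
    ring is closed (first point equals last).  Infill loops lie strictly
    inside the perimeters.
    """

    z: float
    polygons: list[Polygon]
    infill: list[np.ndarray] = field(default_factory=list)

    def perimeter_rings(self) -> list[np.ndarray]:
        rings = []
        for poly in self.polygons:
            rings.append(np.asarray(poly.exterior.coords))
            for hole in poly.interiors:
                rings.append(np.asarray(hole.coords))
        return rings


def _rings_to_polygons(rings: list[np.ndarray]) -> list[Polygon]:
    """Assemble closed 2D rings into polygons by even-odd containment."""
    shells = [Polygon(r) for r in rings if len(r) >= 4]
    shells = [p if p.is_valid else p.buffer(0) for p in shells]
    shells = [p for p in shells if not p.is_empty and p.area > 0]
    from shapely.geometry import Point

    # test containment with a boundary vertex: the filled shell of an
    # outer ring would wrongly report itself inside its own holes
    probes = [Point(p.exterior.coords[0]) for p in shells]
    depth = []
    for i, p in enumerate(shells):
        d = sum(1 for j, q in enumerate(shells) if i != j and q.contains(probes[i]))
        depth.append(d)
    outers = [i for i, d in enumerate(depth) if d % 2 == 0]
    holes: dict[int, list[int]] = {i: [] for i in outers}
    for i, d in enumerate(depth):
        if d % 2 == 1:
            candidates = [j for j in outers if shells[j].contains(probes[i])]
            if candidates:
                holes[min(candidates, key=lambda j: shells[j].area)].append(i)
    out = []
    for i in outers:
        poly = Polygon(shells[i].exterior,
                       [shells[j].exterior for j in holes[i]])
        out.append(orient(poly, 1.0))  # exterior CCW, holes CW
    return out


def slice_mesh(mesh, params: SliceParams) -> list[SliceLayer]:
    """Cross-section a watertight mesh at mid-layer heights.

    Sections are taken at ``z_min + (k + 0.5) * layer_height`` for
    ``k = 0 .. ceil((z_max - z_min)/h) - 1``; layers whose section is
    empty are skipped.
    """
    tm = mesh.to_trimesh() if hasattr(mesh, "to_trimesh") else mesh
    if not tm.is_watertight:
        edges = tm.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        n_open = int((counts != 2).sum())
        raise ValueError(f"mesh is not watertight ({n_open} non-manifold or "
                         "open edges); cannot slice")
    h = params.layer_height
    zmin, zmax = float(tm.bounds[0][2]), float(tm.bounds[1][2])
    n_layers = max(1, math.ceil((zmax - zmin) / h - 1e-9))
    layers = []
    for k in range(n_layers):
        z = zmin + (k + 0.5) * h
        sec = tm.section(plane_origin=(0.0, 0.0, z), plane_normal=(0.0, 0.0, 1.0))
        if sec is None:
            continue
        rings = [np.asarray(d)[:, :2] for d in sec.discrete]
        polys = _rings_to_polygons(rings)
        if polys:
            layers.append(SliceLayer(z=z, polygons=polys))
    return layers


def concentric_infill(layer: SliceLayer, params: SliceParams) -> list[np.ndarray]:
    """Concentric infill: successive inward offsets of each perimeter.

    The first loop sits one line width inside the perimeter and
    subsequent loops ``line_width / infill_density`` further in, until
    the offset region vanishes.  The loops are stored on the layer and
    returned.
    """
    lw = params.line_width
    spacing = lw / params.infill_density
    loops: list[np.ndarray] = []
    for poly in layer.polygons:
        if not poly.is_valid:
            raise ValueError(f"self-intersecting perimeter at z={layer.z:.3f}")
        k = 0
        while True:
            inset = lw + k * spacing
            inner = poly.buffer(-inset, join_style=2)
            if inner.is_empty or inner.area <= 0:
                break
            parts = getattr(inner, "geoms", [inner])
            for part in parts:
                part = orient(part, 1.0)
                loops.append(np.asarray(part.exterior.coords))
                for hole in part.interiors:
                    loops.append(np.asarray(hole.coords))
            k += 1
            if k > 100000:  # safety; cannot trigger for positive widths
                raise RuntimeError("offset recursion did not terminate")
    layer.infill = loops
    return loops


@dataclass
class GCodeProgram:
    """An ordered G-code program plus its extrusion accounting."""

    lines: list[str]
    path_length_mm: float
    track_volume_mm3: float
    ink_volume_mm3: float
    n_layers: int

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"

    @property
    def construct_ink_ratio(self) -> float:
        return self.track_volume_mm3 / self.ink_volume_mm3


def _q(x: float) -> float:
    """Quantize a coordinate to the printed precision (4 decimals)."""
    return round(float(x), 4)


def _seam_start(ring: np.ndarray) -> np.ndarray:
    """Rotate a closed ring to start at its lowest-then-leftmost vertex."""
    pts = ring[:-1]  # drop duplicate closing point
    i = int(np.lexsort((pts[:, 0], pts[:, 1]))[0])
    rolled = np.roll(pts, -i, axis=0)
    return np.vstack([rolled, rolled[:1]])


def emit_gcode(layers: list[SliceLayer], params: SliceParams,
               name: str = "model",
               reservoir_capacity_mm3: float = RESERVOIR_CAPACITY_MM3) -> GCodeProgram:
    """Generate the printing program for pre-sliced, infilled layers.

    Within each layer, each island prints outermost-to-innermost
    (perimeter, then infill loops inward); islands are visited in
    nearest-neighbour order from the previous position.  Travel moves
    are non-extruding G0; extruding moves are G1 with
    ``F = print_speed * 60`` and cumulative ink volume in E.
    """
    if not layers or all(not ly.polygons for ly in layers):
        raise ValueError("need at least one nonempty layer")
    if params.clearance_z < params.container_height:
        raise ValueError(
            f"clearance_z {params.clearance_z} mm is below the matrix "
            f"container height {params.container_height} mm; homing would "
            "drive the needle into the container")
    lw, lh, rate = params.line_width, params.layer_height, params.extrusion_rate
    feed = params.print_speed * 60.0
    lines = [
        f"; cardiofab embedded-print program: {name}",
        "; E axis: cumulative catalyst ink volume, mm^3",
        f"; line_width {lw:.4f} layer_height {lh:.4f} "
        f"extrusion_rate {rate:.4f} print_speed {params.print_speed:.4f}",
        "G21 ; millimetres",
        "G90 ; absolute coordinates",
        f"G1 Z{_q(params.clearance_z)} F600 ; lift platform clear of the container",
        "G28 X Y ; home in-plane axes",
        "G92 E0 ; zero ink counter",
    ]
    e = 0.0
    path_len = 0.0
    track_vol = 0.0
    pos = np.array([0.0, 0.0])
    for ly in layers:
        lines.append(f"; layer z {_q(ly.z)}")
        islands = []
        for poly in ly.polygons:
            rings = [np.asarray(poly.exterior.coords)]
            rings += [np.asarray(h.coords) for h in poly.interiors]
            own = [lp for lp in ly.infill
                   if poly.buffer(1e-6).contains(Polygon(lp).representative_point())]
            islands.append(rings + own)
        # nearest-neighbour island order from the previous position
        order = []
        remaining = list(range(len(islands)))
        cur = pos
        while remaining:
            dists = [np.linalg.norm(np.asarray(islands[i][0][0]) - cur)
                     for i in remaining]
            nxt = remaining[int(np.argmin(dists))]
            order.append(nxt)
            remaining.remove(nxt)
            cur = np.asarray(islands[nxt][0][0])
        z = _q(ly.z)
        for i in order:
            for ring in islands[i]:
                ring = _seam_start(ring)
                start = ring[0]
                lines.append(f"G0 X{_q(start[0])} Y{_q(start[1])} Z{z}")
                pos = np.array([_q(start[0]), _q(start[1])])
                for pt in ring[1:]:
                    x, y = _q(pt[0]), _q(pt[1])
                    seg = math.hypot(x - pos[0], y - pos[1])
                    if seg == 0.0:
                        continue
                    dv = seg * lw * lh
                    e += rate * dv
                    path_len += seg
                    track_vol += dv
                    lines.append(f"G1 X{x} Y{y} F{feed:.1f} E{e:.9f}")
                    pos = np.array([x, y])
    lines.append(f"G1 Z{_q(params.clearance_z)} F600 ; restore platform clearance")
    lines.append(f"; total path {path_len:.4f} mm, track volume "
                 f"{track_vol:.4f} mm^3, ink {e:.6f} mm^3")
    ink = e
    if ink > reservoir_capacity_mm3:
        refills = math.ceil(ink / reservoir_capacity_mm3) - 1
        warnings.warn(
            f"program needs {ink / 1000.0:.1f} mL of ink, exceeding the "
            f"{reservoir_capacity_mm3 / 1000.0:.0f} mL reservoir; "
            f"{refills} refill(s) required", stacklevel=2)
    return GCodeProgram(lines=lines, path_length_mm=path_len,
                        track_volume_mm3=track_vol, ink_volume_mm3=ink,
                        n_layers=len(layers))


_HEADER_RE = re.compile(
    r"; line_width (?P<lw>[\d.]+) layer_height (?P<lh>[\d.]+) "
    r"extrusion_rate (?P<rate>[\d.]+)")


def resimulate(gcode_text: str) -> dict[str, float]:
    """Re-integrate a program's moves and recover its totals.

    Parses the header for the track geometry parameters, replays every
    move, and recomputes path length, track volume and ink volume with
    the same arithmetic the emitter used on the same (quantized)
    coordinates, so totals agree to round-off.
    """
    lw = lh = rate = None
    m = _HEADER_RE.search(gcode_text)
    if m:
        lw, lh, rate = (float(m.group(k)) for k in ("lw", "lh", "rate"))
    x = y = None
    path_len = 0.0
    track_vol = 0.0
    ink = 0.0
    for lineno, raw in enumerate(gcode_text.splitlines(), 1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        cmd = parts[0]
        if cmd in ("G21", "G90", "G28", "G92"):
            continue
        if cmd not in ("G0", "G1"):
            raise ValueError(f"unknown command {cmd!r} on line {lineno}")
        coords = {p[0]: float(p[1:]) for p in parts[1:]}
        nx, ny = coords.get("X", x), coords.get("Y", y)
        extruding = cmd == "G1" and "E" in coords
        if extruding and ("X" in coords or "Y" in coords):
            if x is None or lw is None:
                raise ValueError(f"extruding move before position/header "
                                 f"established (line {lineno})")
            seg = math.hypot(nx - x, ny - y)
            dv = seg * lw * lh
            path_len += seg
            track_vol += dv
            ink += rate * dv
        x, y = nx, ny
    return {"path_length_mm": path_len, "track_volume_mm3": track_vol,
            "ink_volume_mm3": ink}
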