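"""Slicing geometry, concentric infill, G-code emission and re-simulation."""

import math

import numpy as np
import pytest
import trimesh
from shapely.geometry import Point, Polygon

from cardiofab.meshing import SurfaceMesh
from cardiofab.slicer import (GCodeProgram, SliceParams, concentric_infill,
                              emit_gcode, resimulate, slice_mesh)


@pytest.fixture(scope="module")
def params():
    return SliceParams()


@pytest.fixture(scope="module")
def sliced_cube(cube_mesh_mod, params):
    layers = slice_mesh(cube_mesh_mod, params)
    for ly in layers:
        concentric_infill(ly, params)
    return layers


@pytest.fixture(scope="module")
def cube_mesh_mod():
    return SurfaceMesh.from_trimesh(trimesh.creation.box((10.0, 10.0, 10.0)))


@pytest.fixture(scope="module")
def cube_program(sliced_cube, params):
    return emit_gcode(sliced_cube, params, "cube")


def test_cube_layer_count_and_perimeter(sliced_cube):
    """10 mm / 0.4 mm layers -> 25 layers, each a 40 mm square contour."""
    assert len(sliced_cube) == 25
    for ly in sliced_cube:
        assert len(ly.polygons) == 1
        assert ly.polygons[0].exterior.length == pytest.approx(40.0, abs=1e-6)


def test_sphere_mid_layer_circumference(params):
    mesh = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(4, 5.0))
    layers = slice_mesh(mesh, params)
    mid = min(layers, key=lambda l: abs(l.z))
    analytic = 2 * math.pi * math.sqrt(25.0 - mid.z ** 2)
    assert abs(mid.polygons[0].exterior.length - analytic) / analytic < 0.01


def test_torus_layers_have_nested_contours(params):
    mesh = SurfaceMesh.from_trimesh(trimesh.creation.torus(9.0, 2.0))
    layers = slice_mesh(mesh, params)
    mid = min(layers, key=lambda l: abs(l.z))
    assert len(mid.polygons) == 1
    assert len(mid.polygons[0].interiors) == 1  # annulus: outer wall + hole


def test_contour_orientation_convention(params):
    mesh = SurfaceMesh.from_trimesh(trimesh.creation.torus(9.0, 2.0))
    mid = min(slice_mesh(mesh, params), key=lambda l: abs(l.z))
    poly = mid.polygons[0]
    assert Polygon(poly.exterior).exterior.is_ccw
    assert not poly.interiors[0].is_ccw  # holes clockwise


def test_non_watertight_mesh_rejected(params):
    tm = trimesh.creation.box((5, 5, 5))
    open_mesh = trimesh.Trimesh(vertices=tm.vertices, faces=tm.faces[:-2],
                                process=False)
    with pytest.raises(ValueError, match="watertight"):
        slice_mesh(SurfaceMesh.from_trimesh(open_mesh), params)


def test_disk_infill_radii(params):
    """Disk r=1.05, width 0.3 -> infill loops at r = 0.75, 0.45, 0.15."""
    from cardiofab.slicer import SliceLayer

    ly = SliceLayer(z=0.2, polygons=[Point(0, 0).buffer(1.05, quad_segs=256)])
    loops = concentric_infill(ly, params)
    radii = sorted(Polygon(lp).exterior.length / (2 * math.pi) for lp in loops)
    assert len(loops) == 3
    assert radii == pytest.approx([0.15, 0.45, 0.75], abs=0.01)


def test_square_infill_loop_count(params):
    """3x3 square: floor((1.5-0.15)/0.3)+1 = 5 loops incl. the perimeter."""
    from cardiofab.slicer import SliceLayer

    sq = Polygon([(0, 0), (3, 0), (3, 3), (0, 3)])
    ly = SliceLayer(z=0.2, polygons=[sq])
    loops = concentric_infill(ly, params)
    assert 1 + len(loops) == math.floor((1.5 - 0.15) / 0.3) + 1


def test_region_narrower_than_line_width_gets_no_infill(params):
    from cardiofab.slicer import SliceLayer

    sliver = Polygon([(0, 0), (5, 0), (5, 0.2), (0, 0.2)])
    ly = SliceLayer(z=0.2, polygons=[sliver])
    assert concentric_infill(ly, params) == []


def test_full_density_infill_covers_interior(sliced_cube, params):
    """Deposited tracks (loops dilated by half a width) cover >= 98%."""
    from shapely.ops import unary_union
    from shapely.geometry import LineString

    ly = sliced_cube[len(sliced_cube) // 2]
    tracks = [LineString(ly.polygons[0].exterior.coords)]
    tracks += [LineString(lp) for lp in ly.infill]
    covered = unary_union([t.buffer(params.line_width / 2) for t in tracks])
    interior = ly.polygons[0]
    assert covered.intersection(interior).area / interior.area >= 0.98


def test_single_segment_ink_arithmetic():
    """10 mm track at 0.3x0.4 mm cross-section, 4% -> 0.048 mm^3 ink."""
    p = SliceParams()
    dv = 10.0 * p.line_width * p.layer_height
    assert p.extrusion_rate * dv == pytest.approx(0.048)


def test_construct_ink_ratio_25_to_1(cube_program):
    assert cube_program.construct_ink_ratio == pytest.approx(25.0, rel=1e-9)


def test_extruding_feed_is_900(cube_program):
    feeds = {l.split("F")[1].split()[0] for l in cube_program.lines
             if l.startswith("G1 X")}
    assert feeds == {"900.0"}


def test_preamble_lifts_platform_before_homing(cube_program):
    lines = cube_program.lines
    z_lift = next(i for i, l in enumerate(lines) if l.startswith("G1 Z"))
    home = next(i for i, l in enumerate(lines) if l.startswith("G28"))
    assert z_lift < home
    assert lines[-2].startswith("G1 Z")  # postamble restores clearance


def test_clearance_below_container_refused(sliced_cube):
    with pytest.raises(ValueError, match="container"):
        emit_gcode(sliced_cube, SliceParams(clearance_z=10.0,
                                            container_height=60.0), "cube")


def test_resimulation_reproduces_totals_exactly(cube_program):
    tot = resimulate(cube_program.text)
    assert tot["track_volume_mm3"] == pytest.approx(
        cube_program.track_volume_mm3, rel=1e-12)
    assert tot["ink_volume_mm3"] == pytest.approx(
        cube_program.ink_volume_mm3, rel=1e-12)
    assert tot["path_length_mm"] == pytest.approx(
        cube_program.path_length_mm, rel=1e-12)


def test_resimulated_cube_volume_conservation(cube_program):
    """100% concentric infill reconstructs the solid volume within 15%."""
    tot = resimulate(cube_program.text)
    assert 0.85 * 1000.0 <= tot["track_volume_mm3"] <= 1.15 * 1000.0


def test_hand_written_program_totals():
    text = "\n".join([
        "; line_width 0.3000 layer_height 0.4000 extrusion_rate 0.0400 "
        "print_speed 15.0000",
        "G90",
        "G0 X0 Y0 Z0.2",
        "G1 X10 Y0 F900.0 E0.048",
        "G1 X10 Y5 F900.0 E0.072",
    ])
    tot = resimulate(text)
    assert tot["path_length_mm"] == pytest.approx(15.0)
    assert tot["track_volume_mm3"] == pytest.approx(15.0 * 0.3 * 0.4)
    assert tot["ink_volume_mm3"] == pytest.approx(0.04 * 15.0 * 0.3 * 0.4)


def test_unknown_command_reports_line_number():
    with pytest.raises(ValueError, match="line 2"):
        resimulate("G90\nM104 S200\n")


def test_ink_ratio_exact_for_random_programs(params):
    """ink volume / track volume = extrusion_rate for every program."""
    rng = np.random.default_rng(0)
    for _ in range(3):
        size = rng.uniform(3, 8, size=3)
        mesh = SurfaceMesh.from_trimesh(trimesh.creation.box(size))
        layers = slice_mesh(mesh, params)
        for ly in layers:
            concentric_infill(ly, params)
        prog = emit_gcode(layers, params, "box")
        assert prog.ink_volume_mm3 / prog.track_volume_mm3 == pytest.approx(
            params.extrusion_rate, rel=1e-9)


def test_extruding_points_inside_perimeter(sliced_cube, params):
    """Sampled extruding coordinates lie within the layer's perimeter."""
    prog = emit_gcode(sliced_cube, params, "cube")
    from shapely.geometry import Point as P

    layer_poly = sliced_cube[0].polygons[0].buffer(1e-6)
    z = None
    for line in prog.lines[:400]:
        if line.startswith("; layer z"):
            z = float(line.split()[-1])
        if z == sliced_cube[0].z and line.startswith("G1 X"):
            parts = {p[0]: float(p[1:]) for p in line.split()[1:]}
            assert layer_poly.contains(P(parts["X"], parts["Y"]))


def test_reservoir_warning_on_large_program(sliced_cube, params):
    with pytest.warns(UserWarning, match="refill"):
        emit_gcode(sliced_cube, params, "cube", reservoir_capacity_mm3=10.0)
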