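"""Synthetic labeled cardiac CT phantoms.

Real multi-structure cardiac CT with expert contours is rarely shareable,
so the package generates parametric phantoms that reproduce the
*statistical difficulties* of such data rather than its anatomy in
detail: ten labeled substructures with a large chamber/vessel scale
disparity (the left ventricle encloses roughly ten times the volume of
the superior vena cava), low grayscale contrast between adjacent
structures, additive Gaussian noise, and isotropic blur.  Chambers are
rendered as ellipsoids and vessels as capped tubes; each vessel is
6-connected to the chamber it drains into or arises from (SVC/IVC to RA,
PV to LA, PA to RV, AA to LV; DA is a free posterior tube).

Conventions: voxel indices are 0-based in (z, y, x) order, the world
position of a voxel is ``index * spacing`` in millimetres, and an axial
slice is a fixed-z plane.  Intensities are abstract 0-1000 pseudo-HU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .anatomy import ATTACHMENTS, BY_ABBREV, DEFAULT_DIAMETERS_MM, SUBSTRUCTURES

__all__ = [
    "PhantomSpec",
    "LabeledVolume",
    "PhantomSizingError",
    "generate_phantom",
    "generate_cases",
    "split_cases",
    "interface_contrast",
    "save_nifti",
    "load_nifti",
]


class PhantomSizingError(ValueError):
    """A structure does not fit inside the requested grid."""


# Ellipsoid semi-axes of each chamber as fractions of its landmark
# diameter, in (z, y, x) order.  The in-plane semi-axes are d/2 so that
# the landmark diameter is realized in the axial plane.
_CHAMBER_AXES = {
    "LA": (0.45, 0.50, 0.50),
    "RA": (0.45, 0.50, 0.50),
    "LV": (0.65, 0.50, 0.50),
    "RV": (0.60, 0.50, 0.50),
}

# Vessel length as a multiple of its diameter.  SVC length is chosen so
# the analytic LV:SVC volume ratio sits near 10.
_VESSEL_LENGTH = {
    "SVC": 1.45,
    "IVC": 1.20,
    "PA": 1.30,
    "PV": 1.40,
    "AA": 1.40,
    "DA": 2.20,
}

# Relative grayscale offsets; base level = 400 + offset * 300 * contrast.
# Large structures are mutually separated (min gap 0.2) so they are
# locally identifiable, as chambers and arteries are in real CT; each
# small vein is an intensity twin of a large structure elsewhere in the
# volume (gap 0.05, far below the noise floor), so veins can only be
# resolved from spatial context -- the cascade's anatomical prior.
_INTENSITY_OFFSET = {
    "LA": +1.00,
    "RA": -1.00,
    "LV": +0.60,
    "RV": -0.60,
    "PA": -0.20,
    "AA": +0.20,
    "DA": 0.00,
    "SVC": -0.65,   # twin of RV
    "IVC": -0.55,   # twin of RV, other side
    "PV": +0.65,    # twin of LV
}

_BACKGROUND_LEVEL = 150.0
_MID_LEVEL = 400.0
_LEVEL_RANGE = 300.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic labeled cardiac CT volume.

    Parameters
    ----------
    grid_shape : tuple of int or None
        Volume shape in voxels, (z, y, x).  ``None`` auto-fits the grid
        to the requested diameters at the given spacing.
    spacing : tuple of float
        Voxel spacing in mm, (z, y, x).
    diameters : dict
        Landmark diameter per substructure abbreviation, mm.  Defaults
        to the reference digital-model values.
    contrast_separation : float
        In [0, 1]; scales the grayscale gap between adjacent structures.
    noise_sd : float
        Additive Gaussian noise, pseudo-HU.
    blur_sigma : float
        Gaussian blur applied after noise, in voxels.
    jitter : float
        Per-case relative variation of diameters and positions (drawn
        from the case seed), emulating inter-patient variability.
    seed : int
        Seed; identical spec (same seed) gives bit-identical output.
    """

    grid_shape: tuple[int, int, int] | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    diameters: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DIAMETERS_MM))
    contrast_separation: float = 0.30
    noise_sd: float = 15.0
    blur_sigma: float = 0.6
    jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast_separation <= 1.0:
            raise ValueError("contrast_separation must be in [0, 1]")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be >= 0")
        missing = set(DEFAULT_DIAMETERS_MM) - set(self.diameters)
        if missing:
            raise ValueError(f"diameters missing for {sorted(missing)}")
        for k, v in self.diameters.items():
            if v <= 0:
                raise ValueError(f"diameter of {k} must be > 0")

    def with_seed(self, seed: int) -> "PhantomSpec":
        return dataclasses.replace(self, seed=seed)

    @classmethod
    def desk(
        cls,
        grid_shape: tuple[int, int, int] = (48, 48, 48),
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        **kwargs,
    ) -> "PhantomSpec":
        """Desk-scale spec: reference diameters uniformly shrunk to fit.

        All ten diameters are scaled by one factor, preserving the
        chamber/vessel volume ratios, so that the jittered anatomy fits
        the requested grid with margin.
        """
        nominal = cls(grid_shape=None, spacing=spacing, **kwargs)
        pen = 2.0 * max(spacing)
        extent = _layout_extent(nominal.diameters, pen)
        margin = np.asarray(_margins_mm(nominal, pen))
        avail = np.asarray(grid_shape) * np.asarray(spacing) - 2.0 * margin
        if np.any(avail <= 0):
            raise PhantomSizingError(f"grid {grid_shape} too small at spacing {spacing}")
        s = float(np.min(avail / np.asarray(extent)))
        diam = {k: v * s for k, v in nominal.diameters.items()}
        return cls(grid_shape=tuple(grid_shape), spacing=tuple(spacing),
                   diameters=diam, **kwargs)


@dataclass
class LabeledVolume:
    """A 3D intensity volume with an integer label map.

    ``intensity`` and ``labels`` share one (z, y, x) grid; ``labels``
    holds the substructure codes 1..10 with 0 background; ``spacing`` is
    mm per voxel.
    """

    intensity: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.intensity.shape != self.labels.shape:
            raise ValueError("intensity and labels must share a grid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensity.shape

    def mask(self, key) -> np.ndarray:
        """Binary mask of one substructure (by code or abbreviation)."""
        from .anatomy import substructure

        return self.labels == substructure(key).code

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _margins_mm(spec: PhantomSpec, pen: float) -> tuple[float, float, float]:
    # background margin: >= 2 voxels plus headroom for per-case jitter
    head = spec.jitter * max(spec.diameters.values()) + 1.0
    return tuple(2.0 * s + head for s in spec.spacing)


def _layout(diameters: dict[str, float], pen: float) -> dict[str, dict]:
    """Place all ten structures in a content frame (mm, origin at 0).

    Returns a dict abbrev -> primitive description.  Chambers are
    ellipsoids; vessels are tubes along z (or x for the PV) that
    penetrate ``pen`` mm into their attached chamber to guarantee
    6-connectivity after voxelization.
    """
    d = diameters
    semi = {c: tuple(f * d[c] for f in _CHAMBER_AXES[c]) for c in _CHAMBER_AXES}
    r = {v: d[v] / 2.0 for v in _VESSEL_LENGTH}
    L = {v: f * d[v] for v, f in _VESSEL_LENGTH.items()}
    scale = d["LV"] / DEFAULT_DIAMETERS_MM["LV"]
    gap = 1.5 * scale

    # --- x: left column (LV, LA, AA, PV) then right column (RV, RA, ...)
    x_left = max(semi["LV"][2], r["AA"], semi["LA"][2] + L["PV"] - pen)
    x_la = x_lv = x_left
    # chambers overlap slightly in x so the septum interface survives
    # voxelization and per-case jitter (later paint order wins the sliver)
    septum = pen / 2.0
    x_ra = x_la + 0.96 * (semi["LA"][2] + semi["RA"][2]) - septum
    x_rv = x_lv + 0.96 * (semi["LV"][2] + semi["RV"][2]) - septum

    # --- y: ventricle/artery plane in front, atrial plane behind, DA last.
    y_v = max(semi["LV"][1], semi["RV"][1], r["AA"], r["PA"])
    clearance = max(r["IVC"] + max(semi["RV"][1], semi["LV"][1]),
                    r["SVC"] + r["PA"]) + gap
    y_a = y_v + clearance
    y_da = y_a + max(semi["LA"][1], semi["RA"][1]) + r["DA"] + gap

    # --- z: ventricles low, atria 0.25*d_LV higher, vessels beyond.
    z_v = max(semi["LV"][0], semi["RV"][0])
    z_a = z_v + 0.25 * d["LV"]
    ivc_bottom = z_a - semi["RA"][0] + pen - L["IVC"]
    lift = max(0.0, -ivc_bottom)
    z_v += lift
    z_a += lift

    prims: dict[str, dict] = {}
    for c, (zc, yc, xc) in [("LA", (z_a, y_a, x_la)), ("RA", (z_a, y_a, x_ra)),
                            ("LV", (z_v, y_v, x_lv)), ("RV", (z_v, y_v, x_rv))]:
        prims[c] = {"kind": "ellipsoid", "center": (zc, yc, xc), "semi": semi[c]}

    def ztube(name, x, y, z0, up):
        lo, hi = (z0, z0 + L[name]) if up else (z0 - L[name], z0)
        prims[name] = {"kind": "tube", "axis": 0, "radius": r[name],
                       "span": (lo, hi), "perp": (y, x)}

    ztube("SVC", x_ra, y_a, z_a + semi["RA"][0] - pen, up=True)
    ztube("IVC", x_ra, y_a, z_a - semi["RA"][0] + pen, up=False)
    ztube("PA", x_rv, y_v, z_v + semi["RV"][0] - pen, up=True)
    ztube("AA", x_lv, y_v, z_v + semi["LV"][0] - pen, up=True)
    # DA: free vertical tube at the posterior edge, spanning mid-heart.
    prims["DA"] = {"kind": "tube", "axis": 0, "radius": r["DA"],
                   "span": (z_v - semi["LV"][0], z_v - semi["LV"][0] + L["DA"]),
                   "perp": (y_da, (x_la + x_ra) / 2.0)}
    # PV: horizontal tube entering the LA from the left (-x).
    x0 = x_la - semi["LA"][2] + pen
    prims["PV"] = {"kind": "tube", "axis": 2, "radius": r["PV"],
                   "span": (x0 - L["PV"], x0), "perp": (z_a, y_a)}
    return prims


def _prim_extent(p: dict) -> np.ndarray:
    """(2, 3) min/max mm extents of a primitive, axes (z, y, x)."""
    if p["kind"] == "ellipsoid":
        c, s = np.asarray(p["center"]), np.asarray(p["semi"])
        return np.stack([c - s, c + s])
    lo = np.empty(3)
    hi = np.empty(3)
    ax = p["axis"]
    lo[ax], hi[ax] = p["span"]
    others = [a for a in (0, 1, 2) if a != ax]
    for a, pc in zip(others, p["perp"]):
        lo[a], hi[a] = pc - p["radius"], pc + p["radius"]
    return np.stack([lo, hi])


def _layout_extent(diameters: dict[str, float], pen: float) -> np.ndarray:
    prims = _layout(diameters, pen)
    ext = np.stack([_prim_extent(p) for p in prims.values()])
    return ext[:, 1, :].max(axis=0) - np.minimum(ext[:, 0, :].min(axis=0), 0.0)


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Render one labeled phantom volume from its spec.

    Chambers are painted first; each vessel then claims background
    voxels plus voxels of its attached chamber inside the penetration
    cap, which guarantees the vessel is 6-connected to that chamber
    while keeping all labels pairwise disjoint.
    """
    rng = np.random.default_rng(spec.seed)
    pen = 2.0 * max(spec.spacing)
    margin = np.asarray(_margins_mm(spec, pen))

    # per-case anatomical variability, drawn before any geometry
    jd = {k: v * (1.0 + rng.uniform(-spec.jitter, spec.jitter))
          for k, v in spec.diameters.items()}
    offsets = {s.abbrev: rng.normal(0.0, 0.6 * spec.jitter * jd[s.abbrev], size=3)
               for s in SUBSTRUCTURES}

    prims = _layout(jd, pen)
    for name, p in prims.items():
        off = offsets[name]
        if p["kind"] == "ellipsoid":
            p["center"] = tuple(np.asarray(p["center"]) + off)
        else:
            ax = p["axis"]
            p["span"] = (p["span"][0] + off[ax], p["span"][1] + off[ax])
            others = [a for a in (0, 1, 2) if a != ax]
            p["perp"] = tuple(p["perp"][i] + off[others[i]] for i in range(2))

    ext = np.stack([_prim_extent(p) for p in prims.values()])
    lo_all = ext[:, 0, :].min(axis=0)
    shift = margin - np.minimum(lo_all, 0.0)  # content starts at the margin
    spacing = np.asarray(spec.spacing, dtype=float)

    if spec.grid_shape is None:
        hi_all = ext[:, 1, :].max(axis=0)
        shape = np.ceil((hi_all + shift + margin) / spacing).astype(int)
    else:
        shape = np.asarray(spec.grid_shape, dtype=int)

    grid_mm = shape * spacing
    names = list(prims)
    for i, name in enumerate(names):
        lo = ext[i, 0, :] + shift
        hi = ext[i, 1, :] + shift
        if np.any(lo < 2.0 * spacing - 1e-9) or np.any(hi > grid_mm - 2.0 * spacing + 1e-9):
            raise PhantomSizingError(
                f"{name} (extent {np.round(hi - lo, 1)} mm) does not fit grid "
                f"{tuple(shape)} at spacing {tuple(spacing)} with a 2-voxel margin"
            )

    zz = (np.arange(shape[0]) * spacing[0])[:, None, None]
    yy = (np.arange(shape[1]) * spacing[1])[None, :, None]
    xx = (np.arange(shape[2]) * spacing[2])[None, None, :]
    coords = (zz, yy, xx)

    labels = np.zeros(tuple(shape), dtype=np.uint8)

    def prim_mask(p) -> np.ndarray:
        if p["kind"] == "ellipsoid":
            c = np.asarray(p["center"]) + shift
            s = np.asarray(p["semi"])
            q = ((coords[0] - c[0]) / s[0]) ** 2 + ((coords[1] - c[1]) / s[1]) ** 2 \
                + ((coords[2] - c[2]) / s[2]) ** 2
            return q <= 1.0
        ax = p["axis"]
        others = [a for a in (0, 1, 2) if a != ax]
        pc = [p["perp"][i] + shift[others[i]] for i in range(2)]
        rr = (coords[others[0]] - pc[0]) ** 2 + (coords[others[1]] - pc[1]) ** 2
        lo, hi = p["span"][0] + shift[ax], p["span"][1] + shift[ax]
        return (rr <= p["radius"] ** 2) & (coords[ax] >= lo) & (coords[ax] <= hi)

    # chambers first, then vessels (vessels may claim their own chamber's cap)
    order = ["LA", "RA", "LV", "RV", "SVC", "IVC", "PA", "PV", "AA", "DA"]
    for name in order:
        m = prim_mask(prims[name])
        code = BY_ABBREV[name].code
        attach = ATTACHMENTS.get(name)
        if attach is None and name in _VESSEL_LENGTH:
            m &= labels == 0
        elif attach is not None:
            m &= (labels == 0) | (labels == BY_ABBREV[attach].code)
        labels[m] = code
        if not m.any():
            raise PhantomSizingError(f"{name} occupies no voxels on this grid")

    levels = np.full(11, _BACKGROUND_LEVEL, dtype=np.float32)
    for s in SUBSTRUCTURES:
        levels[s.code] = _MID_LEVEL + _INTENSITY_OFFSET[s.abbrev] * _LEVEL_RANGE \
            * spec.contrast_separation
    intensity = levels[labels]
    intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    if spec.blur_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, sigma=spec.blur_sigma)
    intensity = intensity.astype(np.float32)

    return LabeledVolume(intensity=intensity, labels=labels,
                         spacing=tuple(float(s) for s in spacing),
                         case_id=f"case_{spec.seed:05d}")


def generate_cases(spec: PhantomSpec, n: int, base_seed: int | None = None) -> list[LabeledVolume]:
    """Generate ``n`` phantoms differing only by seed (base_seed + i)."""
    if base_seed is None:
        base_seed = spec.seed
    return [generate_phantom(spec.with_seed(base_seed + i)) for i in range(n)]


def split_cases(
    case_ids: list,
    ratios: tuple[float, float, float] = (6, 2, 2),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Partition cases into train/val/test by quota apportionment.

    Quotas are ``n * ratio`` after normalizing the ratios; each
    partition gets the floor of its quota and leftover cases go to the
    partitions with the largest ratios first (train absorbs the extra
    case of a 117-case 6:2:2 split, giving 71/23/23).  The assignment of
    cases is a seeded shuffle; identical seed gives identical partitions.
    """
    r = np.asarray(ratios, dtype=float)
    if r.min() < 0 or r.sum() <= 0:
        raise ValueError("ratios must be nonnegative and sum to > 0")
    r = r / r.sum()
    n = len(case_ids)
    if n < np.count_nonzero(r):
        raise ValueError(f"{n} cases cannot fill {np.count_nonzero(r)} partitions")
    quota = n * r
    sizes = np.floor(quota).astype(int)
    order = np.argsort(-r, kind="stable")
    for i in range(n - sizes.sum()):
        sizes[order[i % len(order)]] += 1
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [case_ids[i] for i in perm]
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]


def interface_contrast(vol: LabeledVolume, a, b) -> float:
    """Mean absolute intensity difference across the a/b interface.

    Averages intensity over the voxels of each structure that are
    6-adjacent to the other structure and returns the absolute
    difference of the two means.  Raises if the structures do not touch.
    """
    ma, mb = vol.mask(a), vol.mask(b)
    st = ndimage.generate_binary_structure(3, 1)
    ta = ma & ndimage.binary_dilation(mb, st)
    tb = mb & ndimage.binary_dilation(ma, st)
    if not ta.any() or not tb.any():
        raise ValueError("structures share no 6-connected interface")
    return float(abs(vol.intensity[ta].mean() - vol.intensity[tb].mean()))


def save_nifti(vol: LabeledVolume, directory, prefix: str | None = None) -> tuple[str, str]:
    """Write the intensity/label pair as uncompressed NIfTI files."""
    import os

    import nibabel as nib

    prefix = prefix or (vol.case_id or "case")
    affine = np.diag(list(vol.spacing) + [1.0])
    img_path = os.path.join(str(directory), f"{prefix}_image.nii")
    lab_path = os.path.join(str(directory), f"{prefix}_labels.nii")
    nib.save(nib.Nifti1Image(vol.intensity.astype(np.float32), affine), img_path)
    nib.save(nib.Nifti1Image(vol.labels.astype(np.uint8), affine), lab_path)
    return img_path, lab_path


def load_nifti(image_path, labels_path=None, case_id: str = "") -> LabeledVolume:
    """Read a NIfTI intensity volume (and optional label map)."""
    import nibabel as nib

    img = nib.load(str(image_path))
    intensity = np.asarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if labels_path is not None:
        labels = np.asarray(nib.load(str(labels_path)).dataobj).astype(np.uint8)
    else:
        labels = np.zeros(intensity.shape, dtype=np.uint8)
    return LabeledVolume(intensity=intensity, labels=labels, spacing=spacing,
                         case_id=case_id)
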