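"""Phantom generator: determinism, geometry, connectivity, contrast."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import pdist

from cardiofab.anatomy import ATTACHMENTS, SUBSTRUCTURES
from cardiofab.phantom import (PhantomSizingError, PhantomSpec,
                               generate_phantom, interface_contrast,
                               load_nifti, save_nifti, split_cases)


def test_same_seed_bit_identical(desk_spec):
    a = generate_phantom(desk_spec.with_seed(7))
    b = generate_phantom(desk_spec.with_seed(7))
    assert np.array_equal(a.intensity, b.intensity)
    assert np.array_equal(a.labels, b.labels)


def test_different_seeds_differ(desk_spec):
    a = generate_phantom(desk_spec.with_seed(1))
    b = generate_phantom(desk_spec.with_seed(2))
    assert not np.array_equal(a.labels, b.labels)


def test_lv_svc_volume_ratio_near_ten():
    """The LV encloses roughly ten times the volume of the SVC."""
    vol = generate_phantom(PhantomSpec(spacing=(0.5, 0.5, 0.5), seed=3,
                                       jitter=0.0))
    ratio = vol.mask("LV").sum() / vol.mask("SVC").sum()
    assert 8.0 <= ratio <= 12.0


def test_desk_scale_preserves_volume_ratio(desk_phantom):
    ratio = desk_phantom.mask("LV").sum() / desk_phantom.mask("SVC").sum()
    assert 8.0 <= ratio <= 12.0


def test_svc_feret_diameter_matches_spec():
    """SVC diameter 18.38 mm at 0.5 mm spacing -> ~36.8 voxel Feret width.

    Oracle: exhaustive pairwise distances between boundary voxels of the
    generated mask, in a mid-height axial slice.
    """
    vol = generate_phantom(PhantomSpec(spacing=(0.5, 0.5, 0.5), seed=3,
                                       jitter=0.0))
    assert vol.shape[0] > 100  # full-scale grid
    m = vol.mask("SVC")
    zs = np.where(m.any(axis=(1, 2)))[0]
    sl = m[zs[len(zs) // 2]]
    boundary = sl & ~ndimage.binary_erosion(sl)
    feret = pdist(np.argwhere(boundary)).max()
    assert abs(feret - 36.8) <= 2.0


@pytest.mark.parametrize("seed", range(50))
def test_labels_disjoint_and_complete(desk_spec, seed):
    """All ten labels present; codes within 0..10 on every case."""
    vol = generate_phantom(desk_spec.with_seed(seed))
    present = set(np.unique(vol.labels).tolist())
    assert present == set(range(11))


@pytest.mark.parametrize("seed", range(0, 50, 5))
def test_vessel_chamber_connectivity(desk_spec, seed):
    """Each vessel is one 6-connected component touching its chamber."""
    vol = generate_phantom(desk_spec.with_seed(seed))
    st = ndimage.generate_binary_structure(3, 1)
    for vessel, chamber in ATTACHMENTS.items():
        if chamber is None:
            continue
        lab, n = ndimage.label(vol.mask(vessel), st)
        grown = ndimage.binary_dilation(vol.mask(chamber), st)
        touching = [i for i in range(1, n + 1) if (grown & (lab == i)).any()]
        assert n == 1, f"{vessel} split into {n} components (seed {seed})"
        assert touching == [1], f"{vessel} not attached to {chamber}"


def test_contrast_separation_monotonicity(desk_spec):
    """Lower contrast strictly shrinks the LA/RA interface gap."""
    means = []
    for c in (0.05, 0.15, 0.30):
        vals = [interface_contrast(
            generate_phantom(PhantomSpec.desk((48, 48, 48),
                                              contrast_separation=c, seed=s)),
            "LA", "RA") for s in range(10)]
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_structure_too_large_raises():
    spec = PhantomSpec(grid_shape=(24, 24, 24))  # full-size diameters
    with pytest.raises(PhantomSizingError):
        generate_phantom(spec)


def test_split_exact_ratio():
    tr, va, te = split_cases(list(range(10)), (6, 2, 2), seed=0)
    assert (len(tr), len(va), len(te)) == (6, 2, 2)


def test_split_117_cases_quota_apportionment():
    tr, va, te = split_cases(list(range(117)), (6, 2, 2), seed=0)
    assert (len(tr), len(va), len(te)) == (71, 23, 23)
    assert sorted(tr + va + te) == list(range(117))
    assert not (set(tr) & set(va)) and not (set(va) & set(te))


def test_split_deterministic_and_seed_sensitive():
    a = split_cases(list(range(20)), (6, 2, 2), seed=5)
    b = split_cases(list(range(20)), (6, 2, 2), seed=5)
    c = split_cases(list(range(20)), (6, 2, 2), seed=6)
    assert a == b
    assert a != c


def test_split_too_few_cases():
    with pytest.raises(ValueError):
        split_cases([1, 2], (6, 2, 2), seed=0)


def test_nifti_roundtrip(tmp_path, desk_phantom):
    img, lab = save_nifti(desk_phantom, tmp_path, "rt")
    back = load_nifti(img, lab)
    assert np.allclose(back.intensity, desk_phantom.intensity)
    assert np.array_equal(back.labels, desk_phantom.labels)
    assert back.spacing == pytest.approx(desk_phantom.spacing)
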