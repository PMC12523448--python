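import numpy as np
import pytest
import trimesh

from cardiofab.meshing import SurfaceMesh
from cardiofab.phantom import LabeledVolume, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def desk_spec() -> PhantomSpec:
    return PhantomSpec.desk((48, 48, 48))


@pytest.fixture(scope="session")
def desk_phantom(desk_spec) -> LabeledVolume:
    return generate_phantom(desk_spec.with_seed(7))


@pytest.fixture(scope="session")
def cube_mesh() -> SurfaceMesh:
    """10 mm cube centred at the origin."""
    return SurfaceMesh.from_trimesh(trimesh.creation.box((10.0, 10.0, 10.0)))


@pytest.fixture(scope="session")
def sphere_mesh() -> SurfaceMesh:
    """Sphere of radius 5 mm (icosphere, subdivision 4)."""
    return SurfaceMesh.from_trimesh(trimesh.creation.icosphere(4, 5.0))


@pytest.fixture()
def voxel_sphere_volume() -> LabeledVolume:
    """Digital sphere of radius 10 voxels at 0.5 mm isotropic spacing."""
    n, r = 28, 10
    zz, yy, xx = np.ogrid[:n, :n, :n]
    mask = (zz - 14) ** 2 + (yy - 14) ** 2 + (xx - 14) ** 2 <= r * r
    labels = np.where(mask, 3, 0).astype(np.uint8)  # LV code
    return LabeledVolume(intensity=labels.astype(np.float32) * 400.0,
                         labels=labels, spacing=(0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def write_dicom_series():
    """Factory writing a small synthetic CT DICOM series to a directory."""

    def _write(directory, n=5, spacing=(0.7, 0.7), thickness=2.5,
               series_uid="1.2.3.4", shuffle=False):
        import os

        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        os.makedirs(directory, exist_ok=True)
        rng = np.random.default_rng(0)
        order = list(range(n))
        names = [f"slice_{i:02d}.dcm" for i in order]
        if shuffle:
            names = names[::-1]
        for i, name in zip(order, names):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(name, {}, file_meta=meta, preamble=b"\0" * 128)
            ds.SOPClassUID = meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series_uid
            ds.Modality = "CT"
            ds.Rows = ds.Columns = 16
            ds.PixelSpacing = [str(spacing[0]), str(spacing[1])]
            ds.SliceThickness = str(thickness)
            ds.ImagePositionPatient = ["0", "0", str(i * thickness)]
            ds.InstanceNumber = i + 1
            ds.RescaleSlope = "2.0"
            ds.RescaleIntercept = "-1000.0"
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.PixelData = rng.integers(0, 1000, (16, 16),
                                        dtype=np.uint16).tobytes()
            ds.save_as(os.path.join(directory, name),
                       enforce_file_format=True)

    return _write
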