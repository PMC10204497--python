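"""Shared fixtures: small grids, random mask pairs, synthetic DICOM series."""

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from mrsipipe import BinaryMask, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20230906)


def random_mask_pair(rng, max_side=16, allow_empty=False):
    """Two random masks on one grid with random anisotropic spacing."""
    shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
    spacing = tuple(float(rng.uniform(0.5, 3.0)) for _ in range(3))
    while True:
        a = rng.random(shape) < rng.uniform(0.05, 0.5)
        b = rng.random(shape) < rng.uniform(0.05, 0.5)
        if allow_empty or (a.any() or b.any()):
            break
    return BinaryMask(a, spacing), BinaryMask(b, spacing)


@pytest.fixture
def small_volume():
    return VolumeGrid(np.arange(64, dtype=np.float64).reshape(4, 4, 4),
                      spacing=(1.0, 1.0, 2.0))


def write_dicom_series(directory, data, pixel_spacing=(1.0, 1.0),
                       slice_spacing=2.0, skip_slices=()):
    """Write a synthetic axial DICOM series; data is (rows, cols, nslices)."""
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    for k in range(data.shape[2]):
        if k in skip_slices:
            continue
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, Dataset(), file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.Rows, ds.Columns = data.shape[0], data.shape[1]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelSpacing = [str(pixel_spacing[0]), str(pixel_spacing[1])]
        ds.SliceThickness = str(slice_spacing)
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, k * slice_spacing]
        ds.PixelData = np.ascontiguousarray(
            data[:, :, k].astype(np.uint16)).tobytes()
        pydicom.dcmwrite(directory / f"slice_{k:03d}.dcm", ds,
                         write_like_original=False)
    return directory
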