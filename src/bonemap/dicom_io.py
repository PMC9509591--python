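"""Reading and writing CT volumes: DICOM series, NIfTI-1, MetaImage.

The stored-value <-> Hounsfield-unit contract lives here. A CT DICOM file
keeps integer *stored* pixel values; the rescale tags (0028,1052)
(intercept ``b``) and (0028,1053) (slope ``m``) define

    HU = m * stored + b.

Everything downstream of calibration works on stored values; HU
conversion is provided for display and for users whose phantom
measurements were taken on the HU scale.

DICOM series are handled with pydicom (single-frame CT, one file per
slice, slices ordered by the projection of ImagePositionPatient onto the
slice normal — never by filename). NIfTI-1 and MetaImage go through
SimpleITK; note its LPS world convention matches the DICOM patient
coordinate system used throughout, so geometry round-trips exactly.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import DataError
from .volume import CTVolume, ScalarVolume

logger = logging.getLogger(__name__)

_FORMATS = ("nifti", "metaimage", "dicom")
_SUFFIX_FORMAT = {".nii": "nifti", ".gz": "nifti", ".mhd": "metaimage", ".mha": "metaimage"}


# -- stored <-> HU --------------------------------------------------------


def stored_to_hu(v: CTVolume) -> ScalarVolume:
    """Apply the rescale equation HU = m*stored + b voxelwise."""
    hu = v.rescale_slope * v.voxels.astype(float) + v.rescale_intercept
    return ScalarVolume.like(v, hu, "HU")


def hu_to_stored(hu: ScalarVolume, m: float = 1.0, b: float = 0.0,
                 dtype=np.int16) -> CTVolume:
    """Invert the rescale equation: stored = round((HU - b) / m).

    Composing with :func:`stored_to_hu` reproduces the HU values to
    within ``|m| / 2`` (the rounding half-step).
    """
    if hu.units != "HU":
        raise DataError(f"expected an HU volume, got units {hu.units!r}")
    if m == 0:
        raise DataError("rescale slope m must be non-zero")
    stored = np.round((hu.values - b) / m)
    info = np.iinfo(dtype)
    if stored.min() < info.min or stored.max() > info.max:
        bad = stored.min() if stored.min() < info.min else stored.max()
        raise DataError(
            f"stored value {bad:.0f} falls outside the representable range "
            f"[{info.min}, {info.max}] for {np.dtype(dtype).name}"
        )
    return CTVolume(
        voxels=stored.astype(dtype),
        spacing=hu.spacing, origin=hu.origin, orientation=hu.orientation,
        rescale_slope=m, rescale_intercept=b, source_id=hu.source_id,
    )


# -- DICOM series ---------------------------------------------------------


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Assemble a single CT series from a directory of DICOM files.

    Slices are sorted by spatial position along the slice normal. The
    rescale slope/intercept are taken from tags (0028,1053)/(0028,1052),
    defaulting to 1 and 0 with a warning when absent. Stored values are
    returned untouched (never rescaled).
    """
    directory = Path(directory)
    datasets = []
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue  # non-DICOM clutter is tolerated
        datasets.append(ds)
    if not datasets:
        raise DataError(f"no readable DICOM files in {directory}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise DataError(f"directory mixes {len(uids)} series UIDs: {sorted(uids)}")
    first = datasets[0]
    if "PixelData" not in first:
        raise DataError("series has no pixel data")

    iop = np.asarray(first.ImageOrientationPatient, dtype=float)
    ps = np.asarray(first.PixelSpacing, dtype=float)  # (row, col) spacing
    shape_rc = (int(first.Rows), int(first.Columns))
    for ds in datasets[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, float), iop, atol=1e-6):
            raise DataError("slices disagree on image orientation")
        if not np.allclose(np.asarray(ds.PixelSpacing, float), ps, atol=1e-9):
            raise DataError("slices disagree on pixel spacing")
        if (int(ds.Rows), int(ds.Columns)) != shape_rc:
            raise DataError("slices disagree on matrix size")

    row, col = iop[:3], iop[3:]
    normal = np.cross(row, col)
    datasets.sort(key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)))

    if "RescaleSlope" in first:
        m, b = float(first.RescaleSlope), float(first.RescaleIntercept)
    else:
        m, b = 1.0, 0.0
        warnings.warn(
            "series carries no rescale tags (0028,1052)/(0028,1053); "
            "assuming slope=1, intercept=0 — verify stored-value consistency "
            "before calibrating",
            stacklevel=2,
        )

    voxels = np.stack([ds.pixel_array for ds in datasets])
    if not np.issubdtype(voxels.dtype, np.integer):
        raise DataError(f"stored pixel values must be integer, got {voxels.dtype}")

    if len(datasets) > 1:
        positions = [float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))
                     for ds in datasets]
        gaps = np.diff(positions)
        slice_spacing = float(np.mean(gaps))
        if np.ptp(gaps) > 1e-3:
            warnings.warn(f"non-uniform slice spacing (gaps {gaps})", stacklevel=2)
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0) or 1.0)

    return CTVolume(
        voxels=voxels,
        spacing=np.array([slice_spacing, ps[0], ps[1]]),
        origin=np.asarray(datasets[0].ImagePositionPatient, dtype=float),
        orientation=np.stack([row, col]),
        rescale_slope=m,
        rescale_intercept=b,
        source_id=str(first.SeriesInstanceUID),
    )


def _base_ct_dataset(rows: int, cols: int) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "CT"
    ds.Rows = rows
    ds.Columns = cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    return ds


def write_dicom_series(v: CTVolume, directory: str | Path) -> list[Path]:
    """Write a CTVolume as one single-frame CT DICOM file per slice."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    n_slices, rows, cols = v.shape

    if v.voxels.dtype not in (np.int16, np.uint16):
        info16 = np.iinfo(np.int16)
        if v.voxels.min() < info16.min or v.voxels.max() > info16.max:
            raise DataError("stored values exceed 16-bit signed range")
        voxels = v.voxels.astype(np.int16)
    else:
        voxels = v.voxels
    signed = voxels.dtype == np.int16

    normal = v.slice_normal
    paths = []
    for s in range(n_slices):
        ds = _base_ct_dataset(rows, cols)
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = s + 1
        ds.PixelRepresentation = 1 if signed else 0
        ds.ImageOrientationPatient = [*map(float, v.orientation[0]), *map(float, v.orientation[1])]
        position = v.origin + s * v.spacing[0] * normal
        ds.ImagePositionPatient = [float(x) for x in position]
        ds.PixelSpacing = [float(v.spacing[1]), float(v.spacing[2])]
        ds.SliceThickness = float(v.spacing[0])
        # DS values are capped at 16 chars; 10 significant digits always fit
        ds.RescaleSlope = f"{v.rescale_slope:.10g}"
        ds.RescaleIntercept = f"{v.rescale_intercept:.10g}"
        ds.RescaleType = "HU"
        ds.PixelData = np.ascontiguousarray(voxels[s]).tobytes()
        path = directory / f"slice_{s:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def encode_scalar_as_ct(vol: ScalarVolume) -> tuple[CTVolume, float, float]:
    """Quantize a float field into unsigned 16-bit stored values.

    Encoding: intercept 0 and slope ``max/(2**16 - 1)`` so the full
    stored range spans [0, max]; the slope/intercept pair is recorded in
    the output tags, preserving relative precision across the range.
    Negative values are not representable by this scheme and are rejected.
    """
    vmax = float(vol.values.max())
    vmin = float(vol.values.min())
    if vmin < 0:
        raise DataError(
            f"cannot encode negative values (min {vmin:.3g}) as unsigned DICOM"
        )
    # round to the 10 significant digits the DICOM DS tag will carry, so
    # quantization and the stored tag use the identical slope
    slope = float(f"{vmax / 65535.0:.10g}") if vmax > 0 else 1.0
    stored = np.round(np.clip(vol.values / slope, 0, 65535)).astype(np.uint16)
    ct = CTVolume(
        voxels=stored, spacing=vol.spacing, origin=vol.origin,
        orientation=vol.orientation, rescale_slope=slope, rescale_intercept=0.0,
        source_id=vol.source_id,
    )
    return ct, slope, 0.0


# -- NIfTI / MetaImage via SimpleITK --------------------------------------


def _to_sitk(values: np.ndarray, spacing, origin, orientation) -> sitk.Image:
    img = sitk.GetImageFromArray(values)  # (slice,row,col) -> ITK (x=col, y=row, z=slice)
    img.SetSpacing((float(spacing[2]), float(spacing[1]), float(spacing[0])))
    img.SetOrigin(tuple(float(x) for x in origin))
    row, col = orientation
    normal = np.cross(row, col)
    direction = np.column_stack([row, col, normal])  # columns: x, y, z world dirs
    img.SetDirection(tuple(direction.ravel(order="C")))
    return img


def _from_sitk(img: sitk.Image):
    values = sitk.GetArrayFromImage(img)
    sx, sy, sz = img.GetSpacing()
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    row = direction[:, 0]
    col = direction[:, 1]
    return values, np.array([sz, sy, sx]), np.asarray(img.GetOrigin()), np.stack([row, col])


def infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in _SUFFIX_FORMAT:
        return _SUFFIX_FORMAT[suffix]
    return "dicom"  # directories / extensionless -> DICOM series


def write_volume(vol: ScalarVolume | CTVolume, path: str | Path,
                 format: str | None = None) -> None:
    """Write a volume as NIfTI, MetaImage, or a DICOM series.

    Float ``ScalarVolume`` data written to DICOM is quantized via
    :func:`encode_scalar_as_ct`; NIfTI and MetaImage store floats
    losslessly.
    """
    if not str(path):
        raise DataError("empty output path")
    fmt = (format or infer_format(path)).lower()
    if fmt not in _FORMATS:
        raise DataError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")

    if fmt == "dicom":
        if isinstance(vol, ScalarVolume):
            ct, slope, _ = encode_scalar_as_ct(vol)
            logger.info("DICOM re-encoding with slope %.6g, intercept 0", slope)
        else:
            ct = vol
        write_dicom_series(ct, path)
        return

    if isinstance(vol, CTVolume):
        img = _to_sitk(vol.voxels, vol.spacing, vol.origin, vol.orientation)
        img.SetMetaData("bonemap_rescale_slope", str(vol.rescale_slope))
        img.SetMetaData("bonemap_rescale_intercept", str(vol.rescale_intercept))
    else:
        img = _to_sitk(vol.values, vol.spacing, vol.origin, vol.orientation)
        img.SetMetaData("bonemap_units", vol.units)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path, units: str | None = None):
    """Read a volume written by :func:`write_volume`.

    Returns a ``CTVolume`` for integer data without ``units`` and for
    DICOM series; otherwise a ``ScalarVolume`` with the given units
    (MetaImage files written by this package carry the units in their
    metadata and need no argument).
    """
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    img = sitk.ReadImage(str(path))
    values, spacing, origin, orientation = _from_sitk(img)
    keys = img.GetMetaDataKeys()
    if units is None and "bonemap_units" in keys:
        units = img.GetMetaData("bonemap_units")
    if units is None and np.issubdtype(values.dtype, np.integer):
        m = float(img.GetMetaData("bonemap_rescale_slope")) if "bonemap_rescale_slope" in keys else 1.0
        b = float(img.GetMetaData("bonemap_rescale_intercept")) if "bonemap_rescale_intercept" in keys else 0.0
        return CTVolume(
            voxels=values, spacing=spacing, origin=origin, orientation=orientation,
            rescale_slope=m, rescale_intercept=b, source_id=str(path),
        )
    if units is None:
        raise DataError(f"{path} carries no units; pass units= explicitly")
    return ScalarVolume(
        values=values, units=units, spacing=spacing, origin=origin,
        orientation=orientation, source_id=str(path),
    )
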