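"""Voxel-grid containers for CT data.

Two containers cover the whole pipeline:

``CTVolume``
    the raw scan: a rectangular grid of *stored* integer pixel values plus
    the affine rescale metadata (slope ``m``, intercept ``b``) that maps
    stored values to Hounsfield units, ``HU = m * stored + b``.

``ScalarVolume``
    any derived floating-point field (HU, QCT density in mg/cm3, wet
    apparent density in g/cm3, Young's modulus in MPa) carrying the same
    geometry voxel-for-voxel.

Array axis order is ``(slice, row, column)`` and voxel indices are 0-based.
World coordinates follow the scanner patient coordinate system: a voxel at
index ``(s, r, c)`` sits at

    origin + c*spacing_c*X + r*spacing_r*Y + s*spacing_s*N

where ``X``/``Y`` are the DICOM row/column direction cosines and
``N = X x Y`` is the slice normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError

#: Physical units a ScalarVolume may carry.
VALID_UNITS = ("HU", "mg/cm3", "g/cm3", "MPa")

_DEFAULT_ORIENTATION = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def _check_geometry(spacing, origin, orientation):
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    orientation = np.asarray(orientation, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise DataError(f"spacing must be 3 positive components, got {spacing}")
    if origin.shape != (3,):
        raise DataError(f"origin must be a 3-vector, got shape {origin.shape}")
    if orientation.shape != (2, 3):
        raise DataError("orientation must be a (2, 3) array of row/column cosines")
    for v in orientation:
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise DataError("orientation cosines must be unit vectors")
    return spacing, origin, orientation


@dataclass
class CTVolume:
    """A CT series as stored integer voxels plus rescale metadata.

    Parameters
    ----------
    voxels : (n_slices, n_rows, n_cols) integer ndarray
        Stored pixel values exactly as found in the DICOM files (never
        rescaled to HU).
    spacing : (3,) float
        Voxel size in mm along (slice, row, column).
    origin : (3,) float
        World position (mm) of voxel (0, 0, 0).
    orientation : (2, 3) float
        Direction cosines of the image rows and columns
        (DICOM ImageOrientationPatient split into two unit vectors).
    rescale_slope, rescale_intercept : float
        ``m`` and ``b`` of ``HU = m * stored + b``.
    source_id : str
        Free-text provenance (series UID, generator description, ...).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: _DEFAULT_ORIENTATION.copy())
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    source_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise DataError("voxels must be a non-empty 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise DataError(f"stored voxels must be integers, got {self.voxels.dtype}")
        self.spacing, self.origin, self.orientation = _check_geometry(
            self.spacing, self.origin, self.orientation
        )
        if self.rescale_slope == 0:
            raise DataError("rescale slope m must be non-zero")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def slice_normal(self) -> np.ndarray:
        row, col = self.orientation
        return np.cross(row, col)

    def world_from_index(self, index: np.ndarray) -> np.ndarray:
        """Map continuous (slice, row, col) indices to world mm coordinates."""
        index = np.atleast_2d(np.asarray(index, dtype=float))
        row, col = self.orientation
        basis = np.stack([self.slice_normal, col, row])  # world dirs of s, r, c
        offsets = (index * self.spacing) @ basis
        return np.squeeze(self.origin + offsets)

    def index_from_world(self, points: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to continuous (slice, row, col) indices."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        row, col = self.orientation
        basis = np.stack([self.slice_normal, col, row])
        # basis is orthonormal, so the inverse is the transpose
        offsets = (points - self.origin) @ basis.T
        return np.squeeze(offsets / self.spacing)

    def geometry_of(self) -> dict:
        return {
            "spacing": self.spacing.copy(),
            "origin": self.origin.copy(),
            "orientation": self.orientation.copy(),
        }


@dataclass
class ScalarVolume:
    """A floating-point field with physical units on a CT grid."""

    values: np.ndarray
    units: str
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: _DEFAULT_ORIENTATION.copy())
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise DataError("values must be a non-empty 3D array")
        if self.units not in VALID_UNITS:
            raise DataError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        self.spacing, self.origin, self.orientation = _check_geometry(
            self.spacing, self.origin, self.orientation
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @classmethod
    def like(cls, source: "CTVolume | ScalarVolume", values: np.ndarray, units: str) -> "ScalarVolume":
        """Build a ScalarVolume inheriting ``source``'s geometry bit-for-bit."""
        arr = np.asarray(values, dtype=float)
        ref = source.voxels if isinstance(source, CTVolume) else source.values
        if arr.shape != ref.shape:
            raise DataError(f"shape {arr.shape} does not match source {ref.shape}")
        return cls(
            values=arr,
            units=units,
            spacing=source.spacing,
            origin=source.origin,
            orientation=source.orientation,
            source_id=source.source_id,
        )

    def with_values(self, values: np.ndarray, units: str) -> "ScalarVolume":
        return ScalarVolume.like(self, values, units)

    def copy(self) -> "ScalarVolume":
        return replace(self, values=self.values.copy())
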