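"""Phantom-based grayscale -> QCT density calibration.

A calibration phantom contains inserts of manufacturer-specified
bone-mineral-equivalent (QCT) density. Sampling each insert's mean stored
grayscale and regressing density on grayscale gives the linear map used to
convert every voxel of the scan to QCT density.

Sampling mirrors the two ways practitioners measure inserts: a profile
line drawn through an insert (values trilinearly interpolated at uniform
steps along the line) or a cylindrical region of interest pooling every
voxel center inside the cylinder.

The regression runs on STORED grayscale values, not HU: the calibration
must live on the same scale as the voxel data it will be applied to, and
an affine HU rescale would simply be absorbed into the fitted slope and
intercept anyway. Ordinary (unweighted) least squares is used, with
density as the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DataError, GeometryError
from .volume import CTVolume, ScalarVolume

logger = logging.getLogger(__name__)

#: Warn when a phantom fit's R^2 drops below this; phantom scales are
#: near-linear by construction, so poor fits indicate a setup error.
DEFAULT_R2_WARN = 0.99


@dataclass(frozen=True)
class PhantomSample:
    """One calibration insert: known density paired with measured grayscale."""

    label: str
    qct_density: float  # mg/cm3, manufacturer-defined
    mean_grayscale: float  # stored-value units
    sd_grayscale: float = 0.0
    n: int = 1

    def __post_init__(self):
        if self.qct_density < 0:
            raise DataError(f"insert {self.label!r}: qct_density must be >= 0")
        if self.n < 1:
            raise DataError(f"insert {self.label!r}: sample needs n >= 1 points")
        if self.sd_grayscale < 0:
            raise DataError(f"insert {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class ProfileLine:
    """A straight sampling segment in world coordinates (mm).

    ``step`` is the sampling interval in mm; ``None`` defers to half the
    smallest voxel spacing of the volume being sampled.
    """

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    step: float | None = None

    def __post_init__(self):
        if np.allclose(self.start, self.end):
            raise DataError("profile line start and end coincide")
        if self.step is not None and self.step <= 0:
            raise DataError("profile line step must be positive")


@dataclass(frozen=True)
class CylinderROI:
    """A finite cylinder in world coordinates (mm)."""

    center: tuple[float, float, float]
    radius: float
    half_height: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.radius <= 0 or self.half_height <= 0:
            raise DataError("cylinder radius and half_height must be positive")
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise DataError("cylinder axis must be a unit vector")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear map stored grayscale -> QCT density (mg/cm3).

    ``slope`` is in mg/cm3 per stored unit, ``intercept`` in mg/cm3.
    ``slope_se``/``intercept_se`` are the OLS standard errors (NaN when
    fitted from exactly two points).
    """

    slope: float
    intercept: float
    r_squared: float
    residual_se: float
    n_samples: int
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def __post_init__(self):
        if self.n_samples < 2:
            raise DataError("a calibration needs at least 2 samples")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise DataError(f"r_squared out of [0, 1]: {self.r_squared}")

    def predict(self, grayscale):
        """Fitted QCT density (mg/cm3) for stored grayscale value(s)."""
        g = np.asarray(grayscale, dtype=float)
        out = self.slope * g + self.intercept
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "slope_mg_cm3_per_stored": self.slope,
            "intercept_mg_cm3": self.intercept,
            "r_squared": self.r_squared,
            "residual_se_mg_cm3": self.residual_se,
            "n_samples": self.n_samples,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            slope=float(d["slope_mg_cm3_per_stored"]),
            intercept=float(d["intercept_mg_cm3"]),
            r_squared=float(d["r_squared"]),
            residual_se=float(d["residual_se_mg_cm3"]),
            n_samples=int(d["n_samples"]),
            slope_se=float(d.get("slope_se", float("nan"))),
            intercept_se=float(d.get("intercept_se", float("nan"))),
        )


class GrayscaleCalibrator(RegressorMixin, BaseEstimator):
    """scikit-learn estimator for the phantom calibration line.

    ``fit(X, y)`` takes mean stored grayscale values as the single feature
    and manufacturer QCT densities (mg/cm3) as the response, and fits
    ordinary least squares. Fitted attributes follow sklearn conventions.

    Parameters
    ----------
    r2_warn_threshold : float
        Log a warning when the fitted R^2 falls below this value.
    """

    def __init__(self, r2_warn_threshold: float = DEFAULT_R2_WARN):
        self.r2_warn_threshold = r2_warn_threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise DataError("GrayscaleCalibrator expects a single grayscale feature")
        y = np.asarray(y, dtype=float)
        g = X[:, 0]
        if g.size < 2 or y.size != g.size:
            raise DataError("need at least 2 (grayscale, density) pairs")
        if np.ptp(g) == 0:
            raise DataError("all grayscale values identical; the line is undefined")

        res = stats.linregress(g, y)
        self.n_features_in_ = 1
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.slope_se_ = float(res.stderr)
        self.intercept_se_ = float(res.intercept_stderr)
        resid = y - (self.slope_ * g + self.intercept_)
        dof = g.size - 2
        self.residual_se_ = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
        self.n_samples_ = int(g.size)
        if self.r_squared_ < self.r2_warn_threshold:
            logger.warning(
                "calibration R^2 = %.4f below %.2f: check phantom measurements",
                self.r_squared_, self.r2_warn_threshold,
            )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.slope_ * X[:, 0] + self.intercept_

    def to_model(self) -> CalibrationModel:
        return CalibrationModel(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            residual_se=self.residual_se_,
            n_samples=self.n_samples_,
            slope_se=self.slope_se_,
            intercept_se=self.intercept_se_,
        )


# -- sampling ------------------------------------------------------------


def sample_profile_line(v: CTVolume, line: ProfileLine, label: str = "") -> PhantomSample:
    """Average stored values along a line through an insert.

    Values are trilinearly interpolated at uniform steps from ``start``
    towards ``end`` (both endpoints included when the length is an exact
    multiple of the step).
    """
    start = np.asarray(line.start, dtype=float)
    end = np.asarray(line.end, dtype=float)
    step = line.step if line.step is not None else 0.5 * float(np.min(v.spacing))
    length = float(np.linalg.norm(end - start))
    direction = (end - start) / length
    t = np.arange(0.0, length + 1e-9, step)
    points = start + t[:, None] * direction
    idx = np.atleast_2d(v.index_from_world(points))

    upper = np.asarray(v.shape, dtype=float) - 1.0
    inside = np.all((idx >= -1e-9) & (idx <= upper + 1e-9), axis=1)
    if not np.all(inside):
        first_bad = float(t[np.argmin(inside)])
        raise GeometryError(
            f"profile line leaves the volume at t = {first_bad:.3f} mm from its start"
        )
    vals = ndimage.map_coordinates(v.voxels.astype(float), idx.T, order=1, mode="nearest")
    return _make_sample(label, vals)


def _make_sample(label: str, vals: np.ndarray, qct_density: float = 0.0) -> PhantomSample:
    return PhantomSample(
        label=label,
        qct_density=qct_density,
        mean_grayscale=float(np.mean(vals)),
        sd_grayscale=float(np.std(vals, ddof=0)),
        n=int(vals.size),
    )


def sample_cylinder_roi(v: CTVolume, roi: CylinderROI, label: str = "") -> PhantomSample:
    """Average stored values over all voxel centers inside a cylinder."""
    center = np.asarray(roi.center, dtype=float)
    axis = np.asarray(roi.axis, dtype=float)

    # bounding sphere of the cylinder -> conservative index-space window
    reach = float(np.hypot(roi.radius, roi.half_height))
    lo_idx = np.floor(v.index_from_world(center) - reach / v.spacing - 1).astype(int)
    hi_idx = np.ceil(v.index_from_world(center) + reach / v.spacing + 1).astype(int)
    lo_idx = np.clip(lo_idx, 0, np.asarray(v.shape) - 1)
    hi_idx = np.clip(hi_idx, 0, np.asarray(v.shape) - 1)

    grids = np.meshgrid(
        *[np.arange(lo, hi + 1) for lo, hi in zip(lo_idx, hi_idx)], indexing="ij"
    )
    idx = np.stack([g.ravel() for g in grids], axis=1)
    world = np.atleast_2d(v.world_from_index(idx))
    rel = world - center
    along = rel @ axis
    radial2 = np.einsum("ij,ij->i", rel, rel) - along**2
    inside = (np.abs(along) <= roi.half_height) & (radial2 <= roi.radius**2 + 1e-12)
    if not np.any(inside):
        raise GeometryError(
            f"cylinder ROI at {tuple(center)} contains no voxel centers"
        )
    sel = idx[inside]
    vals = v.voxels[sel[:, 0], sel[:, 1], sel[:, 2]].astype(float)
    return _make_sample(label, vals)


# -- fitting and application ---------------------------------------------


def fit_calibration(samples: list[PhantomSample],
                    r2_warn_threshold: float = DEFAULT_R2_WARN) -> CalibrationModel:
    """OLS fit of QCT density (response) on mean stored grayscale."""
    if len(samples) < 2:
        raise DataError(f"need >= 2 phantom samples, got {len(samples)}")
    g = np.array([s.mean_grayscale for s in samples], dtype=float)
    rho = np.array([s.qct_density for s in samples], dtype=float)
    est = GrayscaleCalibrator(r2_warn_threshold=r2_warn_threshold).fit(g[:, None], rho)
    return est.to_model()


def propagated_coefficient_se(samples: list[PhantomSample],
                              model: CalibrationModel) -> tuple[float, float]:
    """Coefficient standard errors propagated from insert measurement noise.

    The regression's x values are insert-mean grayscales, each measured
    with known uncertainty ``sd / sqrt(n)`` from its ROI, while the
    manufacturer densities (y) are taken as exact. First-order
    propagation of those x-errors through the OLS estimator gives

        SE(slope)     = |slope| * sqrt(sum d_i^2 s_i^2) / Sxx
        SE(intercept) = sqrt(sum (slope * (xbar*d_i/Sxx - 1/n))^2 s_i^2)

    with ``d_i = x_i - xbar`` and ``Sxx = sum d_i^2``. Unlike the
    residual-based OLS errors (which for a handful of inserts rest on
    very few degrees of freedom and have heavy t tails), these are
    estimated from the thousands of voxels behind each mean, so +/-3 SE
    intervals carry near-Gaussian coverage.
    """
    x = np.array([s.mean_grayscale for s in samples], dtype=float)
    s_i = np.array([s.sd_grayscale / np.sqrt(s.n) for s in samples], dtype=float)
    xbar = x.mean()
    d = x - xbar
    sxx = float(np.sum(d**2))
    if sxx == 0:
        raise DataError("all grayscale values identical; SEs undefined")
    se_slope = abs(model.slope) * float(np.sqrt(np.sum(d**2 * s_i**2))) / sxx
    c = model.slope * (xbar * d / sxx - 1.0 / len(x))
    se_intercept = float(np.sqrt(np.sum(c**2 * s_i**2)))
    return se_slope, se_intercept


def apply_calibration(v: CTVolume, model: CalibrationModel) -> ScalarVolume:
    """Convert every stored voxel to QCT density (mg/cm3).

    Negative calibrated densities are retained; downstream they map below
    zero apparent density and land in the air branch.
    """
    values = model.slope * v.voxels.astype(float) + model.intercept
    return ScalarVolume.like(v, values, "mg/cm3")
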