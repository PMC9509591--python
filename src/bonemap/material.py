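"""Density-to-modulus material law for voxel-based bone FE models.

The mapping has two stages:

1. QCT (bone-mineral-equivalent) density to wet apparent density via the
   Lotz linear relation

       rho_app [g/cm3] = 0.0012 * rho_CT [mg/cm3] + 0.17

2. wet apparent density to Young's modulus via a three-branch piecewise
   law that treats air pockets, trabecular bone and cortical bone as
   distinct materials:

       rho_app <= 0            ->  E = 1 MPa            (air)
       0 < rho_app <= cutoff   ->  E = 11417.6 * rho_app**1.89 MPa
       rho_app > cutoff        ->  E = 17000 MPa        (cortical)

   with cutoff = 1 g/cm3 by default (user-settable). The trabecular
   coefficient is the Morgan power-law coefficient (8920) already scaled
   by the 1.28 transverse-stiffness factor: 8920 * 1.28 = 11417.6.

The strict inequalities of the published branches leave rho_app = 0 and
rho_app = cutoff undefined; this implementation assigns the boundaries as
rho <= 0 -> air and rho <= cutoff -> trabecular, a measure-zero choice
documented in the methods note. A configurable modulus floor (default
equal to the air modulus) keeps vanishingly small positive densities from
receiving sub-air stiffness, which would ill-condition FE solves; set
``modulus_floor=0`` to disable it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataError
from .volume import CTVolume, ScalarVolume

logger = logging.getLogger(__name__)

#: Morgan et al. trabecular coefficient before transverse adjustment, MPa.
MORGAN_BASE_COEFFICIENT = 8920.0


@dataclass(frozen=True)
class MaterialLaw:
    """Constants of the piecewise density -> Young's modulus mapping.

    Attributes
    ----------
    lotz_slope : float
        Lotz slope, g/cm3 of apparent density per mg/cm3 of QCT density.
    lotz_intercept : float
        Lotz intercept, g/cm3.
    air_modulus : float
        Modulus assigned to air pockets (rho_app <= 0), MPa.
    trab_coefficient : float
        Trabecular power-law coefficient, MPa per (g/cm3)**exponent, with
        the transverse factor already folded in.
    trab_exponent : float
        Trabecular power-law exponent, unitless.
    transverse_factor : float
        The transverse-stiffness adjustment already contained in
        ``trab_coefficient`` (kept explicit so a base Morgan coefficient
        can be scaled via :meth:`from_morgan`).
    cortical_modulus : float
        Constant cortical modulus, MPa.
    cutoff_density : float
        Trabecular/cortical cutoff, g/cm3.
    modulus_floor : float
        Lower clamp on the trabecular branch, MPa (0 disables).
    """

    lotz_slope: float = 0.0012
    lotz_intercept: float = 0.17
    air_modulus: float = 1.0
    trab_coefficient: float = 11417.6
    trab_exponent: float = 1.89
    transverse_factor: float = 1.28
    cortical_modulus: float = 17000.0
    cutoff_density: float = 1.0
    modulus_floor: float = 1.0

    def __post_init__(self):
        if self.air_modulus <= 0 or self.cortical_modulus <= 0 or self.trab_coefficient <= 0:
            raise DataError("all moduli must be positive")
        if self.cutoff_density <= 0:
            raise DataError("cutoff_density must be positive")
        if self.trab_exponent <= 0:
            raise DataError("trab_exponent must be positive")
        if self.modulus_floor < 0:
            raise DataError("modulus_floor must be non-negative")
        if self.trabecular_modulus_at_cutoff > self.cortical_modulus:
            warnings.warn(
                "trabecular law at the cutoff "
                f"({self.trabecular_modulus_at_cutoff:.1f} MPa) exceeds the cortical "
                f"modulus ({self.cortical_modulus:.1f} MPa); the mapping is no longer "
                "monotone in density",
                stacklevel=2,
            )

    @property
    def trabecular_modulus_at_cutoff(self) -> float:
        return self.trab_coefficient * self.cutoff_density**self.trab_exponent

    @property
    def cutoff_jump(self) -> float:
        """Magnitude of the modulus discontinuity at the cutoff, MPa."""
        return self.cortical_modulus - self.trabecular_modulus_at_cutoff

    @classmethod
    def from_morgan(cls, base_coefficient: float = MORGAN_BASE_COEFFICIENT,
                    transverse_factor: float = 1.28, **kwargs) -> "MaterialLaw":
        """Build a law from an unadjusted Morgan-style coefficient.

        The transverse factor is applied explicitly:
        ``trab_coefficient = base_coefficient * transverse_factor``.
        """
        return cls(
            trab_coefficient=base_coefficient * transverse_factor,
            transverse_factor=transverse_factor,
            **kwargs,
        )

    def with_cutoff(self, cutoff_density: float) -> "MaterialLaw":
        return replace(self, cutoff_density=cutoff_density)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialLaw":
        return cls(**d)


def qct_to_apparent(rho_ct, law: MaterialLaw | None = None):
    """Convert QCT density (mg/cm3) to wet apparent density (g/cm3).

    Accepts scalars, arrays or a ``ScalarVolume`` tagged mg/cm3. Negative
    inputs are allowed and map below zero; they drive the air branch
    downstream.
    """
    law = law or MaterialLaw()
    if isinstance(rho_ct, ScalarVolume):
        if rho_ct.units != "mg/cm3":
            raise DataError(f"expected a mg/cm3 volume, got units {rho_ct.units!r}")
        out = law.lotz_slope * rho_ct.values + law.lotz_intercept
        return rho_ct.with_values(out, "g/cm3")
    rho_ct = np.asarray(rho_ct, dtype=float)
    out = law.lotz_slope * rho_ct + law.lotz_intercept
    return out if out.ndim else float(out)


def apparent_to_modulus(rho_app, law: MaterialLaw | None = None):
    """Map wet apparent density (g/cm3) to Young's modulus (MPa).

    Branch assignment: ``rho <= 0`` air; ``0 < rho <= cutoff`` trabecular
    power law (clamped at ``modulus_floor``); ``rho > cutoff`` cortical.
    Accepts scalars, arrays or a g/cm3 ``ScalarVolume``.
    """
    law = law or MaterialLaw()
    if isinstance(rho_app, ScalarVolume):
        if rho_app.units != "g/cm3":
            raise DataError(f"expected a g/cm3 volume, got units {rho_app.units!r}")
        return rho_app.with_values(_modulus_array(rho_app.values, law), "MPa")
    rho = np.asarray(rho_app, dtype=float)
    out = _modulus_array(rho, law)
    return out if out.ndim else float(out)


def _modulus_array(rho: np.ndarray, law: MaterialLaw) -> np.ndarray:
    trab = law.trab_coefficient * np.power(np.clip(rho, 0.0, None), law.trab_exponent)
    trab = np.maximum(trab, law.modulus_floor)
    out = np.where(
        rho <= 0.0,
        law.air_modulus,
        np.where(rho <= law.cutoff_density, trab, law.cortical_modulus),
    )
    return out


def branch_labels(rho_app: np.ndarray, law: MaterialLaw) -> np.ndarray:
    """Per-voxel branch index: 0 air, 1 trabecular, 2 cortical."""
    rho = np.asarray(rho_app, dtype=float)
    return np.where(rho <= 0.0, 0, np.where(rho <= law.cutoff_density, 1, 2)).astype(np.int8)


def branch_counts(rho_app: np.ndarray, law: MaterialLaw) -> dict[str, int]:
    labels = branch_labels(rho_app, law)
    return {
        "air": int(np.sum(labels == 0)),
        "trabecular": int(np.sum(labels == 1)),
        "cortical": int(np.sum(labels == 2)),
    }


class ModulusMapper(TransformerMixin, BaseEstimator):
    """Stateless scikit-learn transformer wrapping the material law.

    ``transform`` maps densities elementwise to Young's modulus in MPa.
    ``input_units`` selects whether inputs are QCT density (mg/cm3, the
    Lotz conversion is applied first) or already wet apparent density
    (g/cm3).
    """

    def __init__(self, law: MaterialLaw | None = None, input_units: str = "g/cm3"):
        self.law = law
        self.input_units = input_units

    def fit(self, X=None, y=None):
        if self.input_units not in ("g/cm3", "mg/cm3"):
            raise DataError("input_units must be 'g/cm3' or 'mg/cm3'")
        self.law_ = self.law or MaterialLaw()
        return self

    def transform(self, X):
        if not hasattr(self, "law_"):
            self.fit()
        rho = np.asarray(X, dtype=float)
        if self.input_units == "mg/cm3":
            rho = qct_to_apparent(rho, self.law_)
        return _modulus_array(rho, self.law_)


@dataclass
class ConversionResult:
    """Output bundle of :func:`convert_volume`."""

    modulus: ScalarVolume
    qct_density: ScalarVolume | None
    apparent_density: ScalarVolume | None
    branch_counts: dict[str, int]
    law: MaterialLaw
    calibration: "object"

    def summary(self) -> dict:
        e = self.modulus.values
        total = int(e.size)
        counts = dict(self.branch_counts)
        assert counts["air"] + counts["trabecular"] + counts["cortical"] == total
        return {
            "voxels_total": total,
            "branch_counts": counts,
            "modulus_MPa": {
                "min": float(e.min()),
                "median": float(np.median(e)),
                "max": float(e.max()),
            },
            "cutoff_density_g_cm3": self.law.cutoff_density,
            "cutoff_jump_MPa": self.law.cutoff_jump,
            "calibration": {
                "slope_mg_cm3_per_stored": self.calibration.slope,
                "intercept_mg_cm3": self.calibration.intercept,
                "r_squared": self.calibration.r_squared,
            }
            if self.calibration is not None
            else None,
            "material_law": self.law.to_dict(),
        }


def convert_volume(v: CTVolume, model, law: MaterialLaw | None = None,
                   keep_intermediates: bool = True) -> ConversionResult:
    """Run the full stored-grayscale -> modulus pipeline on a volume.

    Equivalent voxel-for-voxel to
    ``apparent_to_modulus(qct_to_apparent(apply_calibration(v)))``.

    Parameters
    ----------
    v : CTVolume
    model : CalibrationModel
        Fitted grayscale -> QCT-density calibration.
    law : MaterialLaw, optional
    keep_intermediates : bool
        Also return the mg/cm3 and g/cm3 density volumes.
    """
    from .calibration import apply_calibration  # local import: avoid cycle

    law = law or MaterialLaw()
    qct = apply_calibration(v, model)
    app = qct_to_apparent(qct, law)
    e = apparent_to_modulus(app, law)
    counts = branch_counts(app.values, law)
    logger.info(
        "converted %s voxels: air=%d trabecular=%d cortical=%d",
        v.voxels.size, counts["air"], counts["trabecular"], counts["cortical"],
    )
    return ConversionResult(
        modulus=e,
        qct_density=qct if keep_intermediates else None,
        apparent_density=app if keep_intermediates else None,
        branch_counts=counts,
        law=law,
        calibration=model,
    )
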