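"""Synthetic CT phantoms and bone-like volumes with exact ground truth.

Real QCT calibration needs a scanned phantom; none ships with this
package, so this module fabricates one. A phantom scan is emulated as
cylindrical inserts of known QCT density embedded in a uniform background,
with stored grayscale values generated by inverting a chosen linear
grayscale<->density relation and adding independent Gaussian noise on the
stored-value scale. A bone-like volume emulates the anatomy the pipeline
targets: a dense cortical block enclosing an ellipsoidal trabecular core
with an optional internal air pocket, so that every branch of the material
law is exercised.

Each generator returns the ``CTVolume`` plus a ``GroundTruth`` carrying
the exact noiseless density, apparent-density and modulus fields computed
with the same closed-form law the pipeline uses, so tests can demand
bit-equality instead of tolerances. All randomness flows from a single
``numpy.random.default_rng`` (PCG64) seed recorded in the output.

What this emulation leaves out, deliberately: beam hardening, scatter,
partial-volume blur, spatially correlated noise and scanner transfer
functions. Passing tests therefore validate the calibration/conversion
arithmetic, not robustness to CT physics artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CylinderROI, PhantomSample
from .errors import DataError
from .material import MaterialLaw, apparent_to_modulus, branch_counts, qct_to_apparent
from .volume import CTVolume, ScalarVolume

STORED_MIN, STORED_MAX = -32768, 32767  # int16 stored-value range


@dataclass(frozen=True)
class InsertSpec:
    """One phantom insert: a cylinder of known QCT density (mg/cm3)."""

    label: str
    qct_density: float
    center: tuple[float, float, float]  # world mm
    radius: float
    half_height: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def roi(self) -> CylinderROI:
        return CylinderROI(
            center=self.center, radius=self.radius,
            half_height=self.half_height, axis=self.axis,
        )


@dataclass(frozen=True)
class PhantomDesign:
    """Geometry and ground-truth scale of a synthetic phantom acquisition.

    ``true_slope`` (mg/cm3 per stored unit) and ``true_intercept``
    (mg/cm3) define the density = slope*stored + intercept line the
    generator inverts; a perfect calibration recovers exactly these.
    ``noise_sd`` is the Gaussian noise standard deviation in stored-value
    units (HU-scale noise for a slope-1 rescale).
    """

    shape: tuple[int, int, int] = (24, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 0.8, 0.8)
    inserts: tuple[InsertSpec, ...] = ()
    background_density: float = 0.0
    true_slope: float = 2.0
    true_intercept: float = -100.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if self.true_slope == 0:
            raise DataError("true_slope must be non-zero")
        if not self.inserts:
            raise DataError("a phantom design needs at least one insert")


@dataclass
class GroundTruth:
    """Exact noiseless fields carried alongside a synthetic volume."""

    density: ScalarVolume  # mg/cm3
    apparent_density: ScalarVolume  # g/cm3
    modulus: ScalarVolume  # MPa
    insert_means: dict[str, float] = field(default_factory=dict)  # label -> stored mean
    insert_densities: dict[str, float] = field(default_factory=dict)
    branch_counts: dict[str, int] = field(default_factory=dict)
    n_clipped: int = 0
    rng_seed: int = 0


def default_phantom_design(noise_sd: float = 0.0, rng_seed: int = 0) -> PhantomDesign:
    """Five-insert design spanning water to dense cortical-equivalent.

    Densities 0/100/200/400/800 mg/cm3 follow the spread of commercial
    tissue-equivalent calibration inserts; with the default slope-2,
    intercept -100 line they invert to exact integer stored values, so a
    noiseless acquisition is lossless. Insert cylinders (radius 4 mm,
    height 16 mm on 0.8 mm pixels) contain well over 200 voxel centers
    each.
    """
    densities = (0.0, 100.0, 200.0, 400.0, 800.0)
    inserts = tuple(
        InsertSpec(
            label=f"insert_{int(rho)}",
            qct_density=rho,
            center=(8.0 + 9.6 * i, 25.6, 12.0),
            radius=4.0,
            half_height=8.0,
            axis=(0.0, 0.0, 1.0),
        )
        for i, rho in enumerate(densities)
    )
    return PhantomDesign(inserts=inserts, noise_sd=noise_sd, rng_seed=rng_seed)


def _validate_disjoint_inside(design: PhantomDesign, vol: CTVolume) -> None:
    corners_lo = vol.world_from_index([0, 0, 0])
    corners_hi = vol.world_from_index(np.asarray(vol.shape) - 1)
    lo = np.minimum(corners_lo, corners_hi)
    hi = np.maximum(corners_lo, corners_hi)
    for ins in design.inserts:
        c = np.asarray(ins.center)
        a = np.abs(np.asarray(ins.axis, dtype=float))
        # exact world-axis extent of a finite cylinder
        reach = ins.radius * np.sqrt(np.clip(1 - a**2, 0, 1)) + ins.half_height * a
        if np.any(c - reach < lo - 1e-9) or np.any(c + reach > hi + 1e-9):
            raise DataError(f"insert {ins.label!r} extends outside the volume")
    for i, a in enumerate(design.inserts):
        for b in design.inserts[i + 1:]:
            dist = np.linalg.norm(np.asarray(a.center) - np.asarray(b.center))
            if dist < a.radius + b.radius:  # coaxial z-cylinders: radial test suffices
                raise DataError(f"inserts {a.label!r} and {b.label!r} overlap")


def _density_field(design: PhantomDesign, vol_shape, spacing, origin, orientation) -> np.ndarray:
    probe = CTVolume(
        voxels=np.zeros(vol_shape, dtype=np.int16),
        spacing=spacing, origin=origin, orientation=orientation,
    )
    grids = np.meshgrid(*[np.arange(n) for n in vol_shape], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    world = np.atleast_2d(probe.world_from_index(idx))
    rho = np.full(idx.shape[0], design.background_density, dtype=float)
    for ins in design.inserts:
        rel = world - np.asarray(ins.center)
        along = rel @ np.asarray(ins.axis, dtype=float)
        radial2 = np.einsum("ij,ij->i", rel, rel) - along**2
        inside = (np.abs(along) <= ins.half_height) & (radial2 <= ins.radius**2 + 1e-12)
        rho[inside] = ins.qct_density
    return rho.reshape(vol_shape)


def make_phantom_volume(design: PhantomDesign,
                        law: MaterialLaw | None = None) -> tuple[CTVolume, GroundTruth]:
    """Synthesize a phantom acquisition and its exact ground truth.

    Stored values are ``round((rho - intercept) / slope)`` plus Gaussian
    noise of standard deviation ``noise_sd``, re-rounded to integers and
    clipped to the int16 range (clipping events are counted). The ground
    truth carries the noiseless density implied by the rounded stored
    values, so the generator and the calibration line are mutually exact.
    """
    law = law or MaterialLaw()
    spacing = np.asarray(design.spacing, dtype=float)
    origin = np.zeros(3)
    orientation = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])

    rho_nominal = _density_field(design, design.shape, spacing, origin, orientation)
    stored_exact = np.round((rho_nominal - design.true_intercept) / design.true_slope)

    rng = np.random.default_rng(design.rng_seed)
    noisy = stored_exact
    if design.noise_sd > 0:
        noisy = stored_exact + rng.normal(0.0, design.noise_sd, size=stored_exact.shape)
        noisy = np.round(noisy)
    n_clipped = int(np.sum((noisy < STORED_MIN) | (noisy > STORED_MAX)))
    stored = np.clip(noisy, STORED_MIN, STORED_MAX).astype(np.int16)

    vol = CTVolume(
        voxels=stored, spacing=spacing, origin=origin, orientation=orientation,
        rescale_slope=1.0, rescale_intercept=-1024.0,
        source_id=f"synthetic-phantom(seed={design.rng_seed})",
    )
    _validate_disjoint_inside(design, vol)

    # exact density implied by the (rounded) noiseless stored values
    rho_true = design.true_slope * stored_exact + design.true_intercept
    density = ScalarVolume.like(vol, rho_true, "mg/cm3")
    apparent = qct_to_apparent(density, law)
    modulus = apparent_to_modulus(apparent, law)

    truth = GroundTruth(
        density=density,
        apparent_density=apparent,
        modulus=modulus,
        insert_means={
            ins.label: float(np.round((ins.qct_density - design.true_intercept) / design.true_slope))
            for ins in design.inserts
        },
        insert_densities={ins.label: ins.qct_density for ins in design.inserts},
        branch_counts=branch_counts(apparent.values, law),
        n_clipped=n_clipped,
        rng_seed=design.rng_seed,
    )
    return vol, truth


def sample_design_inserts(vol: CTVolume, design: PhantomDesign) -> list[PhantomSample]:
    """Measure every insert of a design with its cylindrical ROI."""
    from dataclasses import replace

    from .calibration import sample_cylinder_roi

    out = []
    for ins in design.inserts:
        s = sample_cylinder_roi(vol, ins.roi(), label=ins.label)
        out.append(replace(s, qct_density=ins.qct_density))
    return out


def make_bone_volume(
    shape: tuple[int, int, int] = (32, 48, 48),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    shell_density: float = 1200.0,
    interior_density_range: tuple[float, float] = (100.0, 500.0),
    pocket_density: float | None = -400.0,
    pocket_radius_fraction: float = 0.35,
    core_fraction: float = 0.7,
    law: MaterialLaw | None = None,
    rng_seed: int = 0,
) -> tuple[CTVolume, GroundTruth]:
    """Synthesize a bone-like volume: cortical block, trabecular core, air pocket.

    The whole volume is cortical-density material except an ellipsoidal
    core (semi-axes ``core_fraction`` of each half-dimension; 0 yields a
    shell-only, uniformly cortical volume) filled with voxelwise
    uniform-random trabecular densities, and, unless ``pocket_density`` is
    None, a central sphere of sub-air density. Stored values equal
    ``round(density)`` (an identity mg/cm3-per-stored calibration), so the
    pipeline run with the generator's own line reproduces the ground truth
    exactly.

    Densities are validated against the material law's branch windows:
    the shell must map above the cutoff, the interior strictly inside
    (0, cutoff], and the pocket below zero apparent density.
    """
    law = law or MaterialLaw()

    def app(rho):
        return qct_to_apparent(float(rho), law)

    if app(shell_density) <= law.cutoff_density:
        raise DataError(
            f"shell_density {shell_density} maps to apparent density "
            f"{app(shell_density):.3f} g/cm3, not above the cutoff {law.cutoff_density}"
        )
    lo, hi = interior_density_range
    if not (0.0 < app(lo) and app(hi) <= law.cutoff_density):
        raise DataError(
            f"interior_density_range {interior_density_range} must map inside "
            f"(0, {law.cutoff_density}] g/cm3 apparent"
        )
    if pocket_density is not None and app(pocket_density) > 0:
        raise DataError(
            f"pocket_density {pocket_density} maps to apparent density "
            f"{app(pocket_density):.3f} g/cm3, not below zero"
        )

    if not 0.0 <= core_fraction < 1.0:
        raise DataError("core_fraction must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    dims = np.asarray(shape, dtype=float)
    center = (dims - 1) / 2
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    rho = np.full(shape, float(shell_density))
    if core_fraction > 0:
        rel = [(g - c) / (core_fraction * (d / 2)) for g, c, d in zip(grids, center, dims)]
        core = rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2 <= 1.0
        interior_draw = rng.uniform(lo, hi, size=shape)
        rho[core] = interior_draw[core]

    if pocket_density is not None and core_fraction > 0:
        pocket_r = pocket_radius_fraction * core_fraction * (dims.min() / 2)  # voxel units
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        rho[d2 <= pocket_r**2] = float(pocket_density)

    stored = np.clip(np.round(rho), STORED_MIN, STORED_MAX).astype(np.int16)
    rho_true = stored.astype(float)  # identity calibration on rounded values

    vol = CTVolume(
        voxels=stored, spacing=np.asarray(spacing, dtype=float),
        rescale_slope=1.0, rescale_intercept=-1024.0,
        source_id=f"synthetic-bone(seed={rng_seed})",
    )
    density = ScalarVolume.like(vol, rho_true, "mg/cm3")
    apparent = qct_to_apparent(density, law)
    modulus = apparent_to_modulus(apparent, law)
    truth = GroundTruth(
        density=density,
        apparent_density=apparent,
        modulus=modulus,
        branch_counts=branch_counts(apparent.values, law),
        n_clipped=0,
        rng_seed=rng_seed,
    )
    return vol, truth


def calibration_recovery_study(n_runs: int = 100, noise_sd: float = 20.0,
                               base_seed: int = 0) -> dict:
    """Parameter-recovery simulation for the phantom calibration.

    For each of ``n_runs`` seeds, synthesize the default five-insert
    phantom with Gaussian stored-value noise, measure every insert with
    its cylindrical ROI, fit the calibration line, and test whether both
    the fitted slope and intercept fall within 3 propagated standard
    errors of the generator's true line.

    Returns a dict with the per-run hit count, the hit rate, and the mean
    absolute coefficient errors.
    """
    from .calibration import fit_calibration, propagated_coefficient_se

    hits = 0
    slope_errs, int_errs = [], []
    for k in range(n_runs):
        design = default_phantom_design(noise_sd=noise_sd, rng_seed=base_seed + k)
        vol, _ = make_phantom_volume(design)
        samples = sample_design_inserts(vol, design)
        model = fit_calibration(samples)
        se_slope, se_int = propagated_coefficient_se(samples, model)
        ok_slope = abs(model.slope - design.true_slope) <= 3 * se_slope
        ok_int = abs(model.intercept - design.true_intercept) <= 3 * se_int
        hits += ok_slope and ok_int
        slope_errs.append(abs(model.slope - design.true_slope))
        int_errs.append(abs(model.intercept - design.true_intercept))
    return {
        "n_runs": n_runs,
        "hits": int(hits),
        "hit_rate": hits / n_runs,
        "mean_abs_slope_error": float(np.mean(slope_errs)),
        "mean_abs_intercept_error": float(np.mean(int_errs)),
    }


def identity_calibration() -> "object":
    """The CalibrationModel matching :func:`make_bone_volume`'s encoding."""
    from .calibration import CalibrationModel

    return CalibrationModel(
        slope=1.0, intercept=0.0, r_squared=1.0, residual_se=0.0, n_samples=2,
    )
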