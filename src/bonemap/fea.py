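"""Binning voxel modulus maps into FEA material assignments.

FE preprocessors typically accept a modest number of distinct isotropic
materials rather than one per voxel. This module partitions a Young's
modulus volume into bins: air voxels always get the reserved bin 0 and
the constant cortical modulus its own top bin, while the trabecular range
in between is split into ``n_bins`` intervals of equal width either in
modulus or in the apparent density that produced it. Each bin's
representative modulus is the mean of its member voxels.

The Poisson ratio written into solver snippets is NOT part of the
density-modulus model; it is a user-supplied constant (default 0.3) and
the output header says so.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError
from .material import MaterialLaw
from .volume import ScalarVolume

STRATEGIES = ("equal_width_E", "equal_width_rho")


@dataclass
class MaterialBinning:
    """A complete voxel -> material-bin assignment.

    ``labels`` holds one bin index per voxel; ``edges`` are the modulus
    bin edges (MPa) covering bins 1..n_trabecular; bin 0 is air and the
    highest index is cortical. ``representatives[i]`` is the mean modulus
    of bin ``i`` (NaN for unoccupied bins).
    """

    labels: np.ndarray
    edges: np.ndarray
    representatives: np.ndarray
    counts: np.ndarray
    strategy: str
    geometry: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.representatives)

    @property
    def occupied(self) -> np.ndarray:
        return np.flatnonzero(self.counts > 0)

    def table(self) -> list[tuple[int, float, int]]:
        """(bin_id, representative E in MPa, voxel count) for occupied bins."""
        return [(int(i), float(self.representatives[i]), int(self.counts[i]))
                for i in self.occupied]


def bin_materials(e: ScalarVolume, n_bins: int = 10,
                  strategy: str = "equal_width_E",
                  law: MaterialLaw | None = None) -> MaterialBinning:
    """Partition a modulus volume into FEA material bins.

    Parameters
    ----------
    e : ScalarVolume
        Young's modulus field in MPa.
    n_bins : int
        Number of trabecular bins (>= 1). Air and cortical voxels always
        occupy their own reserved bins regardless.
    strategy : {"equal_width_E", "equal_width_rho"}
        Equal-width intervals in modulus, or in the apparent density
        recovered by inverting the trabecular power law.
    law : MaterialLaw, optional
        Identifies the air and cortical constants; defaults used if None.
    """
    if e.units != "MPa":
        raise DataError(f"expected a MPa volume, got units {e.units!r}")
    if n_bins < 1:
        raise DataError("n_bins must be >= 1")
    if strategy not in STRATEGIES:
        raise DataError(f"strategy must be one of {STRATEGIES}")
    law = law or MaterialLaw()

    vals = e.values
    is_air = vals == law.air_modulus
    is_cort = vals == law.cortical_modulus
    is_trab = ~(is_air | is_cort)
    trab_vals = vals[is_trab]

    if trab_vals.size:
        lo, hi = float(trab_vals.min()), float(trab_vals.max())
        n_distinct = np.unique(trab_vals).size
        if n_bins > n_distinct:
            warnings.warn(
                f"n_bins={n_bins} exceeds the {n_distinct} distinct trabecular "
                "values; collapsing to that many bins",
                stacklevel=2,
            )
            n_bins = n_distinct
        if strategy == "equal_width_E" or lo == hi:
            edges = np.linspace(lo, hi, n_bins + 1)
        else:
            # equal width in density: invert E = c * rho**p on the occupied range
            rho = (trab_vals / law.trab_coefficient) ** (1.0 / law.trab_exponent)
            rho_edges = np.linspace(float(rho.min()), float(rho.max()), n_bins + 1)
            edges = law.trab_coefficient * rho_edges**law.trab_exponent
        edges = np.unique(edges)
        n_bins = len(edges) - 1 if len(edges) > 1 else 1
    else:
        edges = np.array([law.air_modulus, law.cortical_modulus])
        n_bins = 1

    # label layout: 0 air | 1..n_bins trabecular | n_bins+1 cortical
    labels = np.zeros(vals.shape, dtype=np.int32)
    if trab_vals.size and len(edges) > 1:
        trab_labels = np.clip(np.searchsorted(edges, trab_vals, side="right"), 1, n_bins)
        labels[is_trab] = trab_labels
    elif trab_vals.size:
        labels[is_trab] = 1
    labels[is_cort] = n_bins + 1

    total_bins = n_bins + 2
    counts = np.bincount(labels.ravel(), minlength=total_bins)
    reps = np.full(total_bins, np.nan)
    sums = np.bincount(labels.ravel(), weights=vals.ravel(), minlength=total_bins)
    occ = counts > 0
    reps[occ] = sums[occ] / counts[occ]

    return MaterialBinning(
        labels=labels, edges=edges, representatives=reps,
        counts=counts, strategy=strategy,
        geometry={"spacing": e.spacing, "origin": e.origin, "orientation": e.orientation},
    )


def write_material_table(b: MaterialBinning, path: str | Path,
                         dialect: str = "csv", poisson_ratio: float = 0.3) -> Path:
    """Write the bin table as CSV or as an Abaqus-style material snippet.

    The snippet emits one isotropic elastic material per occupied bin.
    The Poisson ratio is a configuration constant, not derived from any
    imaging data, and the file header flags it as such.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = b.table()
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["bin_id", "E_MPa", "voxel_count"])
            for bin_id, rep, count in rows:
                w.writerow([bin_id, repr(rep), count])
    elif dialect == "abaqus":
        lines = [
            "** Voxel material bins exported by bonemap",
            f"** Poisson ratio {poisson_ratio} is a user-supplied constant,",
            "** NOT derived from the CT density pipeline.",
        ]
        for bin_id, rep, count in rows:
            lines += [
                f"*Material, name=BONE_BIN_{bin_id}",
                "*Elastic",
                f"{rep:.6g}, {poisson_ratio}",
            ]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise DataError(f"unknown dialect {dialect!r}; expected 'csv' or 'abaqus'")
    return path


def read_material_table(path: str | Path) -> list[tuple[int, float, int]]:
    """Read back a CSV written by :func:`write_material_table`."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [(int(r["bin_id"]), float(r["E_MPa"]), int(r["voxel_count"])) for r in rows]


def label_volume(b: MaterialBinning) -> ScalarVolume:
    """The bin-index field as a ScalarVolume (for NIfTI export)."""
    return ScalarVolume(
        values=b.labels.astype(float), units="MPa",  # index field; units tag is nominal
        spacing=b.geometry["spacing"], origin=b.geometry["origin"],
        orientation=b.geometry["orientation"],
    )
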