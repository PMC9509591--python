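"""YAML configuration: material-law files and phantom specifications."""

from __future__ import annotations

from dataclasses import replace
from importlib import resources
from pathlib import Path

import yaml

from .calibration import CylinderROI, PhantomSample, ProfileLine
from .errors import DataError
from .material import MaterialLaw

_LAW_KEYS = set(MaterialLaw().to_dict())


def default_law_path():
    return resources.files("bonemap.data") / "material_law.yaml"


def load_material_law(path: str | Path | None = None) -> MaterialLaw:
    """Load a MaterialLaw from YAML; no path loads the packaged defaults."""
    if path is None:
        text = default_law_path().read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise DataError("material-law file must be a YAML mapping")
    unknown = set(raw) - _LAW_KEYS
    if unknown:
        raise DataError(f"unknown material-law keys: {sorted(unknown)}")
    try:
        return MaterialLaw(**{k: float(v) for k, v in raw.items()})
    except (TypeError, ValueError) as exc:
        raise DataError(f"bad material-law file: {exc}") from exc


def save_material_law(law: MaterialLaw, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(law.to_dict(), sort_keys=False))


def load_phantom_spec(path: str | Path):
    """Parse a phantom specification file.

    Layout::

        inserts:
          - label: water
            qct_density_mg_cm3: 0.0
            mean_grayscale: 512.0            # typed-in measurement, or
            roi:                             # geometry to measure from the scan
              type: cylinder                 # or: line
              center_mm: [25.0, 25.0, 12.0]
              radius_mm: 4.0
              half_height_mm: 8.0
              axis: [0, 0, 1]                # optional

    Returns a list of ``(label, qct_density, sample_or_geometry)`` where the
    third element is a ready PhantomSample (typed-in mean), a CylinderROI
    or a ProfileLine.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "inserts" not in raw:
        raise DataError(f"{path}: phantom spec needs a top-level 'inserts' list")
    out = []
    for i, entry in enumerate(raw["inserts"]):
        try:
            label = str(entry.get("label", f"insert_{i}"))
            rho = float(entry["qct_density_mg_cm3"])
        except (KeyError, TypeError, ValueError) as exc:
            raise DataError(f"{path}: insert {i}: {exc}") from exc
        if "mean_grayscale" in entry:
            sample = PhantomSample(
                label=label, qct_density=rho,
                mean_grayscale=float(entry["mean_grayscale"]),
                sd_grayscale=float(entry.get("sd_grayscale", 0.0)),
                n=int(entry.get("n", 1)),
            )
            out.append((label, rho, sample))
            continue
        roi = entry.get("roi")
        if roi is None:
            raise DataError(
                f"{path}: insert {label!r} needs either mean_grayscale or roi"
            )
        kind = roi.get("type", "cylinder")
        if kind == "cylinder":
            geom = CylinderROI(
                center=tuple(float(x) for x in roi["center_mm"]),
                radius=float(roi["radius_mm"]),
                half_height=float(roi["half_height_mm"]),
                axis=tuple(float(x) for x in roi.get("axis", (0.0, 0.0, 1.0))),
            )
        elif kind == "line":
            geom = ProfileLine(
                start=tuple(float(x) for x in roi["start_mm"]),
                end=tuple(float(x) for x in roi["end_mm"]),
                step=float(roi["step_mm"]) if "step_mm" in roi else None,
            )
        else:
            raise DataError(f"{path}: insert {label!r}: unknown roi type {kind!r}")
        out.append((label, rho, geom))
    return out


def measure_phantom(volume, spec_entries) -> list[PhantomSample]:
    """Turn parsed phantom-spec entries into PhantomSamples.

    Typed-in samples pass through; geometric entries are measured from the
    volume. Multiple entries sharing a label are pooled by inverse of
    their counts (a plain weighted mean of means).
    """
    from .calibration import sample_cylinder_roi, sample_profile_line

    measured: dict[str, list[PhantomSample]] = {}
    for label, rho, item in spec_entries:
        if isinstance(item, PhantomSample):
            s = item
        elif isinstance(item, CylinderROI):
            s = replace(sample_cylinder_roi(volume, item, label=label), qct_density=rho)
        elif isinstance(item, ProfileLine):
            s = replace(sample_profile_line(volume, item, label=label), qct_density=rho)
        else:  # pragma: no cover - guarded by the parser
            raise DataError(f"unsupported phantom entry for {label!r}")
        measured.setdefault(label, []).append(s)

    pooled = []
    for label, group in measured.items():
        if len(group) == 1:
            pooled.append(group[0])
            continue
        n = sum(s.n for s in group)
        mean = sum(s.mean_grayscale * s.n for s in group) / n
        # pooled spread: combine within- and between-measurement variance
        var = sum(s.n * (s.sd_grayscale**2 + (s.mean_grayscale - mean) ** 2) for s in group) / n
        pooled.append(PhantomSample(
            label=label, qct_density=group[0].qct_density,
            mean_grayscale=mean, sd_grayscale=float(var**0.5), n=n,
        ))
    return pooled
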