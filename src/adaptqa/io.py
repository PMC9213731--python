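"""NIfTI I/O for structure sets and dose grids.

A structure set on disk is a directory of single-structure NIfTI masks
(uint8, strictly 0/1) plus a ``structures.json`` sidecar::

    {
      "rx_Gy": 40.0,
      "axis_order": "xyz (index-to-world affine is diagonal, mm)",
      "structures": [
        {"name": "PTV", "file": "PTV.nii.gz", "role": "PTV"},
        {"name": "stomach", "file": "stomach.nii.gz", "role": "OAR"},
        ...
      ]
    }

Doses are single NIfTI volumes (float) with a ``<stem>.json`` sidecar
carrying ``rx_Gy``.  Round-trips are lossless for mask content, geometry
and names.  Any mask value other than 0/1 is rejected rather than
thresholded, and geometry mismatches across files of one set are errors —
there is deliberately no resampling path.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import ROLES, BinaryStructure, DoseGrid, GridGeometry, StructureSet

__all__ = [
    "read_structure_set",
    "write_structure_set",
    "read_dose",
    "write_dose",
]

SIDECAR_NAME = "structures.json"


def _geometry_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> GridGeometry:
    lin = np.asarray(affine)[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.abs(off_diag).max() > 1e-6:
        raise ValueError(
            "only axis-aligned (diagonal-affine) NIfTI volumes are supported; "
            "resample/reorient upstream"
        )
    spacing = np.diag(lin)
    if np.any(spacing <= 0):
        raise ValueError("NIfTI affine must have positive diagonal spacing")
    origin = np.asarray(affine)[:3, 3]
    return GridGeometry(tuple(shape), tuple(spacing), tuple(origin))


def _load_nifti(path: Path) -> tuple[np.ndarray, GridGeometry]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return data, _geometry_from_affine(img.affine, data.shape)


def write_structure_set(sset: StructureSet, directory: str | Path) -> Path:
    """Write every structure as uint8 NIfTI plus the JSON sidecar.

    Returns the sidecar path.  JSON keys are sorted so repeated writes of
    the same set are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = sset.geometry.affine()
    entries = []
    for name, struct in sset.structures.items():
        fname = f"{name}.nii.gz"
        img = nib.Nifti1Image(struct.mask.astype(np.uint8), affine)
        img.to_filename(str(directory / fname))
        entries.append({"name": name, "file": fname, "role": sset.roles[name]})
    sidecar = {
        "axis_order": "xyz (index-to-world affine is diagonal, mm)",
        "structures": entries,
    }
    if sset.rx_Gy is not None:
        sidecar["rx_Gy"] = sset.rx_Gy
    path = directory / SIDECAR_NAME
    path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return path


def read_structure_set(
    directory: str | Path, required_roles: tuple[str, ...] = ("PTV",)
) -> StructureSet:
    """Load a structure-set directory written by :func:`write_structure_set`.

    ``required_roles`` lists roles that must be present (default: the PTV,
    which every downstream clipping/ring operation needs); a missing role
    raises an error naming it.
    """
    directory = Path(directory)
    sidecar_path = directory / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "structures" not in sidecar:
        raise ValueError(f"{sidecar_path}: missing required key 'structures'")

    geometry: GridGeometry | None = None
    structures: dict[str, BinaryStructure] = {}
    roles: dict[str, str] = {}
    for entry in sidecar["structures"]:
        for key in ("name", "file", "role"):
            if key not in entry:
                raise ValueError(f"{sidecar_path}: structure entry missing key '{key}'")
        if entry["role"] not in ROLES:
            raise ValueError(
                f"{sidecar_path}: unknown role '{entry['role']}' for '{entry['name']}'"
            )
        data, geom = _load_nifti(directory / entry["file"])
        if geometry is None:
            geometry = geom
        elif geom != geometry:
            raise ValueError(
                f"{entry['file']}: geometry differs from the rest of the set"
            )
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(
                f"{entry['file']}: mask must contain only 0/1, got values {uniq[:10]}"
            )
        structures[entry["name"]] = BinaryStructure(entry["name"], geom, data.astype(bool))
        roles[entry["name"]] = entry["role"]
    if geometry is None:
        raise ValueError(f"{sidecar_path}: structure list is empty")

    present_roles = set(roles.values())
    for role in required_roles:
        if role not in present_roles:
            raise ValueError(f"structure set at {directory} is missing role '{role}'")

    return StructureSet(
        geometry=geometry,
        structures=structures,
        roles=roles,
        rx_Gy=sidecar.get("rx_Gy"),
    )


def write_dose(dose: DoseGrid, path: str | Path) -> Path:
    """Write a dose grid as NIfTI plus a tiny JSON sidecar with ``rx_Gy``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(dose.dose_Gy.astype(np.float64), dose.geometry.affine())
    img.to_filename(str(path))
    sidecar = _dose_sidecar_path(path)
    sidecar.write_text(json.dumps({"rx_Gy": dose.rx_Gy}, sort_keys=True) + "\n")
    return path


def read_dose(path: str | Path, rx_Gy: float | None = None) -> DoseGrid:
    """Load a dose NIfTI; ``rx_Gy`` comes from the sidecar unless given."""
    path = Path(path)
    data, geom = _load_nifti(path)
    if rx_Gy is None:
        sidecar = _dose_sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"missing dose sidecar {sidecar} (or pass rx_Gy)")
        rx_Gy = json.loads(sidecar.read_text())["rx_Gy"]
    return DoseGrid(geom, np.asarray(data, dtype=float), rx_Gy)


def _dose_sidecar_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + ".json")
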