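"""Voxel-grid data model and set/distance primitives.

Every structure mask and dose grid in the pipeline lives on a shared
:class:`GridGeometry` — an axis-aligned lattice of voxel centers with
anisotropic spacing.  No resampling is implemented anywhere: objects on
mismatched geometries are a hard error, which mirrors a workflow where all
contours and doses for one treatment fraction are defined on the same CT
frame (rigid transfer having happened upstream).

Conventions
-----------
* Indices are 0-based; world coordinate of voxel ``(i, j, k)`` is
  ``origin_mm + index * spacing_mm`` (voxel *center*).
* All distances are Euclidean distances between voxel centers, in mm,
  honoring anisotropic spacing.
* Masks are boolean arrays; volumes are reported in cc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

__all__ = [
    "GridGeometry",
    "BinaryStructure",
    "DoseGrid",
    "StructureSet",
    "distance_map",
    "expand",
    "union",
    "intersection",
    "volume_cc",
]

#: tolerance (mm) within which two geometries compare equal
GEOMETRY_ATOL_MM = 1e-6


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned voxel lattice shared by masks and dose grids.

    Parameters
    ----------
    shape
        Number of voxels along each axis (``nx, ny, nz``).
    spacing_mm
        Voxel spacing along each axis, mm; strictly positive.
    origin_mm
        World position (mm) of the *center* of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))
        if len(self.shape) != 3 or len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise ValueError("GridGeometry is strictly 3-D")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing_mm}")

    # equality is tolerance-based (1e-6 mm), so identity hashing is disabled
    def __eq__(self, other: object) -> bool:  # noqa: D105
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=GEOMETRY_ATOL_MM, rtol=0.0)
            and np.allclose(self.origin_mm, other.origin_mm, atol=GEOMETRY_ATOL_MM, rtol=0.0)
        )

    __hash__ = None  # type: ignore[assignment]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the lattice (mm), center-to-center plus one voxel."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def affine(self) -> np.ndarray:
        """4x4 index-to-world affine (diagonal; no axis flips)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis (broadcastable)."""
        axes = [
            o + s * np.arange(n, dtype=float)
            for n, s, o in zip(self.shape, self.spacing_mm, self.origin_mm)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


def _check_same_geometry(*objs) -> GridGeometry:
    geom = objs[0].geometry
    for other in objs[1:]:
        if other.geometry != geom:
            raise ValueError(
                "geometry mismatch: all structures/doses must share one grid "
                f"({geom} vs {other.geometry})"
            )
    return geom


@dataclass
class BinaryStructure:
    """A named boolean voxel mask (organ, target, ring or derived structure)."""

    name: str
    geometry: GridGeometry
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != np.bool_:
            uniq = np.unique(self.mask)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(
                    f"structure '{self.name}': mask values must be 0/1, got {uniq[:10]}"
                )
            self.mask = self.mask.astype(bool)
        if self.mask.shape != tuple(self.geometry.shape):
            raise ValueError(
                f"structure '{self.name}': mask shape {self.mask.shape} does not "
                f"match geometry shape {self.geometry.shape}"
            )

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.geometry.voxel_volume_cc

    def with_mask(self, mask: np.ndarray, name: str | None = None) -> "BinaryStructure":
        """Derived structure on the parent geometry."""
        return BinaryStructure(name or self.name, self.geometry, mask)


@dataclass
class DoseGrid:
    """Per-voxel absorbed dose (Gy) with its prescription dose."""

    geometry: GridGeometry
    dose_Gy: np.ndarray
    rx_Gy: float

    def __post_init__(self) -> None:
        self.dose_Gy = np.asarray(self.dose_Gy, dtype=float)
        if self.dose_Gy.shape != tuple(self.geometry.shape):
            raise ValueError(
                f"dose shape {self.dose_Gy.shape} does not match geometry "
                f"shape {self.geometry.shape}"
            )
        if np.any(self.dose_Gy < 0):
            raise ValueError("dose grid contains negative values")
        self.rx_Gy = float(self.rx_Gy)
        if self.rx_Gy <= 0:
            raise ValueError("prescription dose rx_Gy must be > 0")


#: structure roles understood by the sidecar / pipeline
ROLES = ("GTV", "PTV", "OAR", "other")

#: organ names whose union forms the combined gastro-intestinal structure
GIO_ORGANS = ("stomach", "duodenum", "bowel")
GIO_NAME = "GIO"


@dataclass
class StructureSet:
    """A named collection of structures on one geometry, with roles.

    Roles follow the treatment-planning convention: ``GTV`` and ``PTV`` are
    targets, ``OAR`` organs-at-risk, anything else ``other``.
    """

    geometry: GridGeometry
    structures: dict[str, BinaryStructure] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)
    rx_Gy: float | None = None

    def __post_init__(self) -> None:
        for name, struct in self.structures.items():
            if struct.geometry != self.geometry:
                raise ValueError(f"structure '{name}' is not on the set geometry")
            self.roles.setdefault(name, "other")
        for name, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role '{role}' for structure '{name}'")

    def __getitem__(self, name: str) -> BinaryStructure:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    @property
    def names(self) -> list[str]:
        return list(self.structures)

    def add(self, structure: BinaryStructure, role: str = "other") -> None:
        if structure.geometry != self.geometry:
            raise ValueError(f"structure '{structure.name}' is not on the set geometry")
        if role not in ROLES:
            raise ValueError(f"unknown role '{role}'")
        self.structures[structure.name] = structure
        self.roles[structure.name] = role

    def by_role(self, role: str) -> list[BinaryStructure]:
        return [s for n, s in self.structures.items() if self.roles[n] == role]

    def single(self, role: str) -> BinaryStructure:
        """The unique structure with a given role (e.g. the PTV)."""
        matches = self.by_role(role)
        if len(matches) != 1:
            raise KeyError(
                f"structure set must contain exactly one '{role}' structure, "
                f"found {len(matches)}"
            )
        return matches[0]

    @property
    def oar_names(self) -> list[str]:
        return [n for n in self.structures if self.roles[n] == "OAR"]


# ---------------------------------------------------------------------------
# distance / set operations
# ---------------------------------------------------------------------------


def distance_map(structure: BinaryStructure, signed: bool = False) -> np.ndarray:
    """Euclidean distance (mm) from each voxel center to the structure.

    Unsigned mode returns the distance to the nearest structure voxel center
    (0 on the structure itself).  Signed mode is negative inside the
    structure — minus the distance to the nearest *outside* voxel center —
    and positive outside.
    """
    if structure.is_empty:
        raise ValueError("cannot compute distance map of empty structure")
    spacing = structure.geometry.spacing_mm
    outside = ndimage.distance_transform_edt(~structure.mask, sampling=spacing)
    if not signed:
        return outside
    if structure.mask.all():
        raise ValueError("signed distance map undefined for an all-true mask")
    inside = ndimage.distance_transform_edt(structure.mask, sampling=spacing)
    return np.where(structure.mask, -inside, outside)


def expand(structure: BinaryStructure, r_mm: float, name: str | None = None) -> BinaryStructure:
    """Isotropic expansion: voxels within ``r_mm`` of the structure (inclusive)."""
    if r_mm < 0:
        raise ValueError(f"expansion radius must be >= 0, got {r_mm}")
    dist = distance_map(structure)
    # tiny epsilon absorbs float round-off on exactly-on-radius voxels
    mask = dist <= r_mm + 1e-9
    return BinaryStructure(name or f"{structure.name}+{r_mm:g}mm", structure.geometry, mask)


def union(structures: Iterable[BinaryStructure], name: str | None = None) -> BinaryStructure:
    """Voxelwise logical OR of structures sharing one geometry."""
    structures = list(structures)
    if not structures:
        raise ValueError("union requires at least one structure")
    geom = _check_same_geometry(*structures)
    mask = np.zeros(geom.shape, dtype=bool)
    for s in structures:
        mask |= s.mask
    if name is None:
        names = {s.name for s in structures}
        name = GIO_NAME if names == set(GIO_ORGANS) else "|".join(sorted(names))
    return BinaryStructure(name, geom, mask)


def intersection(a: BinaryStructure, b: BinaryStructure, name: str | None = None) -> BinaryStructure:
    """Voxelwise logical AND."""
    geom = _check_same_geometry(a, b)
    return BinaryStructure(name or f"{a.name}&{b.name}", geom, a.mask & b.mask)


def volume_cc(structure: BinaryStructure) -> float:
    """Structure volume in cc (true-voxel count x voxel volume)."""
    return structure.volume_cc


def gio_union(sset: StructureSet) -> BinaryStructure | None:
    """Combined gastro-intestinal structure (stomach + duodenum + bowel).

    Returns ``None`` when any of the three organs is absent.
    """
    if not all(n in sset for n in GIO_ORGANS):
        return None
    return union([sset[n] for n in GIO_ORGANS], name=GIO_NAME)
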