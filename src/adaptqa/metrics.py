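"""Geometric agreement and proximity metrics for contour QA.

Implements the four agreement metrics recommended for registration /
auto-segmentation QA (Dice coefficient, symmetric mean surface distance,
Hausdorff distance and volumetric difference) plus target-to-organ
proximity measures (signed minimum distance and overlap volume with an
expanded PTV), evaluated on whole organs, on organs clipped to within a
distance of the PTV, and on isotropic rings around the PTV.

Surface voxels are defined by 6-connectivity: a true voxel with at least
one face-adjacent false voxel (out-of-grid counts as false).  Surface
distances are voxel-center distances between the two surface voxel sets.
The Hausdorff distance is the exact maximum (no percentile trimming); the
mean surface distance is symmetrized, weighting each direction by its
surface-voxel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import (
    GIO_NAME,
    BinaryStructure,
    StructureSet,
    _check_same_geometry,
    distance_map,
    gio_union,
)

__all__ = [
    "GeomMetrics",
    "ProximityMetrics",
    "dice",
    "surface_mask",
    "mean_surface_distance",
    "hausdorff",
    "volume_difference",
    "clip_to_target",
    "ring",
    "min_distance",
    "overlap_volume",
    "compare_structure_sets",
    "proximity_table",
]

_FACES = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class GeomMetrics:
    """Agreement metrics for one auto-vs-manual structure pair."""

    dc: float
    msd_mm: float
    hd_mm: float
    vol_auto_cc: float
    vol_man_cc: float

    @property
    def vol_diff_cc(self) -> float:
        """auto - manual volume; positive = auto overestimates."""
        return self.vol_auto_cc - self.vol_man_cc


@dataclass(frozen=True)
class ProximityMetrics:
    """Signed target clearance and overlap with the expanded target."""

    min_dist_mm: float
    ovlp_cc: float
    expansion_mm: float


def dice(a: BinaryStructure, b: BinaryStructure) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) on voxel counts.

    Both empty is defined as 1.0 (with a warning); exactly one empty is 0.0.
    """
    _check_same_geometry(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        warnings.warn("Dice of two empty structures defined as 1.0", stacklevel=2)
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    inter = int((a.mask & b.mask).sum())
    return 2.0 * inter / (na + nb)


def surface_mask(structure: BinaryStructure) -> np.ndarray:
    """True voxels with >= 1 face-adjacent false voxel (edges count as outside)."""
    eroded = ndimage.binary_erosion(structure.mask, structure=_FACES, border_value=0)
    return structure.mask & ~eroded


def _surface_distances(a: BinaryStructure, b: BinaryStructure) -> tuple[np.ndarray, np.ndarray]:
    """Directed surface-to-surface distances (a->b surfaces, b->a surfaces)."""
    for s in (a, b):
        if s.is_empty:
            raise ValueError(f"surface metrics undefined for empty structure '{s.name}'")
    geom = _check_same_geometry(a, b)
    surf_a = surface_mask(a)
    surf_b = surface_mask(b)
    dist_to_b = ndimage.distance_transform_edt(~surf_b, sampling=geom.spacing_mm)
    dist_to_a = ndimage.distance_transform_edt(~surf_a, sampling=geom.spacing_mm)
    return dist_to_b[surf_a], dist_to_a[surf_b]


def mean_surface_distance(a: BinaryStructure, b: BinaryStructure) -> float:
    """Symmetric MSD: surface-voxel-count-weighted mean of both directed means."""
    d_ab, d_ba = _surface_distances(a, b)
    return float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size))


def hausdorff(a: BinaryStructure, b: BinaryStructure) -> float:
    """Exact (100th percentile) symmetric Hausdorff distance, mm."""
    d_ab, d_ba = _surface_distances(a, b)
    return float(max(d_ab.max(), d_ba.max()))


def volume_difference(auto: BinaryStructure, man: BinaryStructure) -> float:
    """auto minus manual volume, cc; positive = auto overestimates."""
    _check_same_geometry(auto, man)
    return auto.volume_cc - man.volume_cc


def clip_to_target(
    oar: BinaryStructure,
    ptv: BinaryStructure,
    d_mm: float,
    ptv_distance: np.ndarray | None = None,
) -> BinaryStructure:
    """OAR restricted to within ``d_mm`` of the PTV (PTV interior included).

    ``ptv_distance`` may carry a precomputed unsigned PTV distance map to
    amortize the transform across clip levels.
    """
    if ptv.is_empty:
        raise ValueError("cannot clip to an empty PTV")
    if d_mm < 0:
        raise ValueError("clip distance must be >= 0")
    _check_same_geometry(oar, ptv)
    if ptv_distance is None:
        ptv_distance = distance_map(ptv)
    mask = oar.mask & (ptv_distance <= d_mm + 1e-9)
    return BinaryStructure(f"{oar.name}@{d_mm:g}mm", oar.geometry, mask)


def ring(
    ptv: BinaryStructure,
    d1_mm: float,
    d2_mm: float,
    ptv_distance: np.ndarray | None = None,
) -> BinaryStructure:
    """Isotropic shell between expansions d1 and d2 of the PTV, PTV excluded.

    ``ring(0, d)`` is the shell from the PTV surface out to ``d``; rings over
    a partition of [0, d] tile ``ring(0, d)`` exactly.
    """
    if d1_mm < 0:
        raise ValueError("ring inner distance must be >= 0")
    if d1_mm >= d2_mm:
        raise ValueError(f"ring requires d1 < d2, got {d1_mm} >= {d2_mm}")
    if ptv.is_empty:
        raise ValueError("cannot build a ring around an empty PTV")
    if ptv_distance is None:
        ptv_distance = distance_map(ptv)
    outer = ptv_distance <= d2_mm + 1e-9
    inner = ptv_distance <= d1_mm + 1e-9  # d1=0 reduces to the PTV itself
    mask = outer & ~inner
    return BinaryStructure(f"ring:{d1_mm:g}-{d2_mm:g}mm", ptv.geometry, mask)


def min_distance(
    target: BinaryStructure,
    oar: BinaryStructure,
    target_signed_distance: np.ndarray | None = None,
) -> float:
    """Signed minimum distance (mm) from the target to the OAR.

    Minimum over OAR voxel centers of the signed target distance; negative
    values measure the deepest OAR penetration into the target.
    """
    if target.is_empty or oar.is_empty:
        raise ValueError("min_distance undefined for empty structures")
    _check_same_geometry(target, oar)
    if target_signed_distance is None:
        target_signed_distance = distance_map(target, signed=True)
    return float(target_signed_distance[oar.mask].min())


def overlap_volume(
    ptv: BinaryStructure,
    r_mm: float,
    oar: BinaryStructure,
    ptv_distance: np.ndarray | None = None,
) -> float:
    """Volume (cc) of the OAR inside the PTV expanded by ``r_mm``."""
    if ptv.is_empty:
        raise ValueError("overlap_volume requires a non-empty PTV")
    if r_mm < 0:
        raise ValueError("expansion must be >= 0")
    _check_same_geometry(ptv, oar)
    if ptv_distance is None:
        ptv_distance = distance_map(ptv)
    mask = oar.mask & (ptv_distance <= r_mm + 1e-9)
    return int(mask.sum()) * ptv.geometry.voxel_volume_cc


def _pair_metrics(auto: BinaryStructure, man: BinaryStructure) -> tuple[GeomMetrics, bool]:
    """Metrics for one pair; flags (rather than raises on) empty inputs."""
    empty = auto.is_empty or man.is_empty
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # flagged row stands in for the warning
        dc = dice(auto, man)
    if empty:
        msd = hd = float("nan")
    else:
        d_ab, d_ba = _surface_distances(auto, man)
        msd = float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size))
        hd = float(max(d_ab.max(), d_ba.max()))
    return GeomMetrics(dc, msd, hd, auto.volume_cc, man.volume_cc), empty


def compare_structure_sets(
    man: StructureSet,
    auto: StructureSet,
    ptv: BinaryStructure | None = None,
    clip_distances_mm: tuple[float, ...] = (30.0, 10.0, 5.0),
    gtv: BinaryStructure | None = None,
    ovlp_expansions_mm: tuple[float, float] = (5.0, 10.0),
    ids: dict | None = None,
) -> pd.DataFrame:
    """Per-structure x clip-level agreement table of an auto set vs manual.

    One row per OAR (plus the combined GIO union when stomach, duodenum and
    bowel are all present) at each level (``whole`` and each clip distance),
    with agreement metrics, the auto structure's proximity to GTV/PTV, and
    overlap volumes with the expanded PTV.  Pairs that are empty after
    clipping yield a flagged row (``empty_flag``), never an error.
    """
    if ptv is None:
        ptv = man.single("PTV")
    if gtv is None:
        gtv_matches = man.by_role("GTV")
        gtv = gtv_matches[0] if len(gtv_matches) == 1 else None
    organ_names = man.oar_names
    missing = [n for n in organ_names if n not in auto]
    if missing:
        raise KeyError(f"auto set is missing structures: {missing}")
    if ptv.is_empty:
        raise ValueError("PTV is empty")

    ptv_dist = distance_map(ptv)
    ptv_signed = distance_map(ptv, signed=True)
    gtv_signed = distance_map(gtv, signed=True) if gtv is not None and not gtv.is_empty else None

    pairs: list[tuple[str, BinaryStructure, BinaryStructure]] = [
        (n, man[n], auto[n]) for n in organ_names
    ]
    man_gio = gio_union(man)
    if man_gio is not None:
        auto_gio = gio_union(auto)
        pairs.append((GIO_NAME, man_gio, auto_gio))

    base = dict(ids or {})
    rows = []
    for name, man_s, auto_s in pairs:
        prox: dict[str, float] = {}
        if not auto_s.is_empty:
            prox["min_dist_ptv_mm"] = float(ptv_signed[auto_s.mask].min())
            if gtv_signed is not None:
                prox["min_dist_gtv_mm"] = float(gtv_signed[auto_s.mask].min())
            for r in ovlp_expansions_mm:
                prox[f"ovlp_{r:g}mm_cc"] = overlap_volume(ptv, r, auto_s, ptv_distance=ptv_dist)
        for level_label, d in [("whole", None)] + [(f"{d:g}", d) for d in clip_distances_mm]:
            if d is None:
                man_c, auto_c = man_s, auto_s
            else:
                man_c = clip_to_target(man_s, ptv, d, ptv_distance=ptv_dist)
                auto_c = clip_to_target(auto_s, ptv, d, ptv_distance=ptv_dist)
            gm, empty = _pair_metrics(auto_c, man_c)
            rows.append(
                {
                    **base,
                    "structure": name,
                    "clip_mm": level_label,
                    "dc": gm.dc,
                    "msd_mm": gm.msd_mm,
                    "hd_mm": gm.hd_mm,
                    "vol_auto_cc": gm.vol_auto_cc,
                    "vol_man_cc": gm.vol_man_cc,
                    "vol_diff_cc": gm.vol_diff_cc,
                    **prox,
                    "empty_flag": empty,
                }
            )
    return pd.DataFrame(rows)


def proximity_table(
    sset: StructureSet,
    ptv: BinaryStructure | None = None,
    gtv: BinaryStructure | None = None,
    ovlp_expansions_mm: tuple[float, float] = (5.0, 10.0),
    ids: dict | None = None,
) -> pd.DataFrame:
    """MIN_DIST (GTV/PTV to OAR) and OVLP (expanded PTV ∩ OAR) per organ."""
    if ptv is None:
        ptv = sset.single("PTV")
    if gtv is None:
        gtv_matches = sset.by_role("GTV")
        gtv = gtv_matches[0] if len(gtv_matches) == 1 else None
    ptv_dist = distance_map(ptv)
    ptv_signed = distance_map(ptv, signed=True)
    gtv_signed = distance_map(gtv, signed=True) if gtv is not None else None
    rows = []
    for name in sset.oar_names:
        organ = sset[name]
        if organ.is_empty:
            continue
        row = {**(ids or {}), "structure": name}
        row["min_dist_ptv_mm"] = float(ptv_signed[organ.mask].min())
        if gtv_signed is not None:
            row["min_dist_gtv_mm"] = float(gtv_signed[organ.mask].min())
        for r in ovlp_expansions_mm:
            row[f"ovlp_{r:g}mm_cc"] = overlap_volume(ptv, r, organ, ptv_distance=ptv_dist)
        rows.append(row)
    return pd.DataFrame(rows)
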