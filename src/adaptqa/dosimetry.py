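"""DVH parameter extraction and clinical-constraint evaluation.

Dose metrics are voxel-count DVH quantities (no sub-voxel interpolation):
structures and doses share one grid by construction, so every reported cc
is an exact voxel count times the voxel volume.  The dose threshold bound
is closed (voxels at exactly the threshold count toward VxGy), and the
constraint comparator is strict (value must be < limit to pass) — both
conventions matter for cc-level near-maximum constraints such as
V35 Gy < 0.5 cc.

All plan evaluation runs on the designated *manual* (ground-truth) contour
set, regardless of which contours the plan was optimized on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import BinaryStructure, DoseGrid, StructureSet, _check_same_geometry

__all__ = [
    "DvhMetrics",
    "ConstraintSpec",
    "default_constraints",
    "v_at_dose",
    "dvh_metrics",
    "check_constraints",
    "evaluate_fraction",
]


@dataclass(frozen=True)
class DvhMetrics:
    """DVH summary for one structure under one dose."""

    structure: str
    volume_cc: float
    dmean_Gy: float
    dmin_Gy: float
    dmax_Gy: float
    v_at: dict[float, float] = field(default_factory=dict)  # threshold Gy -> cc
    coverage_pct: float | None = None  # targets only


@dataclass(frozen=True)
class ConstraintSpec:
    """One clinical dose constraint; passes iff value < limit (strict)."""

    structure: str
    kind: str  # v_at_max_cc | v_at_max_pct | mean_max_Gy | max_Gy
    limit: float
    dose_Gy: float | None = None  # threshold for v_at_* kinds

    KINDS = ("v_at_max_cc", "v_at_max_pct", "mean_max_Gy", "max_Gy")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown constraint kind '{self.kind}'")
        if self.kind.startswith("v_at") and self.dose_Gy is None:
            raise ValueError(f"constraint kind '{self.kind}' needs dose_Gy")

    def value_from(self, m: DvhMetrics) -> float:
        if self.kind == "v_at_max_cc":
            return m.v_at[self.dose_Gy]
        if self.kind == "v_at_max_pct":
            return 100.0 * m.v_at[self.dose_Gy] / m.volume_cc if m.volume_cc > 0 else 0.0
        if self.kind == "mean_max_Gy":
            return m.dmean_Gy
        return m.dmax_Gy

    @property
    def label(self) -> str:
        if self.kind == "v_at_max_cc":
            return f"{self.structure} V{self.dose_Gy:g}Gy < {self.limit:g} cc"
        if self.kind == "v_at_max_pct":
            return f"{self.structure} V{self.dose_Gy:g}Gy < {self.limit:g} %"
        if self.kind == "mean_max_Gy":
            return f"{self.structure} Dmean < {self.limit:g} Gy"
        return f"{self.structure} Dmax < {self.limit:g} Gy"


def default_constraints(extended: bool = False) -> list[ConstraintSpec]:
    """The protocol's OAR constraint set.

    Core: stomach / duodenum / bowel V35 Gy < 0.5 cc.  With
    ``extended=True`` also liver V20 Gy < 700 cc, kidneys Dmean < 15 Gy and
    V15 Gy < 30 %, and spinal-cord Dmax < 27.5 Gy.
    """
    specs = [
        ConstraintSpec(organ, "v_at_max_cc", 0.5, dose_Gy=35.0)
        for organ in ("stomach", "duodenum", "bowel")
    ]
    if extended:
        specs += [
            ConstraintSpec("liver", "v_at_max_cc", 700.0, dose_Gy=20.0),
            ConstraintSpec("kidneys", "mean_max_Gy", 15.0),
            ConstraintSpec("kidneys", "v_at_max_pct", 30.0, dose_Gy=15.0),
            ConstraintSpec("cord", "max_Gy", 27.5),
        ]
    return specs


def v_at_dose(dose: DoseGrid, structure: BinaryStructure, threshold_Gy: float) -> float:
    """Volume (cc) of the structure receiving >= ``threshold_Gy`` (closed bound)."""
    _check_same_geometry(dose, structure)
    count = int((structure.mask & (dose.dose_Gy >= threshold_Gy)).sum())
    return count * structure.geometry.voxel_volume_cc


def dvh_metrics(
    dose: DoseGrid,
    structure: BinaryStructure,
    rx_Gy: float | None = None,
    thresholds_Gy: tuple[float, ...] = (35.0,),
    is_target: bool = False,
) -> DvhMetrics:
    """DVH summary of one structure; coverage is reported for targets only.

    Coverage is the percentage of the structure volume receiving at least
    95% of the prescription dose.
    """
    if structure.is_empty:
        raise ValueError(f"DVH metrics undefined for empty structure '{structure.name}'")
    _check_same_geometry(dose, structure)
    vals = dose.dose_Gy[structure.mask]
    v_at = {
        float(t): int((vals >= t).sum()) * structure.geometry.voxel_volume_cc
        for t in thresholds_Gy
    }
    coverage = None
    if is_target:
        rx = dose.rx_Gy if rx_Gy is None else rx_Gy
        coverage = 100.0 * float((vals >= 0.95 * rx).sum()) / vals.size
    return DvhMetrics(
        structure=structure.name,
        volume_cc=structure.volume_cc,
        dmean_Gy=float(vals.mean()),
        dmin_Gy=float(vals.min()),
        dmax_Gy=float(vals.max()),
        v_at=v_at,
        coverage_pct=coverage,
    )


def check_constraints(
    metrics: dict[str, DvhMetrics] | list[DvhMetrics],
    specs: list[ConstraintSpec],
) -> tuple[pd.DataFrame, bool]:
    """Per-constraint pass/violate flags plus the fraction-level verdict.

    The comparator is strict: a value exactly at the limit violates.  The
    verdict is "obeys" iff every constraint passes.
    """
    if not isinstance(metrics, dict):
        metrics = {m.structure: m for m in metrics}
    rows = []
    for spec in specs:
        if spec.structure not in metrics:
            raise KeyError(f"constraint references missing structure '{spec.structure}'")
        value = spec.value_from(metrics[spec.structure])
        rows.append(
            {
                "constraint": spec.label,
                "structure": spec.structure,
                "kind": spec.kind,
                "dose_Gy": spec.dose_Gy,
                "limit": spec.limit,
                "value": value,
                "passes": bool(value < spec.limit),
            }
        )
    table = pd.DataFrame(rows)
    return table, bool(table["passes"].all())


def evaluate_fraction(
    bundle,
    specs: list[ConstraintSpec] | None = None,
    thresholds_Gy: tuple[float, ...] = (35.0,),
    plans: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every plan of a fraction bundle on the MAN contours.

    Returns ``(metrics, verdicts)``: one metrics row per plan x structure
    (targets carry coverage, all structures carry Dmean/Dmin/Dmax and VxGy
    columns), and one verdict row per plan x constraint with the per-plan
    "obeys" flag.  Doses are *never* evaluated on auto contours.
    """
    if specs is None:
        specs = default_constraints()
    man = bundle.man_set
    if man is None:
        raise ValueError("fraction bundle has no MAN structure set")
    thresholds = tuple(sorted(set(thresholds_Gy) | {
        s.dose_Gy for s in specs if s.dose_Gy is not None
    }))
    plan_names = list(plans) if plans is not None else list(bundle.doses)
    metric_rows = []
    verdict_rows = []
    ids = {"patient": bundle.patient, "fraction": bundle.fraction}
    for plan in plan_names:
        dose = bundle.doses[plan]
        per_structure: dict[str, DvhMetrics] = {}
        for name, struct in man.structures.items():
            role = man.roles[name]
            if struct.is_empty:
                continue
            m = dvh_metrics(
                dose,
                struct,
                thresholds_Gy=thresholds,
                is_target=role in ("GTV", "PTV"),
            )
            per_structure[name] = m
            metric_rows.append(
                {
                    **ids,
                    "plan": plan,
                    "structure": name,
                    "role": role,
                    "volume_cc": m.volume_cc,
                    "dmean_Gy": m.dmean_Gy,
                    "dmin_Gy": m.dmin_Gy,
                    "dmax_Gy": m.dmax_Gy,
                    "coverage_pct": m.coverage_pct,
                    **{f"v{t:g}Gy_cc": v for t, v in m.v_at.items()},
                }
            )
        table, obeys = check_constraints(per_structure, specs)
        table.insert(0, "plan", plan)
        for key, val in reversed(ids.items()):
            table.insert(0, key, val)
        table["obeys"] = obeys
        verdict_rows.append(table)
    return pd.DataFrame(metric_rows), pd.concat(verdict_rows, ignore_index=True)
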