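"""Cohort-level analysis: paired plan comparisons, fraction classification
and the ring-based contour-error vs constraint-violation analysis.

The analysis consumes per-fraction records (DVH metrics and constraint
verdicts per plan, geometric agreement per structure and clip level, and
per-ring volumetric differences) and produces four summary tables:

1. target-organ proximity (signed minimum distance, overlap volumes) per
   contouring method;
2. each replan vs the non-adapted plan (median paired differences with
   Wilcoxon signed-rank p-values);
3. auto-contour replans vs the manual-contour replan;
4. per-ring volumetric difference of auto vs manual contours, split by
   whether that method's replan violates the organ's dose constraint
   (Mann-Whitney between violators and non-violators).

Medians are reported with the interquartile range (Q1, Q3).  No
multiple-testing correction is applied; each comparison is reported at its
own p-value.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .dosimetry import ConstraintSpec, default_constraints, evaluate_fraction
from .grids import GIO_ORGANS, distance_map
from .metrics import compare_structure_sets, proximity_table, ring
from .phantom import FractionBundle, load_cohort
from .stats import mann_whitney, wilcoxon_signed_rank

__all__ = [
    "DEFAULT_RINGS_MM",
    "paired_summary",
    "build_fraction_records",
    "classify_fractions",
    "plan_comparison_table",
    "ring_violation_analysis",
    "analyze_records",
    "make_report",
    "parse_rings",
]

#: default ring partition (mm): 0-1.5 cm vs 1.5-3 cm from the PTV
DEFAULT_RINGS_MM: tuple[tuple[float, float], ...] = ((0.0, 15.0), (15.0, 30.0))

#: alternative partitions available for sensitivity checks
ALT_RINGS_MM = (((0.0, 10.0), (10.0, 30.0)), ((0.0, 20.0), (20.0, 30.0)))

MIN_GROUP_SIZE = 3


def _iqr(values: np.ndarray) -> tuple[float, float, float]:
    values = np.asarray(values, dtype=float)
    return (
        float(np.median(values)),
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
    )


def paired_summary(values_a, values_b) -> dict:
    """Median (Q1, Q3) of paired differences ``b - a`` with Wilcoxon p.

    Fewer than 5 pairs is flagged ``insufficient`` (the p-value is still
    reported for completeness but should not be interpreted).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = b - a
    med, q1, q3 = _iqr(d)
    test = wilcoxon_signed_rank(a, b)
    return {
        "n": int(a.size),
        "median_diff": med,
        "q1": q1,
        "q3": q3,
        "p": test["p"],
        "insufficient": test["insufficient"],
    }


# ---------------------------------------------------------------------------
# record building
# ---------------------------------------------------------------------------


def build_fraction_records(
    bundles: Iterable[FractionBundle],
    specs: list[ConstraintSpec] | None = None,
    clip_distances_mm: tuple[float, ...] = (30.0, 10.0, 5.0),
    rings_mm: tuple[tuple[float, float], ...] = DEFAULT_RINGS_MM,
    ovlp_expansions_mm: tuple[float, float] = (5.0, 10.0),
    with_geometry: bool = True,
) -> dict[str, pd.DataFrame]:
    """Long-format per-fraction record tables for a whole cohort.

    Returns a dict of DataFrames: ``dvh`` (plan x structure DVH rows),
    ``verdicts`` (plan x constraint flags), ``geom`` (method x structure x
    clip level agreement), ``rings`` (method x structure x ring VOL_DIFF),
    ``proximity`` (method x organ MIN_DIST / OVLP) and ``bias`` (which auto
    sets received their near-PTV bias — phantom bookkeeping).
    """
    if specs is None:
        specs = default_constraints()
    dvh_rows, verdict_rows, geom_rows, ring_rows, prox_rows, bias_rows = [], [], [], [], [], []
    for bundle in bundles:
        ids = {"patient": bundle.patient, "fraction": bundle.fraction}
        man = bundle.man_set
        ptv = man.single("PTV")
        ptv_dist = distance_map(ptv)

        dvh, verdicts = evaluate_fraction(bundle, specs)
        dvh_rows.append(dvh)
        verdict_rows.append(verdicts)

        prox_rows.append(proximity_table(man, ptv=ptv, ids={**ids, "method": "MAN"},
                                         ovlp_expansions_mm=ovlp_expansions_mm))
        ring_structs = {
            f"{d1:g}-{d2:g}": ring(ptv, d1, d2, ptv_distance=ptv_dist)
            for d1, d2 in rings_mm
        }
        for method, auto in bundle.auto_sets.items():
            if with_geometry:
                geom = compare_structure_sets(
                    man, auto, ptv=ptv, clip_distances_mm=clip_distances_mm,
                    ovlp_expansions_mm=ovlp_expansions_mm, ids={**ids, "method": method},
                )
                geom_rows.append(geom)
            prox_rows.append(proximity_table(auto, ptv=ptv, ids={**ids, "method": method},
                                             ovlp_expansions_mm=ovlp_expansions_mm))
            for organ in man.oar_names:
                man_mask = man[organ].mask
                auto_mask = auto[organ].mask
                for label, rg in ring_structs.items():
                    n_auto = int((auto_mask & rg.mask).sum())
                    n_man = int((man_mask & rg.mask).sum())
                    d1, d2 = label.split("-")
                    ring_rows.append(
                        {
                            **ids,
                            "method": method,
                            "structure": organ,
                            "ring": label,
                            "d1_mm": float(d1),
                            "d2_mm": float(d2),
                            "vol_diff_cc": (n_auto - n_man) * man.geometry.voxel_volume_cc,
                        }
                    )
            bias_rows.append({**ids, "method": method,
                              "bias_applied": bundle.bias_applied.get(method, False)})
    return {
        "dvh": pd.concat(dvh_rows, ignore_index=True),
        "verdicts": pd.concat(verdict_rows, ignore_index=True),
        "geom": pd.concat(geom_rows, ignore_index=True) if geom_rows else pd.DataFrame(),
        "rings": pd.DataFrame(ring_rows),
        "proximity": pd.concat(prox_rows, ignore_index=True),
        "bias": pd.DataFrame(bias_rows),
    }


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _replan_methods(dvh: pd.DataFrame) -> list[str]:
    return sorted(
        p[len("replan_"):] for p in dvh["plan"].unique() if p.startswith("replan_")
    )


def classify_fractions(
    dvh: pd.DataFrame,
    verdicts: pd.DataFrame,
    gio_organs: tuple[str, ...] = GIO_ORGANS,
    v_column: str = "v35Gy_cc",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per fraction x method flags plus cohort proportions.

    A replan *improves* on the non-adapted plan iff its V35Gy is <= the
    non-adapted V35Gy for all GIO organs, with strict improvement in at
    least one organ whenever any non-adapted V35Gy is positive (when every
    V35Gy is already zero in both, the tie at the optimum counts as
    improved).  A plan *obeys* iff every constraint passes.
    """
    methods = _replan_methods(dvh)
    keys = ["patient", "fraction"]
    v35 = dvh.pivot_table(index=keys + ["structure"], columns="plan",
                          values=v_column, aggfunc="first")
    obeys = verdicts.groupby(keys + ["plan"])["obeys"].first()

    rows = []
    for (patient, fraction), grp in dvh.groupby(keys):
        organs_present = [o for o in gio_organs if o in set(grp["structure"])]
        for method in methods:
            plan = f"replan_{method}"
            if plan not in set(grp["plan"]):
                raise KeyError(f"missing plan rows for '{plan}' in fraction {fraction}")
            noad_v = np.array([v35.loc[(patient, fraction, o), "noad"] for o in organs_present])
            rp_v = np.array([v35.loc[(patient, fraction, o), plan] for o in organs_present])
            all_le = bool(np.all(rp_v <= noad_v))
            if np.any(noad_v > 0):
                improved = all_le and bool(np.any(rp_v < noad_v))
            else:
                improved = all_le  # both at the optimum
            rows.append(
                {
                    "patient": patient,
                    "fraction": fraction,
                    "method": method,
                    "improved_vs_noad": improved,
                    "obeys_constraints": bool(obeys.loc[(patient, fraction, plan)]),
                }
            )
    per_fraction = pd.DataFrame(rows)

    n_fx = len(per_fraction[["patient", "fraction"]].drop_duplicates())
    noad_obeys = obeys.xs("noad", level="plan")
    prop_rows = [
        {
            "method": "NoAd",
            "n_fractions": n_fx,
            "obeys_pct": 100.0 * float(noad_obeys.mean()),
            "improved_pct": np.nan,
        }
    ]
    for method in methods:
        sub = per_fraction[per_fraction["method"] == method]
        prop_rows.append(
            {
                "method": method,
                "n_fractions": len(sub),
                "obeys_pct": 100.0 * float(sub["obeys_constraints"].mean()),
                "improved_pct": 100.0 * float(sub["improved_vs_noad"].mean()),
            }
        )
    return per_fraction, pd.DataFrame(prop_rows)


# ---------------------------------------------------------------------------
# plan comparison tables
# ---------------------------------------------------------------------------

#: (role, parameter column) pairs reported per structure class
_TARGET_PARAMS = ("coverage_pct", "dmean_Gy", "dmin_Gy")
_OAR_PARAMS = ("v35Gy_cc", "dmean_Gy")


def plan_comparison_table(
    dvh: pd.DataFrame,
    baseline_plan: str,
    compare_plans: list[str] | None = None,
) -> pd.DataFrame:
    """Median (Q1, Q3) per-parameter table of plans vs a baseline plan.

    One row per structure x parameter x compared plan carrying the baseline
    median (Q1, Q3), the median (Q1, Q3) of the paired differences, and
    the two-sided Wilcoxon signed-rank p.
    """
    if compare_plans is None:
        compare_plans = [
            p for p in dvh["plan"].unique()
            if p.startswith("replan_") and p != baseline_plan
        ]
    keys = ["patient", "fraction"]
    rows = []
    for structure, grp in dvh.groupby("structure", sort=False):
        role = grp["role"].iloc[0]
        params = _TARGET_PARAMS if role in ("GTV", "PTV") else _OAR_PARAMS
        wide = grp.pivot_table(index=keys, columns="plan", aggfunc="first")
        for param in params:
            if param not in {c[0] for c in wide.columns}:
                continue
            base_vals = wide[(param, baseline_plan)].dropna()
            if base_vals.empty:
                continue
            b_med, b_q1, b_q3 = _iqr(base_vals.to_numpy())
            for plan in compare_plans:
                if (param, plan) not in wide.columns:
                    continue
                both = wide[[(param, baseline_plan), (param, plan)]].dropna()
                summ = paired_summary(
                    both[(param, baseline_plan)].to_numpy(),
                    both[(param, plan)].to_numpy(),
                )
                rows.append(
                    {
                        "structure": structure,
                        "parameter": param,
                        "baseline_plan": baseline_plan,
                        "plan": plan,
                        "n": summ["n"],
                        "baseline_median": b_med,
                        "baseline_q1": b_q1,
                        "baseline_q3": b_q3,
                        "diff_median": summ["median_diff"],
                        "diff_q1": summ["q1"],
                        "diff_q3": summ["q3"],
                        "p": summ["p"],
                        "insufficient": summ["insufficient"],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ring analysis
# ---------------------------------------------------------------------------


def ring_violation_analysis(
    rings: pd.DataFrame,
    verdicts: pd.DataFrame,
    min_group_size: int = MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Per structure x method x ring: VOL_DIFF of violators vs non-violators.

    A fraction is a *violator* for (structure, method) when that method's
    replan violates the structure's own dose constraint (evaluated on the
    manual contours).  Groups smaller than ``min_group_size`` are flagged
    insufficient and not tested; a cohort with no violators at all is
    therefore all-insufficient rather than an error.
    """
    keys = ["patient", "fraction"]
    viol = verdicts.copy()
    viol["method"] = viol["plan"].str.removeprefix("replan_")
    viol = viol[viol["plan"].str.startswith("replan_")]
    # a fraction violates for (method, structure) if any of that structure's
    # constraints fails under that method's replan
    viol = viol.groupby(keys + ["method", "structure"])["passes"].all()

    rows = []
    for (structure, method, label), grp in rings.groupby(
        ["structure", "method", "ring"], sort=True
    ):
        flags = []
        for _, r in grp.iterrows():
            key = (r["patient"], r["fraction"], method, structure)
            flags.append(not bool(viol.get(key, True)))
        grp = grp.assign(violates=flags)
        vio = grp.loc[grp["violates"], "vol_diff_cc"].to_numpy()
        ok = grp.loc[~grp["violates"], "vol_diff_cc"].to_numpy()
        row = {
            "structure": structure,
            "method": method,
            "ring": label,
            "d1_mm": grp["d1_mm"].iloc[0],
            "d2_mm": grp["d2_mm"].iloc[0],
            "n_violate": int(vio.size),
            "n_ok": int(ok.size),
        }
        for name, vals in (("violate", vio), ("ok", ok)):
            if vals.size:
                med, q1, q3 = _iqr(vals)
            else:
                med = q1 = q3 = float("nan")
            row[f"{name}_median"] = med
            row[f"{name}_q1"] = q1
            row[f"{name}_q3"] = q3
        if min(vio.size, ok.size) < min_group_size:
            row.update(p=float("nan"), insufficient=True)
        else:
            row.update(p=mann_whitney(vio, ok)["p"], insufficient=False)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["structure", "method", "d1_mm"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def _summarize_proximity(prox: pd.DataFrame) -> pd.DataFrame:
    value_cols = [c for c in prox.columns
                  if c not in ("patient", "fraction", "method", "structure")]
    rows = []
    for (structure, method), grp in prox.groupby(["structure", "method"], sort=True):
        for col in value_cols:
            vals = grp[col].dropna().to_numpy()
            if not vals.size:
                continue
            med, q1, q3 = _iqr(vals)
            rows.append(
                {
                    "structure": structure,
                    "method": method,
                    "metric": col,
                    "n": vals.size,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)


def analyze_records(records: dict[str, pd.DataFrame]) -> dict:
    """All cohort tables from the long-format record tables."""
    dvh, verdicts = records["dvh"], records["verdicts"]
    per_fraction, proportions = classify_fractions(dvh, verdicts)
    table1 = _summarize_proximity(records["proximity"])
    table2 = plan_comparison_table(dvh, baseline_plan="noad")
    auto_plans = [p for p in dvh["plan"].unique()
                  if p.startswith("replan_") and p != "replan_man"]
    table3 = plan_comparison_table(dvh, baseline_plan="replan_man",
                                   compare_plans=auto_plans)
    table4 = ring_violation_analysis(records["rings"], verdicts)
    return {
        "table1_proximity": table1,
        "table2_vs_noad": table2,
        "table3_vs_man_replan": table3,
        "table4_rings": table4,
        "per_fraction": per_fraction,
        "proportions": proportions,
    }


def make_report(
    cohort_dir: str | Path,
    out_dir: str | Path,
    specs: list[ConstraintSpec] | None = None,
    clip_distances_mm: tuple[float, ...] = (30.0, 10.0, 5.0),
    rings_mm: tuple[tuple[float, float], ...] = DEFAULT_RINGS_MM,
) -> dict:
    """Run the full analysis on a cohort directory and write the report set.

    Writes ``table1.csv`` … ``table4.csv``, the long record tables,
    ``summary.json`` (cohort proportions) and ``run_log.json`` (config,
    seed, version, analysis parameters).  Outputs are deterministic:
    rerunning on the same cohort produces byte-identical files.
    """
    cohort_dir, out_dir = Path(cohort_dir), Path(out_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    records = build_fraction_records(
        load_cohort(cohort_dir),
        specs=specs,
        clip_distances_mm=clip_distances_mm,
        rings_mm=rings_mm,
    )
    result = analyze_records(records)
    out_dir.mkdir(parents=True, exist_ok=True)
    for stem, key in (
        ("table1", "table1_proximity"),
        ("table2", "table2_vs_noad"),
        ("table3", "table3_vs_man_replan"),
        ("table4", "table4_rings"),
        ("per_fraction", "per_fraction"),
        ("proportions", "proportions"),
    ):
        result[key].to_csv(out_dir / f"{stem}.csv", index=False)
    for stem in ("dvh", "verdicts", "geom", "rings", "proximity"):
        records[stem].to_csv(out_dir / f"records_{stem}.csv", index=False)

    summary = {
        "n_fractions": int(
            len(records["dvh"][["patient", "fraction"]].drop_duplicates())
        ),
        "proportions": result["proportions"].to_dict(orient="records"),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    run_log = {
        "config": manifest.get("config"),
        "seed": manifest.get("seed"),
        "adaptqa_version": __version__,
        "clip_distances_mm": list(clip_distances_mm),
        "rings_mm": [list(r) for r in rings_mm],
        "constraints": [s.label for s in (specs or default_constraints())],
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True) + "\n")
    result["records"] = records
    result["summary"] = summary
    return result


def parse_rings(text: str) -> tuple[tuple[float, float], ...]:
    """Parse a CLI ring spec like ``"0-15,15-30"`` (mm) into pairs."""
    rings = []
    for part in text.split(","):
        d1, d2 = part.strip().split("-")
        rings.append((float(d1), float(d2)))
    return tuple(rings)
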