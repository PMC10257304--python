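"""Cohort-level summaries: class tallies, carrier counts, depth/VAF
statistics and the stage-count grid.

All summaries are permutation-invariant in their input order, and distinct
variant identity is always the (chrom, pos, ref, alt) key — HGVS strings are
display only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_model import (
    AnnotatedVariant,
    ClinSigClass,
    Cohort,
    compute_vaf,
)
from .filter_cascade import CascadeResult, StageRoute

#: Display labels for the reported-class tally.
CLASS_LABELS: Mapping[ClinSigClass, str] = {
    ClinSigClass.CLASS_45: "P/LP",
    ClinSigClass.CLASS_3: "VUS",
    ClinSigClass.CLASS_3PLUS: "CI",
    ClinSigClass.CLASS_2PLUS: "CI",
    ClinSigClass.CLASS_12: "B/LB",
    ClinSigClass.UNKNOWN: "NR",
}


def summarize_classes(variants: Sequence[AnnotatedVariant]) -> dict[str, int]:
    """Tally distinct variants per reported-class label.

    A variant carried by several samples counts once; labels follow the
    reporting convention P/LP (class 4&5), VUS (class 3), CI (conflicting,
    classes 2+ and 3+), NR (not reported in ClinVar), B/LB (class 1&2).
    """
    tally = {label: 0 for label in ("P/LP", "VUS", "CI", "NR", "B/LB")}
    seen = set()
    for v in variants:
        if v.key in seen:
            continue
        seen.add(v.key)
        clin_class = v.clin_class or ClinSigClass.UNKNOWN
        tally[CLASS_LABELS[clin_class]] += 1
    return tally


def count_carriers(
    variants: Sequence[AnnotatedVariant], cohort: Optional[Cohort] = None
) -> tuple[dict[tuple, int], int]:
    """Carrier count per distinct variant, plus the number of samples that
    carry at least one of the listed variants."""
    per_variant: dict[tuple, int] = {}
    hit_samples: set[str] = set()
    for v in variants:
        carriers = v.carriers()
        if v.key not in per_variant:
            per_variant[v.key] = len(carriers)
        hit_samples.update(carriers)
    if cohort is not None:
        hit_samples &= set(cohort.sample_ids)
    return per_variant, len(hit_samples)


@dataclass(frozen=True)
class DepthVafSummary:
    depth_mean: Optional[float]
    depth_median: Optional[float]
    depth_max: Optional[int]
    vaf_min: Optional[float]
    vaf_mean: Optional[float]
    vaf_max: Optional[float]

    def display(self) -> str:
        if self.depth_mean is None:
            return "no depth data"
        return (
            f"depth {round(self.depth_mean)}X mean / "
            f"{round(self.depth_median)}X median / {self.depth_max}X max; "
            f"VAF {self.vaf_min:.2f}-{self.vaf_max:.2f} "
            f"(mean {self.vaf_mean:.2f})"
        )


def depth_vaf_summary(variants: Sequence[AnnotatedVariant]) -> DepthVafSummary:
    """Depth and VAF statistics over all (variant, carrier) observations.

    Depths are the per-carrier site depths; VAFs the defined allele
    fractions, rounded to two decimals for display.
    """
    depths: list[int] = []
    vafs: list[float] = []
    for v in variants:
        for sid in v.carriers():
            call = v.sample_calls[sid]
            if call.site_depth is not None:
                depths.append(call.site_depth)
            vaf = compute_vaf(call)
            if vaf is not None:
                vafs.append(vaf)
    return DepthVafSummary(
        depth_mean=float(np.mean(depths)) if depths else None,
        depth_median=float(np.median(depths)) if depths else None,
        depth_max=max(depths) if depths else None,
        vaf_min=min(vafs) if vafs else None,
        vaf_mean=round(float(np.mean(vafs)), 2) if vafs else None,
        vaf_max=max(vafs) if vafs else None,
    )


# ---------------------------------------------------------------------------
# Stage-count grid
# ---------------------------------------------------------------------------

_GRID_CLASS_ORDER = (
    ClinSigClass.UNKNOWN,
    ClinSigClass.CLASS_3,
    ClinSigClass.CLASS_3PLUS,
    ClinSigClass.CLASS_45,
    ClinSigClass.CLASS_12,
    ClinSigClass.CLASS_2PLUS,
)
_BRANCHES = (
    StageRoute.S3_0_NO_SCORES,
    StageRoute.S3_1_RANKSCORE,
    StageRoute.S3_2_1_SPLICING,
    StageRoute.S3_2_2_FRAMESHIFT,
)


def stage_count_table(result: CascadeResult) -> pd.DataFrame:
    """Long-form stage-count grid keyed (stage, clin_class, branch).

    Rows: the stage-1 pass total; per-class stage-2 totals; per-(class,
    branch) stage-3 survivor counts; and the final total.  Conservation is
    asserted: per-class branch members sum to the class total, class totals
    sum to the stage-1 count, and the final total equals the sum of the
    selected terminal cells.
    """
    rows = [
        {"stage": "input", "clin_class": "ALL", "branch": "", "n_variants":
         result.n_input},
        {"stage": "stage1", "clin_class": "ALL", "branch": "", "n_variants":
         result.n_stage1_pass},
    ]
    s2 = result.stage2_counts()
    for clin_class in _GRID_CLASS_ORDER:
        rows.append({
            "stage": "stage2", "clin_class": clin_class.value, "branch": "",
            "n_variants": s2[clin_class],
        })
    routed = result.stage3_counts()
    survivors = result.stage3_survivors()
    for clin_class in (ClinSigClass.UNKNOWN, ClinSigClass.CLASS_3,
                       ClinSigClass.CLASS_3PLUS):
        for branch in _BRANCHES:
            key = (clin_class, branch)
            rows.append({
                "stage": "stage3", "clin_class": clin_class.value,
                "branch": branch.value,
                "n_variants": survivors.get(key, 0),
                "n_routed": routed.get(key, 0),
            })
    rows.append({
        "stage": "final", "clin_class": "ALL", "branch": "",
        "n_variants": result.n_final,
    })
    grid = pd.DataFrame(rows)
    _check_conservation(grid, result)
    return grid


def _check_conservation(grid: pd.DataFrame, result: CascadeResult) -> None:
    s2 = result.stage2_counts()
    assert sum(s2.values()) == result.n_stage1_pass, "stage-2 totals must sum to stage-1 pass count"
    routed = result.stage3_counts()
    for clin_class in (ClinSigClass.UNKNOWN, ClinSigClass.CLASS_3,
                       ClinSigClass.CLASS_3PLUS):
        routed_total = sum(
            n for (c, _b), n in routed.items() if c is clin_class
        )
        assert routed_total == s2[clin_class], (
            f"stage-3 routing must partition class {clin_class.value}"
        )
    survivors = result.stage3_survivors()
    for key, n in survivors.items():
        assert n <= routed.get(key, 0), "branch survivors cannot exceed members"
    expected_final = final_total_from_grid(grid, result.config.final_selection)
    assert expected_final == result.n_final, (
        "final total must equal the sum of selected terminal cells"
    )


def final_total_from_grid(grid: pd.DataFrame, final_selection) -> int:
    """Apply the final-selection rule to a stage-count grid.

    The final output is the class-4&5 stage-2 bypass plus the survivors of
    every selected stage-3 branch, summed across classes.
    """
    total = 0
    if "bypass-keep" in final_selection:
        cell = grid[(grid["stage"] == "stage2")
                    & (grid["clin_class"] == ClinSigClass.CLASS_45.value)]
        total += int(cell["n_variants"].sum())
    for branch in final_selection - {"bypass-keep"}:
        cells = grid[(grid["stage"] == "stage3") & (grid["branch"] == branch)]
        total += int(cells["n_variants"].sum())
    return total


def grid_from_audits(result: CascadeResult) -> pd.DataFrame:
    """Recompute the stage grid directly from the per-variant audit trail.

    Independent second path used to cross-check the accumulated grid.
    """
    rows = []
    for a in result.audits:
        rows.append({
            "passed_stage1": a.passed_stage1,
            "clin_class": a.clin_class.value if a.clin_class else "",
            "route": a.route.value if a.route else "",
            "branch_pass": bool(a.branch_pass),
            "in_final": a.in_final,
        })
    df = pd.DataFrame(rows)
    out = [
        {"stage": "input", "clin_class": "ALL", "branch": "",
         "n_variants": len(df)},
        {"stage": "stage1", "clin_class": "ALL", "branch": "",
         "n_variants": int(df["passed_stage1"].sum()) if len(df) else 0},
    ]
    passed = df[df["passed_stage1"]] if len(df) else df
    for clin_class in _GRID_CLASS_ORDER:
        n = int((passed["clin_class"] == clin_class.value).sum()) if len(df) else 0
        out.append({"stage": "stage2", "clin_class": clin_class.value,
                    "branch": "", "n_variants": n})
    for clin_class in (ClinSigClass.UNKNOWN, ClinSigClass.CLASS_3,
                       ClinSigClass.CLASS_3PLUS):
        for branch in _BRANCHES:
            if len(df):
                mask = (
                    (passed["clin_class"] == clin_class.value)
                    & (passed["route"] == branch.value)
                )
                n_routed = int(mask.sum())
                n_surv = int((mask & passed["branch_pass"]).sum())
            else:
                n_routed = n_surv = 0
            out.append({"stage": "stage3", "clin_class": clin_class.value,
                        "branch": branch.value, "n_variants": n_surv,
                        "n_routed": n_routed})
    out.append({"stage": "final", "clin_class": "ALL", "branch": "",
                "n_variants": int(df["in_final"].sum()) if len(df) else 0})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Bundled machine-readable summary
# ---------------------------------------------------------------------------


def cohort_summary(
    cohort: Cohort,
    result: CascadeResult,
    final: Sequence[AnnotatedVariant],
) -> dict:
    """Single JSON-serializable bundle of every cohort-level count."""
    per_variant, samples_with_hits = count_carriers(final, cohort)
    dv = depth_vaf_summary(final)
    return {
        "n_input_variants": result.n_input,
        "n_stage1_pass": result.n_stage1_pass,
        "stage2_counts": {
            c.value: n for c, n in sorted(
                result.stage2_counts().items(), key=lambda kv: kv[0].value
            )
        },
        "n_variants_final": result.n_final,
        "n_genes_final": len({v.gene_symbol.upper() for v in final}),
        "class_tally": summarize_classes(final),
        "samples_with_hits": samples_with_hits,
        "max_carriers": max(per_variant.values(), default=0),
        "depth_vaf": asdict(dv),
    }


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
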