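"""Recompute every reported result surface from the packaged fixtures.

Each check re-derives a published count from the transcribed tables through
the package's own operations (cascade arithmetic, class tallies, carrier
counts, the worked filter examples) and pairs it with the expected value, so
a fresh checkout can prove the fixtures and the code agree.
"""

from __future__ import annotations

from .cohort_model import SampleCall, ToolScorePanel, compute_vaf
from .filter_cascade import CascadeConfig, default_class_filters, eval_expression
from .cohort_model import ClinSigClass
from .gene_crossref import extract_high_impact
from .reporting import count_carriers, final_total_from_grid, summarize_classes
from .synthetic_cohort import acmg_overrides, cohort_from_table3, load_fixture

HIGH_IMPACT_GENES = ("BRCA2", "MLH1", "MSH2", "MSH6", "PMS2", "PTCH1", "SDHA")


def _recurrence(cohort, gene: str, hgvs_c: str) -> int:
    for v in cohort.variants:
        ann = v.annotation
        if ann.gene_symbol == gene and ann.hgvs_c == hgvs_c:
            return len(v.carriers())
    return 0


def fixture_report() -> dict[str, dict]:
    """All fixture-derived checks as ``{name: {value, expected, n, ok}}``."""
    checks: dict[str, dict] = {}

    def add(name: str, value, expected, n: int) -> None:
        checks[name] = {
            "value": value, "expected": expected, "n": n,
            "ok": value == expected,
        }

    # final-selection arithmetic over the transcribed stage-count grid
    table2 = load_fixture("table2")
    grid = table2.rename(columns={"clin_class": "clin_class"})
    config = CascadeConfig()
    final_total = final_total_from_grid(grid, config.final_selection)
    add("table2_final_variants", final_total, 346, len(table2))

    # the 45-variant / 32-sample listing
    cohort = cohort_from_table3()
    add("table3_distinct_variants", len(cohort.variants), 45, len(cohort.variants))
    _, samples_with_hits = count_carriers(cohort.variants, cohort)
    add("table3_carrier_samples", samples_with_hits, 32, len(cohort.samples))
    tally = summarize_classes(cohort.variants)
    add("table3_plp_variants", tally["P/LP"], 14, len(cohort.variants))
    add("table3_vus_variants", tally["VUS"], 6, len(cohort.variants))
    add("table3_ci_variants", tally["CI"], 4, len(cohort.variants))
    add("table3_nr_variants", tally["NR"], 21, len(cohort.variants))
    add("pabpc1_splice_carriers", _recurrence(cohort, "PABPC1", "c.739-1G>A"),
        7, len(cohort.samples))
    add("tyro3_splice_carriers", _recurrence(cohort, "TYRO3", "c.1660+1G>C"),
        3, len(cohort.samples))
    add("cftr_missense_carriers", _recurrence(cohort, "CFTR", "c.1392G>T"),
        5, len(cohort.samples))

    # known high-impact genes, with expert ACMG-AMP classes applied
    overrides = acmg_overrides(cohort)
    _, summary = extract_high_impact(
        cohort.variants, HIGH_IMPACT_GENES,
        min_class=ClinSigClass.CLASS_3, class_override=overrides,
    )
    add("high_impact_genes", summary.n_genes, 7, len(cohort.variants))
    add("high_impact_variants", summary.n_variants, 9, len(cohort.variants))
    add("high_impact_patients", summary.n_patients, 10, len(cohort.samples))

    # worked filter examples: one near-miss, one single-tool pass
    filters = default_class_filters()
    msh2_panel = ToolScorePanel(rank_scores={
        "T1": 0.98, "T2": 0.98, "T3": 0.98, "T4": 0.98, "T5": 0.98,
        "T6": 0.98, "T7": 0.78,
    })
    msh2_pass, _ = eval_expression(filters[ClinSigClass.UNKNOWN], msh2_panel)
    add("msh2_unknown_filter_pass", int(msh2_pass), 0, 7)
    ptch1_panel = ToolScorePanel(rank_scores={
        "T1": 0.2, "T2": 0.1, "T3": 0.15, "T4": 0.1, "T5": 0.2,
        "T6": 0.99639, "T7": 0.3,
    })
    ptch1_pass, _ = eval_expression(filters[ClinSigClass.CLASS_3], ptch1_panel)
    add("ptch1_class3_filter_pass", int(ptch1_pass), 1, 7)

    # VAF worked example
    vaf = compute_vaf(SampleCall("S", ("0", "1"), depth_ref=35, depth_alt=3))
    add("vaf_worked_example", vaf, 0.08, 38)

    return checks
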