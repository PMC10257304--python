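"""Cascade engine tests: expression grammar, branch filters, routing and the
end-to-end stage bookkeeping."""

import itertools
import random

import pytest

from varcascade.cohort_model import ClinSigClass, LofConfidence, ToolScorePanel, TOOL_SLOTS
from varcascade.filter_cascade import (
    CascadeConfig,
    FilterExpression,
    StageRoute,
    default_class_filters,
    eval_expression,
    final_variants,
    lof_filter,
    route_stage3,
    run_cascade,
    splicing_filter,
    stage1_frequency,
)

from conftest import make_cohort, make_variant


# ---------------------------------------------------------------------------
# expression grammar
# ---------------------------------------------------------------------------


def test_parse_bracket_notation():
    expr = FilterExpression.parse("[T2-cutoff-0.99] || [T7-cutoff-0.8]")
    assert expr.clauses == (("T2", 0.99), ("T7", 0.8))
    assert expr.combinator == "OR"
    assert FilterExpression.parse(str(expr)) == expr


def test_parse_and_combinator():
    expr = FilterExpression.parse("[T1-cutoff-0.5] && [T3-cutoff-0.6]")
    assert expr.combinator == "AND"


@pytest.mark.parametrize(
    "bad",
    [
        "",
        "[T8-cutoff-0.5]",
        "[T1-cutoff-1.5]",
        "[T1-cutoff-0.5] || [T2-cutoff-0.6] && [T3-cutoff-0.7]",
        "[T1-cutoff-0.5] nonsense",
    ],
)
def test_parse_rejects_malformed(bad):
    with pytest.raises(ValueError):
        FilterExpression.parse(bad)


def test_eval_expression_worked_examples():
    unknown = default_class_filters()[ClinSigClass.UNKNOWN]
    # high everywhere but 0.78 in the CADD slot: near-miss, filtered out
    near_miss = ToolScorePanel(rank_scores={"T2": 0.95, "T7": 0.78})
    assert eval_expression(unknown, near_miss) == (False, [])
    # boundary is inclusive: 0.81 >= 0.8 passes under OR
    passing = ToolScorePanel(rank_scores={"T7": 0.81})
    ok, fired = eval_expression(unknown, passing)
    assert ok and fired == ["[T7-cutoff-0.8]"]
    # a single extreme M-CAP rank score carries the class-3 expression
    class3 = default_class_filters()[ClinSigClass.CLASS_3]
    mcap_only = ToolScorePanel(rank_scores={
        "T1": 0.2, "T2": 0.1, "T6": 0.99639, "T7": 0.3,
    })
    assert eval_expression(class3, mcap_only)[0]


def test_eval_expression_matches_truth_table_oracle():
    """Exhaustive equivalence with brute-force enumeration.

    Every slot independently takes one of three states — absent, present
    below cutoff, present at-or-above cutoff — and the oracle combines
    clause truths with plain any()/all().
    """
    expressions = [
        FilterExpression(tuple((s, 0.5 + 0.05 * i) for i, s in enumerate(TOOL_SLOTS)),
                         comb)
        for comb in ("OR", "AND")
    ] + [
        default_class_filters()[ClinSigClass.UNKNOWN],
        default_class_filters()[ClinSigClass.CLASS_3],
    ]
    for expr in expressions:
        slots = [slot for slot, _ in expr.clauses]
        cutoffs = dict(expr.clauses)
        for states in itertools.product(("absent", "fail", "pass"),
                                        repeat=len(slots)):
            scores = {}
            clause_truth = []
            for slot, state in zip(slots, states):
                if state == "absent":
                    clause_truth.append(False)
                    continue
                scores[slot] = (cutoffs[slot] if state == "pass"
                                else max(0.0, cutoffs[slot] - 0.01))
                clause_truth.append(state == "pass")
            oracle = (all(clause_truth) if expr.combinator == "AND"
                      else any(clause_truth))
            got, _ = eval_expression(expr, ToolScorePanel(rank_scores=scores))
            assert got == oracle, (expr, states)


# ---------------------------------------------------------------------------
# single-stage filters
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "af,expected",
    [(0.0005, True), (None, True), (0.001, False), (0.01, False), (0.0, True)],
)
def test_stage1_frequency_gate(af, expected):
    v = make_variant(af=af)
    assert stage1_frequency(v, 0.001) is expected


@pytest.mark.parametrize(
    "deltas,cutoff,expected",
    [
        ((0.1, 0.0, 1.0, 0.2), 0.5, True),
        ((0.1, 0.2, 0.49, 0.3), 0.5, False),
        ((0.5, 0.0, 0.0, 0.0), 0.5, True),  # boundary inclusive
        (None, 0.5, False),
    ],
)
def test_splicing_filter(deltas, cutoff, expected):
    assert splicing_filter(ToolScorePanel(spliceai_deltas=deltas), cutoff) is expected


@pytest.mark.parametrize(
    "lof,expected",
    [
        (LofConfidence.HIGH_CONFIDENCE, True),
        (LofConfidence.LOW_CONFIDENCE, False),
        (LofConfidence.ABSENT, False),
    ],
)
def test_lof_filter_high_confidence_rule(lof, expected):
    panel = ToolScorePanel(lof_confidence=lof)
    assert lof_filter(panel, LofConfidence.HIGH_CONFIDENCE) is expected


# ---------------------------------------------------------------------------
# stage-3 routing
# ---------------------------------------------------------------------------


def _routed(variant):
    variant.clin_class = ClinSigClass.UNKNOWN
    return route_stage3(variant)


def test_routing_by_consequence():
    missense = make_variant(consequence="missense_variant",
                            rank_scores={"T1": 0.5})
    assert _routed(missense) is StageRoute.S3_1_RANKSCORE
    splice = make_variant(consequence="splice_acceptor_variant",
                          spliceai=(0.9, 0.0, 0.0, 0.0))
    assert _routed(splice) is StageRoute.S3_2_1_SPLICING
    frameshift = make_variant(ref="AT", alt="A",
                              consequence="frameshift_variant",
                              lof=LofConfidence.HIGH_CONFIDENCE)
    assert _routed(frameshift) is StageRoute.S3_2_2_FRAMESHIFT
    unscored = make_variant(consequence="synonymous_variant")
    assert _routed(unscored) is StageRoute.S3_0_NO_SCORES
    # missense without any rank score cannot enter the rank-score branch
    bare_missense = make_variant(consequence="missense_variant")
    assert _routed(bare_missense) is StageRoute.S3_0_NO_SCORES


def test_routing_priority_rankscore_over_splice():
    both = make_variant(consequence="missense_variant&splice_region_variant",
                        rank_scores={"T1": 0.5})
    assert _routed(both) is StageRoute.S3_1_RANKSCORE


def test_routing_rejects_bypass_classes():
    v = make_variant(clinvar="Pathogenic")
    v.clin_class = ClinSigClass.CLASS_45
    with pytest.raises(ValueError):
        route_stage3(v)


# ---------------------------------------------------------------------------
# end-to-end cascade
# ---------------------------------------------------------------------------


def test_cascade_bypass_and_drop_rules():
    variants = [
        # rare pathogenic, no scores at all: kept via class-4&5 bypass
        make_variant(pos=100, clinvar="Pathogenic"),
        # rare benign: dropped without stage-3 scrutiny
        make_variant(pos=200, clinvar="Benign"),
        # common variant: stage-1 failure regardless of class
        make_variant(pos=300, af=0.05, clinvar="Pathogenic"),
        # rare unknown missense passing the class-unknown expression
        make_variant(pos=400, rank_scores={"T7": 0.92}),
        # rare unknown missense failing it
        make_variant(pos=500, rank_scores={"T7": 0.10}),
    ]
    cohort = make_cohort(variants)
    result = run_cascade(cohort)
    finals = {key[1] for key in result.final_keys()}
    assert finals == {100, 400}
    by_pos = {a.key[1]: a for a in result.audits}
    assert by_pos[100].route is StageRoute.BYPASS_KEEP
    assert by_pos[200].route is StageRoute.BYPASS_DROP
    assert not by_pos[300].passed_stage1
    assert by_pos[400].firing_clauses == ("[T7-cutoff-0.8]",)


def test_no_scores_bucket_counted_but_excluded():
    v = make_variant(consequence="synonymous_variant")
    result = run_cascade(make_cohort([v]))
    audit = result.audits[0]
    assert audit.route is StageRoute.S3_0_NO_SCORES
    assert audit.branch_pass and not audit.in_final


def test_config_requires_all_stage3_class_filters():
    filters = default_class_filters()
    del filters[ClinSigClass.CLASS_3]
    with pytest.raises(ValueError, match="CLASS_3"):
        CascadeConfig(class_filters=filters)


def test_all_common_means_empty_final(sim_cohort):
    from dataclasses import replace

    from varcascade.cohort_model import Cohort

    cohort, _ = sim_cohort
    common = Cohort(
        samples=list(cohort.samples),
        variants=[replace(v, population_af=0.05) for v in cohort.variants],
    )
    result = run_cascade(common)
    assert result.n_final == 0 and result.n_stage1_pass == 0


def test_cascade_partition_and_conservation(sim_cohort):
    cohort, _ = sim_cohort
    result = run_cascade(cohort)
    s2 = result.stage2_counts()
    assert sum(s2.values()) == result.n_stage1_pass
    routed = result.stage3_counts()
    for clin_class in (ClinSigClass.UNKNOWN, ClinSigClass.CLASS_3,
                       ClinSigClass.CLASS_3PLUS):
        assert sum(n for (c, _), n in routed.items() if c is clin_class) == s2[clin_class]
    # every audit got exactly one terminal assignment
    for a in result.audits:
        assert a.passed_stage1 == (a.route is not None)


def test_cascade_determinism_under_input_order(sim_cohort):
    cohort, _ = sim_cohort
    shuffled = make_cohort_copy(cohort)
    random.Random(3).shuffle(shuffled.variants)
    r1, r2 = run_cascade(cohort), run_cascade(shuffled)
    assert [a.key for a in r1.audits] == [a.key for a in r2.audits]
    assert r1.final_keys() == r2.final_keys()


def make_cohort_copy(cohort):
    from varcascade.cohort_model import Cohort

    return Cohort(samples=list(cohort.samples), variants=list(cohort.variants))


def test_cascade_idempotent_on_its_final_set(sim_cohort):
    from varcascade.cohort_model import Cohort

    cohort, _ = sim_cohort
    result = run_cascade(cohort)
    final = final_variants(cohort, result)
    rerun = run_cascade(Cohort(samples=list(cohort.samples), variants=final))
    assert rerun.final_keys() == result.final_keys()
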