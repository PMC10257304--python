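"""Three-stage germline variant prioritization cascade.

Stage 1 is a population-frequency gate (rare means gnomAD allele frequency
strictly below a cutoff; variants absent from the population database count
as frequency zero and therefore pass).  Stage 2 stratifies survivors into six
ClinVar-derived classes.  Pathogenic / likely-pathogenic variants (class 4&5)
bypass stage 3 and are kept; benign-side classes (1&2 and 2+) bypass stage 3
and are dropped.  The remaining classes (unknown, 3, 3+) are routed into one
of four stage-3 branches by consequence type:

* 3.1  rank-score consensus over the seven missense-class tools, evaluated
       against a per-class boolean cutoff expression,
* 3.2.1 splicing: maximum SpliceAI delta against a threshold,
* 3.2.2 frameshift / loss of function: LOFTEE confidence,
* 3.0  residual bucket for variants with no applicable scores; its members
       are counted but never enter the final selection.

Cutoff expressions use a compact bracket notation, e.g.
``[T2-cutoff-0.99] || [T7-cutoff-0.8]``: a clause is true iff the slot's rank
score is present and >= the cutoff (a score exactly at the cutoff passes).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import yaml

from .cohort_model import (
    AnnotatedVariant,
    ClinSigClass,
    Cohort,
    LofConfidence,
    TOOL_SLOTS,
    ToolScorePanel,
    parse_clinsig,
)

# Default tool-slot assignment.  T7 carries CADD (raw-score rank); the
# remaining six predictors fill T1..T6 with M-CAP in slot T6 so the class-3
# expression [T6-cutoff-0.8] || [T1-cutoff-0.99] tests M-CAP and REVEL.
DEFAULT_TOOL_SLOT_MAP: Mapping[str, str] = {
    "T1": "REVEL",
    "T2": "ClinPred",
    "T3": "VEST4",
    "T4": "MetaSVM",
    "T5": "BayesDel",
    "T6": "M-CAP",
    "T7": "CADD",
}

#: Consequences handled by the rank-score branch (3.1).
RANKSCORE_CONSEQUENCES = frozenset(
    {"missense_variant", "stop_gained", "start_lost"}
)
#: Consequences handled by the splicing branch (3.2.1).
SPLICE_CONSEQUENCES = frozenset(
    {
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
        "splice_donor_5th_base_variant",
        "splice_donor_region_variant",
        "splice_polypyrimidine_tract_variant",
    }
)
#: Consequences handled by the frameshift/LoF branch (3.2.2).
FRAMESHIFT_CONSEQUENCES = frozenset(
    {"frameshift_variant", "stop_gained", "inframe_deletion", "inframe_insertion"}
)


class StageRoute(enum.Enum):
    """Terminal routing of one stage-1 survivor."""

    S3_0_NO_SCORES = "3.0"
    S3_1_RANKSCORE = "3.1"
    S3_2_1_SPLICING = "3.2.1"
    S3_2_2_FRAMESHIFT = "3.2.2"
    BYPASS_KEEP = "bypass-keep"
    BYPASS_DROP = "bypass-drop"


#: Classes that bypass stage 3 and are kept / dropped outright.
BYPASS_KEEP_CLASSES = frozenset({ClinSigClass.CLASS_45})
BYPASS_DROP_CLASSES = frozenset({ClinSigClass.CLASS_12, ClinSigClass.CLASS_2PLUS})
#: Classes whose variants are routed through stage 3.
STAGE3_CLASSES = frozenset(
    {ClinSigClass.UNKNOWN, ClinSigClass.CLASS_3, ClinSigClass.CLASS_3PLUS}
)


# ---------------------------------------------------------------------------
# Cutoff expressions
# ---------------------------------------------------------------------------

_CLAUSE_RE = re.compile(r"\[\s*(T[1-7])\s*-\s*cutoff\s*-\s*([0-9.]+)\s*\]")


@dataclass(frozen=True)
class FilterExpression:
    """Boolean combination of per-tool rank-score cutoff clauses."""

    clauses: tuple[tuple[str, float], ...]
    combinator: str = "OR"  # "OR" | "AND"

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("a filter expression needs at least one clause")
        if self.combinator not in {"OR", "AND"}:
            raise ValueError(f"combinator must be OR or AND, got {self.combinator!r}")
        for slot, cutoff in self.clauses:
            if slot not in TOOL_SLOTS:
                raise ValueError(f"unknown tool slot {slot!r}")
            if not (0.0 <= cutoff <= 1.0):
                raise ValueError(f"cutoff {cutoff} for {slot} outside [0, 1]")

    @classmethod
    def parse(cls, text: str) -> "FilterExpression":
        """Parse ``[T2-cutoff-0.99] || [T7-cutoff-0.8]`` style notation.

        Grammar: ``expr := clause (('||' | '&&') clause)*`` with a single
        combinator throughout (mixing ``||`` and ``&&`` is rejected).
        """
        clauses = [(m.group(1), float(m.group(2))) for m in _CLAUSE_RE.finditer(text)]
        if not clauses:
            raise ValueError(f"no cutoff clauses found in {text!r}")
        residue = _CLAUSE_RE.sub("", text)
        ops = set(re.findall(r"\|\||&&", residue))
        leftovers = re.sub(r"\|\||&&|\s", "", residue)
        if leftovers:
            raise ValueError(f"unparseable tokens {leftovers!r} in {text!r}")
        if len(ops) > 1:
            raise ValueError(f"mixed || and && combinators in {text!r}")
        combinator = "AND" if ops == {"&&"} else "OR"
        return cls(tuple(clauses), combinator)

    def __str__(self) -> str:
        sep = " || " if self.combinator == "OR" else " && "
        return sep.join(f"[{slot}-cutoff-{cutoff:g}]" for slot, cutoff in self.clauses)


def eval_expression(
    expr: FilterExpression, panel: ToolScorePanel
) -> tuple[bool, list[str]]:
    """Evaluate a cutoff expression against a score panel.

    A clause fires iff its slot has a score and the score is >= the cutoff;
    an absent score makes the clause false.  Returns the overall verdict and
    the list of firing clauses (for the audit trail).
    """
    truths: list[bool] = []
    firing: list[str] = []
    for slot, cutoff in expr.clauses:
        score = panel.rank_scores.get(slot)
        ok = score is not None and score >= cutoff
        truths.append(ok)
        if ok:
            firing.append(f"[{slot}-cutoff-{cutoff:g}]")
    verdict = all(truths) if expr.combinator == "AND" else any(truths)
    return verdict, firing


def splicing_filter(panel: ToolScorePanel, spliceai_cutoff: float) -> bool:
    """Pass iff the maximum SpliceAI delta is present and >= the cutoff."""
    m = panel.max_spliceai
    return m is not None and m >= spliceai_cutoff


def lof_filter(panel: ToolScorePanel, lof_rule: LofConfidence) -> bool:
    """Pass iff the LOFTEE confidence equals the configured required level."""
    return panel.lof_confidence is lof_rule


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def default_class_filters() -> dict[ClinSigClass, FilterExpression]:
    """Per-class 3.1 cutoff expressions.

    Class-unknown uses ``[T2-cutoff-0.99] || [T7-cutoff-0.8]`` (ClinPred or
    CADD); classes 3 and 3+ use ``[T6-cutoff-0.8] || [T1-cutoff-0.99]``
    (M-CAP or REVEL).  Class 3+ has no published expression of its own and
    defaults to the class-3 one.
    """
    unknown = FilterExpression.parse("[T2-cutoff-0.99] || [T7-cutoff-0.8]")
    class3 = FilterExpression.parse("[T6-cutoff-0.8] || [T1-cutoff-0.99]")
    return {
        ClinSigClass.UNKNOWN: unknown,
        ClinSigClass.CLASS_3: class3,
        ClinSigClass.CLASS_3PLUS: class3,
    }


@dataclass
class CascadeConfig:
    """Every threshold the cascade's counts depend on, in one object."""

    af_cutoff: float = 0.001
    class_filters: dict[ClinSigClass, FilterExpression] = field(
        default_factory=default_class_filters
    )
    spliceai_cutoff: float = 0.5
    lof_rule: LofConfidence = LofConfidence.HIGH_CONFIDENCE
    tool_slot_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TOOL_SLOT_MAP)
    )
    final_selection: frozenset[str] = frozenset(
        {"bypass-keep", "3.1", "3.2.1", "3.2.2"}
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.af_cutoff <= 1.0):
            raise ValueError(f"af_cutoff must lie in (0, 1], got {self.af_cutoff}")
        missing = STAGE3_CLASSES - set(self.class_filters)
        if missing:
            raise ValueError(
                "class_filters must cover all stage-3 classes; missing "
                + ", ".join(sorted(c.value for c in missing))
            )

    def replace(self, **changes) -> "CascadeConfig":
        return replace(self, **changes)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "af_cutoff": self.af_cutoff,
            "class_filters": {
                c.value: str(e) for c, e in sorted(
                    self.class_filters.items(), key=lambda kv: kv[0].value
                )
            },
            "spliceai_cutoff": self.spliceai_cutoff,
            "lof_rule": self.lof_rule.name,
            "tool_slot_map": dict(self.tool_slot_map),
            "final_selection": sorted(self.final_selection),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CascadeConfig":
        kwargs: dict = {}
        if "af_cutoff" in data:
            kwargs["af_cutoff"] = float(data["af_cutoff"])
        if "class_filters" in data:
            kwargs["class_filters"] = {
                ClinSigClass(name): FilterExpression.parse(expr)
                for name, expr in data["class_filters"].items()
            }
        if "spliceai_cutoff" in data:
            kwargs["spliceai_cutoff"] = float(data["spliceai_cutoff"])
        if "lof_rule" in data:
            kwargs["lof_rule"] = LofConfidence[data["lof_rule"]]
        if "tool_slot_map" in data:
            kwargs["tool_slot_map"] = dict(data["tool_slot_map"])
        if "final_selection" in data:
            kwargs["final_selection"] = frozenset(data["final_selection"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "CascadeConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def stage1_frequency(variant: AnnotatedVariant, af_cutoff: float) -> bool:
    """Frequency gate: pass iff AF (absent treated as zero) < cutoff, strictly."""
    af = variant.population_af
    if af is None:
        af = 0.0
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"population AF {af} outside [0, 1]")
    return af < af_cutoff


def stage2_stratify(variant: AnnotatedVariant) -> ClinSigClass:
    """Assign the ClinVar stratification class (also stored on the variant)."""
    clin_class = parse_clinsig(variant.clinvar_raw)
    variant.clin_class = clin_class
    return clin_class


def route_stage3(variant: AnnotatedVariant) -> StageRoute:
    """Route a stage-3 variant to its branch by consequence type.

    Priority: rank-score branch (eligible consequence and at least one of the
    seven tools scored) > splicing > frameshift; everything else — including
    scored variants whose consequence fits no branch — falls into the 3.0
    residual bucket.
    """
    if variant.clin_class not in STAGE3_CLASSES:
        raise ValueError(
            f"route_stage3 called on bypass class {variant.clin_class}"
        )
    terms = variant.annotation.consequence_terms
    panel = variant.scores
    if terms & RANKSCORE_CONSEQUENCES and panel.has_rank_scores:
        return StageRoute.S3_1_RANKSCORE
    if terms & SPLICE_CONSEQUENCES:
        return StageRoute.S3_2_1_SPLICING
    if terms & FRAMESHIFT_CONSEQUENCES:
        return StageRoute.S3_2_2_FRAMESHIFT
    return StageRoute.S3_0_NO_SCORES


# ---------------------------------------------------------------------------
# Cascade result
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantAudit:
    """Per-variant audit trail of one cascade run."""

    key: tuple[str, int, str, str]
    gene_symbol: str
    passed_stage1: bool
    clin_class: Optional[ClinSigClass]
    route: Optional[StageRoute]
    branch_pass: Optional[bool]
    in_final: bool
    firing_clauses: tuple[str, ...] = ()


@dataclass
class CascadeResult:
    """Audit trails plus cohort-level stage counts for one cascade run."""

    config: CascadeConfig
    audits: list[VariantAudit]

    # -- derived views ------------------------------------------------------

    @property
    def n_input(self) -> int:
        return len(self.audits)

    @property
    def n_stage1_pass(self) -> int:
        return sum(a.passed_stage1 for a in self.audits)

    def stage2_counts(self) -> dict[ClinSigClass, int]:
        counts: dict[ClinSigClass, int] = {c: 0 for c in ClinSigClass}
        for a in self.audits:
            if a.passed_stage1:
                counts[a.clin_class] += 1
        return counts

    def stage3_counts(self) -> dict[tuple[ClinSigClass, StageRoute], int]:
        """Routed counts per (class, branch) — membership, not survival."""
        counts: dict[tuple[ClinSigClass, StageRoute], int] = {}
        for a in self.audits:
            if a.passed_stage1 and a.route is not None:
                key = (a.clin_class, a.route)
                counts[key] = counts.get(key, 0) + 1
        return counts

    def stage3_survivors(self) -> dict[tuple[ClinSigClass, StageRoute], int]:
        counts: dict[tuple[ClinSigClass, StageRoute], int] = {}
        for a in self.audits:
            if a.passed_stage1 and a.route is not None and a.branch_pass:
                key = (a.clin_class, a.route)
                counts[key] = counts.get(key, 0) + 1
        return counts

    def final_keys(self) -> set[tuple[str, int, str, str]]:
        return {a.key for a in self.audits if a.in_final}

    @property
    def n_final(self) -> int:
        return sum(a.in_final for a in self.audits)


def _audit_variant(variant: AnnotatedVariant, config: CascadeConfig) -> VariantAudit:
    key = variant.key
    gene = variant.gene_symbol if variant.annotations else ""
    if not stage1_frequency(variant, config.af_cutoff):
        return VariantAudit(key, gene, False, None, None, None, False)
    clin_class = stage2_stratify(variant)
    firing: tuple[str, ...] = ()
    if clin_class in BYPASS_KEEP_CLASSES:
        route, branch_pass = StageRoute.BYPASS_KEEP, True
    elif clin_class in BYPASS_DROP_CLASSES:
        route, branch_pass = StageRoute.BYPASS_DROP, False
    else:
        route = route_stage3(variant)
        if route is StageRoute.S3_1_RANKSCORE:
            branch_pass, fired = eval_expression(
                config.class_filters[clin_class], variant.scores
            )
            firing = tuple(fired)
        elif route is StageRoute.S3_2_1_SPLICING:
            branch_pass = splicing_filter(variant.scores, config.spliceai_cutoff)
        elif route is StageRoute.S3_2_2_FRAMESHIFT:
            branch_pass = lof_filter(variant.scores, config.lof_rule)
        else:  # 3.0: counted as bucket members, never selected
            branch_pass = True
    in_final = route.value in config.final_selection and branch_pass
    return VariantAudit(key, gene, True, clin_class, route, branch_pass, in_final, firing)


def run_cascade(cohort: Cohort, config: Optional[CascadeConfig] = None) -> CascadeResult:
    """Run the full three-stage cascade over a cohort.

    Deterministic: the audit list follows a canonical variant-key order, so
    identical cohorts give identical results regardless of input order.
    """
    if config is None:
        config = CascadeConfig()
    ordered = sorted(cohort.variants, key=lambda v: v.key)
    audits = [_audit_variant(v, config) for v in ordered]
    return CascadeResult(config=config, audits=audits)


def final_variants(cohort: Cohort, result: CascadeResult) -> list[AnnotatedVariant]:
    """The final selected variant objects, in canonical key order."""
    keys = result.final_keys()
    return sorted((v for v in cohort.variants if v.key in keys), key=lambda v: v.key)
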