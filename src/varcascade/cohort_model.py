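"""Core domain model for annotated multi-sample variant cohorts.

The objects here are the in-memory currency of the whole package: a
:class:`Cohort` holds :class:`AnnotatedVariant` records, each of which carries
its genomic :class:`Locus`, one or more per-transcript annotations, a
population allele frequency, a raw ClinVar clinical-significance string, a
panel of in-silico pathogenicity scores and the per-sample genotype calls.

Three elementary per-variant computations live here as well:

* :func:`parse_clinsig` — map a raw ClinVar significance string onto the six
  stratification classes used by the prioritization cascade,
* :func:`compute_vaf` — variant allele fraction from allele depths,
* :func:`select_annotation` — pick the single representative transcript for a
  variant (canonical first, then consequence severity).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

_DNA_RE = re.compile(r"^[ACGTN]+$")

#: Canonical identifiers of the seven missense-class tool slots.
TOOL_SLOTS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7")


class ClinSigClass(enum.Enum):
    """Clinical-significance stratification classes.

    ``CLASS_45`` collects pathogenic / likely-pathogenic variants (ACMG-AMP
    classes 4 and 5), ``CLASS_3`` the variants of uncertain significance,
    ``CLASS_12`` benign / likely benign.  ``CLASS_3PLUS`` marks conflicting
    ClinVar records that contain at least one pathogenic or likely-pathogenic
    assertion; ``CLASS_2PLUS`` marks conflicts confined to benign / likely
    benign / uncertain assertions.  Variants absent from ClinVar are
    ``UNKNOWN``.
    """

    UNKNOWN = "UNKNOWN"
    CLASS_12 = "CLASS_12"
    CLASS_2PLUS = "CLASS_2PLUS"
    CLASS_3 = "CLASS_3"
    CLASS_3PLUS = "CLASS_3PLUS"
    CLASS_45 = "CLASS_45"


#: Severity rank used by :func:`extract` thresholds: only the three classes
#: that receive individual scrutiny participate in the ordering.
CLASS_SEVERITY_RANK: Mapping[ClinSigClass, int] = {
    ClinSigClass.UNKNOWN: 0,
    ClinSigClass.CLASS_12: 0,
    ClinSigClass.CLASS_2PLUS: 0,
    ClinSigClass.CLASS_3: 1,
    ClinSigClass.CLASS_3PLUS: 2,
    ClinSigClass.CLASS_45: 3,
}


class LofConfidence(enum.Enum):
    """Loss-of-function annotation confidence (LOFTEE-style HC/LC)."""

    HIGH_CONFIDENCE = "HC"
    LOW_CONFIDENCE = "LC"
    ABSENT = "ABSENT"


@dataclass(frozen=True, order=True)
class Locus:
    """A genomic variant locus: 1-based position with explicit alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _DNA_RE.match(allele):
                raise ValueError(f"{name} allele {allele!r} is not a [ACGTN]+ string")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One VEP-style per-transcript annotation of a variant."""

    gene_symbol: str
    transcript_id: str
    consequence_terms: frozenset[str]
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    is_canonical: bool = False

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if not self.consequence_terms:
            raise ValueError("consequence_terms must be non-empty")
        if not isinstance(self.consequence_terms, frozenset):
            object.__setattr__(
                self, "consequence_terms", frozenset(self.consequence_terms)
            )


def _check_unit(value: Optional[float], what: str) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{what} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class ToolScorePanel:
    """In-silico scores attached to one variant.

    ``rank_scores`` maps tool slots ``T1``..``T7`` (the seven missense-class
    predictors) to rank scores in [0, 1]; missing entries mean the tool
    produced no score.  ``spliceai_deltas`` are the four splice-altering delta
    probabilities (acceptor gain, acceptor loss, donor gain, donor loss);
    ``lof_confidence`` is the LOFTEE-style loss-of-function call.
    """

    rank_scores: Mapping[str, float] = field(default_factory=dict)
    spliceai_deltas: Optional[tuple[float, float, float, float]] = None
    lof_confidence: LofConfidence = LofConfidence.ABSENT

    def __post_init__(self) -> None:
        for slot, score in self.rank_scores.items():
            if slot not in TOOL_SLOTS:
                raise ValueError(f"unknown tool slot {slot!r}")
            _check_unit(score, f"rank score for {slot}")
        if self.spliceai_deltas is not None:
            if len(self.spliceai_deltas) != 4:
                raise ValueError("spliceai_deltas must have exactly 4 entries")
            for delta in self.spliceai_deltas:
                _check_unit(delta, "SpliceAI delta")

    @property
    def has_rank_scores(self) -> bool:
        return bool(self.rank_scores)

    @property
    def has_any_score(self) -> bool:
        return (
            bool(self.rank_scores)
            or self.spliceai_deltas is not None
            or self.lof_confidence is not LofConfidence.ABSENT
        )

    @property
    def max_spliceai(self) -> Optional[float]:
        if self.spliceai_deltas is None:
            return None
        return max(self.spliceai_deltas)


@dataclass(frozen=True)
class SampleCall:
    """Per-sample genotype call with informative allele depths."""

    sample_id: str
    genotype: tuple[str, str]
    depth_ref: Optional[int] = None
    depth_alt: Optional[int] = None
    site_depth: Optional[int] = None

    def __post_init__(self) -> None:
        for allele in self.genotype:
            if allele not in {"0", "1", "."}:
                raise ValueError(f"genotype allele {allele!r} not in {{0,1,.}}")
        for name, depth in (
            ("depth_ref", self.depth_ref),
            ("depth_alt", self.depth_alt),
            ("site_depth", self.site_depth),
        ):
            if depth is not None and depth < 0:
                raise ValueError(f"{name} must be non-negative, got {depth}")
        if (
            self.depth_ref is not None
            and self.depth_alt is not None
            and self.site_depth is not None
            and self.depth_ref + self.depth_alt > self.site_depth
        ):
            raise ValueError("depth_ref + depth_alt exceeds site_depth")

    @property
    def is_carrier(self) -> bool:
        """A sample carries the variant iff its genotype has >= 1 alt allele."""
        return "1" in self.genotype


@dataclass
class AnnotatedVariant:
    """One alternate allele at one locus with all its annotations."""

    locus: Locus
    annotations: Sequence[TranscriptAnnotation]
    selected_annotation: int = 0
    population_af: Optional[float] = None
    clinvar_raw: Optional[str] = None
    clin_class: Optional[ClinSigClass] = None
    scores: ToolScorePanel = field(default_factory=ToolScorePanel)
    sample_calls: Mapping[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.annotations and not (
            0 <= self.selected_annotation < len(self.annotations)
        ):
            raise ValueError(
                f"selected_annotation {self.selected_annotation} out of range"
            )
        _check_unit(self.population_af, "population_af")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.locus.key

    @property
    def annotation(self) -> TranscriptAnnotation:
        """The representative transcript annotation."""
        if not self.annotations:
            raise ValueError("variant has no annotations")
        return self.annotations[self.selected_annotation]

    @property
    def gene_symbol(self) -> str:
        return self.annotation.gene_symbol

    def carriers(self) -> list[str]:
        return sorted(
            sid for sid, call in self.sample_calls.items() if call.is_carrier
        )


@dataclass(frozen=True)
class Sample:
    sample_id: str
    family_id: Optional[str] = None


@dataclass
class Cohort:
    """A set of samples and the annotated variants observed across them."""

    samples: Sequence[Sample]
    variants: list[AnnotatedVariant]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids must be unique")
        known = set(ids)
        for v in self.variants:
            stray = set(v.sample_calls) - known
            if stray:
                raise ValueError(
                    f"variant {v.key} has calls for unknown samples {sorted(stray)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __len__(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# Clinical-significance parsing
# ---------------------------------------------------------------------------

_PATHOGENIC_TERMS = {
    "pathogenic",
    "likely pathogenic",
    "pathogenic low penetrance",
    "likely pathogenic low penetrance",
    "p",
    "lp",
    "p/lp",
}
_BENIGN_TERMS = {"benign", "likely benign", "b", "lb", "b/lb"}
_VUS_TERMS = {"uncertain significance", "uncertain", "vus"}
_NEUTRAL_TERMS = {
    # ClinVar qualifiers that carry no pathogenicity assertion of their own
    "drug response",
    "risk factor",
    "association",
    "protective",
    "affects",
    "other",
    "not provided",
    "no classification for the single variant",
    "no classifications from unflagged records",
    "confers sensitivity",
    "low penetrance",
}
_UNKNOWN_TERMS = {"", "nr", "not reported", "unknown", "na", "."}

# Accept the cascade's own class labels so the mapping is idempotent.
_SELF_LABELS = {
    "class_45": ClinSigClass.CLASS_45,
    "class_3": ClinSigClass.CLASS_3,
    "class_3plus": ClinSigClass.CLASS_3PLUS,
    "class_2plus": ClinSigClass.CLASS_2PLUS,
    "class_12": ClinSigClass.CLASS_12,
    "ci": ClinSigClass.CLASS_3PLUS,
}

_CONFLICT_RE = re.compile(r"conflicting", re.IGNORECASE)
_PAREN_RE = re.compile(r"\(([^()]*)\)")


def _normalize_term(term: str) -> str:
    term = term.strip().lower().replace("_", " ")
    term = re.sub(r"\s+", " ", term)
    return term


def _split_terms(raw: str) -> list[str]:
    return [t for t in re.split(r"[|,;/&]", raw) if t.strip()]


def parse_clinsig(
    raw: Optional[str],
    asserted: Optional[Iterable[str]] = None,
) -> ClinSigClass:
    """Map a raw ClinVar clinical-significance string onto a stratification class.

    Parameters
    ----------
    raw
        The clinical-significance string as annotated (``CLNSIG``-style, e.g.
        ``"Pathogenic/Likely_pathogenic"`` or
        ``"Conflicting_interpretations_of_pathogenicity"``). ``None`` or an
        empty/unrecognized string maps to :attr:`ClinSigClass.UNKNOWN`.
    asserted
        Optional explicit set of individual submitted assertions
        (``CLNSIGCONF``-style) used to resolve conflicting records.  When
        absent, assertions embedded in parentheses inside ``raw`` are used;
        a conflicting record with no resolvable assertions defaults to
        ``CLASS_3PLUS`` (conflicts are recorded as "P/LP vs VUS" in this
        cohort's reporting convention).

    Notes
    -----
    The mapping is total: every input yields exactly one class, and unknown
    vocabulary logs a warning rather than raising.
    """
    if raw is None:
        return ClinSigClass.UNKNOWN
    # drop ClinVar submission-count qualifiers like "Benign(2)" early so they
    # neither pollute assertion extraction nor look like nested groups
    stripped = re.sub(r"\((\d+)\)", "", raw).strip()
    norm_whole = _normalize_term(stripped).replace(" ", "_")
    if norm_whole in _SELF_LABELS:
        return _SELF_LABELS[norm_whole]
    if _normalize_term(stripped) in _UNKNOWN_TERMS:
        return ClinSigClass.UNKNOWN

    is_conflicting = bool(_CONFLICT_RE.search(stripped))

    if asserted is not None:
        assertion_src: list[str] = list(asserted)
    else:
        assertion_src = []
        for group in _PAREN_RE.findall(stripped):
            assertion_src.extend(_split_terms(group))
    body = _PAREN_RE.sub("", stripped)
    terms = {_normalize_term(t) for t in _split_terms(body)}
    assertions = {_normalize_term(t) for t in assertion_src}

    def bucket(termset: set[str]) -> tuple[bool, bool, bool, set[str]]:
        has_p = bool(termset & _PATHOGENIC_TERMS)
        has_b = bool(termset & _BENIGN_TERMS)
        has_v = bool(termset & _VUS_TERMS)
        unknown = termset - (
            _PATHOGENIC_TERMS
            | _BENIGN_TERMS
            | _VUS_TERMS
            | _NEUTRAL_TERMS
            | _UNKNOWN_TERMS
            | {"conflicting interpretations of pathogenicity",
               "conflicting classifications of pathogenicity",
               "conflicting data from submitters"}
        )
        return has_p, has_b, has_v, unknown

    if is_conflicting:
        has_p, has_b, has_v, unknown = bucket(assertions or terms)
        if unknown:
            logger.warning("unrecognized clinical-significance terms %s in %r",
                           sorted(unknown), raw)
        if has_p:
            return ClinSigClass.CLASS_3PLUS
        if has_b or has_v:
            return ClinSigClass.CLASS_2PLUS
        # conflict with no resolvable assertions: treat as containing P/LP
        return ClinSigClass.CLASS_3PLUS

    has_p, has_b, has_v, unknown = bucket(terms)
    if unknown:
        logger.warning("unrecognized clinical-significance terms %s in %r",
                       sorted(unknown), raw)
    if has_p and (has_b or has_v):
        return ClinSigClass.CLASS_3PLUS
    if has_p:
        return ClinSigClass.CLASS_45
    if has_b and has_v:
        return ClinSigClass.CLASS_2PLUS
    if has_v:
        return ClinSigClass.CLASS_3
    if has_b:
        return ClinSigClass.CLASS_12
    return ClinSigClass.UNKNOWN


# ---------------------------------------------------------------------------
# Variant allele fraction
# ---------------------------------------------------------------------------


def compute_vaf(call: SampleCall, ndigits: int = 2) -> Optional[float]:
    """Variant allele fraction: ``depth_alt / (depth_ref + depth_alt)``.

    Returns ``None`` when either depth is missing or the informative depth is
    zero.  The result is rounded to ``ndigits`` decimals (display convention:
    two decimals, e.g. ref 35 / alt 3 -> 0.08).
    """
    if call.depth_ref is None or call.depth_alt is None:
        return None
    denom = call.depth_ref + call.depth_alt
    if denom == 0:
        return None
    return round(call.depth_alt / denom, ndigits)


# ---------------------------------------------------------------------------
# Representative-transcript selection
# ---------------------------------------------------------------------------

#: Consequence severity from most to least severe (condensed VEP ordering).
CONSEQUENCE_SEVERITY: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_donor_5th_base_variant",
    "splice_region_variant",
    "splice_donor_region_variant",
    "splice_polypyrimidine_tract_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)

_SEVERITY_RANK = {term: i for i, term in enumerate(CONSEQUENCE_SEVERITY)}


def _severity(ann: TranscriptAnnotation) -> int:
    return min(
        (_SEVERITY_RANK.get(t, len(CONSEQUENCE_SEVERITY)) for t in ann.consequence_terms),
        default=len(CONSEQUENCE_SEVERITY),
    )


def select_annotation(variant: AnnotatedVariant) -> int:
    """Index of the representative transcript annotation.

    Canonical transcripts win; among equals the most severe consequence wins;
    remaining ties break on lexicographically smallest transcript id, so the
    choice is deterministic and order-independent.
    """
    if not variant.annotations:
        raise ValueError("cannot select a transcript from an empty annotation list")
    indexed = list(enumerate(variant.annotations))
    indexed.sort(
        key=lambda ia: (not ia[1].is_canonical, _severity(ia[1]), ia[1].transcript_id)
    )
    return indexed[0][0]
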