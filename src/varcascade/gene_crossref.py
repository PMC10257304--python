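"""Cancer-gene cross-referencing, repeat-region exclusion and the
known-high-impact extraction.

The cascade's final variants are checked against externally curated
cancer-gene lists (e.g. a somatic-mutation census, an oncogene/TSG
knowledgebase and a literature-mined tumor-suppressor list).  Matching is
case-insensitive over symbols and aliases; when lists disagree on a gene's
role, a configurable source-priority order decides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .cohort_model import (
    AnnotatedVariant,
    ClinSigClass,
    CLASS_SEVERITY_RANK,
)
from .annotation_io import GeneListEntry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneMatch:
    gene_symbol: str
    sources: frozenset[str]
    role: str


@dataclass
class CrossRefResult:
    """Per-gene matches and per-variant membership flags."""

    genes: dict[str, GeneMatch]
    variant_flags: dict[tuple, dict]

    def matched_symbols(self) -> set[str]:
        return set(self.genes)

    def n_matched_variants(self) -> int:
        return sum(f["in_cancer_gene"] for f in self.variant_flags.values())


def crossref_genes(
    variants: Sequence[AnnotatedVariant],
    gene_lists: Mapping[str, Sequence[GeneListEntry]],
    source_priority: Optional[Sequence[str]] = None,
) -> CrossRefResult:
    """Match variant genes against one or more cancer-gene lists.

    ``gene_lists`` maps a source label to its entries.  A gene matches when
    its symbol (case-insensitive) equals a listed symbol or alias; the
    reported role comes from the highest-priority matching source
    (``source_priority`` defaults to the mapping's own order).
    """
    if not gene_lists or all(not entries for entries in gene_lists.values()):
        logger.warning("no gene-list entries loaded; nothing will match")
    priority = list(source_priority or gene_lists.keys())
    genes: dict[str, GeneMatch] = {}
    flags: dict[tuple, dict] = {}
    for v in variants:
        symbol = v.gene_symbol.upper()
        sources: set[str] = set()
        role_by_source: dict[str, str] = {}
        for source, entries in gene_lists.items():
            for entry in entries:
                if entry.matches(symbol):
                    sources.add(source)
                    role_by_source.setdefault(source, entry.role)
                    break
        matched = bool(sources)
        if matched and symbol not in genes:
            role = next(
                (role_by_source[s] for s in priority if s in role_by_source),
                next(iter(role_by_source.values())),
            )
            genes[symbol] = GeneMatch(symbol, frozenset(sources), role)
        flags[v.key] = {
            "gene_symbol": symbol,
            "in_cancer_gene": matched,
            "in_repeat_region": False,
            "in_high_impact_gene": False,
        }
    return CrossRefResult(genes=genes, variant_flags=flags)


# ---------------------------------------------------------------------------
# Repeat-region exclusion
# ---------------------------------------------------------------------------


def read_bed_intervals(path) -> dict[str, IntervalTree]:
    """Read a BED (3+ columns, 0-based half-open) into per-chromosome trees."""
    trees: dict[str, IntervalTree] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed BED coordinates") from exc
        if end <= start:
            raise ValueError(f"{path}:{lineno}: empty or inverted interval")
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def exclude_repeat_regions(
    variants: Sequence[AnnotatedVariant],
    repeat_bed: Optional[object] = None,
) -> list[AnnotatedVariant]:
    """Drop variants whose anchor position lies in a repeat interval.

    ``repeat_bed`` is a BED path or a pre-built ``{chrom: IntervalTree}``
    mapping; intervals are 0-based half-open, variant positions 1-based, so a
    variant at position ``p`` is excluded iff some interval contains ``p - 1``.
    For indels only the anchor (leftmost) position is tested.  With no BED the
    operation is the identity (with a warning).
    """
    if repeat_bed is None:
        logger.warning("no repeat-region BED supplied; exclusion skipped")
        return list(variants)
    trees = (
        repeat_bed if isinstance(repeat_bed, dict) else read_bed_intervals(repeat_bed)
    )
    kept = []
    for v in variants:
        tree = trees.get(v.locus.chrom)
        if tree is not None and tree.overlaps(v.locus.pos - 1):
            continue
        kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# Known high-impact genes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HighImpactSummary:
    n_genes: int
    n_variants: int
    n_patients: int


def extract_high_impact(
    variants: Sequence[AnnotatedVariant],
    high_impact_symbols: Iterable[str],
    min_class: ClinSigClass = ClinSigClass.CLASS_3,
    class_override: Optional[Mapping[tuple, ClinSigClass]] = None,
) -> tuple[list[AnnotatedVariant], HighImpactSummary]:
    """Subset of variants in named high-penetrance genes at or above a class.

    Class ordering for the threshold is CLASS_3 < CLASS_3PLUS < CLASS_45;
    classes outside that ordering (unknown / benign-side) never qualify.
    ``class_override`` substitutes a per-variant class (e.g. an expert
    ACMG-AMP assignment) for the ClinVar-derived one where provided.
    """
    symbols = {s.upper() for s in high_impact_symbols}
    seen = {v.gene_symbol.upper() for v in variants}
    for symbol in sorted(symbols - seen):
        logger.warning("high-impact symbol %s not present among variants", symbol)
    threshold = CLASS_SEVERITY_RANK[min_class]
    if threshold == 0:
        raise ValueError(f"min_class must be one of CLASS_3/CLASS_3PLUS/CLASS_45")
    subset = []
    patients: set[str] = set()
    genes: set[str] = set()
    for v in variants:
        symbol = v.gene_symbol.upper()
        if symbol not in symbols:
            continue
        clin_class = v.clin_class or ClinSigClass.UNKNOWN
        if class_override and v.key in class_override:
            clin_class = class_override[v.key]
        if CLASS_SEVERITY_RANK[clin_class] < threshold:
            continue
        subset.append(v)
        genes.add(symbol)
        patients.update(v.carriers())
    summary = HighImpactSummary(
        n_genes=len(genes), n_variants=len(subset), n_patients=len(patients)
    )
    return subset, summary
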