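"""Readers and writers for the formats the cascade touches.

Supported inputs are VEP-style annotated VCF (per-transcript CSQ strings with
dbNSFP-plugin score subfields), a flat annotated TSV with one row per
(sample, variant), plain-text cancer-gene lists, and BED repeat tracks (the
BED reader itself lives with the interval logic in :mod:`gene_crossref`).

A deliberate parsing contract throughout: a missing numeric field is kept as
*absent* (``None``), never silently converted to zero — the zero substitution
for population frequency is the stage-1 filter's business, not the parser's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .cohort_model import (
    AnnotatedVariant,
    ClinSigClass,
    Cohort,
    LofConfidence,
    Locus,
    Sample,
    SampleCall,
    ToolScorePanel,
    select_annotation,
    TranscriptAnnotation,
)
from .filter_cascade import DEFAULT_TOOL_SLOT_MAP

logger = logging.getLogger(__name__)


class AnnotationFormatError(ValueError):
    """Raised on fatally malformed annotation inputs."""


# ---------------------------------------------------------------------------
# CSQ field mapping
# ---------------------------------------------------------------------------


@dataclass
class CsqFieldMap:
    """Declared order of CSQ subfields, with name-based index lookup."""

    names: Sequence[str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise AnnotationFormatError("CSQ field names must be unique")
        self._index = {name: i for i, name in enumerate(self.names)}

    def get(self, entry: Sequence[str], name: str) -> Optional[str]:
        idx = self._index.get(name)
        if idx is None or idx >= len(entry):
            return None
        value = entry[idx].strip()
        return value if value not in {"", "."} else None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @classmethod
    def from_header(cls, header: pysam.VariantHeader, info_field: str = "CSQ"
                    ) -> "CsqFieldMap":
        rec = header.info.get(info_field)
        if rec is None:
            raise AnnotationFormatError(
                f"VCF header declares no {info_field} annotation field"
            )
        desc = rec.description or ""
        marker = "Format:"
        if marker not in desc:
            raise AnnotationFormatError(
                f"{info_field} header description lacks a 'Format:' declaration"
            )
        fmt = desc.split(marker, 1)[1].strip().strip('"')
        return cls(tuple(f.strip() for f in fmt.split("|")))


#: Default CSQ subfield names (VEP core fields + dbNSFP-plugin rank scores).
DEFAULT_FIELD_NAMES: Mapping[str, str] = {
    "allele": "Allele",
    "consequence": "Consequence",
    "symbol": "SYMBOL",
    "feature": "Feature",
    "hgvsc": "HGVSc",
    "hgvsp": "HGVSp",
    "canonical": "CANONICAL",
    "af": "gnomAD_AF",
    "clinsig": "ClinVar_CLNSIG",
    "lof": "LoF",
    "spliceai_ag": "SpliceAI_pred_DS_AG",
    "spliceai_al": "SpliceAI_pred_DS_AL",
    "spliceai_dg": "SpliceAI_pred_DS_DG",
    "spliceai_dl": "SpliceAI_pred_DS_DL",
    "REVEL": "REVEL_rankscore",
    "ClinPred": "ClinPred_rankscore",
    "VEST4": "VEST4_rankscore",
    "MetaSVM": "MetaSVM_rankscore",
    "BayesDel": "BayesDel_addAF_rankscore",
    "M-CAP": "M-CAP_rankscore",
    "CADD": "CADD_raw_rankscore",
}


def _merged_field_names(overrides: Optional[Mapping[str, str]]) -> dict[str, str]:
    names = dict(DEFAULT_FIELD_NAMES)
    if overrides:
        names.update(overrides)
    return names


def _float_or_none(value: Optional[str]) -> Optional[float]:
    if value is None:
        return None
    try:
        return float(value)
    except ValueError:
        return None


def _parse_lof(value: Optional[str]) -> LofConfidence:
    if value is None:
        return LofConfidence.ABSENT
    token = value.strip().upper()
    if token in {"HC", "HIGH_CONFIDENCE"}:
        return LofConfidence.HIGH_CONFIDENCE
    if token in {"LC", "LOW_CONFIDENCE"}:
        return LofConfidence.LOW_CONFIDENCE
    return LofConfidence.ABSENT


def _panel_from_getter(get, names: Mapping[str, str],
                       tool_slot_map: Mapping[str, str]) -> ToolScorePanel:
    """Build a score panel from a field-name -> value getter."""
    rank_scores: dict[str, float] = {}
    for slot, tool in tool_slot_map.items():
        score = _float_or_none(get(names.get(tool, tool)))
        if score is not None:
            rank_scores[slot] = score
    deltas = [
        _float_or_none(get(names[k]))
        for k in ("spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl")
    ]
    spliceai = None
    if any(d is not None for d in deltas):
        spliceai = tuple(d if d is not None else 0.0 for d in deltas)
    lof = _parse_lof(get(names["lof"]))
    return ToolScorePanel(rank_scores=rank_scores, spliceai_deltas=spliceai,
                          lof_confidence=lof)


# ---------------------------------------------------------------------------
# Annotated VCF reader
# ---------------------------------------------------------------------------


def _genotype_for_alt(gt: Optional[tuple], alt_index: int) -> tuple[str, str]:
    if gt is None:
        return (".", ".")
    alleles = []
    for a in (list(gt) + [None, None])[:2]:
        if a is None:
            alleles.append(".")
        elif a == alt_index:
            alleles.append("1")
        else:
            alleles.append("0")
    return tuple(alleles)


def read_annotated_vcf(
    path,
    field_map_overrides: Optional[Mapping[str, str]] = None,
    tool_slot_map: Optional[Mapping[str, str]] = None,
    info_field: str = "CSQ",
) -> Cohort:
    """Read a VEP-annotated multi-sample VCF into a :class:`Cohort`.

    Multi-allelic sites are decomposed into one :class:`AnnotatedVariant` per
    alternate allele; CSQ entries are matched to alleles via the CSQ allele
    subfield when it identifies the allele unambiguously, otherwise every
    entry is attached to every alternate allele of the site.  Only carrier
    genotype calls (>= 1 alt allele) are materialized; reference and missing
    genotypes stay implicit.
    """
    names = _merged_field_names(field_map_overrides)
    slots = dict(tool_slot_map or DEFAULT_TOOL_SLOT_MAP)
    with pysam.VariantFile(str(path)) as vcf:
        csq_map = CsqFieldMap.from_header(vcf.header, info_field)
        for required in ("symbol", "consequence", "feature"):
            if names[required] not in csq_map:
                raise AnnotationFormatError(
                    f"CSQ format lacks required field {names[required]!r}"
                )
        sample_ids = list(vcf.header.samples)
        samples = [Sample(sid) for sid in sample_ids]
        variants: list[AnnotatedVariant] = []
        for rec in vcf:
            variants.extend(
                _variants_from_record(rec, csq_map, names, slots, sample_ids,
                                      info_field)
            )
    return Cohort(samples=samples, variants=variants)


def _variants_from_record(rec, csq_map, names, slots, sample_ids, info_field):
    raw_csq = rec.info.get(info_field)
    if raw_csq is None:
        logger.warning("record %s:%s has no %s annotation; skipped",
                       rec.chrom, rec.pos, info_field)
        return
    entries = [str(e).split("|") for e in raw_csq]
    alts = [a for a in (rec.alts or ()) if a and a != "*"]
    for alt_index, alt in enumerate(alts, start=1):
        matched = [
            e for e in entries if csq_map.get(e, names["allele"]) == alt
        ]
        if not matched:
            matched = entries
        annotations = []
        for entry in matched:
            symbol = csq_map.get(entry, names["symbol"])
            feature = csq_map.get(entry, names["feature"])
            consequence = csq_map.get(entry, names["consequence"])
            if not feature or not consequence:
                logger.warning("malformed CSQ entry at %s:%s; entry skipped",
                               rec.chrom, rec.pos)
                continue
            annotations.append(
                TranscriptAnnotation(
                    gene_symbol=symbol or "",
                    transcript_id=feature,
                    consequence_terms=frozenset(consequence.split("&")),
                    hgvs_c=csq_map.get(entry, names["hgvsc"]),
                    hgvs_p=csq_map.get(entry, names["hgvsp"]),
                    is_canonical=csq_map.get(entry, names["canonical"]) == "YES",
                )
            )
        if not annotations:
            continue

        def info_get(field_name: str, _matched=matched) -> Optional[str]:
            for entry in _matched:
                value = csq_map.get(entry, field_name)
                if value is not None:
                    return value
            return None

        panel = _panel_from_getter(info_get, names, slots)
        calls: dict[str, SampleCall] = {}
        for sid in sample_ids:
            s = rec.samples[sid]
            gt = _genotype_for_alt(s.get("GT"), alt_index)
            if "1" not in gt:
                continue
            ad = s.get("AD")
            depth_ref = depth_alt = None
            if ad is not None and ad[0] is not None:
                depth_ref = ad[0]
                if len(ad) > alt_index and ad[alt_index] is not None:
                    depth_alt = ad[alt_index]
            calls[sid] = SampleCall(
                sample_id=sid,
                genotype=gt,
                depth_ref=depth_ref,
                depth_alt=depth_alt,
                site_depth=s.get("DP"),
            )
        variant = AnnotatedVariant(
            locus=Locus(rec.chrom, rec.pos, rec.ref, alt),
            annotations=annotations,
            population_af=_float_or_none(info_get(names["af"])),
            clinvar_raw=info_get(names["clinsig"]),
            scores=panel,
            sample_calls=calls,
        )
        variant.selected_annotation = select_annotation(variant)
        yield variant


# ---------------------------------------------------------------------------
# Annotated VCF writer (used by the synthetic cohort round-trip)
# ---------------------------------------------------------------------------

_CSQ_ORDER = (
    "allele", "consequence", "symbol", "feature", "hgvsc", "hgvsp",
    "canonical", "af", "clinsig",
    "REVEL", "ClinPred", "VEST4", "MetaSVM", "BayesDel", "M-CAP", "CADD",
    "spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl", "lof",
)


def write_annotated_vcf(
    cohort: Cohort,
    path,
    tool_slot_map: Optional[Mapping[str, str]] = None,
) -> None:
    """Write a cohort as a VEP-style annotated VCF (uncompressed text).

    The output is consumable by :func:`read_annotated_vcf` and round-trips
    every field the cohort model carries.
    """
    names = _merged_field_names(None)
    slots = dict(tool_slot_map or DEFAULT_TOOL_SLOT_MAP)
    tool_by_slot = dict(slots)
    csq_fields = [names[k] for k in _CSQ_ORDER]
    chroms = sorted({v.locus.chrom for v in cohort.variants})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in chroms],
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
        'annotations from Ensembl VEP. Format: ' + "|".join(csq_fields) + '">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    sample_ids = cohort.sample_ids
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                   "INFO", "FORMAT"] + sample_ids
    lines.append("\t".join(header_cols))
    for v in sorted(cohort.variants, key=lambda v: v.key):
        csq_entries = []
        for ann in v.annotations:
            values = {
                "allele": v.locus.alt,
                "consequence": "&".join(sorted(ann.consequence_terms)),
                "symbol": ann.gene_symbol,
                "feature": ann.transcript_id,
                "hgvsc": ann.hgvs_c or "",
                "hgvsp": ann.hgvs_p or "",
                "canonical": "YES" if ann.is_canonical else "",
                "af": "" if v.population_af is None else repr(v.population_af),
                "clinsig": v.clinvar_raw or "",
                "lof": (
                    "" if v.scores.lof_confidence is LofConfidence.ABSENT
                    else v.scores.lof_confidence.value
                ),
            }
            for slot, tool in tool_by_slot.items():
                score = v.scores.rank_scores.get(slot)
                values[tool] = "" if score is None else repr(score)
            deltas = v.scores.spliceai_deltas
            for i, key in enumerate(("spliceai_ag", "spliceai_al",
                                     "spliceai_dg", "spliceai_dl")):
                values[key] = "" if deltas is None else repr(deltas[i])
            # commas and pipes are structural inside CSQ: escape to VEP's
            # in-field separator so multi-assertion ClinVar strings survive
            csq_entries.append("|".join(
                str(values[k]).replace(",", "&").replace("|", "&")
                for k in _CSQ_ORDER
            ))
        sample_cols = []
        for sid in sample_ids:
            call = v.sample_calls.get(sid)
            if call is None:
                sample_cols.append("0/0:.:.")
                continue
            gt = "/".join(call.genotype)
            if call.depth_ref is None or call.depth_alt is None:
                ad = "."
            else:
                ad = f"{call.depth_ref},{call.depth_alt}"
            dp = "." if call.site_depth is None else str(call.site_depth)
            sample_cols.append(f"{gt}:{ad}:{dp}")
        row = [
            v.locus.chrom, str(v.locus.pos), ".", v.locus.ref, v.locus.alt,
            ".", "PASS", "CSQ=" + ",".join(csq_entries), "GT:AD:DP",
        ] + sample_cols
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Flat annotated TSV
# ---------------------------------------------------------------------------

_TSV_SYNONYMS = {
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "position"),
    "ref": ("ref",),
    "alt": ("alt",),
    "sample_id": ("sample_id", "sample", "id"),
    "family_id": ("family_id", "fid"),
    "gene": ("gene", "gene_symbol", "symbol"),
    "transcript": ("transcript", "transcript_id", "feature"),
    "consequence": ("consequence", "consequence_terms"),
    "hgvs_c": ("hgvs_c", "hgvsc", "cnomen"),
    "hgvs_p": ("hgvs_p", "hgvsp", "pnomen"),
    "canonical": ("canonical", "is_canonical"),
    "population_af": ("population_af", "af", "gnomad_af"),
    "clinvar": ("clinvar", "clinsig", "clin_class", "clinvar_clnsig"),
    "genotype": ("genotype", "gt"),
    "depth_ref": ("depth_ref",),
    "depth_alt": ("depth_alt",),
    "site_depth": ("site_depth", "dp", "depth"),
    "spliceai_ag": ("spliceai_ag",),
    "spliceai_al": ("spliceai_al",),
    "spliceai_dg": ("spliceai_dg",),
    "spliceai_dl": ("spliceai_dl",),
    "lof": ("lof", "lof_confidence", "loftee"),
}

_TSV_MANDATORY = ("chrom", "pos", "ref", "alt", "sample_id", "gene",
                  "transcript", "consequence")


def _resolve_columns(columns: Iterable[str]) -> dict[str, str]:
    lowered = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for canon, synonyms in _TSV_SYNONYMS.items():
        for syn in synonyms:
            if syn in lowered:
                resolved[canon] = lowered[syn]
                break
    return resolved


def _cell(row, col: Optional[str]) -> Optional[str]:
    if col is None:
        return None
    value = row.get(col)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text if text not in {"", ".", "nan"} else None


def read_annotated_tsv(
    path,
    tool_slot_map: Optional[Mapping[str, str]] = None,
) -> Cohort:
    """Read a flat annotated TSV (one row per sample x variant) into a Cohort.

    Column names are matched case-insensitively against documented synonyms;
    per-tool rank scores come from columns named after the tools themselves
    (``REVEL``, ``CADD``, ...).  Missing mandatory columns raise
    :class:`AnnotationFormatError` listing every missing name.
    """
    slots = dict(tool_slot_map or DEFAULT_TOOL_SLOT_MAP)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns)
    missing = [m for m in _TSV_MANDATORY if m not in cols]
    if missing:
        raise AnnotationFormatError(
            "annotated TSV is missing mandatory columns: " + ", ".join(missing)
        )
    tool_cols = {c.lower(): c for c in df.columns}

    samples: dict[str, Sample] = {}
    grouped: dict[tuple, dict] = {}
    for _, row in df.iterrows():
        sid = _cell(row, cols["sample_id"])
        if sid is None:
            raise AnnotationFormatError("row with empty sample_id")
        fid = _cell(row, cols.get("family_id"))
        if sid not in samples:
            samples[sid] = Sample(sid, fid)
        key = (
            _cell(row, cols["chrom"]),
            int(_cell(row, cols["pos"])),
            _cell(row, cols["ref"]),
            _cell(row, cols["alt"]),
        )
        entry = grouped.setdefault(key, {"rows": [], "calls": {}})
        entry["rows"].append(row)
        gt_text = _cell(row, cols.get("genotype")) or "0/1"
        genotype = tuple((gt_text.replace("|", "/").split("/") + ["."])[:2])

        def _int(name: str) -> Optional[int]:
            text = _cell(row, cols.get(name))
            return None if text is None else int(float(text))

        entry["calls"][sid] = SampleCall(
            sample_id=sid,
            genotype=genotype,
            depth_ref=_int("depth_ref"),
            depth_alt=_int("depth_alt"),
            site_depth=_int("site_depth"),
        )

    variants = []
    names = _merged_field_names(None)
    for key in sorted(grouped, key=lambda k: (k[0], k[1], k[2], k[3])):
        entry = grouped[key]
        row = entry["rows"][0]

        def row_get(field_name: str, _row=row) -> Optional[str]:
            # tool columns are named by tool, spliceai/lof by canonical name
            for canon, vep_name in names.items():
                if vep_name == field_name:
                    field_name = canon
                    break
            if field_name in cols:
                return _cell(_row, cols[field_name])
            return _cell(_row, tool_cols.get(field_name.lower()))

        panel = _panel_from_getter(row_get, names, slots)
        annotation = TranscriptAnnotation(
            gene_symbol=_cell(row, cols["gene"]) or "",
            transcript_id=_cell(row, cols["transcript"]) or "",
            consequence_terms=frozenset(
                (_cell(row, cols["consequence"]) or "").split("&")
            ),
            hgvs_c=_cell(row, cols.get("hgvs_c")),
            hgvs_p=_cell(row, cols.get("hgvs_p")),
            is_canonical=(_cell(row, cols.get("canonical")) or "") in
            {"YES", "True", "true", "1"},
        )
        af_text = _cell(row, cols.get("population_af"))
        variants.append(
            AnnotatedVariant(
                locus=Locus(*key),
                annotations=[annotation],
                population_af=None if af_text is None else float(af_text),
                clinvar_raw=_cell(row, cols.get("clinvar")),
                scores=panel,
                sample_calls=entry["calls"],
            )
        )
    return Cohort(samples=list(samples.values()), variants=variants)


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------


class GeneRole:
    ONCOGENE = "ONCOGENE"
    TSG = "TSG"
    FUSION = "FUSION"
    OTHER = "OTHER"


_ROLE_SYNONYMS = {
    "oncogene": GeneRole.ONCOGENE,
    "og": GeneRole.ONCOGENE,
    "tsg": GeneRole.TSG,
    "tumor suppressor": GeneRole.TSG,
    "tumour suppressor": GeneRole.TSG,
    "tumor suppressor gene": GeneRole.TSG,
    "fusion": GeneRole.FUSION,
    "fusion gene": GeneRole.FUSION,
    "other": GeneRole.OTHER,
}


@dataclass(frozen=True)
class GeneListEntry:
    gene_symbol: str
    role: str
    source: str
    aliases: frozenset[str] = frozenset()

    def matches(self, symbol: str) -> bool:
        symbol = symbol.upper()
        return symbol == self.gene_symbol or symbol in self.aliases


def read_gene_list(path, source_label: str) -> list[GeneListEntry]:
    """Read a cancer-gene list: TSV of symbol, role, optional aliases.

    Symbols and aliases are normalized to uppercase; a header line (first
    column named gene/symbol) is skipped; unknown role strings map to OTHER
    with a warning; a duplicated symbol with a conflicting role keeps the
    first role seen.
    """
    entries: dict[str, GeneListEntry] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        symbol = parts[0].strip().upper()
        if lineno == 1 and symbol in {"GENE", "SYMBOL", "GENE_SYMBOL"}:
            continue
        role_text = parts[1].strip().lower() if len(parts) > 1 else ""
        role = _ROLE_SYNONYMS.get(role_text)
        if role is None:
            logger.warning("%s line %d: unknown role %r mapped to OTHER",
                           path, lineno, role_text)
            role = GeneRole.OTHER
        aliases = frozenset(
            a.strip().upper()
            for a in (parts[2].replace(",", ";").split(";") if len(parts) > 2 else [])
            if a.strip()
        )
        if symbol in entries:
            if entries[symbol].role != role:
                logger.warning("%s line %d: conflicting role for %s; first wins",
                               path, lineno, symbol)
            continue
        entries[symbol] = GeneListEntry(symbol, role, source_label, aliases)
    return list(entries.values())


# ---------------------------------------------------------------------------
# Variant report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "transcript",
    "consequence", "hgvs_c", "hgvs_p", "clinvar", "clin_class",
    "carrier_count", "genotype", "depth_ref", "depth_alt", "site_depth",
)


def write_variant_report(cohort: Cohort, path,
                         variants: Optional[Sequence[AnnotatedVariant]] = None
                         ) -> pd.DataFrame:
    """Write the per-(sample, variant) report TSV.

    One row per carrier sample per variant, ordered by (sample_id, locus);
    ``carrier_count`` repeats the variant's total carrier count on every row.
    Writing the same cohort twice produces byte-identical files.  The output
    is re-readable by :func:`read_annotated_tsv`.
    """
    chosen = cohort.variants if variants is None else list(variants)
    rows = []
    for v in chosen:
        ann = v.annotation
        clin_class = v.clin_class
        n_carriers = len(v.carriers())
        for sid in v.carriers():
            call = v.sample_calls[sid]
            rows.append({
                "sample_id": sid,
                "chrom": v.locus.chrom,
                "pos": v.locus.pos,
                "ref": v.locus.ref,
                "alt": v.locus.alt,
                "gene": ann.gene_symbol,
                "transcript": ann.transcript_id,
                "consequence": "&".join(sorted(ann.consequence_terms)),
                "hgvs_c": v.annotation.hgvs_c or "",
                "hgvs_p": v.annotation.hgvs_p or "",
                "clinvar": v.clinvar_raw or "",
                "clin_class": clin_class.value if clin_class else "",
                "carrier_count": n_carriers,
                "genotype": "/".join(call.genotype),
                "depth_ref": "" if call.depth_ref is None else call.depth_ref,
                "depth_alt": "" if call.depth_alt is None else call.depth_alt,
                "site_depth": "" if call.site_depth is None else call.site_depth,
            })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["sample_id", "chrom", "pos", "ref", "alt"], kind="mergesort"
        ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return df
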