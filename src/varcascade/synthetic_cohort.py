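"""Synthetic annotated cohorts and the packaged printed-table fixtures.

The raw exome data behind the study cohort is not distributable, so the
cascade is exercised two ways:

* :func:`simulate_cohort` draws an annotated multi-sample cohort with the
  statistical structure the cascade assumes — a rare/common population-
  frequency mixture with a point mass of variants absent from the population
  database, a ClinVar class mixture matching the study's stage-2 breakdown,
  in-silico rank scores correlated with a latent pathogenicity label,
  splice-delta and loss-of-function annotations tied to consequence type, and
  per-sample genotypes including related pairs.  The latent truth travels in
  a side channel, never inside the cohort itself.

* :func:`load_fixture` loads verbatim transcriptions of the study's printed
  tables (cohort roster, stage-count grid, the 45-variant/32-sample listing,
  and the known high-impact genes), checksum-verified at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cohort_model import (
    AnnotatedVariant,
    ClinSigClass,
    Cohort,
    LofConfidence,
    Locus,
    Sample,
    SampleCall,
    ToolScorePanel,
    TranscriptAnnotation,
    TOOL_SLOTS,
)
from . import annotation_io

_CONSEQUENCE_TYPES = ("missense", "splice", "frameshift", "synonymous", "other")
_CONSEQUENCE_TERMS = {
    "missense": "missense_variant",
    "splice": "splice_acceptor_variant",
    "frameshift": "frameshift_variant",
    "synonymous": "synonymous_variant",
    "other": "intron_variant",
}

#: ClinVar strings emitted per simulated class (exercises the full parser).
_CLASS_STRINGS: Mapping[ClinSigClass, tuple[str, ...]] = {
    ClinSigClass.UNKNOWN: ("",),
    ClinSigClass.CLASS_45: ("Pathogenic", "Likely_pathogenic",
                            "Pathogenic/Likely_pathogenic"),
    ClinSigClass.CLASS_3: ("Uncertain_significance",),
    ClinSigClass.CLASS_12: ("Benign", "Likely_benign", "Benign/Likely_benign"),
    ClinSigClass.CLASS_3PLUS: (
        "Conflicting_interpretations_of_pathogenicity"
        "(Likely_pathogenic(1)&Uncertain_significance(3))",
    ),
    ClinSigClass.CLASS_2PLUS: (
        "Conflicting_interpretations_of_pathogenicity"
        "(Benign(2)&Uncertain_significance(1))",
    ),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study conditions: 48 samples of which 16 form 8
    related pairs; a stage-1 pass fraction near one fifth of all variants;
    a ClinVar class mixture matching the study's stage-2 breakdown; mean
    site depth 92x.
    """

    n_samples: int = 48
    n_families_paired: int = 8
    n_variants: int = 5000
    prop_absent_from_popdb: float = 0.10
    prop_rare_given_present: float = 0.15
    rare_beta: tuple[float, float] = (0.3, 800.0)
    common_beta: tuple[float, float] = (2.0, 8.0)
    class_mixture: Mapping[ClinSigClass, float] = field(
        default_factory=lambda: {
            ClinSigClass.UNKNOWN: 0.9078,
            ClinSigClass.CLASS_3: 0.0333,
            ClinSigClass.CLASS_3PLUS: 0.0018,
            ClinSigClass.CLASS_45: 0.0030,
            ClinSigClass.CLASS_12: 0.0391,
            ClinSigClass.CLASS_2PLUS: 0.0150,
        }
    )
    latent_pathogenic_rate: float = 0.05
    pathogenic_beta: tuple[float, float] = (8.0, 2.0)
    benign_beta: tuple[float, float] = (1.5, 6.0)
    tool_presence: float = 0.9
    consequence_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "missense": 0.40,
            "splice": 0.08,
            "frameshift": 0.07,
            "synonymous": 0.35,
            "other": 0.10,
        }
    )
    carrier_rate: float = 0.04
    family_share: float = 0.5
    lof_hc_prob: float = 0.9
    mean_depth: float = 92.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mixture, keys in (
            ("class_mixture", self.class_mixture, set(ClinSigClass)),
            ("consequence_mixture", self.consequence_mixture,
             set(_CONSEQUENCE_TYPES)),
        ):
            if set(mixture) != keys:
                raise ValueError(f"{name} must cover exactly {sorted(str(k) for k in keys)}")
            total = sum(mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")

    def replace(self, **changes) -> "SimConfig":
        return replace(self, **changes)


def _draw_deltas(rng: np.random.Generator, pathogenic: bool
                 ) -> tuple[float, float, float, float]:
    deltas = rng.beta(1.0, 15.0, size=4)
    if pathogenic:
        deltas[rng.integers(4)] = rng.beta(6.0, 1.5)
    return tuple(float(d) for d in np.clip(deltas, 0.0, 1.0))


def simulate_cohort(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Draw a synthetic annotated cohort plus its latent truth table.

    Deterministic given ``config.seed``: all randomness flows from a single
    generator with a fixed draw order.  The truth table records, per variant,
    the latent pathogenicity label and the simulated consequence type; it is
    returned separately so the cascade can never consume it by accident.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants

    samples = []
    for f in range(config.n_families_paired):
        fid = f"F.{f + 1}"
        samples.append(Sample(f"S.{2 * f + 1:02d}", fid))
        samples.append(Sample(f"S.{2 * f + 2:02d}", fid))
    for i in range(2 * config.n_families_paired, config.n_samples):
        samples.append(Sample(f"S.{i + 1:02d}"))
    samples = samples[: config.n_samples]
    sample_ids = [s.sample_id for s in samples]
    pair_index = [
        (2 * f, 2 * f + 1)
        for f in range(config.n_families_paired)
        if 2 * f + 1 < config.n_samples
    ]

    # -- vectorized per-variant draws (fixed order) -------------------------
    absent = rng.random(n) < config.prop_absent_from_popdb
    rare = rng.random(n) < config.prop_rare_given_present
    af_rare = rng.beta(*config.rare_beta, size=n)
    af_common = rng.beta(*config.common_beta, size=n)
    classes = rng.choice(
        [c for c in config.class_mixture],
        size=n,
        p=[config.class_mixture[c] for c in config.class_mixture],
    )
    pathogenic = rng.random(n) < config.latent_pathogenic_rate
    consequences = rng.choice(
        _CONSEQUENCE_TYPES,
        size=n,
        p=[config.consequence_mixture[c] for c in _CONSEQUENCE_TYPES],
    )

    variants: list[AnnotatedVariant] = []
    truth_rows = []
    bases = np.array(list("ACGT"))
    for i in range(n):
        chrom = f"chr{(i % 22) + 1}"
        pos = 1_000 + 50 * i + int(rng.integers(0, 40))
        ctype = str(consequences[i])
        ref_b, alt_b = rng.choice(bases, size=2, replace=False)
        if ctype == "frameshift":
            ref, alt = ref_b + alt_b, ref_b
        else:
            ref, alt = str(ref_b), str(alt_b)
        af = None
        if not absent[i]:
            af = float(np.clip(af_rare[i] if rare[i] else af_common[i], 1e-9, 1.0))

        clin_class = classes[i]
        options = _CLASS_STRINGS[clin_class]
        raw = options[int(rng.integers(len(options)))] or None

        is_path = bool(pathogenic[i])
        a, b = config.pathogenic_beta if is_path else config.benign_beta
        rank_scores: dict[str, float] = {}
        if ctype in {"missense", "frameshift"} or (
            ctype == "splice" and rng.random() < 0.3
        ):
            for slot in TOOL_SLOTS:
                if rng.random() < config.tool_presence:
                    rank_scores[slot] = float(np.clip(rng.beta(a, b), 0.0, 1.0))
        deltas = None
        if ctype == "splice" and rng.random() < 0.9:
            deltas = _draw_deltas(rng, is_path)
        lof = LofConfidence.ABSENT
        if ctype == "frameshift":
            if is_path:
                lof = (LofConfidence.HIGH_CONFIDENCE
                       if rng.random() < config.lof_hc_prob
                       else LofConfidence.LOW_CONFIDENCE)
            else:
                u = rng.random()
                lof = (LofConfidence.HIGH_CONFIDENCE if u < 0.05
                       else LofConfidence.LOW_CONFIDENCE if u < 0.65
                       else LofConfidence.ABSENT)

        carriers = rng.random(config.n_samples) < config.carrier_rate
        if not carriers.any():
            carriers[int(rng.integers(config.n_samples))] = True
        is_rare_variant = absent[i] or (af is not None and af < 0.001)
        for first, second in pair_index:
            if is_rare_variant and rng.random() < config.family_share:
                carriers[second] = carriers[first]
        calls: dict[str, SampleCall] = {}
        for idx in np.flatnonzero(carriers):
            sid = sample_ids[idx]
            site_depth = max(1, int(rng.poisson(config.mean_depth)))
            informative = site_depth - int(rng.binomial(site_depth, 0.02))
            hom = rng.random() < 0.05
            p_alt = 0.98 if hom else 0.5
            depth_alt = int(rng.binomial(informative, p_alt))
            calls[sid] = SampleCall(
                sample_id=sid,
                genotype=("1", "1") if hom else ("0", "1"),
                depth_ref=informative - depth_alt,
                depth_alt=depth_alt,
                site_depth=site_depth,
            )

        gene = f"G{(i % max(1, n // 3)):05d}"
        variants.append(
            AnnotatedVariant(
                locus=Locus(chrom, pos, ref, alt),
                annotations=[
                    TranscriptAnnotation(
                        gene_symbol=gene,
                        transcript_id=f"NM_{900000 + i}.1",
                        consequence_terms=frozenset({_CONSEQUENCE_TERMS[ctype]}),
                        is_canonical=True,
                    )
                ],
                population_af=af,
                clinvar_raw=raw,
                scores=ToolScorePanel(
                    rank_scores=rank_scores,
                    spliceai_deltas=deltas,
                    lof_confidence=lof,
                ),
                sample_calls=calls,
            )
        )
        truth_rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": gene, "consequence_type": ctype,
            "latent_pathogenic": is_path,
            "sim_class": clin_class.value,
        })
    cohort = Cohort(samples=samples, variants=variants)
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


def write_synthetic_vcf(
    cohort: Cohort, path, truth: Optional[pd.DataFrame] = None,
    truth_path=None,
) -> None:
    """Write a simulated cohort as annotated VCF (+ optional truth TSV).

    The VCF round-trips through :func:`annotation_io.read_annotated_vcf`;
    the truth labels go to a separate TSV so they can never leak into the
    annotation stream.
    """
    annotation_io.write_annotated_vcf(cohort, path)
    if truth is not None and truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Printed-table fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "table1": "table1_cohort.tsv",
    "table2": "table2_counts.tsv",
    "table3": "table3_variants.tsv",
    "table4": "table4_highimpact.tsv",
}


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture failed its checksum or an internal invariant."""


def _fixture_bytes(filename: str) -> bytes:
    return (resources.files("varcascade") / "fixtures" / filename).read_bytes()


def load_fixture(name: str, verify_checksum: bool = True) -> pd.DataFrame:
    """Load a packaged printed-table fixture as a typed DataFrame.

    ``name`` is one of ``table1`` (cohort roster), ``table2`` (stage-count
    grid), ``table3`` (45 variants x 32 samples), ``table4`` (high-impact
    genes).  Each load verifies the file's checksum against the packaged
    manifest and the table's internal invariants (e.g. table3 must contain
    exactly 45 distinct variants over 32 distinct samples).
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}")
    filename = _FIXTURE_FILES[name]
    raw = _fixture_bytes(filename)
    if verify_checksum:
        manifest = json.loads(_fixture_bytes("MANIFEST.json"))
        digest = hashlib.sha256(raw).hexdigest()
        if manifest.get(filename) != digest:
            raise FixtureIntegrityError(
                f"checksum mismatch for fixture {filename}: {digest}"
            )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", dtype=str, keep_default_na=False)
    _validate_fixture(name, df)
    if name == "table2":
        df["n_variants"] = df["n_variants"].astype(int)
        df["n_genes"] = pd.to_numeric(df["n_genes"], errors="coerce")
    if name == "table3":
        df["n_samples"] = df["n_samples"].astype(int)
    return df


def _validate_fixture(name: str, df: pd.DataFrame) -> None:
    if name == "table1":
        if len(df) != 48 or df["sample_id"].nunique() != 48:
            raise FixtureIntegrityError("table1 must list 48 distinct patients")
        families = df.loc[df["family_id"] != "", "family_id"]
        if families.nunique() != 8 or len(families) != 16:
            raise FixtureIntegrityError("table1 must hold 8 families of 2")
    elif name == "table2":
        if int(df.loc[df["stage"] == "calling", "n_variants"].iloc[0]) != 125686:
            raise FixtureIntegrityError("table2 input count corrupted")
    elif name == "table3":
        key = df["transcript"] + ":" + df["hgvs_c"]
        if key.nunique() != 45:
            raise FixtureIntegrityError(
                f"table3 must contain 45 distinct variants, found {key.nunique()}"
            )
        if df["sample_id"].nunique() != 32:
            raise FixtureIntegrityError("table3 must contain 32 distinct samples")
        counts = df.groupby(key)["sample_id"].nunique()
        declared = df.groupby(key)["n_samples"].first().astype(int)
        mismatched = counts[counts != declared]
        if len(mismatched):
            raise FixtureIntegrityError(
                f"table3 carrier counts disagree with rows: {list(mismatched.index)}"
            )
    elif name == "table4":
        key = df["transcript"] + ":" + df["hgvs_c"]
        if key.nunique() != 9 or df["gene"].nunique() != 7:
            raise FixtureIntegrityError("table4 must hold 9 variants in 7 genes")


def cohort_from_table3(
    table3: Optional[pd.DataFrame] = None,
    table1: Optional[pd.DataFrame] = None,
) -> Cohort:
    """Build an in-memory cohort from the 45-variant listing.

    The printed table identifies variants by transcript-level HGVS only, so
    synthetic placeholder loci (one per distinct variant, in sorted HGVS
    order) stand in for genomic coordinates; carrier genotypes are
    heterozygous and depths absent.  The sample roster comes from the cohort
    table so non-carrier samples are represented.
    """
    if table3 is None:
        table3 = load_fixture("table3")
    if table1 is None:
        table1 = load_fixture("table1")
    samples = [
        Sample(row.sample_id, row.family_id or None)
        for row in table1.itertuples()
    ]
    keys = sorted(set(zip(table3["transcript"], table3["hgvs_c"])))
    locus_by_key = {
        key: Locus("chrU", 1000 + i, "A", "C") for i, key in enumerate(keys)
    }
    variants: dict[tuple, AnnotatedVariant] = {}
    for row in table3.itertuples():
        key = (row.transcript, row.hgvs_c)
        if key not in variants:
            from .cohort_model import parse_clinsig

            variants[key] = AnnotatedVariant(
                locus=locus_by_key[key],
                annotations=[
                    TranscriptAnnotation(
                        gene_symbol=row.gene,
                        transcript_id=row.transcript,
                        consequence_terms=frozenset({"sequence_variant"}),
                        hgvs_c=row.hgvs_c,
                        hgvs_p=row.hgvs_p or None,
                        is_canonical=True,
                    )
                ],
                clinvar_raw=row.clinvar,
                clin_class=parse_clinsig(row.clinvar),
                sample_calls={},
            )
        v = variants[key]
        v.sample_calls = dict(v.sample_calls)
        v.sample_calls[row.sample_id] = SampleCall(
            sample_id=row.sample_id, genotype=("0", "1")
        )
    return Cohort(samples=samples, variants=list(variants.values()))


_ACMG_TO_CLASS = {
    "Class 5": ClinSigClass.CLASS_45,
    "Class 4": ClinSigClass.CLASS_45,
    "Class 3": ClinSigClass.CLASS_3,
}


def acmg_overrides(
    cohort: Cohort, table4: Optional[pd.DataFrame] = None
) -> dict[tuple, ClinSigClass]:
    """Per-variant expert ACMG-AMP classes from the high-impact table.

    Keys are the cohort's variant keys; only variants present in the
    high-impact table receive an override.
    """
    if table4 is None:
        table4 = load_fixture("table4")
    by_hgvs = {
        (row.transcript, row.hgvs_c): _ACMG_TO_CLASS[row.acmg_class]
        for row in table4.itertuples()
    }
    overrides: dict[tuple, ClinSigClass] = {}
    for v in cohort.variants:
        ann = v.annotation
        key = (ann.transcript_id, ann.hgvs_c)
        if key in by_hgvs:
            overrides[v.key] = by_hgvs[key]
    return overrides
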