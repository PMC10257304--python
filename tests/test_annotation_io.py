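"""Reader/writer tests: CSQ parsing, decomposition, TSV and report
round-trips, gene lists."""

import pytest

from varcascade.annotation_io import (
    AnnotationFormatError,
    GeneRole,
    read_annotated_tsv,
    read_annotated_vcf,
    read_gene_list,
    write_annotated_vcf,
    write_variant_report,
)
from varcascade.cohort_model import ClinSigClass
from varcascade.filter_cascade import run_cascade
from varcascade.synthetic_cohort import SimConfig, simulate_cohort

CSQ_FORMAT = "Allele|Consequence|SYMBOL|Feature|HGVSc|HGVSp|CANONICAL|gnomAD_AF|ClinVar_CLNSIG|REVEL_rankscore|CADD_raw_rankscore"

VCF_HEADER = f"""##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: {CSQ_FORMAT}">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS.01\tS.02
"""


def _write_vcf(tmp_path, body, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


def test_vcf_field_passthrough_and_absence(tmp_path):
    body = (
        "chr1\t100\t.\tA\tG\t.\tPASS\t"
        "CSQ=G|missense_variant|MLH1|NM_000249.4|c.1G>A|p.?|YES|0.0005|Pathogenic|0.9|0.8"
        "\tGT:AD:DP\t0/1:30,10:42\t0/0:40,0:41\n"
        "chr1\t200\t.\tC\tT\t.\tPASS\t"
        "CSQ=T|synonymous_variant|MSH2|NM_000251.3|||||||"
        "\tGT:AD:DP\t0/1:20,20:41\t./.:.:.\n"
    )
    cohort = read_annotated_vcf(_write_vcf(tmp_path, body))
    assert len(cohort.variants) == 2
    first, second = sorted(cohort.variants, key=lambda v: v.key)
    assert first.population_af == 0.0005
    assert first.clinvar_raw == "Pathogenic"
    assert first.scores.rank_scores == {"T1": 0.9, "T7": 0.8}
    # absence stays absent, never zero
    assert second.population_af is None
    assert second.clinvar_raw is None
    assert second.scores.rank_scores == {}
    # only carriers materialized
    assert list(first.sample_calls) == ["S.01"]
    call = first.sample_calls["S.01"]
    assert (call.depth_ref, call.depth_alt, call.site_depth) == (30, 10, 42)


def test_vcf_multiallelic_decomposition(tmp_path):
    body = (
        "chr1\t300\t.\tA\tG,T\t.\tPASS\t"
        "CSQ=G|missense_variant|BRCA2|NM_000059.4|||YES|0.0001||0.5|,"
        "T|stop_gained|BRCA2|NM_000059.4|||YES|0.0002||0.7|"
        "\tGT:AD:DP\t1/2:5,10,20:36\t0/1:30,5,0:36\n"
    )
    cohort = read_annotated_vcf(_write_vcf(tmp_path, body))
    assert len(cohort.variants) == 2
    by_alt = {v.locus.alt: v for v in cohort.variants}
    assert set(by_alt) == {"G", "T"}
    assert by_alt["G"].locus.pos == by_alt["T"].locus.pos == 300
    assert by_alt["G"].population_af == 0.0001
    assert by_alt["T"].population_af == 0.0002
    # S.01 is het for both alts, S.02 only for the first
    assert set(by_alt["G"].sample_calls) == {"S.01", "S.02"}
    assert set(by_alt["T"].sample_calls) == {"S.01"}
    assert by_alt["T"].sample_calls["S.01"].depth_alt == 20


def test_vcf_missing_annotation_header_fatal(tmp_path):
    path = tmp_path / "noinfo.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    with pytest.raises(AnnotationFormatError):
        read_annotated_vcf(path)


def test_vcf_writer_round_trips_simulated_cohort(tmp_path):
    cohort, _ = simulate_cohort(SimConfig(seed=5, n_variants=150))
    path = tmp_path / "sim.vcf"
    write_annotated_vcf(cohort, path)
    back = read_annotated_vcf(path)
    assert len(back.variants) == len(cohort.variants)
    orig = {v.key: v for v in cohort.variants}
    for v in back.variants:
        o = orig[v.key]
        assert v.population_af == o.population_af
        assert v.clinvar_raw == o.clinvar_raw
        assert v.scores == o.scores
        assert v.sample_calls == o.sample_calls
        assert v.annotation == o.annotation


def test_vcf_and_tsv_readers_agree_on_paired_fixtures(tmp_path):
    """The same three variants encoded as VCF and as flat TSV parse to
    cohorts with identical keys, frequencies, classes and scores."""
    body = (
        "chr1\t100\t.\tA\tG\t.\tPASS\t"
        "CSQ=G|missense_variant|MLH1|NM_000249.4|c.1G>A||YES|0.0005|Pathogenic|0.9|0.8"
        "\tGT:AD:DP\t0/1:30,10:42\t0/0:.:.\n"
    )
    vcf_cohort = read_annotated_vcf(_write_vcf(tmp_path, body))
    tsv = tmp_path / "paired.tsv"
    tsv.write_text(
        "chrom\tpos\tref\talt\tsample_id\tgene\ttranscript\tconsequence\t"
        "hgvs_c\tcanonical\tpopulation_af\tclinvar\tgenotype\tdepth_ref\t"
        "depth_alt\tsite_depth\tREVEL\tCADD\n"
        "chr1\t100\tA\tG\tS.01\tMLH1\tNM_000249.4\tmissense_variant\t"
        "c.1G>A\tYES\t0.0005\tPathogenic\t0/1\t30\t10\t42\t0.9\t0.8\n"
    )
    tsv_cohort = read_annotated_tsv(tsv)
    v1, v2 = vcf_cohort.variants[0], tsv_cohort.variants[0]
    assert v1.key == v2.key
    assert v1.population_af == v2.population_af
    assert v1.clinvar_raw == v2.clinvar_raw
    assert v1.scores == v2.scores
    assert v1.sample_calls == v2.sample_calls
    assert v1.annotation.gene_symbol == v2.annotation.gene_symbol


def test_tsv_missing_mandatory_columns(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("chrom\tpos\n")
    with pytest.raises(AnnotationFormatError, match="ref"):
        read_annotated_tsv(path)


def test_tsv_empty_with_header_gives_empty_cohort(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text(
        "chrom\tpos\tref\talt\tsample_id\tgene\ttranscript\tconsequence\n"
    )
    cohort = read_annotated_tsv(path)
    assert len(cohort.variants) == 0 and len(cohort.samples) == 0


def test_tsv_dot_means_absent_score(tmp_path):
    path = tmp_path / "dot.tsv"
    path.write_text(
        "chrom\tpos\tref\talt\tsample_id\tgene\ttranscript\tconsequence\tREVEL\n"
        "chr1\t10\tA\tG\tS.01\tG1\tNM_1.1\tmissense_variant\t.\n"
    )
    cohort = read_annotated_tsv(path)
    assert cohort.variants[0].scores.rank_scores == {}


# ---------------------------------------------------------------------------
# variant report round-trip
# ---------------------------------------------------------------------------


def test_report_round_trip_preserves_keys_classes_and_carriers(tmp_path):
    cohort, _ = simulate_cohort(SimConfig(seed=9, n_variants=300))
    run_cascade(cohort)  # assigns clin_class
    path = tmp_path / "report.tsv"
    write_variant_report(cohort, path)
    back = read_annotated_tsv(path)
    orig = {v.key: v for v in cohort.variants if v.carriers()}
    assert {v.key for v in back.variants} == set(orig)
    from varcascade.cohort_model import parse_clinsig

    for v in back.variants:
        o = orig[v.key]
        assert parse_clinsig(v.clinvar_raw) == parse_clinsig(o.clinvar_raw)
        if o.clin_class is not None:  # stage-1 failures are never stratified
            assert parse_clinsig(v.clinvar_raw) == o.clin_class
        assert v.carriers() == o.carriers()


def test_report_written_twice_is_byte_identical(tmp_path):
    cohort, _ = simulate_cohort(SimConfig(seed=9, n_variants=100))
    p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
    write_variant_report(cohort, p1)
    write_variant_report(cohort, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_report_empty_result_is_header_only(tmp_path):
    cohort, _ = simulate_cohort(SimConfig(seed=9, n_variants=50))
    path = tmp_path / "empty_report.tsv"
    write_variant_report(cohort, path, variants=[])
    lines = path.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("sample_id\t")


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------


def test_read_gene_list(tmp_path):
    path = tmp_path / "genes.tsv"
    path.write_text(
        "gene\trole\taliases\n"
        "MLH1\tTSG\n"
        "pms2\ttsg\tPMSL2;PMS2CL\n"
        "PABPC1\toncogene\n"
        "WEIRD\tsomething_odd\n"
        "MLH1\toncogene\n"  # conflicting duplicate: first wins
    )
    entries = {e.gene_symbol: e for e in read_gene_list(path, "listA")}
    assert entries["MLH1"].role == GeneRole.TSG
    assert entries["PMS2"].aliases == {"PMSL2", "PMS2CL"}
    assert entries["PMS2"].matches("pmsl2")
    assert entries["PABPC1"].role == GeneRole.ONCOGENE
    assert entries["WEIRD"].role == GeneRole.OTHER
    assert len(entries) == 4
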