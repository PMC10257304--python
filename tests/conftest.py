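import pytest

from varcascade.cohort_model import (
    AnnotatedVariant,
    Cohort,
    LofConfidence,
    Locus,
    Sample,
    SampleCall,
    ToolScorePanel,
    TranscriptAnnotation,
)
from varcascade.synthetic_cohort import SimConfig, cohort_from_table3, simulate_cohort


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    gene="GENE1",
    transcript="NM_000001.1",
    consequence="missense_variant",
    af=None,
    clinvar=None,
    rank_scores=None,
    spliceai=None,
    lof=LofConfidence.ABSENT,
    carriers=(),
    canonical=True,
):
    """Construct a single-transcript variant with carrier-only calls."""
    calls = {
        sid: SampleCall(sample_id=sid, genotype=("0", "1")) for sid in carriers
    }
    return AnnotatedVariant(
        locus=Locus(chrom, pos, ref, alt),
        annotations=[
            TranscriptAnnotation(
                gene_symbol=gene,
                transcript_id=transcript,
                consequence_terms=frozenset(consequence.split("&")),
                is_canonical=canonical,
            )
        ],
        population_af=af,
        clinvar_raw=clinvar,
        scores=ToolScorePanel(
            rank_scores=rank_scores or {},
            spliceai_deltas=spliceai,
            lof_confidence=lof,
        ),
        sample_calls=calls,
    )


def make_cohort(variants, sample_ids=("S.01", "S.02", "S.03")):
    return Cohort(samples=[Sample(s) for s in sample_ids], variants=list(variants))


@pytest.fixture(scope="session")
def table3_cohort():
    return cohort_from_table3()


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-sized deterministic synthetic cohort shared across tests."""
    cohort, truth = simulate_cohort(SimConfig(seed=11, n_variants=1500))
    return cohort, truth
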