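import pytest

from amefreq import (
    AncestryPanel,
    AnnotationScores,
    ClinvarClass,
    Consequence,
    VariantRecord,
    load_fixture,
    table2_records,
)


@pytest.fixture(scope="session")
def panel() -> AncestryPanel:
    return load_fixture("panel")


@pytest.fixture(scope="session")
def table1(panel):
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2_frame():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table2(panel):
    return table2_records()


def make_variant(
    protein="p.Ala100Val",
    cdna="c.300C>T",
    consequence=Consequence.MISSENSE,
    clinvar=ClinvarClass.NOT_REPORTED,
    literature=False,
    ac=1,
    by_group=None,
    **scores,
) -> VariantRecord:
    """Terse factory for toy variants in tests."""
    return VariantRecord(
        gene="GENE1",
        protein_change=protein,
        cdna_change=cdna,
        consequence=consequence,
        clinvar_class=clinvar,
        literature_reported=literature,
        allele_count_total=ac,
        allele_counts_by_group=by_group or {},
        scores=AnnotationScores(**scores),
    )
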