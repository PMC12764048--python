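"""Three-arm qualification: truth tables, boundary directions, and a
brute-force oracle over randomly generated variants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amefreq import (
    AnnotationScores,
    ClinvarClass,
    Consequence,
    QualificationConfig,
    Tier,
    VariantQualifier,
    VariantRecord,
    assign_tier,
    clinvar_arm,
    in_silico_arm,
    literature_arm,
    qualification_summary,
    qualify_variants,
    tier_subset,
)
from amefreq.schema import BLB_CLASSES, PLP_CLASSES

from conftest import make_variant

DEFAULT = QualificationConfig()


class TestArms:
    @pytest.mark.parametrize(
        "clinvar, expected",
        [
            (ClinvarClass.P, True),
            (ClinvarClass.LP, True),
            (ClinvarClass.P_LP, True),
            (ClinvarClass.VUS, False),
            (ClinvarClass.CONFLICTING, False),
            (ClinvarClass.B_LB, False),
            (ClinvarClass.NOT_REPORTED, False),
        ],
    )
    def test_clinvar_arm(self, clinvar, expected):
        assert clinvar_arm(make_variant(clinvar=clinvar)) is expected

    @pytest.mark.parametrize(
        "clinvar, literature, expected",
        [
            (ClinvarClass.VUS, True, True),  # literature rescues a VUS
            (ClinvarClass.CONFLICTING, True, True),
            (ClinvarClass.P, False, False),  # qualifies via ClinVar, not here
            (ClinvarClass.LB, True, False),  # benign veto
            (ClinvarClass.B_LB, True, False),
        ],
    )
    def test_literature_arm(self, clinvar, literature, expected):
        v = make_variant(clinvar=clinvar, literature=literature)
        assert literature_arm(v) is expected

    def test_truncating_variants_pass_with_no_scores(self):
        for cons in (Consequence.NONSENSE, Consequence.FRAMESHIFT):
            assert in_silico_arm(make_variant(consequence=cons)) is True

    def test_missense_requires_all_four_scores(self):
        passing = dict(cadd=25, sift=0.01, polyphen2=0.95, revel=0.80)
        assert in_silico_arm(make_variant(**passing)) is True
        for dropped in passing:
            partial = {k: v for k, v in passing.items() if k != dropped}
            assert in_silico_arm(make_variant(**partial)) is False

    def test_other_consequence_never_qualifies(self):
        v = make_variant(consequence=Consequence.OTHER, cadd=35.0)
        assert in_silico_arm(v) is False


class TestBoundaries:
    """Every threshold's inequality direction, pinned at the boundary."""

    @pytest.mark.parametrize(
        "scores, expected",
        [
            # CADD strictly greater than 20
            (dict(cadd=20.0, sift=0.01, polyphen2=0.95, revel=0.8), False),
            (dict(cadd=20.01, sift=0.01, polyphen2=0.95, revel=0.8), True),
            # SIFT strictly less than 0.05
            (dict(cadd=25, sift=0.05, polyphen2=0.95, revel=0.8), False),
            (dict(cadd=25, sift=0.049, polyphen2=0.95, revel=0.8), True),
            # PolyPhen2 strictly greater than 0.85
            (dict(cadd=25, sift=0.01, polyphen2=0.85, revel=0.8), False),
            # REVEL strictly greater than 0.75
            (dict(cadd=25, sift=0.01, polyphen2=0.95, revel=0.75), False),
        ],
    )
    def test_missense_thresholds(self, scores, expected):
        assert in_silico_arm(make_variant(**scores)) is expected

    @pytest.mark.parametrize(
        "spliceai, cadd, pangolin, expected",
        [
            (0.8, 22, -0.3, True),  # SpliceAI boundary is inclusive
            (0.79, 22, -0.3, False),
            (0.9, 20.0, -0.3, False),  # CADD strict
            (0.9, 22, 0.2, False),  # |pangolin| strict
            (0.9, 22, -0.21, True),  # sign ignored via absolute value
        ],
    )
    def test_splice_thresholds(self, spliceai, cadd, pangolin, expected):
        v = make_variant(
            protein=None,
            cdna="c.10-1G>A",
            consequence=Consequence.SPLICE_SITE,
            spliceai=spliceai,
            cadd=cadd,
            pangolin=pangolin,
        )
        assert in_silico_arm(v) is expected

    @pytest.mark.parametrize(
        "cadd, damaging, expected",
        [(25.0, True, True), (20.0, True, False), (25.0, False, False), (25.0, None, False)],
    )
    def test_indel_thresholds(self, cadd, damaging, expected):
        v = make_variant(
            protein="p.Ala7del",
            consequence=Consequence.INFRAME_INDEL,
            cadd=cadd,
            sift_indel_damaging=damaging,
        )
        assert in_silico_arm(v) is expected


class TestTiers:
    def test_clinvar_or_literature_is_strict(self):
        assert assign_tier(make_variant(clinvar=ClinvarClass.P)).tier is Tier.STRICT
        assert (
            assign_tier(make_variant(clinvar=ClinvarClass.VUS, literature=True)).tier
            is Tier.STRICT
        )

    def test_in_silico_only_is_liberal_only(self):
        v = make_variant(cadd=25, sift=0.01, polyphen2=0.95, revel=0.9)
        assert assign_tier(v).tier is Tier.LIBERAL_ONLY

    def test_blb_exclusion_dominates(self):
        v = make_variant(clinvar=ClinvarClass.LB, cadd=30, sift=0.0, polyphen2=1.0, revel=1.0)
        r = assign_tier(v)
        assert r.excluded_blb and r.tier is Tier.NONE
        # the literal reading (exclusion only via the literature arm) is switchable
        r2 = assign_tier(v, QualificationConfig(exclude_blb=False))
        assert r2.tier is Tier.LIBERAL_ONLY

    def test_summary_of_toy_set(self):
        toys = [
            make_variant(clinvar=ClinvarClass.P_LP),
            make_variant(cadd=25, sift=0.01, polyphen2=0.95, revel=0.9),
            make_variant(clinvar=ClinvarClass.B_LB),
        ]
        s = qualification_summary(qualify_variants(toys))
        assert (s["clinvar_plp"], s["literature"], s["in_silico"]) == (1, 0, 1)
        assert (s["strict"], s["liberal_only"], s["none"]) == (1, 1, 1)
        assert s["qualifying"] == 2

    def test_summary_empty(self):
        s = qualification_summary([])
        assert s["qualifying"] == 0 and s["n_variants"] == 0

    def test_curated_reference_table_is_all_strict(self, table1):
        s = qualification_summary(qualify_variants(table1))
        assert s["strict"] == 32
        assert s["clinvar_plp"] == 15
        assert s["literature"] == 29


# ---------------------------------------------------------------------------
# randomized oracle + monotonicity properties

_consequences = st.sampled_from(list(Consequence))
_clinvar = st.sampled_from(list(ClinvarClass))
_optional_unit = st.one_of(st.none(), st.floats(0, 1))
_variants = st.builds(
    lambda cons, clin, lit, cadd, sift, pp2, revel, sai, pang, dmg: VariantRecord(
        gene="G",
        protein_change="p.Ala2Val",
        cdna_change=None,
        consequence=cons,
        clinvar_class=clin,
        literature_reported=lit,
        allele_count_total=1,
        scores=AnnotationScores(
            cadd=cadd, sift=sift, polyphen2=pp2, revel=revel,
            spliceai=sai, pangolin=pang, sift_indel_damaging=dmg,
        ),
    ),
    _consequences,
    _clinvar,
    st.booleans(),
    st.one_of(st.none(), st.floats(0, 50)),
    _optional_unit,
    _optional_unit,
    _optional_unit,
    _optional_unit,
    st.one_of(st.none(), st.floats(-1, 1)),
    st.one_of(st.none(), st.booleans()),
)


def _oracle_tier(v: VariantRecord, cfg: QualificationConfig) -> Tier:
    """The qualification rule written as one literal boolean expression."""
    s = v.scores
    blb = v.clinvar_class in BLB_CLASSES
    strict = (v.clinvar_class in PLP_CLASSES) or (v.literature_reported and not blb)
    insil = (
        v.consequence in (Consequence.NONSENSE, Consequence.FRAMESHIFT)
        or (
            v.consequence is Consequence.INFRAME_INDEL
            and s.cadd is not None and s.cadd > cfg.cadd_min
            and s.sift_indel_damaging is True
        )
        or (
            v.consequence is Consequence.SPLICE_SITE
            and s.spliceai is not None and s.spliceai >= cfg.spliceai_min
            and s.cadd is not None and s.cadd > cfg.cadd_min
            and s.pangolin is not None and abs(s.pangolin) > cfg.pangolin_abs_min
        )
        or (
            v.consequence is Consequence.MISSENSE
            and s.cadd is not None and s.cadd > cfg.cadd_min
            and s.sift is not None and s.sift < cfg.sift_max
            and s.polyphen2 is not None and s.polyphen2 > cfg.polyphen2_min
            and s.revel is not None and s.revel > cfg.revel_min
        )
    )
    if cfg.exclude_blb and blb:
        return Tier.NONE
    if strict:
        return Tier.STRICT
    if insil:
        return Tier.LIBERAL_ONLY
    return Tier.NONE


@settings(max_examples=300, derandomize=True)
@given(_variants)
def test_assign_tier_matches_brute_force_oracle(v):
    assert assign_tier(v, DEFAULT).tier is _oracle_tier(v, DEFAULT)


@settings(max_examples=200, derandomize=True)
@given(st.lists(_variants, max_size=20))
def test_strict_set_is_subset_of_liberal_set(vs):
    results = qualify_variants(vs)
    strict = {id(v) for v in tier_subset(vs, results, "strict")}
    liberal = {id(v) for v in tier_subset(vs, results, "liberal")}
    assert strict <= liberal


@settings(max_examples=200, derandomize=True)
@given(
    _variants,
    st.floats(0, 50),
    st.floats(0, 1),
    st.floats(0, 1),
    st.floats(0, 1),
    st.floats(0, 1),
    st.floats(0, 1),
)
def test_raising_thresholds_never_adds_variants(v, cadd, sift, pp2, revel, sai, pang):
    """The in-silico arm is anti-monotone in the thresholds: any tightening
    can only remove variants."""
    base = DEFAULT
    tightened = QualificationConfig(
        cadd_min=max(base.cadd_min, cadd),
        sift_max=min(base.sift_max, sift),
        polyphen2_min=max(base.polyphen2_min, pp2),
        revel_min=max(base.revel_min, revel),
        spliceai_min=max(base.spliceai_min, sai),
        pangolin_abs_min=max(base.pangolin_abs_min, pang),
    )
    if in_silico_arm(v, tightened):
        assert in_silico_arm(v, base)


def test_transformer_interface_and_params(table1):
    q = VariantQualifier(revel_min=0.9)
    frame = q.fit(table1).transform(table1)
    assert list(frame["tier"]).count("strict") == 32
    assert q.get_params()["revel_min"] == 0.9
    q.set_params(revel_min=0.5)
    assert q._config().revel_min == 0.5
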