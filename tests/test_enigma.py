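"""ENIGMA VCEP engine rules: gene-specific code usage and weighting."""

import pytest

from brcaclass.config import DEFAULT_CONFIG
from brcaclass.enigma import (
    assess_bp1,
    assess_bp5_enigma,
    assess_computational_enigma,
    assess_cosegregation,
    assess_functional,
    assess_multifactorial,
    assess_pm2_enigma,
    assess_pm5_ptc,
    assess_pvs1,
    classify_enigma,
)
from brcaclass.model import (
    AnnotationBundle,
    Classification,
    CodeOutcome,
    Consequence,
    Cooccurrence,
    Framework,
    Gene,
    Strength,
    VariantRecord,
    Verdict,
)
from brcaclass.points import classify, parse_token, EvidenceAssignment, total_points
from brcaclass.resources import GeneResourceTables, load_resource_tables
from brcaclass.simulate import SYNTHETIC_DOMAINS

CFG = DEFAULT_CONFIG.enigma


def _record(consequence=Consequence.missense, gene=Gene.BRCA2, hgvs_c="c.100A>G", **ann):
    return VariantRecord(
        variant_id="v1",
        gene=gene,
        hgvs_c=hgvs_c,
        consequence=consequence,
        annotations=AnnotationBundle(**ann),
    )


# -- BP1 (missense outside clinically important domains, strong) -------------


def test_bp1_fires_strong_for_missense_outside_domains():
    a = assess_bp1(Consequence.missense, False, 0.02, CFG)
    assert a.token == "BP1_STR"


@pytest.mark.parametrize(
    "consequence, in_domain, spliceai",
    [
        (Consequence.missense, True, 0.02),  # inside a domain
        (Consequence.nonsense, False, 0.02),  # not a missense code
        (Consequence.missense, None, 0.02),  # domain membership unknown
        (Consequence.missense, False, 0.35),  # splicing flagged instead
    ],
)
def test_bp1_withheld(consequence, in_domain, spliceai):
    assert assess_bp1(consequence, in_domain, spliceai, CFG) is None


def test_bp1_applies_when_spliceai_unknown():
    assert assess_bp1(Consequence.missense, False, None, CFG) is not None


# -- PM2 (absent from both gnomAD noncancer sets) -----------------------------


@pytest.mark.parametrize(
    "ac2, ac3, fires",
    [(0, 0, True), (1, 0, False), (0, 1, False), (5, 0, False)],
)
def test_pm2_requires_absence_from_both_sets(ac2, ac3, fires):
    a = assess_pm2_enigma(ac2, ac3)
    assert (a is not None) is fires


def test_pm2_negative_counts_rejected():
    with pytest.raises(ValueError):
        assess_pm2_enigma(-1, 0)


# -- computational evidence (SpliceAI / BayesDel) -----------------------------


@pytest.mark.parametrize(
    "consequence, in_domain, bayesdel, spliceai, token",
    [
        # missense inside a domain, benign BayesDel, SpliceAI uninformative
        (Consequence.missense, True, 0.10, 0.15, "BP4_SUP"),
        # missense inside a domain, pathogenic BayesDel
        (Consequence.missense, True, 0.50, 0.02, "PP3_SUP"),
        # missense outside domains, SpliceAI flagging -> splicing PP3
        (Consequence.missense, False, 0.05, 0.32, "PP3_SUP"),
        # intronic with negative SpliceAI -> BP4
        (Consequence.intronic, None, None, 0.02, "BP4_SUP"),
        # missense outside domains, negative SpliceAI: BayesDel not permitted
        (Consequence.missense, False, 0.05, 0.02, None),
        # in-domain BayesDel in the uninformative gap
        (Consequence.missense, True, 0.20, 0.02, None),
    ],
)
def test_computational_code_selection(consequence, in_domain, bayesdel, spliceai, token):
    a = assess_computational_enigma(consequence, in_domain, bayesdel, spliceai, CFG)
    assert (a.token if a else None) == token


def test_splicing_pp3_takes_precedence_over_in_domain_bayesdel():
    a = assess_computational_enigma(Consequence.missense, True, 0.10, 0.40, CFG)
    assert a.token == "PP3_SUP"
    assert "SpliceAI" in a.rationale


def test_benign_bayesdel_never_exceeds_supporting():
    for band in CFG.bayesdel_bands:
        if band.code.startswith("B"):
            assert band.strength is Strength.SUP


# -- functional assays (PS3/BS3) ----------------------------------------------


@pytest.fixture()
def assay_tables(tmp_path):
    (tmp_path / "assay_verdicts.tsv").write_text(
        "gene\thgvs_c\tverdict\tcode\tstrength\n"
        "BRCA1\tc.10A>G\trefutes_damaging\tBS3\tSTR\n"
        "BRCA1\tc.20A>G\tsupports_damaging\tPS3\tSUP\n"
        "BRCA2\tc.30A>G\tsupports_damaging\tPS3\tSTR\n"
        "BRCA2\tc.40A>G\trefutes_damaging\tBS3\tSUP\n"
        "BRCA2\tc.50A>G\trefutes_damaging\tno_code\t.\n"
    )
    return load_resource_tables(tmp_path)


@pytest.mark.parametrize(
    "gene, hgvs, token",
    [
        (Gene.BRCA1, "c.10A>G", "BS3_STR"),
        (Gene.BRCA1, "c.20A>G", "PS3_SUP"),
        (Gene.BRCA2, "c.30A>G", "PS3_STR"),
        (Gene.BRCA2, "c.40A>G", "BS3_SUP"),
        (Gene.BRCA2, "c.50A>G", None),  # reviewed but no code assigned
        (Gene.BRCA2, "c.99A>G", None),  # no table entry
    ],
)
def test_functional_assay_lookup(assay_tables, gene, hgvs, token):
    a = assess_functional(gene, hgvs, assay_tables)
    assert (a.token if a else None) == token


def test_conflicting_assay_rows_rejected_at_load(tmp_path):
    (tmp_path / "assay_verdicts.tsv").write_text(
        "gene\thgvs_c\tverdict\tcode\tstrength\n"
        "BRCA1\tc.10A>G\trefutes_damaging\tBS3\tSTR\n"
        "BRCA1\tc.10A>G\tsupports_damaging\tPS3\tSUP\n"
    )
    with pytest.raises(ValueError, match="conflicting"):
        load_resource_tables(tmp_path)


# -- multifactorial combined LR (PP4/BP5) and cosegregation (PP1/BS4) ---------


@pytest.mark.parametrize(
    "lr, token",
    [
        (0.001, "BP5_VSTR"),
        (0.01, "BP5_STR"),
        (0.1, "BP5_MOD"),
        (0.3, "BP5_SUP"),
        (1.0, None),  # uninformative center
        (3.0, "PP4_SUP"),
        (10.0, "PP4_MOD"),
        (100.0, "PP4_STR"),
        (400.0, "PP4_VSTR"),
    ],
)
def test_multifactorial_lr_bands(lr, token):
    a = assess_multifactorial(lr, CFG)
    assert (a.token if a else None) == token


def test_multifactorial_nonpositive_lr_rejected():
    with pytest.raises(ValueError):
        assess_multifactorial(0.0, CFG)


@pytest.mark.parametrize(
    "lr, token",
    [(30.0, "PP1_STR"), (1.0, None), (0.1, "BS4_MOD"), (0.001, "BS4_VSTR")],
)
def test_cosegregation_lr_bands(lr, token):
    a = assess_cosegregation(lr, CFG)
    assert (a.token if a else None) == token


# -- PM5_PTC exon weights and PVS1 decision-tree outcomes ---------------------


@pytest.fixture(scope="module")
def mini_tables():
    t = GeneResourceTables()
    t.exon_weights[(Gene.BRCA1, 2)] = CodeOutcome("PM5", Strength.SUP)
    t.exon_weights[(Gene.BRCA1, 24)] = CodeOutcome(None)
    t.pvs1_outcomes[(Gene.BRCA1, Consequence.splice_site_1_2, "5")] = CodeOutcome(
        "PVS1", Strength.STR
    )
    t.pvs1_outcomes[(Gene.BRCA2, Consequence.exon_deletion, "3")] = CodeOutcome(None)
    return t


@pytest.mark.parametrize(
    "consequence, exon, token",
    [
        (Consequence.nonsense, 2, "PM5_SUP"),
        (Consequence.frameshift, 24, None),  # exon weighted "no code"
        (Consequence.missense, 2, None),  # not a PTC
        (Consequence.nonsense, 99, None),  # exon absent from the table
    ],
)
def test_pm5_ptc_exon_weights(mini_tables, consequence, exon, token):
    a = assess_pm5_ptc(Gene.BRCA1, consequence, exon, mini_tables)
    assert (a.token if a else None) == token


@pytest.mark.parametrize(
    "gene, consequence, site, token",
    [
        (Gene.BRCA1, Consequence.splice_site_1_2, "5", "PVS1_STR"),
        (Gene.BRCA2, Consequence.exon_deletion, "3", None),  # explicit no-code row
        (Gene.BRCA1, Consequence.missense, "5", None),  # ineligible consequence
        (Gene.BRCA1, Consequence.splice_site_1_2, "99", None),  # no table row
    ],
)
def test_pvs1_outcome_lookup(mini_tables, gene, consequence, site, token):
    a = assess_pvs1(gene, consequence, site, mini_tables)
    assert (a.token if a else None) == token


# -- observation-based BP5 policy ---------------------------------------------


def test_bp5_withheld_for_the_pathogenic_pair_scenario():
    assert assess_bp5_enigma(Cooccurrence.with_pathogenic_same_gene_pair, CFG) is None
    assert assess_bp5_enigma(Cooccurrence.none, CFG) is None
    assert assess_bp5_enigma(Cooccurrence.other, CFG) is None  # default policy


def test_bp5_policy_variants():
    from dataclasses import replace

    allow = replace(CFG, bp5_cooccurrence_policy="allow")
    assert assess_bp5_enigma(
        Cooccurrence.with_pathogenic_same_gene_pair, allow
    ).token == "BP5_SUP"

    pair_only = replace(CFG, bp5_cooccurrence_policy="withhold_pair")
    assert assess_bp5_enigma(Cooccurrence.with_pathogenic_same_gene_pair, pair_only) is None
    assert assess_bp5_enigma(Cooccurrence.other, pair_only).token == "BP5_SUP"

    with pytest.raises(ValueError, match="bp5_cooccurrence_policy"):
        replace(CFG, bp5_cooccurrence_policy="sometimes")


# -- full engine ---------------------------------------------------------------


def test_missense_outside_domains_absent_from_gnomad_is_minus_three_lb():
    record = _record(
        in_clinically_important_domain=False,
        ac_noncancer_v2=0,
        ac_noncancer_v3=0,
        spliceai_max=0.02,
    )
    report = classify_enigma(record)
    assert set(report.tokens) == {"BP1_STR", "PM2_SUP"}
    assert report.total_points == -3
    assert report.classification is Classification.LB


def test_missense_outside_domains_in_gnomad_is_minus_four_lb():
    record = _record(
        in_clinically_important_domain=False,
        ac_noncancer_v2=7,
        ac_noncancer_v3=4,
        spliceai_max=0.02,
    )
    report = classify_enigma(record)
    assert report.tokens == ("BP1_STR",)
    assert report.total_points == -4
    assert report.classification is Classification.LB


def test_intronic_negative_spliceai_alone_stays_vus():
    record = _record(
        consequence=Consequence.intronic,
        hgvs_c="c.100+5T>C",
        ac_noncancer_v2=9,
        ac_noncancer_v3=5,
        spliceai_max=0.02,
    )
    report = classify_enigma(record)
    assert report.tokens == ("BP4_SUP",)
    assert report.total_points == -1
    assert report.classification is Classification.VUS


def test_missense_domain_branch_dichotomy():
    """With only consequence and domain membership known, the class is LB via
    BP1_STR outside domains and VUS inside (both branches, exhaustively)."""
    outside = classify_enigma(_record(in_clinically_important_domain=False))
    inside = classify_enigma(_record(in_clinically_important_domain=True))
    assert outside.tokens == ("BP1_STR",)
    assert outside.classification is Classification.LB
    assert inside.tokens == ()
    assert inside.classification is Classification.VUS


def test_domain_membership_derived_from_interval_table():
    tables = GeneResourceTables(domains=dict(SYNTHETIC_DOMAINS))
    dbd = SYNTHETIC_DOMAINS[Gene.BRCA2][0]
    inside = _record(hgvs_c=f"c.{dbd.c_start + 3}A>G")
    outside = _record(hgvs_c="c.100A>G")
    assert classify_enigma(inside, tables).tokens == ()
    assert classify_enigma(outside, tables).tokens == ("BP1_STR",)


def test_direct_domain_annotation_wins_over_table_and_is_logged():
    tables = GeneResourceTables(domains=dict(SYNTHETIC_DOMAINS))
    record = _record(hgvs_c="c.100A>G", in_clinically_important_domain=True)
    report = classify_enigma(record, tables)
    assert report.tokens == ()  # direct in-domain annotation suppresses BP1
    assert any("conflicts" in msg for msg in report.not_evaluated)


def test_bp1_and_in_domain_bayesdel_are_mutually_exclusive(default_cohort, default_tables):
    records, _ = default_cohort
    for record in records:
        report = classify_enigma(record, default_tables)
        in_domain_bp4 = any(
            a.code == "BP4" and "BayesDel" in a.rationale for a in report.assignments
        )
        assert not ("BP1" in report.codes and in_domain_bp4)


def test_single_supporting_benign_code_diverges_between_frameworks():
    """Any lone supporting-strength benign code is LB under the standard
    boundaries but VUS under ENIGMA (threshold divergence)."""
    for code in ("BP1", "BP4", "BP5", "BP7"):
        a = EvidenceAssignment(code=code, strength=Strength.SUP, framework=Framework.enigma)
        pts = total_points([a])
        assert pts == -1
        assert classify(pts, Framework.standard) is Classification.LB
        assert classify(pts, Framework.enigma) is Classification.VUS
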