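"""Standard ACMG/AMP + SVI engine rules and their boundaries."""

import pytest

from brcaclass.config import DEFAULT_CONFIG
from brcaclass.model import (
    AnnotationBundle,
    Classification,
    Consequence,
    Cooccurrence,
    Gene,
    VariantRecord,
)
from brcaclass.standard import (
    assess_bp4_splice_standard,
    assess_bp5_standard,
    assess_bp7_standard,
    assess_computational_standard,
    assess_pm2_standard,
    assess_ps4_standard,
    classify_standard,
)

CFG = DEFAULT_CONFIG.standard


def _record(consequence=Consequence.missense, gene=Gene.BRCA2, **ann):
    return VariantRecord(
        variant_id="v1",
        gene=gene,
        hgvs_c="c.100A>G",
        consequence=consequence,
        annotations=AnnotationBundle(**ann),
    )


# -- PM2 (rarity, gnomAD noncancer v2.1.1 allele-count ceiling) --------------


@pytest.mark.parametrize("ac, fires", [(0, True), (3, True), (5, True), (6, False), (50, False)])
def test_pm2_allele_count_ceiling(ac, fires):
    a = assess_pm2_standard(ac, CFG)
    assert (a is not None) is fires
    if fires:
        assert a.token == "PM2_SUP"


def test_pm2_unknown_count_yields_no_code():
    assert assess_pm2_standard(None, CFG) is None


def test_pm2_negative_count_rejected():
    with pytest.raises(ValueError):
        assess_pm2_standard(-1, CFG)


def test_pm2_is_monotone_nonincreasing_in_allele_count():
    fired = [assess_pm2_standard(ac, CFG) is not None for ac in range(0, 20)]
    # once the code stops firing it never fires again at higher counts
    assert fired == sorted(fired, reverse=True)


# -- PS4 (proband counting) --------------------------------------------------


@pytest.mark.parametrize(
    "probands, too_frequent, fires",
    [(5, False, True), (4, False, False), (12, True, False), (0, False, False)],
)
def test_ps4_proband_counting_and_population_disqualifier(probands, too_frequent, fires):
    a = assess_ps4_standard(probands, too_frequent, CFG)
    assert (a is not None) is fires
    if fires:
        assert a.token == "PS4_SUP"


# -- PP3/BP4 via the REVEL interval table ------------------------------------


@pytest.mark.parametrize(
    "revel, token",
    [
        (0.95, "PP3_STR"),
        (0.80, "PP3_MOD"),
        (0.70, "PP3_SUP"),
        (0.45, None),  # uninformative band midpoint
        (0.25, "BP4_SUP"),
        (0.10, "BP4_MOD"),
        (0.01, "BP4_STR"),
        (0.001, "BP4_VSTR"),
    ],
)
def test_revel_interval_table(revel, token):
    a = assess_computational_standard(Consequence.missense, revel, CFG)
    assert (a.token if a else None) == token


def test_revel_applies_only_to_missense():
    assert assess_computational_standard(Consequence.intronic, 0.01, CFG) is None


def test_revel_out_of_range_rejected():
    with pytest.raises(ValueError):
        assess_computational_standard(Consequence.missense, 1.5, CFG)


# -- BP7 / BP4 for synonymous-intronic variants without splice impact --------


@pytest.mark.parametrize(
    "consequence, spliceai, flag, bp7, bp4",
    [
        (Consequence.intronic, 0.02, None, True, True),
        (Consequence.intronic, None, True, True, True),
        (Consequence.synonymous, 0.05, None, True, True),
        (Consequence.missense, 0.02, None, False, False),
        (Consequence.intronic, 0.5, None, False, False),  # splice impact predicted
    ],
)
def test_splice_negative_gate_for_bp7_and_bp4(consequence, spliceai, flag, bp7, bp4):
    a7 = assess_bp7_standard(consequence, spliceai, flag, CFG)
    a4 = assess_bp4_splice_standard(consequence, spliceai, flag, CFG)
    assert (a7 is not None) is bp7
    assert (a4 is not None) is bp4


# -- BP5 (in-trans pathogenic observation) -----------------------------------


@pytest.mark.parametrize(
    "obs, fires",
    [
        (Cooccurrence.with_pathogenic_same_gene_pair, True),
        (Cooccurrence.other, True),
        (Cooccurrence.none, False),
    ],
)
def test_bp5_in_trans_observation(obs, fires):
    a = assess_bp5_standard(obs)
    assert (a is not None) is fires


# -- full engine --------------------------------------------------------------


def test_benign_moderate_missense_prediction_reaches_likely_benign():
    record = _record(revel=0.10, ac_noncancer_v2=8, proband_count=0)
    report = classify_standard(record)
    assert report.tokens == ("BP4_MOD",)
    assert report.total_points == -2
    assert report.classification is Classification.LB


def test_no_known_annotations_is_vus_with_not_evaluated_log():
    report = classify_standard(_record())
    assert report.total_points == 0
    assert report.classification is Classification.VUS
    assert any("PM2" in msg for msg in report.not_evaluated)
    assert any("REVEL" in msg for msg in report.not_evaluated)


def test_single_supporting_benign_observation_is_likely_benign():
    record = _record(
        revel=0.45,
        ac_noncancer_v2=8,
        proband_count=0,
        cooccurrence=Cooccurrence.with_pathogenic_same_gene_pair,
    )
    report = classify_standard(record)
    assert report.tokens == ("BP5_SUP",)
    assert report.total_points == -1
    assert report.classification is Classification.LB


def test_rule_errors_carry_the_variant_id():
    record = _record()
    record.annotations.revel = 2.0  # bypasses bundle validation on purpose
    with pytest.raises(ValueError, match="v1"):
        classify_standard(record)


def test_engine_alphabet_excludes_gene_specific_codes(default_cohort):
    """The standard arm never emits the ENIGMA-only codes."""
    records, _ = default_cohort
    allowed = {"PM2", "PS4", "PP3", "BP4", "BP7", "BP5"}
    forbidden = {"PVS1", "PM5", "BP1", "PP4", "PP1", "BS4", "PS3", "BS3"}
    seen = set()
    for record in records:
        seen |= set(classify_standard(record).codes)
    assert seen <= allowed
    assert not (seen & forbidden)


def test_removing_one_annotation_never_flips_remaining_assignments():
    """Rules are independent: dropping one annotation only removes its code."""
    record = _record(
        revel=0.10,
        ac_noncancer_v2=0,
        proband_count=7,
        cooccurrence=Cooccurrence.other,
    )
    full = {a.code: a.direction for a in classify_standard(record).assignments}
    for drop in ("revel", "ac_noncancer_v2", "proband_count"):
        reduced = _record(
            **{
                k: v
                for k, v in dict(
                    revel=0.10, ac_noncancer_v2=0, proband_count=7,
                    cooccurrence=Cooccurrence.other,
                ).items()
                if k != drop
            }
        )
        for a in classify_standard(reduced).assignments:
            assert full[a.code] == a.direction
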