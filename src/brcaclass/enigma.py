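"""ENIGMA BRCA1/BRCA2 VCEP rule engine (the t3 reanalysis arm).

Gene-specific specification of the ACMG/AMP codes for BRCA1/BRCA2:

- BP1 at *strong* strength for missense variants outside the (potentially)
  clinically important domains, provided splicing is not predicted affected —
  the single code behind most of the benign reclassification, since -4 points
  alone reaches likely benign;
- PM2 at supporting strength only for variants absent from *both* gnomAD
  noncancer data sets (v2.1.1 and v3.1.2);
- computational evidence split by mechanism: SpliceAI cutoffs for splicing
  (PP3/BP4), BayesDel cutoffs for missense variants *inside* domains with the
  benign arm capped at supporting; at most one computational code, splicing
  PP3 taking precedence;
- PS3/BS3 from reviewed functional-assay verdicts, PM5_PTC by exon-specific
  weights, PVS1 decision-tree outcomes, PP4/BP5 from multifactorial combined
  likelihood-ratio bands, PP1/BS4 from cosegregation likelihood-ratio bands;
- no BP7, and no proband-counting PS4;
- observation-based BP5 withheld for the BRCA1 + BRCA2 pathogenic pair
  scenario (combined-LR-based BP5 is unaffected).
"""

from __future__ import annotations

from typing import Optional

from .config import DEFAULT_CONFIG, EnigmaEngineConfig, band_lookup
from .model import (
    CodeOutcome,
    Consequence,
    Cooccurrence,
    FunctionalEvidence,
    Framework,
    Gene,
    PTC_CONSEQUENCES,
    PVS1_ELIGIBLE,
    Strength,
    VariantRecord,
    Verdict,
)
from .points import ClassificationReport, EvidenceAssignment, PointScale, build_report
from .resources import GeneResourceTables

_FW = Framework.enigma

_SPLICE_BP4_CONSEQUENCES = frozenset({Consequence.synonymous, Consequence.intronic})


def _assign(code: str, strength: Strength, rationale: str) -> EvidenceAssignment:
    return EvidenceAssignment(code=code, strength=strength, framework=_FW, rationale=rationale)


def assess_bp1(
    consequence: Consequence,
    in_clinically_important_domain: Optional[bool],
    spliceai_max: Optional[float],
    config: EnigmaEngineConfig,
) -> Optional[EvidenceAssignment]:
    """BP1_STR for missense variants outside every clinically important domain.

    Withheld when SpliceAI flags a predicted splice impact: a missense change
    whose effect may be on splicing is not covered by the
    missense-outside-domain argument.
    """
    if consequence is not Consequence.missense:
        return None
    if in_clinically_important_domain is None:
        return None
    if spliceai_max is not None and spliceai_max >= config.spliceai_pp3_min:
        return None
    if not in_clinically_important_domain:
        return _assign(
            "BP1", Strength.STR, "missense outside clinically important domains"
        )
    return None


def assess_pm2_enigma(
    ac_noncancer_v2: Optional[int], ac_noncancer_v3: Optional[int]
) -> Optional[EvidenceAssignment]:
    """PM2_SUP only for variants absent from both gnomAD noncancer data sets."""
    if ac_noncancer_v2 is None or ac_noncancer_v3 is None:
        return None
    if ac_noncancer_v2 < 0 or ac_noncancer_v3 < 0:
        raise ValueError("allele counts must be non-negative")
    if ac_noncancer_v2 == 0 and ac_noncancer_v3 == 0:
        return _assign(
            "PM2", Strength.SUP, "absent from gnomAD noncancer v2.1.1 and v3.1.2"
        )
    return None


def assess_computational_enigma(
    consequence: Consequence,
    in_clinically_important_domain: Optional[bool],
    bayesdel: Optional[float],
    spliceai_max: Optional[float],
    config: EnigmaEngineConfig,
) -> Optional[EvidenceAssignment]:
    """At most one computational code: splicing PP3, in-domain BayesDel
    PP3/BP4 (benign capped at supporting), or splice-negative BP4 for
    synonymous/intronic variants.

    Missense variants outside domains receive no BayesDel code — evaluation
    with the missense predictor is not permitted there; BP1 carries the
    benign argument instead.
    """
    if spliceai_max is not None and not (0.0 <= spliceai_max <= 1.0):
        raise ValueError(f"SpliceAI score must lie in [0, 1], got {spliceai_max}")

    splice_flagged = (
        spliceai_max is not None
        and spliceai_max >= config.spliceai_pp3_min
        and config.splice_pp3_precedence
    )
    if splice_flagged:
        return _assign(
            "PP3", Strength.SUP, f"SpliceAI={spliceai_max:g} predicts splice impact"
        )

    if consequence is Consequence.missense and in_clinically_important_domain:
        if bayesdel is not None:
            hit = band_lookup(bayesdel, config.bayesdel_bands)
            if hit is not None:
                code, strength = hit
                return _assign(
                    code, strength, f"BayesDel={bayesdel:g} in configured {code} interval"
                )
        return None

    if consequence in _SPLICE_BP4_CONSEQUENCES and spliceai_max is not None:
        if spliceai_max <= config.spliceai_bp4_max:
            return _assign(
                "BP4", Strength.SUP, f"SpliceAI={spliceai_max:g} negative splice prediction"
            )
    return None


def assess_functional(
    gene: Gene,
    hgvs_c: str,
    tables: GeneResourceTables,
    direct: Optional[FunctionalEvidence] = None,
) -> Optional[EvidenceAssignment]:
    """PS3/BS3 with the reviewed-assay table's strength; a direct annotation
    on the record wins over the table."""
    if direct is not None:
        code = "PS3" if direct.verdict is Verdict.supports_damaging else "BS3"
        return _assign(code, direct.strength, f"functional assay {direct.verdict.value}")
    entry = tables.assay_verdicts.get((gene, hgvs_c))
    if entry is None:
        return None
    verdict, outcome = entry
    if outcome.code is None:
        return None
    return _assign(
        outcome.code, outcome.strength, f"reviewed functional assay {verdict.value}"
    )


def assess_multifactorial(
    multifactorial_lr: Optional[float], config: EnigmaEngineConfig
) -> Optional[EvidenceAssignment]:
    """PP4 (LR in pathogenic bands) or BP5 (benign bands) at band strength."""
    if multifactorial_lr is None:
        return None
    if multifactorial_lr <= 0:
        raise ValueError(f"combined LR must be > 0, got {multifactorial_lr}")
    hit = band_lookup(multifactorial_lr, config.lr_bands_pp4_bp5)
    if hit is None:
        return None
    code, strength = hit
    return _assign(code, strength, f"combined multifactorial LR={multifactorial_lr:g}")


def assess_cosegregation(
    cosegregation_lr: Optional[float], config: EnigmaEngineConfig
) -> Optional[EvidenceAssignment]:
    """PP1 (cosegregation confirmed) or BS4 (lack of cosegregation) by LR band."""
    if cosegregation_lr is None:
        return None
    if cosegregation_lr <= 0:
        raise ValueError(f"cosegregation LR must be > 0, got {cosegregation_lr}")
    hit = band_lookup(cosegregation_lr, config.lr_bands_pp1_bs4)
    if hit is None:
        return None
    code, strength = hit
    return _assign(code, strength, f"cosegregation LR={cosegregation_lr:g}")


def assess_pm5_ptc(
    gene: Gene,
    consequence: Consequence,
    exon: Optional[int],
    tables: GeneResourceTables,
    direct: Optional[CodeOutcome] = None,
) -> Optional[EvidenceAssignment]:
    """PM5 for premature-termination-codon variants at the exon's weight."""
    if consequence not in PTC_CONSEQUENCES:
        return None
    outcome = direct
    if outcome is None and exon is not None:
        outcome = tables.exon_weights.get((gene, exon))
    if outcome is None or outcome.code is None:
        return None
    return _assign("PM5", outcome.strength, f"PTC in exon {exon}, exon-specific weight")


def assess_pvs1(
    gene: Gene,
    consequence: Consequence,
    site: Optional[str],
    tables: GeneResourceTables,
    direct: Optional[CodeOutcome] = None,
) -> Optional[EvidenceAssignment]:
    """Code + strength exactly as the PVS1 decision-tree outcome table gives
    (possibly a downgraded PVS1, or no code at all)."""
    if consequence not in PVS1_ELIGIBLE:
        return None
    outcome = direct
    if outcome is None and site is not None:
        outcome = tables.pvs1_outcomes.get((gene, consequence, site))
    if outcome is None or outcome.code is None:
        return None
    return _assign(
        outcome.code, outcome.strength, f"PVS1 decision tree ({consequence.value}, site {site})"
    )


def assess_bp5_enigma(
    cooccurrence: Cooccurrence, config: EnigmaEngineConfig
) -> Optional[EvidenceAssignment]:
    """Observation-based BP5 under the configured cooccurrence policy.

    Under the default ``withhold_all`` policy a raw in-trans observation
    grants nothing: the cooccurrence signal enters only through the combined
    multifactorial LR (:func:`assess_multifactorial`).  ``withhold_pair``
    grants BP5_SUP for observations other than the BRCA1 + BRCA2 pathogenic
    pair scenario (it is not rare to see pathogenic variants in both genes in
    one patient); ``allow`` grants it for any observation.
    """
    if cooccurrence is Cooccurrence.none:
        return None
    policy = config.bp5_cooccurrence_policy
    if policy == "withhold_all":
        return None
    if policy == "withhold_pair" and cooccurrence is Cooccurrence.with_pathogenic_same_gene_pair:
        return None
    return _assign("BP5", Strength.SUP, f"in-trans pathogenic observation ({cooccurrence.value})")


def _domain_membership(
    record: VariantRecord, tables: GeneResourceTables, skipped: list[str]
) -> Optional[bool]:
    """Direct annotation wins; otherwise derive from the domain interval table."""
    ann = record.annotations
    derived = tables.domain_membership_from_hgvs(record.gene, record.hgvs_c)
    if ann.in_clinically_important_domain is not None:
        if derived is not None and derived != ann.in_clinically_important_domain:
            skipped.append(
                "domain membership: direct annotation conflicts with interval table; "
                "direct annotation used"
            )
        return ann.in_clinically_important_domain
    return derived


def classify_enigma(
    record: VariantRecord,
    tables: Optional[GeneResourceTables] = None,
    config: Optional[EnigmaEngineConfig] = None,
    scale: Optional[PointScale] = None,
) -> ClassificationReport:
    """Run all ENIGMA rules over one record, sum with the shared point scale,
    classify with the ENIGMA boundary table (likely benign from -2 points)."""
    config = config or DEFAULT_CONFIG.enigma
    tables = tables or GeneResourceTables()
    ann = record.annotations
    assignments: list[EvidenceAssignment] = []
    skipped: list[str] = []

    def add(a: Optional[EvidenceAssignment]) -> None:
        if a is None:
            return
        if any(existing.code == a.code for existing in assignments):
            skipped.append(f"{a.code}: duplicate assignment from a second rule ignored")
            return
        assignments.append(a)

    try:
        in_domain = _domain_membership(record, tables, skipped)
        if record.consequence is Consequence.missense and in_domain is None:
            skipped.append("BP1/PP3/BP4: domain membership unknown")

        add(assess_bp1(record.consequence, in_domain, ann.spliceai_max, config))

        if ann.ac_noncancer_v2 is None or ann.ac_noncancer_v3 is None:
            skipped.append("PM2: gnomAD noncancer allele counts incomplete")
        else:
            add(assess_pm2_enigma(ann.ac_noncancer_v2, ann.ac_noncancer_v3))

        add(
            assess_computational_enigma(
                record.consequence, in_domain, ann.bayesdel, ann.spliceai_max, config
            )
        )

        add(assess_functional(record.gene, record.hgvs_c, tables, ann.functional_verdict))

        lr = ann.multifactorial_lr
        if lr is None:
            lr = tables.multifactorial.get((record.gene, record.hgvs_c))
        add(assess_multifactorial(lr, config))

        add(assess_cosegregation(ann.cosegregation_lr, config))

        if record.consequence in PTC_CONSEQUENCES and ann.ptc_exon_weight is None:
            if record.exon is None or (record.gene, record.exon) not in tables.exon_weights:
                skipped.append("PM5_PTC: exon absent from the weight table")
        add(
            assess_pm5_ptc(
                record.gene, record.consequence, record.exon, tables, ann.ptc_exon_weight
            )
        )

        site = str(record.exon) if record.exon is not None else None
        if record.consequence in PVS1_ELIGIBLE and ann.pvs1_outcome is None:
            if site is None or (record.gene, record.consequence, site) not in tables.pvs1_outcomes:
                skipped.append("PVS1: no decision-tree outcome row for this variant")
        add(assess_pvs1(record.gene, record.consequence, site, tables, ann.pvs1_outcome))

        add(assess_bp5_enigma(ann.cooccurrence, config))
    except ValueError as err:
        raise ValueError(f"{record.variant_id}: {err}") from err

    return build_report(record.variant_id, _FW, assignments, skipped, scale)
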