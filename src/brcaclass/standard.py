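"""Standard ACMG/AMP + SVI rule engine (the t2 reanalysis arm).

Operationalizes the general classification system with current SVI
recommendations: PM2 at supporting strength under a gnomAD noncancer v2.1.1
allele-count ceiling, PS4 at supporting strength by proband counting, REVEL
interval calibration for PP3/BP4 with strengths beyond supporting in both
directions, BP7 (plus BP4) for synonymous/intronic variants without predicted
splice impact, and BP5 for in-trans observations with a pathogenic variant.

The engine's code alphabet is deliberately restricted: it never emits the
gene-specific ENIGMA codes (BP1, PM5_PTC, PVS1-tree outcomes, PP4, PP1/BS4,
PS3/BS3).  Conflicting evidence is summed, never dropped.
"""

from __future__ import annotations

from typing import Optional

from .config import DEFAULT_CONFIG, StandardEngineConfig, band_lookup
from .model import Consequence, Cooccurrence, Framework, Strength, VariantRecord
from .points import ClassificationReport, EvidenceAssignment, PointScale, build_report

_FW = Framework.standard

#: Consequences eligible for the BP7 / splice-negative BP4 rule.
_BP7_CONSEQUENCES = frozenset({Consequence.synonymous, Consequence.intronic})


def _assign(code: str, strength: Strength, rationale: str) -> EvidenceAssignment:
    return EvidenceAssignment(code=code, strength=strength, framework=_FW, rationale=rationale)


def assess_pm2_standard(
    ac_noncancer_v2: Optional[int], config: StandardEngineConfig
) -> Optional[EvidenceAssignment]:
    """PM2_SUP iff the gnomAD noncancer v2.1.1 allele count is <= the ceiling."""
    if ac_noncancer_v2 is None:
        return None
    if ac_noncancer_v2 < 0:
        raise ValueError(f"allele count must be non-negative, got {ac_noncancer_v2}")
    if ac_noncancer_v2 <= config.pm2_max_allele_count:
        return _assign(
            "PM2",
            Strength.SUP,
            f"gnomAD noncancer v2.1.1 AC={ac_noncancer_v2} <= {config.pm2_max_allele_count}",
        )
    return None


def assess_ps4_standard(
    proband_count: Optional[int],
    too_frequent_in_population: bool,
    config: StandardEngineConfig,
) -> Optional[EvidenceAssignment]:
    """PS4_SUP by proband counting, withheld for variants too frequent in
    population databases."""
    if proband_count is None:
        return None
    if proband_count >= config.ps4_min_probands and not too_frequent_in_population:
        return _assign(
            "PS4",
            Strength.SUP,
            f"{proband_count} described breast/ovarian-cancer probands "
            f">= {config.ps4_min_probands}",
        )
    return None


def assess_computational_standard(
    consequence: Consequence,
    revel: Optional[float],
    config: StandardEngineConfig,
) -> Optional[EvidenceAssignment]:
    """PP3/BP4 from the REVEL interval table (missense only); strengths may
    exceed supporting in either direction."""
    if consequence is not Consequence.missense or revel is None:
        return None
    if not (0.0 <= revel <= 1.0):
        raise ValueError(f"REVEL score must lie in [0, 1], got {revel}")
    hit = band_lookup(revel, config.revel_bands)
    if hit is None:
        return None
    code, strength = hit
    return _assign(code, strength, f"REVEL={revel:g} in configured {code} interval")


def _no_splice_impact(
    spliceai_max: Optional[float],
    no_predicted_splice_impact: Optional[bool],
    config: StandardEngineConfig,
) -> Optional[bool]:
    """True / False when determinable, None when unknown."""
    if no_predicted_splice_impact is not None:
        return no_predicted_splice_impact
    if spliceai_max is not None:
        return spliceai_max <= config.splice_negative_max
    return None


def assess_bp7_standard(
    consequence: Consequence,
    spliceai_max: Optional[float],
    no_predicted_splice_impact: Optional[bool],
    config: StandardEngineConfig,
) -> Optional[EvidenceAssignment]:
    """BP7_SUP for synonymous/intronic variants with no predicted splice impact."""
    if not config.bp7_enabled or consequence not in _BP7_CONSEQUENCES:
        return None
    if _no_splice_impact(spliceai_max, no_predicted_splice_impact, config):
        return _assign("BP7", Strength.SUP, "synonymous/intronic, no predicted splice impact")
    return None


def assess_bp4_splice_standard(
    consequence: Consequence,
    spliceai_max: Optional[float],
    no_predicted_splice_impact: Optional[bool],
    config: StandardEngineConfig,
) -> Optional[EvidenceAssignment]:
    """BP4_SUP as computational no-impact evidence for synonymous/intronic
    variants with a negative splice prediction (applied alongside BP7)."""
    if consequence not in _BP7_CONSEQUENCES:
        return None
    if _no_splice_impact(spliceai_max, no_predicted_splice_impact, config):
        return _assign("BP4", Strength.SUP, "negative splice prediction (non-coding impact)")
    return None


def assess_bp5_standard(cooccurrence: Cooccurrence) -> Optional[EvidenceAssignment]:
    """BP5_SUP when an in-trans pathogenic variant is recorded, including the
    BRCA1 + BRCA2 pathogenic pair scenario."""
    if cooccurrence in (Cooccurrence.with_pathogenic_same_gene_pair, Cooccurrence.other):
        return _assign("BP5", Strength.SUP, f"in-trans pathogenic observation ({cooccurrence.value})")
    return None


def classify_standard(
    record: VariantRecord,
    config: Optional[StandardEngineConfig] = None,
    scale: Optional[PointScale] = None,
) -> ClassificationReport:
    """Run every standard rule over one record, sum points, classify.

    Unknown annotations skip their rule and are listed in
    ``report.not_evaluated``; they never count as evidence.
    """
    config = config or DEFAULT_CONFIG.standard
    ann = record.annotations
    assignments: list[EvidenceAssignment] = []
    skipped: list[str] = []

    try:
        if ann.ac_noncancer_v2 is None:
            skipped.append("PM2: gnomAD noncancer v2.1.1 allele count unknown")
        elif (a := assess_pm2_standard(ann.ac_noncancer_v2, config)) is not None:
            assignments.append(a)

        if ann.proband_count is None:
            skipped.append("PS4: proband count unknown")
        elif (a := assess_ps4_standard(ann.proband_count, ann.too_frequent_in_population, config)) is not None:
            assignments.append(a)

        if record.consequence is Consequence.missense and ann.revel is None:
            skipped.append("PP3/BP4: REVEL score unknown")
        elif (a := assess_computational_standard(record.consequence, ann.revel, config)) is not None:
            assignments.append(a)

        splice_known = (
            ann.no_predicted_splice_impact is not None or ann.spliceai_max is not None
        )
        if record.consequence in _BP7_CONSEQUENCES and not splice_known:
            skipped.append("BP7/BP4: splice prediction unknown")
        else:
            if (a := assess_bp7_standard(record.consequence, ann.spliceai_max, ann.no_predicted_splice_impact, config)) is not None:
                assignments.append(a)
            if (a := assess_bp4_splice_standard(record.consequence, ann.spliceai_max, ann.no_predicted_splice_impact, config)) is not None:
                assignments.append(a)

        if (a := assess_bp5_standard(ann.cooccurrence)) is not None:
            assignments.append(a)
    except ValueError as err:
        raise ValueError(f"{record.variant_id}: {err}") from err

    return build_report(record.variant_id, _FW, assignments, skipped, scale)
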