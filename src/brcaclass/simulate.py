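"""Seeded synthetic cohorts and miniature resource tables.

The generator emulates the *evidence structure* of a diagnostic BRCA1/BRCA2
VUS cohort — which annotations are available per variant and which rules they
should fire — not mutational spectra or population genetics.  Defaults mirror
the study conditions: 121 VUS (40 BRCA1, 81 BRCA2), 93 missense variants
outside clinically important domains, 10 in-domain BRCA2 missense variants
with a benign missense prediction, 10 variants with a reviewed benign
functional assay, and 12 variants with benign multifactorial combined LRs
(1 very strong, 1 strong, 4 moderate, 6 supporting).

Evidence availability is planted by exact counts (shuffle-then-slice under
the seed), never by independent coin flips, so cohort-level expectations are
exact.  Every generated record is accompanied by a ground-truth ledger entry
listing the code+strength tokens each engine must assign, enabling exact
expected-output checks by independent re-evaluation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .model import (
    AnnotationBundle,
    Classification,
    CodeOutcome,
    Consequence,
    Cooccurrence,
    FunctionalEvidence,
    Gene,
    Strength,
    VariantRecord,
    Verdict,
)
from .points import parse_token, strength_points, code_direction
from .resources import DomainInterval, GeneResourceTables

#: Synthetic clinically important domain intervals (transcript c. space,
#: 1-based inclusive), shaped after the real domain architecture: BRCA1 RING
#: and BRCT regions, BRCA2 C-terminal DNA-binding domain.
SYNTHETIC_DOMAINS: dict[Gene, tuple[DomainInterval, ...]] = {
    Gene.BRCA1: (
        DomainInterval(1, 300, "RING domain"),
        DomainInterval(4948, 5574, "BRCT repeats"),
    ),
    Gene.BRCA2: (DomainInterval(7441, 9558, "DNA-binding domain"),),
}

#: Coding-sequence extent used for drawing synthetic positions.
_CDS_END = {Gene.BRCA1: 5589, Gene.BRCA2: 10254}

_AA3 = ["Ala", "Arg", "Asn", "Asp", "Gly", "His", "Leu", "Lys", "Ser", "Thr", "Val"]
_BASES = ["A", "C", "G", "T"]

# Profile labels (mutually exclusive evidence archetypes).
MISSENSE_OUTSIDE = "missense_outside_domain"
MISSENSE_IN_DOMAIN = "missense_in_domain_benign_prediction"
INTRONIC_NEGATIVE = "intronic_no_splice_impact"
MISSENSE_SPLICE_FLAGGED = "missense_splice_flagged"

_PROFILES = (
    MISSENSE_OUTSIDE,
    MISSENSE_IN_DOMAIN,
    INTRONIC_NEGATIVE,
    MISSENSE_SPLICE_FLAGGED,
)


@dataclass
class CohortSpec:
    """Generator parameters; defaults are the study conditions.

    Profile fractions partition the cohort; overlay fractions plant
    additional evidence on top of (subsets of) the profiles.  All planting is
    by exact count: ``round(fraction * n_total)`` reconciled by largest
    remainder.
    """

    n_total: int = 121
    n_brca1: int = 40
    n_brca2: int = 81
    # mutually exclusive consequence/evidence profiles
    f_missense_outside_domain: float = 93 / 121
    f_missense_in_domain_benign: float = 10 / 121  # BRCA2 DNA-binding domain
    f_intronic_no_splice_impact: float = 12 / 121
    f_missense_splice_flagged: float = 6 / 121
    # overlays
    f_functional_benign: float = 10 / 121  # reviewed assay refuting damage (BS3_STR)
    bp5_band_counts: dict = field(
        default_factory=lambda: {"VSTR": 1, "STR": 1, "MOD": 4, "SUP": 6}
    )
    f_absent_gnomad: float = 20 / 121  # absent from both noncancer sets
    f_low_gnomad: float = 45 / 121  # AC(v2) in 1..5: standard PM2 only
    f_ps4_probands: float = 20 / 121  # >=5 described probands
    # REVEL band structure among missense-outside/in-domain records
    f_revel_benign_supporting: float = 0.45
    f_revel_benign_moderate: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_brca1 + self.n_brca2 != self.n_total:
            raise ValueError(
                f"n_brca1 ({self.n_brca1}) + n_brca2 ({self.n_brca2}) "
                f"must equal n_total ({self.n_total})"
            )
        fracs = {
            k: v
            for k, v in asdict(self).items()
            if k.startswith("f_") and not isinstance(v, dict)
        }
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        profile_sum = (
            self.f_missense_outside_domain
            + self.f_missense_in_domain_benign
            + self.f_intronic_no_splice_impact
            + self.f_missense_splice_flagged
        )
        if self.n_total > 0 and abs(profile_sum - 1.0) > 1e-6:
            raise ValueError(
                f"profile fractions must partition the cohort (sum to 1), "
                f"got {profile_sum:.4f}"
            )
        if self.f_absent_gnomad + self.f_low_gnomad > 1.0 + 1e-9:
            raise ValueError("gnomAD absent + low fractions exceed 1")
        if self.f_revel_benign_supporting + self.f_revel_benign_moderate > 1.0 + 1e-9:
            raise ValueError("REVEL band fractions exceed 1")
        if self.n_total == 0:
            return
        counts = self.profile_counts()
        n_overlay = self.n_functional + sum(self.bp5_band_counts.values())
        if n_overlay > counts[MISSENSE_OUTSIDE]:
            raise ValueError(
                f"functional + multifactorial overlays ({n_overlay}) exceed the "
                f"missense-outside-domain profile count ({counts[MISSENSE_OUTSIDE]}); "
                "reduce the overlay fractions or enlarge the profile"
            )
        if counts[MISSENSE_IN_DOMAIN] > self.n_brca2:
            raise ValueError("in-domain (BRCA2) profile count exceeds n_brca2")

    # -- exact counts -------------------------------------------------------
    def profile_counts(self) -> dict[str, int]:
        """Largest-remainder apportionment of the profile fractions."""
        fracs = [
            self.f_missense_outside_domain,
            self.f_missense_in_domain_benign,
            self.f_intronic_no_splice_impact,
            self.f_missense_splice_flagged,
        ]
        if self.n_total == 0:
            return dict.fromkeys(_PROFILES, 0)
        shares = [f * self.n_total for f in fracs]
        floors = [int(np.floor(s)) for s in shares]
        remainder = self.n_total - sum(floors)
        order = np.argsort([floors[i] - shares[i] for i in range(4)])  # largest frac part first
        counts = floors[:]
        for i in order[:remainder]:
            counts[i] += 1
        return dict(zip(_PROFILES, counts))

    @property
    def n_functional(self) -> int:
        return int(round(self.f_functional_benign * self.n_total))

    @property
    def n_absent(self) -> int:
        return int(round(self.f_absent_gnomad * self.n_total))

    @property
    def n_low(self) -> int:
        return int(round(self.f_low_gnomad * self.n_total))

    @property
    def n_ps4(self) -> int:
        return int(round(self.f_ps4_probands * self.n_total))


def _hgvs_missense(rng: np.random.Generator, pos: int) -> tuple[str, str]:
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    aa = (pos - 1) // 3 + 1
    aa_from, aa_to = rng.choice(_AA3, size=2, replace=False)
    return f"c.{pos}{ref}>{alt}", f"p.({aa_from}{aa}{aa_to})"


def _positions_outside(gene: Gene, rng: np.random.Generator, n: int) -> list[int]:
    """Distinct coding positions outside every synthetic domain interval."""
    pool = np.array(
        [
            p
            for p in range(1, _CDS_END[gene] + 1)
            if not any(d.contains(p) for d in SYNTHETIC_DOMAINS[gene])
        ]
    )
    return list(rng.choice(pool, size=n, replace=False))


def _positions_inside(gene: Gene, rng: np.random.Generator, n: int) -> list[int]:
    dom = SYNTHETIC_DOMAINS[gene][-1]  # BRCA2 C-terminal DNA-binding domain
    pool = np.arange(dom.c_start, dom.c_end + 1)
    return list(rng.choice(pool, size=n, replace=False))


# Band-representative draws.  Intervals stay strictly inside the configured
# default bands so the planted code is unambiguous.
_LR_BAND_RANGES = {
    "SUP": (0.24, 0.47),
    "MOD": (0.06, 0.22),
    "STR": (0.004, 0.05),
    "VSTR": (0.0006, 0.0028),
}
_REVEL_RANGES = {
    "BP4_SUP": (0.19, 0.28),
    "BP4_MOD": (0.02, 0.18),
    "none": (0.31, 0.63),
}


def _expected_class(tokens: list[str], framework: str) -> str:
    """Five-tier class implied by a token list (generator-side bookkeeping)."""
    pts = sum(
        strength_points(parse_token(t)[1], code_direction(parse_token(t)[0]))
        for t in tokens
    )
    if framework == "standard":
        vus_min = 0
    else:
        vus_min = -1
    if pts >= 10:
        return Classification.P.value
    if pts >= 6:
        return Classification.LP.value
    if pts >= vus_min:
        return Classification.VUS.value
    if pts >= -6:
        return Classification.LB.value
    return Classification.B.value


def generate_cohort(
    spec: Optional[CohortSpec] = None,
) -> tuple[list[VariantRecord], dict]:
    """Generate a seeded cohort plus its ground-truth ledger.

    The ledger maps each variant id to its planted profile, overlays, and the
    exact code+strength tokens the standard and ENIGMA engines must assign.
    Ledger tokens are derived from the planted evidence by the generator's own
    bookkeeping, independently of the engine implementations.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    if n == 0:
        return [], {"spec": asdict(spec), "records": {}}

    counts = spec.profile_counts()
    profiles: list[str] = sum(([p] * counts[p] for p in _PROFILES), [])
    profiles = [str(p) for p in np.array(profiles)[rng.permutation(n)]]

    # Gene assignment: the in-domain profile is BRCA2 by construction; the
    # remaining BRCA2 quota is spread over the other records.
    genes: list[Optional[Gene]] = [None] * n
    in_domain_idx = [i for i, p in enumerate(profiles) if p == MISSENSE_IN_DOMAIN]
    for i in in_domain_idx:
        genes[i] = Gene.BRCA2
    rest = [i for i in range(n) if genes[i] is None]
    rest = [int(i) for i in np.array(rest)[rng.permutation(len(rest))]]
    quota_b2 = spec.n_brca2 - len(in_domain_idx)
    for i in rest[:quota_b2]:
        genes[i] = Gene.BRCA2
    for i in rest[quota_b2:]:
        genes[i] = Gene.BRCA1

    # Overlay slices (shuffle-then-slice: exact counts).
    outside_idx = [i for i, p in enumerate(profiles) if p == MISSENSE_OUTSIDE]
    shuffled_outside = (
        [int(i) for i in np.array(outside_idx)[rng.permutation(len(outside_idx))]]
        if outside_idx
        else []
    )
    functional_idx = set(shuffled_outside[: spec.n_functional])
    bp5_strengths: dict[int, str] = {}
    cursor = spec.n_functional
    for label in ("VSTR", "STR", "MOD", "SUP"):
        k = spec.bp5_band_counts.get(label, 0)
        for i in shuffled_outside[cursor : cursor + k]:
            bp5_strengths[i] = label
        cursor += k

    all_shuffled = [int(i) for i in rng.permutation(n)]
    absent_idx = set(all_shuffled[: spec.n_absent])
    low_idx = set(all_shuffled[spec.n_absent : spec.n_absent + spec.n_low])
    ps4_idx = {int(i) for i in rng.permutation(n)[: spec.n_ps4]}

    # REVEL band slices among plain missense records (outside + in-domain).
    revel_eligible = [
        i for i, p in enumerate(profiles) if p in (MISSENSE_OUTSIDE, MISSENSE_IN_DOMAIN)
    ]
    revel_eligible = (
        [int(i) for i in np.array(revel_eligible)[rng.permutation(len(revel_eligible))]]
        if revel_eligible
        else []
    )
    n_rb_sup = int(round(spec.f_revel_benign_supporting * len(revel_eligible)))
    n_rb_mod = int(round(spec.f_revel_benign_moderate * len(revel_eligible)))
    revel_band = dict.fromkeys(revel_eligible, "none")
    for i in revel_eligible[:n_rb_sup]:
        revel_band[i] = "BP4_SUP"
    for i in revel_eligible[n_rb_sup : n_rb_sup + n_rb_mod]:
        revel_band[i] = "BP4_MOD"
    for i, p in enumerate(profiles):
        if p == MISSENSE_SPLICE_FLAGGED:
            revel_band[i] = "BP4_MOD"  # case-2-like: benign-moderate REVEL

    # Distinct coding positions per gene and location class.
    need_out = {g: 0 for g in Gene}
    need_in = 0
    for i, p in enumerate(profiles):
        if p in (MISSENSE_OUTSIDE, MISSENSE_SPLICE_FLAGGED, INTRONIC_NEGATIVE):
            need_out[genes[i]] += 1
        elif p == MISSENSE_IN_DOMAIN:
            need_in += 1
    pos_out = {g: iter(_positions_outside(g, rng, need_out[g])) for g in Gene}
    pos_in = iter(_positions_inside(Gene.BRCA2, rng, need_in))

    records: list[VariantRecord] = []
    ledger: dict[str, dict] = {}
    for i in range(n):
        profile = profiles[i]
        gene = genes[i]
        vid = f"SYN{i + 1:04d}"
        std_tokens: list[str] = []
        eng_tokens: list[str] = []

        # gnomAD annotation
        if i in absent_idx:
            ac2, ac3 = 0, 0
        elif i in low_idx:
            ac2, ac3 = int(rng.integers(1, 6)), int(rng.integers(1, 30))
        else:
            ac2, ac3 = int(rng.integers(6, 50)), int(rng.integers(10, 100))
        if ac2 <= 5:
            std_tokens.append("PM2_SUP")
        if ac2 == 0 and ac3 == 0:
            eng_tokens.append("PM2_SUP")

        # probands
        probands = int(rng.integers(5, 12)) if i in ps4_idx else int(rng.integers(0, 5))
        if i in ps4_idx:
            std_tokens.append("PS4_SUP")

        ann = AnnotationBundle(
            ac_noncancer_v2=ac2, ac_noncancer_v3=ac3, proband_count=probands
        )

        if profile == INTRONIC_NEGATIVE:
            pos = int(next(pos_out[gene]))
            hgvs_c = f"c.{pos}+{int(rng.integers(4, 21))}T>C"
            hgvs_p, consequence = "", Consequence.intronic
            ann.spliceai_max = float(rng.uniform(0.005, 0.09))
            ann.no_predicted_splice_impact = True
            std_tokens += ["BP4_SUP", "BP7_SUP"]
            eng_tokens.append("BP4_SUP")
        else:
            consequence = Consequence.missense
            if profile == MISSENSE_IN_DOMAIN:
                pos = int(next(pos_in))
                ann.in_clinically_important_domain = True
                ann.bayesdel = float(rng.uniform(0.0, 0.14))
                ann.spliceai_max = float(rng.uniform(0.005, 0.09))
                eng_tokens.append("BP4_SUP")
            else:
                pos = int(next(pos_out[gene]))
                ann.in_clinically_important_domain = False
                if profile == MISSENSE_SPLICE_FLAGGED:
                    ann.spliceai_max = float(rng.uniform(0.25, 0.6))
                    eng_tokens.append("PP3_SUP")
                else:
                    ann.spliceai_max = float(rng.uniform(0.005, 0.09))
                    eng_tokens.append("BP1_STR")
            hgvs_c, hgvs_p = _hgvs_missense(rng, pos)
            band = revel_band.get(i, "none")
            lo, hi = _REVEL_RANGES[band]
            ann.revel = float(rng.uniform(lo, hi))
            if band != "none":
                std_tokens.append(band)

        if i in functional_idx:
            ann.functional_verdict = FunctionalEvidence(
                Verdict.refutes_damaging, Strength.STR
            )
            eng_tokens.append("BS3_STR")
        if i in bp5_strengths:
            label = bp5_strengths[i]
            lo, hi = _LR_BAND_RANGES[label]
            ann.multifactorial_lr = float(rng.uniform(lo, hi))
            eng_tokens.append(f"BP5_{label}")

        record = VariantRecord(
            variant_id=vid,
            gene=gene,
            hgvs_c=hgvs_c,
            hgvs_p=hgvs_p,
            consequence=consequence,
            annotations=ann,
        )
        records.append(record)
        std_tokens.sort()
        eng_tokens.sort()
        ledger[vid] = {
            "profile": profile,
            "gene": gene.value,
            "standard": std_tokens,
            "enigma": eng_tokens,
            "standard_class": _expected_class(std_tokens, "standard"),
            "enigma_class": _expected_class(eng_tokens, "enigma"),
        }

    return records, {"spec": asdict(spec), "records": ledger}


def generate_resource_tables(
    spec: Optional[CohortSpec] = None,
    records: Optional[list[VariantRecord]] = None,
    ground_truth: Optional[dict] = None,
) -> GeneResourceTables:
    """Miniature resource tables, internally consistent with a cohort.

    Always contains the synthetic domain intervals (including the BRCA2
    C-terminal DNA-binding domain), a small exon-weight map and PVS1
    decision-tree outcomes; when a generated cohort is supplied, assay
    verdicts and multifactorial scores are emitted for exactly the records
    whose ledger plants them, so every lookup resolves.
    """
    tables = GeneResourceTables(domains=dict(SYNTHETIC_DOMAINS))
    tables.exon_weights.update(
        {
            (Gene.BRCA1, 2): _pm5(Strength.SUP),
            (Gene.BRCA1, 5): _pm5(Strength.MOD),
            (Gene.BRCA1, 10): _pm5(Strength.SUP),
            (Gene.BRCA1, 24): _no_code(),
            (Gene.BRCA2, 3): _pm5(Strength.SUP),
            (Gene.BRCA2, 11): _pm5(Strength.MOD),
            (Gene.BRCA2, 27): _no_code(),
        }
    )
    tables.pvs1_outcomes.update(
        {
            (Gene.BRCA1, Consequence.splice_site_1_2, "5"): _code("PVS1", Strength.STR),
            (Gene.BRCA1, Consequence.nonsense, "10"): _code("PVS1", Strength.VSTR),
            (Gene.BRCA1, Consequence.exon_duplication, "13"): _code("PVS1", Strength.MOD),
            (Gene.BRCA2, Consequence.frameshift, "11"): _code("PVS1", Strength.VSTR),
            (Gene.BRCA2, Consequence.exon_deletion, "3"): _no_code(),
            (Gene.BRCA2, Consequence.initiation_codon, "1"): _code("PM5", Strength.SUP),
        }
    )
    if records is not None and ground_truth is not None:
        by_id = {r.variant_id: r for r in records}
        for vid, entry in ground_truth["records"].items():
            record = by_id[vid]
            if any(t.startswith("BS3") for t in entry["enigma"]):
                tables.assay_verdicts[(record.gene, record.hgvs_c)] = (
                    Verdict.refutes_damaging,
                    _code("BS3", Strength.STR),
                )
            if record.annotations.multifactorial_lr is not None:
                tables.multifactorial[(record.gene, record.hgvs_c)] = (
                    record.annotations.multifactorial_lr
                )
    return tables


def _pm5(strength: Strength) -> CodeOutcome:
    return CodeOutcome(code="PM5", strength=strength)


def _code(code: str, strength: Strength) -> CodeOutcome:
    return CodeOutcome(code=code, strength=strength)


def _no_code() -> CodeOutcome:
    return CodeOutcome(code=None)


def discussion_cases_fixture() -> list[VariantRecord]:
    """The three hand-encoded variants that are likely benign under the
    standard engine but return to uncertain significance under ENIGMA.

    - Case 1, BRCA2 c.8668C>A p.(Leu2890Ile): in-trans observation with a
      pathogenic variant in the sister gene gives BP5 under the standard
      engine; the ENIGMA arm reaches the same -1 point through the combined
      multifactorial LR's weakest benign band, but -1 is still VUS there.
    - Case 2, BRCA2 c.830A>G p.(Asn277Ser): REVEL in the benign-moderate
      interval (standard BP4_MOD, -2, LB); under ENIGMA SpliceAI flags a
      possible splice impact (PP3 for splicing, +1, VUS) and BayesDel is not
      permitted because the variant lies outside clinically important domains.
    - Case 3, BRCA1 c.4096+4T>C: intronic with a negative SpliceAI score;
      standard BP4 + BP7 (-2, LB), ENIGMA BP4 only (-1, VUS).
    """
    case1 = VariantRecord(
        variant_id="case1",
        gene=Gene.BRCA2,
        hgvs_c="c.8668C>A",
        hgvs_p="p.(Leu2890Ile)",
        consequence=Consequence.missense,
        annotations=AnnotationBundle(
            ac_noncancer_v2=8,
            ac_noncancer_v3=3,
            revel=0.45,  # uninformative zone: standard totals -1 via BP5 alone
            in_clinically_important_domain=True,  # DNA-binding domain residue
            cooccurrence=Cooccurrence.with_pathogenic_same_gene_pair,
            multifactorial_lr=0.30,  # weakest benign band -> BP5_SUP
            spliceai_max=0.02,
            proband_count=0,
        ),
    )

    case2 = VariantRecord(
        variant_id="case2",
        gene=Gene.BRCA2,
        hgvs_c="c.830A>G",
        hgvs_p="p.(Asn277Ser)",
        consequence=Consequence.missense,
        annotations=AnnotationBundle(
            ac_noncancer_v2=7,
            ac_noncancer_v3=4,
            revel=0.10,  # benign-moderate interval -> BP4_MOD under standard
            bayesdel=0.05,  # present but not permitted outside domains
            spliceai_max=0.32,  # conspicuous -> ENIGMA PP3 (splicing)
            in_clinically_important_domain=False,
            proband_count=1,
        ),
    )
    case3 = VariantRecord(
        variant_id="case3",
        gene=Gene.BRCA1,
        hgvs_c="c.4096+4T>C",
        consequence=Consequence.intronic,
        annotations=AnnotationBundle(
            ac_noncancer_v2=10,
            ac_noncancer_v3=6,
            spliceai_max=0.02,  # negative splice prediction
            no_predicted_splice_impact=True,
            proband_count=0,
        ),
    )
    return [case1, case2, case3]
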