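"""Domain model: variants, annotations, evidence strengths and five-tier classes.

The classification problem is framed around two reference transcripts only
(BRCA1 NM_007294.4, BRCA2 NM_000059.4).  Every annotation field distinguishes
*unknown* (``None``) from an informative zero/false value; an unknown
annotation never triggers an evidence code, it is logged as not-evaluated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class Gene(str, enum.Enum):
    BRCA1 = "BRCA1"
    BRCA2 = "BRCA2"


#: Reference transcript accepted for each gene.
TRANSCRIPTS = {Gene.BRCA1: "NM_007294.4", Gene.BRCA2: "NM_000059.4"}


class Consequence(str, enum.Enum):
    """Molecular consequence on the reference transcript.

    ``splice_site_1_2`` means a donor/acceptor dinucleotide variant
    (positions +/-1,2 of the exon boundary).
    """

    missense = "missense"
    synonymous = "synonymous"
    intronic = "intronic"
    splice_site_1_2 = "splice_site_1_2"
    nonsense = "nonsense"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    exon_deletion = "exon_deletion"
    exon_duplication = "exon_duplication"
    initiation_codon = "initiation_codon"
    other = "other"


#: Consequences that produce a premature termination codon (PM5_PTC-eligible).
PTC_CONSEQUENCES = frozenset({Consequence.nonsense, Consequence.frameshift})

#: Consequences evaluated against the PVS1 decision trees.
PVS1_ELIGIBLE = frozenset(
    {
        Consequence.splice_site_1_2,
        Consequence.nonsense,
        Consequence.frameshift,
        Consequence.exon_deletion,
        Consequence.exon_duplication,
        Consequence.initiation_codon,
    }
)


class Classification(str, enum.Enum):
    """Five-tier clinical class, ordered B < LB < VUS < LP < P."""

    B = "B"
    LB = "LB"
    VUS = "VUS"
    LP = "LP"
    P = "P"


CLASS_ORDER = [
    Classification.B,
    Classification.LB,
    Classification.VUS,
    Classification.LP,
    Classification.P,
]


class Strength(str, enum.Enum):
    """Evidence strength modifier (supporting, moderate, strong, very strong)."""

    SUP = "SUP"
    MOD = "MOD"
    STR = "STR"
    VSTR = "VSTR"


class Direction(str, enum.Enum):
    pathogenic = "pathogenic"
    benign = "benign"


class Framework(str, enum.Enum):
    """Which rule set produced a report: standard ACMG/AMP + SVI, or ENIGMA VCEP."""

    standard = "standard"
    enigma = "enigma"


class Cooccurrence(str, enum.Enum):
    """In-trans observation with a known pathogenic variant.

    ``with_pathogenic_same_gene_pair`` records the BRCA1 + BRCA2 pathogenic
    pair scenario (one patient carrying a pathogenic variant in the sister
    gene), which the ENIGMA arm treats conservatively for BP5.
    """

    none = "none"
    with_pathogenic_same_gene_pair = "with_pathogenic_same_gene_pair"
    other = "other"


class Verdict(str, enum.Enum):
    supports_damaging = "supports_damaging"
    refutes_damaging = "refutes_damaging"


@dataclass(frozen=True)
class FunctionalEvidence:
    """A reviewed functional-assay verdict with its calibrated strength."""

    verdict: Verdict
    strength: Strength


@dataclass(frozen=True)
class CodeOutcome:
    """A table-given code + strength outcome (e.g. a PVS1 decision-tree cell).

    ``code=None`` encodes the explicit "no code" outcome, distinct from a
    missing table row.
    """

    code: Optional[str]
    strength: Optional[Strength] = None


@dataclass
class AnnotationBundle:
    """All per-variant evidence annotations consumed by the two engines.

    Every field is ``None`` when unknown; unknown never fires a code.
    """

    ac_noncancer_v2: Optional[int] = None  # gnomAD noncancer v2.1.1 allele count
    ac_noncancer_v3: Optional[int] = None  # gnomAD noncancer v3.1.2 allele count
    revel: Optional[float] = None  # missense meta-predictor, [0, 1]
    bayesdel: Optional[float] = None  # deleteriousness score (unbounded)
    spliceai_max: Optional[float] = None  # max delta score across splice events, [0, 1]
    in_clinically_important_domain: Optional[bool] = None
    proband_count: Optional[int] = None  # described affected BC/OC probands
    too_frequent_in_population: bool = False  # disqualifies PS4
    functional_verdict: Optional[FunctionalEvidence] = None
    multifactorial_lr: Optional[float] = None  # combined likelihood ratio, > 0
    cosegregation_lr: Optional[float] = None  # cosegregation likelihood ratio, > 0
    cooccurrence: Cooccurrence = Cooccurrence.none
    ptc_exon_weight: Optional[CodeOutcome] = None  # direct PM5_PTC weight, if annotated
    pvs1_outcome: Optional[CodeOutcome] = None  # direct PVS1 decision-tree outcome
    no_predicted_splice_impact: Optional[bool] = None
    # ``no_predicted_splice_impact`` is the curated flag that a synonymous or
    # deep-intronic variant has no predicted effect on splicing (BP7 gate).

    def __post_init__(self) -> None:
        for name in ("ac_noncancer_v2", "ac_noncancer_v3", "proband_count"):
            v = getattr(self, name)
            if v is not None:
                if int(v) != v or v < 0:
                    raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
                setattr(self, name, int(v))
        for name in ("revel", "spliceai_max"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("multifactorial_lr", "cosegregation_lr"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")


@dataclass
class VariantRecord:
    """One variant: identity, consequence, annotations, and its baseline class.

    ``baseline_class`` is the class recorded at the original interpretation
    (t1); it is consumed as given, never re-derived.
    """

    variant_id: str
    gene: Gene
    hgvs_c: str
    consequence: Consequence
    hgvs_p: str = ""
    transcript: str = ""
    exon: Optional[int] = None
    annotations: AnnotationBundle = field(default_factory=AnnotationBundle)
    baseline_class: Classification = Classification.VUS
    metadata: dict = field(default_factory=dict)  # passthrough columns

    def __post_init__(self) -> None:
        self.gene = Gene(self.gene)
        self.consequence = Consequence(self.consequence)
        self.baseline_class = Classification(self.baseline_class)
        expected = TRANSCRIPTS[self.gene]
        if not self.transcript:
            self.transcript = expected
        elif self.transcript != expected:
            raise ValueError(
                f"{self.variant_id}: transcript {self.transcript!r} does not match "
                f"{self.gene.value} reference transcript {expected!r}"
            )
        if self.exon is not None and self.exon < 1:
            raise ValueError(f"{self.variant_id}: exon index must be >= 1")

    def with_annotations(self, **kwargs) -> "VariantRecord":
        """Return a copy with annotation fields replaced (convenience for tests)."""
        new = replace(self)
        new.annotations = replace(self.annotations, **kwargs)
        return new
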