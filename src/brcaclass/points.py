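"""Bayesian point-based evidence combination.

Each ACMG/AMP evidence code carries a strength (supporting, moderate, strong,
very strong) mapped to exponentially doubling points 1/2/4/8; benign codes
contribute negatively.  The signed sum over all applied codes — conflicting
evidence is summed, never short-circuited — maps to the five-tier class
through a framework-specific boundary table.  The standard framework reaches
likely benign at -1 point; the ENIGMA VCEP framework requires -2, which is
the single boundary difference between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import Classification, Direction, Framework, Strength

#: Points per strength: strictly doubling from supporting to very strong.
STRENGTH_POINTS: Mapping[Strength, int] = {
    Strength.SUP: 1,
    Strength.MOD: 2,
    Strength.STR: 4,
    Strength.VSTR: 8,
}

#: Default ACMG strength implied by a bare code (PS4 -> STR, BP4 -> SUP, ...).
_PREFIX_DEFAULT_STRENGTH = {
    "PVS": Strength.VSTR,
    "PS": Strength.STR,
    "PM": Strength.MOD,
    "PP": Strength.SUP,
    "BS": Strength.STR,
    "BP": Strength.SUP,
}


def code_direction(code: str) -> Direction:
    """Direction implied by the code's letter class: P* pathogenic, B* benign."""
    if code.startswith("P"):
        return Direction.pathogenic
    if code.startswith("B"):
        return Direction.benign
    raise ValueError(f"cannot derive a direction from evidence code {code!r}")


def default_strength(code: str) -> Strength:
    for prefix in ("PVS", "PS", "PM", "PP", "BS", "BP"):
        if code.startswith(prefix):
            return _PREFIX_DEFAULT_STRENGTH[prefix]
    raise ValueError(f"no default strength known for code {code!r}")


@dataclass(frozen=True)
class EvidenceAssignment:
    """One applied evidence code with strength, direction and provenance."""

    code: str  # base code, e.g. "BP1", "PM2", "PVS1"
    strength: Strength
    framework: Framework
    rationale: str = ""

    def __post_init__(self) -> None:
        code_direction(self.code)  # validates the letter class
        if not isinstance(self.strength, Strength):
            object.__setattr__(self, "strength", Strength(self.strength))

    @property
    def direction(self) -> Direction:
        return code_direction(self.code)

    @property
    def points(self) -> int:
        return strength_points(self.strength, self.direction)

    @property
    def token(self) -> str:
        return format_token(self.code, self.strength)


def format_token(code: str, strength: Strength) -> str:
    """Canonical I/O notation CODE_SUP / CODE_MOD / CODE_STR / CODE_VSTR."""
    return f"{code}_{Strength(strength).value}"


def parse_token(token: str) -> tuple[str, Strength]:
    """Parse ``BP1_STR`` -> (BP1, STR); a bare code implies its default strength."""
    token = token.strip()
    if "_" in token:
        code, _, label = token.rpartition("_")
        try:
            return code, Strength(label)
        except ValueError:
            raise ValueError(f"unknown strength label in token {token!r}") from None
    return token, default_strength(token)


def strength_points(strength: Strength | str, direction: Direction | str) -> int:
    """Signed point value of one code: pathogenic positive, benign negative."""
    try:
        pts = STRENGTH_POINTS[Strength(strength)]
    except (KeyError, ValueError):
        raise ValueError(
            f"unknown strength label {strength!r}; expected one of "
            f"{[s.value for s in Strength]}"
        ) from None
    return pts if Direction(direction) is Direction.pathogenic else -pts


def total_points(assignments: Iterable[EvidenceAssignment]) -> int:
    """Arithmetic sum of signed points over assignments.

    Conflicting directions are summed, never dropped.  A duplicate base code
    is rejected: at most one assignment per code per variant per framework.
    """
    seen: set[str] = set()
    total = 0
    for a in assignments:
        if a.code in seen:
            raise ValueError(f"duplicate base code {a.code!r} in assignment set")
        seen.add(a.code)
        total += a.points
    return total


@dataclass(frozen=True)
class ClassBoundaries:
    """Lower-inclusive point cutoffs for P / LP / VUS / LB; below ``lb_min`` is B."""

    p_min: int
    lp_min: int
    vus_min: int
    lb_min: int

    def classify(self, points: int) -> Classification:
        if points >= self.p_min:
            return Classification.P
        if points >= self.lp_min:
            return Classification.LP
        if points >= self.vus_min:
            return Classification.VUS
        if points >= self.lb_min:
            return Classification.LB
        return Classification.B


@dataclass(frozen=True)
class PointScale:
    """Shared strength->point mapping plus per-framework class boundaries.

    The standard boundaries follow the Tavtigian point bands (P >= 10,
    LP 6..9, VUS 0..5, LB -6..-1, B <= -7); the ENIGMA framework is identical
    except that likely benign starts at -2 (VUS covers -1..5).
    """

    boundaries: Mapping[Framework, ClassBoundaries] = field(
        default_factory=lambda: {
            Framework.standard: ClassBoundaries(p_min=10, lp_min=6, vus_min=0, lb_min=-6),
            Framework.enigma: ClassBoundaries(p_min=10, lp_min=6, vus_min=-1, lb_min=-6),
        }
    )

    def classify(self, points: int, framework: Framework | str) -> Classification:
        return self.boundaries[Framework(framework)].classify(points)


DEFAULT_POINT_SCALE = PointScale()


def classify(
    points: int,
    framework: Framework | str,
    scale: Optional[PointScale] = None,
) -> Classification:
    """Map a signed point total to the five-tier class for a framework."""
    return (scale or DEFAULT_POINT_SCALE).classify(points, framework)


@dataclass
class ClassificationReport:
    """Engine output for one variant under one framework."""

    variant_id: str
    framework: Framework
    assignments: tuple[EvidenceAssignment, ...]
    total_points: int
    classification: Classification
    not_evaluated: tuple[str, ...] = ()  # rules skipped for unknown annotations

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(a.token for a in self.assignments)

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(a.code for a in self.assignments)


def build_report(
    variant_id: str,
    framework: Framework,
    assignments: Sequence[EvidenceAssignment],
    not_evaluated: Sequence[str] = (),
    scale: Optional[PointScale] = None,
) -> ClassificationReport:
    """Deduplicate-check, sum and classify a finished assignment set."""
    ordered = tuple(sorted(assignments, key=lambda a: a.code))
    pts = total_points(ordered)
    return ClassificationReport(
        variant_id=variant_id,
        framework=framework,
        assignments=ordered,
        total_points=pts,
        classification=classify(pts, framework, scale),
        not_evaluated=tuple(not_evaluated),
    )
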