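"""Cohort-level runs, class-transition accounting and per-code deltas.

Reproduces the reclassification audit: each variant carries three classes
(baseline t1, standard-engine t2, ENIGMA-engine t3); transitions are counted
per step, and for each evidence code+strength token the number of variants
where the code was added or removed between two report sets is tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

from .config import AppConfig, DEFAULT_CONFIG
from .enigma import classify_enigma
from .model import CLASS_ORDER, Classification, Framework, VariantRecord
from .points import ClassificationReport
from .resources import GeneResourceTables
from .standard import classify_standard

#: Step labels for the two reanalysis transitions.
STEP_T1_T2 = "t1->t2"
STEP_T2_T3 = "t2->t3"


@dataclass
class CohortRunResult:
    """Per-record reports plus collected per-record failures."""

    reports: list[ClassificationReport]
    failures: list[tuple[str, str]] = field(default_factory=list)  # (variant_id, message)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_cohort(
    records: Sequence[VariantRecord],
    framework: Framework | str,
    tables: Optional[GeneResourceTables] = None,
    config: Optional[AppConfig] = None,
) -> CohortRunResult:
    """Classify every record under one framework, order-preserving.

    Per-record failures are collected and the run continues; callers decide
    whether failures are fatal (the CLI reflects them in its exit status).
    """
    framework = Framework(framework)
    config = config or DEFAULT_CONFIG
    result = CohortRunResult(reports=[])
    for record in records:
        try:
            if framework is Framework.standard:
                report = classify_standard(record, config.standard, config.point_scale)
            else:
                report = classify_enigma(record, tables, config.enigma, config.point_scale)
            result.reports.append(report)
        except ValueError as err:
            result.failures.append((record.variant_id, str(err)))
    return result


def round_percent(count: int, total: int) -> float:
    """Percentage rounded half-away-from-zero to one decimal (83.5-style)."""
    if total == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortComparison:
    """Transition counts, per-code deltas and per-timepoint class summaries."""

    per_variant: list[tuple[str, Classification, Classification, Classification]]
    transition_counts: dict[tuple[str, str, str], int]  # (from, to, step) -> count
    code_deltas: dict[tuple[str, str], tuple[int, int]]  # (token, step) -> (added, removed)
    summary: dict[str, dict[str, dict]]  # timepoint -> class -> {count, percent}

    @property
    def n(self) -> int:
        return len(self.per_variant)


def code_delta(
    reports_a: Sequence[ClassificationReport],
    reports_b: Sequence[ClassificationReport],
) -> dict[str, tuple[int, int]]:
    """Per code+strength token: (#variants where added in b, #removed from a).

    For every token, |usage_b| - |usage_a| = added - removed (conservation).
    """
    ids_a = [r.variant_id for r in reports_a]
    ids_b = [r.variant_id for r in reports_b]
    if ids_a != ids_b:
        raise ValueError("variant_id mismatch between the two report sets")
    deltas: dict[str, list[int]] = {}
    for ra, rb in zip(reports_a, reports_b):
        ta, tb = set(ra.tokens), set(rb.tokens)
        for token in tb - ta:
            deltas.setdefault(token, [0, 0])[0] += 1
        for token in ta - tb:
            deltas.setdefault(token, [0, 0])[1] += 1
    return {tok: (a, r) for tok, (a, r) in sorted(deltas.items())}


def _class_summary(labels: Sequence[Classification], total: int) -> dict[str, dict]:
    return {
        cls.value: {
            "count": labels.count(cls),
            "percent": round_percent(labels.count(cls), total),
        }
        for cls in CLASS_ORDER
    }


def transition_summary(
    t1_labels: Sequence[tuple[str, Classification]],
    t2_reports: Sequence[ClassificationReport],
    t3_reports: Sequence[ClassificationReport],
) -> CohortComparison:
    """Build the full three-timepoint comparison.

    ``t1_labels`` are the given baseline classes (never re-derived); t2/t3 are
    the standard- and ENIGMA-engine reports for the same variants in the same
    order.  Baseline carries no evidence codes, so per-code deltas are
    tabulated for the t2->t3 step.
    """
    ids1 = [vid for vid, _ in t1_labels]
    ids2 = [r.variant_id for r in t2_reports]
    ids3 = [r.variant_id for r in t3_reports]
    if not (ids1 == ids2 == ids3):
        raise ValueError("variant_id mismatch across the three timepoints")

    per_variant = [
        (vid, Classification(c1), r2.classification, r3.classification)
        for (vid, c1), r2, r3 in zip(t1_labels, t2_reports, t3_reports)
    ]
    n = len(per_variant)

    transitions: dict[tuple[str, str, str], int] = {}
    for _, c1, c2, c3 in per_variant:
        key12 = (c1.value, c2.value, STEP_T1_T2)
        key23 = (c2.value, c3.value, STEP_T2_T3)
        transitions[key12] = transitions.get(key12, 0) + 1
        transitions[key23] = transitions.get(key23, 0) + 1

    deltas = {
        (token, STEP_T2_T3): counts
        for token, counts in code_delta(t2_reports, t3_reports).items()
    }

    summary = {
        "t1": _class_summary([c1 for _, c1, _, _ in per_variant], n),
        "t2": _class_summary([c2 for _, _, c2, _ in per_variant], n),
        "t3": _class_summary([c3 for _, _, _, c3 in per_variant], n),
    }
    return CohortComparison(
        per_variant=per_variant,
        transition_counts=transitions,
        code_deltas=deltas,
        summary=summary,
    )
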