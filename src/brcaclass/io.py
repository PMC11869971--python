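"""Readers and writers for cohort tables, reports and comparison outputs.

TSV is the canonical dialect (one row per variant, columns mirroring the
annotation fields; empty cell = unknown).  A minimal VCF dialect exists for
interoperability: the same fields as INFO keys (see ``VCF_INFO_KEYS``),
undocumented keys ignored.  All writers are deterministic (stable column
order, trailing newline) and atomic (temp file + rename).
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd

from .cohort import CohortComparison
from .model import (
    AnnotationBundle,
    Classification,
    CodeOutcome,
    Consequence,
    Cooccurrence,
    FunctionalEvidence,
    Framework,
    Gene,
    Strength,
    VariantRecord,
    Verdict,
)
from .points import ClassificationReport, EvidenceAssignment, parse_token, total_points

#: Canonical cohort TSV column order.
COHORT_COLUMNS = [
    "variant_id",
    "gene",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "exon",
    "baseline_class",
    "ac_noncancer_v2",
    "ac_noncancer_v3",
    "revel",
    "bayesdel",
    "spliceai_max",
    "in_clinically_important_domain",
    "proband_count",
    "too_frequent_in_population",
    "functional_verdict",
    "functional_strength",
    "multifactorial_lr",
    "cosegregation_lr",
    "cooccurrence",
    "ptc_exon_weight",
    "pvs1_code",
    "pvs1_strength",
    "no_predicted_splice_impact",
]

MANDATORY_COLUMNS = ["variant_id", "gene", "hgvs_c", "consequence"]

#: Minimal-VCF dialect: INFO key -> cohort column (ID column -> variant_id).
VCF_INFO_KEYS = {
    "GENE": "gene",
    "HGVSC": "hgvs_c",
    "HGVSP": "hgvs_p",
    "CSQ": "consequence",
    "EXON": "exon",
    "BASECLASS": "baseline_class",
    "ACV2": "ac_noncancer_v2",
    "ACV3": "ac_noncancer_v3",
    "REVEL": "revel",
    "BAYESDEL": "bayesdel",
    "SPLICEAI": "spliceai_max",
    "INDOMAIN": "in_clinically_important_domain",
    "PROBANDS": "proband_count",
    "TOOFREQ": "too_frequent_in_population",
    "FUNCVERDICT": "functional_verdict",
    "FUNCSTRENGTH": "functional_strength",
    "MFLR": "multifactorial_lr",
    "COSEGLR": "cosegregation_lr",
    "COOCC": "cooccurrence",
    "PTCW": "ptc_exon_weight",
    "PVS1CODE": "pvs1_code",
    "PVS1STR": "pvs1_strength",
    "NOSPLICE": "no_predicted_splice_impact",
}


# -- atomic, deterministic writing ------------------------------------------


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file in the same directory and an atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not text.endswith("\n"):
        text += "\n"
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _df_to_tsv(df: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


# -- cohort TSV --------------------------------------------------------------


def _opt(value) -> str:
    return "" if value is None else str(value)


def _bool_str(value: Optional[bool]) -> str:
    return "" if value is None else ("true" if value else "false")


def record_to_row(record: VariantRecord) -> dict:
    ann = record.annotations
    fv = ann.functional_verdict
    pvs1 = ann.pvs1_outcome
    ptc = ann.ptc_exon_weight
    return {
        "variant_id": record.variant_id,
        "gene": record.gene.value,
        "transcript": record.transcript,
        "hgvs_c": record.hgvs_c,
        "hgvs_p": record.hgvs_p,
        "consequence": record.consequence.value,
        "exon": _opt(record.exon),
        "baseline_class": record.baseline_class.value,
        "ac_noncancer_v2": _opt(ann.ac_noncancer_v2),
        "ac_noncancer_v3": _opt(ann.ac_noncancer_v3),
        "revel": _opt(ann.revel),
        "bayesdel": _opt(ann.bayesdel),
        "spliceai_max": _opt(ann.spliceai_max),
        "in_clinically_important_domain": _bool_str(ann.in_clinically_important_domain),
        "proband_count": _opt(ann.proband_count),
        "too_frequent_in_population": "true" if ann.too_frequent_in_population else "false",
        "functional_verdict": fv.verdict.value if fv else "",
        "functional_strength": fv.strength.value if fv else "",
        "multifactorial_lr": _opt(ann.multifactorial_lr),
        "cosegregation_lr": _opt(ann.cosegregation_lr),
        "cooccurrence": ann.cooccurrence.value,
        "ptc_exon_weight": ("no_code" if ptc and ptc.code is None else (ptc.strength.value if ptc else "")),
        "pvs1_code": ("no_code" if pvs1 and pvs1.code is None else (pvs1.code if pvs1 else "")),
        "pvs1_strength": (pvs1.strength.value if pvs1 and pvs1.code else ""),
        "no_predicted_splice_impact": _bool_str(ann.no_predicted_splice_impact),
    }


def write_cohort_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    df = pd.DataFrame([record_to_row(r) for r in records], columns=COHORT_COLUMNS)
    _df_to_tsv(df, path)


def _parse_opt(raw: str, cast: Callable):
    raw = raw.strip()
    return None if raw == "" else cast(raw)


def _parse_bool(raw: str) -> Optional[bool]:
    raw = raw.strip().lower()
    if raw == "":
        return None
    if raw in ("true", "1", "yes"):
        return True
    if raw in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {raw!r}")


def row_to_record(row: dict) -> VariantRecord:
    fv = None
    if row.get("functional_verdict", ""):
        fv = FunctionalEvidence(
            Verdict(row["functional_verdict"]), Strength(row["functional_strength"])
        )
    ptc = None
    ptc_raw = row.get("ptc_exon_weight", "").strip()
    if ptc_raw:
        ptc = CodeOutcome(code=None) if ptc_raw == "no_code" else CodeOutcome(
            code="PM5", strength=Strength(ptc_raw)
        )
    pvs1 = None
    pvs1_raw = row.get("pvs1_code", "").strip()
    if pvs1_raw:
        pvs1 = CodeOutcome(code=None) if pvs1_raw == "no_code" else CodeOutcome(
            code=pvs1_raw, strength=Strength(row["pvs1_strength"])
        )
    ann = AnnotationBundle(
        ac_noncancer_v2=_parse_opt(row.get("ac_noncancer_v2", ""), int),
        ac_noncancer_v3=_parse_opt(row.get("ac_noncancer_v3", ""), int),
        revel=_parse_opt(row.get("revel", ""), float),
        bayesdel=_parse_opt(row.get("bayesdel", ""), float),
        spliceai_max=_parse_opt(row.get("spliceai_max", ""), float),
        in_clinically_important_domain=_parse_bool(
            row.get("in_clinically_important_domain", "")
        ),
        proband_count=_parse_opt(row.get("proband_count", ""), int),
        too_frequent_in_population=_parse_bool(row.get("too_frequent_in_population", ""))
        or False,
        functional_verdict=fv,
        multifactorial_lr=_parse_opt(row.get("multifactorial_lr", ""), float),
        cosegregation_lr=_parse_opt(row.get("cosegregation_lr", ""), float),
        cooccurrence=Cooccurrence(row.get("cooccurrence", "") or "none"),
        ptc_exon_weight=ptc,
        pvs1_outcome=pvs1,
        no_predicted_splice_impact=_parse_bool(
            row.get("no_predicted_splice_impact", "")
        ),
    )
    known = set(COHORT_COLUMNS)
    return VariantRecord(
        variant_id=row["variant_id"],
        gene=Gene(row["gene"]),
        transcript=row.get("transcript", "").strip(),
        hgvs_c=row["hgvs_c"],
        hgvs_p=row.get("hgvs_p", ""),
        consequence=Consequence(row["consequence"]),
        exon=_parse_opt(row.get("exon", ""), int),
        annotations=ann,
        baseline_class=Classification(row.get("baseline_class", "") or "VUS"),
        metadata={k: v for k, v in row.items() if k not in known},
    )


def read_cohort(
    path: str | Path, dialect: str = "tsv", skip_invalid: bool = False
) -> list[VariantRecord]:
    """Read and validate a cohort file.

    Invalid rows produce per-row diagnostics (1-based data row numbers); any
    invalid row is a hard failure unless ``skip_invalid`` is set, in which
    case valid rows are returned.
    """
    if dialect == "tsv":
        rows = _tsv_rows(path)
    elif dialect == "vcf-min":
        rows = _vcf_rows(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf-min'")

    records: list[VariantRecord] = []
    errors: list[str] = []
    for idx, row in enumerate(rows, start=1):
        try:
            for col in MANDATORY_COLUMNS:
                if not row.get(col, "").strip():
                    raise ValueError(f"missing mandatory column {col!r}")
            records.append(row_to_record(row))
        except (ValueError, KeyError) as err:
            errors.append(f"row {idx}: {err}")
    if errors and not skip_invalid:
        raise ValueError(
            f"{len(errors)} invalid row(s) in {path}:\n" + "\n".join(errors)
        )
    return records


def _tsv_rows(path: str | Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    return df.to_dict(orient="records")


def _vcf_rows(path: str | Path) -> list[dict]:
    from cyvcf2 import VCF

    rows = []
    for variant in VCF(str(path)):
        row = {"variant_id": variant.ID or ""}
        for key, column in VCF_INFO_KEYS.items():
            value = variant.INFO.get(key)
            if value is None:
                continue
            if value is True:
                value = "true"
            row[column] = str(value)
        row.setdefault("too_frequent_in_population", "false")
        rows.append(row)
    return rows


def write_cohort_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write the minimal-VCF dialect (uncompressed, documented INFO keys).

    CHROM/POS carry the gene's chromosome and the leading c. position as a
    convenience; they are passthrough in this dialect, not genomic mappings.
    """
    from .resources import parse_c_position

    chrom = {Gene.BRCA1: "17", Gene.BRCA2: "13"}
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=13>",
        "##contig=<ID=17>",
    ]
    for key in VCF_INFO_KEYS:
        if key == "TOOFREQ":
            lines.append(f'##INFO=<ID={key},Number=0,Type=Flag,Description="cohort field">')
        else:
            lines.append(f'##INFO=<ID={key},Number=1,Type=String,Description="cohort field">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for record in records:
        row = record_to_row(record)
        info_parts = []
        for key, column in VCF_INFO_KEYS.items():
            value = row.get(column, "")
            if value == "" or value is None:
                continue
            if key == "TOOFREQ":
                if value == "true":
                    info_parts.append(key)
                continue
            info_parts.append(f"{key}={str(value).replace(' ', '_')}")
        pos = parse_c_position(record.hgvs_c) or 1
        ref, alt = "A", "C"
        if ">" in record.hgvs_c:
            tail = record.hgvs_c.split(">")
            if tail[0][-1:].isalpha() and tail[1][:1].isalpha():
                ref, alt = tail[0][-1], tail[1][0]
        lines.append(
            f"{chrom[record.gene]}\t{pos}\t{record.variant_id}\t{ref}\t{alt}\t.\t.\t"
            + (";".join(info_parts) or ".")
        )
    atomic_write_text(path, "\n".join(lines))


# -- reports -----------------------------------------------------------------

REPORT_COLUMNS = ["variant_id", "framework", "codes", "total_points", "classification"]


def write_report_tsv(reports: Sequence[ClassificationReport], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "framework": r.framework.value,
                "codes": ",".join(r.tokens),
                "total_points": r.total_points,
                "classification": r.classification.value,
            }
            for r in reports
        ],
        columns=REPORT_COLUMNS,
    )
    _df_to_tsv(df, path)


def write_report_json(reports: Sequence[ClassificationReport], path: str | Path) -> None:
    payload = [
        {
            "variant_id": r.variant_id,
            "framework": r.framework.value,
            "total_points": r.total_points,
            "classification": r.classification.value,
            "assignments": [
                {
                    "code": a.code,
                    "strength": a.strength.value,
                    "direction": a.direction.value,
                    "points": a.points,
                    "rationale": a.rationale,
                }
                for a in r.assignments
            ],
            "not_evaluated": list(r.not_evaluated),
        }
        for r in reports
    ]
    atomic_write_text(path, json.dumps(payload, indent=2))


def read_report_tsv(path: str | Path) -> list[ClassificationReport]:
    """Reconstruct reports (codes, points, class) from a report TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    reports = []
    for row in df.itertuples(index=False):
        framework = Framework(row.framework)
        assignments = tuple(
            EvidenceAssignment(code=c, strength=s, framework=framework)
            for c, s in (parse_token(t) for t in row.codes.split(",") if t)
        )
        reports.append(
            ClassificationReport(
                variant_id=row.variant_id,
                framework=framework,
                assignments=assignments,
                total_points=int(row.total_points),
                classification=Classification(row.classification),
            )
        )
    return reports


# -- comparison outputs ------------------------------------------------------


def write_comparison(
    comparison: CohortComparison,
    out_dir: str | Path,
    provenance: Optional[dict] = None,
) -> dict[str, Path]:
    """Write transitions TSV, deltas TSV and summary JSON; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transitions": out_dir / "transitions.tsv",
        "deltas": out_dir / "code_deltas.tsv",
        "summary": out_dir / "summary.json",
    }
    trans = pd.DataFrame(
        [
            {"from_class": frm, "to_class": to, "step": step, "count": count}
            for (frm, to, step), count in sorted(comparison.transition_counts.items())
        ],
        columns=["from_class", "to_class", "step", "count"],
    )
    _df_to_tsv(trans, paths["transitions"])

    deltas = pd.DataFrame(
        [
            {"code": token, "step": step, "added": added, "removed": removed}
            for (token, step), (added, removed) in sorted(comparison.code_deltas.items())
        ],
        columns=["code", "step", "added", "removed"],
    )
    _df_to_tsv(deltas, paths["deltas"])

    summary = {
        "n": comparison.n,
        "class_summary": comparison.summary,
        "provenance": provenance or {},
    }
    atomic_write_text(paths["summary"], json.dumps(summary, indent=2, sort_keys=True))
    return paths


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_provenance(
    config_checksum: str,
    seed: Optional[int] = None,
    table_paths: Sequence[str | Path] = (),
    spec_version_label: str = "",
) -> dict:
    return {
        "config_sha256": config_checksum,
        "seed": seed,
        "spec_version_label": spec_version_label,
        "table_sha256": {str(Path(p).name): file_checksum(p) for p in table_paths},
    }


@dataclass
class RunConfig:
    """Resolved CLI run configuration; every referenced path must exist."""

    framework: str
    cohort_path: Path
    tables_dir: Optional[Path]
    config_path: Optional[Path]
    out_dir: Path
    dialect: str = "tsv"
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.framework not in ("standard", "enigma", "both"):
            raise ValueError(f"unknown framework {self.framework!r}")
        if not Path(self.cohort_path).exists():
            raise FileNotFoundError(f"cohort file not found: {self.cohort_path}")
        if self.tables_dir is not None and not Path(self.tables_dir).is_dir():
            raise FileNotFoundError(f"resource-table directory not found: {self.tables_dir}")
        if self.config_path is not None and not Path(self.config_path).exists():
            raise FileNotFoundError(f"config file not found: {self.config_path}")
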