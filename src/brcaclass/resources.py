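"""Gene-specific resource tables consumed by the ENIGMA VCEP engine.

Miniature TSV snapshots mirror the structure of the spreadsheet resources a
curation panel publishes: clinically important domain intervals, exon-specific
PM5_PTC weights, PVS1 decision-tree outcomes, reviewed functional-assay
verdicts, and multifactorial combined likelihood-ratio scores.  Coordinates
are in transcript c. space, 1-based inclusive.

File names and headers (one TSV per table, tab-separated, '.' for empty):

- ``domains.tsv``:            gene  c_start  c_end  label
- ``exon_weights.tsv``:       gene  exon  strength        (strength may be ``no_code``)
- ``pvs1_outcomes.tsv``:      gene  consequence  site  code  strength  (code may be ``no_code``)
- ``assay_verdicts.tsv``:     gene  hgvs_c  verdict  code  strength
- ``multifactorial.tsv``:     gene  hgvs_c  combined_lr
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import CodeOutcome, Consequence, Gene, Strength, Verdict

_NO_CODE = "no_code"

#: Coding position of a purely exonic HGVS c. description, e.g. "c.8668C>A".
#: Descriptions with an intronic offset ("c.4096+4T>C") carry no coding position.
_C_POS_RE = re.compile(r"^c\.(\d+)(?![\d+-])")


def parse_c_position(hgvs_c: str) -> Optional[int]:
    """Leading coding-sequence position of an exonic variant, else None."""
    m = _C_POS_RE.match(hgvs_c.strip())
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class DomainInterval:
    """A (potentially) clinically important functional domain, c.-space inclusive."""

    c_start: int
    c_end: int
    label: str

    def contains(self, c_pos: int) -> bool:
        return self.c_start <= c_pos <= self.c_end


@dataclass
class GeneResourceTables:
    """All per-gene lookup tables, keyed on (gene, ...) tuples."""

    domains: dict[Gene, tuple[DomainInterval, ...]] = field(default_factory=dict)
    exon_weights: dict[tuple[Gene, int], CodeOutcome] = field(default_factory=dict)
    pvs1_outcomes: dict[tuple[Gene, Consequence, str], CodeOutcome] = field(
        default_factory=dict
    )
    assay_verdicts: dict[tuple[Gene, str], tuple[Verdict, CodeOutcome]] = field(
        default_factory=dict
    )
    multifactorial: dict[tuple[Gene, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, intervals in self.domains.items():
            ordered = sorted(intervals, key=lambda d: d.c_start)
            for a, b in zip(ordered, ordered[1:]):
                if b.c_start <= a.c_end:
                    raise ValueError(
                        f"{gene.value}: overlapping domain intervals {a} and {b}"
                    )
            self.domains[gene] = tuple(ordered)

    def in_domain(self, gene: Gene, c_pos: int) -> bool:
        return any(d.contains(c_pos) for d in self.domains.get(gene, ()))

    def domain_membership_from_hgvs(self, gene: Gene, hgvs_c: str) -> Optional[bool]:
        """Derive domain membership from the c. position; None when not derivable."""
        if gene not in self.domains:
            return None
        pos = parse_c_position(hgvs_c)
        if pos is None:
            return None
        return self.in_domain(gene, pos)


def _outcome(code: str, strength: str) -> CodeOutcome:
    if code in (_NO_CODE, "", "."):
        return CodeOutcome(code=None)
    return CodeOutcome(code=code, strength=Strength(strength))


def _read(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)


def load_resource_tables(directory: str | Path) -> GeneResourceTables:
    """Load all resource tables from a directory of TSV files.

    Missing files yield empty tables (the engine then logs not-evaluated for
    the corresponding lookups).  Conflicting duplicate rows for one variant
    in the assay table are rejected at load.
    """
    directory = Path(directory)
    tables = GeneResourceTables()

    p = directory / "domains.tsv"
    if p.exists():
        df = _read(p)
        domains: dict[Gene, list[DomainInterval]] = {}
        for row in df.itertuples(index=False):
            domains.setdefault(Gene(row.gene), []).append(
                DomainInterval(int(row.c_start), int(row.c_end), row.label)
            )
        tables = GeneResourceTables(domains={g: tuple(v) for g, v in domains.items()})

    p = directory / "exon_weights.tsv"
    if p.exists():
        for row in _read(p).itertuples(index=False):
            key = (Gene(row.gene), int(row.exon))
            tables.exon_weights[key] = (
                CodeOutcome(code=None)
                if row.strength == _NO_CODE
                else CodeOutcome(code="PM5", strength=Strength(row.strength))
            )

    p = directory / "pvs1_outcomes.tsv"
    if p.exists():
        for row in _read(p).itertuples(index=False):
            key = (Gene(row.gene), Consequence(row.consequence), str(row.site))
            tables.pvs1_outcomes[key] = _outcome(row.code, row.strength)

    p = directory / "assay_verdicts.tsv"
    if p.exists():
        for row in _read(p).itertuples(index=False):
            key = (Gene(row.gene), row.hgvs_c)
            entry = (Verdict(row.verdict), _outcome(row.code, row.strength))
            if key in tables.assay_verdicts and tables.assay_verdicts[key] != entry:
                raise ValueError(
                    f"assay_verdicts.tsv: conflicting rows for {key[0].value} {key[1]}"
                )
            tables.assay_verdicts[key] = entry

    p = directory / "multifactorial.tsv"
    if p.exists():
        for row in _read(p).itertuples(index=False):
            lr = float(row.combined_lr)
            if lr <= 0:
                raise ValueError(
                    f"multifactorial.tsv: combined_lr must be > 0 for {row.hgvs_c}"
                )
            tables.multifactorial[(Gene(row.gene), row.hgvs_c)] = lr

    return tables


def write_resource_tables(tables: GeneResourceTables, directory: str | Path) -> None:
    """Write all tables as TSVs with the documented headers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {"gene": g.value, "c_start": d.c_start, "c_end": d.c_end, "label": d.label}
            for g, ds in sorted(tables.domains.items())
            for d in ds
        ],
        columns=["gene", "c_start", "c_end", "label"],
    ).to_csv(directory / "domains.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "gene": g.value,
                "exon": exon,
                "strength": out.strength.value if out.code else _NO_CODE,
            }
            for (g, exon), out in sorted(tables.exon_weights.items())
        ],
        columns=["gene", "exon", "strength"],
    ).to_csv(directory / "exon_weights.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "gene": g.value,
                "consequence": cons.value,
                "site": site,
                "code": out.code or _NO_CODE,
                "strength": out.strength.value if out.code else ".",
            }
            for (g, cons, site), out in sorted(
                tables.pvs1_outcomes.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
            )
        ],
        columns=["gene", "consequence", "site", "code", "strength"],
    ).to_csv(directory / "pvs1_outcomes.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "gene": g.value,
                "hgvs_c": hgvs,
                "verdict": verdict.value,
                "code": out.code or _NO_CODE,
                "strength": out.strength.value if out.code else ".",
            }
            for (g, hgvs), (verdict, out) in sorted(tables.assay_verdicts.items())
        ],
        columns=["gene", "hgvs_c", "verdict", "code", "strength"],
    ).to_csv(directory / "assay_verdicts.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"gene": g.value, "hgvs_c": hgvs, "combined_lr": lr}
            for (g, hgvs), lr in sorted(tables.multifactorial.items())
        ],
        columns=["gene", "hgvs_c", "combined_lr"],
    ).to_csv(directory / "multifactorial.tsv", sep="\t", index=False)
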