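"""Configuration: threshold-band tables, engine parameters and class boundaries.

All numeric cutoffs are data, not code: the package ships a default YAML
(``brcaclass/data/default_config.yaml``) and any subset of it can be
overridden from a user YAML file.  See that file for the band-table schema.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .model import Framework, Strength
from .points import ClassBoundaries, PointScale


@dataclass(frozen=True)
class Band:
    """One first-match threshold entry: ``score >= t`` (ge) or ``score <= t`` (le)."""

    op: str
    threshold: float
    code: str
    strength: Strength

    def matches(self, value: float) -> bool:
        return value >= self.threshold if self.op == "ge" else value <= self.threshold


def validate_bands(bands: Sequence[Band], name: str = "bands") -> None:
    """Enforce disjoint, ordered bands: ge thresholds strictly decreasing,
    le thresholds strictly increasing, every le below every ge."""
    ge = [b.threshold for b in bands if b.op == "ge"]
    le = [b.threshold for b in bands if b.op == "le"]
    for b in bands:
        if b.op not in ("ge", "le"):
            raise ValueError(f"{name}: unknown op {b.op!r}")
    if any(a <= b for a, b in zip(ge, ge[1:])):
        raise ValueError(f"{name}: 'ge' thresholds must be strictly decreasing")
    if any(a >= b for a, b in zip(le, le[1:])):
        raise ValueError(f"{name}: 'le' thresholds must be strictly increasing")
    if ge and le and max(le) >= min(ge):
        raise ValueError(f"{name}: benign ('le') and pathogenic ('ge') zones overlap")


def band_lookup(value: float, bands: Sequence[Band]) -> Optional[tuple[str, Strength]]:
    """First matching band, or None when the value is uninformative."""
    for b in bands:
        if b.matches(value):
            return b.code, b.strength
    return None


def _parse_bands(entries, name: str) -> tuple[Band, ...]:
    bands = tuple(
        Band(
            op=e["op"],
            threshold=float(e["threshold"]),
            code=e["code"],
            strength=Strength(e["strength"]),
        )
        for e in entries
    )
    validate_bands(bands, name)
    return bands


@dataclass(frozen=True)
class StandardEngineConfig:
    """Parameters of the standard ACMG/AMP + SVI engine."""

    pm2_max_allele_count: int = 5
    ps4_min_probands: int = 5
    bp7_enabled: bool = True
    splice_negative_max: float = 0.10
    revel_bands: tuple[Band, ...] = ()


@dataclass(frozen=True)
class EnigmaEngineConfig:
    """Parameters of the ENIGMA BRCA1/BRCA2 VCEP engine."""

    spliceai_pp3_min: float = 0.20
    spliceai_bp4_max: float = 0.10
    bayesdel_bands: tuple[Band, ...] = ()
    lr_bands_pp4_bp5: tuple[Band, ...] = ()
    lr_bands_pp1_bs4: tuple[Band, ...] = ()
    bp5_cooccurrence_policy: str = "withhold_all"
    splice_pp3_precedence: bool = True

    def __post_init__(self) -> None:
        if self.bp5_cooccurrence_policy not in ("withhold_pair", "withhold_all", "allow"):
            raise ValueError(
                f"unknown bp5_cooccurrence_policy {self.bp5_cooccurrence_policy!r}"
            )
        for b in self.bayesdel_bands:
            if b.code.startswith("B") and b.strength is not Strength.SUP:
                raise ValueError(
                    "BayesDel-derived benign evidence is restricted to supporting strength"
                )


@dataclass(frozen=True)
class AppConfig:
    """Full resolved configuration: point scale plus both engine configs."""

    point_scale: PointScale
    standard: StandardEngineConfig
    enigma: EnigmaEngineConfig
    spec_version_label: str = "ENIGMA v1.1.0"
    raw: dict = field(default_factory=dict, compare=False)

    def checksum(self) -> str:
        """Stable hash of the effective configuration, for run provenance."""
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _build(raw: dict) -> AppConfig:
    bounds = {
        Framework(fw): ClassBoundaries(**vals)
        for fw, vals in raw["point_scale"]["boundaries"].items()
    }
    std = raw["standard"]
    eng = raw["enigma"]
    return AppConfig(
        point_scale=PointScale(boundaries=bounds),
        standard=StandardEngineConfig(
            pm2_max_allele_count=int(std["pm2_max_allele_count"]),
            ps4_min_probands=int(std["ps4_min_probands"]),
            bp7_enabled=bool(std["bp7_enabled"]),
            splice_negative_max=float(std["splice_negative_max"]),
            revel_bands=_parse_bands(std["revel_bands"], "revel_bands"),
        ),
        enigma=EnigmaEngineConfig(
            spliceai_pp3_min=float(eng["spliceai_pp3_min"]),
            spliceai_bp4_max=float(eng["spliceai_bp4_max"]),
            bayesdel_bands=_parse_bands(eng["bayesdel_bands"], "bayesdel_bands"),
            lr_bands_pp4_bp5=_parse_bands(eng["lr_bands_pp4_bp5"], "lr_bands_pp4_bp5"),
            lr_bands_pp1_bs4=_parse_bands(eng["lr_bands_pp1_bs4"], "lr_bands_pp1_bs4"),
            bp5_cooccurrence_policy=eng["bp5_cooccurrence_policy"],
            splice_pp3_precedence=bool(eng["splice_pp3_precedence"]),
        ),
        spec_version_label=raw.get("spec_version_label", "ENIGMA v1.1.0"),
        raw=raw,
    )


def default_raw_config() -> dict:
    text = resources.files("brcaclass.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: Optional[str | Path] = None) -> AppConfig:
    """Load the default configuration, optionally deep-merged with a YAML file."""
    raw = default_raw_config()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        raw = _deep_merge(raw, override)
    return _build(raw)


DEFAULT_CONFIG = load_config()
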