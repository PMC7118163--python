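"""Pipeline configuration: every threshold of the discovery cascade in one
validated record, loadable from YAML and mirrorable by CLI flags."""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


class AnMode(enum.Enum):
    """How the reference allele-number denominator is chosen.

    GLOBAL uses 2 x (reference individuals) for every gene; PER_GENE uses
    the maximum AN over each gene's qualifying variants, which tracks
    per-gene coverage in the reference call set.
    """

    GLOBAL = "global"
    PER_GENE = "per_gene"


class FoldCheckMode(enum.Enum):
    """Scope of the >= fold-enrichment prioritisation rule.

    PRIMARY: risk ratio against the primary reference population only.
    ALL_OUTBRED: additionally require that no major outbred sub-population
    has a combined carrier frequency exceeding case_freq / fold.
    """

    PRIMARY = "primary"
    ALL_OUTBRED = "all_outbred"


@dataclass
class DiscoveryConfig:
    """Thresholds and modes for one discovery run.

    Defaults are the published cascade: rarity at MAF <= 0.005 on both the
    total population and the outbred popmax; prioritisation at >= 3 case
    carriers, >= 3-fold enrichment and a Benjamini-Hochberg threshold at
    FDR 0.3; QC review flags at quality < 500, depth < 60, alt fraction
    < 0.35 or non-bidirectional calls.
    """

    maf_threshold: float = 0.005
    fdr: float = 0.3
    fold_threshold: float = 3.0
    min_carriers: int = 3
    p_report_cut: float = 0.01
    min_quality_score: float = 500.0
    min_read_depth: int = 60
    min_alt_fraction: float = 0.35
    drop_flagged: bool = False
    an_mode: AnMode = AnMode.GLOBAL
    fold_check_mode: FoldCheckMode = FoldCheckMode.ALL_OUTBRED
    global_ref_an: int = 118_190
    annotation_field: str = "CSQ"
    reference_filter_flags: tuple[str, ...] = ("InbreedingCoeff", "AC0", "RF")

    def __post_init__(self) -> None:
        if isinstance(self.an_mode, str):
            self.an_mode = AnMode(self.an_mode)
        if isinstance(self.fold_check_mode, str):
            self.fold_check_mode = FoldCheckMode(self.fold_check_mode)
        if not 0.0 < self.fdr < 1.0:
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")
        for name in (
            "maf_threshold",
            "fold_threshold",
            "p_report_cut",
            "min_quality_score",
            "min_alt_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_carriers <= 0 or self.min_read_depth <= 0:
            raise ValueError("min_carriers and min_read_depth must be positive")
        if self.global_ref_an <= 0:
            raise ValueError("global_ref_an must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DiscoveryConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "reference_filter_flags" in raw:
            raw["reference_filter_flags"] = tuple(raw["reference_filter_flags"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["an_mode"] = self.an_mode.value
        d["fold_check_mode"] = self.fold_check_mode.value
        d["reference_filter_flags"] = list(self.reference_filter_flags)
        return d
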