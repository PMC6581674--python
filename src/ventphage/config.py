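"""Pipeline configuration: every module threshold in one YAML-round-trippable object."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .caller import CallerParams


@dataclass
class PipelineConfig:
    # inputs
    fasta: str = ""
    gff: str = ""
    recruitment: str = ""
    mda: str = ""
    transcripts: str = ""
    outdir: str = "ventphage_out"
    seed: int = 0

    # marker_scan
    extra_keywords: list[str] = field(default_factory=list)
    extra_exclusions: list[str] = field(default_factory=list)

    # composition_anomaly
    skew_window: int = 1000
    skew_step: int = 500
    skew_k: float = 3.0
    tetramer_window: int = 5000
    tetramer_step: int = 1000
    tetramer_k: float = 2.0

    # prophage_caller
    min_markers: int = 3
    marker_window_bp: int = 10_000
    trna_link_bp: int = 5_000
    min_region_len: int = 5_000

    # recruitment_islands
    island_id_threshold: float = 75.0
    island_window: int = 1000
    island_step: int = 500
    island_cov_threshold: float = 0.50
    island_min_len: int = 2000

    # mda_diagnostics
    mda_outlier_threshold: float = 2.5

    # ani_clock
    ani_method: str = "global"
    myr_per_percent: float = 50.0

    # expression_fpkm
    min_aa_identity: float = 95.0

    def caller_params(self) -> CallerParams:
        return CallerParams(
            min_markers=self.min_markers,
            marker_window_bp=self.marker_window_bp,
            trna_link_bp=self.trna_link_bp,
            min_region_len=self.min_region_len,
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
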