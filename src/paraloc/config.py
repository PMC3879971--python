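"""Pipeline configuration: thresholds, windows and paths in one
serialisable structure (YAML on disk; CLI flags override file values)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    # inputs
    fasta: Optional[str] = None
    id_map: Optional[str] = None
    alignments: Optional[str] = None        # precomputed BLAST tabular
    alignment_lengths: Optional[str] = None  # sidecar for the above
    predictions: Optional[str] = None
    predictions_dialect: str = "simple"
    species_id: str = "species"
    group_label: str = "fungi"
    genetic_code: int = 1

    # pair-detection thresholds
    max_e_value: float = 1e-3
    min_bsr: float = 0.33
    min_coverage: float = 0.8
    long_cutoff_length: int = 150
    long_cutoff_identity: float = 30.0
    localization_min_identity: float = 50.0

    # clustering
    gene_conversion_max_matches: int = 5
    apply_gene_conversion_filter: bool = False

    # divergence / survival
    omega_threshold: float = 1.5
    ks_windows: list = field(
        default_factory=lambda: [
            [0.0, 0.05], [0.0, 0.1], [0.0, 0.25], [0.0, 0.5], [0.0, 0.75], [0.0, 1.0]
        ]
    )
    ks_min: float = 0.0  # set to 0.01 for the high-similarity sensitivity run
    ties_method: str = "efron"

    # NTP
    ntp_window_length: int = 60
    complete_min_gap: int = 30

    # misc
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        if not (0 < self.min_bsr <= 1):
            raise ValueError("min_bsr must lie in (0, 1]")
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must lie in (0, 1]")
        if self.max_e_value <= 0:
            raise ValueError("max_e_value must be positive")
        if self.ties_method not in ("efron", "breslow"):
            raise ValueError("ties_method must be 'efron' or 'breslow'")
        for lo, hi in self.ks_windows:
            if not lo < hi:
                raise ValueError(f"bad Ks window ({lo}, {hi})")
        if self.ks_min < 0:
            raise ValueError("ks_min must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as out:
            yaml.safe_dump(asdict(self), out, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg
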