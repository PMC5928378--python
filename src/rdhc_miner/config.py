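"""Pipeline configuration: one structured document holding every tunable.

Defaults carry the published study parameters (95% clustering identity,
0.050 Da fragment / 10 ppm parent tolerances) alongside the package's own
topology and classification defaults.  Configs round-trip through YAML
unchanged, and every pipeline run writes its effective config next to its
outputs for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .seqio import RdhcError


@dataclass
class PipelineConfig:
    # motif scanning
    fmn_motif: str = "FMN_CONSENSUS"
    cx3cp_motif: str = "CX3CP"
    # clustering
    cluster_threshold: float = 0.95
    identity_denominator: str = "shorter"
    # topology
    topology_window: int = 19
    tm_threshold: float = 1.6
    tm_min_len: int = 15
    tm_max_len: int = 30
    tm_merge_gap: int = 3
    n_term_side: str = "auto"  # 'auto' (positive-inside), 'I', or 'O'
    # family classification
    min_tm: int = 3
    min_cx3cp: int = 2
    # surfaceome
    exposure_threshold: float = 1.0
    max_missed_cleavages: int = 0
    # mass spectrometry
    frag_tol_da: float = 0.050
    parent_tol_ppm: float = 10.0
    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise RdhcError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise RdhcError("config YAML must be a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())
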