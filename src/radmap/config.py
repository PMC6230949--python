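"""Run configuration: every stage parameter with paper-style defaults,
YAML round-trip, unknown keys rejected."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


def _default_hotspots() -> list[list]:
    # three 100 kb hotspots at 100 cM/Mb on the first three chromosomes
    return [
        ["chr01", 1_000_000, 1_100_000, 100.0],
        ["chr02", 2_500_000, 2_600_000, 100.0],
        ["chr03", 4_000_000, 4_100_000, 100.0],
    ]


def _default_coldspots() -> list[list]:
    # one 2 Mb zero-recombination segment
    return [["chr04", 1_500_000, 3_500_000]]


@dataclass
class RunConfig:
    # genome / simulation scale (scaled down so the pipeline runs in minutes)
    n_chrom: int = 19
    chrom_len: int = 5_000_000
    gene_density_profile: str = "sinusoidal"
    mean_gene_density_per_100kb: float = 2.82
    gc: float = 0.344
    scaffold_mean_len: int = 1_000_000
    # crossover landscape
    background_rate: float = 5.5
    hotspots: list = field(default_factory=_default_hotspots)
    coldspots: list = field(default_factory=_default_coldspots)
    # cross design
    markers_per_mb: float = 30.0
    n_progeny: int = 184
    error_rate: float = 0.005
    missing_rate: float = 0.15
    mean_depth: float = 20.0
    decoys_per_mb: float = 2.0
    # marker calling
    min_parent_depth: int = 5
    het_min_minor_frac: float = 0.25
    min_depth: int = 3
    depth_rule: str = "site"
    max_missing: float = 0.5
    dup_identity: float = 0.95
    min_shared: int = 100
    # linkage map
    max_rf: float = 0.4
    min_lod: float = 10.0
    # anchoring
    gap: int = 100
    # landscape
    hotspot_fold: float = 10.0
    min_coldspot_mb: float = 1.0
    density_threshold: float = 3.0
    # run control
    emit_sequences: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
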