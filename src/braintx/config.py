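"""Run configuration: one root seed, every statistical threshold of the
pipeline, and the desk-scale simulation sizes."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Thresholds default to the study's values: permutation alpha 0.001 with
    10,000 permutations, BH q 0.001 for the imaging contrasts, DE alpha
    0.01, STRING score threshold 900, enrichment filters (p<0.01, count>=3,
    factor>1.5).
    """

    seed: int = 0
    alpha_assoc: float = 0.001
    n_perm: int = 10_000
    alpha_de: float = 0.01
    bh_q: float = 0.001
    string_threshold: int = 900
    enrich_alpha: float = 0.01
    enrich_min_count: int = 3
    enrich_min_factor: float = 1.5
    sexdiff_alpha: float = 0.01
    grid_alpha: float = 0.01
    # simulation sizes (desk scale)
    n_sites: int = 200
    n_genes: int = 2000
    n_class1: int = 150
    n_class2: int = 200
    n_per_group: int = 100
    corr_strength: float = 0.8
    effect_amplitude: float = 0.5
    noise_sd: float = 1.0
    n_per_cell: int = 4
    network_nodes: int = 2000
    hub_fraction: float = 0.05
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha_assoc", "alpha_de", "bh_q", "enrich_alpha",
                     "sexdiff_alpha", "grid_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
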