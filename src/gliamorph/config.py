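"""Analysis configuration: one object holding every tunable constant.

The defaults encode the standard analysis: human species mode (master
mask from HLA-DR + CD68 + Iba1; mouse uses Iba1 only), FDR q = 0.01,
correlation strength cutoffs 0.4/0.7, clustering at resolution 1.0 with
k = floor(sqrt(N)) and 7,340 cells per group. Configs round-trip through
YAML for reproducible runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .morphometry import MorphParams

HUMAN_MASTER_CHANNELS = ("hladr", "cd68", "iba1")
MOUSE_MASTER_CHANNELS = ("iba1",)


@dataclass
class ThresholdParams:
    adaptive_window_um: float = 20.0
    adaptive_offset: float = 20.0
    min_object_area_um2: float = 5.0
    ptdp43_clip_min: float = 400.0


@dataclass
class ClusterParams:
    per_group_n: int = 7340
    resolution: float = 1.0
    knn_rule: str = "sqrt_floor"
    mutual: bool = False
    standardize: bool = False
    include_hladr: bool = True
    pseudocount: float = 1.0
    seed: int = 20250221


@dataclass
class StatsParams:
    fdr_q: float = 0.01
    moderate_r: float = 0.4
    strong_r: float = 0.7
    alpha: float = 0.05


@dataclass
class AnalysisConfig:
    species: str = "human"                    # "human" | "mouse"
    pixel_size_um: float = 0.32
    channel_map: dict[str, int] = field(default_factory=dict)  # marker -> TIFF page
    morph: MorphParams = field(default_factory=MorphParams)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    stats: StatsParams = field(default_factory=StatsParams)

    @property
    def master_channels(self) -> tuple[str, ...]:
        return HUMAN_MASTER_CHANNELS if self.species == "human" else MOUSE_MASTER_CHANNELS

    def validate(self) -> None:
        if self.species not in {"human", "mouse"}:
            raise ValueError("species must be 'human' or 'mouse'")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.channel_map:
            for ch in self.master_channels + ("iba1",):
                if ch not in self.channel_map:
                    raise ValueError(f"channel map lacks required channel {ch!r}")
        if not 0 < self.stats.moderate_r < self.stats.strong_r <= 1:
            raise ValueError("need 0 < moderate_r < strong_r <= 1")
        if self.cluster.knn_rule not in {"sqrt_floor", "fixed"}:
            raise ValueError("knn_rule must be 'sqrt_floor' or 'fixed'")
        self.morph.validate()

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key, sub in (("morph", MorphParams), ("threshold", ThresholdParams),
                         ("cluster", ClusterParams), ("stats", StatsParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
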