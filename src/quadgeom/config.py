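"""Analysis configuration: every geometric threshold in one place.

Thresholds are explicit and serializable so a run can be reproduced from
its manifest and so sensitivity scans (threshold perturbation) are easy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    # quartet detection / core assembly
    hbond_max: float = 3.5          # donor-acceptor heavy-atom cutoff, A
    planarity_max: float = 1.0      # quartet plane RMS cutoff, A
    stack_window: tuple[float, float] = (2.8, 4.5)  # layer separation, A
    # base orientation
    stack_lateral_max: float = 2.5  # ring-centroid lateral offset, A
    stack_axial_window: tuple[float, float] = (3.0, 4.2)  # pi-stack rise, A
    elevation_cut: float = 30.0     # up/down vs out, degrees
    plane_angle_max: float = 30.0   # ring-plane angle for stacking, degrees
    # ions
    radial_max: float = 2.5         # channel-ion distance to axis, A
    # clustering
    k_max: int = 10
    seed: int = 0
    stride: int = 1                 # frame stride for transition counting
    # flexibility
    normalization: str = "zscore"   # zscore | minmax
    atom_scope: str = "all"         # all | base_only
    # cleft reporting: pairs of sequential (5'->3') nucleotide positions
    cleft_pairs: tuple[tuple[int, int], ...] = ((8, 20),)

    def __post_init__(self):
        positives = {
            "hbond_max": self.hbond_max,
            "planarity_max": self.planarity_max,
            "stack_lateral_max": self.stack_lateral_max,
            "elevation_cut": self.elevation_cut,
            "plane_angle_max": self.plane_angle_max,
            "radial_max": self.radial_max,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stack_window"] = list(d["stack_window"])
        d["stack_axial_window"] = list(d["stack_axial_window"])
        d["cleft_pairs"] = [list(p) for p in d["cleft_pairs"]]
        return d

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        for key in ("stack_window", "stack_axial_window"):
            if key in data:
                data[key] = tuple(data[key])
        if "cleft_pairs" in data:
            data["cleft_pairs"] = tuple(tuple(p) for p in data["cleft_pairs"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, seed=seed)
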