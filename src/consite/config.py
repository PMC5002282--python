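"""Run configuration: every tunable of the prediction pipeline in one place.

Defaults follow the published operating point of the method: 0.5 A grid,
10 A energy cutoff, 6 A conservation gate, cluster cap P_num = 500 with
0.1 kcal/mol threshold steps and 1 A linkage, and score weights
(w1, w2, w3) = (1, -0.05, 9).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .scoring import Weights


@dataclass
class RunConfig:
    spacing: float = 0.5
    margin: float = 8.0
    cutoff: float = 10.0
    conservation_cutoff: float = 6.0
    p_num: int = 500
    threshold_step: float = 0.1
    linkage_radius: float = 1.0
    prune_e_max: float = 0.0
    top_k: int = 3
    weights: Weights = field(default_factory=Weights)
    precision_threshold: float = 25.0
    s_residue_threshold: float = 25.0
    overlap_radius: float = 1.6
    contact_radius: float = 5.0
    truth_radius: float = 4.0
    background: str = "blosum62"
    dedup: bool = True
    ignore_hydrogens: bool = False
    strict_conservation: bool = False
    cross_term_gated: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = [self.weights.w1, self.weights.w2, self.weights.w3]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "weights" in d and not isinstance(d["weights"], Weights):
            d["weights"] = Weights(*d["weights"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
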