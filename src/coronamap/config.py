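"""Run configuration: every tunable default in one versioned, hashable place.

A prediction is reproducible bit-for-bit from the input structure plus this
configuration; the config hash is embedded in every output so published
predictions can be traced to the exact parameter set that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

CONFIG_VERSION = 1


@dataclass
class RunConfig:
    # SASA
    probe_radius: float = 1.4        # Å, water probe
    n_sphere_points: int = 960       # golden-spiral quadrature size
    # surface grid
    grid_spacing: float = 1.5        # Å
    shell_inner: float = 1.4         # Å from the vdW surface
    shell_outer: float = 4.0         # Å
    neighbor_cutoff: float = 8.0     # Å, residue-to-grid-point averaging
    weighting: str = "uniform"       # or "inverse-distance"
    # thresholding / patches
    threshold_percentile: float = 75.0
    threshold_absolute: float | None = None
    adjacency_factor: float = 1.7320508075688772  # sqrt(3): 26-neighbourhood
    min_patch_size: int = 3
    # occlusion call
    contact_cutoff: float = 6.0      # Å
    occlusion_fraction: float = 0.5
    # chemistry policies
    disulfide_policy: str = "serine"
    sg_cutoff: float = 2.5           # Å, SG-SG disulfide detection
    keep_het: bool = True
    model_index: int = 0
    # randomness (synthetic data only; the prediction itself is deterministic)
    seed: int = 20221127
    version: int = CONFIG_VERSION

    @property
    def adjacency(self) -> float:
        return self.adjacency_factor * self.grid_spacing

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
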