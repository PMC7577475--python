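"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]

K_MIN, K_MAX = 5, 69


@dataclass
class RunConfig:
    """Validated pipeline settings; defaults follow the reference setup.

    ``l2_strength`` is the L2 penalty weight (larger = stronger penalty,
    C = 1/l2_strength in sklearn terms).
    """

    k: int = 45
    n_clusters: int = 3
    contact_threshold: float = 8.0
    split_fraction: float = 0.5
    l2_strength: float = 1.0
    seed: int = 0
    n_families: int = 40
    n_filter_families: int = 10
    p_det: float = 0.5
    signal: float = 0.4
    sigma: float = 0.1
    background: float = 0.002
    n_spurious_stripes: int = 2
    meff: float = 300.0
    calibration_bins: int = 10
    ppv_n: int = 100
    exclude_junction: int = 0

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError(f"window size k must be odd, got {self.k}")
        if not (K_MIN <= self.k <= K_MAX):
            raise ValueError(f"window size k must be in [{K_MIN}, {K_MAX}], got {self.k}")
        if self.contact_threshold <= 0:
            raise ValueError("contact threshold must be positive")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split fraction must be in (0, 1)")
        if self.l2_strength <= 0:
            raise ValueError("l2_strength must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    @property
    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
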