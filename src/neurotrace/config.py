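"""Run configuration: defaults, YAML loading, and range validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults.

    Distances suffixed ``_sx`` are in voxel units (multiples of s_x);
    they are converted to physical units where a stack is in hand.
    """

    voxel_size: tuple = (1.0, 1.0, 1.0)
    seed_threshold: float = 0.3
    seed_min_separation_sx: float = 10.0
    smoothing_sigma: float = 1.0
    d_max_sx: float = 15.0
    stop_fraction: float = 0.2
    alpha_r: float = 1.0
    alpha_R: float = 1.0
    beta: float = 0.5
    rel_tol: float = 1e-8
    max_iter: int = 100
    cluster_threshold_sx: float = 10.0
    kappa: float = 1.0
    C: float = 2.0**20
    T_conf: float = 1.0
    d: float = 0.25
    h: float = 10.0
    min_terminal_len: float = 12.0
    min_intensity: float = 0.12
    rng_seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        checks = [
            ("seed_threshold", 0 < self.seed_threshold < 1, "(0, 1)"),
            ("seed_min_separation_sx", self.seed_min_separation_sx > 0, "> 0"),
            ("d_max_sx", self.d_max_sx > 0, "> 0"),
            ("stop_fraction", 0 <= self.stop_fraction < 1, "[0, 1)"),
            ("alpha_r", self.alpha_r > 0, "> 0"),
            ("alpha_R", self.alpha_R > 0, "> 0"),
            ("beta", self.beta > 0, "> 0"),
            ("rel_tol", 0 < self.rel_tol < 1, "(0, 1)"),
            ("cluster_threshold_sx", self.cluster_threshold_sx > 0, "> 0"),
            ("kappa", self.kappa >= 0, ">= 0"),
            ("C", self.C > 0, "> 0"),
            ("T_conf", self.T_conf > 0, "> 0"),
            ("d", self.d > 0, "> 0"),
            ("h", self.h > 0, "> 0"),
            ("min_terminal_len", self.min_terminal_len >= 0, ">= 0"),
            ("min_intensity", 0 <= self.min_intensity <= 1, "[0, 1]"),
            ("voxel_size", all(s > 0 for s in self.voxel_size), "all > 0"),
        ]
        for name, ok, rng in checks:
            if not ok:
                raise ValueError(
                    f"parameter {name} = {getattr(self, name)} outside valid range {rng}"
                )

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        data = {}
        if path is not None:
            with open(path) as f:
                data = yaml.safe_load(f) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if isinstance(cfg.voxel_size, list):
            cfg.voxel_size = tuple(cfg.voxel_size)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        text = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        from neurotrace import __version__

        return {"version": __version__, "config_hash": self.config_hash(),
                "rng_seed": self.rng_seed}
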