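"""Declarative run configuration (YAML) and run metadata.

A run is fully described by one YAML document; command-line flags may
override individual fields.  Everything except the Z-matrix path and the
torsion names has a default, and every run writes a metadata file
(config hash, seed, package version) next to its outputs so results can
be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .search import SearchConfig


@dataclass
class RunConfig:
    zmatrix: str = ""
    torsion_names: list[str] | None = None
    preconditioned: list[list[float]] | None = None   # default: sp3 {180,60,300} per torsion
    has_sym_plane: bool = False
    backend: str = "threefold"                        # fixture-library backend name
    backend_params: dict = field(default_factory=dict)
    batches: list[dict] = field(default_factory=list)
    d: float = 30.0
    eps_red: float = 3.0
    eps_freq: float = 5.0
    k_bond: float = 1.3
    grad_tol: float = 1e-6
    seed: int = 0
    temperatures: list[float] = field(default_factory=lambda: [298.15])
    lambda_zpe: float = 1.0
    output_dir: str = "torsearch_run"

    def __post_init__(self):
        for batch in self.batches:
            if float(batch.get("d", self.d)) <= 0:
                raise ValueError("batch hypercube half-edge d must be positive")
        if any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be strictly positive")

    def search_config(self) -> SearchConfig:
        return SearchConfig(d=self.d, eps_red=self.eps_red, eps_freq=self.eps_freq,
                            k_bond=self.k_bond, grad_tol=self.grad_tol,
                            has_sym_plane=self.has_sym_plane, seed=self.seed,
                            batches=[dict(b) for b in self.batches])

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_metadata(out_dir, cfg: RunConfig) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.digest(), "seed": cfg.seed,
            "torsearch_version": __version__,
            "config": asdict(cfg)}
    path = out_dir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path
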