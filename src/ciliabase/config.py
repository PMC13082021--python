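"""Run configuration: one YAML document with per-stage parameter blocks.

Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults), and every stage's defaults are materialized so the persisted
config next to a run's outputs is a complete record of the parameters used.
One global seed feeds every stage; module substreams are derived from it
deterministically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class VotingBlock:
    window: float = 24.0
    use_3d_neighbors: bool = False
    k: int = 15
    max_iter: int = 50


@dataclass
class LatticeBlock:
    bandwidth: float = 4.0
    n_doublets: int = 9


@dataclass
class XlBlock:
    fdr_a: float = 0.01
    fdr_b: float = 0.05
    cutoff: float = 35.0
    strip_isoform: bool = True


@dataclass
class UexmBlock:
    reference: float = 250.0
    threshold_frac: float = 0.5
    channel: str = "gt335"


@dataclass
class SyntheticBlock:
    label_noise: float = 0.2
    jitter_sigma: float = 1.0
    noise_sigma: float = 0.5
    missing_fraction: float = 0.0


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)
    voting: VotingBlock = field(default_factory=VotingBlock)
    lattice: LatticeBlock = field(default_factory=LatticeBlock)
    xl: XlBlock = field(default_factory=XlBlock)
    uexm: UexmBlock = field(default_factory=UexmBlock)
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)

    _BLOCKS = {
        "voting": VotingBlock,
        "lattice": LatticeBlock,
        "xl": XlBlock,
        "uexm": UexmBlock,
        "synthetic": SyntheticBlock,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        cfg = cls()
        scalar_keys = {"seed", "output_dir", "log_level", "inputs"}
        unknown = set(data) - scalar_keys - set(cls._BLOCKS)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in scalar_keys:
            if key in data:
                setattr(cfg, key, data[key])
        for name, block_cls in cls._BLOCKS.items():
            if name not in data:
                continue
            block_data = data[name] or {}
            valid = {f.name for f in dataclasses.fields(block_cls)}
            bad = set(block_data) - valid
            if bad:
                raise ConfigError(f"unknown key(s) in '{name}' block: {sorted(bad)}")
            setattr(cfg, name, block_cls(**block_data))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "log_level": self.log_level,
            "inputs": dict(self.inputs),
        }
        for name in self._BLOCKS:
            out[name] = dataclasses.asdict(getattr(self, name))
        return out

    def persist(self, directory) -> Path:
        """Write the fully resolved config next to a run's outputs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "run_config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    def substream(self, stage: str) -> int:
        """Deterministic per-stage seed (< 2**31) derived from the global seed."""
        import zlib

        import numpy as np

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31))
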