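"""Experiment configuration: YAML round trip, run manifests, seeding."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .losses import LossWeights
from .training import VariantConfig

__all__ = ["ExperimentConfig", "substream", "write_run_manifest"]

PACKAGE_VERSION = "0.1.0"


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, deterministic random substream of a single global seed.

    Different names yield independent streams, so adding a consumer (say,
    augmentation) does not perturb another (phantom generation).
    """
    tag = (int(seed) * 2654435761 + zlib.crc32(name.encode())) % (2 ** 31 - 1)
    return np.random.default_rng(tag)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one run."""

    seed: int = 0
    out_dir: str = "runs/exp"
    image_size: int = 64
    checkpoint_every: int = 1000
    # dataset: synthetic parameters or a manifest directory
    dataset_dir: str | None = None
    n_subjects: int = 250
    slices_per_subject: int = 4
    pair_fraction: float = 0.43
    variant: VariantConfig = field(default_factory=VariantConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        vd = dict(d.pop("variant", {}))
        wd = dict(vd.pop("weights", {}))
        for key in ("gen_filters", "disc_filters"):
            if key in vd and vd[key] is not None:
                vd[key] = tuple(vd[key])
        variant = VariantConfig(weights=LossWeights(**wd), **vd)
        return cls(variant=variant, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def write_run_manifest(out_dir: str | Path, config: ExperimentConfig) -> Path:
    """Record config hash, seed and package version next to run outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": PACKAGE_VERSION,
        "config": config.to_dict(),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
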