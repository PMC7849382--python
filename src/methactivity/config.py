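"""Run configuration with the published defaults, plus seed fan-out."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed from the single run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass
class RunConfig:
    flank: int = 5000
    bin_size: int = 500
    n_variable_promoters: int = 5000
    pca_d: int = 10
    knn_k: int = 20
    include_self: bool = True
    subsample_n: int = 100_000
    rf_trees: int = 500
    rf_frac: float = 0.8
    en_alpha: float = 0.5
    en_folds: int = 10
    cnn_filters: int = 50
    cnn_kernel: int = 5
    cnn_pool: int = 4
    cnn_dropout: float = 0.2
    cnn_patience: int = 10
    cnn_dense_units: int = 64
    cnn_max_epochs: int = 200
    ensemble_rule: str = "unweighted"
    seed: int = 0

    @property
    def n_bins(self) -> int:
        if (2 * self.flank) % self.bin_size != 0:
            raise ValueError("bin_size must divide 2 * flank")
        return 2 * self.flank // self.bin_size

    def component_params(self) -> dict:
        return {
            "random_forest": {
                "n_trees": self.rf_trees,
                "sample_frac": self.rf_frac,
                "seed": derive_seed(self.seed, "rf"),
            },
            "elastic_net": {
                "alpha_mix": self.en_alpha,
                "n_cv_folds": self.en_folds,
                "seed": derive_seed(self.seed, "en"),
            },
            "cnn": {
                "n_filters": self.cnn_filters,
                "kernel": self.cnn_kernel,
                "pool": self.cnn_pool,
                "dropout": self.cnn_dropout,
                "patience": self.cnn_patience,
                "dense_units": self.cnn_dense_units,
                "max_epochs": self.cnn_max_epochs,
                "seed": derive_seed(self.seed, "cnn"),
            },
        }

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
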