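"""Run configuration: every open default lives here, serializable to YAML."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .network import PriorConfig
from .reporting import BandDefinition, DEFAULT_BANDS

__all__ = ["GridConfig", "VLConfig", "SimConfig", "Config"]


@dataclass(frozen=True)
class GridConfig:
    fmin: float = 1.0
    fmax: float = 100.0
    df: float = 1.0

    def frequencies(self) -> np.ndarray:
        return np.arange(self.fmin, self.fmax + 0.5 * self.df, self.df, dtype=float)


@dataclass(frozen=True)
class VLConfig:
    max_iter: int = 128
    tol: float = 1e-2
    fd_step: float = 1e-3
    hyper_mean: float = 6.0        # prior mean of the noise log precisions
    hyper_var: float = 1.0 / 128.0  # precise prior on the precisions


@dataclass(frozen=True)
class SimConfig:
    fs: float = 2000.0            # integration at dt = 0.5 ms
    epoch_length_s: float = 0.5
    duration_s: float = 600.0


@dataclass(frozen=True)
class Config:
    priors: PriorConfig = field(default_factory=PriorConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    vl: VLConfig = field(default_factory=VLConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    log_precision: float = 7.0    # simulated signal/noise variance ratio exp(7)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["bands"] = [asdict(b) for b in self.bands]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        payload = yaml.safe_load(Path(path).read_text())
        bands = tuple(BandDefinition(**b) for b in payload.pop("bands", []))
        return cls(
            priors=PriorConfig(**payload.get("priors", {})),
            grid=GridConfig(**payload.get("grid", {})),
            vl=VLConfig(**payload.get("vl", {})),
            sim=SimConfig(**payload.get("sim", {})),
            bands=bands or DEFAULT_BANDS,
            log_precision=payload.get("log_precision", 7.0),
            seed=payload.get("seed", 0),
        )

    def hash(self) -> str:
        payload = asdict(self)
        payload["bands"] = [asdict(b) for b in self.bands]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]
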