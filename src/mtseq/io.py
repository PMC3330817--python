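"""Configuration parsing, run manifests and tabular/gridded writers.

Units are fixed package-wide (µm, s); configs carry plain numbers.  Configs
are JSON or YAML, validated strictly (unknown keys rejected, offending key
named).  Gridded fields are written as .npy arrays next to a JSON header;
tables as CSV.  Every output file is listed in the run manifest with a
sha256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .engine import KineticParams
from .geometry import EnergidDomain, SpindleSpec
from .mean_field import FieldParams


class SimConfig(BaseModel):
    """Top-level simulation configuration; every omitted field falls back to
    the package defaults (the reference parameter table)."""
    model_config = ConfigDict(extra="forbid")

    kinetics: KineticParams = KineticParams()
    spindle: SpindleSpec = SpindleSpec()
    n_particles: int = 1000
    duration: float = 20.0
    snapshot_stride: int = 10_000
    motor: str = "dynein"


class FieldConfig(BaseModel):
    """Mean-field (FRAP/FLIP) configuration."""
    model_config = ConfigDict(extra="forbid")

    domain: EnergidDomain = EnergidDomain()
    params: FieldParams = FieldParams()
    duration: float = 300.0
    dt: float = 0.1


class ConfigError(ValueError):
    pass


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path, model=SimConfig):
    """Load and validate a JSON/YAML config file into `model`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text)) or {}
    try:
        return model(**data)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {_format_validation_error(exc)}") from exc


def dump_config(cfg: BaseModel, path) -> None:
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=2) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Bookkeeping for one seeded run: config hash, seeds, inventory."""
    config_hash: str
    seeds: list
    version: str = __version__
    started: float = dc_field(default_factory=time.time)
    finished: float | None = None
    files: dict = dc_field(default_factory=dict)

    @classmethod
    def for_config(cls, cfg: BaseModel, seeds) -> "RunManifest":
        payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
        return cls(config_hash=hashlib.sha256(payload).hexdigest(),
                   seeds=list(seeds))

    def register(self, path) -> None:
        path = Path(path)
        self.files[path.name] = _sha256(path)

    def write(self, out_dir) -> Path:
        self.finished = time.time()
        out = Path(out_dir) / "manifest.json"
        out.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
        return out


def write_snapshot_table(result, path) -> None:
    """Long-format CSV: one row per (snapshot, particle)."""
    T, N, _ = result.positions.shape
    df = pd.DataFrame({
        "time": np.repeat(result.times, N),
        "particle": np.tile(np.arange(N), T),
        "x": result.positions[:, :, 0].ravel(),
        "y": result.positions[:, :, 1].ravel(),
        "z": result.positions[:, :, 2].ravel(),
        "state": result.states.ravel(),
        "host_pole": result.host_pole.ravel(),
    })
    df.to_csv(path, index=False)


def read_snapshot_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bound_counts(result, path) -> None:
    cols = {f"bound_pole_{p}": result.bound_per_pole[:, p]
            for p in range(result.bound_per_pole.shape[1])}
    pd.DataFrame({"time": result.times, **cols}).to_csv(path, index=False)


def write_field(field_pair, out_dir, stem: str) -> list[Path]:
    """Gridded field pair as flat .npy arrays + a JSON header."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in (("rho_f", field_pair.rho_f), ("rho_b", field_pair.rho_b)):
        p = out_dir / f"{stem}_{name}.npy"
        np.save(p, arr)
        paths.append(p)
    header = out_dir / f"{stem}.json"
    header.write_text(json.dumps({"time": field_pair.time,
                                  "shape": list(field_pair.rho_f.shape)}) + "\n")
    paths.append(header)
    return paths


def write_outputs(result, manifest: RunManifest, out_dir) -> dict:
    """Standard agent-run output bundle: snapshots, bound counts, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snap = out_dir / "snapshots.csv"
    write_snapshot_table(result, snap)
    counts = out_dir / "bound_counts.csv"
    write_bound_counts(result, counts)
    for p in (snap, counts):
        manifest.register(p)
    manifest.write(out_dir)
    return manifest.files
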