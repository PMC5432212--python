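"""Run configuration and manifests for the command-line pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from typing import Any, Mapping

import yaml

from .inference import PAPER_MCMC, REDUCED_MCMC, McmcConfig

__all__ = ["RunConfig", "mcmc_preset", "write_manifest"]

MCMC_PRESETS = {"paper": PAPER_MCMC, "reduced": REDUCED_MCMC}


def mcmc_preset(name: str, seed: int = 0) -> McmcConfig:
    try:
        base = MCMC_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown MCMC preset {name!r}; choose from {sorted(MCMC_PRESETS)}") from None
    return dataclasses.replace(base, seed=seed)


@dataclasses.dataclass
class RunConfig:
    """Configuration for a pipeline run (simulate / fit / recover)."""

    model: str = "M4"
    n_subjects: int = 20
    n_reps: int = 40
    validity: float = 0.8
    mcmc_preset: str = "reduced"
    seed: int = 0
    coupling: dict[str, float] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "RunConfig":
        data = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | pathlib.Path) -> None:
        pathlib.Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def write_manifest(directory: str | pathlib.Path, **entries: Any) -> pathlib.Path:
    """Write a run manifest (seeds, config hash, package version) next to the
    outputs so every artifact is reproducible from it."""
    from . import __version__

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload: Mapping[str, Any] = {"package_version": __version__, **entries}
    path = directory / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
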