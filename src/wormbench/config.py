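"""Run configuration: YAML in, manifest out.

A :class:`RunConfig` bundles everything a run needs -- seed, action
rates, engine options, the protocol to run and its parameters -- and is
embedded verbatim in the run's output manifest so any artifact can be
regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .bench import ActionRates
from .transmission import EngineConfig


@dataclass
class RunConfig:
    seed: int = 1
    protocol: str = ""
    rates: ActionRates = field(default_factory=ActionRates)
    engine: EngineConfig = field(default_factory=EngineConfig)
    params: dict = field(default_factory=dict)
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "protocol": self.protocol,
            "rates": self.rates.to_dict(),
            "engine": self.engine.to_dict(),
            "params": self.params,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        rates = ActionRates(**d.get("rates", {}))
        engine = EngineConfig(**d.get("engine", {}))
        return cls(
            seed=int(d.get("seed", 1)),
            protocol=d.get("protocol", ""),
            rates=rates,
            engine=engine,
            params=dict(d.get("params", {})),
            out_dir=d.get("out_dir", "runs"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def write_manifest(out_dir, config: RunConfig, extra: Optional[dict] = None
                   ) -> Path:
    """Write the manifest (config + seed + version) a run's artifacts can
    be regenerated from."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "wormbench",
        "version": __version__,
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
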