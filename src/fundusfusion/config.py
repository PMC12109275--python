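"""YAML run configuration.

One file configures every stage (phantom cohort, preprocessing, model
specs, schedule, loss, DOE).  Unknown keys are rejected, values are
validated by the owning dataclasses, and every run freezes its fully
resolved configuration next to its outputs so any artifact is
reproducible from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lossfn import LossParams
from .models import AnnSpec, ConcatSpec
from .phantom import PhantomSpec
from .training import Schedule, SplitSpec


@dataclass(frozen=True)
class DoeConfig:
    replicates: int = 2
    blocks_per_run: int = 5

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.blocks_per_run < 1:
            raise ValueError("DOE replicates and blocks_per_run must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for one run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    schedule: Schedule = field(default_factory=Schedule)
    loss: LossParams = field(default_factory=LossParams)
    ann: AnnSpec = field(default_factory=AnnSpec)
    head: ConcatSpec = field(default_factory=ConcatSpec)
    doe: DoeConfig = field(default_factory=DoeConfig)
    n_kernels: int = 32
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "phantom": PhantomSpec,
    "split": SplitSpec,
    "schedule": Schedule,
    "loss": LossParams,
    "ann": AnnSpec,
    "head": ConcatSpec,
    "doe": DoeConfig,
}


def _build_section(cls, payload: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} for section {cls.__name__}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in payload:
            v = payload[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; ``overrides`` win over the file."""
    payload: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
            payload = loaded
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict):
                payload.setdefault(key, {}).update(val)
            else:
                payload[key] = val
    unknown = set(payload) - set(_SECTIONS) - {"n_kernels", "seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, payload.get(name, {})) for name, cls in _SECTIONS.items()
    }
    kwargs["n_kernels"] = int(payload.get("n_kernels", 32))
    kwargs["seed"] = int(payload.get("seed", 0))
    return RunConfig(**kwargs)


def freeze_config(config: RunConfig, directory: str | Path) -> Path:
    """Write the resolved config into a run directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "config.resolved.yaml"
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
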