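"""Run configuration: one YAML file binding the whole pipeline.

Sections map onto the dataclasses of the library: ``gait`` →
:class:`~gaitgcn.simulate.GaitParams` (plus cohort size), ``model`` →
:class:`~gaitgcn.model.ModelConfig`, ``train`` →
:class:`~gaitgcn.training.TrainConfig`.  A single root ``seed`` seeds
every stochastic stage unless a section overrides it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .model import ModelConfig
from .simulate import GaitParams
from .training import TrainConfig

__all__ = ["RunConfig", "load_config"]


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    if cls is ModelConfig and "branches" in data:
        data = dict(data, branches=tuple(data["branches"]))
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    seed: int = 0
    dataset: str = "dataset.h5"
    outdir: str = "runs"
    n_subjects: int = 8
    trials_per_class: int = 10
    gait: GaitParams = field(default_factory=GaitParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def seeded(self) -> "RunConfig":
        """Propagate the root seed into every stochastic section."""
        return replace(
            self,
            gait=replace(self.gait, seed=self.seed),
            model=replace(self.model, seed=self.seed),
            train=replace(self.train, seed=self.seed),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["model"]["branches"] = list(payload["model"]["branches"])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(
    path: str | Path | None = None, overrides: dict | None = None
) -> RunConfig:
    """Load a RunConfig from YAML, applying flat overrides last.

    Override keys use dotted paths into sections, e.g.
    ``{"model.branch_width": 32, "seed": 7}``.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        if "." in key:
            section, name = key.split(".", 1)
            data.setdefault(section, {})[name] = value
        else:
            data[key] = value
    gait = _build(GaitParams, data.pop("gait", {}))
    model = _build(ModelConfig, data.pop("model", {}))
    train = _build(TrainConfig, data.pop("train", {}))
    cfg = _build(
        RunConfig, dict(data, gait=gait, model=model, train=train)
    )
    return cfg
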