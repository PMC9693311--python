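"""Run configuration: every tunable of the pipeline, YAML round-trippable.

Defaults follow the method's stated constants — λ = 0.6, η = 1e−5,
verification threshold 0.62 — with the remaining tunables carrying each
module's documented defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InvalidConfigError
from .registration import DEFAULT_STIFFNESS_SCHEDULE
from .synthetic import PopulationConfig
from .ymo import FitConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables with their defaults."""

    seed: int = 0
    # YMO fitting
    lambda_stiffness: float = 0.6
    eta: float = 1e-5
    max_iter: int = 100
    verify_threshold: float = 0.62
    residual: str = "rms"
    # model
    d: int | None = None
    variance_cutoff: float = 0.98
    # correspondence
    rounds: int = 2
    template_size: int = 250
    stiffness_schedule: tuple[float, ...] = DEFAULT_STIFFNESS_SCHEDULE
    # recognition
    metric: str = "SP"
    minkowski_p: float = 3.0
    # synthetic population
    population: dict = field(default_factory=dict)

    def fit_config(self) -> FitConfig:
        return FitConfig(
            lambda_stiffness=self.lambda_stiffness,
            eta=self.eta,
            max_iter=self.max_iter,
            verify_threshold=self.verify_threshold,
            residual=self.residual,
        )

    def population_config(self, seed: int | None = None) -> PopulationConfig:
        kwargs = dict(self.population)
        kwargs.setdefault("seed", self.seed if seed is None else seed)
        if seed is not None:
            kwargs["seed"] = seed
        return PopulationConfig(**kwargs)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["stiffness_schedule"] = list(self.stiffness_schedule)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stiffness_schedule" in data:
            data["stiffness_schedule"] = tuple(float(x) for x in data["stiffness_schedule"])
        return cls(**data)
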