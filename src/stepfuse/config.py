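"""Run configuration: one YAML document driving every pipeline stage.

All constants that are tool decisions rather than physical anchors (Gaussian
spreads, trapezoid vertices, the reference accuracy ``a0``, the GPS gate
``w_min``, the decision threshold ``theta``, the PSD peak floor) surface
here with their defaults, so a run is fully described by its config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from stepfuse.labeler import FuzzyConfig
from stepfuse.simulate import SimulationConfig


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class EvaluationSettings:
    folds: int = 10
    test_fraction: float = 0.10
    noise_rates: tuple[float, ...] = (0.0, 0.1, 0.2)
    models: tuple[str, ...] = ("all",)
    alpha: float = 1.0

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "test_fraction": self.test_fraction,
            "noise_rates": list(self.noise_rates),
            "models": list(self.models),
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationSettings":
        kwargs = {}
        for key in ("folds",):
            if key in d:
                kwargs[key] = int(d[key])
        for key in ("test_fraction", "alpha"):
            if key in d:
                kwargs[key] = float(d[key])
        if "noise_rates" in d:
            kwargs["noise_rates"] = tuple(float(r) for r in d["noise_rates"])
        if "models" in d:
            kwargs["models"] = tuple(d["models"])
        return cls(**kwargs)


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    fuzzy: FuzzyConfig = field(default_factory=FuzzyConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)
    seed: int = 0
    days: float = 2.0
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        """A per-stage seed derived deterministically from the global seed."""
        order = ("simulate", "weak-label", "extract", "build", "evaluate")
        if stage not in order:
            raise ConfigError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence(self.seed, spawn_key=(order.index(stage),))
        return int(ss.generate_state(1)[0])

    def to_dict(self) -> dict:
        return {
            "fuzzy": self.fuzzy.to_dict(),
            "simulation": self.simulation.to_dict(),
            "evaluation": self.evaluation.to_dict(),
            "seed": self.seed,
            "days": self.days,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if not isinstance(d, dict):
            raise ConfigError("config document must be a mapping")
        unknown = set(d) - {"fuzzy", "simulation", "evaluation", "seed", "days", "log_level"}
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        try:
            return cls(
                fuzzy=FuzzyConfig.from_dict(d.get("fuzzy", {})),
                simulation=SimulationConfig.from_dict(d.get("simulation", {})),
                evaluation=EvaluationSettings.from_dict(d.get("evaluation", {})),
                seed=int(d.get("seed", 0)),
                days=float(d.get("days", 2.0)),
                log_level=str(d.get("log_level", "INFO")),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path, require_sections: Sequence[str] = ()) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for section in require_sections:
            if section not in doc:
                raise ConfigError(f"config is missing the required {section!r} section")
        return cls.from_dict(doc)
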