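"""Prior, sampler and path-sampling grid configuration.

Defaults mirror the reference trial analysis: a unit-information g-prior on
the fixed effects (g = number of observations in the current study),
half-normal(0, 1) priors on random-effect SDs, an LKJ(1) prior on the
random-effect correlation, half-normal(0, 4) on the error SD, a Beta(1, 1)
prior on the power parameter (Beta(1, 2) available as a skeptical
sensitivity option), 4 chains of 2000 iterations with 1000 burn-in, and a
power grid from 0 to 1 in steps of 0.02 with 100 iterations per node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PriorSpec", "McmcSettings", "GridSettings", "ModelConfig"]


@dataclass(frozen=True)
class PriorSpec:
    g: float | str = "auto"
    re_sd_scale: float = 1.0
    err_sd_scale: float = 4.0
    lkj_eta: float = 1.0
    alpha_prior: tuple[float, float] = (1.0, 1.0)
    commensurate_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.g != "auto" and not float(self.g) > 0:
            raise ValueError("g must be positive or 'auto'")
        for name in ("re_sd_scale", "err_sd_scale", "lkj_eta",
                     "commensurate_sd_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        a, b = self.alpha_prior
        if not (a > 0 and b > 0):
            raise ValueError("alpha_prior parameters must be positive")

    def g_value(self, n_obs_current: int) -> float:
        return float(n_obs_current) if self.g == "auto" else float(self.g)


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 4
    iterations: int = 2000
    burn_in: int = 1000
    target_accept: float = 0.44
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass(frozen=True)
class GridSettings:
    step: float = 0.02
    iterations_per_node: int = 100
    node_burn_in: int = 50
    prior_draws: int = 2000  # direct prior draws at the alpha = 0 endpoint
    interpolation: str = "log"  # interpolate log c ("log") or c ("linear")

    def __post_init__(self) -> None:
        if not 0.0 < self.step <= 1.0:
            raise ValueError("step must lie in (0, 1]")
        n = 1.0 / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step must divide 1 into an integer number of intervals")
        if self.node_burn_in >= self.iterations_per_node:
            raise ValueError("node_burn_in must be smaller than iterations_per_node")
        if self.interpolation not in ("log", "linear"):
            raise ValueError("interpolation must be 'log' or 'linear'")

    @property
    def n_nodes(self) -> int:
        return int(round(1.0 / self.step)) + 1


@dataclass(frozen=True)
class ModelConfig:
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    grid: GridSettings = field(default_factory=GridSettings)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        prior = d.get("prior", {})
        if "alpha_prior" in prior:
            prior = {**prior, "alpha_prior": tuple(prior["alpha_prior"])}
        return cls(
            prior=PriorSpec(**prior),
            mcmc=McmcSettings(**d.get("mcmc", {})),
            grid=GridSettings(**d.get("grid", {})),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prior"]["alpha_prior"] = list(d["prior"]["alpha_prior"])
        return d


#: reduced-scale settings for quick interactive runs and smoke tests
REDUCED = ModelConfig(
    mcmc=McmcSettings(chains=2, iterations=1000, burn_in=500),
    grid=GridSettings(step=0.05, iterations_per_node=60, node_burn_in=20,
                      prior_draws=500),
)
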