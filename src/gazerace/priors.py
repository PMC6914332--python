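"""Prior configuration for GLAM parameter estimation.

Individual and pooled models use uninformative uniform priors between limits
derived from earlier applications of the model to four empirical datasets:

    v ~ U(0, 4)    gamma ~ U(-2, 1)    sigma ~ U(0, 4)    tau ~ U(0, 10)

Hierarchical models place truncated-normal group distributions over subject
parameters, with weakly informative truncated-normal hyperpriors on the group
means and standard deviations.  Hyperprior locations/scales come from the
across-dataset distribution of group-level estimates; the scale is widened by
a vagueness factor ``f`` (default 10), i.e. group mean of v has prior
``N(0.63, f * 0.26)`` truncated to [0, 2], and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PARAMETERS", "canonical_parameter", "HyperPrior", "PriorConfig",
           "default_priors"]

#: Canonical parameter order used everywhere in the package.
PARAMETERS = ("v", "gamma", "sigma", "tau")

_ALIASES = {"s": "sigma", "sd": "sigma", "g": "gamma"}


def canonical_parameter(name: str) -> str:
    """Map user-facing parameter names (including the 's' alias) to canonical ones."""
    name = _ALIASES.get(name, name)
    if name not in PARAMETERS:
        raise ValueError(
            f"unknown parameter {name!r}; expected one of {PARAMETERS} (or 's')"
        )
    return name


@dataclass(frozen=True)
class HyperPrior:
    """A truncated-normal prior: N(loc, scale) truncated to [lower, upper]."""

    loc: float
    scale: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        if not self.upper > self.lower:
            raise ValueError("bounds must be ordered")

    def scaled(self, f: float) -> "HyperPrior":
        return HyperPrior(self.loc, f * self.scale, self.lower, self.upper)


def _default_uniform() -> dict:
    return {"v": (0.0, 4.0), "gamma": (-2.0, 1.0),
            "sigma": (0.0, 4.0), "tau": (0.0, 10.0)}


def _default_group_mu() -> dict:
    return {"v": HyperPrior(0.63, 0.26, 0.0, 2.0),
            "gamma": HyperPrior(0.12, 0.11, -2.0, 1.0),
            "sigma": HyperPrior(0.27, 0.08, 0.0, 1.0),
            "tau": HyperPrior(1.03, 0.58, 0.0, 5.0)}


def _default_group_sd() -> dict:
    return {"v": HyperPrior(0.26, 0.11, 0.0, 1.0),
            "gamma": HyperPrior(0.35, 0.10, 0.0, 1.0),
            "sigma": HyperPrior(0.05, 0.01, 0.0, 0.2),
            "tau": HyperPrior(0.62, 0.26, 0.0, 3.0)}


@dataclass
class PriorConfig:
    """Priors for all model kinds.

    ``uniform_bounds`` doubles as the truncation support of the subject-level
    group distributions in hierarchical models.  ``f`` is the hyperprior
    vagueness factor; hyperprior scales are multiplied by it.
    """

    uniform_bounds: dict = field(default_factory=_default_uniform)
    group_mu: dict = field(default_factory=_default_group_mu)
    group_sd: dict = field(default_factory=_default_group_sd)
    f: float = 10.0

    def bounds(self, param: str) -> tuple:
        return self.uniform_bounds[canonical_parameter(param)]

    def mu_hyper(self, param: str) -> HyperPrior:
        return self.group_mu[canonical_parameter(param)].scaled(self.f)

    def sd_hyper(self, param: str) -> HyperPrior:
        return self.group_sd[canonical_parameter(param)].scaled(self.f)


def default_priors(f: float = 10.0) -> PriorConfig:
    """The package's default :class:`PriorConfig` with vagueness factor ``f``."""
    return PriorConfig(f=f)
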