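"""Bayesian estimation of GLAM variants.

``build_model`` compiles a trial table plus a :class:`ModelSpec` into a
:class:`GLAMModel` whose log-density is the sum of per-trial race-mixture
log-likelihoods and the prior terms for the chosen model kind:

- ``individual``: an independent parameter set per subject (uniform priors);
- ``pooled``: one shared parameter set (uniform priors);
- ``hierarchical``: subject parameters drawn from truncated-normal group
  distributions whose means and SDs carry truncated-normal hyperpriors.

``depends_on`` maps a parameter to a factor column, splitting that parameter
by condition level; within- and between-subject factors are handled by the
same mechanism (a subject simply only owns the levels it has trials for).
Parameters can instead be fixed to constants (scalar or per-subject).

Fitting is by adaptive Metropolis-within-Gibbs MCMC (default) or a mean-field
variational approximation; results are returned as a :class:`Posterior`
holding per-parameter samples, pointwise log-likelihoods (for WAIC/LOO) and
convergence diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import data as _data
from ._mcmc import run_mcmc
from ._stats import hpd_interval, kde_map
from .likelihood import table_log_likelihood
from .priors import PARAMETERS, PriorConfig, canonical_parameter, default_priors

__all__ = ["ModelSpec", "Instance", "GLAMModel", "Posterior", "build_model",
           "fit_mcmc", "fit_vi", "extract_estimates", "predict_from_posterior"]

_KINDS = ("individual", "pooled", "hierarchical")


@dataclass
class ModelSpec:
    """Model kind, parameter dependencies and fixed-value overrides."""

    kind: str = "individual"
    depends_on: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    error_weight: float = 0.05
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        self.depends_on = {canonical_parameter(k): v
                           for k, v in self.depends_on.items()}
        self.fixed = {canonical_parameter(k): v for k, v in self.fixed.items()}
        both = set(self.depends_on) & set(self.fixed)
        if both:
            raise ValueError(f"parameters {sorted(both)} are both fixed and dependent")
        if not 0.0 <= self.error_weight <= 1.0:
            raise ValueError("error_weight must be in [0, 1]")


@dataclass(frozen=True)
class Instance:
    """One free-parameter instance: a parameter, optionally tied to a level."""

    param: str
    level: object  # None when the parameter has no condition dependency
    name: str


class GLAMModel:
    """A compiled model: data arrays, parameter design and log-density."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec,
                 priors: Optional[PriorConfig] = None):
        self.spec = spec
        self.priors = priors if priors is not None else default_priors()
        self.kind = spec.kind
        self.n_items = _data.validate_trial_table(data)
        self.data = data.reset_index(drop=True)
        self.name = spec.name or f"glam_{spec.kind}"

        vcols, gcols = _data.item_columns(self.n_items)
        self.values = self.data[vcols].to_numpy(float)
        self.gazes = self.data[gcols].to_numpy(float)
        self.choice = self.data["choice"].to_numpy(int)
        self.rt = self.data["rt"].to_numpy(float)
        self.n_trials = len(self.data)
        self.subject_of_trial = self.data["subject"].to_numpy(int)
        self.n_subjects = int(self.subject_of_trial.max()) + 1

        if spec.kind == "pooled":
            self.n_units = 1
            self.unit_of_trial = np.zeros(self.n_trials, dtype=int)
        else:
            self.n_units = self.n_subjects
            self.unit_of_trial = self.subject_of_trial

        # contaminant: participant-specific uniform density over observed RTs
        bounds = self.data.groupby("subject")["rt"].agg(["min", "max"])
        rng_width = (bounds["max"] - bounds["min"]).to_numpy()
        if np.any(rng_width <= 0):
            raise ValueError("each subject needs a positive observed RT range "
                             "for the contaminant model")
        log_u_subject = -np.log(self.n_items * rng_width)
        self.log_u = log_u_subject[self.subject_of_trial]

        self._build_design()

    # -- design ---------------------------------------------------------
    def _build_design(self) -> None:
        spec, data = self.spec, self.data
        factors = _data.factor_columns(data, self.n_items)
        self.instances: list[Instance] = []
        self.trial_col: dict[str, np.ndarray] = {}
        self.fixed_values: dict[str, np.ndarray] = {}

        for p in PARAMETERS:
            if p in spec.fixed:
                val = spec.fixed[p]
                if np.ndim(val) == 0:
                    arr = np.full(self.n_trials, float(val))
                else:
                    val = np.asarray(val, float)
                    if val.shape != (self.n_subjects,):
                        raise ValueError(
                            f"fixed values for {p!r} must be a scalar or a "
                            f"length-{self.n_subjects} per-subject list"
                        )
                    arr = val[self.subject_of_trial]
                self.fixed_values[p] = arr
                continue
            if p in spec.depends_on:
                col = spec.depends_on[p]
                if col not in factors:
                    raise ValueError(
                        f"depends_on[{p!r}] names unknown factor column {col!r}; "
                        f"available factors: {factors}"
                    )
                levels = sorted(pd.unique(data[col]), key=str)
                level_idx = {lev: i for i, lev in enumerate(levels)}
                base = len(self.instances)
                for lev in levels:
                    self.instances.append(Instance(p, lev, f"{p}_{lev}"))
                self.trial_col[p] = base + data[col].map(level_idx).to_numpy(int)
            else:
                self.instances.append(Instance(p, None, p))
                self.trial_col[p] = np.full(self.n_trials, len(self.instances) - 1)

        self.n_instances = len(self.instances)
        self.bounds_lo = np.array([self.priors.bounds(i.param)[0]
                                   for i in self.instances])
        self.bounds_hi = np.array([self.priors.bounds(i.param)[1]
                                   for i in self.instances])
        self.used = np.zeros((self.n_units, self.n_instances), dtype=bool)
        for p, cols in self.trial_col.items():
            self.used[self.unit_of_trial, cols] = True

        if spec.kind == "hierarchical":
            self.hyper_mu = [self.priors.mu_hyper(i.param) for i in self.instances]
            self.hyper_sd = [self.priors.sd_hyper(i.param) for i in self.instances]

    @property
    def n_free_parameters(self) -> int:
        """Number of free scalar parameters at the subject/unit level."""
        return int(self.used.sum())

    # -- log-density ----------------------------------------------------
    def per_trial_parameters(self, theta: np.ndarray) -> dict:
        """Resolve per-trial parameter vectors from a (n_units, K) state."""
        out = {}
        for p in PARAMETERS:
            if p in self.fixed_values:
                out[p] = self.fixed_values[p]
            else:
                out[p] = theta[self.unit_of_trial, self.trial_col[p]]
        return out

    def loglik_pointwise(self, theta: np.ndarray) -> np.ndarray:
        """Per-trial log-likelihood (race + contaminant mixture)."""
        par = self.per_trial_parameters(theta)
        with np.errstate(over="ignore", under="ignore", invalid="ignore",
                         divide="ignore"):
            return table_log_likelihood(
                self.values, self.gazes, self.choice, self.rt,
                par["v"], par["gamma"], par["sigma"], par["tau"],
                self.spec.error_weight, self.log_u)

    def unit_loglik(self, pointwise: np.ndarray) -> np.ndarray:
        return np.bincount(self.unit_of_trial, weights=pointwise,
                           minlength=self.n_units)


def build_model(data: pd.DataFrame, kind: str = "individual",
                depends_on: Optional[dict] = None, fixed: Optional[dict] = None,
                error_weight: float = 0.05, priors: Optional[PriorConfig] = None,
                f: float = 10.0, name: Optional[str] = None,
                **param_vals) -> GLAMModel:
    """Build a :class:`GLAMModel` from a trial table.

    Fixed values may be given either via ``fixed={'gamma': 1}`` or the
    ``gamma_val=1`` keyword style; per-subject lists are allowed for the
    individual kind.
    """
    fixed = dict(fixed or {})
    for key, val in param_vals.items():
        if not key.endswith("_val"):
            raise TypeError(f"unexpected keyword argument {key!r}")
        fixed[canonical_parameter(key[:-4])] = val
    spec = ModelSpec(kind=kind, depends_on=dict(depends_on or {}), fixed=fixed,
                     error_weight=error_weight, name=name)
    if priors is None:
        priors = default_priors(f)
    return GLAMModel(data, spec, priors)


# -- posterior ----------------------------------------------------------
@dataclass
class Posterior:
    """Posterior (or variational) samples with diagnostics helpers.

    ``samples`` maps variable names (``"v[3]"``, ``"gamma_fast[0]"``,
    ``"tau_mu"``...) to ``(chains, draws)`` arrays; ``index`` describes each
    variable (parameter, level, subject, role); ``pointwise`` holds per-trial
    log-likelihood draws for information criteria.
    """

    model: GLAMModel
    samples: dict
    index: pd.DataFrame
    pointwise: Optional[np.ndarray]
    metadata: dict

    def __post_init__(self):
        self._idata = None

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.samples.values())).shape[1]

    def stacked(self, var: str) -> np.ndarray:
        """All samples of one variable, chains pooled."""
        return self.samples[var].reshape(-1)

    def to_inference_data(self):
        """Convert to an :class:`arviz.InferenceData` (cached)."""
        import arviz as az

        if self._idata is None:
            groups = {"posterior": {k: v for k, v in self.samples.items()}}
            if self.pointwise is not None:
                groups["log_likelihood"] = {
                    "rt_choice": self.pointwise.astype(np.float64)}
            idata = az.from_dict(**groups)
            meta = {"model_name": self.model.name,
                    "kind": self.model.spec.kind,
                    "subject_of_trial": self.model.subject_of_trial.tolist(),
                    **{k: v for k, v in self.metadata.items() if np.isscalar(v)}}
            # netCDF attributes cannot hold booleans or None
            idata.attrs.update({
                k: (int(v) if isinstance(v, (bool, np.bool_)) else v)
                for k, v in meta.items() if v is not None
            })
            self._idata = idata
        return self._idata

    def diagnostics(self) -> pd.DataFrame:
        """Split-R-hat and effective sample sizes per variable."""
        import arviz as az

        idata = self.to_inference_data()
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        ess_tail = az.ess(idata, method="tail")
        rows = [{"variable": v,
                 "rhat": float(rhat[v].values),
                 "ess_bulk": float(ess[v].values),
                 "ess_tail": float(ess_tail[v].values)}
                for v in self.samples]
        return pd.DataFrame(rows)

    def max_rhat(self) -> float:
        return float(self.diagnostics()["rhat"].max())


def _assemble_posterior(model: GLAMModel, theta, group, pointwise,
                        metadata) -> Posterior:
    samples: dict[str, np.ndarray] = {}
    rows = []
    for k, inst in enumerate(model.instances):
        if model.spec.kind == "pooled":
            samples[inst.name] = theta[:, :, 0, k]
            rows.append({"variable": inst.name, "parameter": inst.param,
                         "level": inst.level, "subject": None, "role": "pooled"})
        else:
            for u in range(model.n_units):
                if not model.used[u, k]:
                    continue
                var = f"{inst.name}[{u}]"
                samples[var] = theta[:, :, u, k]
                rows.append({"variable": var, "parameter": inst.param,
                             "level": inst.level, "subject": u,
                             "role": "subject"})
        if group is not None:
            for j, suffix in enumerate(("mu", "sd")):
                var = f"{inst.name}_{suffix}"
                samples[var] = group[:, :, k, j]
                rows.append({"variable": var, "parameter": inst.param,
                             "level": inst.level, "subject": None,
                             "role": f"group_{suffix}"})
    return Posterior(model=model, samples=samples, index=pd.DataFrame(rows),
                     pointwise=pointwise, metadata=metadata)


def fit_mcmc(model: GLAMModel, draws: int = 2000, tune: int = 2000,
             chains: int = 4, seed: Optional[int] = None,
             step: str = "metropolis") -> Posterior:
    """Fit by adaptive Metropolis-within-Gibbs MCMC.

    ``step='mala'`` switches the subject-level updates to Metropolis-adjusted
    Langevin proposals with finite-difference gradients.  At least two chains
    are required so that split-R-hat and effective-sample-size diagnostics
    are meaningful.
    """
    if draws <= 0 or tune <= 0:
        raise ValueError("draws and tune must be positive")
    if chains < 2:
        raise ValueError("need at least two chains for convergence diagnostics")
    theta, group, pointwise = run_mcmc(model, draws, tune, chains, seed, step)
    meta = {"method": "MCMC", "step": step, "draws": draws, "tune": tune,
            "chains": chains, "seed": seed, "approximate": False,
            "name": model.name}
    return _assemble_posterior(model, theta, group, pointwise, meta)


def fit_vi(model: GLAMModel, iterations: int = 5000, n_draws: int = 1000,
           learning_rate: float = 0.05, seed: Optional[int] = None) -> Posterior:
    """Fit by mean-field variational inference (fast, approximate).

    A diagonal Gaussian over logit-transformed parameters is optimized with
    a stochastic reparameterization estimate of the evidence lower bound.
    Estimates are flagged ``approximate`` — use MCMC for final analyses.
    """
    from ._vi import run_vi

    theta, group, pointwise, trace = run_vi(model, iterations, n_draws,
                                            learning_rate, seed)
    meta = {"method": "VI", "iterations": iterations, "draws": n_draws // 2,
            "chains": 2, "seed": seed, "approximate": True, "name": model.name,
            "elbo_trace": trace}
    return _assemble_posterior(model, theta, group, pointwise, meta)


# -- estimates ----------------------------------------------------------
def _map_hpd(samples: np.ndarray) -> tuple:
    lo, hi = hpd_interval(samples, 0.95)
    return kde_map(samples), lo, hi


def extract_estimates(posterior: Posterior, level: str = "subject",
                      include_fixed: bool = False) -> pd.DataFrame:
    """MAP and 95% HPD estimates as a tidy table.

    ``level='subject'`` gives one row per subject x condition combination
    (pooled fits are replicated across subjects so the table composes
    directly with :func:`gazerace.simulate.predict`).  ``level='group'``
    returns the hierarchical group-level means and SDs.  MAP is the Gaussian-
    KDE mode of the marginal samples; the HPD is the shortest contiguous 95%
    interval.
    """
    model = posterior.model
    if posterior.n_chains * posterior.n_draws < 100:
        raise ValueError("need at least 100 posterior samples for MAP estimation")
    if level == "group":
        if model.spec.kind != "hierarchical":
            raise ValueError("group-level estimates require a hierarchical fit")
        rows = []
        for inst in model.instances:
            row = {"parameter": inst.param, "condition": inst.level}
            for suffix in ("mu", "sd"):
                m, lo, hi = _map_hpd(posterior.stacked(f"{inst.name}_{suffix}"))
                row[suffix] = m
                row[f"{suffix}_hpd_2.5"] = lo
                row[f"{suffix}_hpd_97.5"] = hi
            rows.append(row)
        return pd.DataFrame(rows)
    if level != "subject":
        raise ValueError("level must be 'subject' or 'group'")

    factors = list(dict.fromkeys(model.spec.depends_on.values()))
    levels_per_factor = [sorted(pd.unique(model.data[c]), key=str)
                         for c in factors]
    combos = [()]
    for lv in levels_per_factor:
        combos = [c + (x,) for c in combos for x in lv]

    free_params = [p for p in PARAMETERS if p not in model.fixed_values]
    rows = []
    for s in range(model.n_subjects):
        for combo in combos:
            row = {"subject": s, **dict(zip(factors, combo))}
            any_value = False
            for p in free_params:
                factor = model.spec.depends_on.get(p)
                lev = combo[factors.index(factor)] if factor else None
                iname = f"{p}_{lev}" if factor else p
                var = iname if model.spec.kind == "pooled" else f"{iname}[{s}]"
                if var in posterior.samples:
                    m, lo, hi = _map_hpd(posterior.stacked(var))
                    any_value = True
                else:
                    m = lo = hi = np.nan
                row[p] = m
                row[f"{p}_hpd_2.5"] = lo
                row[f"{p}_hpd_97.5"] = hi
            if include_fixed:
                for p, arr in model.fixed_values.items():
                    mask = model.subject_of_trial == s
                    row[p] = float(arr[mask][0]) if mask.any() else np.nan
            if any_value:
                rows.append(row)
    return pd.DataFrame(rows)


def predict_from_posterior(posterior: Posterior, data: Optional[pd.DataFrame] = None,
                           n_repeats: int = 1, seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate response data from a fit's MAP estimates (fixed values included)."""
    from .simulate import predict

    estimates = extract_estimates(posterior, "subject", include_fixed=True)
    if data is None:
        data = posterior.model.data
    return predict(data, estimates, n_repeats=n_repeats,
                   error_weight=posterior.model.spec.error_weight, seed=seed)
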