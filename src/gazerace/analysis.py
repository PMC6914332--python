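"""Model comparison, parameter contrasts and recovery workflows.

Information criteria (WAIC, PSIS-LOO) are computed from the pointwise
per-trial log-likelihood draws stored with each fit and reported on the
deviance scale (-2 * elpd, lower is better), with plain pseudo-BMA (Akaike)
weights.  For individually-fitted models the comparison is carried out per
subject on that subject's trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import hpd_interval
from .inference import Posterior, build_model, fit_mcmc
from .priors import canonical_parameter

__all__ = ["compare_models", "compare_idata", "compare_parameters",
           "model_recovery", "RecoveryResult", "out_of_sample_split",
           "waic_from_pointwise"]

_IC_COLUMNS = {"WAIC": ("WAIC", "pWAIC", "dWAIC"),
               "LOO": ("LOO", "pLOO", "dLOO")}


def waic_from_pointwise(log_lik: np.ndarray) -> dict:
    """WAIC on the deviance scale from a (chains, draws, n) log-lik array.

    ``lppd`` is the summed log posterior-mean pointwise density; the
    effective-parameter penalty ``p_waic`` is the summed posterior variance of
    the pointwise log-likelihood; ``WAIC = -2 (lppd - p_waic)``.
    """
    from scipy.special import logsumexp

    ll = np.asarray(log_lik, dtype=float)
    ll = ll.reshape(-1, ll.shape[-1])
    s = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0)  # population variance, matching the reported tables
    elpd_i = lppd_i - p_i
    n = ll.shape[1]
    return {
        "waic": float(-2.0 * elpd_i.sum()),
        "p_waic": float(p_i.sum()),
        "se": float(2.0 * np.sqrt(n * elpd_i.var())),
        "warning": bool((p_i > 0.4).any()),
    }


def _slice_idata(fit: Posterior, trial_mask: Optional[np.ndarray]):
    import arviz as az

    if fit.pointwise is None:
        raise ValueError(f"fit {fit.model.name!r} has no stored pointwise "
                         "log-likelihoods")
    ll = fit.pointwise.astype(float)
    if trial_mask is not None:
        ll = ll[:, :, trial_mask]
    anyvar = next(iter(fit.samples.values()))
    return az.from_dict(posterior={"theta": anyvar},
                        log_likelihood={"rt_choice": ll})


def compare_idata(idatas: dict, ic: str = "WAIC") -> pd.DataFrame:
    """Rank models (arviz) and map to the toolbox's comparison-table schema."""
    import arviz as az

    ic = ic.upper()
    if ic not in _IC_COLUMNS:
        raise ValueError("ic must be 'WAIC' or 'LOO'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp = az.compare(idatas, ic=ic.lower(), method="pseudo-BMA",
                         scale="deviance", var_name="rt_choice")
    ic_col, p_col, d_col = _IC_COLUMNS[ic]
    out = pd.DataFrame({
        "model": cmp.index,
        ic_col: cmp[f"elpd_{ic.lower()}"].to_numpy(),
        p_col: cmp[f"p_{ic.lower()}"].to_numpy(),
        d_col: cmp["elpd_diff"].to_numpy(),
        "weight": cmp["weight"].to_numpy(),
        "SE": cmp["se"].to_numpy(),
        "dSE": cmp["dse"].to_numpy(),
        "var_warn": cmp["warning"].to_numpy().astype(int),
    })
    return out.sort_values(ic_col, ignore_index=True)


def compare_models(fits: Sequence[Posterior], ic: str = "WAIC") -> pd.DataFrame:
    """Information-criterion comparison of GLAM variants fitted to the same data.

    Individual-kind fits are compared per subject (one block of rows per
    subject, ``dIC = 0`` for that subject's best model); pooled/hierarchical
    fits get a single comparison.  Output columns follow the toolbox schema:
    ``model, WAIC, pWAIC, dWAIC, weight, SE, dSE, var_warn`` (or the LOO
    equivalents).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to compare")
    ref = fits[0].model
    names = []
    for f in fits:
        name = f.metadata.get("name") or f.model.name
        names.append(name if name not in names else f"{name}_{len(names)}")
    for f in fits[1:]:
        if f.model.n_trials != ref.n_trials or not np.array_equal(
                f.model.subject_of_trial, ref.subject_of_trial):
            raise ValueError("fits must share the same trial table")

    if all(f.model.spec.kind == "individual" for f in fits):
        frames = []
        for s in range(ref.n_subjects):
            mask = ref.subject_of_trial == s
            idatas = {nm: _slice_idata(f, mask) for nm, f in zip(names, fits)}
            tab = compare_idata(idatas, ic)
            tab.insert(0, "subject", s)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)
    idatas = {nm: _slice_idata(f, None) for nm, f in zip(names, fits)}
    return compare_idata(idatas, ic)


def compare_parameters(fit: Posterior, parameters: Sequence[str],
                       comparisons: Sequence[tuple]) -> pd.DataFrame:
    """Posterior contrasts of parameters between condition/group levels.

    For hierarchical fits the contrast is between group-level *mean*
    parameters; for individual fits, per-subject differences (subjects
    lacking one of the levels are skipped).  Each row reports the mean
    posterior difference, the fraction of the posterior above zero, and the
    95% HPD of the difference.
    """
    model = fit.model
    parameters = [canonical_parameter(p) for p in parameters]
    rows = []
    for p in parameters:
        available = sorted({i.level for i in model.instances if i.param == p
                            and i.level is not None}, key=str)
        for a, b in comparisons:
            for lev in (a, b):
                if lev not in available:
                    raise ValueError(
                        f"unknown level {lev!r} for parameter {p!r}; "
                        f"available levels: {available}"
                    )
            if model.spec.kind == "hierarchical":
                diff = fit.stacked(f"{p}_{a}_mu") - fit.stacked(f"{p}_{b}_mu")
                rows.append(_contrast_row(p, a, b, diff, subject=None))
            else:
                for s in range(model.n_subjects):
                    va, vb = f"{p}_{a}[{s}]", f"{p}_{b}[{s}]"
                    if va not in fit.samples or vb not in fit.samples:
                        continue
                    diff = fit.stacked(va) - fit.stacked(vb)
                    rows.append(_contrast_row(p, a, b, diff, subject=s))
    return pd.DataFrame(rows)


def _contrast_row(p, a, b, diff, subject):
    lo, hi = hpd_interval(diff, 0.95)
    row = {"parameter": p, "level_a": a, "level_b": b,
           "mean_difference": float(diff.mean()),
           "p_above_zero": float((diff > 0).mean()),
           "hpd_2.5": lo, "hpd_97.5": hi}
    if subject is not None:
        row = {"subject": subject, **row}
    return row


@dataclass
class RecoveryResult:
    """Per-subject model-recovery classification and overall accuracy."""

    table: pd.DataFrame
    accuracy: float


def model_recovery(simulated, draws: int = 2000, tune: int = 2000,
                   chains: int = 2, seed: Optional[int] = None,
                   ic: str = "WAIC", error_weight: float = 0.05) -> RecoveryResult:
    """Can WAIC tell gaze-biased from no-bias subjects in simulated data?

    ``simulated`` is a :class:`gazerace.simulate.SimulationResult` (or a
    :class:`GroupSpec`, which is simulated first).  Both the full model and
    the gamma=1 variant are fitted individually; each subject is classified
    by the preferred variant and checked against the generating gamma.
    """
    from .simulate import GroupSpec, SimulationResult, simulate_group

    if isinstance(simulated, GroupSpec):
        simulated = simulate_group(simulated)
    if not isinstance(simulated, SimulationResult):
        raise TypeError("simulated must be a GroupSpec or SimulationResult")

    data = simulated.data
    truth_nobias = np.isclose(simulated.parameters["gamma"].to_numpy(), 1.0)
    full = build_model(data, kind="individual", name="glam_bias",
                       error_weight=error_weight)
    nobias = build_model(data, kind="individual", gamma_val=1.0,
                         name="glam_nobias", error_weight=error_weight)
    rng = np.random.SeedSequence(seed).spawn(2)
    fit_full = fit_mcmc(full, draws=draws, tune=tune, chains=chains,
                        seed=rng[0].generate_state(1)[0] % (2**31))
    fit_nobias = fit_mcmc(nobias, draws=draws, tune=tune, chains=chains,
                          seed=rng[1].generate_state(1)[0] % (2**31))
    cmp = compare_models([fit_full, fit_nobias], ic=ic)
    ic_col = _IC_COLUMNS[ic.upper()][0]
    rows = []
    for s, grp in cmp.groupby("subject"):
        best = grp.loc[grp[ic_col].idxmin(), "model"]
        pred_nobias = best == "glam_nobias"
        rows.append({"subject": s, "generating_gamma":
                     float(simulated.parameters["gamma"].iloc[int(s)]),
                     "true_no_bias": bool(truth_nobias[int(s)]),
                     "preferred_model": best,
                     "correct": bool(pred_nobias == truth_nobias[int(s)])})
    table = pd.DataFrame(rows)
    return RecoveryResult(table, float(table["correct"].mean()))


def out_of_sample_split(data: pd.DataFrame) -> tuple:
    """Split each subject's trials into even- and odd-numbered halves.

    Fitting on the even half and predicting the odd half gives an
    out-of-sample check of absolute model fit.
    """
    even = data[data["trial"] % 2 == 0].reset_index(drop=True)
    odd = data[data["trial"] % 2 == 1].reset_index(drop=True)
    for side, name in ((even, "even"), (odd, "odd")):
        missing = set(data["subject"].unique()) - set(side["subject"].unique())
        if missing:
            warnings.warn(f"subjects {sorted(missing)} have no {name}-numbered "
                          "trials")
    return even, odd
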