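"""Trial-table I/O, validation and behavioural summaries.

A trial table is a tidy pandas DataFrame with one row per trial:

    subject, trial, choice, rt, item_value_0..N-1, gaze_0..N-1, <factors...>

``subject`` ids are a contiguous 0-based range, ``choice`` indexes the chosen
item, ``rt`` is in seconds, ``gaze_i`` is the fraction of trial time spent on
item ``i`` (per-trial gaze may sum to less than 1: off-item gaze is allowed).
Any extra columns are treated as categorical factors (groups/conditions) and
preserved.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "SchemaError",
    "ValidationError",
    "load_trial_table",
    "validate_trial_table",
    "infer_n_items",
    "item_columns",
    "factor_columns",
    "long_item_table",
    "aggregate_subject_level_data",
    "behavioural_curves",
]

_REQUIRED = ("subject", "trial", "choice", "rt")
_GAZE_SUM_TOL = 1e-4


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ValidationError(ValueError):
    """Trial values violate the table invariants."""


def infer_n_items(data: pd.DataFrame) -> int:
    n = 0
    while f"item_value_{n}" in data.columns:
        n += 1
    if n < 2:
        raise SchemaError(
            "could not infer item count: need columns item_value_0, item_value_1, ..."
        )
    return n


def item_columns(n_items: int) -> tuple[list, list]:
    return ([f"item_value_{i}" for i in range(n_items)],
            [f"gaze_{i}" for i in range(n_items)])


def factor_columns(data: pd.DataFrame, n_items: int) -> list:
    """Columns that are neither core variables nor item value/gaze columns."""
    vcols, gcols = item_columns(n_items)
    core = set(_REQUIRED) | set(vcols) | set(gcols) | {"repeat"}
    return [c for c in data.columns if c not in core]


def validate_trial_table(data: pd.DataFrame, n_items: int | None = None) -> int:
    """Validate a trial table in place; returns the number of items N."""
    for col in _REQUIRED:
        if col not in data.columns:
            raise SchemaError(f"missing required column {col!r}")
    if n_items is None:
        n_items = infer_n_items(data)
    vcols, gcols = item_columns(n_items)
    for col in vcols + gcols:
        if col not in data.columns:
            raise SchemaError(f"missing required column {col!r}")

    gaze = data[gcols].to_numpy(float)
    bad = np.flatnonzero((gaze < 0).any(axis=1) | (gaze > 1).any(axis=1))
    if bad.size:
        raise ValidationError(
            f"gaze outside [0, 1] in rows {bad.tolist()[:20]}"
        )
    bad = np.flatnonzero(gaze.sum(axis=1) > 1.0 + _GAZE_SUM_TOL)
    if bad.size:
        raise ValidationError(f"per-trial gaze sums exceed 1 in rows {bad.tolist()[:20]}")
    rt = data["rt"].to_numpy(float)
    bad = np.flatnonzero(~(rt > 0))
    if bad.size:
        raise ValidationError(f"rt must be > 0; offending rows {bad.tolist()[:20]}")
    choice = data["choice"].to_numpy()
    bad = np.flatnonzero((choice < 0) | (choice >= n_items))
    if bad.size:
        raise ValidationError(
            f"choice outside 0..{n_items - 1} in rows {bad.tolist()[:20]}"
        )
    subjects = np.unique(data["subject"].to_numpy())
    if not np.array_equal(subjects, np.arange(len(subjects))):
        raise ValidationError(
            "subject ids must form a contiguous 0-based range "
            f"(got {subjects.tolist()[:20]})"
        )
    return n_items


def load_trial_table(path, n_items: int | None = None) -> pd.DataFrame:
    """Read and validate a trial-table CSV (``#`` lines are metadata comments).

    ``n_items`` is inferred from the ``item_value_*`` columns when omitted.
    """
    data = pd.read_csv(path, comment="#")
    validate_trial_table(data, n_items)
    return data


def long_item_table(data: pd.DataFrame, n_items: int) -> pd.DataFrame:
    """One row per item x trial: relative value/gaze and the choice indicator.

    ``rel_value``/``rel_gaze`` are the item's value/gaze minus the maximum of
    the other items' values/gazes in that trial; ``chosen`` is 1 for the
    chosen item.
    """
    vcols, gcols = item_columns(n_items)
    values = data[vcols].to_numpy(float)
    gazes = data[gcols].to_numpy(float)
    choice = data["choice"].to_numpy(int)

    from .likelihood import _max_of_others

    rel_value = values - _max_of_others(values)
    rel_gaze = gazes - _max_of_others(gazes)
    n, N = values.shape
    return pd.DataFrame({
        "subject": np.repeat(data["subject"].to_numpy(), N),
        "row": np.repeat(np.arange(n), N),
        "item": np.tile(np.arange(N), n),
        "rel_value": rel_value.ravel(),
        "rel_gaze": rel_gaze.ravel(),
        "chosen": (np.tile(np.arange(N), n) == np.repeat(choice, N)).astype(float),
    })


def _value_model_residuals(items: pd.DataFrame) -> np.ndarray:
    """Observed minus value-predicted choice probability per item-trial.

    Per subject, a logistic regression of the choice indicator on the item's
    relative value captures how far value alone carries choice; the residual
    is what gaze (or anything else) adds.
    """
    resid = np.empty(len(items))
    for _, grp in items.groupby("subject", sort=False):
        X = grp[["rel_value"]].to_numpy()
        y = grp["chosen"].to_numpy()
        model = LogisticRegression(penalty=None, max_iter=1000, tol=1e-8)
        with warnings.catch_warnings():
            # perfect value-based separation saturates the fit; the resulting
            # ~0/1 probabilities are exactly what the residual measure needs
            warnings.simplefilter("ignore")
            model.fit(X, y)
        p = model.predict_proba(X)[:, 1]
        resid[grp.index.to_numpy()] = y - p
    return resid


def aggregate_subject_level_data(data: pd.DataFrame, n_items: int) -> pd.DataFrame:
    """Per-subject behavioural summary: mean RT, p(choose best), gaze influence.

    ``p_choose_best`` is the fraction of trials in which the chosen item has
    the maximal value (a choice of any tied-maximal item counts).
    ``gaze_influence`` is the mean, over item-trials in which the item
    received more gaze than every other item, of the observed choice indicator
    minus the probability predicted from relative value alone — the average
    increase in choice probability for longer-fixated items after correcting
    for item value.
    """
    n_items = validate_trial_table(data, n_items)
    data = data.reset_index(drop=True)
    vcols, _ = item_columns(n_items)
    values = data[vcols].to_numpy(float)
    chosen_value = values[np.arange(len(data)), data["choice"].to_numpy(int)]
    best = chosen_value >= values.max(axis=1)

    items = long_item_table(data, n_items)
    items["residual"] = _value_model_residuals(items)

    rows = []
    for subject, grp in data.groupby("subject", sort=True):
        if len(grp) == 0:  # pragma: no cover - degenerate guard
            warnings.warn(f"subject {subject} has no trials; excluded")
            continue
        sub_items = items[items["subject"] == subject]
        pos = sub_items[sub_items["rel_gaze"] > 0]
        rows.append({
            "subject": subject,
            "mean_rt": float(grp["rt"].mean()),
            "p_choose_best": float(best[grp.index.to_numpy()].mean()),
            "gaze_influence": float(pos["residual"].mean()) if len(pos) else np.nan,
        })
    out = pd.DataFrame(rows)
    # carry over between-subject factor labels where they are constant
    for col in factor_columns(data, n_items):
        per_subject = data.groupby("subject", sort=True)[col].agg(
            lambda s: s.iloc[0] if s.nunique() == 1 else np.nan
        )
        if not per_subject.isna().all():
            out[col] = per_subject.reindex(out["subject"]).to_numpy()
    return out


def _binned(x: np.ndarray, y: np.ndarray, n_bins: int) -> pd.DataFrame:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:  # degenerate range: center the single bin on the value
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        n = int(mask.sum())
        rows.append({
            "bin": b,
            "left": edges[b],
            "right": edges[b + 1],
            "center": 0.5 * (edges[b] + edges[b + 1]),
            "count": n,
            "mean": float(y[mask].mean()) if n else np.nan,
        })
    return pd.DataFrame(rows)


def behavioural_curves(data: pd.DataFrame, n_bins: int = 8) -> dict:
    """The four binned behavioural curves summarizing choice and RT patterns.

    Returns a dict of DataFrames (columns bin/left/right/center/count/mean):

    - ``rt_by_difficulty``: mean RT vs trial difficulty (best minus
      second-best item value).
    - ``p_choose_by_value``: P(item chosen) vs the item's relative value.
    - ``p_choose_by_gaze``: P(item chosen) vs the item's relative gaze.
    - ``corrected_p_choose_by_gaze``: choice probability corrected for
      relative value (observed minus value-model prediction) vs relative gaze.

    Bins are equal-width over the observed range; empty bins are reported
    with count 0 and an undefined (NaN) mean.
    """
    n_items = validate_trial_table(data, None)
    data = data.reset_index(drop=True)
    vcols, _ = item_columns(n_items)
    values = data[vcols].to_numpy(float)

    from .likelihood import _max_of_others

    difficulty = values.max(axis=1) - _max_of_others(values)[
        np.arange(len(data)), values.argmax(axis=1)
    ]
    items = long_item_table(data, n_items)
    items["residual"] = _value_model_residuals(items)

    return {
        "rt_by_difficulty": _binned(difficulty, data["rt"].to_numpy(float), n_bins),
        "p_choose_by_value": _binned(items["rel_value"].to_numpy(),
                                     items["chosen"].to_numpy(), n_bins),
        "p_choose_by_gaze": _binned(items["rel_gaze"].to_numpy(),
                                    items["chosen"].to_numpy(), n_bins),
        "corrected_p_choose_by_gaze": _binned(items["rel_gaze"].to_numpy(),
                                              items["residual"].to_numpy(), n_bins),
    }
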