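"""Train/validation splitting, cross-validation labels, and comparison
metrics (AIC, deviance-explained R^2, RMSE, rank correlations) plus the
observed-vs-predicted bias diagnostic."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SplitPlan", "make_split", "metrics", "obs_vs_pred_diagnostic"]


@dataclass(frozen=True)
class SplitPlan:
    """80:20 train/holdout split with tenfold CV labels on the training part.

    Each CV iteration therefore trains on 9 folds = 80% x 9/10 = 72% of all
    rows and tests on one fold (8%), with the 20% holdout reserved for final
    assessment.  ``subset`` restricts rows first: nymph_only / adult_only
    keep the corresponding life stage, ``all`` keeps everything (zeros
    included).
    """

    train_fraction: float = 0.8
    cv_folds: int = 10
    seed: int = 0
    subset: str = "all"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.subset not in ("all", "nymph_only", "adult_only"):
            raise ValueError(f"unknown subset {self.subset!r}")


def make_split(table: pd.DataFrame, plan: SplitPlan) -> pd.DataFrame:
    """Return the (subset of the) table with a ``split_label`` column:
    'holdout' for the final-assessment rows, 'fold01'..'foldNN' otherwise."""
    if plan.subset == "nymph_only":
        table = table[table["stage"] == "nymph"]
    elif plan.subset == "adult_only":
        table = table[table["stage"] == "adult"]
    table = table.reset_index(drop=True)
    n = len(table)
    if n == 0:
        raise ValueError(f"subset {plan.subset!r} selected no rows")
    if n < plan.cv_folds:
        raise ValueError("fewer rows than CV folds")
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(n)
    n_hold = int(round((1.0 - plan.train_fraction) * n))
    labels = np.empty(n, dtype=object)
    labels[order[:n_hold]] = "holdout"
    train_idx = order[n_hold:]
    for f, chunk in enumerate(np.array_split(train_idx, plan.cv_folds), start=1):
        labels[chunk] = f"fold{f:02d}"
    out = table.copy()
    out["split_label"] = labels
    out.attrs = dict(table.attrs)
    return out


def metrics(observed, predicted, model_meta: dict | None = None) -> dict:
    """Comparison metrics for one model.

    RMSE is computed on whatever scale the inputs are on (by convention the
    transformed, sixth-root scale); R^2 (deviance explained) and AIC come
    from the fit itself via ``model_meta``; rank correlations use
    average-rank tie handling.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("observed/predicted must be finite")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    rho = float(stats.spearmanr(obs, pred).statistic)
    tau = float(stats.kendalltau(obs, pred).statistic)
    out = {
        "rmse": rmse,
        "spearman_rho": rho,
        "kendall_tau": tau,
        "n": int(len(obs)),
        "rmse_scale": "transformed (density^lambda)",
    }
    if model_meta:
        for key in ("aic", "r_squared", "n_variables", "model", "metric_split"):
            if key in model_meta:
                out[key] = model_meta[key]
    return out


#: Default observed-density bin edges (individuals/m^2); the first bin
#: isolates exact zeros, the rest straddle the 0.6 and 1.0 densities where
#: over/under-estimation flips in this class of model.
_DEFAULT_BIN_EDGES = (0.0, 1e-9, 0.2, 0.6, 1.0, 2.0, np.inf)


def obs_vs_pred_diagnostic(
    observed_density, predicted_density, bin_edges=_DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Mean bias (predicted - observed) per observed-density bin, plus the
    identity-line scatter columns, for over/under-estimation diagnostics."""
    obs = np.asarray(observed_density, dtype=float)
    pred = np.asarray(predicted_density, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    which = np.clip(np.digitize(obs, edges[1:-1], right=False), 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        nb = int(sel.sum())
        bias = float(np.mean(pred[sel] - obs[sel])) if nb else np.nan
        se = (
            float(np.std(pred[sel] - obs[sel], ddof=1) / np.sqrt(nb))
            if nb > 1
            else np.nan
        )
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n": nb,
                "bias": bias,
                "bias_se": se,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["scatter"] = pd.DataFrame({"observed": obs, "predicted": pred})
    return out
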