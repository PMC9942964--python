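"""Analyses of the three simulated psychophysics experiments.

Rating normalization and attribute correlations, translucency binning,
discrimination summaries, 9-cell choice heat maps, and a multinomial-logit
choice model (maximum likelihood with observer-cluster bootstrap
confidence intervals for the conditional cell probabilities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from tagprobe.observer_sim import CHOICE_OPTIONS

PAIR_LEVELS = ("OO", "OT", "TT")  # reference: OO
LAYER_LEVELS = ("early", "middle", "late")  # reference: early
REFERENCE_CHOICE = "shape_orientation"

TRANSLUCENCY_BINS = {"low": (0.0, 0.2), "intermediate": (0.2, 0.6), "high": (0.6, 1.0)}


# ---------------------------------------------------------------------------
# ratings


def normalize_ratings(table: pd.DataFrame):
    """Per-observer min-max normalization, then mean over observers.

    Returns ``(mean_ratings, flags)`` where ``mean_ratings`` is an
    images x attributes frame of values in [0, 1] and ``flags`` lists
    (observer, attribute) pairs whose ratings were constant (mapped to the
    uninformative center 0.5 rather than dropped).
    """
    flags = []
    parts = []
    for (obs, attr), grp in table.groupby(["observer", "attribute"]):
        r = grp.rating.to_numpy(dtype=float)
        lo, hi = r.min(), r.max()
        if hi == lo:
            norm = np.full(len(r), 0.5)
            flags.append((obs, attr))
        else:
            norm = (r - lo) / (hi - lo)
        parts.append(
            pd.DataFrame(
                {
                    "observer": obs,
                    "attribute": attr,
                    "stimulus": grp.stimulus.to_numpy(),
                    "norm": norm,
                }
            )
        )
    normed = pd.concat(parts, ignore_index=True)
    mean = (
        normed.groupby(["stimulus", "attribute"]).norm.mean().unstack("attribute")
    )
    mean.index.name = "stimulus"
    return mean, flags


def attribute_correlations(mean_ratings: pd.DataFrame):
    """Symmetric Pearson matrix with p-values over attribute pairs."""
    if len(mean_ratings) < 10:
        raise ValueError("need at least 10 images")
    attrs = list(mean_ratings.columns)
    r = pd.DataFrame(np.eye(len(attrs)), index=attrs, columns=attrs)
    p = pd.DataFrame(np.zeros((len(attrs), len(attrs))), index=attrs, columns=attrs)
    flagged = []
    for i, a in enumerate(attrs):
        for j, b in enumerate(attrs):
            if j <= i:
                continue
            x = mean_ratings[a].to_numpy(dtype=float)
            y = mean_ratings[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                flagged.append((a, b))
                continue
            rr, pp = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p, flagged


def bin_by_translucency(values: Sequence[float]) -> List[str]:
    """Bin mean translucency ratings: low [0,.2), intermediate [.2,.6), high [.6,1]."""
    out = []
    for v in np.asarray(values, dtype=float):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"rating {v} outside [0, 1]")
        if v < 0.2:
            out.append("low")
        elif v < 0.6:
            out.append("intermediate")
        else:
            out.append("high")
    return out


# ---------------------------------------------------------------------------
# discrimination


def discrimination_summary(judgments: pd.DataFrame) -> dict:
    """Error rates per condition/repeat + per-image misjudgment distribution."""
    by_cond = (
        judgments.assign(error=~judgments.correct)
        .groupby(["is_real", "repeat"])
        .error.mean()
    )
    per_image = (
        judgments.assign(error=~judgments.correct)
        .groupby(["image", "is_real"])
        .error.mean()
        .reset_index()
        .rename(columns={"error": "misjudged_fraction"})
    )
    overall = {
        "generated_error": float(
            judgments.loc[~judgments.is_real, "correct"].eq(False).mean()
        ),
        "real_error": float(
            judgments.loc[judgments.is_real, "correct"].eq(False).mean()
        ),
    }
    return {
        "overall": overall,
        "per_condition_repeat": by_cond,
        "per_image": per_image,
    }


# ---------------------------------------------------------------------------
# choice heat map


def choice_heatmap(choices: pd.DataFrame):
    """9-cell x 4-attribute proportion matrix plus across-observer SDs."""
    cells = list(product(LAYER_LEVELS, PAIR_LEVELS))
    for layer, pair in cells:
        sub = choices[
            (choices.layer_group == layer) & (choices.pair_condition == pair)
        ]
        if sub.empty:
            raise ValueError(f"empty design cell: ({pair}, {layer})")
    idx = pd.MultiIndex.from_tuples(cells, names=["layer_group", "pair_condition"])
    props = pd.DataFrame(0.0, index=idx, columns=list(CHOICE_OPTIONS))
    sds = pd.DataFrame(0.0, index=idx, columns=list(CHOICE_OPTIONS))
    for layer, pair in cells:
        sub = choices[
            (choices.layer_group == layer) & (choices.pair_condition == pair)
        ]
        counts = sub.choice.value_counts(normalize=True)
        for opt in CHOICE_OPTIONS:
            props.loc[(layer, pair), opt] = counts.get(opt, 0.0)
        per_obs = (
            sub.groupby("observer")
            .choice.value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=list(CHOICE_OPTIONS), fill_value=0.0)
        )
        sds.loc[(layer, pair)] = per_obs.std(axis=0, ddof=1).to_numpy()
    return props, sds


# ---------------------------------------------------------------------------
# multinomial choice model


def _design_row(layer: str, pair: str, formula: str) -> np.ndarray:
    if formula == "intercept":
        return np.array([1.0])
    row = [1.0]
    row += [1.0 if layer == lv else 0.0 for lv in LAYER_LEVELS[1:]]
    row += [1.0 if pair == pv else 0.0 for pv in PAIR_LEVELS[1:]]
    for lv in LAYER_LEVELS[1:]:
        for pv in PAIR_LEVELS[1:]:
            row.append(1.0 if (layer == lv and pair == pv) else 0.0)
    return np.array(row)


def _cell_counts(choices: pd.DataFrame) -> pd.DataFrame:
    tab = (
        choices.groupby(["layer_group", "pair_condition"])
        .choice.value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CHOICE_OPTIONS), fill_value=0)
    )
    cells = list(product(LAYER_LEVELS, PAIR_LEVELS))
    return tab.reindex(pd.MultiIndex.from_tuples(cells, names=tab.index.names),
                       fill_value=0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _fit_softmax(X: np.ndarray, N: np.ndarray, ridge: float = 0.0):
    """Weighted multinomial-logit MLE on cell-aggregated counts.

    ``X`` is cells x P, ``N`` is cells x K counts; the first category is
    the reference (its coefficients are fixed at zero).  Returns the
    (K-1) x P coefficient matrix and a convergence flag.
    """
    n_cells, P = X.shape
    K = N.shape[1]

    def nll_grad(theta):
        B = theta.reshape(K - 1, P)
        logits = np.concatenate(
            [np.zeros((n_cells, 1)), X @ B.T], axis=1
        )
        p = _softmax(logits)
        ll = (N * np.log(np.maximum(p, 1e-300))).sum()
        resid = N - N.sum(axis=1, keepdims=True) * p  # cells x K
        grad = -(resid[:, 1:].T @ X)
        if ridge > 0:
            ll -= 0.5 * ridge * (theta**2).sum()
            grad += ridge * B
        return -ll, grad.ravel()

    x0 = np.zeros((K - 1) * P)
    res = optimize.minimize(
        nll_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
    )
    return res.x.reshape(K - 1, P), bool(res.success)


@dataclass
class ChoiceModelResult:
    coefficients: pd.DataFrame  # (category, predictor) log-odds vs reference
    cell_probs: pd.DataFrame  # cells x categories fitted probabilities
    ci_lower: Optional[pd.DataFrame]
    ci_upper: Optional[pd.DataFrame]
    converged: bool
    separation_flagged: bool
    ridge: float


def fit_choice_model(
    choices: pd.DataFrame,
    formula: str = "full",
    n_bootstrap: int = 200,
    seed: int = 0,
    ridge: float = 0.0,
    coef_bound: float = 15.0,
) -> ChoiceModelResult:
    """Multinomial logistic regression of choices on the design cells.

    Predictors are the layer-manipulation method, the source-target pair
    type and their interaction (reference coding; ``formula='intercept'``
    drops all predictors).  95% confidence intervals for the conditional
    cell probabilities come from a cluster bootstrap that resamples
    observers with replacement.  Complete separation (divergent
    coefficients) triggers a warning and a small-ridge refit.
    """
    if choices.choice.nunique() < 2:
        raise ValueError("need at least 2 observed choice categories")
    counts = _cell_counts(choices)
    cells = list(counts.index)
    X = np.stack([_design_row(l, p, formula) for l, p in cells])
    N = counts.to_numpy(dtype=float)

    B, ok = _fit_softmax(X, N, ridge=ridge)
    flagged = False
    if (np.abs(B) > coef_bound).any() or not ok:
        flagged = True
        warnings.warn(
            "possible complete separation; refitting with a small ridge penalty",
            RuntimeWarning,
            stacklevel=2,
        )
        B, ok = _fit_softmax(X, N, ridge=max(ridge, 1e-3))

    def cell_probabilities(Bmat):
        logits = np.concatenate([np.zeros((len(cells), 1)), X @ Bmat.T], axis=1)
        return _softmax(logits)

    probs = cell_probabilities(B)
    idx = pd.MultiIndex.from_tuples(cells, names=["layer_group", "pair_condition"])
    cell_probs = pd.DataFrame(probs, index=idx, columns=list(CHOICE_OPTIONS))

    ci_lo = ci_hi = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB00)))
        observers = choices.observer.unique()
        grouped = {o: g for o, g in choices.groupby("observer")}
        boots = np.empty((n_bootstrap, len(cells), len(CHOICE_OPTIONS)))
        eff_ridge = max(ridge, 1e-3) if flagged else ridge
        for b in range(n_bootstrap):
            draw = rng.choice(observers, size=len(observers), replace=True)
            samp = pd.concat([grouped[o] for o in draw], ignore_index=True)
            Nb = _cell_counts(samp).to_numpy(dtype=float)
            Bb, _ = _fit_softmax(X, Nb, ridge=eff_ridge)
            boots[b] = cell_probabilities(Bb)
        # bootstrap standard-error interval with t(G-1) quantiles: with few
        # observer clusters this outperforms raw percentile intervals,
        # whose quantile noise makes them undercover
        from scipy.stats import t as t_dist

        tcrit = t_dist.ppf(0.975, max(len(observers) - 1, 1))
        half = tcrit * boots.std(axis=0, ddof=1)
        lo = np.clip(probs - half, 0.0, 1.0)
        hi = np.clip(probs + half, 0.0, 1.0)
        ci_lo = pd.DataFrame(lo, index=idx, columns=list(CHOICE_OPTIONS))
        ci_hi = pd.DataFrame(hi, index=idx, columns=list(CHOICE_OPTIONS))

    pred_names = (
        ["intercept"]
        if formula == "intercept"
        else (
            ["intercept"]
            + [f"layer[{lv}]" for lv in LAYER_LEVELS[1:]]
            + [f"pair[{pv}]" for pv in PAIR_LEVELS[1:]]
            + [
                f"layer[{lv}]:pair[{pv}]"
                for lv in LAYER_LEVELS[1:]
                for pv in PAIR_LEVELS[1:]
            ]
        )
    )
    coef = pd.DataFrame(B, index=list(CHOICE_OPTIONS)[1:], columns=pred_names)
    return ChoiceModelResult(
        coefficients=coef,
        cell_probs=cell_probs,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        converged=ok,
        separation_flagged=flagged,
        ridge=ridge,
    )


__all__ = [
    "PAIR_LEVELS",
    "LAYER_LEVELS",
    "REFERENCE_CHOICE",
    "TRANSLUCENCY_BINS",
    "ChoiceModelResult",
    "normalize_ratings",
    "attribute_correlations",
    "bin_by_translucency",
    "discrimination_summary",
    "choice_heatmap",
    "fit_choice_model",
]
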