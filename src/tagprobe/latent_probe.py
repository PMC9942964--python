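"""Per-layer linear decision boundaries and the layer-wise tuning curve.

One max-margin linear classifier is trained per latent layer on that
layer's ``n x d`` slice, with the regularization constant chosen by nested
cross-validation over a strong-regularization grid (``C`` in
``[0.001, 0.1]``, 5 outer x 3 inner stratified folds, one-standard-error
tie-breaking toward the smallest C).  Boundaries are oriented so the
positive signed-distance side is the ``milky`` (opaque) class.

Predictions are min-max normalized signed distances over a fixed
evaluation set; correlating each layer's predictions with mean observer
attribute ratings yields the layer-wise tuning curve.  Pixel-space
embedding baselines (t-SNE / MDS + the same linear-probe protocol) are
provided as controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import MDS, TSNE
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from tagprobe.multiscale_generator import LatentCode

C_GRID = np.logspace(-3, -1, 7)
POSITIVE_CLASS = "milky"  # positive signed distance = milky/opaque side


@dataclass
class BoundaryModel:
    """One layer's linear decision boundary."""

    layer_index: int  # 1-based
    weights: np.ndarray
    bias: float
    C_selected: float
    cv_accuracy: float
    norm_bounds: Optional[Tuple[float, float]] = None

    def raw_distance(self, x: np.ndarray) -> np.ndarray:
        """Signed euclidean distance(s) from the boundary; milky positive."""
        x = np.asarray(x, dtype=float)
        return (x @ self.weights + self.bias) / np.linalg.norm(self.weights)


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        return (labels == POSITIVE_CLASS).astype(int)
    return labels.astype(int)


def _fit_svc(X, y, C, seed=0) -> LinearSVC:
    clf = LinearSVC(
        C=C, loss="hinge", dual=True, max_iter=200_000, tol=1e-6, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def _inner_select_C(X, y, seed, n_inner=3) -> float:
    """3-fold CV over the C grid; 1-SE rule favouring the smallest C."""
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
    accs = np.zeros((len(C_GRID), n_inner))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        for ci, C in enumerate(C_GRID):
            clf = _fit_svc(X[tr], y[tr], C, seed)
            accs[ci, f] = clf.score(X[te], y[te])
    mean = accs.mean(axis=1)
    se = accs.std(axis=1, ddof=1) / np.sqrt(n_inner)
    best = int(np.argmax(mean))
    thresh = mean[best] - se[best]
    eligible = np.flatnonzero(mean >= thresh)
    return float(C_GRID[eligible.min()])


def train_single_boundary(
    X: np.ndarray,
    labels,
    seed: int = 0,
    layer_index: int = 1,
    n_outer: int = 5,
    n_inner: int = 3,
) -> BoundaryModel:
    """Nested-CV linear boundary on one feature slice."""
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = len(y)
    min_class = np.bincount(y).min()
    if n < 20 or min_class < n_outer:
        raise ValueError(
            f"n={n} (min class {min_class}) too small for "
            f"{n_outer}x{n_inner} nested cross-validation"
        )
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    outer_scores = []
    for tr, te in outer.split(X, y):
        C = _inner_select_C(X[tr], y[tr], seed, n_inner)
        clf = _fit_svc(X[tr], y[tr], C, seed)
        outer_scores.append(clf.score(X[te], y[te]))
    C_final = _inner_select_C(X, y, seed, n_inner)
    clf = _fit_svc(X, y, C_final, seed)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    # orient: milky (y == 1) on the positive side
    if (X[y == 1] @ w + b).mean() < (X[y == 0] @ w + b).mean():
        w, b = -w, -b
    return BoundaryModel(
        layer_index=layer_index,
        weights=w,
        bias=b,
        C_selected=C_final,
        cv_accuracy=float(np.mean(outer_scores)),
    )


def train_layer_boundaries(
    latents: np.ndarray, labels, seed: int = 0
) -> List[BoundaryModel]:
    """One boundary per layer of an ``n x L x d`` latent stack."""
    latents = np.asarray(latents, dtype=float)
    if latents.ndim != 3:
        raise ValueError("latents must be an n x L x d array")
    n, L, d = latents.shape
    return [
        train_single_boundary(latents[:, i, :], labels, seed=seed, layer_index=i + 1)
        for i in range(L)
    ]


def finalize_norm_bounds(
    boundaries: Sequence[BoundaryModel], eval_latents: np.ndarray
) -> None:
    """Fix each boundary's min/max raw distance over the evaluation set."""
    eval_latents = np.asarray(eval_latents, dtype=float)
    for bm in boundaries:
        raw = bm.raw_distance(eval_latents[:, bm.layer_index - 1, :])
        bm.norm_bounds = (float(raw.min()), float(raw.max()))


def predict_translucency(code: LatentCode, boundary: BoundaryModel) -> float:
    """Min-max normalized signed distance of one code from the boundary."""
    if boundary.norm_bounds is None:
        raise ValueError(
            "norm_bounds unset; call finalize_norm_bounds over the "
            "evaluation set first"
        )
    lo, hi = boundary.norm_bounds
    raw = float(boundary.raw_distance(code.layers[boundary.layer_index - 1]))
    if hi <= lo:
        return 0.5
    return float(np.clip((raw - lo) / (hi - lo), 0.0, 1.0))


def layer_scores(boundary: BoundaryModel, latents: np.ndarray) -> np.ndarray:
    """Vectorized ``predict_translucency`` over an ``n x L x d`` stack."""
    if boundary.norm_bounds is None:
        raise ValueError("norm_bounds unset")
    lo, hi = boundary.norm_bounds
    raw = boundary.raw_distance(
        np.asarray(latents, float)[:, boundary.layer_index - 1, :]
    )
    if hi <= lo:
        return np.full(len(raw), 0.5)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class TuningCurve:
    """Per-layer, per-attribute correlation between predictions and ratings."""

    table: pd.DataFrame  # columns: layer, attribute, r, p, significant, computed

    def peak_layer(self, attribute: str) -> int:
        sub = self.table[
            (self.table.attribute == attribute) & self.table.computed
        ]
        row = sub.loc[sub.r.abs().idxmax()]
        return int(row.layer)

    def r(self, layer: int, attribute: str) -> float:
        sub = self.table[
            (self.table.layer == layer) & (self.table.attribute == attribute)
        ]
        return float(sub.r.iloc[0])


def tuning_curve(
    boundaries: Sequence[BoundaryModel],
    eval_latents: np.ndarray,
    ratings: pd.DataFrame,
    alpha: float = 0.05,
) -> TuningCurve:
    """Pearson r (two-sided p) per layer per rating attribute.

    ``ratings`` is an images x attributes frame aligned with
    ``eval_latents``; zero-variance predictions or ratings are flagged as
    not computed rather than reported as spurious correlations.
    """
    eval_latents = np.asarray(eval_latents, dtype=float)
    if len(ratings) != len(eval_latents):
        raise ValueError("ratings must align with evaluation codes")
    if len(ratings) < 10:
        raise ValueError("need at least 10 evaluation images")
    rows = []
    for bm in boundaries:
        preds = layer_scores(bm, eval_latents)
        for attr in ratings.columns:
            vals = ratings[attr].to_numpy(dtype=float)
            if np.ptp(preds) == 0 or np.ptp(vals) == 0:
                rows.append((bm.layer_index, attr, np.nan, np.nan, False, False))
                continue
            r, p = stats.pearsonr(preds, vals)
            rows.append((bm.layer_index, attr, r, p, p < alpha, True))
    return TuningCurve(
        pd.DataFrame(
            rows, columns=["layer", "attribute", "r", "p", "significant", "computed"]
        )
    )


# ---------------------------------------------------------------------------
# pixel-embedding baselines


def _flatten(images) -> np.ndarray:
    return np.stack([np.asarray(im.pixels if hasattr(im, "pixels") else im).ravel()
                     for im in images])


def pixel_embedding_baseline(
    train_images,
    train_labels,
    eval_images,
    method: str,
    embed_dim: int = 16,
    ratings: Optional[pd.DataFrame] = None,
    perplexity: float = 15.0,
    max_iter: int = 300,
    seed: int = 0,
) -> Dict:
    """Linear-probe protocol applied to a pixel-space embedding.

    A joint embedding of train + eval images is computed (the classifier
    then sees training rows only), a linear boundary is trained on it with
    the same nested-CV protocol as the latent probes, and normalized
    distances over the eval rows are correlated with the ratings.
    """
    if method not in ("tsne", "mds"):
        raise ValueError(f"unknown embedding method: {method!r}")
    Xtr, Xev = _flatten(train_images), _flatten(eval_images)
    n_train = len(Xtr)
    X = np.concatenate([Xtr, Xev])
    if method == "tsne":
        if perplexity >= n_train:
            raise ValueError("perplexity must be smaller than n_train")
        emb = TSNE(
            n_components=embed_dim,
            method="exact",
            perplexity=perplexity,
            max_iter=max_iter,
            init="random",
            random_state=seed,
        ).fit_transform(X)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            emb = MDS(
                n_components=embed_dim,
                dissimilarity="euclidean",
                max_iter=max_iter,
                normalized_stress=False,
                random_state=seed,
                n_init=1,
            ).fit_transform(X)

    bm = train_single_boundary(emb[:n_train], train_labels, seed=seed, layer_index=1)
    stack = emb[n_train:][:, None, :]
    finalize_norm_bounds([bm], stack)
    scores = layer_scores(bm, stack)

    out = {
        "method": method,
        "embedding": emb,
        "boundary": bm,
        "scores": scores,
        "cv_accuracy": bm.cv_accuracy,
    }
    if ratings is not None:
        r_hc = {}
        for attr in ratings.columns:
            vals = ratings[attr].to_numpy(dtype=float)
            if np.std(scores) == 0 or np.std(vals) == 0:
                r_hc[attr] = (np.nan, np.nan)
            else:
                r_hc[attr] = stats.pearsonr(scores, vals)
        out["r_hc"] = {k: {"r": v[0], "p": v[1]} for k, v in r_hc.items()}
    return out


__all__ = [
    "BoundaryModel",
    "TuningCurve",
    "C_GRID",
    "POSITIVE_CLASS",
    "train_single_boundary",
    "train_layer_boundaries",
    "finalize_norm_bounds",
    "predict_translucency",
    "layer_scores",
    "tuning_curve",
    "pixel_embedding_baseline",
]
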