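"""Downstream evaluation: multi-label metrics, ML-kNN, aRRMSE, rank scores.

The benchmarking protocol mirrors standard filter-selection practice:
repeated 50/50 holdout splits (stratified by labelset frequency where
feasible), feature selection and classifier training on the training half
only, evaluation of top-K feature prefixes on the held-out half, and
per-K rank scores averaged over the K grid to compare criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import f1_score, hamming_loss, label_ranking_loss
from sklearn.neighbors import KNeighborsRegressor, NearestNeighbors
from sklearn.model_selection import train_test_split

__all__ = [
    "EvalProtocol",
    "multilabel_metrics",
    "mlknn_predict",
    "arrmse",
    "rank_scores",
    "balanced_holdout_split",
    "run_protocol",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def multilabel_metrics(scores, predictions, truth) -> dict[str, float]:
    """Hamming loss, ranking loss, normalized coverage and macro-F1.

    - hamming: mean bitwise disagreement between predictions and truth.
    - ranking_loss: mean fraction of (relevant, irrelevant) label pairs
      ordered wrongly by the scores; a score tie counts as misordered
      (pessimistic convention). Samples with no relevant or no irrelevant
      labels contribute 0.
    - normalized_coverage: mean depth down the score ranking needed to
      cover every relevant label, divided by the number of labels m
      (so it lies in [0, 1]).
    - macro_f: unweighted mean per-label F1; a label with no positives in
      either truth or prediction scores F1 = 1 by convention.
    """
    scores = np.asarray(scores, dtype=float)
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if not (scores.shape == predictions.shape == truth.shape):
        raise ValueError("scores, predictions and truth must share one shape")
    m = truth.shape[1]
    any_pos = truth.any(axis=0).any()
    return {
        "hamming": float(hamming_loss(truth, predictions)),
        "ranking_loss": float(label_ranking_loss(truth, scores)) if any_pos else 0.0,
        # coverage_error counts ranks starting at 1; samples without
        # relevant labels contribute 0 depth
        "normalized_coverage": float(
            np.mean(_coverage_depths(truth, scores)) / m
        ),
        "macro_f": float(
            f1_score(truth, predictions, average="macro", zero_division=1.0)
        ),
    }


def _coverage_depths(truth: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Per-sample ranking depth needed to cover all relevant labels.

    Ties in the scores are resolved pessimistically (a relevant label tied
    with irrelevant ones counts the full tied block), matching
    sklearn's ``coverage_error``; samples with no relevant label get 0.
    """
    n, m = truth.shape
    depths = np.zeros(n)
    t = truth.astype(bool)
    for i in range(n):
        if t[i].any():
            worst_rel = scores[i][t[i]].min()
            depths[i] = np.sum(scores[i] >= worst_rel)
    return depths


def arrmse(predictions, truth, train_mean) -> float:
    """Average relative root mean squared error across targets.

    Per target: RMSE of the predictions divided by the RMSE of always
    predicting the training-set mean, then averaged over targets.
    """
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    train_mean = np.asarray(train_mean, dtype=float)
    if predictions.shape != truth.shape:
        raise ValueError("shape mismatch between predictions and truth")
    num = np.sqrt(np.mean((predictions - truth) ** 2, axis=0))
    den = np.sqrt(np.mean((truth - train_mean[None, :]) ** 2, axis=0))
    for t, d in enumerate(den):
        if d == 0:
            raise ValueError(f"target {t} has zero variance around the training mean")
    return float(np.mean(num / den))


def rank_scores(per_k_losses, higher_is_better: bool = False) -> np.ndarray:
    """Average per-K dense ranks of competing methods.

    ``per_k_losses`` is a (n_methods, n_K) array; for every K the best
    method gets rank 1 (ties share the average rank), and ranks are then
    averaged over the K grid.
    """
    losses = np.asarray(per_k_losses, dtype=float)
    if np.isnan(losses).any():
        raise ValueError("NaN losses in rank_scores input")
    if higher_is_better:
        losses = -losses
    ranks = np.apply_along_axis(lambda col: rankdata(col, method="average"),
                                0, losses)
    return ranks.mean(axis=1)


# ---------------------------------------------------------------------------
# ML-kNN (multi-label k-nearest-neighbour classifier)
# ---------------------------------------------------------------------------


def mlknn_predict(train_X, train_Y, test_X, k: int = 7, smoothing: float = 1.0):
    """ML-kNN posterior label scores and hard predictions.

    For each label the classifier estimates, with Laplace smoothing ``s``,
    the prior of the label and the likelihood of observing ``c`` positive
    neighbours (c = 0..k) given the label's presence/absence, from
    leave-one-out neighbour counts on the training set. Test scores are the
    posterior probabilities of label presence given the test point's
    neighbour count; predictions threshold the posterior at 0.5.
    Neighbour ties are resolved by the search backend's index order.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_Y = np.asarray(train_Y, dtype=np.int64)
    test_X = np.asarray(test_X, dtype=float)
    n, m = train_Y.shape
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n_train={n}")
    s = float(smoothing)

    prior1 = (s + train_Y.sum(axis=0)) / (2 * s + n)
    prior0 = 1.0 - prior1

    nn = NearestNeighbors(n_neighbors=k + 1).fit(train_X)
    _, idx = nn.kneighbors(train_X)
    # drop each point itself (leave-one-out); it is its own nearest neighbour
    loo = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k]
        loo[i] = row
    counts = train_Y[loo].sum(axis=1)  # (n, m): positive neighbours per label

    # kj1[l, c]: training points with label l and c positive neighbours
    kj1 = np.zeros((m, k + 1))
    kj0 = np.zeros((m, k + 1))
    for l in range(m):
        pos = train_Y[:, l] == 1
        kj1[l] = np.bincount(counts[pos, l], minlength=k + 1)
        kj0[l] = np.bincount(counts[~pos, l], minlength=k + 1)
    like1 = (s + kj1) / (s * (k + 1) + kj1.sum(axis=1, keepdims=True))
    like0 = (s + kj0) / (s * (k + 1) + kj0.sum(axis=1, keepdims=True))

    _, tidx = nn.kneighbors(test_X, n_neighbors=k)
    tcounts = train_Y[tidx].sum(axis=1)  # (n_test, m)
    p1 = prior1[None, :] * like1[np.arange(m)[None, :], tcounts]
    p0 = prior0[None, :] * like0[np.arange(m)[None, :], tcounts]
    scores = p1 / (p1 + p0)
    return scores, (scores > 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------


@dataclass
class EvalProtocol:
    """Repeated balanced-holdout evaluation protocol.

    Defaults follow the standard benchmark setting: 30 repeats of a 50/50
    split, top-K grid K = 1..50, 7 neighbours for ML-kNN classification and
    10 for kNN regression.
    """

    n_repeats: int = 30
    split_fraction: float = 0.5
    k_grid: tuple[int, ...] = tuple(range(1, 51))
    knn_k: int = 7
    knn_k_regression: int = 10
    seed: int | None = None


def balanced_holdout_split(Y, test_fraction: float, rng: np.random.Generator,
                           task: str = "classification"):
    """One train/test split, stratified by labelset frequency when feasible.

    Labelsets with at least two occurrences stratify the split; rarer ones
    are pooled into a single stratum (or, for regression, the split is a
    plain random one). Returns (train_idx, test_idx).
    """
    Y = np.asarray(Y)
    n = Y.shape[0]
    strat = None
    if task == "classification":
        _, codes, counts = np.unique(Y, axis=0, return_inverse=True,
                                     return_counts=True)
        strat = np.where(counts[codes] >= 2, codes, -1)
        pool = strat == -1
        if pool.sum() == 1 or (strat != -1).sum() == 0:
            strat = None  # a singleton stratum cannot be split
    seed = int(rng.integers(2**31))
    idx = np.arange(n)
    try:
        train_idx, test_idx = train_test_split(
            idx, test_size=test_fraction, random_state=seed, stratify=strat)
    except ValueError:
        train_idx, test_idx = train_test_split(
            idx, test_size=test_fraction, random_state=seed, stratify=None)
    return np.sort(train_idx), np.sort(test_idx)


def run_protocol(X, Y, criteria: dict, protocol: EvalProtocol,
                 task: str = "classification", n_bins: int = 5,
                 return_selections: bool = False):
    """Run the repeated-holdout benchmark for a set of criteria.

    ``criteria`` maps a method name to a :class:`~groupjmi.criteria.CriterionSpec`
    (group criteria are re-seeded per repeat from the protocol stream).
    Feature selection sees only the training half — discretization and
    selection never touch the test rows. Returns a tidy frame with one row
    per (method, metric, K, repeat); with ``return_selections=True`` also
    returns a {(method, repeat): ordered feature list} dict.
    """
    from dataclasses import replace as _replace

    from .criteria import CriterionSpec, forward_select
    from .mi_core import DiscretizedMatrix, discretize_equal_width

    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    rng = np.random.default_rng(protocol.seed)
    k_max = max(protocol.k_grid)
    rows = []
    selections: dict[tuple[str, int], list[int]] = {}
    for rep in range(protocol.n_repeats):
        train_idx, test_idx = balanced_holdout_split(
            Y, 1.0 - protocol.split_fraction, rng, task)
        Xtr_raw, Xte_raw = X[train_idx], X[test_idx]
        Ytr, Yte = Y[train_idx], Y[test_idx]
        # bin on the training half only
        codes = np.empty_like(Xtr_raw, dtype=np.int64)
        for j in range(X.shape[1]):
            codes[:, j], _ = discretize_equal_width(Xtr_raw[:, j], n_bins)
        disc = DiscretizedMatrix(codes, [], n_bins)

        for name, spec in criteria.items():
            spec_r = spec
            if spec.grouping is not None:
                g = _replace(spec.grouping, seed=int(rng.integers(2**31)))
                spec_r = CriterionSpec(spec.name, g, spec.tiebreak)
            target_arg = Ytr if task == "classification" else Ytr.astype(float)
            state = forward_select(disc, target_arg, min(k_max, X.shape[1]),
                                   spec_r)
            order = state.selected
            selections[(name, rep)] = list(order)
            for K in protocol.k_grid:
                feats = order[:K]
                if task == "classification":
                    scores, preds = mlknn_predict(
                        Xtr_raw[:, feats], Ytr, Xte_raw[:, feats],
                        k=protocol.knn_k)
                    metrics = multilabel_metrics(scores, preds, Yte)
                else:
                    reg = KNeighborsRegressor(
                        n_neighbors=protocol.knn_k_regression)
                    reg.fit(Xtr_raw[:, feats], Ytr)
                    pred = reg.predict(Xte_raw[:, feats])
                    metrics = {"arrmse": arrmse(pred, Yte, Ytr.mean(axis=0))}
                for metric, value in metrics.items():
                    rows.append({"method": name, "metric": metric, "K": K,
                                 "repeat": rep, "value": value})
    table = pd.DataFrame(rows)
    if return_selections:
        return table, selections
    return table
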