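"""Discretization and plug-in estimation of entropy and mutual information.

All information quantities are maximum-likelihood ("plug-in") estimates on
discrete codes and are returned in nats (natural log). Multiply by
``1 / ln 2`` (≈1.4427) to convert to bits.

The estimators here are deliberately the raw plug-in quantities: no
Miller–Madow or other small-sample bias correction is applied, because the
selection criteria built on top of them compare scores whose biases largely
cancel, and because reproducibility of the exact estimator matters more for
a filter method than absolute accuracy of each entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscretizedMatrix",
    "JointDistribution",
    "discretize_equal_width",
    "estimate_joint",
    "entropy",
    "mutual_information",
    "joint_pair_mi",
    "conditional_mi",
]


class DataError(ValueError):
    """Raised when input data violate the estimator's preconditions."""


def discretize_equal_width(values, n_bins: int, name: str | None = None):
    """Discretize a real-valued column into equal-width bins.

    The range [min, max] is split into ``n_bins`` intervals of equal width.
    The leftmost interval is closed on the left and every interval is closed
    on the right: a value equal to an interior cut point falls in the lower
    bin, and the maximum falls in the top bin. A constant column maps to the
    single code 0 with no cut points.

    Parameters
    ----------
    values : array-like of shape (N,)
        Finite real values, N >= 1.
    n_bins : int
        Number of bins requested (>= 1). The effective number of bins may be
        smaller when the column carries fewer distinct values.
    name : str, optional
        Column name used in error messages.

    Returns
    -------
    codes : ndarray of int64, shape (N,)
    edges : ndarray of float, shape (b - 1,)
        Interior cut points; empty for constant columns or ``n_bins == 1``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise DataError("discretize_equal_width expects a non-empty 1-d column")
    if not np.all(np.isfinite(v)):
        label = f" {name!r}" if name else ""
        raise DataError(f"non-finite values in column{label}")
    if int(n_bins) < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    n_bins = int(n_bins)
    lo, hi = v.min(), v.max()
    if lo == hi or n_bins == 1:
        return np.zeros(v.shape[0], dtype=np.int64), np.empty(0, dtype=float)
    edges = lo + (hi - lo) * np.arange(1, n_bins) / n_bins
    # side='left': value == edge counts as "not beyond", i.e. lower bin.
    codes = np.searchsorted(edges, v, side="left").astype(np.int64)
    return codes, edges


@dataclass
class DiscretizedMatrix:
    """Integer-coded feature matrix: the estimator's sole feature input.

    ``codes[:, j]`` takes values in ``{0, ..., n_levels[j] - 1}``.
    Columns declared categorical are passed through with a bijective code
    map and carry no bin edges.
    """

    codes: np.ndarray
    bin_edges: list[np.ndarray]
    n_bins_requested: int
    feature_names: list[str] = field(default_factory=list)
    categorical: np.ndarray | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be an N x d matrix")
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(self.codes.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_features(self) -> int:
        return self.codes.shape[1]

    @property
    def n_levels(self) -> np.ndarray:
        return self.codes.max(axis=0) + 1

    def column(self, j: int) -> np.ndarray:
        return self.codes[:, j]

    @classmethod
    def from_data(cls, X, n_bins: int = 5, categorical=None, feature_names=None):
        """Bin a raw feature matrix column by column.

        Columns flagged in ``categorical`` (boolean mask or list of column
        indices/names) are re-coded bijectively instead of binned; detection
        is never inferred from the data. Accepts a DataFrame or 2-d array.
        """
        try:
            import pandas as pd

            if isinstance(X, pd.DataFrame):
                if feature_names is None:
                    feature_names = [str(c) for c in X.columns]
                if categorical is not None and not isinstance(categorical, np.ndarray):
                    cat_list = list(categorical)
                    if cat_list and isinstance(cat_list[0], str):
                        categorical = [c in cat_list for c in X.columns]
                X = X.to_numpy()
        except ImportError:  # pragma: no cover
            pass
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-d")
        n, d = X.shape
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(d)]
        if categorical is None:
            cat = np.zeros(d, dtype=bool)
        else:
            cat = np.zeros(d, dtype=bool)
            cat_arr = np.asarray(categorical)
            if cat_arr.dtype == bool:
                cat[:] = cat_arr
            else:
                cat[cat_arr.astype(int)] = True
        codes = np.empty((n, d), dtype=np.int64)
        edges: list[np.ndarray] = []
        for j in range(d):
            col = X[:, j]
            if cat[j]:
                _, inv = np.unique(col, return_inverse=True)
                codes[:, j] = inv
                edges.append(np.empty(0, dtype=float))
            else:
                codes[:, j], e = discretize_equal_width(
                    col.astype(float), n_bins, name=feature_names[j]
                )
                edges.append(e)
        return cls(codes, edges, int(n_bins), list(feature_names), cat)


# ---------------------------------------------------------------------------
# Plug-in estimation
# ---------------------------------------------------------------------------


def _as_codes(x) -> np.ndarray:
    """Collapse 1-d or 2-d integer input to a single compressed code column."""
    a = np.asarray(x)
    if a.size == 0:
        raise DataError("empty input")
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise DataError("inputs must be 1-d or 2-d integer arrays")
    if a.shape[1] == 1:
        _, inv = np.unique(a[:, 0], return_inverse=True)
        return inv.astype(np.int64)
    _, inv = np.unique(a, axis=0, return_inverse=True)
    return inv.astype(np.int64)


def _check_lengths(*arrays):
    n = len(arrays[0])
    for a in arrays[1:]:
        if len(a) != n:
            raise DataError(f"length mismatch: {n} vs {len(a)}")


@dataclass
class JointDistribution:
    """Dense maximum-likelihood joint probability table over observed alphabets."""

    axes: list[str]
    probs: np.ndarray
    n_samples: int
    levels: list[np.ndarray]


def estimate_joint(codes_a, codes_b) -> JointDistribution:
    """Maximum-likelihood joint distribution of two (possibly vector) variables.

    The table's alphabets are the values observed in the sample; every cell
    is exactly count / n_samples.
    """
    a = np.asarray(codes_a)
    b = np.asarray(codes_b)
    _check_lengths(np.atleast_2d(a.T).T, np.atleast_2d(b.T).T)
    ca, cb = _as_codes(a), _as_codes(b)
    _check_lengths(ca, cb)
    la = np.unique(a.reshape(len(ca), -1), axis=0)
    lb = np.unique(b.reshape(len(cb), -1), axis=0)
    na, nb = ca.max() + 1, cb.max() + 1
    counts = np.bincount(ca * nb + cb, minlength=na * nb).reshape(na, nb)
    return JointDistribution(
        axes=["A", "B"],
        probs=counts / len(ca),
        n_samples=int(len(ca)),
        levels=[la, lb],
    )


def _mi_from_counts(counts: np.ndarray) -> float:
    # work on integer marginal counts so that degenerate tables (constant
    # margins, deterministic dependence) cancel exactly in floating point
    n = counts.sum()
    ra = counts.sum(axis=1)
    cb = counts.sum(axis=0)
    i, j = np.nonzero(counts)
    c = counts[i, j].astype(float)
    # grouping chosen so that degenerate margins cancel exactly:
    # constant B: both brackets are 0; constant A: the brackets are equal
    terms = (np.log(c) - np.log(ra[i].astype(float))) \
        - (np.log(cb[j].astype(float)) - np.log(float(n)))
    mi = float(np.sum((c / n) * terms))
    return max(mi, 0.0)


def _mi_codes(ca: np.ndarray, na: int, cb: np.ndarray, nb: int) -> float:
    """MI of two pre-compressed code columns (fast path, no re-compression)."""
    counts = np.bincount(ca * nb + cb, minlength=na * nb).reshape(na, nb)
    return _mi_from_counts(counts)


def entropy(x) -> float:
    """Plug-in entropy H(X) in nats."""
    c = _as_codes(x)
    counts = np.bincount(c)
    p = counts[counts > 0] / len(c)
    return float(-np.sum(p * np.log(p)))


def mutual_information(a, b) -> float:
    """Plug-in mutual information I(A;B) in nats, clamped to be >= 0.

    Accepts 1-d code columns or 2-d blocks (a block is treated as its joint
    Cartesian-coded variable). Symmetric in its arguments.
    """
    ca, cb = _as_codes(a), _as_codes(b)
    _check_lengths(ca, cb)
    return _mi_codes(ca, int(ca.max()) + 1, cb, int(cb.max()) + 1)


def joint_pair_mi(xj, xk, t) -> float:
    """I(Xj Xk; T): mutual information between a feature pair and a target.

    The pair (Xj, Xk) is Cartesian-coded into one variable; the result is
    exactly ``mutual_information`` applied to that paired variable and T.
    """
    xj = np.asarray(xj)
    xk = np.asarray(xk)
    _check_lengths(xj, xk)
    cj, ck = _as_codes(xj), _as_codes(xk)
    pair = cj * (int(ck.max()) + 1) + ck
    return mutual_information(pair, t)


def conditional_mi(a, b, c) -> float:
    """Plug-in conditional mutual information I(A;B|C) in nats.

    Computed as the C-weighted average of within-stratum MI:
    sum_c p(c) I(A;B | C=c).
    """
    ca, cb, cc = _as_codes(a), _as_codes(b), _as_codes(c)
    _check_lengths(ca, cb, cc)
    n = len(ca)
    total = 0.0
    for level in np.unique(cc):
        mask = cc == level
        w = mask.sum() / n
        total += w * mutual_information(ca[mask], cb[mask])
    return max(total, 0.0)
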