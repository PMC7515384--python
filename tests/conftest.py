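"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's fast paths: the MI oracle
is a literal triple sum over observed alphabets, and the selection oracle
recomputes every candidate score from scratch at every greedy step through
the public scoring functions.
"""

import numpy as np
import pytest


def naive_joint_pair_mi(xj, xk, t):
    """Literal triple sum: I(Xj Xk; T) over all observed value triples."""
    xj, xk, t = (np.asarray(a) for a in (xj, xk, t))
    n = len(t)
    total = 0.0
    for vj in np.unique(xj):
        for vk in np.unique(xk):
            pjk = np.mean((xj == vj) & (xk == vk))
            if pjk == 0:
                continue
            for vt in np.unique(t):
                pt = np.mean(t == vt)
                pjkt = np.mean((xj == vj) & (xk == vk) & (t == vt))
                if pjkt > 0:
                    total += pjkt * np.log(pjkt / (pjk * pt))
    return total


def naive_mi(a, b):
    """Literal double sum over observed alphabets."""
    a, b = np.asarray(a), np.asarray(b)
    total = 0.0
    for va in np.unique(a):
        pa = np.mean(a == va)
        for vb in np.unique(b):
            pb = np.mean(b == vb)
            pab = np.mean((a == va) & (b == vb))
            if pab > 0:
                total += pab * np.log(pab / (pa * pb))
    return total


def naive_forward_select(codes, targets, k, criterion, quantized_codes=None):
    """Greedy selection recomputing every score naively at every step.

    ``criterion``: 'mim-br', 'single-jmi', 'joint-jmi' or 'group-jmi' (the
    last scores against precomputed ``quantized_codes``). First step uses
    the relevancy-only rule for every criterion; ties go to the lowest
    feature index (numpy argmax on an index-ordered array).
    """
    codes = np.asarray(codes)
    d = codes.shape[1]
    if criterion == "group-jmi":
        target_matrix = np.asarray(quantized_codes)
    elif criterion == "joint-jmi":
        Y = np.asarray(targets)
        _, inv = np.unique(Y, axis=0, return_inverse=True)
        target_matrix = inv[:, None]
    else:
        target_matrix = np.asarray(targets)
        if target_matrix.ndim == 1:
            target_matrix = target_matrix[:, None]
    selected: list[int] = []
    trace_scores: list[np.ndarray] = []
    for _ in range(k):
        scores = np.full(d, -np.inf)
        for j in range(d):
            if j in selected:
                continue
            if not selected or criterion == "mim-br":
                scores[j] = sum(naive_mi(codes[:, j], target_matrix[:, i])
                                for i in range(target_matrix.shape[1]))
            else:
                scores[j] = sum(
                    naive_joint_pair_mi(codes[:, s], codes[:, j],
                                        target_matrix[:, i])
                    for s in selected
                    for i in range(target_matrix.shape[1])
                )
        trace_scores.append(scores)
        selected.append(int(np.argmax(scores)))
    return selected, trace_scores


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_discrete_instance(rng, n_max=50, d_max=4, alphabet_max=4):
    """A small random discrete dataset for estimator property tests."""
    n = int(rng.integers(4, n_max + 1))
    cols = [rng.integers(0, int(rng.integers(2, alphabet_max + 1)), size=n)
            for _ in range(d_max)]
    return [np.asarray(c) for c in cols]
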