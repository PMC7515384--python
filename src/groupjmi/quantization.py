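"""Output-space quantization: random target grouping + k-medoids clustering.

The multi-target output space ``Y = Y1..Ym`` is transformed into
pseudo-targets ``Ỹ = Ỹ1..Ỹm`` in two steps:

1. *Grouping* — draw ``n_groups`` random subsets of the targets, each a
   without-replacement sample of ``round(m * PoT)`` targets (PoT =
   Proportion of Targets). Overlap between groups is allowed.
2. *Clustering* — for each group, cluster the samples' restricted output
   vectors into NoC clusters with k-medoids (Hamming distance for
   categorical/binary targets, Euclidean for continuous ones) and take the
   cluster index as a new categorical pseudo-target.

Each pseudo-target is a low-cardinality summary of the joint behaviour of
its group, so mutual-information expressions against it stay estimable from
modest samples while still reflecting inter-target dependence.

The randomized variant draws, independently for every group, PoT uniformly
from [0.25, 0.75] and NoC uniformly from {4, ..., 16}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TargetGroup",
    "GroupingConfig",
    "QuantizedTargets",
    "sample_target_groups",
    "kmedoids_cluster",
    "quantize_output_space",
    "draw_rand_params",
    "RAND_POT_RANGE",
    "RAND_NOC_RANGE",
]

logger = logging.getLogger(__name__)

# Randomized-parameter ranges of the Group-JMI-Rand criterion.
RAND_POT_RANGE = (0.25, 0.75)
RAND_NOC_RANGE = (4, 16)

MAX_ITER = 100


@dataclass(frozen=True)
class TargetGroup:
    """One random subset of target indices (0-based), overlap allowed."""

    member_indices: tuple[int, ...]
    group_id: int

    def __post_init__(self):
        if len(self.member_indices) == 0:
            raise ValueError("a target group cannot be empty")
        if len(set(self.member_indices)) != len(self.member_indices):
            raise ValueError("duplicate target indices within a group")


@dataclass
class GroupingConfig:
    """Parameters that fully determine the output-space transformation.

    ``pot`` and ``noc`` may be fixed values or (lo, hi) ranges; ranges mean
    every group independently draws its own value (continuous-uniform for
    pot, discrete-uniform for noc), which is the randomized variant.
    """

    pot: float | tuple[float, float] = 0.5
    noc: int | tuple[int, int] = 8
    metric: str = "hamming"
    seed: int | None = None
    n_groups: int | None = None  # defaults to the number of targets m

    def __post_init__(self):
        if self.metric not in ("hamming", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if isinstance(self.pot, (tuple, list)):
            lo, hi = self.pot
            if not (0 < lo <= hi <= 1):
                raise ValueError(f"pot range must satisfy 0 < lo <= hi <= 1, got {self.pot}")
            self.pot = (float(lo), float(hi))
        elif not (0 < self.pot <= 1):
            raise ValueError(f"pot must be in (0, 1], got {self.pot}")
        if isinstance(self.noc, (tuple, list)):
            lo, hi = self.noc
            if not (2 <= lo <= hi):
                raise ValueError(f"noc range must satisfy 2 <= lo <= hi, got {self.noc}")
            self.noc = (int(lo), int(hi))
        elif int(self.noc) < 1:
            raise ValueError(f"noc must be >= 1, got {self.noc}")

    @classmethod
    def randomized(cls, metric: str = "hamming", seed: int | None = None,
                   n_groups: int | None = None) -> "GroupingConfig":
        """The Group-JMI-Rand parameterization: PoT ~ U[0.25, 0.75], NoC ~ U{4..16}."""
        return cls(pot=RAND_POT_RANGE, noc=RAND_NOC_RANGE, metric=metric,
                   seed=seed, n_groups=n_groups)


@dataclass
class QuantizedTargets:
    """The transformed output space: one categorical pseudo-target per group.

    ``codes[:, i]`` takes values in {1, ..., per_group_noc[i]}.
    """

    codes: np.ndarray
    groups: list[TargetGroup]
    per_group_noc: list[int]
    medoids: list[np.ndarray]

    @property
    def n_groups(self) -> int:
        return self.codes.shape[1]

    def column(self, i: int) -> np.ndarray:
        return self.codes[:, i]


def group_size(m: int, pot: float) -> int:
    """Round-half-up of m * pot, clamped to [1, m]."""
    s = int(np.floor(m * pot + 0.5))
    return min(max(s, 1), m)


def sample_target_groups(m: int, pot: float, n_groups: int,
                         rng: np.random.Generator) -> list[TargetGroup]:
    """Draw ``n_groups`` independent without-replacement target subsets."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < pot <= 1):
        raise ValueError(f"pot must be in (0, 1], got {pot}")
    s = group_size(m, pot)
    return [
        TargetGroup(tuple(sorted(rng.choice(m, size=s, replace=False).tolist())), i)
        for i in range(n_groups)
    ]


def _pairwise_distance(u: np.ndarray, metric: str) -> np.ndarray:
    if metric == "hamming":
        return (u[:, None, :] != u[None, :, :]).sum(axis=2).astype(float)
    diff = u[:, None, :] - u[None, :, :]
    return np.sqrt((diff * diff).sum(axis=2))


def kmedoids_cluster(rows, noc: int, metric: str, rng: np.random.Generator,
                     max_iter: int = MAX_ITER, trace_objective: bool = False):
    """PAM-style k-medoids on the rows of a point matrix.

    Alternates nearest-medoid assignment with per-cluster medoid updates
    (the member minimizing total within-cluster distance), starting from a
    seeded random draw of ``noc`` distinct rows. Assignment ties go to the
    lowest medoid index; the within-cluster objective is non-increasing so
    the loop terminates. If fewer than ``noc`` distinct rows exist the
    effective cluster count is silently reduced to that number (logged).

    Returns
    -------
    labels : ndarray of int, shape (N,), values in {1, ..., effective_noc}
    medoid_rows : ndarray, the medoid points (one per cluster)
    """
    if metric not in ("hamming", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    pts = np.asarray(rows)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 1 or noc < 1:
        raise ValueError("need at least one row and noc >= 1")
    uniq, first, inverse, counts = np.unique(
        pts, axis=0, return_index=True, return_inverse=True, return_counts=True)
    # re-order distinct rows by first occurrence: the ordering (and with it
    # every index-based tie-break and the seeded initialization) then depends
    # only on row identity, not on the column order of the group
    order = np.argsort(first, kind="stable")
    uniq, counts = uniq[order], counts[order]
    inverse = np.argsort(order)[inverse]
    u = uniq.shape[0]
    k = int(noc)
    if k > u:
        logger.warning("noc=%d exceeds %d distinct rows; reducing", k, u)
        k = u
    if k == u:
        labels = inverse + 1
        if trace_objective:
            return labels.astype(np.int64), uniq.copy(), [0.0]
        return labels.astype(np.int64), uniq.copy()
    dist = _pairwise_distance(uniq, metric)
    wdist = dist * counts[None, :]  # wdist[i, j]: cost of serving row j from medoid i
    medoids = np.sort(rng.choice(u, size=k, replace=False))
    objective: list[float] = []
    for _ in range(max_iter):
        # ties: argmin returns the first occurrence; medoids kept sorted,
        # so the tie goes to the lowest medoid index
        assign = np.argmin(dist[medoids], axis=0)
        objective.append(float((wdist[medoids] * (assign[None, :] ==
                                np.arange(k)[:, None])).sum()))
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            costs = wdist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(costs))]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = np.argmin(dist[medoids], axis=0)
    labels = assign[inverse] + 1
    if trace_objective:
        return labels.astype(np.int64), uniq[medoids], objective
    return labels.astype(np.int64), uniq[medoids]


def draw_rand_params(rng: np.random.Generator) -> tuple[float, int]:
    """One independent (PoT, NoC) draw of the randomized parameterization."""
    pot = rng.uniform(*RAND_POT_RANGE)
    noc = int(rng.integers(RAND_NOC_RANGE[0], RAND_NOC_RANGE[1] + 1))
    return pot, noc


def _standardize(block: np.ndarray) -> np.ndarray:
    mu = block.mean(axis=0)
    sd = block.std(axis=0)
    out = block - mu
    ok = sd > 0
    out[:, ok] /= sd[ok]
    out[:, ~ok] = 0.0
    return out


def quantize_output_space(Y, config: GroupingConfig,
                          rng: np.random.Generator | None = None) -> QuantizedTargets:
    """Transform a target matrix into cluster-index pseudo-targets.

    Every group gets its own child RNG stream (spawned hierarchically from
    the config seed), so adding groups never perturbs earlier ones. With
    ``metric='euclidean'`` the restricted targets are z-standardized per
    group before clustering so distances are scale-free across targets.
    When ``pot``/``noc`` are ranges, each group draws its own values from
    the group's stream before sampling and clustering.
    """
    Y = np.asarray(Y)
    if Y.ndim == 1:
        Y = Y[:, None]
    m = Y.shape[1]
    if m < 1:
        raise ValueError("Y must have at least one target column")
    n_groups = config.n_groups if config.n_groups is not None else m
    seed_seq = (np.random.SeedSequence(config.seed) if rng is None
                else np.random.SeedSequence(rng.integers(2**31)))
    children = seed_seq.spawn(n_groups)
    codes = np.empty((Y.shape[0], n_groups), dtype=np.int64)
    groups: list[TargetGroup] = []
    per_noc: list[int] = []
    medoids: list[np.ndarray] = []
    for i in range(n_groups):
        g_rng = np.random.default_rng(children[i])
        pot = g_rng.uniform(*config.pot) if isinstance(config.pot, tuple) else config.pot
        if isinstance(config.noc, tuple):
            noc = int(g_rng.integers(config.noc[0], config.noc[1] + 1))
        else:
            noc = int(config.noc)
        group = sample_target_groups(m, pot, 1, g_rng)[0]
        group = TargetGroup(group.member_indices, i)
        block = Y[:, list(group.member_indices)]
        if config.metric == "euclidean":
            block = _standardize(block.astype(float))
        labels, meds = kmedoids_cluster(block, noc, config.metric, g_rng)
        codes[:, i] = labels
        groups.append(group)
        per_noc.append(int(labels.max()))
        medoids.append(meds)
    return QuantizedTargets(codes, groups, per_noc, medoids)
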