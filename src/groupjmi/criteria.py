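"""Scoring criteria and greedy forward feature selection.

The family of criteria scores a candidate feature ``Xk`` given the ordered
set of already-selected features ``Xθ`` and the (possibly transformed)
targets:

- ``mim-br``      : sum over targets of I(Xk; Yi); pure relevancy ranking.
- ``single-jmi``  : sum over selected Xj and targets Yi of I(Xj Xk; Yi)
                    (binary-relevance view: targets treated independently).
- ``joint-jmi``   : sum over selected Xj of I(Xj Xk; Y) with Y the
                    labelset-encoded joint target (label-powerset view).
- ``group-jmi``   : sum over selected Xj and pseudo-targets Ỹi of
                    I(Xj Xk; Ỹi), where Ỹ comes from random target grouping
                    plus k-medoids quantization.
- ``group-jmi-rand``: group-jmi with per-group random (PoT, NoC) draws.

All selection is greedy forward search: at each step the candidate with the
highest score enters the selected list; ties are broken deterministically by
the lowest feature index. At the first step (empty Xθ) every JMI-family sum
is empty, so the relevancy-only score sum_i I(Xk; target_i) is used — the
standard convention in the JMI literature, and the one that makes the
criteria comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mi_core import (
    DataError,
    DiscretizedMatrix,
    _as_codes,
    _mi_codes,
    conditional_mi,
    mutual_information,
)
from .quantization import GroupingConfig, QuantizedTargets, quantize_output_space

__all__ = [
    "CRITERIA",
    "CriterionSpec",
    "SelectionState",
    "StepRecord",
    "encode_labelset",
    "score_mim_br",
    "score_single_jmi",
    "score_joint_jmi",
    "score_group_jmi",
    "score_group_jmi_decomposed",
    "forward_select",
]

CRITERIA = ("mim-br", "single-jmi", "joint-jmi", "group-jmi", "group-jmi-rand")
_GROUP_CRITERIA = ("group-jmi", "group-jmi-rand")


@dataclass
class StepRecord:
    """One greedy step: the winner, its score, and every candidate's score."""

    chosen: int
    score: float
    candidate_scores: dict[int, float]
    relevancy: float | None = None
    redundancy: float | None = None
    complementarity: float | None = None


@dataclass
class SelectionState:
    """Ordered selected features, remaining candidates, per-step traces."""

    selected: list[int] = field(default_factory=list)
    candidates: list[int] = field(default_factory=list)
    trace: list[StepRecord] = field(default_factory=list)

    def validate(self) -> None:
        if set(self.selected) & set(self.candidates):
            raise ValueError("selected and candidate sets overlap")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate features in selected list")
        if len(self.trace) != len(self.selected):
            raise ValueError("trace length must equal number of selected features")


@dataclass
class CriterionSpec:
    """A selectable criterion plus, for the group family, its grouping config."""

    name: str
    grouping: GroupingConfig | None = None
    tiebreak: str = "lowest-index"

    def __post_init__(self):
        if self.name not in CRITERIA:
            raise ValueError(f"unknown criterion {self.name!r}; choose from {CRITERIA}")
        if self.name in _GROUP_CRITERIA and self.grouping is None:
            if self.name == "group-jmi-rand":
                self.grouping = GroupingConfig.randomized()
            else:
                raise ValueError(f"{self.name} requires a GroupingConfig")
        if self.name not in _GROUP_CRITERIA and self.grouping is not None:
            raise ValueError(f"{self.name} does not take a GroupingConfig")
        if self.tiebreak != "lowest-index":
            raise ValueError("only the 'lowest-index' tie-break is implemented")


# ---------------------------------------------------------------------------
# Target handling
# ---------------------------------------------------------------------------


def _require_categorical(Y: np.ndarray, context: str) -> np.ndarray:
    arr = np.asarray(Y)
    if arr.ndim == 1:
        arr = arr[:, None]
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.isfinite(arr)) or not np.all(arr == np.round(arr)):
            raise DataError(
                f"{context} requires categorical targets; "
                "continuous targets must be quantized first (group criteria)"
            )
        arr = arr.astype(np.int64)
    return arr


def encode_labelset(Y) -> np.ndarray:
    """Bijectively encode the distinct rows of Y as one categorical column.

    This is the label-powerset transformation: each observed joint label
    configuration becomes one category, so the alphabet size is at most
    min(N, prod of per-target alphabets).
    """
    arr = _require_categorical(Y, "labelset encoding")
    _, inv = np.unique(arr, axis=0, return_inverse=True)
    return inv.astype(np.int64)


def _target_columns(targets) -> list[np.ndarray]:
    """Normalize a target argument to a list of compressed code columns."""
    if isinstance(targets, QuantizedTargets):
        return [_as_codes(targets.codes[:, i]) for i in range(targets.n_groups)]
    arr = np.asarray(targets)
    if arr.ndim == 1:
        arr = arr[:, None]
    return [_as_codes(arr[:, i]) for i in range(arr.shape[1])]


# ---------------------------------------------------------------------------
# Scoring functions (functional API; selected features passed as columns)
# ---------------------------------------------------------------------------


def score_mim_br(xk, Y) -> float:
    """Relevancy-only score: sum over targets of I(Xk; Yi)."""
    cols = _target_columns(_require_categorical(Y, "mim-br"))
    return float(sum(mutual_information(xk, t) for t in cols))


def _jmi_sum(xk, selected_columns, target_cols) -> float:
    xk = _as_codes(xk)
    nk = int(xk.max()) + 1
    total = 0.0
    for xj in selected_columns:
        cj = _as_codes(xj)
        pair = _as_codes(cj * nk + xk)
        npair = int(pair.max()) + 1
        for t in target_cols:
            total += _mi_codes(pair, npair, t, int(t.max()) + 1)
    return float(total)


def score_single_jmi(xk, selected_columns, Y) -> float:
    """Binary-relevance JMI: sum_{Xj in Xθ} sum_i I(Xj Xk; Yi)."""
    cols = _target_columns(_require_categorical(Y, "single-jmi"))
    return _jmi_sum(xk, selected_columns, cols)


def score_joint_jmi(xk, selected_columns, Y) -> float:
    """Label-powerset JMI: sum_{Xj in Xθ} I(Xj Xk; Y) on the joint target."""
    t = encode_labelset(Y)
    return _jmi_sum(xk, selected_columns, [t])


def score_group_jmi(xk, selected_columns, quantized) -> float:
    """Group-JMI: sum_{Xj in Xθ} sum_i I(Xj Xk; Ỹi) over pseudo-targets."""
    return _jmi_sum(xk, selected_columns, _target_columns(quantized))


def score_group_jmi_decomposed(xk, selected_columns, quantized):
    """Ranking-equivalent decomposition of Group-JMI.

    Returns ``(score, relevancy, redundancy, complementarity)`` where

        score = relevancy - redundancy + complementarity
        relevancy       = sum_i I(Xk; Ỹi)
        redundancy      = (1/|Xθ|) sum_j sum_i I(Xk; Xj)
        complementarity = (1/|Xθ|) sum_j sum_i I(Xk; Xj | Ỹi)

    The greedy argmax of this score coincides with the argmax of the plain
    Group-JMI sum at every step (the two differ by a positive affine
    transform that does not depend on the candidate).
    """
    cols = _target_columns(quantized)
    rel = float(sum(mutual_information(xk, t) for t in cols))
    if not selected_columns:
        return rel, rel, 0.0, 0.0
    red = 0.0
    comp = 0.0
    for xj in selected_columns:
        mi_jk = mutual_information(xk, xj)
        for t in cols:
            red += mi_jk
            comp += conditional_mi(xk, xj, t)
    s = len(selected_columns)
    red /= s
    comp /= s
    return rel - red + comp, rel, red, comp


# ---------------------------------------------------------------------------
# Greedy forward search
# ---------------------------------------------------------------------------


def _resolve_targets(targets, spec: CriterionSpec,
                     rng: np.random.Generator | None) -> list[np.ndarray]:
    if spec.name in _GROUP_CRITERIA:
        if isinstance(targets, QuantizedTargets):
            qt = targets
        else:
            qt = quantize_output_space(np.asarray(targets), spec.grouping, rng)
        return [_as_codes(qt.codes[:, i]) for i in range(qt.n_groups)]
    if spec.name == "joint-jmi":
        return [encode_labelset(targets)]
    return _target_columns(_require_categorical(targets, spec.name))


def forward_select(X, targets, k: int, spec: CriterionSpec,
                   rng: np.random.Generator | None = None) -> SelectionState:
    """Greedy forward selection of ``k`` features under a criterion.

    Parameters
    ----------
    X : DiscretizedMatrix or (N, d) integer array
        Discretized/categorical feature codes.
    targets : array or QuantizedTargets
        Raw targets for mim-br/single-jmi/joint-jmi; raw targets or a
        precomputed :class:`QuantizedTargets` for the group criteria (raw
        targets are quantized once, before the greedy loop, using the
        criterion's grouping config).
    k : int
        Number of features to select (0 <= k <= d).
    rng : numpy Generator, optional
        Overrides the grouping seed for the quantization step.

    Returns
    -------
    SelectionState with the ordered selection and full per-step score traces.
    For the group criteria each step also records the relevancy /
    redundancy / complementarity decomposition of the chosen feature.
    """
    if isinstance(X, DiscretizedMatrix):
        codes = X.codes
    else:
        codes = np.asarray(X)
        if codes.ndim != 2:
            raise ValueError("X must be 2-d")
    n, d = codes.shape
    if not (0 <= k <= d):
        raise ValueError(f"k must be in [0, {d}], got {k}")
    target_cols = _resolve_targets(targets, spec, rng)
    tlevels = [int(t.max()) + 1 for t in target_cols]

    cols = [_as_codes(codes[:, j]) for j in range(d)]
    nlev = [int(c.max()) + 1 for c in cols]

    state = SelectionState(candidates=list(range(d)))
    if k == 0:
        return state

    # relevancy scores: first greedy step for every criterion, and every
    # step for mim-br
    rel = np.array([
        sum(_mi_codes(cols[j], nlev[j], t, lt) for t, lt in zip(target_cols, tlevels))
        for j in range(d)
    ])

    cum = np.zeros(d)  # running JMI score sum over selected features
    active = np.ones(d, dtype=bool)
    for step in range(k):
        if step == 0 or spec.name == "mim-br":
            scores = rel.copy()
        else:
            scores = cum.copy()
        scores[~active] = -np.inf
        chosen = int(np.argmax(scores))  # first max = lowest feature index
        record = StepRecord(
            chosen=chosen,
            score=float(scores[chosen]),
            candidate_scores={j: float(scores[j]) for j in range(d) if active[j]},
        )
        if spec.name in _GROUP_CRITERIA:
            sel_cols = [cols[j] for j in state.selected]
            _, r, rd, cp = score_group_jmi_decomposed(
                cols[chosen], sel_cols, np.column_stack(target_cols)
            )
            record.relevancy, record.redundancy, record.complementarity = r, rd, cp
        state.selected.append(chosen)
        state.trace.append(record)
        active[chosen] = False

        if spec.name != "mim-br" and step < k - 1:
            # fold the newly selected feature's pair terms into every
            # remaining candidate's cumulative score
            cs, ns = cols[chosen], nlev[chosen]
            for j in np.flatnonzero(active):
                pair = cs * nlev[j] + cols[j]
                npair = ns * nlev[j]
                cum[j] += sum(
                    _mi_codes(pair, npair, t, lt)
                    for t, lt in zip(target_cols, tlevels)
                )
    state.candidates = [j for j in range(d) if active[j]]
    state.validate()
    return state
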