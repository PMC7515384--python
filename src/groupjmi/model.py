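"""Model/Results front end for multi-target feature selection.

:class:`GroupJMISelector` is constructed from data (arrays or a DataFrame),
holds the discretized design and the criterion configuration, and
``fit(k)`` runs the greedy forward search, returning a
:class:`SelectionResults` carrying the ranking, per-step scores, the
relevancy/redundancy/complementarity decomposition (group criteria) and a
``summary()`` table.

Example
-------
>>> from groupjmi import GroupJMISelector
>>> from groupjmi.synthetic import make_spec, gen_multilabel
>>> data = gen_multilabel(make_spec(500, 20, 6, n_relevant=4, seed=7))
>>> model = GroupJMISelector(data.X, data.Y, criterion="group-jmi-rand", seed=7)
>>> res = model.fit(k=5)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .criteria import CRITERIA, CriterionSpec, SelectionState, forward_select
from .mi_core import DiscretizedMatrix
from .quantization import GroupingConfig

__all__ = ["GroupJMISelector", "SelectionResults"]


class GroupJMISelector:
    """Greedy information-theoretic feature selector for multi-target data.

    Parameters
    ----------
    X : (N, d) array or DataFrame
        Features; continuous columns are discretized into ``n_bins``
        equal-width bins, columns listed in ``categorical`` are re-coded
        bijectively instead.
    Y : (N, m) array or DataFrame
        Targets. ``target_kind='binary'``/``'categorical'`` for
        classification, ``'continuous'`` for multivariate regression
        (continuous targets require a group criterion, which quantizes the
        output space with Euclidean k-medoids).
    criterion : one of 'mim-br', 'single-jmi', 'joint-jmi', 'group-jmi',
        'group-jmi-rand'.
    pot, noc : fixed value or (lo, hi) range, group criteria only.
        Defaults: the randomized ranges for 'group-jmi-rand'
        (PoT in [0.25, 0.75], NoC in {4..16}); PoT=0.5, NoC=8 for
        'group-jmi'.
    n_groups : number of pseudo-targets (default: one per target).
    seed : seed of the grouping/clustering randomness.
    """

    def __init__(self, X, Y, criterion: str = "group-jmi-rand", *,
                 n_bins: int = 5, categorical=None, target_kind: str = "auto",
                 pot=None, noc=None, n_groups: int | None = None,
                 seed: int | None = None):
        if criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {criterion!r}")
        if isinstance(Y, pd.DataFrame):
            self.target_names = [str(c) for c in Y.columns]
            Y = Y.to_numpy()
        else:
            Y = np.asarray(Y)
            if Y.ndim == 1:
                Y = Y[:, None]
            self.target_names = [f"y{t}" for t in range(Y.shape[1])]
        self.Y = Y
        if target_kind == "auto":
            target_kind = ("continuous"
                           if np.issubdtype(Y.dtype, np.floating)
                           and not np.all(Y == np.round(Y))
                           else "binary")
        self.target_kind = target_kind
        self.design = (X if isinstance(X, DiscretizedMatrix)
                       else DiscretizedMatrix.from_data(
                           X, n_bins=n_bins, categorical=categorical))
        if self.design.n_samples != Y.shape[0]:
            raise ValueError("X and Y disagree on the number of samples")
        self.criterion = criterion
        self.seed = seed
        if criterion in ("group-jmi", "group-jmi-rand"):
            metric = "euclidean" if target_kind == "continuous" else "hamming"
            if criterion == "group-jmi-rand":
                grouping = GroupingConfig.randomized(
                    metric=metric, seed=seed, n_groups=n_groups)
                if pot is not None or noc is not None:
                    grouping = GroupingConfig(
                        pot=pot if pot is not None else grouping.pot,
                        noc=noc if noc is not None else grouping.noc,
                        metric=metric, seed=seed, n_groups=n_groups)
            else:
                grouping = GroupingConfig(
                    pot=0.5 if pot is None else pot,
                    noc=8 if noc is None else noc,
                    metric=metric, seed=seed, n_groups=n_groups)
            self.spec = CriterionSpec(criterion, grouping)
        else:
            if target_kind == "continuous":
                raise ValueError(
                    f"{criterion} is undefined for continuous targets; "
                    "use a group criterion")
            self.spec = CriterionSpec(criterion)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target_columns=None,
                       targets_last: int | None = None, **kwargs):
        """Build a selector from one DataFrame with declared target columns."""
        if (target_columns is None) == (targets_last is None):
            raise ValueError("give exactly one of target_columns or targets_last")
        if targets_last is not None:
            target_columns = list(df.columns[-targets_last:])
        X = df.drop(columns=list(target_columns))
        Y = df[list(target_columns)]
        return cls(X, Y, **kwargs)

    def fit(self, k: int | None = None) -> "SelectionResults":
        """Run the greedy forward search and return the results object."""
        if k is None:
            k = self.design.n_features
        target = (self.Y.astype(float) if self.target_kind == "continuous"
                  else self.Y)
        state = forward_select(self.design, target, k, self.spec)
        return SelectionResults(self, state)


class SelectionResults:
    """Fitted selection: ordered features, scores, decomposition, summary."""

    def __init__(self, model: GroupJMISelector, state: SelectionState):
        self.model = model
        self.state = state
        self.selected_idx = list(state.selected)
        names = model.design.feature_names
        self.selected_features = [names[j] for j in self.selected_idx]

    @property
    def k(self) -> int:
        return len(self.selected_idx)

    def to_frame(self) -> pd.DataFrame:
        """Ranking table: one row per selected feature, in selection order."""
        rows = []
        for rank, rec in enumerate(self.state.trace, start=1):
            rows.append({
                "rank": rank,
                "feature": self.model.design.feature_names[rec.chosen],
                "index": rec.chosen,
                "step_score": rec.score,
                "relevancy": rec.relevancy,
                "redundancy": rec.redundancy,
                "complementarity": rec.complementarity,
            })
        return pd.DataFrame(rows)

    def transform(self, X):
        """Restrict a feature matrix (array or DataFrame) to the selection."""
        if isinstance(X, pd.DataFrame):
            return X[self.selected_features]
        return np.asarray(X)[:, self.selected_idx]

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Multi-target feature selection",
            "=" * 62,
            f"criterion: {spec.name}    features: {self.model.design.n_features}"
            f"    targets: {self.model.Y.shape[1]}",
            f"samples: {self.model.design.n_samples}    selected: {self.k}"
            f"    bins: {self.model.design.n_bins_requested}",
        ]
        if spec.grouping is not None:
            g = spec.grouping
            lines.append(
                f"grouping: pot={g.pot} noc={g.noc} metric={g.metric} "
                f"seed={g.seed}")
        lines.append("-" * 62)
        df = self.to_frame()
        with pd.option_context("display.float_format", "{:.4f}".format):
            lines.append(df.to_string(index=False))
        lines.append("-" * 62)
        lines.append("scores in nats; decomposition columns only for group "
                     "criteria")
        return "\n".join(lines)

    def save_tsv(self, path, header_comment: str | None = None) -> None:
        """Write the ranking table as TSV, with the run config in # comments."""
        from . import __version__

        spec = self.model.spec
        g = spec.grouping
        meta = [
            f"# groupjmi {__version__}",
            f"# criterion={spec.name} k={self.k} "
            f"n_bins={self.model.design.n_bins_requested} seed={self.model.seed}",
        ]
        if g is not None:
            meta.append(f"# pot={g.pot} noc={g.noc} metric={g.metric} "
                        f"n_groups={g.n_groups}")
        if header_comment:
            meta.append(f"# {header_comment}")
        body = self.to_frame().to_csv(sep="\t", index=False)
        with open(path, "w") as fh:
            fh.write("\n".join(meta) + "\n" + body)

    def plot_scores(self, ax=None):
        """Bar plot of per-step winning scores (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, 0.4 * self.k), 3))
        df = self.to_frame()
        ax.bar(df["rank"], df["step_score"])
        ax.set_xlabel("selection step")
        ax.set_ylabel("winning score (nats)")
        ax.set_xticks(df["rank"])
        ax.set_xticklabels(df["feature"], rotation=90, fontsize=8)
        return ax
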