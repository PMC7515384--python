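"""Seeded synthetic multi-target data with known ground-truth feature roles.

The generators plant four feature roles so that every selection criterion's
behaviour is testable without external data:

- *relevant* features: noisy continuous copies of the latent signals that
  drive the targets;
- *redundant* features: noisy copies of relevant feature columns (identical
  to their source before the copy's own measurement noise is added);
- *complementary* pairs (A, B): two features whose XOR drives one target.
  A is drawn Bernoulli(0.5) and B Bernoulli(0.3), so A carries a modest
  marginal signal while B is marginally independent of the target
  (structurally zero MI) and only becomes visible through its interaction
  with A — the classic blind spot of pure-relevancy rankings;
- *noise* features: standard normal, independent of everything.

Inter-target dependence is induced by a shared latent factor: each
(non-XOR) target's latent copies the shared factor with probability
``target_dependence`` per sample and is otherwise an independent coin flip.
At dependence 0 the labels are pairwise independent; at 1 they collapse to
one factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SyntheticSpec", "SyntheticDataset", "make_spec",
           "gen_multilabel", "gen_multitarget_regression"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth structure of a generated dataset.

    ``relevant_idx``, ``redundant_idx``, the flattened ``complementary_pairs``
    and ``noise_idx`` must be disjoint subsets of {0..n_features-1}; feature
    indices not listed anywhere are implicitly noise.
    """

    n_samples: int
    n_features: int
    n_targets: int
    relevant_idx: tuple[int, ...] = ()
    redundant_idx: tuple[int, ...] = ()
    complementary_pairs: tuple[tuple[int, int], ...] = ()
    noise_idx: tuple[int, ...] = ()
    target_dependence: float = 0.5
    label_noise: float = 0.05
    feature_noise: float = 0.5   # sd of measurement noise on unit-scale signals
    target_noise: float = 0.5    # sd of additive target noise (regression)
    xor_partner_rate: float = 0.3  # success prob of the marginally-hidden pair member
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_features < 1 or self.n_targets < 1:
            raise ValueError("sizes must be positive")
        if not (0 <= self.target_dependence <= 1):
            raise ValueError("target_dependence must be in [0, 1]")
        if not (0 <= self.label_noise < 1):
            raise ValueError("label_noise must be in [0, 1)")
        flat_pairs = tuple(i for p in self.complementary_pairs for i in p)
        all_idx = (tuple(self.relevant_idx) + tuple(self.redundant_idx)
                   + flat_pairs + tuple(self.noise_idx))
        if len(set(all_idx)) != len(all_idx):
            raise ValueError("feature role index sets must be disjoint")
        if all_idx and (min(all_idx) < 0 or max(all_idx) >= self.n_features):
            raise ValueError("feature role indices out of range")
        if len(self.complementary_pairs) > self.n_targets:
            raise ValueError("more complementary pairs than targets")
        if self.relevant_idx and len(self.complementary_pairs) >= self.n_targets:
            raise ValueError("relevant features need at least one non-XOR target")

    @property
    def useful_idx(self) -> tuple[int, ...]:
        """Indices a selector ought to find: relevant + complementary members."""
        return tuple(self.relevant_idx) + tuple(
            i for p in self.complementary_pairs for i in p
        )


def make_spec(n_samples: int, n_features: int, n_targets: int,
              n_relevant: int = 0, n_redundant: int = 0, n_xor_pairs: int = 0,
              **kwargs) -> SyntheticSpec:
    """Allocate role indices contiguously: relevant, redundant, pairs, noise."""
    pos = 0
    relevant = tuple(range(pos, pos + n_relevant)); pos += n_relevant
    redundant = tuple(range(pos, pos + n_redundant)); pos += n_redundant
    pairs = tuple((pos + 2 * i, pos + 2 * i + 1) for i in range(n_xor_pairs))
    pos += 2 * n_xor_pairs
    noise = tuple(range(pos, n_features))
    if pos > n_features:
        raise ValueError("role counts exceed n_features")
    return SyntheticSpec(n_samples, n_features, n_targets,
                         relevant_idx=relevant, redundant_idx=redundant,
                         complementary_pairs=pairs, noise_idx=noise, **kwargs)


@dataclass
class SyntheticDataset:
    """Generated data plus the ground-truth role table."""

    X: np.ndarray
    Y: np.ndarray
    spec: SyntheticSpec
    roles: pd.DataFrame
    weights: np.ndarray | None = None  # regression: targets x features weight matrix

    @property
    def feature_names(self) -> list[str]:
        return list(self.roles["feature"])

    @property
    def target_names(self) -> list[str]:
        return [f"y{t}" for t in range(self.Y.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        for t, name in enumerate(self.target_names):
            df[name] = self.Y[:, t]
        return df


def _role_table(spec: SyntheticSpec) -> pd.DataFrame:
    roles = np.full(spec.n_features, "noise", dtype=object)
    for i in spec.relevant_idx:
        roles[i] = "relevant"
    for i in spec.redundant_idx:
        roles[i] = "redundant"
    for a, b in spec.complementary_pairs:
        roles[a] = "complementary"
        roles[b] = "complementary"
    return pd.DataFrame({
        "feature": [f"x{j}" for j in range(spec.n_features)],
        "index": np.arange(spec.n_features),
        "role": roles,
    })


def gen_multilabel(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a multi-label classification dataset from a spec.

    Targets: the last ``len(complementary_pairs)`` targets are XOR targets
    (label = A xor B of their pair); the remaining targets follow the
    shared-factor latent model. Every label is then flipped independently
    with probability ``label_noise``. Features are continuous noisy
    encodings of their latent signals; output is a pure function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, m = spec.n_samples, spec.n_features, spec.n_targets
    n_pairs = len(spec.complementary_pairs)
    n_plain = m - n_pairs

    shared = rng.integers(0, 2, size=n)
    latents = np.empty((n, m), dtype=np.int64)
    for t in range(n_plain):
        own = rng.integers(0, 2, size=n)
        use_shared = rng.random(n) < spec.target_dependence
        latents[:, t] = np.where(use_shared, shared, own)

    X = rng.normal(0.0, 1.0, size=(n, d))  # default: pure noise features
    for p, (a, b) in enumerate(spec.complementary_pairs):
        bit_a = rng.integers(0, 2, size=n)
        bit_b = (rng.random(n) < spec.xor_partner_rate).astype(np.int64)
        latents[:, n_plain + p] = bit_a ^ bit_b
        X[:, a] = bit_a + rng.normal(0.0, spec.feature_noise, size=n)
        X[:, b] = bit_b + rng.normal(0.0, spec.feature_noise, size=n)

    for j, idx in enumerate(spec.relevant_idx):
        t = j % max(n_plain, 1)
        X[:, idx] = latents[:, t] + rng.normal(0.0, spec.feature_noise, size=n)
    for j, idx in enumerate(spec.redundant_idx):
        if not spec.relevant_idx:
            raise ValueError("redundant features require relevant features to copy")
        src = spec.relevant_idx[j % len(spec.relevant_idx)]
        X[:, idx] = X[:, src] + rng.normal(0.0, spec.feature_noise, size=n)

    flips = rng.random((n, m)) < spec.label_noise
    Y = (latents ^ flips.astype(np.int64)).astype(np.int64)
    return SyntheticDataset(X, Y, spec, _role_table(spec))


def gen_multitarget_regression(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a multivariate regression dataset from a spec.

    Linear-plus-interaction model: relevant features are iid standard
    normal; target t is a weighted sum of them with weights that mix a
    shared loading vector (weight ``target_dependence``) and a
    target-specific loading on one assigned feature (weight
    ``1 - target_dependence``), plus, for each complementary pair, a
    product interaction feeding one designated target, plus
    N(0, target_noise^2) noise. The full weight matrix is returned so the
    implied target covariance is available in closed form.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, m = spec.n_samples, spec.n_features, spec.n_targets
    n_pairs = len(spec.complementary_pairs)
    n_plain = m - n_pairs
    rel = list(spec.relevant_idx)

    X = rng.normal(0.0, 1.0, size=(n, d))
    W = np.zeros((m, d))
    if rel:
        shared_w = np.ones(len(rel)) / np.sqrt(len(rel))
        for t in range(n_plain):
            own = np.zeros(len(rel))
            own[t % len(rel)] = 1.0
            W[t, rel] = spec.target_dependence * shared_w \
                + (1.0 - spec.target_dependence) * own
    for j, idx in enumerate(spec.redundant_idx):
        src = rel[j % len(rel)] if rel else None
        if src is None:
            raise ValueError("redundant features require relevant features to copy")
        X[:, idx] = X[:, src] + rng.normal(0.0, spec.feature_noise, size=n)

    Y = X @ W.T
    for p, (a, b) in enumerate(spec.complementary_pairs):
        Y[:, n_plain + p] += X[:, a] * X[:, b]
    if spec.target_noise > 0:
        Y += rng.normal(0.0, spec.target_noise, size=(n, m))
    return SyntheticDataset(X, Y, spec, _role_table(spec), weights=W)
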