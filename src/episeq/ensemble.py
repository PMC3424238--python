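"""Imbalance-handling bootstrap ensembles of random forests.

Epitope residues are a small minority of any antigen, so a single
classifier trained on the raw windows is dominated by negatives. The
remedy used here: the negative pool is split into n ~ neg/pos chunks,
each chunk is paired with *all* positives to form a class-balanced
sample, one random forest is fitted per sample, and the mean of the n
forests' positive-class vote fractions is the ensemble score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import EpiseqError, NotFittedError
from .features import FeatureEncoder
from .windowing import WindowInstance, class_counts

#: sampling modes for the negative pool
SAMPLING_MODES = ("partition", "bootstrap")


def compute_n(pos: int, neg: int) -> int:
    """Number of rebalanced sub-samples: the majority/minority ratio.

    ``max(1, round(neg / pos))`` with halves rounded up, so balanced data
    degenerates to a single base learner.
    """
    if pos < 1:
        raise EpiseqError("no positive instances: cannot train an ensemble")
    if neg < 1:
        raise EpiseqError("no negative instances: cannot train an ensemble")
    return max(1, int(np.floor(neg / pos + 0.5)))


def _negative_chunks(
    n_neg: int, n_pos: int, n: int, rng: np.random.Generator, mode: str
) -> list[np.ndarray]:
    """Index chunks into the negative pool, one per sub-sample.

    ``partition``: shuffle the pool once and cut it into n near-equal
    contiguous chunks (every negative is used); a chunk shorter than the
    positive count is extended by cycling through the shuffled pool.
    ``bootstrap``: n independent draws of n_pos negatives with
    replacement.
    """
    if mode not in SAMPLING_MODES:
        raise EpiseqError(f"unknown sampling mode {mode!r}")
    if mode == "bootstrap":
        return [rng.integers(0, n_neg, size=n_pos) for _ in range(n)]
    perm = rng.permutation(n_neg)
    base, extra = divmod(n_neg, n)
    chunks: list[np.ndarray] = []
    start = 0
    for i in range(n):
        size = base + (1 if i < extra else 0)
        chunk = perm[start : start + size]
        start += size
        if len(chunk) < n_pos:  # cycle the shuffled pool to reach n_pos
            need = n_pos - len(chunk)
            fill = perm[np.arange(start, start + need) % n_neg]
            chunk = np.concatenate([chunk, fill])
        chunks.append(chunk)
    return chunks


def make_balanced_samples(
    instances: list[WindowInstance],
    n: int,
    seed: int,
    mode: str = "partition",
) -> list[list[WindowInstance]]:
    """Build n class-balanced instance samples (all positives + negatives)."""
    if n < 1:
        raise EpiseqError("n must be >= 1")
    pos = [w for w in instances if w.label == 1]
    neg = [w for w in instances if w.label == 0]
    if not neg:
        raise EpiseqError("no negative instances")
    if not pos:
        raise EpiseqError("no positive instances")
    rng = np.random.default_rng(seed)
    chunks = _negative_chunks(len(neg), len(pos), n, rng, mode)
    return [pos + [neg[j] for j in chunk] for chunk in chunks]


@dataclass
class BootstrapEnsemble:
    """n random forests, each trained on one rebalanced sample.

    The base learner keeps scikit-learn's default hyperparameters; only
    ``random_state`` is pinned for reproducibility. ``base_params``
    overrides forest constructor arguments when explicitly requested.
    """

    encoder_name: str = ""
    seed: int = 0
    sampling: str = "partition"
    base_params: dict = field(default_factory=dict)
    n: int | None = None
    members: list[RandomForestClassifier] = field(default_factory=list)
    n_pos: int = 0
    n_neg: int = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BootstrapEnsemble":
        X = np.asarray(X)
        y = np.asarray(y).astype(int)
        if X.shape[0] != y.shape[0]:
            raise EpiseqError("X and y disagree on the number of instances")
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        self.n_pos, self.n_neg = len(pos_idx), len(neg_idx)
        self.n = compute_n(self.n_pos, self.n_neg)
        rng = np.random.default_rng(self.seed)
        chunks = _negative_chunks(
            self.n_neg, self.n_pos, self.n, rng, self.sampling
        )
        self.members = []
        for i, chunk in enumerate(chunks):
            idx = np.concatenate([pos_idx, neg_idx[chunk]])
            clf = RandomForestClassifier(
                random_state=(self.seed + 7919 * i) % (2**31 - 1),
                **self.base_params,
            )
            clf.fit(X[idx], y[idx])
            self.members.append(clf)
        return self

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Mean positive-class vote fraction of the n members, in [0, 1]."""
        if not self.members:
            raise NotFittedError("ensemble has no fitted members")
        X = np.asarray(X)
        acc = np.zeros(X.shape[0])
        for clf in self.members:
            proba = clf.predict_proba(X)
            pos_col = list(clf.classes_).index(1)
            acc += proba[:, pos_col]
        return acc / len(self.members)

    def member_scores(self, X: np.ndarray) -> np.ndarray:
        """(n_members, n_instances) matrix of individual member scores."""
        if not self.members:
            raise NotFittedError("ensemble has no fitted members")
        rows = []
        for clf in self.members:
            proba = clf.predict_proba(np.asarray(X))
            rows.append(proba[:, list(clf.classes_).index(1)])
        return np.vstack(rows)


def train_bootstrap_ensemble(
    instances: list[WindowInstance],
    encoder: FeatureEncoder,
    seed: int = 0,
    sampling: str = "partition",
    base_params: dict | None = None,
) -> BootstrapEnsemble:
    """Encode labelled *instances* with *encoder* and fit an ensemble."""
    pos, neg = class_counts(instances)  # also validates labels
    if pos == 0 or neg == 0:
        raise EpiseqError(
            f"need both classes to train (pos={pos}, neg={neg})"
        )
    X = encoder.encode_windows(instances)
    y = np.array([w.label for w in instances])
    ens = BootstrapEnsemble(
        encoder_name=encoder.name,
        seed=seed,
        sampling=sampling,
        base_params=base_params or {},
    )
    return ens.fit(X, y)


def ensemble_score(
    ensemble: BootstrapEnsemble, window: WindowInstance, encoder: FeatureEncoder
) -> float:
    """Score a single window: arithmetic mean of the members' votes."""
    return float(ensemble.score_matrix(encoder.encode(window)[None, :])[0])
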