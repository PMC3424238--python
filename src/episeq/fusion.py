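"""Score normalization and weighted fusion of the sub-classifiers.

Each feature-specific bootstrap ensemble produces a raw score in [0, 1].
Raw score distributions differ between sub-classifiers, so before
combination each score s is mapped through the tanh-estimator

    s' = 0.5 * (tanh(c * (s - mu) / sigma) + 1)

with (mu, sigma) the mean and standard deviation of that sub-classifier's
training scores and c a small gain constant (default 0.01). The fused
prediction is a convex combination sum_i w_i * s'_i with weights on the
probability simplex, found by exhaustive grid search (step 0.05) or taken
from the published optimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import EpiseqError, MissingTrackError, NotFittedError
from .ensemble import BootstrapEnsemble
from .features import FeatureEncoder
from .io import ChainRecord
from .windowing import extract_windows

logger = logging.getLogger(__name__)

SIGMA_EPSILON = 1e-9

#: canonical sub-classifier order; published optimal weights map onto it
FUSION_ORDER: tuple[str, ...] = (
    "propensity",
    "functional_composition",
    "evolutionary",
    "sparse",
    "ss",
    "rasa",
    "pair_profile",
)

#: published optimal weights (grid step 0.05) in FUSION_ORDER
DEFAULT_WEIGHTS: tuple[float, ...] = (0.1, 0.0, 0.5, 0.0, 0.1, 0.2, 0.1)

STRATEGIES = ("weighted", "mean", "median")
TERMINAL_POLICIES = ("full_ensemble", "composition_only")


@dataclass
class NormalizationParams:
    """Per-sub-classifier (mu, sigma) pairs, in sub-classifier order."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise EpiseqError("mu and sigma shapes differ")
        if (self.sigma < SIGMA_EPSILON).any():
            raise EpiseqError(f"sigma below epsilon {SIGMA_EPSILON}")


def fit_normalization(training_scores: list[np.ndarray]) -> NormalizationParams:
    """Fit (mu_i, sigma_i) from each sub-classifier's training scores.

    Population standard deviation (ddof=0). A constant score list gets
    sigma floored at epsilon with a warning.
    """
    mus, sigmas = [], []
    for i, scores in enumerate(training_scores):
        scores = np.asarray(scores, dtype=float)
        if scores.size < 2:
            raise EpiseqError(
                f"sub-classifier {i}: need >= 2 training scores"
            )
        mu = float(scores.mean())
        sigma = float(scores.std(ddof=0))
        if sigma < SIGMA_EPSILON:
            logger.warning(
                "sub-classifier %d: constant training scores; sigma floored "
                "at %g", i, SIGMA_EPSILON,
            )
            sigma = SIGMA_EPSILON
        mus.append(mu)
        sigmas.append(sigma)
    return NormalizationParams(np.array(mus), np.array(sigmas))


def normalize_score(
    s: np.ndarray | float, mu: float, sigma: float, c: float = 0.01
) -> np.ndarray | float:
    """tanh-estimator: ``0.5 * (tanh(c * (s - mu) / sigma) + 1)``.

    Strictly increasing in s, maps mu to 0.5, saturates to (0, 1).
    """
    if sigma <= 0:
        raise EpiseqError("sigma must be positive")
    return 0.5 * (np.tanh(c * (np.asarray(s, dtype=float) - mu) / sigma) + 1.0)


def normalize_matrix(
    raw: np.ndarray, norm: NormalizationParams, c: float = 0.01
) -> np.ndarray:
    """Normalize a (k, n) raw-score matrix row-wise."""
    raw = np.asarray(raw, dtype=float)
    return 0.5 * (np.tanh(c * (raw - norm.mu[:, None]) / norm.sigma[:, None]) + 1.0)


def normalize_per_instance(raw: np.ndarray, c: float = 0.01) -> np.ndarray:
    """Alternative scope: z-score across the k sub-classifiers per instance.

    Provided because the normalization sentence can be read either way;
    the per-sub-classifier scope is the package default.
    """
    raw = np.asarray(raw, dtype=float)
    mu = raw.mean(axis=0, keepdims=True)
    sigma = np.maximum(raw.std(axis=0, ddof=0, keepdims=True), SIGMA_EPSILON)
    return 0.5 * (np.tanh(c * (raw - mu) / sigma) + 1.0)


# ---------------------------------------------------------------------------
# Combination strategies


def _check_weights(normalized: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    normalized = np.asarray(normalized, dtype=float)
    w = np.asarray(w, dtype=float)
    if normalized.shape[0] != w.shape[0]:
        raise EpiseqError(
            f"{normalized.shape[0]} scores vs {w.shape[0]} weights"
        )
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise EpiseqError("weights must be nonnegative and sum to 1")
    return normalized, w


def fuse_weighted(normalized: np.ndarray, w: np.ndarray) -> np.ndarray | float:
    """Convex combination of normalized scores; axis 0 = sub-classifier."""
    normalized, w = _check_weights(normalized, w)
    return w @ normalized


def fuse_mean(normalized: np.ndarray) -> np.ndarray | float:
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape[0] == 0:
        raise EpiseqError("no scores to fuse")
    return normalized.mean(axis=0)


def fuse_median(normalized: np.ndarray) -> np.ndarray | float:
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape[0] == 0:
        raise EpiseqError("no scores to fuse")
    return np.median(normalized, axis=0)


# ---------------------------------------------------------------------------
# Weight grid


def enumerate_weight_grid(k: int, step: float = 0.05) -> np.ndarray:
    """All k-vectors of nonnegative multiples of *step* summing to 1.

    Count = C(1/step + k - 1, k - 1); returned in lexicographic order.
    """
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise EpiseqError(f"step {step} does not divide 1")
    if k < 1:
        raise EpiseqError("k must be >= 1")
    # stars and bars: place k-1 cut points among m + k - 1 slots
    grids = []
    for cuts in combinations(range(m + k - 1), k - 1):
        prev = -1
        parts = []
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(m + k - 2 - prev)
        grids.append(parts)
    out = np.asarray(grids, dtype=float) * step
    # lexicographic order on the weight vectors themselves
    order = np.lexsort(out.T[::-1])
    return out[order]


def grid_count(k: int, step: float = 0.05) -> int:
    """Closed-form grid size C(1/step + k - 1, k - 1)."""
    m = round(1.0 / step)
    return math.comb(m + k - 1, k - 1)


def grid_search_weights(
    sub_scores: np.ndarray,
    labels: np.ndarray,
    antigen_ids: np.ndarray,
    step: float = 0.05,
    objective=None,
) -> np.ndarray:
    """Exhaustive simplex grid search for the fusion weights.

    *sub_scores* is a (k, n) matrix of normalized sub-classifier scores;
    the default objective is the mean per-antigen AUC of the fused score.
    Ties are broken by the lexicographically smallest weight vector
    (guaranteed by search order).
    """
    from .evaluation import mean_per_antigen_auc  # local import, no cycle

    sub_scores = np.asarray(sub_scores, dtype=float)
    labels = np.asarray(labels)
    antigen_ids = np.asarray(antigen_ids)
    if objective is None:
        def objective(fused: np.ndarray) -> float:
            return mean_per_antigen_auc(fused, labels, antigen_ids)

    grid = enumerate_weight_grid(sub_scores.shape[0], step)
    best_w = None
    best_val = -np.inf
    for w in grid:
        val = objective(w @ sub_scores)
        if val > best_val + 1e-12:
            best_val = val
            best_w = w
    if best_w is None:
        raise EpiseqError("empty weight grid")
    return best_w


# ---------------------------------------------------------------------------
# The fused model


@dataclass
class FusionModel:
    """Fitted sub-ensembles plus normalization and combination rule.

    ``encoder_names`` fixes the sub-classifier order (a subset of
    FUSION_ORDER for reduced models). ``composition_model`` is the
    separate window-composition ensemble used for terminal residues
    under ``terminal_policy='composition_only'``; it sits outside the
    weight vector.
    """

    encoder_names: tuple[str, ...]
    encoders: dict[str, FeatureEncoder]
    sub_ensembles: dict[str, BootstrapEnsemble]
    norm: NormalizationParams
    weights: np.ndarray
    L: int = 9
    strategy: str = "weighted"
    c: float = 0.01
    terminal_policy: str = "full_ensemble"
    composition_model: BootstrapEnsemble | None = None
    composition_encoder: FeatureEncoder | None = None
    format_version: int = 1
    _extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise EpiseqError(f"unknown strategy {self.strategy!r}")
        if self.terminal_policy not in TERMINAL_POLICIES:
            raise EpiseqError(
                f"unknown terminal policy {self.terminal_policy!r}"
            )
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.encoder_names):
            raise EpiseqError("one weight per sub-classifier required")
        if (
            self.terminal_policy == "composition_only"
            and self.composition_model is None
        ):
            raise EpiseqError(
                "terminal_policy='composition_only' needs a composition model"
            )

    def active_encoder_names(self) -> tuple[str, ...]:
        """Sub-classifiers that actually contribute to the fused score.

        Under weighted fusion, encoders with weight exactly 0 are pruned
        (their input tracks need not be present at prediction time).
        """
        if self.strategy != "weighted":
            return self.encoder_names
        return tuple(
            name
            for name, w in zip(self.encoder_names, self.weights)
            if w > 0.0
        )

    def raw_chain_scores(self, chain: ChainRecord, antigen_id: str = "") -> np.ndarray:
        """(k, N) raw sub-classifier scores for every residue of *chain*."""
        windows = extract_windows(chain, self.L, antigen_id)
        active = set(self.active_encoder_names())
        rows = []
        for name in self.encoder_names:
            if name not in active:
                rows.append(np.zeros(len(windows)))
                continue
            enc = self.encoders[name]
            missing = [t for t in enc.requires if getattr(chain, t) is None]
            if missing:
                raise MissingTrackError(
                    f"encoder {name!r} needs track(s) {missing} on chain "
                    f"{antigen_id}/{chain.chain_id}"
                )
            X = enc.encode_windows(windows)
            rows.append(self.sub_ensembles[name].score_matrix(X))
        return np.vstack(rows)

    def predict_chain(self, chain: ChainRecord, antigen_id: str = "") -> np.ndarray:
        """Fused per-residue scores in [0, 1]; output length = chain length."""
        if not self.sub_ensembles:
            raise NotFittedError("fusion model has no fitted sub-ensembles")
        raw = self.raw_chain_scores(chain, antigen_id)
        normalized = normalize_matrix(raw, self.norm, self.c)
        # pruned encoders carry weight 0, so their placeholder rows vanish
        if self.strategy == "weighted":
            fused = fuse_weighted(normalized, self.weights)
        elif self.strategy == "mean":
            fused = fuse_mean(normalized)
        else:
            fused = fuse_median(normalized)
        fused = np.asarray(fused, dtype=float)

        if self.terminal_policy == "composition_only":
            flank = (self.L - 1) // 2
            windows = extract_windows(chain, self.L, antigen_id)
            Xc = self.composition_encoder.encode_windows(windows)
            comp = self.composition_model.score_matrix(Xc)
            n = len(chain)
            terminal = np.zeros(n, dtype=bool)
            terminal[: min(flank, n)] = True
            terminal[max(0, n - flank):] = True
            fused[terminal] = comp[terminal]
        return fused
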