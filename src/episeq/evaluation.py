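"""Evaluation metrics and antigen-level leave-one-out cross-validation.

The unit of cross-validation is the antigen, not the chain: all chains
of the held-out antigen are scored by a model trained on the remaining
antigens. The headline number is the unweighted mean of per-antigen
AUCs over antigens that contain both classes; SN/SP/ACC/F are reported
at a configurable threshold (default 0.5) alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ensemble import BootstrapEnsemble, compute_n
from .errors import EpiseqError
from .features import get_encoder
from .fusion import (
    FUSION_ORDER,
    FusionModel,
    NormalizationParams,
    fit_normalization,
    fuse_mean,
    fuse_median,
    fuse_weighted,
    grid_search_weights,
    normalize_matrix,
)
from .io import AntigenRecord
from .windowing import extract_windows

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Threshold scores (score >= threshold is a positive call) and count."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise EpiseqError("scores/labels length mismatch")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def sensitivity(cc: ConfusionCounts) -> float:
    return cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn else float("nan")


def specificity(cc: ConfusionCounts) -> float:
    return cc.tn / (cc.tn + cc.fp) if cc.tn + cc.fp else float("nan")


def accuracy(cc: ConfusionCounts) -> float:
    return (cc.tp + cc.tn) / cc.total if cc.total else float("nan")


def f_measure(cc: ConfusionCounts) -> float:
    """F1 = 2*P*SN / (P + SN); undefined denominators propagate as NaN."""
    if cc.tp + cc.fp == 0 or cc.tp + cc.fn == 0:
        return float("nan")
    p = cc.tp / (cc.tp + cc.fp)
    sn = cc.tp / (cc.tp + cc.fn)
    if p + sn == 0:
        return float("nan")
    return 2 * p * sn / (p + sn)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) ROC area with average ranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise EpiseqError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def mean_per_antigen_auc(
    scores: np.ndarray, labels: np.ndarray, antigen_ids: np.ndarray
) -> float:
    """Unweighted mean AUC over antigens with both classes present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    antigen_ids = np.asarray(antigen_ids)
    aucs = []
    for ant in pd.unique(antigen_ids):
        mask = antigen_ids == ant
        lab = labels[mask]
        if (lab == 1).any() and (lab == 0).any():
            aucs.append(auc(scores[mask], lab))
    if not aucs:
        raise EpiseqError("no antigen has both classes")
    return float(np.mean(aucs))


@dataclass
class EvaluationReport:
    """LOOCV outcome: per-antigen table, aggregates and a config echo."""

    per_antigen: pd.DataFrame
    mean_auc: float
    mean_auc_by_encoder: dict[str, float]
    pooled: dict[str, float]
    weights: np.ndarray | None
    config: dict = field(default_factory=dict)
    oof_scores: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = ["Antigen-level LOOCV report", "=" * 40]
        lines.append(f"antigens evaluated : {len(self.per_antigen)}")
        lines.append(f"mean AUC (fused)   : {self.mean_auc:.3f}")
        for name, val in self.mean_auc_by_encoder.items():
            lines.append(f"mean AUC [{name:<22s}]: {val:.3f}")
        if self.weights is not None:
            names = self.config.get("encoders", [])
            wstr = ", ".join(
                f"{n}={w:.2f}" for n, w in zip(names, self.weights)
            )
            lines.append(f"weights            : {wstr}")
        lines.append(
            "pooled (t={:.2f})   : SN={:.3f} SP={:.3f} ACC={:.3f} F={:.3f}".format(
                self.config.get("threshold", 0.5),
                self.pooled["sn"],
                self.pooled["sp"],
                self.pooled["acc"],
                self.pooled["f"],
            )
        )
        return "\n".join(lines)


def _dataset_matrices(
    records: list[AntigenRecord], encoder_names: tuple[str, ...], L: int
):
    """Windows + per-encoder feature matrices for the whole dataset."""
    encoders = {name: get_encoder(name) for name in encoder_names}
    windows = []
    for rec in records:
        for ch in rec.chains:
            windows.extend(extract_windows(ch, L, rec.antigen_id))
    labels = np.array([w.label for w in windows])
    if (labels == None).any():  # noqa: E711  — mixed None check before cast
        raise EpiseqError("LOOCV requires labels on every residue")
    labels = labels.astype(int)
    antigen_ids = np.array([w.antigen_id for w in windows])
    X = {name: enc.encode_windows(windows) for name, enc in encoders.items()}
    meta = pd.DataFrame(
        {
            "antigen_id": antigen_ids,
            "chain_id": [w.chain_id for w in windows],
            "position": [w.center + 1 for w in windows],
            "label": labels,
        }
    )
    return windows, X, labels, antigen_ids, meta


def loocv(
    records: list[AntigenRecord],
    encoder_names: tuple[str, ...] = FUSION_ORDER,
    L: int = 9,
    strategy: str = "weighted",
    weights: np.ndarray | str | None = "search",
    threshold: float = 0.5,
    c: float = 0.01,
    sampling: str = "partition",
    base_params: dict | None = None,
    grid_step: float = 0.05,
    seed: int = 0,
) -> EvaluationReport:
    """Antigen-level LOOCV of the full pipeline.

    For each fold, the sub-ensembles and normalization parameters are
    fitted on the training antigens only; the held-out antigen's chains
    are scored out-of-fold. With ``weights="search"`` the simplex grid
    search runs once on the pooled out-of-fold normalized scores (the
    protocol used to derive the published optimum); with an explicit
    weight vector the fused scores use it directly; with ``None`` the
    normalized scores are combined by *strategy* without a search.
    """
    if len(records) < 2:
        raise EpiseqError("LOOCV needs at least 2 antigens")
    ids = [r.antigen_id for r in records]
    if len(set(ids)) != len(ids):
        raise EpiseqError("duplicate antigen ids in dataset")

    encoder_names = tuple(encoder_names)
    k = len(encoder_names)
    windows, X, labels, antigen_ids, meta = _dataset_matrices(
        records, encoder_names, L
    )

    oof_norm = np.full((k, len(labels)), np.nan)
    for fold, rec in enumerate(records):
        test_mask = antigen_ids == rec.antigen_id
        train_mask = ~test_mask
        y_train = labels[train_mask]
        if y_train.sum() == 0:
            raise EpiseqError(
                f"fold {rec.antigen_id}: no positive training instance"
            )
        train_scores, test_scores = [], []
        for e_idx, name in enumerate(encoder_names):
            ens = BootstrapEnsemble(
                encoder_name=name,
                seed=(seed * 100003 + fold * 131 + e_idx) % (2**31 - 1),
                sampling=sampling,
                base_params=base_params or {},
            )
            ens.fit(X[name][train_mask], y_train)
            train_scores.append(ens.score_matrix(X[name][train_mask]))
            test_scores.append(ens.score_matrix(X[name][test_mask]))
        norm = fit_normalization(train_scores)
        oof_norm[:, test_mask] = normalize_matrix(
            np.vstack(test_scores), norm, c
        )

    # per-encoder out-of-fold performance
    mean_auc_by_encoder = {
        name: mean_per_antigen_auc(oof_norm[i], labels, antigen_ids)
        for i, name in enumerate(encoder_names)
    }

    w_used: np.ndarray | None
    if strategy == "weighted":
        if isinstance(weights, str) and weights == "search":
            w_used = grid_search_weights(
                oof_norm, labels, antigen_ids, step=grid_step
            )
        elif weights is None:
            w_used = np.full(k, 1.0 / k)
        else:
            w_used = np.asarray(weights, dtype=float)
            if w_used.shape != (k,):
                raise EpiseqError(f"expected {k} weights, got {w_used.shape}")
        fused = np.asarray(fuse_weighted(oof_norm, w_used))
    elif strategy == "mean":
        w_used = None
        fused = np.asarray(fuse_mean(oof_norm))
    elif strategy == "median":
        w_used = None
        fused = np.asarray(fuse_median(oof_norm))
    else:
        raise EpiseqError(f"unknown strategy {strategy!r}")

    rows = []
    skipped = []
    for rec in records:
        mask = antigen_ids == rec.antigen_id
        lab = labels[mask]
        row: dict = {
            "antigen_id": rec.antigen_id,
            "n_residues": int(mask.sum()),
            "n_pos": int(lab.sum()),
            "n_neg": int((lab == 0).sum()),
        }
        if row["n_pos"] == 0 or row["n_neg"] == 0:
            skipped.append(rec.antigen_id)
            continue
        row["auc"] = auc(fused[mask], lab)
        for i, name in enumerate(encoder_names):
            row[f"auc_{name}"] = auc(oof_norm[i][mask], lab)
        cc = confusion(fused[mask], lab, threshold)
        row.update(
            sn=sensitivity(cc), sp=specificity(cc),
            acc=accuracy(cc), f=f_measure(cc),
        )
        rows.append(row)
    if skipped:
        logger.info(
            "excluded %d single-class antigen(s) from mean AUC: %s",
            len(skipped), skipped,
        )
    per_antigen = pd.DataFrame(rows)
    if per_antigen.empty:
        raise EpiseqError("no antigen has both classes; nothing to evaluate")

    cc_all = confusion(fused, labels, threshold)
    pooled = {
        "sn": sensitivity(cc_all),
        "sp": specificity(cc_all),
        "acc": accuracy(cc_all),
        "f": f_measure(cc_all),
        "auc": auc(fused, labels),
    }
    meta = meta.copy()
    meta["score"] = fused
    for i, name in enumerate(encoder_names):
        meta[f"score_{name}"] = oof_norm[i]

    return EvaluationReport(
        per_antigen=per_antigen,
        mean_auc=float(per_antigen["auc"].mean()),
        mean_auc_by_encoder=mean_auc_by_encoder,
        pooled=pooled,
        weights=w_used,
        config={
            "encoders": list(encoder_names),
            "L": L,
            "strategy": strategy,
            "threshold": threshold,
            "c": c,
            "sampling": sampling,
            "grid_step": grid_step,
            "seed": seed,
        },
        oof_scores=meta,
    )
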