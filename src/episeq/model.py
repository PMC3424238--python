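"""Model / Results objects wrapping the full prediction pipeline.

:class:`EpitopeEnsembleModel` is constructed from labelled antigen
records and a configuration; ``fit()`` trains one imbalance-handling
bootstrap ensemble per feature encoding, fits the tanh-estimator
normalization on the training scores, resolves the fusion weights and
returns an :class:`EpitopeEnsembleResults` carrying the fitted
:class:`~episeq.fusion.FusionModel`, training diagnostics, prediction
and persistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .ensemble import BootstrapEnsemble, compute_n
from .errors import EpiseqError, NotFittedError
from .evaluation import EvaluationReport, loocv, mean_per_antigen_auc
from .features import get_encoder
from .fusion import (
    DEFAULT_WEIGHTS,
    FUSION_ORDER,
    FusionModel,
    fit_normalization,
    grid_search_weights,
    normalize_matrix,
)
from .io import AntigenRecord, load_dataset, write_predictions
from .windowing import class_counts, extract_windows

BUNDLE_FORMAT_VERSION = 1


def default_weights_for(encoder_names: tuple[str, ...]) -> np.ndarray:
    """Published optimal weights when the full seven-encoder panel is
    used in canonical order; uniform weights for any other panel."""
    if tuple(encoder_names) == FUSION_ORDER:
        return np.asarray(DEFAULT_WEIGHTS)
    k = len(encoder_names)
    return np.full(k, 1.0 / k)


class EpitopeEnsembleModel:
    """Sequence-based conformational epitope predictor.

    Parameters
    ----------
    records : list of AntigenRecord
        Labelled training antigens with whatever tracks the chosen
        encoders require.
    encoder_names : tuple of str
        Sub-classifier panel, in fusion order. Default: the seven-encoder
        panel (propensity, functional_composition, evolutionary, sparse,
        ss, rasa, pair_profile).
    weights : array, "search", or None
        Fusion weights. ``None`` uses the published optimum (full panel)
        or uniform weights (reduced panel); ``"search"`` runs the simplex
        grid search on the training scores (mean per-antigen AUC
        objective); an explicit array is used as given.
    window_length : int
        Odd sliding-window length L (default 9).
    strategy : {"weighted", "mean", "median"}
    terminal_policy : {"full_ensemble", "composition_only"}
        How the first/last (L-1)/2 residues are scored at prediction
        time: through the fused model on X-padded windows (default), or
        by a separate window-composition ensemble.
    """

    def __init__(
        self,
        records: list[AntigenRecord],
        encoder_names: tuple[str, ...] = FUSION_ORDER,
        window_length: int = 9,
        strategy: str = "weighted",
        weights: np.ndarray | str | None = None,
        c: float = 0.01,
        terminal_policy: str = "full_ensemble",
        sampling: str = "partition",
        base_params: dict | None = None,
        grid_step: float = 0.05,
        seed: int = 0,
    ) -> None:
        if not records:
            raise EpiseqError("no training records")
        self.records = records
        self.encoder_names = tuple(encoder_names)
        self.window_length = window_length
        self.strategy = strategy
        self.weights = weights
        self.c = c
        self.terminal_policy = terminal_policy
        self.sampling = sampling
        self.base_params = base_params or {}
        self.grid_step = grid_step
        self.seed = seed

    @classmethod
    def from_files(
        cls,
        fasta_path: str | Path,
        labels_path: str | Path,
        pssm_dir: str | Path | None = None,
        struct_dir: str | Path | None = None,
        **kwargs,
    ) -> "EpitopeEnsembleModel":
        records = load_dataset(fasta_path, labels_path, pssm_dir, struct_dir)
        return cls(records, **kwargs)

    def fit(self) -> "EpitopeEnsembleResults":
        encoders = {name: get_encoder(name) for name in self.encoder_names}
        windows = []
        for rec in self.records:
            for ch in rec.chains:
                windows.extend(
                    extract_windows(ch, self.window_length, rec.antigen_id)
                )
        n_pos, n_neg = class_counts(windows)
        if n_pos == 0 or n_neg == 0:
            raise EpiseqError(
                f"training data needs both classes (pos={n_pos}, neg={n_neg})"
            )
        y = np.array([w.label for w in windows])
        antigen_ids = np.array([w.antigen_id for w in windows])

        sub_ensembles: dict[str, BootstrapEnsemble] = {}
        train_scores = []
        for e_idx, name in enumerate(self.encoder_names):
            X = encoders[name].encode_windows(windows)
            ens = BootstrapEnsemble(
                encoder_name=name,
                seed=(self.seed * 100003 + e_idx) % (2**31 - 1),
                sampling=self.sampling,
                base_params=self.base_params,
            )
            ens.fit(X, y)
            sub_ensembles[name] = ens
            train_scores.append(ens.score_matrix(X))
        norm = fit_normalization(train_scores)
        normalized = normalize_matrix(np.vstack(train_scores), norm, self.c)

        if isinstance(self.weights, str) and self.weights == "search":
            w = grid_search_weights(
                normalized, y, antigen_ids, step=self.grid_step
            )
        elif self.weights is None:
            w = default_weights_for(self.encoder_names)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.encoder_names),):
                raise EpiseqError(
                    f"expected {len(self.encoder_names)} weights, got {w.shape}"
                )

        composition_model = composition_encoder = None
        if self.terminal_policy == "composition_only":
            composition_encoder = get_encoder("composition")
            Xc = composition_encoder.encode_windows(windows)
            composition_model = BootstrapEnsemble(
                encoder_name="composition",
                seed=(self.seed * 100003 + 97) % (2**31 - 1),
                sampling=self.sampling,
                base_params=self.base_params,
            ).fit(Xc, y)

        fusion = FusionModel(
            encoder_names=self.encoder_names,
            encoders=encoders,
            sub_ensembles=sub_ensembles,
            norm=norm,
            weights=w,
            L=self.window_length,
            strategy=self.strategy,
            c=self.c,
            terminal_policy=self.terminal_policy,
            composition_model=composition_model,
            composition_encoder=composition_encoder,
        )
        train_auc = {
            name: mean_per_antigen_auc(normalized[i], y, antigen_ids)
            for i, name in enumerate(self.encoder_names)
        }
        return EpitopeEnsembleResults(
            model=self,
            fusion=fusion,
            n_pos=n_pos,
            n_neg=n_neg,
            train_auc_by_encoder=train_auc,
        )

    def loocv(self, weights: np.ndarray | str | None = "search") -> EvaluationReport:
        """Antigen-level leave-one-out cross-validation of this config."""
        return loocv(
            self.records,
            encoder_names=self.encoder_names,
            L=self.window_length,
            strategy=self.strategy,
            weights=weights,
            c=self.c,
            sampling=self.sampling,
            base_params=self.base_params,
            grid_step=self.grid_step,
            seed=self.seed,
        )


@dataclass
class EpitopeEnsembleResults:
    """Fitted predictor: estimates, diagnostics, prediction, persistence."""

    model: EpitopeEnsembleModel
    fusion: FusionModel
    n_pos: int
    n_neg: int
    train_auc_by_encoder: dict[str, float] = field(default_factory=dict)

    @property
    def weights(self) -> np.ndarray:
        return self.fusion.weights

    @property
    def imbalance_n(self) -> int:
        """Number of rebalanced sub-samples implied by the class ratio."""
        return compute_n(self.n_pos, self.n_neg)

    def predict(
        self, records: list[AntigenRecord] | None = None, threshold: float = 0.5
    ) -> pd.DataFrame:
        """Score every residue of *records* (default: the training set).

        Returns a tidy frame: antigen_id, chain_id, position (1-based),
        residue, score, predicted_label.
        """
        records = records if records is not None else self.model.records
        rows = []
        for rec in records:
            for ch in rec.chains:
                scores = self.fusion.predict_chain(ch, rec.antigen_id)
                for i, (aa, s) in enumerate(zip(ch.sequence, scores)):
                    rows.append(
                        (
                            rec.antigen_id,
                            ch.chain_id,
                            i + 1,
                            aa,
                            float(s),
                            int(s >= threshold),
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "antigen_id",
                "chain_id",
                "position",
                "residue",
                "score",
                "predicted_label",
            ],
        )

    def predict_to_file(
        self,
        records: list[AntigenRecord],
        path: str | Path,
        threshold: float = 0.5,
    ) -> None:
        scores = {
            (rec.antigen_id, ch.chain_id): self.fusion.predict_chain(
                ch, rec.antigen_id
            )
            for rec in records
            for ch in rec.chains
        }
        write_predictions(records, scores, path, threshold)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Epitope ensemble model (fitted)",
            "=" * 46,
            f"window length L          : {m.window_length}",
            f"strategy                 : {m.strategy}",
            f"terminal policy          : {m.terminal_policy}",
            f"training windows         : {self.n_pos + self.n_neg} "
            f"({self.n_pos} pos / {self.n_neg} neg)",
            f"rebalanced sub-samples n : {self.imbalance_n}",
            "",
            f"{'sub-classifier':<24s} {'weight':>7s} {'train AUC':>10s} "
            f"{'mu':>7s} {'sigma':>7s}",
        ]
        for i, name in enumerate(m.encoder_names):
            lines.append(
                f"{name:<24s} {self.fusion.weights[i]:>7.2f} "
                f"{self.train_auc_by_encoder.get(name, float('nan')):>10.3f} "
                f"{self.fusion.norm.mu[i]:>7.3f} {self.fusion.norm.sigma[i]:>7.3f}"
            )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Persist the fitted bundle (versioned joblib archive)."""
        payload = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "package_version": _pkg_version,
            "config": {
                "encoder_names": self.model.encoder_names,
                "window_length": self.model.window_length,
                "strategy": self.model.strategy,
                "c": self.model.c,
                "terminal_policy": self.model.terminal_policy,
                "sampling": self.model.sampling,
                "seed": self.model.seed,
            },
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "train_auc_by_encoder": self.train_auc_by_encoder,
            "weights": np.asarray(self.fusion.weights),
            "norm_mu": np.asarray(self.fusion.norm.mu),
            "norm_sigma": np.asarray(self.fusion.norm.sigma),
            "sub_ensembles": self.fusion.sub_ensembles,
            "composition_model": self.fusion.composition_model,
        }
        joblib.dump(payload, path)


def load_results(path: str | Path) -> EpitopeEnsembleResults:
    """Load a bundle written by :meth:`EpitopeEnsembleResults.save`.

    The returned results object has an empty training-record list; it
    supports prediction, not refitting.
    """
    payload = joblib.load(path)
    if payload.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise EpiseqError(
            f"unsupported bundle format {payload.get('format_version')!r}"
        )
    cfg = payload["config"]
    from .fusion import NormalizationParams  # local to avoid re-export noise

    encoder_names = tuple(cfg["encoder_names"])
    encoders = {name: get_encoder(name) for name in encoder_names}
    composition_model = payload.get("composition_model")
    fusion = FusionModel(
        encoder_names=encoder_names,
        encoders=encoders,
        sub_ensembles=payload["sub_ensembles"],
        norm=NormalizationParams(payload["norm_mu"], payload["norm_sigma"]),
        weights=payload["weights"],
        L=cfg["window_length"],
        strategy=cfg["strategy"],
        c=cfg["c"],
        terminal_policy=cfg["terminal_policy"],
        composition_model=composition_model,
        composition_encoder=(
            get_encoder("composition") if composition_model is not None else None
        ),
    )
    model = EpitopeEnsembleModel.__new__(EpitopeEnsembleModel)
    model.records = []
    model.encoder_names = encoder_names
    model.window_length = cfg["window_length"]
    model.strategy = cfg["strategy"]
    model.weights = payload["weights"]
    model.c = cfg["c"]
    model.terminal_policy = cfg["terminal_policy"]
    model.sampling = cfg["sampling"]
    model.base_params = {}
    model.grid_step = 0.05
    model.seed = cfg["seed"]
    return EpitopeEnsembleResults(
        model=model,
        fusion=fusion,
        n_pos=payload["n_pos"],
        n_neg=payload["n_neg"],
        train_auc_by_encoder=payload["train_auc_by_encoder"],
    )
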