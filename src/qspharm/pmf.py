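"""Probabilistic matrix factorization of the binary interaction matrix.

The sparse drug x target matrix R (N x M) is decomposed as R ~ U^T V with a
D-dimensional latent vector per drug (columns of U, D x N) and per target
(columns of V, D x M). Factors are fit by minimizing the squared
reconstruction error over the observed positives (value 1) and a seeded
sample of unobserved pairs treated as negatives (value 0), with L2
regularization on both factor matrices — the implicit-feedback variant of
PMF needed when only positive interactions are recorded. The reconstructed
value U_i . V_j for an unobserved pair, mapped into [0, 1], is its
*confidence score*; the selection rule keeps, per drug, candidates with
confidence strictly above a cutoff (default 0.7) within the top-k ranks
(default 10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import (
    AnalysisError,
    ConfigurationError,
    EvaluationError,
    TrainingError,
    ValidationError,
)
from .interactions import InteractionMatrix


@dataclass(frozen=True)
class PMFConfig:
    """Training hyperparameters.

    ``neg_ratio`` unobserved pairs per observed positive are resampled each
    epoch as zeros (0 disables negative sampling); ``score_map`` maps raw
    factor products to [0, 1] (``clamp`` or ``logistic``).
    """

    n_factors: int = 50
    reg_u: float = 0.01
    reg_v: float = 0.01
    learn_rate: float = 0.01
    epochs: int = 200
    tol: float = 1e-5
    neg_ratio: float = 5.0
    seed: int = 0
    score_map: str = "clamp"
    optimizer: str = "full_batch"  # full_batch | sgd
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ConfigurationError("n_factors must be >= 1")
        if self.reg_u < 0 or self.reg_v < 0:
            raise ConfigurationError("regularization weights must be >= 0")
        if self.learn_rate <= 0:
            raise ConfigurationError("learn_rate must be > 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.neg_ratio < 0:
            raise ConfigurationError("neg_ratio must be >= 0")
        if self.score_map not in ("clamp", "logistic"):
            raise ConfigurationError(f"unknown score_map {self.score_map!r}")
        if self.optimizer not in ("full_batch", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class PMFModel:
    """Trained factors plus provenance of the training matrix."""

    U: np.ndarray  # D x N drug factors
    V: np.ndarray  # D x M target factors
    config: PMFConfig
    loss_trace: list[float]
    drug_ids: list[str]
    target_ids: list[str]
    training_entries: frozenset[tuple[int, int]]
    matrix_hash: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.U.shape[1], self.V.shape[1]

    def raw_score(self, drug_index: int, target_index: int) -> float:
        n, m = self.shape
        if not (0 <= drug_index < n and 0 <= target_index < m):
            raise LookupError(
                f"index ({drug_index}, {target_index}) outside {n}x{m} model"
            )
        return float(self.U[:, drug_index] @ self.V[:, target_index])

    def save(self, path: str | Path) -> None:
        """JSON checkpoint holding factors, config, and the matrix fingerprint."""
        payload = {
            "U": self.U.tolist(),
            "V": self.V.tolist(),
            "config": self.config.__dict__,
            "loss_trace": self.loss_trace,
            "drug_ids": self.drug_ids,
            "target_ids": self.target_ids,
            "training_entries": sorted(self.training_entries),
            "matrix_hash": self.matrix_hash,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PMFModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            U=np.asarray(payload["U"], dtype=float),
            V=np.asarray(payload["V"], dtype=float),
            config=PMFConfig(**payload["config"]),
            loss_trace=list(payload["loss_trace"]),
            drug_ids=list(payload["drug_ids"]),
            target_ids=list(payload["target_ids"]),
            training_entries=frozenset(
                (int(i), int(j)) for i, j in payload["training_entries"]
            ),
            matrix_hash=payload["matrix_hash"],
        )

    def check_matrix(self, matrix: InteractionMatrix) -> None:
        if matrix.entry_hash() != self.matrix_hash:
            raise ValidationError(
                "model was trained on a different interaction matrix "
                "(fingerprint mismatch)"
            )


@dataclass(frozen=True)
class Prediction:
    drug_id: str
    target_id: str
    confidence: float
    rank: int
    novelty: str  # new_interaction_known_target | new_target


def _map_score(raw: np.ndarray | float, score_map: str):
    if score_map == "clamp":
        return np.clip(raw, 0.0, 1.0)
    return 1.0 / (1.0 + np.exp(-np.asarray(raw, dtype=float)))


def _sample_negatives(
    rng: np.random.Generator,
    n: int,
    m: int,
    positives: set[tuple[int, int]],
    count: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``count`` unobserved (i, j) pairs uniformly, rejection-style."""
    out_i: list[int] = []
    out_j: list[int] = []
    needed = count
    while needed > 0:
        draw = max(needed * 2, 16)
        ii = rng.integers(0, n, size=draw)
        jj = rng.integers(0, m, size=draw)
        for i, j in zip(ii, jj):
            if (int(i), int(j)) not in positives:
                out_i.append(int(i))
                out_j.append(int(j))
                needed -= 1
                if needed == 0:
                    break
    return np.asarray(out_i), np.asarray(out_j)


def train_pmf(
    matrix: InteractionMatrix,
    config: PMFConfig,
    exclude_from_negatives: Iterable[tuple[int, int]] | None = None,
) -> PMFModel:
    """Fit PMF factors to a binary interaction matrix.

    Deterministic for a given (matrix, config): factor initialization and
    per-epoch negative resampling both derive from ``config.seed``. Training
    stops early when the relative loss change drops below ``config.tol``;
    a non-finite loss aborts with a :class:`TrainingError`.

    ``exclude_from_negatives`` marks unobserved pairs as missing rather than
    candidate negatives — used in masking experiments where held-out
    positives must not be sampled as zeros.
    """
    if matrix.n_entries == 0:
        raise AnalysisError("cannot train on an empty interaction matrix")
    n, m = matrix.shape
    d = config.n_factors
    rng = np.random.default_rng(config.seed)
    U = rng.normal(scale=config.init_scale, size=(d, n))
    V = rng.normal(scale=config.init_scale, size=(d, m))

    positives = sorted(matrix.entries)
    pos_i = np.asarray([i for i, _ in positives])
    pos_j = np.asarray([j for _, j in positives])
    pos_set = set(matrix.entries)
    if exclude_from_negatives:
        pos_set = pos_set | {(int(i), int(j)) for i, j in exclude_from_negatives}
    n_neg = int(round(config.neg_ratio * len(positives)))
    n_neg = min(n_neg, n * m - len(pos_set))

    loss_trace: list[float] = []
    prev_loss = None
    for epoch in range(config.epochs):
        if n_neg > 0:
            neg_i, neg_j = _sample_negatives(rng, n, m, pos_set, n_neg)
            ii = np.concatenate([pos_i, neg_i])
            jj = np.concatenate([pos_j, neg_j])
            rr = np.concatenate(
                [np.ones(len(pos_i)), np.zeros(len(neg_i))]
            )
        else:
            ii, jj, rr = pos_i, pos_j, np.ones(len(pos_i))

        if config.optimizer == "sgd":
            order = rng.permutation(len(ii))
            for idx in order:
                i, j = int(ii[idx]), int(jj[idx])
                err = rr[idx] - U[:, i] @ V[:, j]
                du = err * V[:, j] - config.reg_u * U[:, i]
                dv = err * U[:, i] - config.reg_v * V[:, j]
                U[:, i] += config.learn_rate * du
                V[:, j] += config.learn_rate * dv
            pred = np.einsum("di,di->i", U[:, ii], V[:, jj])
            err = rr - pred
        else:
            pred = np.einsum("di,di->i", U[:, ii], V[:, jj])
            err = rr - pred
            # gradient of the half summed-squared-error objective
            gU = np.zeros_like(U)
            gV = np.zeros_like(V)
            np.add.at(gU.T, ii, err[:, None] * V[:, jj].T)
            np.add.at(gV.T, jj, err[:, None] * U[:, ii].T)
            gU -= config.reg_u * U
            gV -= config.reg_v * V
            U += config.learn_rate * gU
            V += config.learn_rate * gV
            pred = np.einsum("di,di->i", U[:, ii], V[:, jj])
            err = rr - pred

        with np.errstate(over="ignore"):
            loss = float(
                np.sum(err**2)
                + config.reg_u * np.sum(U**2)
                + config.reg_v * np.sum(V**2)
            )
        if not np.isfinite(loss):
            raise TrainingError(
                f"training diverged at epoch {epoch}: loss is non-finite; "
                f"try a smaller learn_rate than {config.learn_rate}"
            )
        loss_trace.append(loss)
        if (
            prev_loss is not None
            and abs(prev_loss - loss) / max(prev_loss, 1e-12) < config.tol
        ):
            break
        prev_loss = loss

    return PMFModel(
        U=U,
        V=V,
        config=config,
        loss_trace=loss_trace,
        drug_ids=list(matrix.drug_ids),
        target_ids=list(matrix.target_ids),
        training_entries=matrix.entries,
        matrix_hash=matrix.entry_hash(),
    )


def predict_confidence(model: PMFModel, drug_index: int, target_index: int) -> float:
    """Confidence score in [0, 1] for one (drug, target) pair."""
    raw = model.raw_score(drug_index, target_index)
    return float(_map_score(raw, model.config.score_map))


def drug_confidences(model: PMFModel, drug_index: int) -> np.ndarray:
    """Confidence scores for one drug against every target."""
    n, _ = model.shape
    if not 0 <= drug_index < n:
        raise LookupError(f"drug index {drug_index} outside model")
    raw = model.U[:, drug_index] @ model.V
    return np.asarray(_map_score(raw, model.config.score_map), dtype=float)


def select_novel_predictions(
    model: PMFModel,
    matrix: InteractionMatrix,
    top_k: int = 10,
    min_conf: float = 0.7,
) -> list[Prediction]:
    """Per-drug selection of novel interactions.

    Non-observed targets are ranked by confidence descending (ties broken by
    target id ascending); a candidate is kept iff its rank is <= ``top_k``
    and its confidence is strictly above ``min_conf``. Drugs with no
    training interaction are skipped (cold start is undefined). Novelty is
    annotated relative to the set of targets with any observed interaction.
    """
    model.check_matrix(matrix)
    observed_by_drug: dict[int, set[int]] = {}
    known_targets: set[int] = set()
    for i, j in matrix.entries:
        observed_by_drug.setdefault(i, set()).add(j)
        known_targets.add(j)

    predictions: list[Prediction] = []
    n, m = matrix.shape
    for i in range(n):
        observed = observed_by_drug.get(i)
        if not observed:
            continue
        conf = drug_confidences(model, i)
        candidates = [j for j in range(m) if j not in observed]
        candidates.sort(key=lambda j: (-conf[j], matrix.target_ids[j]))
        for rank, j in enumerate(candidates, start=1):
            if rank > top_k:
                break
            if conf[j] <= min_conf:
                continue
            novelty = (
                "new_interaction_known_target" if j in known_targets else "new_target"
            )
            predictions.append(
                Prediction(
                    drug_id=matrix.drug_ids[i],
                    target_id=matrix.target_ids[j],
                    confidence=float(conf[j]),
                    rank=rank,
                    novelty=novelty,
                )
            )
    return predictions


def write_predictions_tsv(predictions: Iterable[Prediction], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("drug_id\ttarget_id\tconfidence\trank\tnovelty\n")
        for p in predictions:
            fh.write(
                f"{p.drug_id}\t{p.target_id}\t{p.confidence:.6f}\t{p.rank}\t{p.novelty}\n"
            )


@dataclass(frozen=True)
class HeldoutEvaluation:
    auc: float
    hit_rate_at_k: float
    top_k: int
    n_positives: int
    n_negatives: int


def evaluate_heldout(
    model: PMFModel,
    heldout_positives: Sequence[tuple[int, int]],
    heldout_negatives: Sequence[tuple[int, int]],
    top_k: int = 10,
) -> HeldoutEvaluation:
    """Ranking quality on held-out pairs: ROC AUC and hit rate at ``top_k``.

    AUC compares the confidences of held-out positives against held-out
    negatives; the hit rate is the fraction of held-out positives ranked
    within the drug's top ``top_k`` non-training targets.
    """
    positives = [(int(i), int(j)) for i, j in heldout_positives]
    negatives = [(int(i), int(j)) for i, j in heldout_negatives]
    if not positives or not negatives:
        raise EvaluationError("held-out positives and negatives must be non-empty")
    overlap = (set(positives) | set(negatives)) & model.training_entries
    if overlap:
        raise EvaluationError(
            f"{len(overlap)} held-out pair(s) overlap the training entries"
        )

    scores = [predict_confidence(model, i, j) for i, j in positives] + [
        predict_confidence(model, i, j) for i, j in negatives
    ]
    labels = [1] * len(positives) + [0] * len(negatives)
    auc = float(roc_auc_score(labels, scores))

    observed_by_drug: dict[int, set[int]] = {}
    for i, j in model.training_entries:
        observed_by_drug.setdefault(i, set()).add(j)
    _, m = model.shape
    hits = 0
    for i, j in positives:
        conf = drug_confidences(model, i)
        observed = observed_by_drug.get(i, set())
        candidates = [t for t in range(m) if t not in observed]
        candidates.sort(key=lambda t: (-conf[t], t))
        rank = candidates.index(j) + 1
        if rank <= top_k:
            hits += 1
    return HeldoutEvaluation(
        auc=auc,
        hit_rate_at_k=hits / len(positives),
        top_k=top_k,
        n_positives=len(positives),
        n_negatives=len(negatives),
    )
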