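"""Cross-validated training, the six evaluation metrics, and grid search.

Training follows the reference configuration: Adam, learning rate 1e-3,
200 epochs, batch size 96, five-fold cross-validation, with AUC, AUPR,
accuracy, precision, recall and F1 reported overall and per hyperedge
order. Folds are stratified by (label, order); per fold the coupling-channel
hypergraph is rebuilt from that fold's *training* positives only, so test
hyperedges never leak into the incidence matrix.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .genome_io import ValidationError
from .hypergraph import Hyperedge, Hypergraph, HyperedgeSet, build_hypergraph
from .model import (
    ModelConfig,
    ModelParams,
    batch_from_samples,
    classify,
    forward,
    hconv,
    init_params,
    total_loss,
)
from .optim import Adam
from .sampling import LabeledSample

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auc", "aupr", "accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (model hyperparameters live in ModelConfig)."""

    batch_size: int = 96
    dropout: float = 0.4
    learning_rate: float = 1e-3
    epochs: int = 200
    lambda_kl: float = 1.0
    seed: int = 0
    folds: int = 5
    val_fraction: float = 0.1
    variant: str = "full"
    threshold: float = 0.5

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValidationError("batch_size must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")


@dataclass
class MetricsReport:
    """Six metrics, overall and per order, plus the training loss curve."""

    overall: dict[str, float | None]
    per_order: dict[int, dict[str, float | None]] = field(default_factory=dict)
    loss_curve: list[float] = field(default_factory=list)
    val_loss_curve: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "overall": self.overall,
                "per_order": {str(k): v for k, v in self.per_order.items()},
                "loss_curve": self.loss_curve,
                "val_loss_curve": self.val_loss_curve,
            },
            indent=2,
        )


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float | None]:
    """Threshold-free AUC/AUPR plus thresholded accuracy/precision/recall/F1.

    With a single-class label vector the ranking metrics are undefined and
    reported as ``None`` rather than 0.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    single_class = len(np.unique(labels)) < 2
    predictions = classify(scores, threshold)
    return {
        "auc": None if single_class else float(roc_auc_score(labels, scores)),
        "aupr": None if single_class else float(average_precision_score(labels, scores)),
        "accuracy": float(accuracy_score(labels, predictions)),
        "precision": float(precision_score(labels, predictions, zero_division=0)),
        "recall": float(recall_score(labels, predictions, zero_division=0)),
        "f1": float(f1_score(labels, predictions, zero_division=0)),
    }


def pairwise_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Brute-force concordant-pair AUC (independent oracle for small n)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("pairwise AUC needs both classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def kfold_split(
    samples: Sequence[LabeledSample], k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition over (label, order) strata.

    Folds are disjoint, cover all samples, and differ in size by at most one.
    """
    if len(samples) < k:
        raise ValidationError(f"need at least {k} samples for {k}-fold CV")
    strata = np.array([f"{s.label}:{s.order}" for s in samples])
    # strata rarer than k members cannot be split evenly; merge them by label
    values, counts = np.unique(strata, return_counts=True)
    rare = {v for v, c in zip(values, counts) if c < k}
    if rare:
        labels_only = np.array([str(s.label) for s in samples])
        strata = np.where(np.isin(strata, list(rare)), labels_only, strata)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train_idx, test_idx)
        for train_idx, test_idx in splitter.split(np.zeros(len(samples)), strata)
    ]


def graph_from_samples(samples: Sequence[LabeledSample], n_bins: int) -> Hypergraph:
    """Incidence matrices from the positive samples of a training fold."""
    edges = tuple(
        Hyperedge(s.bins, 1) for s in sorted(
            (s for s in samples if s.label == 1), key=lambda s: s.bins
        )
    )
    return build_hypergraph(HyperedgeSet(edges, n_bins))


@dataclass
class TrainResult:
    params: ModelParams
    report: MetricsReport


def _epoch_loss(
    params: ModelParams,
    samples: Sequence[LabeledSample],
    embeddings: np.ndarray,
    graph: Hypergraph | None,
    lambda_kl: float,
    batch_size: int,
) -> float:
    total, n = 0.0, 0
    structural = None
    if params.config.variant != "noCHE":
        structural = hconv(embeddings, graph, params).detach()
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        batch = batch_from_samples(chunk, embeddings, params.config.max_order)
        p, kl = forward(params, batch, structural=structural)
        loss = total_loss(p, batch.labels, kl, lambda_kl)
        total += loss.item() * len(chunk)
        n += len(chunk)
    return total / max(n, 1)


def train(
    samples: Sequence[LabeledSample],
    embeddings: np.ndarray,
    graph: Hypergraph,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> TrainResult:
    """Train the scorer; returns best-epoch parameters by validation loss.

    A ``val_fraction`` stratified slice of the input is held out for epoch
    selection; the coupling-channel graph is recomputed from parameters at
    every step (it is part of the differentiable path). Divergence
    (non-finite loss) aborts with the last finite-loss parameters.
    """
    if model_config is None:
        model_config = ModelConfig(
            feature_dim=embeddings.shape[1],
            dropout=config.dropout,
            lambda_kl=config.lambda_kl,
            variant=config.variant,
        )
    vertex_ids = {v for s in samples for v in s.bins}
    if max(vertex_ids) >= embeddings.shape[0]:
        raise ValidationError("embeddings do not cover all vertex ids in samples")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    params = init_params(model_config, seed=config.seed)
    optimizer = Adam(params.all_tensors(), lr=config.learning_rate)

    strata = [f"{s.label}:{s.order}" for s in samples]
    indices = np.arange(len(samples))
    if config.val_fraction > 0 and len(samples) >= 10:
        try:
            train_idx, val_idx = train_test_split(
                indices,
                test_size=config.val_fraction,
                random_state=config.seed,
                stratify=strata,
            )
        except ValueError:  # a stratum with a single member
            train_idx, val_idx = train_test_split(
                indices, test_size=config.val_fraction, random_state=config.seed
            )
    else:
        train_idx, val_idx = indices, np.array([], dtype=int)
    train_samples = [samples[i] for i in train_idx]
    val_samples = [samples[i] for i in val_idx]

    use_graph = model_config.variant != "noCHE"
    loss_curve: list[float] = []
    val_curve: list[float] = []
    best_state = params.state_dict()
    best_val = np.inf
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_samples))
        epoch_total, seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            chunk = [train_samples[i] for i in order[start : start + config.batch_size]]
            batch = batch_from_samples(chunk, embeddings, model_config.max_order)
            structural = hconv(embeddings, graph, params) if use_graph else None
            p, kl = forward(params, batch, structural=structural, rng=rng)
            loss = total_loss(p, batch.labels, kl, config.lambda_kl)
            if not np.isfinite(loss.item()):
                logger.error("non-finite loss at epoch %d; aborting with last checkpoint", epoch)
                params.load_state(best_state)
                report = MetricsReport({}, loss_curve=loss_curve, val_loss_curve=val_curve)
                return TrainResult(params, report)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_total += loss.item() * len(chunk)
            seen += len(chunk)
        loss_curve.append(epoch_total / max(seen, 1))
        if val_samples:
            val_loss = _epoch_loss(
                params, val_samples, embeddings, graph if use_graph else None,
                config.lambda_kl, config.batch_size,
            )
            val_curve.append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_state = params.state_dict()
        else:
            best_state = params.state_dict()
    params.load_state(best_state)
    report = MetricsReport(overall={}, loss_curve=loss_curve, val_loss_curve=val_curve)
    return TrainResult(params, report)


def score_samples(
    params: ModelParams,
    samples: Sequence[LabeledSample],
    embeddings: np.ndarray,
    graph: Hypergraph | None,
    batch_size: int = 4096,
) -> np.ndarray:
    structural = None
    if params.config.variant != "noCHE":
        structural = hconv(embeddings, graph, params).detach()
    scores = np.empty(len(samples))
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        batch = batch_from_samples(chunk, embeddings, params.config.max_order)
        p, _ = forward(params, batch, structural=structural)
        scores[start : start + len(chunk)] = p.data
    return scores


def evaluate(
    params: ModelParams,
    samples: Sequence[LabeledSample],
    embeddings: np.ndarray,
    graph: Hypergraph | None = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Metrics on a sample set, overall and sliced per hyperedge order."""
    scores = score_samples(params, samples, embeddings, graph)
    labels = np.array([s.label for s in samples])
    orders = np.array([s.order for s in samples])
    report = MetricsReport(overall=compute_metrics(labels, scores, threshold))
    for order in sorted(set(orders)):
        sel = orders == order
        report.per_order[int(order)] = compute_metrics(labels[sel], scores[sel], threshold)
    return report


def cross_validate(
    samples: Sequence[LabeledSample],
    embeddings: np.ndarray,
    n_bins: int,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> list[MetricsReport]:
    """Five-fold CV; the graph per fold uses only that fold's train positives."""
    reports = []
    for fold, (train_idx, test_idx) in enumerate(
        kfold_split(samples, config.folds, config.seed)
    ):
        train_set = [samples[i] for i in train_idx]
        test_set = [samples[i] for i in test_idx]
        graph = graph_from_samples(train_set, n_bins)
        result = train(train_set, embeddings, graph, config, model_config)
        report = evaluate(result.params, test_set, embeddings, graph, config.threshold)
        report.loss_curve = result.report.loss_curve
        report.val_loss_curve = result.report.val_loss_curve
        logger.info("fold %d: %s", fold, report.overall)
        reports.append(report)
    return reports


def mean_metric(reports: Sequence[MetricsReport], name: str = "auc") -> float:
    values = [r.overall[name] for r in reports if r.overall.get(name) is not None]
    return float(np.mean(values))


# -- grid search --------------------------------------------------------------

PAPER_GRIDS: dict[str, tuple] = {
    "batch_size": (64, 96, 128),
    "dropout": (0.1, 0.2, 0.3, 0.4, 0.5),
    "learning_rate": (0.0001, 0.0005, 0.001, 0.005, 0.01),
}


def enumerate_grid(grids: dict[str, Sequence]) -> list[dict]:
    """Cartesian product of hyperparameter grids, in deterministic order."""
    keys = sorted(grids)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grids[k] for k in keys))]


def grid_search(
    samples: Sequence[LabeledSample],
    embeddings: np.ndarray,
    n_bins: int,
    base_config: TrainConfig,
    grids: dict[str, Sequence],
) -> tuple[list[dict], dict]:
    """Evaluate every grid combination by k-fold CV mean metrics.

    Returns (table, best_row); the best row maximizes mean AUC.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValidationError("grids must be nonempty")
    table = []
    for combo in enumerate_grid(grids):
        config = replace(base_config, **combo)
        reports = cross_validate(samples, embeddings, n_bins, config)
        row = dict(combo)
        for name in METRIC_NAMES:
            row[f"mean_{name}"] = mean_metric(reports, name)
        table.append(row)
        logger.info("grid %s -> AUC %.4f", combo, row["mean_auc"])
    best = max(table, key=lambda r: r["mean_auc"])
    return table, best
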