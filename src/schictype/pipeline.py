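"""End-to-end orchestration: binning -> QC -> imputation -> embedding -> classifier.

The split protocol is inductive by default: the two-stage PCA is fitted on
training cells only and held-out cells are projected through the stored
transforms before prediction.  ``transductive=True`` embeds all cells
jointly before the split instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classifier, metrics
from .classifier import ModelConfig, TrainedModel
from .contacts import CellContactSet, GenomeSpec, bin_pairs, filter_cells, read_pairs
from .embedding import CellEmbedder, EmbedParams
from .imputation import ImputationParams, impute_cell

__all__ = ["PipelineConfig", "PipelineResult", "prepare_cells", "impute_cells", "embed_and_classify", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """One config object driving every stage; all randomness derives from ``seed``."""

    resolution: int = 1_000_000
    min_contacts: int = 5000
    imputation: ImputationParams = field(default_factory=ImputationParams)
    embedding: EmbedParams = field(default_factory=EmbedParams)
    hidden_sizes: tuple[int, ...] = (256, 64)
    dropout_rate: float = 0.5
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    test_fraction: float = 0.3
    transductive: bool = False
    cv_folds: int = 10
    seed: int = 0


@dataclass
class PipelineResult:
    model: TrainedModel
    embedder: CellEmbedder
    train_ids: list[str]
    test_ids: list[str]
    predictions: dict[str, str]
    report: dict


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels table needs >= 2 columns (cell_id, cell_type)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def prepare_cells(
    pairs_path: str | Path,
    genome: GenomeSpec,
    min_contacts: int = 5000,
    on_error: str = "raise",
) -> tuple[list[CellContactSet], list]:
    """Read + bin pairs, then QC-filter; returns (kept cells, removed-with-reasons)."""
    cells = bin_pairs(read_pairs(pairs_path, genome, on_error=on_error), genome)
    return filter_cells(list(cells.values()), min_contacts)


def impute_cells(
    cells: Sequence[CellContactSet], params: ImputationParams | None = None
) -> dict[str, dict[str, np.ndarray]]:
    params = params or ImputationParams()
    return {cell.cell_id: impute_cell(cell, params) for cell in cells}


def _split_ids(ids: list[str], test_fraction: float, seed: int) -> tuple[list[str], list[str]]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = int(round(test_fraction * len(ids)))
    test = [ids[i] for i in perm[:n_test]]
    train = [ids[i] for i in perm[n_test:]]
    return train, test


def embed_and_classify(
    imputed: dict[str, dict[str, np.ndarray]],
    labels: dict[str, str],
    config: PipelineConfig,
    chrom_order: Sequence[str] | None = None,
) -> PipelineResult:
    """Split cells, embed, train the network, and evaluate on the held-out cells."""
    ids = [cid for cid in imputed if cid in labels]
    if len(ids) < 4:
        raise ValueError("need at least 4 labelled cells")
    train_ids, test_ids = _split_ids(ids, config.test_fraction, config.seed)

    embedder = CellEmbedder(config.embedding, chrom_order)
    if config.transductive:
        emb_all = embedder.fit({cid: imputed[cid] for cid in ids})
        lookup = {cid: emb_all.features[i] for i, cid in enumerate(emb_all.cell_ids)}
        X_train = np.array([lookup[cid] for cid in train_ids])
        X_test = np.array([lookup[cid] for cid in test_ids])
    else:
        emb_train = embedder.fit({cid: imputed[cid] for cid in train_ids})
        X_train = emb_train.features
        X_test = (
            embedder.transform({cid: imputed[cid] for cid in test_ids}).features
            if test_ids
            else np.empty((0, X_train.shape[1]))
        )

    y_train = [labels[cid] for cid in train_ids]
    y_test = [labels[cid] for cid in test_ids]
    model_config = ModelConfig(
        input_dim=X_train.shape[1],
        n_classes=len(set(labels[cid] for cid in ids)),
        hidden_sizes=config.hidden_sizes,
        dropout_rate=config.dropout_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    model = classifier.train(X_train, y_train, model_config)

    report: dict = {"n_train": len(train_ids), "n_test": len(test_ids)}
    predictions: dict[str, str] = {}
    if test_ids:
        pred = classifier.predict(model, X_test)
        predictions = dict(zip(test_ids, pred))
        scores = classifier.predict_proba(model, X_test)
        report.update(metrics.evaluate(y_test, pred, scores, model.classes))
    return PipelineResult(model, embedder, train_ids, test_ids, predictions, report)


def crossvalidate(
    imputed: dict[str, dict[str, np.ndarray]],
    labels: dict[str, str],
    config: PipelineConfig,
    chrom_order: Sequence[str] | None = None,
) -> metrics.CVResult:
    """K-fold CV over a joint embedding of all cells (the transductive protocol)."""
    ids = [cid for cid in imputed if cid in labels]
    embedder = CellEmbedder(config.embedding, chrom_order)
    emb = embedder.fit({cid: imputed[cid] for cid in ids})
    X = emb.features
    y = [labels[cid] for cid in emb.cell_ids]

    def trainer(X_tr, y_tr):
        cfg = ModelConfig(
            input_dim=X_tr.shape[1],
            n_classes=len(set(y)),
            hidden_sizes=config.hidden_sizes,
            dropout_rate=config.dropout_rate,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=config.seed,
        )
        model = classifier.train(np.asarray(X_tr), list(y_tr), cfg)
        return lambda X_te: classifier.predict(model, X_te)

    return metrics.kfold_cv(X, y, trainer, metrics.CVConfig(k=config.cv_folds, seed=config.seed))


def run_pipeline(
    pairs_path: str | Path,
    chrom_sizes_path: str | Path,
    labels_path: str | Path,
    config: PipelineConfig | None = None,
    with_cv: bool = False,
) -> PipelineResult:
    """Full pipeline from files on disk to a held-out evaluation report."""
    config = config or PipelineConfig()
    genome = GenomeSpec.from_chrom_sizes(chrom_sizes_path, config.resolution)
    labels = read_labels(labels_path)
    kept, removed = prepare_cells(pairs_path, genome, config.min_contacts)
    if not kept:
        raise ValueError("no cell passed quality control")
    imputed = impute_cells(kept, config.imputation)
    result = embed_and_classify(imputed, labels, config, genome.chrom_names)
    result.report["n_input_cells"] = len(kept) + len(removed)
    result.report["n_qc_removed"] = len(removed)
    if with_cv:
        cv = crossvalidate(imputed, labels, config, genome.chrom_names)
        result.report["cv_fold_accuracies"] = cv.fold_accuracies
        result.report["cv_mean_accuracy"] = cv.mean_accuracy
    return result
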