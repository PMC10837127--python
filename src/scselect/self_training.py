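"""Self-training (pseudo-labelling) and entropy-based mislabel detection.

One round of self-training: fit a model on the labelled cells, predict the
remaining unlabelled training cells, keep the top 10/50/100% most
confident predictions by entropy, and add them — with their predicted
labels — to the training set of the downstream classifier.

The same entropy statistic doubles as a quality-control tool: cells whose
given label disagrees with their expression profile receive visibly higher
predictive entropy from a model trained on that very labelled set, which
ranks mis-annotated cells near the top.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .active_learning import (
    entropy,
    predict_probabilities,
    scaled_entropy,
    train_uncertainty_model,
)
from .core_data import validate_labels

logger = logging.getLogger(__name__)

TOP_PERCENT_CHOICES = (10, 50, 100)


@dataclass
class AugmentedTrainingSet:
    """Oracle-labelled cells plus confidently pseudo-labelled cells.

    ``source`` distinguishes oracle from pseudo cells; ``confidence`` holds
    the scaled predictive entropy at pseudo-labelling time (0 for oracle
    cells — they were never predicted).  Oracle labels are never
    overwritten.
    """

    cell_ids: np.ndarray
    labels: np.ndarray
    source: np.ndarray       # "oracle" | "pseudo"
    confidence: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if not (len(self.labels) == len(self.source) == len(self.confidence) == n):
            raise ValueError("augmented training set field length mismatch")
        if len(np.unique(self.cell_ids)) != n:
            raise ValueError("duplicate cells in augmented training set")

    def oracle_mask(self) -> np.ndarray:
        return self.source == "oracle"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids, "label": self.labels,
            "source": self.source, "scaled_entropy": self.confidence,
        })


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def pseudo_label(X_labeled: np.ndarray, y_labeled, X_unlabeled: np.ndarray,
                 labeled_ids, unlabeled_ids, model_kind: str = "random_forest",
                 top_percent: float = 10, seed: int = 0) -> AugmentedTrainingSet:
    """Augment a labelled set with the most confident predictions.

    Trains the model on the labelled cells, predicts the unlabelled pool,
    ranks by ascending entropy (most confident first, ties by cell id) and
    keeps the top *top_percent* of the pool, rounded half up, with their
    argmax labels attached.
    """
    y_labeled = validate_labels(y_labeled)
    labeled_ids = np.asarray(labeled_ids, dtype=str)
    unlabeled_ids = np.asarray(unlabeled_ids, dtype=str)
    base = AugmentedTrainingSet(
        cell_ids=labeled_ids.copy(), labels=y_labeled.copy(),
        source=np.asarray(["oracle"] * len(labeled_ids)),
        confidence=np.zeros(len(labeled_ids)),
    )
    if len(unlabeled_ids) == 0:
        warnings.warn("empty unlabelled pool; returning labelled set unchanged")
        return base
    clf = train_uncertainty_model(X_labeled, y_labeled, model_kind, seed=seed)
    P = predict_probabilities(clf, X_unlabeled, unlabeled_ids)
    se = scaled_entropy(entropy(P))
    n_take = _round_half_up(top_percent / 100.0 * len(unlabeled_ids))
    order = np.lexsort((unlabeled_ids, se))  # ascending entropy, ties by id
    take = order[:n_take]
    pred = np.asarray(P.class_names)[P.probs.argmax(axis=1)]
    return AugmentedTrainingSet(
        cell_ids=np.concatenate([base.cell_ids, unlabeled_ids[take]]),
        labels=np.concatenate([base.labels, pred[take]]),
        source=np.concatenate([base.source, ["pseudo"] * len(take)]),
        confidence=np.concatenate([base.confidence, se[take]]),
    )


def corrupt_labels(truth, fraction: float = 0.10,
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mis-assign a random fraction of labels to a different class.

    Returns the corrupted label vector and a boolean corruption mask.  Each
    corrupted cell's new label is drawn uniformly from the other classes.
    """
    y = validate_labels(truth).copy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to corrupt labels")
    n_corrupt = _round_half_up(fraction * len(y))
    rng = np.random.default_rng(seed)
    mask = np.zeros(len(y), dtype=bool)
    if n_corrupt:
        hit = rng.choice(len(y), size=n_corrupt, replace=False)
        mask[hit] = True
        for i in hit:
            others = classes[classes != y[i]]
            y[i] = rng.choice(others)
    return y, mask


def detect_mislabeled(X: np.ndarray, labels, cell_ids,
                      model_kind: str = "random_forest",
                      seed: int = 0) -> pd.DataFrame:
    """Rank training cells by predictive entropy to flag suspect labels.

    The model is fit on the given (possibly corrupted) training set and its
    scaled entropy is evaluated on those same cells; high entropy marks
    cells whose label is inconsistent with their neighbourhood in feature
    space.  Returns a frame sorted by descending scaled entropy.
    """
    labels = validate_labels(labels)
    cell_ids = np.asarray(cell_ids, dtype=str)
    clf = train_uncertainty_model(X, labels, model_kind, seed=seed)
    P = predict_probabilities(clf, X, cell_ids)
    se = scaled_entropy(entropy(P))
    df = pd.DataFrame({"cell_id": cell_ids, "label": labels,
                       "scaled_entropy": se})
    return df.sort_values(["scaled_entropy", "cell_id"],
                          ascending=[False, True], kind="mergesort",
                          ignore_index=True)


def self_training_gain(ds, labeled_ids, truth: pd.Series, test_ids,
                       model_kind: str = "random_forest",
                       top_percent: float = 10, seed: int = 0,
                       n_components: int = 20, downstream_grid=None) -> dict:
    """Measure what one round of pseudo-labelling buys downstream.

    Trains the downstream random-forest classifier on (a) the oracle cells
    only and (b) the augmented set, evaluates both on the held-out test
    cells, and returns both metric records plus their differences.
    """
    from .core_data import fit_embedding, project
    from .evaluation import evaluate_predictions, train_downstream_rf

    labeled_ids = np.asarray(labeled_ids, dtype=str)
    test_ids = np.asarray(test_ids, dtype=str)
    if set(labeled_ids) & set(test_ids):
        raise ValueError("labelled training cells overlap the test set")
    id_pos = pd.Series(np.arange(ds.n_cells), index=ds.cell_ids)
    train_pool = np.setdiff1d(ds.cell_ids, test_ids)
    unlabeled_ids = np.setdiff1d(train_pool, labeled_ids)

    pool_ds = ds.subset_cells(id_pos.loc[train_pool].to_numpy())
    emb = fit_embedding(pool_ds, min(n_components,
                                     min(pool_ds.n_cells, pool_ds.n_features)))
    Z = project(pool_ds, emb)
    zpos = pd.Series(np.arange(pool_ds.n_cells), index=pool_ds.cell_ids)

    aug = pseudo_label(
        Z[zpos.loc[labeled_ids].to_numpy()], truth.loc[labeled_ids].to_numpy(),
        Z[zpos.loc[unlabeled_ids].to_numpy()], labeled_ids, unlabeled_ids,
        model_kind=model_kind, top_percent=top_percent, seed=seed,
    )

    X_test = ds.values[id_pos.loc[test_ids].to_numpy()]
    y_test = truth.loc[test_ids].to_numpy()
    records = {}
    for name, (ids, ys) in {
        "baseline": (labeled_ids, truth.loc[labeled_ids].to_numpy()),
        "augmented": (aug.cell_ids, aug.labels),
    }.items():
        X_tr = ds.values[id_pos.loc[ids].to_numpy()]
        clf = train_downstream_rf(X_tr, ys, ds.modality, seed=seed,
                                  param_grid=downstream_grid)
        pred = clf.predict(X_test)
        records[name] = evaluate_predictions(pred, y_test)
    gain = {
        m: getattr(records["augmented"], m) - getattr(records["baseline"], m)
        for m in ("sensitivity", "f1", "mcc", "kappa", "balanced_accuracy")
    }
    return {"baseline": records["baseline"], "augmented": records["augmented"],
            "gain": gain, "augmented_set": aug}
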