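"""Uncertainty-driven active learning for cell-type annotation.

The loop: train a probabilistic classifier on the labelled cells (in a
fixed 20-component PCA space fit once on the whole pool), score every
unlabelled cell by predictive uncertainty — Shannon entropy in bits,

    H(p) = -sum_i p_i log2 p_i,

or the maximum class probability (low = uncertain) — pick a batch of 10 at
a chosen certainty percentile, reveal their ground-truth labels, and repeat
until the label budget is spent.  Selecting at the 95th or 75th percentile
rather than the extreme protects against preferentially querying doublets
or mislabelled cells, which tend to dominate the far tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .core_data import ExpressionDataset, fit_embedding, project, validate_labels
from .initial_selection import SelectionResult

logger = logging.getLogger(__name__)

MODEL_KINDS = ("random_forest", "logistic_regression")
UNCERTAINTY_METRICS = ("entropy", "max_probability")

_ROW_SUM_TOL = 1e-6


@dataclass
class ProbabilityMatrix:
    """Per-cell class-probability vectors over the classes seen in training."""

    probs: np.ndarray
    class_names: list[str]
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.class_names):
            raise ValueError("probability matrix shape mismatch")
        if len(self.cell_ids) != self.probs.shape[0]:
            raise ValueError("cell id length mismatch")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities outside [0, 1]")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _ROW_SUM_TOL):
            raise ValueError("probability rows must sum to 1")
        self.probs = self.probs / sums[:, None]  # exact renormalisation

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class UncertaintyScores:
    """Per-cell uncertainty statistic derived from a ProbabilityMatrix."""

    metric: str
    values: np.ndarray
    n_classes: int
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.metric not in UNCERTAINTY_METRICS:
            raise ValueError(f"unknown uncertainty metric {self.metric!r}")

    def oriented(self) -> np.ndarray:
        """Scores oriented so that larger always means more uncertain."""
        return self.values if self.metric == "entropy" else -self.values


@dataclass
class ALConfig:
    """Knobs of one active-learning run."""

    model_kind: str = "random_forest"
    metric: str = "entropy"
    percentile: float = 100.0   # certainty percentile on the entropy scale
    batch_size: int = 10
    initial_n: int = 20
    budget: int = 100
    n_components: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.metric not in UNCERTAINTY_METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.budget < self.initial_n:
            raise ValueError("budget must be at least the initial set size")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")


def train_uncertainty_model(X: np.ndarray, y, kind: str = "random_forest",
                            seed: int = 0):
    """Fit the probabilistic classifier that drives uncertainty sampling.

    Random forest: 500 trees with square-root feature subsampling.
    Logistic regression: L2-penalised, strength chosen by internal
    stratified 5-fold CV over a small fixed grid (plain C=1 when classes are
    too small to fold).  Trained from scratch on every call.
    """
    y = validate_labels(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to quantify uncertainty")
    if kind == "random_forest":
        model = RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed, n_jobs=1
        )
    elif kind == "logistic_regression":
        folds = int(min(5, counts.min()))
        if folds >= 2:
            model = LogisticRegressionCV(
                Cs=[0.01, 0.1, 1.0, 10.0], penalty="l2", max_iter=2000,
                cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
            )
        else:
            model = LogisticRegression(C=1.0, penalty="l2", max_iter=2000)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(X, y)
    return model


def predict_probabilities(model, X: np.ndarray, cell_ids) -> ProbabilityMatrix:
    return ProbabilityMatrix(
        probs=model.predict_proba(X),
        class_names=[str(c) for c in model.classes_],
        cell_ids=np.asarray(cell_ids, dtype=str),
    )


def entropy(P: ProbabilityMatrix) -> UncertaintyScores:
    """Base-2 Shannon entropy per cell, with 0*log(0) := 0."""
    p = P.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return UncertaintyScores("entropy", -terms.sum(axis=1), P.n_classes,
                             P.cell_ids.copy())


def max_probability(P: ProbabilityMatrix) -> UncertaintyScores:
    """Highest predicted class probability per cell; low = uncertain."""
    return UncertaintyScores("max_probability", P.probs.max(axis=1),
                             P.n_classes, P.cell_ids.copy())


def scaled_entropy(U: UncertaintyScores) -> np.ndarray:
    """Entropy divided by its maximum possible value, log2(n_classes)."""
    if U.metric != "entropy":
        raise ValueError("scaled_entropy expects entropy scores")
    if U.n_classes < 2:
        raise ValueError("scaled entropy undefined for fewer than two classes")
    return U.values / np.log2(U.n_classes)


def select_at_percentile(U: UncertaintyScores, q: float, batch: int,
                         strategy: str | None = None) -> SelectionResult:
    """Select a batch of cells at a certainty percentile.

    Scores are oriented so larger = more uncertain (entropy as-is, maximum
    probability negated); *q* is always stated on that oriented scale, so
    q=100 means the most uncertain cells for either metric.  For q<100 the
    batch sits at the q-th percentile of the oriented distribution and walks
    toward lower values: cells at or below the percentile value, most
    uncertain first.  Ties break by ascending cell id.
    """
    if batch > len(U.cell_ids):
        raise ValueError(f"batch {batch} exceeds pool of {len(U.cell_ids)}")
    oriented = U.oriented()
    # stable order: descending oriented score, ties by ascending cell id
    order = np.lexsort((U.cell_ids, -oriented))
    if q >= 100:
        start = 0
    else:
        v = np.percentile(oriented, q)
        # first position at or below the percentile value
        start = int(np.searchsorted(-oriented[order], -v, side="left"))
    picked = list(order[start:start + batch])
    if len(picked) < batch:  # walk upward past the percentile if exhausted
        deficit = batch - len(picked)
        picked = list(order[start - deficit:start]) + picked
    strategy = strategy or ("al_entropy" if U.metric == "entropy" else "al_maxprob")
    return SelectionResult(U.cell_ids[np.asarray(picked)], strategy,
                           {"percentile": q, "batch": batch, "metric": U.metric})


def active_learning_loop(ds: ExpressionDataset, oracle: pd.Series,
                         cfg: ALConfig, initial: SelectionResult) -> SelectionResult:
    """Run the full uncertainty-sampling loop up to the label budget.

    The embedding is fit once on the whole pool (transductive), so scores
    remain comparable across iterations; the classifier is retrained from
    scratch each round.  Returns the selection with per-cell iteration
    indices and a per-iteration accuracy trace on the remaining unlabelled
    cells.
    """
    missing = set(initial.cell_ids) - set(oracle.index)
    if missing:
        raise ValueError(f"oracle missing initial cells: {sorted(missing)[:5]}")
    if cfg.budget > ds.n_cells:
        raise ValueError("budget exceeds the number of cells in the pool")
    model = fit_embedding(ds, cfg.n_components)
    Z = project(ds, model)
    id_pos = pd.Series(np.arange(ds.n_cells), index=ds.cell_ids)

    selected = list(initial.cell_ids)
    iteration_of = [0] * len(selected)
    history: list[dict] = []
    strategy = "al_entropy" if cfg.metric == "entropy" else "al_maxprob"
    iteration = 0
    while len(selected) < cfg.budget:
        iteration += 1
        labelled_pos = id_pos.loc[selected].to_numpy()
        unlabelled_mask = np.ones(ds.n_cells, dtype=bool)
        unlabelled_mask[labelled_pos] = False
        unlabelled_pos = np.flatnonzero(unlabelled_mask)
        clf = train_uncertainty_model(
            Z[labelled_pos], oracle.loc[selected].to_numpy(),
            cfg.model_kind, seed=cfg.seed,
        )
        P = predict_probabilities(clf, Z[unlabelled_pos],
                                  ds.cell_ids[unlabelled_pos])
        scores = entropy(P) if cfg.metric == "entropy" else max_probability(P)
        batch_n = min(cfg.batch_size, cfg.budget - len(selected))
        batch = select_at_percentile(scores, cfg.percentile, batch_n)
        acc = float(np.mean(
            clf.predict(Z[unlabelled_pos])
            == oracle.loc[ds.cell_ids[unlabelled_pos]].to_numpy()
        ))
        history.append({"iteration": iteration, "n_labelled": len(selected),
                        "unlabelled_accuracy": acc})
        queried = set(batch.cell_ids) - set(oracle.index)
        if queried:
            raise ValueError(f"oracle missing queried cells: {sorted(queried)[:5]}")
        selected.extend(batch.cell_ids)
        iteration_of.extend([iteration] * len(batch.cell_ids))
    return SelectionResult(
        np.asarray(selected, dtype=str), strategy,
        {"model_kind": cfg.model_kind, "metric": cfg.metric,
         "percentile": cfg.percentile, "budget": cfg.budget,
         "batch_size": cfg.batch_size, "seed": cfg.seed},
        iteration_of=np.asarray(iteration_of),
        history=history,
    )


def novel_type_entropy_report(ds: ExpressionDataset, oracle: pd.Series,
                              held_out_type: str, n_copies: int,
                              cfg: ALConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Scaled entropies of unlabelled cells when a type is (almost) unseen.

    Builds a 20-cell initial set containing exactly *n_copies* cells of
    *held_out_type* (the remainder drawn at random from the other types),
    trains the configured model on it, and reports per-cell scaled entropy
    for all remaining cells, grouped by ground-truth type.  Types missing
    from the training set cannot be predicted, so their cells should show
    elevated entropy — the signal that a novel type is present.
    """
    labels = oracle.loc[ds.cell_ids]
    held_pos = np.flatnonzero(labels.to_numpy() == held_out_type)
    if held_pos.size == 0:
        raise ValueError(f"held-out type {held_out_type!r} absent from data")
    if n_copies > held_pos.size:
        raise ValueError("n_copies exceeds the number of held-out-type cells")
    rng = np.random.default_rng(cfg.seed)
    chosen_held = rng.choice(held_pos, size=n_copies, replace=False)
    other_pos = np.flatnonzero(labels.to_numpy() != held_out_type)
    chosen_other = rng.choice(other_pos, size=cfg.initial_n - n_copies,
                              replace=False)
    initial_pos = np.concatenate([chosen_held, chosen_other])

    model = fit_embedding(ds, cfg.n_components)
    Z = project(ds, model)
    clf = train_uncertainty_model(Z[initial_pos],
                                  labels.iloc[initial_pos].to_numpy(),
                                  cfg.model_kind, seed=cfg.seed)
    rest = np.setdiff1d(np.arange(ds.n_cells), initial_pos)
    P = predict_probabilities(clf, Z[rest], ds.cell_ids[rest])
    se = scaled_entropy(entropy(P))
    df = pd.DataFrame({
        "cell_id": ds.cell_ids[rest],
        "true_type": labels.iloc[rest].to_numpy(),
        "scaled_entropy": se,
    })
    medians = df.groupby("true_type")["scaled_entropy"].median()
    return df, medians
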