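"""Benchmarking harness: downstream classifier, metrics, imbalance designs,
cell-type similarity, marker corruption and the strategy-comparison grid.

Every benchmark cell is a (split, strategy, budget) combination: cells are
selected from the training half by one strategy, labelled with ground
truth, used to train the downstream random-forest classifier, and scored on
the held-out test half with five multiclass metrics — macro sensitivity,
macro F1, Matthews correlation coefficient, Cohen's kappa and balanced
accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    balanced_accuracy_score,
    cohen_kappa_score,
    f1_score,
    matthews_corrcoef,
    recall_score,
)
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .active_learning import ALConfig, active_learning_loop
from .adaptive_reweighting import (
    assign_clusters_to_types,
    cluster_cells,
    sample_even_by_cluster,
    sample_even_by_type,
)
from .core_data import (
    RESERVED_LABELS,
    ExpressionDataset,
    MarkerSpec,
    fit_embedding,
    project,
    stratified_split,
    validate_labels,
)
from .initial_selection import (
    score_cells_by_markers,
    select_initial_random,
    select_initial_ranked,
)

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "f1", "mcc", "kappa", "balanced_accuracy")

IMBALANCE_SCHEMES = ("two_type_similar", "two_type_different",
                     "two_type_balanced", "multi_imbalanced", "multi_balanced")


@dataclass
class MetricsRecord:
    """The five evaluation metrics for one benchmark cell."""

    sensitivity: float
    f1: float
    mcc: float
    kappa: float
    balanced_accuracy: float
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in METRIC_NAMES:
            v = getattr(self, m)
            if not np.isfinite(v):
                raise ValueError(f"metric {m} is not finite")
        for m in ("kappa", "mcc"):
            if not -1 - 1e-9 <= getattr(self, m) <= 1 + 1e-9:
                raise ValueError(f"metric {m} outside [-1, 1]")
        for m in ("sensitivity", "f1", "balanced_accuracy"):
            if not -1e-9 <= getattr(self, m) <= 1 + 1e-9:
                raise ValueError(f"metric {m} outside [0, 1]")

    def to_dict(self) -> dict:
        out = {m: getattr(self, m) for m in METRIC_NAMES}
        out.update(self.context)
        return out


@dataclass
class SimilarityMatrix:
    """Symmetric variance-weighted cosine distances between type centroids."""

    distances: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.distances.to_numpy()
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(d), 0, atol=1e-9):
            raise ValueError("similarity matrix diagonal must be zero")
        if d.min() < -1e-9:
            raise ValueError("distances must be nonnegative")

    def closest_pair(self) -> tuple[str, str]:
        return self._extreme_pair(np.argmin)

    def farthest_pair(self) -> tuple[str, str]:
        return self._extreme_pair(np.argmax)

    def _extreme_pair(self, arg) -> tuple[str, str]:
        d = self.distances.to_numpy().copy()
        fill = np.inf if arg is np.argmin else -np.inf
        np.fill_diagonal(d, fill)
        i, j = np.unravel_index(arg(d), d.shape)
        return (self.distances.index[i], self.distances.columns[j])


def evaluate_predictions(pred, truth, context: dict | None = None) -> MetricsRecord:
    """Five multiclass metrics after dropping cells predicted unassigned.

    Macro averaging over the classes present in truth; MCC in the Gorodkin
    multiclass form; balanced accuracy is the mean per-class recall.
    """
    pred = np.asarray(pred, dtype=str)
    truth = validate_labels(truth)
    if len(pred) != len(truth):
        raise ValueError("prediction and truth length mismatch")
    keep = ~np.isin(pred, list(RESERVED_LABELS))
    pred, truth = pred[keep], truth[keep]
    if len(pred) == 0:
        raise ValueError("no cells left after removing unassigned predictions")
    labels = sorted(set(truth))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent classes yield 0, not a warning
        return MetricsRecord(
            sensitivity=float(recall_score(truth, pred, labels=labels,
                                           average="macro", zero_division=0)),
            f1=float(f1_score(truth, pred, labels=labels, average="macro",
                              zero_division=0)),
            mcc=float(matthews_corrcoef(truth, pred)),
            kappa=float(cohen_kappa_score(truth, pred)),
            balanced_accuracy=float(balanced_accuracy_score(truth, pred)),
            context=context or {},
        )


def default_param_grid(modality: str) -> dict:
    """The downstream random-forest search grid."""
    n_pcs = [25, 50] if modality == "rna" else [20, 39]
    return {
        "pca__n_components": n_pcs,
        "rf__max_features": [4, 6, 10],
        "rf__n_estimators": [100, 150],
    }


def train_downstream_rf(X, y, modality: str = "rna", seed: int = 0,
                        param_grid: dict | None = None, cv_folds: int = 5):
    """Grid-searched random-forest cell-type classifier.

    Scales and PCA-transforms the expression values, then fits a random
    forest; hyperparameters chosen by stratified cross-validated macro F1
    and refit on all training cells.  Folds shrink with a warning when a
    class has fewer members than the fold count.
    """
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    y = validate_labels(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to train a classifier")
    grid = dict(param_grid or default_param_grid(modality))
    cap = min(X.shape[0], X.shape[1])
    pcs = sorted({min(p, cap) for p in grid["pca__n_components"]})
    if pcs != sorted(grid["pca__n_components"]):
        logger.warning("PCA components capped to %s for %d x %d data",
                       pcs, *X.shape)
    grid["pca__n_components"] = pcs
    grid["rf__max_features"] = sorted(
        {min(f, min(pcs)) for f in grid["rf__max_features"]}
    )

    folds = int(min(cv_folds, counts.min()))
    if folds < cv_folds:
        warnings.warn(
            f"smallest class has {counts.min()} cells; "
            f"using {max(folds, 2)}-fold CV"
        )
    if folds >= 2:
        cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
    else:
        cv = KFold(2, shuffle=True, random_state=seed)
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("pca", PCA(svd_solver="full", random_state=seed)),
        ("rf", RandomForestClassifier(random_state=seed, n_jobs=1)),
    ])
    search = GridSearchCV(pipe, grid, scoring="f1_macro", cv=cv, refit=True,
                          n_jobs=1, error_score="raise")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    return search


def cell_type_similarity(Z: np.ndarray, variance_explained: np.ndarray,
                         truth) -> SimilarityMatrix:
    """Variance-weighted cosine distance between cell-type centroids.

    s(a, b) = sum_i w_i a_i b_i / (sqrt(sum w_i a_i^2) sqrt(sum w_i b_i^2))
    with w the per-component variance-explained fractions; distance is
    1 - s, clipped into [0, 2] -> reported nonnegative.
    """
    truth = validate_labels(truth, n_cells=Z.shape[0])
    types = sorted(set(truth))
    w = np.asarray(variance_explained, dtype=float)
    if len(w) != Z.shape[1]:
        raise ValueError("variance weights do not match embedding width")
    centroids = np.vstack([Z[truth == t].mean(axis=0) for t in types])
    wc = centroids * np.sqrt(w)
    norms = np.linalg.norm(wc, axis=1)
    if np.any(norms == 0):
        bad = [t for t, n in zip(types, norms) if n == 0]
        raise ValueError(f"zero-norm centroid for types {bad}")
    sim = (wc @ wc.T) / np.outer(norms, norms)
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    return SimilarityMatrix(pd.DataFrame(dist, index=types, columns=types))


def make_imbalanced_subsets(ds: ExpressionDataset, truth: pd.Series,
                            scheme: str, similarity: SimilarityMatrix | None = None,
                            types: tuple | None = None,
                            seed: int = 0) -> tuple[ExpressionDataset, pd.Series]:
    """Construct the artificial (im)balanced benchmark subsets.

    Two-type schemes draw 450/50 (imbalanced) or 250/250 (balanced) cells
    from a chosen pair — the most similar or most distant pair by the
    similarity matrix, unless *types* names the pair explicitly.  Multi-type
    schemes draw 100 from the majority type and 25 from each minority type
    (imbalanced) or 100 from every type (balanced).
    """
    if scheme not in IMBALANCE_SCHEMES:
        raise ValueError(f"unknown imbalance scheme {scheme!r}")
    y = truth.loc[ds.cell_ids]
    rng = np.random.default_rng(seed)

    def draw(t: str, n: int) -> np.ndarray:
        pool = np.flatnonzero(y.to_numpy() == t)
        if len(pool) < n:
            raise ValueError(f"cell type {t!r} has {len(pool)} cells, need {n}")
        return rng.choice(pool, size=n, replace=False)

    if scheme.startswith("two_type"):
        if types is None:
            if similarity is None:
                raise ValueError("need a SimilarityMatrix or an explicit pair")
            types = (similarity.closest_pair() if scheme == "two_type_similar"
                     else similarity.farthest_pair())
        a, b = types
        counts = (250, 250) if scheme == "two_type_balanced" else (450, 50)
        idx = np.concatenate([draw(a, counts[0]), draw(b, counts[1])])
    else:
        all_types, sizes = np.unique(y.to_numpy(), return_counts=True)
        majority = (types[0] if types else all_types[np.argmax(sizes)])
        if scheme == "multi_imbalanced":
            idx = np.concatenate(
                [draw(majority, 100)]
                + [draw(t, 25) for t in all_types if t != majority]
            )
        else:
            idx = np.concatenate([draw(t, 100) for t in all_types])
    idx = np.sort(idx)
    sub = ds.subset_cells(idx)
    return sub, y.iloc[idx]


def corrupt_markers(spec: MarkerSpec, ds: ExpressionDataset,
                    fraction: float = 0.10, seed: int = 0,
                    pool_size: int = 10_000) -> MarkerSpec:
    """Replace a fraction of markers with random highly expressed genes.

    Corrupted markers (pooled over types and directions) are swapped for
    random genes among the *pool_size* most highly expressed, excluding
    every gene already in the marker file; type membership and direction
    are preserved.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    entries = [(t, d, i)
               for t in spec.types
               for d, table in (("positive", spec.positive),
                                ("negative", spec.negative))
               for i in range(len(table[t]))]
    n_replace = int(np.floor(fraction * len(entries) + 0.5))
    totals = np.asarray(ds.values.sum(axis=0)).ravel()
    top = ds.feature_ids[np.argsort(-totals, kind="stable")[:pool_size]]
    candidates = [g for g in top if g not in spec.all_markers()]
    if len(candidates) < n_replace:
        raise ValueError("replacement gene pool exhausted")
    rng = np.random.default_rng(seed)
    hit = rng.choice(len(entries), size=n_replace, replace=False)
    replacements = rng.choice(np.asarray(candidates), size=n_replace,
                              replace=False)
    positive = {t: list(v) for t, v in spec.positive.items()}
    negative = {t: list(v) for t, v in spec.negative.items()}
    for e, g in zip(hit, replacements):
        t, d, i = entries[e]
        (positive if d == "positive" else negative)[t][i] = str(g)
    return MarkerSpec(types=list(spec.types), positive=positive,
                      negative=negative)


# ---------------------------------------------------------------------------
# Benchmark grid
# ---------------------------------------------------------------------------

def _strategy_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def select_cells(ds_train: ExpressionDataset, strategy: str, budget: int,
                 seed: int, markers: MarkerSpec | None = None,
                 al_model: str = "random_forest", al_percentile: float = 100.0,
                 al_initial: str = "random", oracle: pd.Series | None = None,
                 batch_size: int = 10, initial_n: int = 20):
    """Dispatch one selection strategy on a (transformed) training pool."""
    if strategy == "random":
        return select_initial_random(ds_train.cell_ids, budget, seed)
    if strategy == "ranked":
        if markers is None:
            raise ValueError("ranked selection needs a marker specification")
        return select_initial_ranked(score_cells_by_markers(ds_train, markers),
                                     budget)
    if strategy in {"al_entropy", "al_maxprob"}:
        if oracle is None:
            raise ValueError("active learning needs an oracle label vector")
        init_n = min(initial_n, budget)
        if al_initial == "ranked" and markers is not None:
            initial = select_initial_ranked(
                score_cells_by_markers(ds_train, markers), init_n)
        else:
            initial = select_initial_random(ds_train.cell_ids, init_n, seed)
        cfg = ALConfig(
            model_kind=al_model,
            metric="entropy" if strategy == "al_entropy" else "max_probability",
            percentile=al_percentile, batch_size=batch_size,
            initial_n=init_n, budget=budget,
            n_components=min(20, min(ds_train.n_cells, ds_train.n_features)),
            seed=seed,
        )
        return active_learning_loop(ds_train, oracle, cfg, initial)
    if strategy in {"ar_naive", "ar_marker"}:
        n_pcs = min(30, min(ds_train.n_cells, ds_train.n_features))
        emb = fit_embedding(ds_train, n_pcs)
        Z = project(ds_train, emb)
        ca = cluster_cells(Z, resolution=0.8, n_neighbors=20, seed=seed,
                           cell_ids=ds_train.cell_ids)
        if strategy == "ar_naive":
            return sample_even_by_cluster(ca, budget, seed)
        if markers is None:
            raise ValueError("marker-aware reweighting needs markers")
        ctm = assign_clusters_to_types(ds_train, ca, markers)
        return sample_even_by_type(ctm, ca, budget, seed)
    raise ValueError(f"unknown selection strategy {strategy!r}")


def run_benchmark(ds: ExpressionDataset, truth: pd.Series,
                  strategies=("random", "al_entropy"), budgets=(100,),
                  n_splits: int = 10, seed: int = 0,
                  markers: MarkerSpec | None = None,
                  al_model: str = "random_forest", al_percentile: float = 100.0,
                  al_initial: str = "random",
                  downstream_grid: dict | None = None) -> pd.DataFrame:
    """The full selection-strategy comparison grid.

    For each stratified split x strategy x budget: select cells from the
    training half, label them with ground truth, train the downstream
    random forest, and evaluate on the test half.  Returns a tidy table of
    MetricsRecords; identical seeds reproduce it bit for bit.
    """
    if ds.transform_state not in {"lognorm", "arcsinh"}:
        raise ValueError("run_benchmark expects transformed expression data")
    y_all = truth.loc[ds.cell_ids]
    splits = stratified_split(y_all.to_numpy(), 0.5, n_splits, seed)
    rows = []
    for si, (train_idx, test_idx) in enumerate(splits):
        ds_train = ds.subset_cells(train_idx)
        ds_test = ds.subset_cells(test_idx)
        y_test = y_all.iloc[test_idx].to_numpy()
        for sti, strategy in enumerate(strategies):
            for bi, budget in enumerate(budgets):
                run_seed = _strategy_seed(seed, si, sti, bi)
                sel = select_cells(
                    ds_train, strategy, budget, run_seed, markers=markers,
                    al_model=al_model, al_percentile=al_percentile,
                    al_initial=al_initial, oracle=y_all,
                )
                pos = pd.Series(np.arange(ds_train.n_cells),
                                index=ds_train.cell_ids)
                sel_pos = pos.loc[sel.cell_ids].to_numpy()
                clf = train_downstream_rf(
                    ds_train.values[sel_pos],
                    y_all.loc[sel.cell_ids].to_numpy(),
                    ds.modality, seed=run_seed, param_grid=downstream_grid,
                )
                pred = clf.predict(ds_test.to_dense())
                rec = evaluate_predictions(pred, y_test, context={
                    "split": si, "strategy": strategy, "budget": budget,
                    "classifier": "random_forest", "seed": run_seed,
                })
                rows.append(rec.to_dict())
    return pd.DataFrame(rows)


def rank_strategies(results: pd.DataFrame) -> pd.DataFrame:
    """Strategy ranking by median balanced accuracy and sensitivity."""
    agg = (results.groupby("strategy")[["balanced_accuracy", "sensitivity"]]
           .median().sort_values("balanced_accuracy", ascending=False))
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg
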