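"""Seeding the active-learning loop: the first 20 labelled cells.

Two procedures: a uniform random draw, and a marker-ranked draw that cycles
over the cell types in marker-file order and, at each turn, takes the
highest-scoring not-yet-selected cell for the current type.  Ranked
selection is the cheap way to guarantee rare types appear in the initial
training set when markers are informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import ExpressionDataset, MarkerSpec, validate_labels

logger = logging.getLogger(__name__)

STRATEGIES = ("random", "ranked", "al_entropy", "al_maxprob", "ar_naive", "ar_marker")


@dataclass
class MarkerScoreMatrix:
    """Per-cell, per-type mean expression of the type's positive markers."""

    scores: np.ndarray       # cells x types
    cell_ids: np.ndarray
    types: list[str]

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.cell_ids), len(self.types)):
            raise ValueError("score matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("marker scores must be finite")


@dataclass
class SelectionResult:
    """An ordered set of selected cells with provenance.

    Stores cell ids (not positions) so the selection survives subsetting.
    ``iteration_of`` records, for active learning, the loop iteration at
    which each cell was queried (0 for the initial set).
    """

    cell_ids: np.ndarray
    strategy: str
    params: dict = field(default_factory=dict)
    iteration_of: np.ndarray | None = None
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=str)
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("selection contains duplicate cells")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.iteration_of is not None:
            self.iteration_of = np.asarray(self.iteration_of, dtype=int)
            if len(self.iteration_of) != len(self.cell_ids):
                raise ValueError("iteration_of length mismatch")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cell_id": self.cell_ids,
            "strategy": self.strategy,
            "rank": np.arange(len(self.cell_ids)),
        })
        if self.iteration_of is not None:
            df["iteration"] = self.iteration_of
        return df


def score_cells_by_markers(ds: ExpressionDataset, spec: MarkerSpec) -> MarkerScoreMatrix:
    """Score each cell for each type by mean positive-marker expression.

    Computed on the lognorm/arcsinh scale so means are comparable across
    markers.  Markers absent from the data are dropped with a warning; a
    type with none of its markers present is an error.
    """
    if ds.transform_state not in {"lognorm", "arcsinh"}:
        raise ValueError("marker scoring expects lognorm or arcsinh data")
    feat_index = pd.Index(ds.feature_ids)
    X = ds.values
    scores = np.zeros((ds.n_cells, len(spec.types)))
    for j, t in enumerate(spec.types):
        present = [m for m in spec.positive[t] if m in feat_index]
        missing = sorted(set(spec.positive[t]) - set(present))
        if missing:
            logger.warning("markers absent from data for type %r: %s", t, missing)
        if not present:
            raise ValueError(f"no markers of type {t!r} present in the data")
        cols = feat_index.get_indexer(present)
        sub = X[:, cols]
        scores[:, j] = np.asarray(sub.mean(axis=1)).ravel()
    return MarkerScoreMatrix(scores=scores, cell_ids=ds.cell_ids.copy(),
                             types=list(spec.types))


def select_initial_random(cell_ids: Sequence[str], n: int = 20,
                          seed: int = 0) -> SelectionResult:
    """Uniform sample of *n* cells without replacement."""
    pool = np.asarray(cell_ids, dtype=str)
    if n > len(pool):
        raise ValueError(f"requested {n} cells from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n, replace=False)
    return SelectionResult(chosen, "random", {"n": n, "seed": seed})


def select_initial_ranked(scores: MarkerScoreMatrix, n: int = 20) -> SelectionResult:
    """Round-robin over types, best-scoring unselected cell each turn.

    Deterministic: score ties break by lexicographic cell id.  If two types
    share the same best cell the later type takes its runner-up.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if n > len(scores.cell_ids):
        raise ValueError(f"requested {n} cells from {len(scores.cell_ids)}")
    # per-type ranking: descending score, ties by ascending cell id
    orderings = [
        np.lexsort((scores.cell_ids, -scores.scores[:, j]))
        for j in range(len(scores.types))
    ]
    cursors = [0] * len(scores.types)
    taken: set[int] = set()
    chosen: list[int] = []
    t = 0
    while len(chosen) < n:
        order = orderings[t % len(scores.types)]
        c = cursors[t % len(scores.types)]
        while c < len(order) and order[c] in taken:
            c += 1
        cursors[t % len(scores.types)] = c
        if c < len(order):
            taken.add(order[c])
            chosen.append(order[c])
        t += 1
    return SelectionResult(scores.cell_ids[np.asarray(chosen)], "ranked", {"n": n})


def cell_type_coverage(sel: SelectionResult, truth: pd.Series) -> float:
    """Fraction of ground-truth cell types represented in a selection."""
    labels = validate_labels(truth.to_numpy())
    missing = set(sel.cell_ids) - set(truth.index)
    if missing:
        raise ValueError(f"truth missing selected cells: {sorted(missing)[:5]}")
    selected_types = set(truth.loc[sel.cell_ids])
    return len(selected_types) / len(set(labels))
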