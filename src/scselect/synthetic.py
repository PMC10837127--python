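"""Synthetic single-cell data with controllable imbalance and similarity.

Emulates the statistical structure the selection strategies are sensitive
to: K cell types with type-specific over-expressed marker genes, tunable
type proportions down to rare types, and tunable between-type similarity
via shared expression programs.  RNA counts are negative-binomial around
type-specific means (field-standard overdispersion model); CyTOF-like
intensities are nonnegative-truncated Gaussians on the raw scale.

This is a stated world, not a fit to any real dataset: no batch effects,
no doublets, no dropout beyond the zeros the NB produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ExpressionDataset, MarkerSpec


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic dataset.

    ``marker_effect`` is the log2-fold over-expression of a type's markers
    over the baseline mean.  ``similarity_links`` are (type_a, type_b,
    shared_fraction) triples: type_b's mean expression program is blended
    toward type_a's by the shared fraction, so 1.0 makes the two types
    indistinguishable in expectation.
    """

    n_cells: int = 1000
    n_genes: int = 500
    proportions: dict[str, float] = field(
        default_factory=lambda: {f"type{i}": 0.2 for i in range(5)}
    )
    markers_per_type: int = 5
    marker_effect: float = 2.0
    program_genes_per_type: int = 20
    program_effect: float = 1.0
    similarity_links: list[tuple[str, str, float]] = field(default_factory=list)
    modality: str = "rna"
    dispersion: float = 2.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"type proportions sum to {total}, expected 1")
        if self.marker_effect < 0:
            raise ValueError("marker_effect must be nonnegative")
        for a, b, f in self.similarity_links:
            if not 0 <= f <= 1:
                raise ValueError("shared fraction must be in [0, 1]")
            if a not in self.proportions or b not in self.proportions:
                raise ValueError(f"similarity link names unknown type: {(a, b)}")
        need = (self.markers_per_type + self.program_genes_per_type) * len(
            self.proportions
        )
        if need > self.n_genes:
            raise ValueError(
                "not enough genes for the requested markers and programs"
            )

    @property
    def types(self) -> list[str]:
        return list(self.proportions)


def _type_means(cfg: GeneratorConfig, rng: np.random.Generator):
    """Per-type mean expression vectors plus the true marker map."""
    base = 2.0 ** rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                             cfg.n_genes)
    means: dict[str, np.ndarray] = {}
    markers: dict[str, list[int]] = {}
    n_marked = cfg.markers_per_type * len(cfg.types)
    # beyond the named markers, each type over-expresses a broader private
    # program, as real cell types do; drawn from the unmarked genes
    program_pool = rng.permutation(np.arange(n_marked, cfg.n_genes))
    for i, t in enumerate(cfg.types):
        mu = base.copy()
        block = np.arange(i * cfg.markers_per_type, (i + 1) * cfg.markers_per_type)
        mu[block] *= 2.0 ** cfg.marker_effect
        program = program_pool[i * cfg.program_genes_per_type:
                               (i + 1) * cfg.program_genes_per_type]
        mu[program] *= 2.0 ** cfg.program_effect
        means[t] = mu
        markers[t] = block.tolist()
    # blend shared expression programs after markers are planted
    for a, b, f in cfg.similarity_links:
        means[b] = f * means[a] + (1 - f) * means[b]
    return means, markers


def generate(cfg: GeneratorConfig) -> tuple[ExpressionDataset, pd.Series, MarkerSpec]:
    """Draw one dataset; returns (raw dataset, truth labels, true markers).

    Type assignment is multinomial in the configured proportions; fixing
    the seed fixes every byte of the output.
    """
    rng = np.random.default_rng(cfg.seed)
    types = cfg.types
    probs = np.asarray([cfg.proportions[t] for t in types])
    assignment = rng.choice(len(types), size=cfg.n_cells, p=probs)
    means, marker_idx = _type_means(cfg, rng)

    X = np.empty((cfg.n_cells, cfg.n_genes))
    for i, t in enumerate(types):
        cells = np.flatnonzero(assignment == i)
        if cells.size == 0:
            continue
        mu = means[t]
        if cfg.modality == "rna":
            r = cfg.dispersion
            p = r / (r + mu)
            X[cells] = rng.negative_binomial(
                r, p[None, :], size=(cells.size, cfg.n_genes)
            )
        else:
            X[cells] = np.clip(
                rng.normal(mu[None, :], 0.25 * (1 + mu[None, :]),
                           size=(cells.size, cfg.n_genes)),
                0.0, None,
            )
    cell_ids = np.asarray([f"cell{i:05d}" for i in range(cfg.n_cells)])
    prefix = "gene" if cfg.modality == "rna" else "marker"
    feature_ids = np.asarray([f"{prefix}{j:04d}" for j in range(cfg.n_genes)])
    ds = ExpressionDataset(X, cell_ids, feature_ids, cfg.modality)
    truth = pd.Series(np.asarray(types)[assignment], index=cell_ids)
    spec = MarkerSpec(
        types=list(types),
        positive={t: [str(feature_ids[j]) for j in marker_idx[t]]
                  for t in types},
    )
    return ds, truth, spec


def generate_similar_pair(cfg: GeneratorConfig, shared_fraction: float):
    """Two-type dataset whose between-type distance shrinks with sharing.

    Keeps the first two configured types and links them with the given
    shared fraction; centroid distance (variance-weighted cosine) decreases
    monotonically as *shared_fraction* rises and vanishes at 1.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    if len(cfg.types) < 2:
        raise ValueError("need at least two types")
    a, b = cfg.types[0], cfg.types[1]
    from dataclasses import replace

    cfg2 = replace(cfg, similarity_links=[(a, b, shared_fraction)])
    return generate(cfg2)
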