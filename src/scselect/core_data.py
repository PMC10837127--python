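"""Data model, file I/O and preprocessing transforms.

The central container is :class:`ExpressionDataset`, a cells x features
matrix with string identifiers, a modality tag (``rna`` or ``cytof``) and an
explicit transformation state.  Transform states move one way only:
``raw -> lognorm|arcsinh -> scaled``; every downstream module states which
state it expects.

Supported on-disk formats are MatrixMarket triplets with barcode/feature TSV
sidecars (10x layout, genes x cells, transposed on load), dense CSV/TSV
(cells x features, first column holds cell ids) and the community h5ad
container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

MODALITIES = ("rna", "cytof")
TRANSFORM_STATES = ("raw", "lognorm", "arcsinh", "scaled")

#: Label tokens reserved for cells of unknown type; never valid in ground
#: truth used for training.
RESERVED_LABELS = frozenset({"unassigned", "unknown"})

# transform_state transitions are one-way
_ALLOWED_TRANSITIONS = {
    ("raw", "lognorm"),
    ("raw", "arcsinh"),
    ("lognorm", "scaled"),
    ("arcsinh", "scaled"),
}


def _as_str_array(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=str)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    if len(np.unique(arr)) != len(arr):
        dupes = pd.Index(arr)[pd.Index(arr).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return arr


@dataclass
class ExpressionDataset:
    """Cells x features expression matrix with identifiers and provenance.

    ``values`` may be a dense ndarray or a scipy sparse matrix; sparse inputs
    stay sparse through log-normalisation and are densified only by scaling.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    modality: str
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids, "cell ids")
        self.feature_ids = _as_str_array(self.feature_ids, "feature ids")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.transform_state not in TRANSFORM_STATES:
            raise ValueError(f"unknown transform state {self.transform_state!r}")
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
        else:
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features"
            )
        if self.transform_state == "raw":
            mn = self.values.min() if not sp.issparse(self.values) else (
                self.values.data.min() if self.values.nnz else 0.0
            )
            if mn < 0:
                raise ValueError("raw expression values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def subset_cells(self, index: np.ndarray) -> "ExpressionDataset":
        """Positional subset along the cell axis (order preserving)."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[index],
            cell_ids=self.cell_ids[index],
        )

    def with_values(self, values, transform_state: str) -> "ExpressionDataset":
        if (self.transform_state, transform_state) not in _ALLOWED_TRANSITIONS:
            raise ValueError(
                f"illegal transform transition "
                f"{self.transform_state!r} -> {transform_state!r}"
            )
        return replace(self, values=values, transform_state=transform_state)


@dataclass
class MarkerSpec:
    """Ordered map of cell type -> positive (and optional negative) markers.

    Type order is semantic: it fixes the round-robin order of ranked initial
    selection and breaks argmax ties in cluster-to-type assignment.
    """

    types: list[str]
    positive: dict[str, list[str]]
    negative: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.types)) != len(self.types):
            raise ValueError("duplicate cell types in marker specification")
        for t in self.types:
            pos = self.positive.get(t, [])
            if not pos:
                raise ValueError(f"cell type {t!r} has no positive markers")
            neg = self.negative.get(t, [])
            overlap = set(pos) & set(neg)
            if overlap:
                raise ValueError(
                    f"markers {sorted(overlap)} listed both positive and "
                    f"negative for type {t!r}"
                )
        self.negative = {t: list(self.negative.get(t, [])) for t in self.types}
        self.positive = {t: list(self.positive[t]) for t in self.types}

    def all_markers(self) -> set[str]:
        out: set[str] = set()
        for t in self.types:
            out.update(self.positive[t])
            out.update(self.negative[t])
        return out


@dataclass
class EmbeddingModel:
    """Truncated PCA fit on centred, unit-scaled features.

    Zero-variance features get scale 1 so they survive scaling as exact
    zeros.  The loading sign convention (largest-magnitude loading of each
    component is positive) makes the embedding deterministic.
    """

    n_components: int
    loadings: np.ndarray           # features x components
    variance_explained: np.ndarray  # per-component fraction, non-increasing
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.variance_explained) > 1e-12):
            raise ValueError("variance_explained must be non-increasing")
        if self.variance_explained.sum() > 1 + 1e-9:
            raise ValueError("variance_explained must sum to at most 1")


def validate_labels(labels: Sequence[str], n_cells: int | None = None,
                    allow_reserved: bool = False) -> np.ndarray:
    """Validate a per-cell label vector; returns it as a string array."""
    arr = np.asarray(labels, dtype=str)
    if arr.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    if n_cells is not None and len(arr) != n_cells:
        raise ValueError(f"expected {n_cells} labels, got {len(arr)}")
    if not allow_reserved:
        bad = RESERVED_LABELS.intersection(arr.tolist())
        if bad:
            raise ValueError(
                f"reserved label tokens {sorted(bad)} not allowed in ground truth"
            )
    return arr


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    if path.is_dir() or path.suffix == ".mtx":
        return "mtx"
    if path.suffix in {".csv", ".tsv"}:
        return "csv"
    if path.suffix in {".h5ad", ".h5"}:
        return "h5container"
    raise ValueError(f"cannot infer expression format from {path}")


def load_expression(path, format: str | None = None,
                    modality: str = "rna") -> ExpressionDataset:
    """Read an expression matrix as a raw :class:`ExpressionDataset`.

    ``mtx``: *path* is a directory holding ``matrix.mtx`` (genes x cells),
    ``features.tsv`` and ``barcodes.tsv``, or the ``.mtx`` file itself with
    those sidecars next to it.  ``csv``: dense cells x features with a header
    row of feature ids and cell ids in the first column.  ``h5container``:
    community h5ad layout via :mod:`anndata`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    if fmt == "mtx":
        mtx = path / "matrix.mtx" if path.is_dir() else path
        base = mtx.parent
        feat_f, bc_f = base / "features.tsv", base / "barcodes.tsv"
        for f in (mtx, feat_f, bc_f):
            if not f.exists():
                raise FileNotFoundError(f"missing MatrixMarket sidecar {f}")
        try:
            mat = mmread(str(mtx))
        except Exception as exc:  # surface the offending file
            raise ValueError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
        features = pd.read_csv(feat_f, sep="\t", header=None)[0].astype(str)
        barcodes = pd.read_csv(bc_f, sep="\t", header=None)[0].astype(str)
        values = sp.csr_matrix(mat).T  # genes x cells on disk -> cells x genes
        return ExpressionDataset(values, barcodes.to_numpy(),
                                 features.to_numpy(), modality)
    if fmt == "csv":
        sep = "\t" if path.suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionDataset(df.to_numpy(dtype=float),
                                 df.index.astype(str).to_numpy(),
                                 df.columns.astype(str).to_numpy(), modality)
    if fmt == "h5container":
        import anndata as ad

        adata = ad.read_h5ad(path)
        values = adata.X
        return ExpressionDataset(
            values if sp.issparse(values) else np.asarray(values, dtype=float),
            adata.obs_names.astype(str).to_numpy(),
            adata.var_names.astype(str).to_numpy(),
            adata.uns.get("modality", modality),
            adata.uns.get("transform_state", "raw"),
        )
    raise ValueError(f"unknown expression format {fmt!r}")


def write_expression(ds: ExpressionDataset, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        mat = ds.values if sp.issparse(ds.values) else sp.csr_matrix(ds.values)
        mmwrite(str(path / "matrix.mtx"), mat.T.tocoo())
        pd.Series(ds.feature_ids).to_csv(path / "features.tsv", sep="\t",
                                         header=False, index=False)
        pd.Series(ds.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    elif fmt == "csv":
        sep = "\t" if path.suffix == ".tsv" else ","
        pd.DataFrame(ds.to_dense(), index=ds.cell_ids,
                     columns=ds.feature_ids).to_csv(path, sep=sep)
    elif fmt == "h5container":
        import anndata as ad

        adata = ad.AnnData(
            X=ds.values,
            obs=pd.DataFrame(index=pd.Index(ds.cell_ids)),
            var=pd.DataFrame(index=pd.Index(ds.feature_ids)),
        )
        adata.uns["modality"] = ds.modality
        adata.uns["transform_state"] = ds.transform_state
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def load_markers(path, format: str | None = None) -> MarkerSpec:
    """Read a marker table from YAML or long-format CSV.

    YAML: ``type -> {positive: [...], negative: [...]}`` (a bare list is read
    as positive markers).  CSV: columns ``cell_type, marker, direction`` with
    direction in {positive, negative}.  Order of first appearance defines the
    type order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("csv" if path.suffix in {".csv", ".tsv"} else "yaml")

    types: list[str] = []
    positive: dict[str, list[str]] = {}
    negative: dict[str, list[str]] = {}
    if fmt == "yaml":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"marker YAML {path} must map types to markers")
        for t, entry in raw.items():
            t = str(t)
            types.append(t)
            if isinstance(entry, list):
                positive[t] = [str(m) for m in entry]
                negative[t] = []
            elif isinstance(entry, dict):
                positive[t] = [str(m) for m in (entry.get("positive") or [])]
                negative[t] = [str(m) for m in (entry.get("negative") or [])]
            else:
                raise ValueError(f"malformed marker entry for type {t!r}")
    elif fmt == "csv":
        df = pd.read_csv(path)
        required = {"cell_type", "marker", "direction"}
        if not required.issubset(df.columns):
            raise ValueError(f"marker CSV needs columns {sorted(required)}")
        bad = set(df["direction"]) - {"positive", "negative"}
        if bad:
            raise ValueError(f"unknown marker direction values: {sorted(bad)}")
        for _, row in df.iterrows():
            t = str(row["cell_type"])
            if t not in positive:
                types.append(t)
                positive[t], negative[t] = [], []
            (positive if row["direction"] == "positive" else negative)[t].append(
                str(row["marker"])
            )
    else:
        raise ValueError(f"unknown marker format {fmt!r}")
    return MarkerSpec(types=types, positive=positive, negative=negative)


def write_markers(spec: MarkerSpec, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix in {".csv", ".tsv"} else "yaml")
    if fmt == "yaml":
        doc = {
            t: {"positive": spec.positive[t], "negative": spec.negative[t]}
            for t in spec.types
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
    else:
        rows = [
            {"cell_type": t, "marker": m, "direction": d}
            for t in spec.types
            for d, table in (("positive", spec.positive), ("negative", spec.negative))
            for m in table[t]
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def load_labels(path) -> pd.Series:
    """Two-column CSV (cell_id, cell_type) -> Series indexed by cell id."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("label CSV needs cell_id and cell_type columns")
    s = pd.Series(df.iloc[:, 1].astype(str).to_numpy(),
                  index=df.iloc[:, 0].astype(str).to_numpy())
    if s.index.duplicated().any():
        raise ValueError("duplicate cell ids in label file")
    return s


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def lognormalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Library-size normalised log2 counts.

    Per-cell size factor = total counts / mean of totals (so factors average
    to 1); each value becomes log2(count / size_factor + 1).
    """
    if ds.modality != "rna":
        raise ValueError("lognormalize applies to RNA counts only")
    if ds.transform_state != "raw":
        raise ValueError("lognormalize expects raw counts")
    totals = np.asarray(ds.values.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts: {ds.cell_ids[zero][:10].tolist()}"
        )
    sf = totals / totals.mean()
    if sp.issparse(ds.values):
        out = ds.values.tocsr(copy=True).astype(float)
        row_rep = np.repeat(sf, np.diff(out.indptr))
        out.data = np.log2(out.data / row_rep + 1.0)
    else:
        out = np.log2(ds.values / sf[:, None] + 1.0)
    return ds.with_values(out, "lognorm")


def arcsinh_transform(ds: ExpressionDataset, cofactor: float = 5.0) -> ExpressionDataset:
    """arcsinh(value / cofactor), the standard mass-cytometry transform."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if ds.modality != "cytof":
        raise ValueError("arcsinh_transform applies to cytof intensities only")
    if ds.transform_state != "raw":
        raise ValueError("arcsinh_transform expects raw intensities")
    if sp.issparse(ds.values):
        out = ds.values.tocsr(copy=True).astype(float)
        out.data = np.arcsinh(out.data / cofactor)
    else:
        out = np.arcsinh(ds.values / cofactor)
    return ds.with_values(out, "arcsinh")


def _center_scale(X: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (X - center) / scale


def fit_embedding(ds: ExpressionDataset, n_components: int = 20) -> EmbeddingModel:
    """PCA on centred, unit-scaled transformed expression.

    Deterministic: full SVD plus a sign convention making the
    largest-magnitude loading of each component positive.
    """
    if ds.transform_state not in {"lognorm", "arcsinh"}:
        raise ValueError("fit_embedding expects lognorm or arcsinh data")
    n_max = min(ds.n_cells, ds.n_features)
    if not 1 <= n_components <= n_max:
        raise ValueError(f"n_components must be in [1, {n_max}]")
    X = ds.to_dense()
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)  # zero-variance features kept
    Z = _center_scale(X, center, scale)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    loadings = Vt[:n_components].T.copy()
    for j in range(n_components):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    return EmbeddingModel(
        n_components=n_components,
        loadings=loadings,
        variance_explained=ratio[:n_components],
        center=center,
        scale=scale,
    )


def project(ds: ExpressionDataset, model: EmbeddingModel) -> np.ndarray:
    """Project cells into the embedding's component space."""
    if ds.transform_state not in {"lognorm", "arcsinh"}:
        raise ValueError("project expects lognorm or arcsinh data")
    if ds.n_features != model.loadings.shape[0]:
        raise ValueError("feature dimension does not match embedding")
    return _center_scale(ds.to_dense(), model.center, model.scale) @ model.loadings


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def _largest_remainder_counts(sizes: np.ndarray, fraction: float) -> np.ndarray:
    """Per-group train counts hitting the overall fraction within one cell."""
    target = int(np.floor(fraction * sizes.sum() + 0.5))
    quotas = sizes * fraction
    base = np.floor(quotas).astype(int)
    base = np.minimum(base, sizes - 1)  # keep >=1 test cell per group
    base = np.maximum(base, 1)          # and >=1 train cell per group
    deficit = target - base.sum()
    remainders = quotas - np.floor(quotas)
    order = np.lexsort((np.arange(len(sizes)), -remainders))
    counts = base.copy()
    i = 0
    while deficit > 0 and i < len(order):
        g = order[i]
        if counts[g] < sizes[g] - 1:
            counts[g] += 1
            deficit -= 1
        i += 1
    return counts


def stratified_split(labels: Sequence[str], train_fraction: float = 0.5,
                     n_splits: int = 10, seed: int = 0):
    """Replicated stratified train/test splits preserving type proportions.

    Returns a list of ``(train_index, test_index)`` positional arrays, one
    per replicate, reproducible from *seed*.
    """
    y = validate_labels(labels)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    types, counts = np.unique(y, return_counts=True)
    singles = types[counts < 2]
    if singles.size:
        raise ValueError(
            f"cell types with a single cell cannot be split: {singles.tolist()}"
        )
    train_counts = _largest_remainder_counts(counts, train_fraction)
    splits = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_splits):
        rng = np.random.default_rng(child)
        train_idx: list[np.ndarray] = []
        test_idx: list[np.ndarray] = []
        for t, k in zip(types, train_counts):
            pos = np.flatnonzero(y == t)
            perm = rng.permutation(pos)
            train_idx.append(perm[:k])
            test_idx.append(perm[k:])
        splits.append((np.sort(np.concatenate(train_idx)),
                       np.sort(np.concatenate(test_idx))))
    return splits
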