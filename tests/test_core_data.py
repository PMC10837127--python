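import numpy as np
import pandas as pd
import pytest

from scselect import (
    ExpressionDataset,
    MarkerSpec,
    arcsinh_transform,
    fit_embedding,
    load_expression,
    load_markers,
    lognormalize,
    project,
    stratified_split,
    write_expression,
    write_markers,
)


def _toy_ds(values, modality="rna", state="raw"):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        values,
        [f"c{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
        modality,
        state,
    )


class TestExpressionDataset:
    def test_duplicate_cell_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate cell ids"):
            ExpressionDataset(np.ones((2, 2)), ["c1", "c1"], ["g1", "g2"], "rna")

    def test_negative_raw_values_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            _toy_ds([[1, -1]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            ExpressionDataset(np.ones((2, 3)), ["c1", "c2"], ["g1"], "rna")

    def test_transform_transitions_are_one_way(self):
        ds = _toy_ds([[1, 2], [3, 4]])
        logged = lognormalize(ds)
        with pytest.raises(ValueError, match="illegal transform transition"):
            logged.with_values(logged.values, "raw")
        with pytest.raises(ValueError, match="expects raw"):
            lognormalize(logged)


@pytest.mark.parametrize("fmt,name", [("mtx", "matrix"), ("csv", "x.csv"),
                                      ("h5container", "x.h5ad")])
def test_expression_round_trip(tmp_path, small_rna, fmt, name):
    """Write/read identity for every supported on-disk format."""
    ds, _, _ = small_rna
    path = tmp_path / name
    write_expression(ds, path, format=fmt)
    back = load_expression(path, format=fmt)
    np.testing.assert_allclose(back.to_dense(), ds.to_dense())
    assert list(back.cell_ids) == list(ds.cell_ids)
    assert list(back.feature_ids) == list(ds.feature_ids)


def test_csv_duplicate_cell_id_is_validation_error(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text(",g1,g2\nc1,1,2\nc1,3,4\n")
    with pytest.raises(ValueError, match="duplicate cell ids"):
        load_expression(p)


class TestMarkers:
    YAML = "Tcell:\n  positive: [CD3D, CD3E]\nBcell:\n  positive: [CD79A]\n  negative: [CD3D]\n"

    def test_yaml_preserves_type_order(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text(self.YAML)
        spec = load_markers(p)
        assert spec.types == ["Tcell", "Bcell"]
        assert spec.negative["Bcell"] == ["CD3D"]

    def test_csv_yaml_equivalence(self, tmp_path):
        """The two encodings of one marker table load identically."""
        py = tmp_path / "m.yaml"
        py.write_text(self.YAML)
        spec = load_markers(py)
        pc = tmp_path / "m.csv"
        write_markers(spec, pc, format="csv")
        again = load_markers(pc)
        assert again.types == spec.types
        assert again.positive == spec.positive
        assert again.negative == spec.negative

    def test_type_without_positive_markers_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("Tcell:\n  positive: []\n")
        with pytest.raises(ValueError, match="no positive markers"):
            load_markers(p)

    def test_marker_in_both_directions_rejected(self):
        with pytest.raises(ValueError, match="both positive and negative"):
            MarkerSpec(types=["T"], positive={"T": ["CD3D"]},
                       negative={"T": ["CD3D"]})


class TestLognormalize:
    def test_equal_totals_give_unit_size_factors(self):
        ds = _toy_ds([[1, 3], [3, 1]])
        out = lognormalize(ds)
        np.testing.assert_allclose(out.to_dense(), np.log2(ds.to_dense() + 1))

    def test_single_cell_closed_form(self):
        out = lognormalize(_toy_ds([[0, 3]]))
        np.testing.assert_allclose(out.to_dense(), [[0.0, 2.0]])

    def test_matches_direct_formula_oracle(self, small_rna):
        ds, _, _ = small_rna
        X = ds.to_dense()
        sf = X.sum(axis=1) / X.sum(axis=1).mean()
        expected = np.log2(X / sf[:, None] + 1)
        np.testing.assert_allclose(lognormalize(ds).to_dense(), expected)

    def test_zero_count_cell_named_in_error(self):
        with pytest.raises(ValueError, match="c1"):
            lognormalize(_toy_ds([[1, 2], [0, 0]]))

    def test_monotone_and_permutation_equivariant(self, small_rna, rng):
        ds, _, _ = small_rna
        perm = rng.permutation(ds.n_cells)
        out = lognormalize(ds)
        out_perm = lognormalize(ds.subset_cells(perm))
        np.testing.assert_allclose(out_perm.to_dense(),
                                   out.to_dense()[perm])
        # strictly monotone per cell in the raw counts
        row = ds.to_dense()[0]
        t = out.to_dense()[0]
        order = np.argsort(row)
        assert np.all(np.diff(t[order]) >= 0)


class TestArcsinh:
    def test_closed_forms(self, small_cytof):
        ds, _, _ = small_cytof
        out = arcsinh_transform(ds, cofactor=5)
        np.testing.assert_allclose(out.to_dense(),
                                   np.arcsinh(ds.to_dense() / 5))
        assert out.to_dense()[ds.to_dense() == 0].sum() == 0

    def test_value_five_cofactor_five(self):
        ds = _toy_ds([[5.0]], modality="cytof")
        np.testing.assert_allclose(arcsinh_transform(ds, 5).to_dense(),
                                   [[np.arcsinh(1.0)]])

    def test_monotone(self, small_cytof):
        ds, _, _ = small_cytof
        out = arcsinh_transform(ds)
        flat_in = np.sort(ds.to_dense().ravel())
        flat_out = np.sort(out.to_dense().ravel())
        assert np.all(np.diff(np.interp(flat_in, flat_in, flat_out)) >= 0)

    def test_nonpositive_cofactor_rejected(self, small_cytof):
        ds, _, _ = small_cytof
        with pytest.raises(ValueError, match="cofactor"):
            arcsinh_transform(ds, 0.0)


class TestEmbedding:
    def test_variance_explained_non_increasing(self, small_rna_lognorm):
        ds, _, _ = small_rna_lognorm
        model = fit_embedding(ds, 20)
        assert np.all(np.diff(model.variance_explained) <= 1e-12)
        assert model.variance_explained.sum() <= 1 + 1e-9

    def test_rank_two_matrix_recovered_exactly(self):
        rng = np.random.default_rng(0)
        L = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 8))  # rank 2
        ds = ExpressionDataset(L, [f"c{i}" for i in range(30)],
                               [f"g{j}" for j in range(8)], "rna", "lognorm")
        # centering and per-feature scaling keep the rank at most 3
        model = fit_embedding(ds, 3)
        Z = project(ds, model)
        recon = Z @ model.loadings.T * model.scale + model.center
        np.testing.assert_allclose(recon, L, atol=1e-8)

    def test_deterministic_and_cell_order_invariant(self, small_rna_lognorm, rng):
        ds, _, _ = small_rna_lognorm
        m1 = fit_embedding(ds, 10)
        m2 = fit_embedding(ds, 10)
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        perm = rng.permutation(ds.n_cells)
        m3 = fit_embedding(ds.subset_cells(perm), 10)
        np.testing.assert_allclose(np.abs(m3.loadings), np.abs(m1.loadings),
                                   atol=1e-8)
        Z1 = project(ds, m1)
        Z3 = project(ds.subset_cells(perm), m3)
        np.testing.assert_allclose(np.abs(Z3), np.abs(Z1[perm]), atol=1e-6)

    def test_n_components_out_of_range(self, small_rna_lognorm):
        ds, _, _ = small_rna_lognorm
        with pytest.raises(ValueError, match="n_components"):
            fit_embedding(ds, ds.n_features + 1)


class TestStratifiedSplit:
    def test_per_type_counts(self):
        labels = ["A"] * 100 + ["B"] * 10
        (tr, te), = stratified_split(labels, 0.5, n_splits=1, seed=0)
        y = np.asarray(labels)
        assert (y[tr] == "A").sum() == 50
        assert (y[tr] == "B").sum() == 5

    def test_reproducible_from_seed(self):
        labels = ["A"] * 40 + ["B"] * 20
        s1 = stratified_split(labels, 0.5, 3, seed=9)
        s2 = stratified_split(labels, 0.5, 3, seed=9)
        for (a, b), (c, d) in zip(s1, s2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_partition_property(self, small_rna):
        _, truth, _ = small_rna
        for tr, te in stratified_split(truth.to_numpy(), 0.5, 5, seed=2):
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.union1d(tr, te)) == len(truth)

    def test_singleton_type_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            stratified_split(["A", "A", "B"], 0.5)
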