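"""QC filtering, normalization, HVG selection, PCA and kNN graph."""

import numpy as np
import pytest

from scresolve import (
    CountMatrix,
    Embedding,
    QCParams,
    build_neighbor_graph,
    normalize,
    pca_embed,
    qc_filter,
    select_hvg,
)


def counts_from_columns(cols, mito_rows=0):
    """Build a CountMatrix from per-cell count vectors (genes on rows)."""
    values = np.array(cols).T
    n_genes = values.shape[0]
    mask = np.zeros(n_genes, dtype=bool)
    mask[:mito_rows] = True
    return CountMatrix(
        values=values,
        gene_ids=[f"mt-{i}" if i < mito_rows else f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{j}" for j in range(values.shape[1])],
        mito_mask=mask,
    )


def cell(total, mito_frac, n_genes=10, mito_rows=2):
    """A count vector with the requested total and mito fraction."""
    mito = int(round(total * mito_frac))
    rest = total - mito
    vec = np.zeros(n_genes, dtype=int)
    vec[0] = mito
    vec[mito_rows] = rest
    return vec


class TestQCFilter:
    def test_three_cell_fixture_all_rejected(self):
        counts = counts_from_columns(
            [cell(150, 0.02), cell(1200, 0.12), cell(3000, 0.05)], mito_rows=2
        )
        filtered, report = qc_filter(counts)
        assert report.n_cells_kept == 0
        assert filtered.n_cells == 0
        assert list(report.per_cell["reason"]) == ["low_umi", "high_mito", "high_umi"]

    def test_boundary_cell_is_kept(self):
        # bounds are strict ("fewer than", "exceeding"), so 200 UMIs / 10% pass
        counts = counts_from_columns([cell(200, 0.10)], mito_rows=2)
        filtered, report = qc_filter(counts)
        assert report.n_cells_kept == 1
        assert filtered.cell_ids == ["c0"]

    def test_interior_cell_is_kept(self):
        counts = counts_from_columns([cell(1000, 0.0)], mito_rows=2)
        _, report = qc_filter(counts)
        assert report.n_cells_kept == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 60, size=(20, 30))
        counts = CountMatrix(
            values=vals,
            gene_ids=[f"g{i}" for i in range(20)],
            cell_ids=[f"c{j}" for j in range(30)],
            mito_mask=np.zeros(20, dtype=bool),
        )
        once, rep1 = qc_filter(counts)
        twice, rep2 = qc_filter(once)
        assert np.array_equal(once.values, twice.values)
        assert once.cell_ids == twice.cell_ids
        assert rep2.n_cells_kept == rep2.n_cells_in == rep1.n_cells_kept

    def test_report_reasons_partition_the_discarded_set(self):
        rng = np.random.default_rng(1)
        cols = [cell(int(t), f) for t, f in zip(rng.integers(50, 4000, 40), rng.uniform(0, 0.3, 40))]
        counts = counts_from_columns(cols, mito_rows=2)
        _, report = qc_filter(counts)
        tab = report.per_cell
        assert report.n_cells_in == len(tab)
        assert (tab["kept"].sum()) == report.n_cells_kept
        assert ((~tab["kept"]) == (tab["reason"] != "")).all()

    def test_missing_mito_annotation_warns(self):
        counts = CountMatrix(
            values=np.full((3, 2), 100),
            gene_ids=["a", "b", "c"],
            cell_ids=["c0", "c1"],
            mito_mask=np.zeros(3, dtype=bool),
        )
        with pytest.warns(UserWarning, match="mitochondrial"):
            qc_filter(counts)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            QCParams(min_umi=500, max_umi=100)
        with pytest.raises(ValueError):
            QCParams(max_mito_frac=1.5)


class TestNormalize:
    def make(self, cols):
        return counts_from_columns(cols, mito_rows=0)

    def test_single_gene_closed_form(self):
        counts = self.make([[0, 100, 0]])
        norm = normalize(counts, target_sum=10_000)
        assert norm[1, 0] == pytest.approx(np.log1p(10_000))
        assert norm[0, 0] == 0 and norm[2, 0] == 0

    def test_depth_invariance_doubling(self):
        rng = np.random.default_rng(2)
        base = rng.integers(1, 30, size=8)
        norm = normalize(self.make([base, 2 * base]))
        assert np.allclose(norm[:, 0], norm[:, 1])

    def test_zero_count_cell_raises(self):
        with pytest.raises(ValueError):
            normalize(self.make([[0, 0, 0]]))


class TestSelectHVG:
    def test_fewer_candidates_than_requested(self):
        rng = np.random.default_rng(3)
        norm = np.zeros((10, 20))
        norm[[1, 3, 5, 7, 9]] = rng.normal(size=(5, 20))
        idx = select_hvg(norm, n_top=3000)
        assert sorted(idx) == [1, 3, 5, 7, 9]

    def test_argmax_case(self):
        norm = np.vstack([np.linspace(0, 1, 10), np.linspace(0, 10, 10), np.linspace(0, 2, 10)])
        assert list(select_hvg(norm, n_top=1)) == [1]

    def test_tie_prefers_lower_index(self):
        row = np.linspace(0, 1, 10)
        norm = np.vstack([row, row, row * 2])
        assert list(select_hvg(norm, n_top=2)) == [0, 2]
        assert list(select_hvg(norm, n_top=1)) == [2]

    def test_all_constant_raises(self):
        with pytest.raises(ValueError, match="no variable genes"):
            select_hvg(np.ones((5, 8)))


class TestPCA:
    def test_isometry_on_planar_data(self):
        rng = np.random.default_rng(4)
        basis = np.linalg.qr(rng.normal(size=(30, 2)))[0]  # genes x 2
        scores2d = rng.normal(size=(50, 2)) * [5, 2]
        X = (scores2d @ basis.T).T  # genes x cells
        emb = pca_embed(X, [f"c{i}" for i in range(50)], n_pcs=2, seed=0)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(emb.coords), pdist(X.T), atol=1e-8)

    def test_dominant_direction_recovered(self):
        rng = np.random.default_rng(5)
        direction = rng.normal(size=20)
        direction /= np.linalg.norm(direction)
        t = rng.normal(size=100) * 10
        X = (np.outer(t, direction) + rng.normal(size=(100, 20)) * 0.1).T
        emb = pca_embed(X, [f"c{i}" for i in range(100)], n_pcs=1, seed=0)
        # explicit eigen-decomposition oracle
        Xc = X.T - X.T.mean(axis=0)
        w, v = np.linalg.eigh(Xc.T @ Xc)
        proj = Xc @ v[:, -1]
        r = np.corrcoef(emb.coords[:, 0], proj)[0, 1]
        assert abs(r) > 0.99

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 60))
        e1 = pca_embed(X, [f"c{i}" for i in range(60)], n_pcs=5, seed=1)
        e2 = pca_embed(X, [f"c{i}" for i in range(60)], n_pcs=5, seed=1)
        assert np.array_equal(e1.coords, e2.coords)

    def test_too_many_components_raises(self):
        X = np.random.default_rng(7).normal(size=(5, 10))
        with pytest.raises(ValueError, match="maximum"):
            pca_embed(X, [f"c{i}" for i in range(10)], n_pcs=9)


class TestNeighborGraph:
    def edges_set(self, graph):
        return {tuple(e) for e in graph.edges}

    def test_collinear_points_k1(self):
        emb = Embedding(np.array([[0.0], [1.0], [3.0]]), ["a", "b", "c"])
        g = build_neighbor_graph(emb, k_neighbors=1)
        assert (0, 1) in self.edges_set(g)  # middle point linked to nearer endpoint
        assert len(g.edges) >= 2

    def test_duplicated_points_are_mutual_neighbors(self):
        emb = Embedding(np.array([[0.0, 0], [0, 0], [9, 9], [9, 9]]), list("abcd"))
        g = build_neighbor_graph(emb, k_neighbors=1)
        assert (0, 1) in self.edges_set(g)
        assert (2, 3) in self.edges_set(g)

    def test_far_blobs_have_no_cross_edges(self):
        rng = np.random.default_rng(8)
        A = rng.normal(0, 0.5, size=(30, 2))
        B = rng.normal(100, 0.5, size=(30, 2))
        emb = Embedding(np.vstack([A, B]), [f"c{i}" for i in range(60)])
        g = build_neighbor_graph(emb, k_neighbors=5)
        for i, j in g.edges:
            assert (i < 30) == (j < 30)
        # brute-force kNN cross-check
        from scipy.spatial.distance import cdist

        D = cdist(emb.coords, emb.coords)
        np.fill_diagonal(D, np.inf)
        expected = set()
        for i in range(60):
            for j in np.argsort(D[i], kind="stable")[:5]:
                expected.add((min(i, j), max(i, j)))
        assert self.edges_set(g) == expected

    def test_k_too_large_raises(self):
        emb = Embedding(np.zeros((4, 2)), list("abcd"))
        with pytest.raises(ValueError):
            build_neighbor_graph(emb, k_neighbors=4)
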