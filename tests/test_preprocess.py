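"""QC, normalization, regression scaling, HVG, PCA, SNN graph, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.metrics import adjusted_rand_score

from svfcomm import (
    QCThresholds,
    SimulationSpec,
    build_neighbors,
    cluster_graph,
    normalize,
    qc_filter,
    run_pca,
    scale_and_regress,
    select_hvg,
    simulate_counts,
)
from svfcomm.preprocess import EmbeddingMatrix, NeighborGraph

from conftest import make_count_matrix, make_normalized

import igraph
import pandas as pd


# ---------------------------------------------------------------- QC filter
def test_qc_filter_matches_per_cell_oracle():
    """5-cell toy, 2 violators by construction: exactly the 3 compliant kept.

    Thresholds scaled to the toy (min 2, max 5, mito < 0.4); the expected
    set is recomputed by an independent per-cell check.
    """
    # genes: g0..g4, g4 mitochondrial
    counts = np.array(
        [
            [1, 1, 1, 0, 0],   # 3 detected, mito 0      -> keep
            [5, 0, 0, 0, 0],   # 1 detected (== too few) -> drop
            [1, 1, 0, 0, 8],   # mito 0.8                -> drop
            [2, 2, 2, 2, 0],   # 4 detected              -> keep
            [1, 1, 1, 0, 1],   # mito 0.25               -> keep
        ]
    )
    is_mito = np.array([False, False, False, False, True])
    m = make_count_matrix(counts, is_mito=is_mito)
    t = QCThresholds(min_genes=2, max_genes=5, max_mito_frac=0.4)

    expected = []
    for i in range(5):
        row = counts[i]
        det = (row > 0).sum()
        mito = row[is_mito].sum() / row.sum()
        if det > t.min_genes and det < t.max_genes and mito < t.max_mito_frac:
            expected.append(m.barcodes[i])
    out = qc_filter(m, t)
    assert list(out.barcodes) == expected == ["c0", "c3", "c4"]


def test_qc_filter_strict_boundaries():
    """Detected == min, detected == max and mito == threshold are all removed."""
    counts = np.array(
        [
            [1, 1, 0, 0, 0],    # detected == min_genes (2): removed
            [1, 1, 1, 1, 1],    # detected == max_genes (5): removed
            [1, 1, 1, 0, 2],    # mito 2/5 == 0.4 exactly: removed
            [1, 1, 1, 0, 1],    # compliant
        ]
    )
    m = make_count_matrix(counts, is_mito=[False] * 4 + [True])
    out = qc_filter(m, QCThresholds(min_genes=2, max_genes=5, max_mito_frac=0.4))
    assert list(out.barcodes) == ["c3"]


def test_qc_filter_empty_and_idempotent(default_dataset):
    empty = make_count_matrix(np.zeros((0, 3), dtype=int), barcodes=[])
    assert qc_filter(empty).n_cells == 0

    once = qc_filter(default_dataset.counts)
    twice = qc_filter(once)
    assert list(twice.barcodes) == list(once.barcodes)
    assert (twice.counts != once.counts).nnz == 0

    with pytest.warns(UserWarning, match="every cell"):
        out = qc_filter(make_count_matrix([[1, 0, 0]]), QCThresholds(2, 3, 0.5))
    assert out.n_cells == 0


# ------------------------------------------------------------- normalization
def test_normalize_formula():
    m = make_count_matrix([[2, 3, 5]])
    nm = normalize(m, scale_factor=1e6)
    expected = np.log([2e5 + 1, 3e5 + 1, 5e5 + 1])
    np.testing.assert_allclose(nm.dense()[0], expected, rtol=1e-12)


def test_normalize_zero_cell_stays_zero():
    nm = normalize(make_count_matrix([[0, 0, 0], [1, 1, 0]]))
    assert nm.dense()[0].sum() == 0
    assert (nm.dense()[1] > 0).sum() == 2


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    hnp.arrays(np.int64, hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=8),
               elements=st.integers(0, 1000))
)
def test_normalize_expm1_sums_to_scale_factor(counts):
    """Sum of expm1 over each nonzero cell equals the scale factor."""
    nm = normalize(make_count_matrix(counts), scale_factor=1e6)
    sums = np.asarray(nm.linear().sum(axis=1)).ravel()
    nonzero = counts.sum(axis=1) > 0
    np.testing.assert_allclose(sums[nonzero], 1e6, rtol=1e-9)
    assert (sums[~nonzero] == 0).all()


def test_normalize_rejects_negative():
    nm = make_normalized([[0.0]])
    nm_counts = make_count_matrix([[1]])
    nm_counts.counts = nm_counts.counts.astype(float)
    nm_counts.counts.data[:] = -1
    with pytest.raises(ValueError, match="negative"):
        normalize(nm_counts)


# ------------------------------------------------------- regression scaling
def test_scale_and_regress_orthogonality():
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 5, size=(20, 5))
    nm = make_normalized(values)
    cov = rng.uniform(1, 100, size=20)
    scaled = scale_and_regress(nm, cov)
    # residuals orthogonal to covariate and intercept, unit variance
    centered_cov = cov - cov.mean()
    for j in range(5):
        assert abs(scaled[:, j] @ centered_cov) < 1e-8 * np.abs(centered_cov).sum()
        assert abs(scaled[:, j].mean()) < 1e-10
        np.testing.assert_allclose(scaled[:, j].std(), 1.0, rtol=1e-9)


def test_scale_and_regress_constant_covariate_is_zscore():
    rng = np.random.default_rng(1)
    values = rng.uniform(0, 5, size=(10, 3))
    nm = make_normalized(values)
    scaled = scale_and_regress(nm, np.full(10, 7.0))
    expected = (values - values.mean(0)) / values.std(0)
    np.testing.assert_allclose(scaled, expected, atol=1e-10)


def test_scale_and_regress_linear_gene_goes_to_zero():
    cov = np.arange(12, dtype=float)
    values = np.column_stack([3.0 + 2.0 * cov, np.random.default_rng(2).uniform(0, 1, 12)])
    scaled = scale_and_regress(make_normalized(values), cov)
    np.testing.assert_allclose(scaled[:, 0], 0.0, atol=1e-10)


# ------------------------------------------------------------- HVG selection
def test_select_hvg_tie_break_lexicographic():
    """All genes distributionally identical -> lexicographically first n_top."""
    col = np.array([[0.0], [1.0], [2.0], [3.0]])
    values = np.tile(col, (1, 6))
    nm = make_normalized(values, genes=["gB", "gA", "gD", "gC", "gF", "gE"])
    assert list(select_hvg(nm, n_top=3)) == ["gA", "gB", "gC"]


def test_select_hvg_finds_inflated_variance_gene():
    rng = np.random.default_rng(3)
    values = rng.normal(5, 1, size=(200, 30)).clip(min=0)
    values[:, 17] = 5 + (values[:, 17] - 5) * np.sqrt(10)  # 10x variance, same mean
    values = values.clip(min=0)
    nm = make_normalized(values)
    assert "g17" in set(select_hvg(nm, n_top=5))


def test_select_hvg_identity_and_warning():
    nm = make_normalized(np.random.default_rng(4).uniform(0, 2, (10, 5)))
    assert set(select_hvg(nm, n_top=5)) == set(nm.gene_names)
    with pytest.warns(UserWarning, match="returning all genes"):
        assert len(select_hvg(nm, n_top=99)) == 5


# ----------------------------------------------------------------------- PCA
def test_pca_rank1_captures_everything():
    u = np.arange(10, dtype=float)[:, None]
    v = np.array([[1.0, -2.0, 0.5]])
    with pytest.warns(UserWarning, match="rank"):
        emb = run_pca(u @ v, pd.Index([f"c{i}" for i in range(10)]), n_components=2)
    assert emb.explained_variance_ratio[0] > 1 - 1e-10
    assert emb.n_components < 2  # truncated to the actual rank


def test_pca_recovers_block_subspace():
    """Orthogonal two-block toy: leading 2-dim subspace matches construction."""
    rng = np.random.default_rng(5)
    n = 300
    scores_true = rng.normal(0, [5.0, 3.0], size=(n, 2))
    basis = np.zeros((2, 10))
    basis[0, :5] = 1 / np.sqrt(5)
    basis[1, 5:] = 1 / np.sqrt(5)
    X = scores_true @ basis + rng.normal(0, 1e-8, (n, 10))
    emb = run_pca(X, pd.Index([f"c{i}" for i in range(n)]), n_components=2)
    # principal angles between recovered scores and true scores ~ 0
    q1, _ = np.linalg.qr(emb.scores)
    q2, _ = np.linalg.qr(scores_true - scores_true.mean(0))
    sv = np.linalg.svd(q1.T @ q2, compute_uv=False)
    assert np.arccos(np.clip(sv.min(), -1, 1)) < 1e-6
    assert np.all(np.diff(emb.explained_variance_ratio) <= 1e-12)


def test_pca_identical_rows_zero_scores():
    X = np.ones((8, 4))
    with pytest.warns(UserWarning, match="zero variance"):
        emb = run_pca(X, pd.Index([f"c{i}" for i in range(8)]), n_components=2)
    assert np.allclose(emb.scores, 0)


# -------------------------------------------------------------- SNN neighbors
def _embedding(points):
    points = np.asarray(points, dtype=float)
    return EmbeddingMatrix(
        scores=points,
        explained_variance_ratio=np.ones(points.shape[1]) / points.shape[1],
        barcodes=pd.Index([f"c{i}" for i in range(len(points))]),
    )


def test_neighbors_two_blobs_no_cross_edges():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, (40, 3))
    b = rng.normal(100, 1, (40, 3))
    g = build_neighbors(_embedding(np.vstack([a, b])), k=10)
    edges = np.array(g.graph.get_edgelist())
    cross = ((edges < 40).sum(axis=1) == 1).sum()
    assert cross == 0
    assert g.graph.ecount() > 0


def test_neighbors_complete_when_k_is_n_minus_1():
    pts = np.random.default_rng(7).normal(size=(12, 2))
    g = build_neighbors(_embedding(pts), k=11)
    assert g.graph.ecount() == 12 * 11 // 2
    assert np.allclose(g.graph.es["weight"], 1.0)


def test_neighbors_duplicates_deterministic_and_k_validated():
    pts = np.zeros((6, 2))  # all duplicate points: ties broken by index
    g1 = build_neighbors(_embedding(pts), k=3)
    g2 = build_neighbors(_embedding(pts), k=3)
    assert g1.graph.get_edgelist() == g2.graph.get_edgelist()
    with pytest.raises(ValueError):
        build_neighbors(_embedding(pts), k=0)
    with pytest.raises(ValueError):
        build_neighbors(_embedding(pts), k=6)


# ----------------------------------------------------------------- clustering
def _snn_from_igraph(g: igraph.Graph, barcodes) -> NeighborGraph:
    if "weight" not in g.edge_attributes():
        g.es["weight"] = [1.0] * g.ecount()
    return NeighborGraph(graph=g, k=0, barcodes=pd.Index(barcodes))


def test_cluster_two_cliques():
    g = igraph.Graph.Full(8) + igraph.Graph.Full(8)  # disjoint union
    ng = _snn_from_igraph(g, [f"c{i}" for i in range(16)])
    for resolution in (0.1, 0.5, 1.5):
        ca = cluster_graph(ng, resolution=resolution, seed=0)
        assert len(ca.types()) == 2
        # each clique uniformly labeled
        labs = ca.labels.values
        assert len(set(labs[:8])) == 1 and len(set(labs[8:])) == 1


def test_cluster_complete_graph_low_resolution_single_cluster():
    ng = _snn_from_igraph(igraph.Graph.Full(10), [f"c{i}" for i in range(10)])
    ca = cluster_graph(ng, resolution=0.01, seed=0)
    assert len(ca.types()) == 1
    assert ca.types() == ["0"]


def test_cluster_empty_graph_errors():
    ng = _snn_from_igraph(igraph.Graph(), [])
    with pytest.raises(ValueError, match="empty"):
        cluster_graph(ng)


def test_cluster_labels_sorted_by_size():
    g = igraph.Graph.Full(5) + igraph.Graph.Full(9)
    ng = _snn_from_igraph(g, [f"c{i}" for i in range(14)])
    ca = cluster_graph(ng, resolution=0.5, seed=0)
    sizes = ca.sizes()
    assert sizes.loc["0"] == 9 and sizes.loc["1"] == 5


def test_clustering_recovers_planted_types_small():
    """End-to-end preprocessing recovers a 4-type partition (ARI >= 0.9)."""
    spec = SimulationSpec(seed=8, cells_per_type=100, n_genes=400,
                          n_mito_genes=5, markers_per_type=20,
                          qc_violator_fraction=0.0)
    data = simulate_counts(spec)
    nm = normalize(data.counts)
    hvg = select_hvg(nm, n_top=400)
    scaled = scale_and_regress(
        nm.subset_genes(nm.gene_names.get_indexer(hvg)), data.counts.total_counts()
    )
    emb = run_pca(scaled, data.counts.barcodes, n_components=30)
    ca = cluster_graph(build_neighbors(emb, k=20), resolution=1.5, seed=0)
    ari = adjusted_rand_score(data.labels.labels.values, ca.labels.values)
    assert ari >= 0.9
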