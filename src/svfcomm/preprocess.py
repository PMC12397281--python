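"""Seurat-style preprocessing of droplet scRNA-seq counts.

Stages, in pipeline order: strict-inequality QC filtering (detected genes
> 200 and < 6,500, mitochondrial fraction < 40%), log-CPM normalization
with scale factor 1e6, per-gene regression of the total-count covariate
followed by z-scoring, highly-variable-gene selection against a binned
mean-variance trend, PCA (30 components), a shared-nearest-neighbor
graph (Jaccard overlap of k-NN sets, pruned at 1/15), and Leiden
modularity clustering at resolution 1.5. Every threshold is an explicit
argument; defaults reproduce the study settings.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import pairwise_distances

from .containers import ClusterAssignment, CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "qc_filter",
    "normalize",
    "scale_and_regress",
    "select_hvg",
    "EmbeddingMatrix",
    "run_pca",
    "NeighborGraph",
    "build_neighbors",
    "cluster_graph",
]


@dataclasses.dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC cutoffs; all three comparisons are strict inequalities.

    A cell is kept iff detected genes > ``min_genes``, detected genes <
    ``max_genes`` and mitochondrial count fraction < ``max_mito_frac``.
    """

    min_genes: int = 200
    max_genes: int = 6500
    max_mito_frac: float = 0.40

    def __post_init__(self) -> None:
        if not 0 <= self.min_genes < self.max_genes:
            raise ValueError("require 0 <= min_genes < max_genes")
        if not 0 < self.max_mito_frac <= 1:
            raise ValueError("require 0 < max_mito_frac <= 1")


def qc_filter(m: CountMatrix, thresholds: QCThresholds = QCThresholds()) -> CountMatrix:
    """Drop cells failing any QC cutoff; genes and cell order are untouched.

    Removing every cell is legal (a warning, not an error) so that the
    pipeline degrades gracefully on pathological inputs.
    """
    detected = m.detected_genes()
    mito = m.mito_fraction()
    keep = (
        (detected > thresholds.min_genes)
        & (detected < thresholds.max_genes)
        & (mito < thresholds.max_mito_frac)
    )
    if m.n_cells and not keep.any():
        warnings.warn("QC filter removed every cell", stacklevel=2)
    out = m.subset_cells(keep)
    logger.info("QC filter: %d -> %d cells", m.n_cells, out.n_cells)
    return out


def normalize(m: CountMatrix, scale_factor: float = 1e6) -> NormalizedMatrix:
    """Log-CPM normalization: ``ln(count / cell_total * scale_factor + 1)``.

    Cells with zero total count map to all-zero rows. For every other cell
    ``sum(expm1(row)) == scale_factor`` exactly (up to float rounding).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    counts = sp.csr_matrix(m.counts, dtype=np.float64)
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("negative counts")
    totals = np.asarray(counts.sum(axis=1)).ravel()
    inv = np.zeros_like(totals)
    nz = totals > 0
    inv[nz] = scale_factor / totals[nz]
    values = sp.diags(inv) @ counts
    values.data = np.log1p(values.data)
    return NormalizedMatrix(
        values=values,
        barcodes=m.barcodes,
        gene_names=m.gene_names,
        scale_factor=scale_factor,
        is_mito=m.is_mito,
    )


def scale_and_regress(nm: NormalizedMatrix, covariate: np.ndarray) -> np.ndarray:
    """Regress out a per-cell covariate gene-wise, then z-score each gene.

    For each gene, ordinary-least-squares residuals of its normalized
    expression on ``[1, covariate]`` are computed (so residuals are exactly
    orthogonal to the covariate and to the intercept), then divided by
    their standard deviation. Zero-variance genes map to all-zero columns.
    A constant covariate degenerates to plain per-gene centering and
    scaling. Returns a dense cells x genes array.
    """
    covariate = np.asarray(covariate, dtype=float).ravel()
    if covariate.shape[0] != nm.n_cells:
        raise ValueError("covariate length must equal the number of cells")
    X = nm.dense()
    design = np.column_stack([np.ones_like(covariate), covariate])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    sd = resid.std(axis=0, ddof=0)
    out = np.zeros_like(resid)
    ok = sd > 1e-12
    out[:, ok] = resid[:, ok] / sd[ok]
    return out


def select_hvg(nm: NormalizedMatrix, n_top: int = 2000, n_bins: int = 20) -> pd.Index:
    """Top ``n_top`` highly variable genes by trend-standardized variance.

    Genes are binned into ``n_bins`` equal-count bins by mean normalized
    expression; each gene's variance is divided by its bin's mean variance
    (a binned mean-variance trend), and genes are ranked by that
    standardized variance. Ties break lexicographically by gene name, so
    the selection is deterministic. Returns gene names ordered by
    decreasing standardized variance.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > nm.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds {nm.n_genes} genes; returning all genes",
            stacklevel=2,
        )
        n_top = nm.n_genes
    X = nm.values
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)

    stats = pd.DataFrame({"gene": nm.gene_names, "mean": mean, "var": var})
    try:
        stats["bin"] = pd.qcut(stats["mean"], q=min(n_bins, len(stats)), duplicates="drop")
    except ValueError:  # all means identical
        stats["bin"] = 0
    trend = stats.groupby("bin", observed=True)["var"].transform("mean")
    with np.errstate(invalid="ignore", divide="ignore"):
        stats["std_var"] = np.where(trend > 0, stats["var"] / trend, 0.0)
    ranked = stats.sort_values(
        ["std_var", "gene"], ascending=[False, True], kind="mergesort"
    )
    return pd.Index(ranked["gene"].head(n_top).tolist())


@dataclasses.dataclass
class EmbeddingMatrix:
    """PCA scores (cells x components) with explained-variance shares.

    Components are ordered by decreasing explained variance; the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    barcodes: pd.Index

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(
    scaled: np.ndarray,
    barcodes: pd.Index,
    n_components: int = 30,
    seed: int = 0,
) -> EmbeddingMatrix:
    """PCA scores of the scaled (HVG-restricted) matrix.

    Uses a full deterministic SVD. If the matrix rank is below
    ``n_components``, trailing zero-variance components are dropped with a
    warning — except for an entirely constant input, which keeps a single
    all-zero component so downstream stages still receive an embedding.
    """
    scaled = np.asarray(scaled, dtype=float)
    n, p = scaled.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(cells, genes)")
    del seed  # deterministic full SVD; kept for interface stability
    centered = scaled - scaled.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    var = S**2 / max(n - 1, 1)
    total = var.sum()
    if total <= 1e-24:
        warnings.warn("input has zero variance; returning a single zero component",
                      stacklevel=2)
        return EmbeddingMatrix(
            scores=np.zeros((n, 1)),
            explained_variance_ratio=np.zeros(1),
            barcodes=pd.Index(barcodes),
        )
    keep = min(n_components, int((var > 1e-12 * var[0]).sum()))
    if keep < n_components:
        warnings.warn(
            f"matrix rank {keep} < n_components={n_components}; truncating",
            stacklevel=2,
        )
    scores = U[:, :keep] * S[:keep]
    return EmbeddingMatrix(
        scores=scores,
        explained_variance_ratio=var[:keep] / total,
        barcodes=pd.Index(barcodes),
    )


@dataclasses.dataclass
class NeighborGraph:
    """Undirected SNN graph over cells, Jaccard-weighted."""

    graph: igraph.Graph
    k: int
    barcodes: pd.Index


def build_neighbors(
    emb: EmbeddingMatrix,
    k: int = 20,
    prune: float = 1.0 / 15.0,
) -> NeighborGraph:
    """Shared-nearest-neighbor graph from a PCA embedding.

    Each cell's neighborhood is itself plus its ``k`` nearest cells by
    Euclidean distance in the embedding (distance ties broken by ascending
    cell index). Edge weight between two cells is the Jaccard overlap of
    their neighborhoods; edges with weight below ``prune`` are removed.
    With ``k = n - 1`` every neighborhood is the full cell set, so every
    Jaccard weight is 1.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = emb.scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")
    D = pairwise_distances(emb.scores, metric="euclidean")
    np.fill_diagonal(D, -1.0)  # the cell itself always heads its own list
    order = np.argsort(D, axis=1, kind="stable")
    nbhd = order[:, : k + 1]  # self + k nearest, ties by index

    rows = np.repeat(np.arange(n), k + 1)
    member = sp.csr_matrix(
        (np.ones(n * (k + 1)), (rows, nbhd.ravel())), shape=(n, n)
    )
    inter = (member @ member.T).tocoo()
    mask = inter.row < inter.col
    i, j, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jac = shared / (2 * (k + 1) - shared)
    keep = jac >= prune
    edges = list(zip(i[keep].tolist(), j[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges, edge_attrs={"weight": jac[keep].tolist()})
    return NeighborGraph(graph=g, k=k, barcodes=pd.Index(emb.barcodes))


def cluster_graph(
    g: NeighborGraph,
    resolution: float = 1.5,
    seed: int = 0,
) -> ClusterAssignment:
    """Leiden modularity clustering of the SNN graph at a given resolution.

    Uses the RB-configuration (resolution-scaled modularity) quality
    function on the Jaccard edge weights. Cluster labels are "0", "1", ...
    in order of decreasing size (ties by discovery order); the result is
    deterministic given the seed.
    """
    if g.graph.vcount() == 0:
        raise ValueError("cannot cluster an empty graph")
    part = leidenalg.find_partition(
        g.graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if g.graph.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    membership = np.asarray(part.membership)
    sizes = np.bincount(membership)
    rank = {
        old: new
        for new, old in enumerate(sorted(range(len(sizes)), key=lambda c: (-sizes[c], c)))
    }
    labels = pd.Series(
        [str(rank[c]) for c in membership], index=g.barcodes, dtype=object
    )
    return ClusterAssignment(
        labels,
        params={
            "resolution": resolution,
            "k_neighbors": g.k,
            "seed": seed,
            "n_clusters": int(len(sizes)),
        },
    )
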