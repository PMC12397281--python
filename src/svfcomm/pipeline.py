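"""End-to-end pipeline: counts -> QC -> clusters -> communication network.

Stage order mirrors the study's analysis: QC filtering, log-CPM
normalization, then either user-supplied cell-type labels or the full
clustering route (covariate regression + scaling on highly variable genes,
PCA, SNN graph, Leiden), followed by ligand/receptor fold changes, the
weighted communication graph, connection weights, the label-permutation
significance test, and incoming/outgoing strength summaries. The run is
fully deterministic given the seed, and every emitted file is listed with
its checksum in the :class:`RunReport` manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

from . import io as svfio
from .network import (
    ExpressionRule,
    build_communication_graph,
    compute_fold_changes,
    connection_weights,
    node_strengths,
)
from .permutation import PermutationConfig, run_permutation_test
from .preprocess import (
    QCThresholds,
    build_neighbors,
    cluster_graph,
    normalize,
    qc_filter,
    run_pca,
    scale_and_regress,
    select_hvg,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Paths and every tunable parameter of the pipeline.

    Defaults reproduce the study's stated settings: QC 200 / 6,500 / 40%,
    scale factor 1e6, 30 PCs, clustering resolution 1.5, 100,000
    permutations, alpha 0.01.
    """

    counts_path: str  # 10x triplet directory, or a dense TSV file
    lr_path: str
    assoc_path: str
    out_dir: str
    labels_path: str | None = None  # skip clustering when provided
    alias_path: str | None = None

    min_genes: int = 200
    max_genes: int = 6500
    max_mito_frac: float = 0.40
    scale_factor: float = 1e6
    n_hvg: int = 2000
    n_pcs: int = 30
    k_neighbors: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 1.5
    min_frac: float = 0.10
    min_log2fc: float = 0.0
    n_permutations: int = 100_000
    alpha_adj: float = 0.01
    only_significant_strengths: bool = True
    include_self_strengths: bool = False
    seed: int = 0
    log_level: str = "INFO"

    _FLOAT_KEYS = {
        "max_mito_frac", "scale_factor", "snn_prune", "resolution",
        "min_frac", "min_log2fc", "alpha_adj",
    }
    _INT_KEYS = {
        "min_genes", "max_genes", "n_hvg", "n_pcs", "k_neighbors",
        "n_permutations", "seed",
    }
    _BOOL_KEYS = {"only_significant_strengths", "include_self_strengths"}

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Build from a flat key=value file; keyword overrides win."""
        raw = svfio.read_config(path)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        kwargs = {}
        for key, value in raw.items():
            if key in cls._FLOAT_KEYS:
                value = float(value)
            elif key in cls._INT_KEYS:
                value = int(value)
            elif key in cls._BOOL_KEYS and isinstance(value, str):
                value = value.lower() in ("1", "true", "yes")
            kwargs[key] = value
        return cls(**kwargs)

    def validate(self) -> None:
        for name in ("counts_path", "lr_path", "assoc_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for name in ("labels_path", "alias_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        QCThresholds(self.min_genes, self.max_genes, self.max_mito_frac)
        PermutationConfig(
            n_permutations=self.n_permutations, alpha_adj=self.alpha_adj, seed=self.seed
        )
        if self.n_hvg < 1 or self.n_pcs < 1 or self.k_neighbors < 1:
            raise ValueError("n_hvg, n_pcs and k_neighbors must be positive")


@dataclasses.dataclass
class RunReport:
    """What the pipeline did: per-stage sizes, parameters, warnings, outputs."""

    stages: list[dict]
    params: dict
    warnings: list[str]
    manifest: dict[str, str]  # file name -> sha256

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage and write all result tables under ``cfg.out_dir``."""
    cfg.validate()
    logging.getLogger("svfcomm").setLevel(cfg.log_level)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    warnings_log: list[str] = []
    emitted: list[Path] = []

    def stage(name: str, **info):
        entry = {"stage": name, **info}
        stages.append(entry)
        logger.info("stage %s: %s", name, info)

    t0 = time.perf_counter()
    counts_path = Path(cfg.counts_path)
    if counts_path.is_dir():
        cm = svfio.read_counts_10x(counts_path)
    else:
        cm = svfio.read_counts_tsv(counts_path)
    stage("load_counts", cells=cm.n_cells, genes=cm.n_genes,
          elapsed=round(time.perf_counter() - t0, 3))

    thresholds = QCThresholds(cfg.min_genes, cfg.max_genes, cfg.max_mito_frac)
    filtered = qc_filter(cm, thresholds)
    if filtered.n_cells == 0:
        warnings_log.append("QC filter removed every cell")
    stage("qc_filter", cells_in=cm.n_cells, cells_out=filtered.n_cells)

    nm = normalize(filtered, cfg.scale_factor)
    stage("normalize", scale_factor=cfg.scale_factor)

    if cfg.labels_path is not None:
        ca = svfio.read_labels(cfg.labels_path)
        missing = filtered.barcodes.difference(ca.barcodes)
        if len(missing):
            raise ValueError(
                f"labels file lacks {len(missing)} post-QC barcode(s), e.g. {missing[0]!r}"
            )
        ca = ca.subset(filtered.barcodes)
        stage("labels", source="supplied", types=len(ca.types()))
    else:
        hvg = select_hvg(nm, n_top=cfg.n_hvg)
        nm_hvg = nm.subset_genes(nm.gene_names.get_indexer(hvg))
        scaled = scale_and_regress(nm_hvg, filtered.total_counts())
        n_comp = min(cfg.n_pcs, min(scaled.shape) - 1) or 1
        emb = run_pca(scaled, filtered.barcodes, n_components=n_comp, seed=cfg.seed)
        graph = build_neighbors(emb, k=min(cfg.k_neighbors, filtered.n_cells - 1),
                                prune=cfg.snn_prune)
        ca = cluster_graph(graph, resolution=cfg.resolution, seed=cfg.seed)
        stage("cluster", hvg=len(hvg), pcs=emb.n_components,
              clusters=len(ca.types()))
    emitted.append(svfio.write_labels(ca, out_dir / "labels.tsv"))

    lr, assoc = svfio.read_knowledge_tables(cfg.lr_path, cfg.assoc_path, cfg.alias_path)
    stage("knowledge_tables", lr_pairs=len(lr), assoc_rows=len(assoc))

    rule = ExpressionRule(min_frac=cfg.min_frac, min_log2fc=cfg.min_log2fc)
    fct = compute_fold_changes(nm, ca, genes=lr.genes())
    fct_path = out_dir / "fold_changes.tsv"
    fct.to_csv(fct_path, sep="\t", index=False, float_format="%.6g")
    emitted.append(fct_path)

    graph = build_communication_graph(fct, lr, assoc, rule)
    edges_path = out_dir / "graph_edges.tsv"
    graph.to_edge_list().to_csv(edges_path, sep="\t", index=False, float_format="%.6g")
    emitted.append(edges_path)

    ct = connection_weights(graph)
    stage("network", connections=int((ct["weight"] > 0).sum()),
          total_weight=float(ct["weight"].sum()))

    perm_cfg = PermutationConfig(
        n_permutations=cfg.n_permutations, alpha_adj=cfg.alpha_adj, seed=cfg.seed
    )
    res = run_permutation_test(nm, ca, lr, assoc, perm_cfg, rule)
    # the graph route and the permutation engine must agree on observed weights
    merged = ct.merge(res, on=["source_type", "target_type"], suffixes=("", "_perm"))
    if not ((merged["weight"] - merged["weight_perm"]).abs() < 1e-9).all():
        raise AssertionError("graph-route and permutation-engine weights disagree")
    res_path = out_dir / "connections.tsv"
    out_cols = ["source_type", "target_type", "weight", "n_pairs", "is_self",
                "null_mean", "null_sd", "p", "padj", "significant"]
    merged[out_cols].to_csv(res_path, sep="\t", index=False, float_format="%.6g")
    emitted.append(res_path)
    stage("permutation_test", n_permutations=cfg.n_permutations,
          significant=int(merged["significant"].sum()))

    strengths = node_strengths(
        merged,
        only_significant=cfg.only_significant_strengths,
        include_self=cfg.include_self_strengths,
    )
    s_path = out_dir / "strengths.tsv"
    strengths.to_csv(s_path, sep="\t", index=False, float_format="%.6g")
    emitted.append(s_path)
    stage("strengths", incoming_total=float(strengths["incoming"].sum()),
          outgoing_total=float(strengths["outgoing"].sum()))

    manifest = {p.name: _sha256(p) for p in emitted}
    report = RunReport(
        stages=stages,
        params=dataclasses.asdict(cfg),
        warnings=warnings_log,
        manifest=manifest,
    )
    report.to_json(out_dir / "report.json")
    return report
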