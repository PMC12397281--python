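"""Weighted directed ligand-receptor communication networks between cell types.

The model: a 'source' cell type communicates with a 'target' cell type
through a ligand-receptor (LR) pair when the source expresses the ligand
and the target expresses the receptor. Each complete path

    source type --w_sl--> ligand --w_lr--> receptor --w_rt--> target type

is weighted by the product of three edges: the ligand's log2 fold change
in the source type (clamped at 0), the STRING-style association score of
the pair scaled to [0, 1], and the receptor's log2 fold change in the
target type (clamped at 0). The connection weight of an ordered type
pair is the sum of its path weights over all LR pairs; per-type
incoming/outgoing strengths are row and column sums of that table.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .containers import ClusterAssignment, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LRPairTable",
    "AssociationScoreTable",
    "ExpressionRule",
    "FC_EPSILON",
    "compute_fold_changes",
    "is_expressed",
    "CommunicationGraph",
    "build_communication_graph",
    "connection_weights",
    "node_strengths",
]

#: Pseudocount (in CPM units) added to both group means in the fold change;
#: avoids division by zero when a gene drops out of the baseline entirely.
FC_EPSILON = 1.0


class LRPairTable:
    """Curated ligand-receptor pairs, one row per unique (ligand, receptor).

    Duplicate rows are dropped with a logged count; empty gene ids are
    rejected.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"ligand_gene", "receptor_gene"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"LR pair table missing column(s): {sorted(missing)}")
        df = table.loc[:, ["ligand_gene", "receptor_gene"]].astype(str)
        if (df == "").any().any():
            raise ValueError("LR pair table contains empty gene ids")
        n_before = len(df)
        df = df.drop_duplicates(ignore_index=True)
        self.n_duplicates_dropped = n_before - len(df)
        if self.n_duplicates_dropped:
            logger.warning(
                "dropped %d duplicate ligand-receptor row(s)", self.n_duplicates_dropped
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def pairs(self) -> list[tuple[str, str]]:
        return list(self.df.itertuples(index=False, name=None))

    def genes(self) -> list[str]:
        """All genes referenced by the table, ligands then receptors, deduplicated."""
        seen: dict[str, None] = {}
        for lig, rec in self.pairs():
            seen.setdefault(lig, None)
            seen.setdefault(rec, None)
        return list(seen)


class AssociationScoreTable:
    """Symmetric (gene_a, gene_b) -> combined_score lookup, scores in [0, 1000].

    Mirrors the STRING 'combined score' convention; ``score(a, b)`` equals
    ``score(b, a)``. Duplicate unordered pairs keep the maximum score.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"gene_a", "gene_b", "combined_score"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(
                f"association score table missing column(s): {sorted(missing)}"
            )
        scores = pd.to_numeric(table["combined_score"], errors="raise")
        bad = (scores < 0) | (scores > 1000)
        if bad.any():
            raise ValueError(
                f"combined_score outside [0, 1000]: {scores[bad].tolist()[:5]}"
            )
        self._scores: dict[tuple[str, str], int] = {}
        for a, b, s in zip(table["gene_a"], table["gene_b"], scores):
            key = (str(a), str(b)) if str(a) <= str(b) else (str(b), str(a))
            prev = self._scores.get(key)
            self._scores[key] = int(s) if prev is None else max(prev, int(s))
        self.df = pd.DataFrame(
            [(a, b, s) for (a, b), s in sorted(self._scores.items())],
            columns=["gene_a", "gene_b", "combined_score"],
        )

    def __len__(self) -> int:
        return len(self._scores)

    def score(self, a: str, b: str) -> int | None:
        key = (a, b) if a <= b else (b, a)
        return self._scores.get(key)


@dataclasses.dataclass(frozen=True)
class ExpressionRule:
    """When does a cell type 'express' a gene, for edge-existence purposes?

    A gene is expressed in a type iff at least ``min_frac`` of the type's
    cells have a nonzero count (>= rule, boundary counts as expressed) and
    its log2 fold change versus all other cells exceeds ``min_log2fc``
    (strict >).
    """

    min_frac: float = 0.10
    min_log2fc: float = 0.0


def compute_fold_changes(
    nm: NormalizedMatrix,
    ca: ClusterAssignment,
    genes=None,
    eps: float = FC_EPSILON,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-(gene, cell type) expression fold change versus all other cells.

    Means are taken on the linear (CPM) scale, i.e. on ``expm1`` of the
    log-normalized values. The fold change is
    ``fc = (mean_in + eps) / (mean_out + eps)`` with ``eps`` = 1 CPM, and
    ``frac_expressing`` is the fraction of the type's cells with a nonzero
    count. Types with fewer than ``min_cells`` cells are excluded with a
    warning.

    Returns a data frame with columns ``gene``, ``cell_type``, ``mean_in``,
    ``mean_out``, ``fc``, ``log2fc``, ``frac_expressing``.
    """
    if not nm.barcodes.equals(ca.barcodes):
        ca = ca.subset(nm.barcodes)
    if genes is None:
        gene_list = list(nm.gene_names)
    else:
        gene_list = [g for g in genes if g in set(nm.gene_names)]
        missing = [g for g in genes if g not in set(nm.gene_names)]
        if missing:
            logger.warning("%d requested gene(s) absent from matrix", len(missing))
    col = nm.gene_names.get_indexer(gene_list)
    linear = np.asarray(nm.linear()[:, col].todense())
    detected = linear > 0
    codes, types = ca.codes()
    n = nm.n_cells
    rows = []
    total = linear.sum(axis=0)
    for t_idx, t in enumerate(types):
        in_t = codes == t_idx
        n_t = int(in_t.sum())
        if n_t < min_cells:
            logger.warning("cell type %r has %d cells (< %d); excluded", t, n_t, min_cells)
            continue
        mean_in = linear[in_t].mean(axis=0)
        n_out = n - n_t
        mean_out = (
            (total - linear[in_t].sum(axis=0)) / n_out if n_out else np.zeros_like(mean_in)
        )
        fc = (mean_in + eps) / (mean_out + eps)
        frac = detected[in_t].mean(axis=0)
        for j, g in enumerate(gene_list):
            rows.append((g, t, mean_in[j], mean_out[j], fc[j], np.log2(fc[j]), frac[j]))
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "cell_type",
            "mean_in",
            "mean_out",
            "fc",
            "log2fc",
            "frac_expressing",
        ],
    )


def is_expressed(
    fct: pd.DataFrame,
    gene: str,
    cell_type: str,
    min_frac: float = 0.10,
    min_log2fc: float = 0.0,
) -> bool:
    """Apply the expression rule to one (gene, cell type) fold-change row.

    A missing row (gene absent from the table, or its type excluded) is
    treated as not expressed, with a warning.
    """
    row = fct[(fct["gene"] == gene) & (fct["cell_type"] == cell_type)]
    if row.empty:
        logger.warning("no fold-change row for gene %r in type %r", gene, cell_type)
        return False
    r = row.iloc[0]
    return bool(r["frac_expressing"] >= min_frac and r["log2fc"] > min_log2fc)


@dataclasses.dataclass
class CommunicationGraph:
    """Tripartite weighted directed graph: types -> ligands -> receptors -> types.

    ``source_edges``: (source_type, ligand, weight) where weight is the
    clamped log2 fold change of the ligand in the source type.
    ``lr_edges``: (ligand, receptor, weight, combined_score, in_assoc);
    weight is combined_score / 1000, or 0 for pairs absent from the
    association table. ``target_edges``: (receptor, target_type, weight).
    """

    cell_types: list[str]
    source_edges: pd.DataFrame
    lr_edges: pd.DataFrame
    target_edges: pd.DataFrame

    def to_edge_list(self) -> pd.DataFrame:
        """Flat edge-list view (node_type, from, to, weight, provenance)."""
        columns = ["edge_type", "from", "to", "weight", "provenance"]
        parts = []
        s = self.source_edges
        parts.append(
            pd.DataFrame(
                {
                    "edge_type": "source_ligand",
                    "from": s["source_type"],
                    "to": s["ligand"],
                    "weight": s["weight"],
                    "provenance": "log2fc(" + s["ligand"] + "," + s["source_type"] + ")",
                }
            )
        )
        lr = self.lr_edges
        parts.append(
            pd.DataFrame(
                {
                    "edge_type": "ligand_receptor",
                    "from": lr["ligand"],
                    "to": lr["receptor"],
                    "weight": lr["weight"],
                    "provenance": "combined_score=" + lr["combined_score"].astype(str),
                }
            )
        )
        t = self.target_edges
        parts.append(
            pd.DataFrame(
                {
                    "edge_type": "receptor_target",
                    "from": t["receptor"],
                    "to": t["target_type"],
                    "weight": t["weight"],
                    "provenance": "log2fc(" + t["receptor"] + "," + t["target_type"] + ")",
                }
            )
        )
        parts = [p for p in parts if len(p)]
        if not parts:
            return pd.DataFrame(columns=columns)
        return pd.concat(parts, ignore_index=True)


def build_communication_graph(
    fct: pd.DataFrame,
    lr: LRPairTable,
    assoc: AssociationScoreTable,
    rule: ExpressionRule = ExpressionRule(),
) -> CommunicationGraph:
    """Assemble the tripartite communication graph from fold changes and tables.

    A source->ligand edge exists iff the ligand satisfies the expression
    rule in that type; its weight is the log2 fold change clamped at 0
    (only enrichment drives communication). Receptor->target edges are
    analogous. Ligand->receptor edges carry ``combined_score / 1000``;
    pairs missing from the association table get weight 0 (their paths
    contribute nothing) with a logged notice.
    """
    cell_types = sorted(fct["cell_type"].unique())
    idx = fct.set_index(["gene", "cell_type"])

    def expressed_edges(gene: str) -> list[tuple[str, float]]:
        out = []
        for t in cell_types:
            try:
                row = idx.loc[(gene, t)]
            except KeyError:
                continue
            if row["frac_expressing"] >= rule.min_frac and row["log2fc"] > rule.min_log2fc:
                out.append((t, max(float(row["log2fc"]), 0.0)))
        return out

    src_rows, lr_rows, tgt_rows = [], [], []
    seen_lig: set[str] = set()
    seen_rec: set[str] = set()
    for lig, rec in lr.pairs():
        s = assoc.score(lig, rec)
        if s is None:
            logger.info("pair (%s, %s) absent from association table; weight 0", lig, rec)
        lr_rows.append((lig, rec, (s or 0) / 1000.0, s if s is not None else 0, s is not None))
        if lig not in seen_lig:
            seen_lig.add(lig)
            for t, w in expressed_edges(lig):
                src_rows.append((t, lig, w))
        if rec not in seen_rec:
            seen_rec.add(rec)
            for t, w in expressed_edges(rec):
                tgt_rows.append((rec, t, w))

    return CommunicationGraph(
        cell_types=cell_types,
        source_edges=pd.DataFrame(src_rows, columns=["source_type", "ligand", "weight"]),
        lr_edges=pd.DataFrame(
            lr_rows, columns=["ligand", "receptor", "weight", "combined_score", "in_assoc"]
        ),
        target_edges=pd.DataFrame(tgt_rows, columns=["receptor", "target_type", "weight"]),
    )


def connection_weights(g: CommunicationGraph) -> pd.DataFrame:
    """Connection weight per ordered (source type, target type) pair.

    ``weight(s, t)`` sums ``w_sl * w_lr * w_rt`` over every complete
    source->ligand->receptor->target path; ``n_pairs`` counts LR pairs
    with at least one complete path between the two types.
    Self-connections (source == target) are included and flagged. The
    returned frame covers every ordered pair of cell types (zero weight
    where no path exists) and carries the per-path breakdown in
    ``df.attrs['per_pair']``.
    """
    paths = g.lr_edges.merge(
        g.source_edges.rename(columns={"weight": "w_sl"}), on="ligand", how="inner"
    ).merge(
        g.target_edges.rename(columns={"weight": "w_rt"}), on="receptor", how="inner"
    )
    paths = paths.rename(columns={"weight": "w_lr"})
    paths["path_weight"] = paths["w_sl"] * paths["w_lr"] * paths["w_rt"]

    index = pd.MultiIndex.from_product(
        [g.cell_types, g.cell_types], names=["source_type", "target_type"]
    )
    if len(paths):
        grouped = paths.groupby(["source_type", "target_type"]).agg(
            weight=("path_weight", "sum"),
            n_pairs=("ligand", "size"),
        )
        table = grouped.reindex(index, fill_value=0)
    else:
        table = pd.DataFrame({"weight": 0.0, "n_pairs": 0}, index=index)
    table = table.reset_index()
    table["weight"] = table["weight"].astype(float)
    table["n_pairs"] = table["n_pairs"].astype(int)
    table["is_self"] = table["source_type"] == table["target_type"]
    table.attrs["per_pair"] = paths[
        ["ligand", "receptor", "source_type", "target_type", "w_sl", "w_lr", "w_rt", "path_weight"]
    ]
    return table


def node_strengths(
    ct: pd.DataFrame,
    only_significant: bool = False,
    include_self: bool = False,
) -> pd.DataFrame:
    """Incoming and outgoing communication strength per cell type.

    ``outgoing(t)`` sums connection weights with ``t`` as source,
    ``incoming(t)`` those with ``t`` as target, over the selected
    connection set. By construction the incoming total, outgoing total
    and total connection weight all coincide. Self-connections are
    excluded by default.
    """
    sel = ct
    if only_significant:
        if "significant" not in sel.columns:
            raise ValueError(
                "only_significant requires a 'significant' column (run the permutation test)"
            )
        sel = sel[sel["significant"]]
    if not include_self:
        sel = sel[sel["source_type"] != sel["target_type"]]
    types = sorted(set(ct["source_type"]) | set(ct["target_type"]))
    outgoing = sel.groupby("source_type")["weight"].sum().reindex(types, fill_value=0.0)
    incoming = sel.groupby("target_type")["weight"].sum().reindex(types, fill_value=0.0)
    return pd.DataFrame(
        {"cell_type": types, "incoming": incoming.values, "outgoing": outgoing.values}
    )
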