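"""Readers and writers for the on-disk formats the pipeline consumes.

Count matrices travel as 10x-style MatrixMarket triplet directories
(``matrix.mtx`` genes x cells, ``barcodes.tsv``, ``features.tsv``), with a
dense TSV fallback (rows = barcodes, columns = genes). Knowledge tables,
labels, and all result tables are plain TSV. Everything transparently
accepts gzipped files (``.gz`` suffix).

Convention: MatrixMarket coordinates are 1-based on disk per the standard
and 0-based in memory; the 10x orientation (rows = features) is transposed
to the package's cells x genes layout on read.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, ClusterAssignment, mito_flags_from_names
from .network import AssociationScoreTable, LRPairTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts_10x",
    "write_counts_10x",
    "read_counts_tsv",
    "read_labels",
    "write_labels",
    "read_knowledge_tables",
    "read_config",
]


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dir_path}")


def _validate_mtx(path: Path) -> None:
    """Cheap structural check so shortfalls are reported with a line number."""
    with _open_text(path) as fh:
        header = None
        n_entries = 0
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if header is None:
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}: malformed size line at line {line_no}: {line!r}"
                    )
                header = tuple(int(x) for x in parts)
            else:
                n_entries += 1
        if header is None:
            raise ValueError(f"{path}: no MatrixMarket size line found")
        if n_entries != header[2]:
            raise ValueError(
                f"{path}: header declares {header[2]} entries but "
                f"{n_entries} present (last line {line_no})"
            )


def _disambiguate(names: list[str]) -> list[str]:
    """Suffix repeated gene names with .1, .2, ... (first occurrence unchanged)."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_counts_10x(dir_path, mito_genes=None) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet directory into a CountMatrix.

    Gene names come from the second column of ``features.tsv`` (the first
    if only one exists); duplicated names are disambiguated by suffixing.
    Mitochondrial flags follow the ``mt-``/``MT-`` prefix rule unless an
    explicit ``mito_genes`` list is given.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    _validate_mtx(mtx_path)
    with _open_text(mtx_path, "rb" if str(mtx_path).endswith(".gz") else "r") as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat.T)  # 10x stores genes x cells

    with _open_text(_find(dir_path, "barcodes.tsv")) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_text(_find(dir_path, "features.tsv")) as fh:
        feat_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    names = [row[1] if len(row) > 1 else row[0] for row in feat_rows]
    names = _disambiguate(names)

    if mat.shape != (len(barcodes), len(names)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(barcodes)} barcodes "
            f"x {len(names)} features"
        )
    return CountMatrix(
        counts=mat,
        barcodes=pd.Index(barcodes),
        gene_names=pd.Index(names),
        is_mito=mito_flags_from_names(names, mito_genes),
    )


def write_counts_10x(m: CountMatrix, dir_path) -> list[Path]:
    """Write a CountMatrix as a plain-text 10x triplet directory."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    mtx = dir_path / "matrix.mtx"
    scipy.io.mmwrite(str(mtx), sp.coo_matrix(m.counts.T), field="integer")
    bc = dir_path / "barcodes.tsv"
    bc.write_text("".join(f"{b}\n" for b in m.barcodes))
    ft = dir_path / "features.tsv"
    ft.write_text("".join(f"{g}\t{g}\tGene Expression\n" for g in m.gene_names))
    return [mtx, bc, ft]


def read_counts_tsv(path, mito_genes=None) -> CountMatrix:
    """Dense TSV fallback: rows = barcodes, columns = genes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or (counts < 0).any():
        raise ValueError(f"{path}: counts must be non-negative numbers")
    names = _disambiguate([str(c) for c in df.columns])
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=pd.Index(df.index.astype(str)),
        gene_names=pd.Index(names),
        is_mito=mito_flags_from_names(names, mito_genes),
    )


def read_labels(path) -> ClusterAssignment:
    """Two-column TSV (barcode, label), with or without a header line."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    if df.iloc[0, 0] in ("barcode", "cell"):
        df = df.iloc[1:]
    return ClusterAssignment(
        pd.Series(df.iloc[:, 1].values, index=pd.Index(df.iloc[:, 0].values)),
        params={"source": str(path)},
    )


def write_labels(ca: ClusterAssignment, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("barcode\tlabel\n")
        for bc, lab in ca.labels.items():
            fh.write(f"{bc}\t{lab}\n")
    return path


def read_knowledge_tables(
    lr_path,
    assoc_path,
    alias_path=None,
) -> tuple[LRPairTable, AssociationScoreTable]:
    """Read the ligand-receptor pair table and the association-score table.

    The association table accepts either gene symbols directly or, with an
    alias TSV (``protein_id``, ``gene_symbol``), the STRING protein-links
    dialect: protein ids are mapped to symbols and rows with unmapped ids
    are dropped with a logged count. Duplicate LR rows are deduplicated
    with a logged count; scores outside [0, 1000] raise.
    """
    lr_df = pd.read_csv(lr_path, sep="\t", dtype=str)
    lr = LRPairTable(lr_df)

    assoc_df = pd.read_csv(assoc_path, sep="\t")
    missing = {"gene_a", "gene_b", "combined_score"} - set(assoc_df.columns)
    if missing:
        raise ValueError(f"{assoc_path}: missing column(s) {sorted(missing)}")
    if alias_path is not None:
        alias = pd.read_csv(alias_path, sep="\t", dtype=str)
        if not {"protein_id", "gene_symbol"} <= set(alias.columns):
            raise ValueError(f"{alias_path}: need columns protein_id, gene_symbol")
        mapping = dict(zip(alias["protein_id"], alias["gene_symbol"]))
        n_before = len(assoc_df)
        assoc_df["gene_a"] = assoc_df["gene_a"].map(mapping)
        assoc_df["gene_b"] = assoc_df["gene_b"].map(mapping)
        assoc_df = assoc_df.dropna(subset=["gene_a", "gene_b"]).reset_index(drop=True)
        if len(assoc_df) < n_before:
            logger.warning(
                "alias mapping dropped %d unmapped association row(s)",
                n_before - len(assoc_df),
            )
    assoc = AssociationScoreTable(assoc_df)
    return lr, assoc


def read_config(path) -> dict:
    """Flat ``key = value`` configuration file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with _open_text(Path(path)) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{line_no}: expected 'key = value'")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg
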