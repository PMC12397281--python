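"""Synthetic stromal-vascular-fraction (SVF) scRNA-seq data with known truth.

Emulates a droplet experiment on a dissociated adipose stromal fraction:
several cell types, negative-binomial UMI counts with per-cell library-size
variation, a small set of mitochondrial genes, deliberate QC-violating
cells, and — the part the communication pipeline is tested against —
planted ligand-receptor co-expression between chosen source and target
types. Matching ligand-receptor and association-score tables are generated
alongside, so every downstream stage (QC, clustering, network, permutation
test) can be validated against ground truth.

Counts are drawn per gene g and cell i of type t as

    NB(mean = libsize_i * base_g * fold(g, t),  size = nb_dispersion)

in the mean/size parameterization: ``size`` is the inverse dispersion, so
``var = mean + mean**2 / size``. The library-size factor is log-normal
with unit mean and coefficient of variation ``libsize_cv``; the draw stays
a genuine NB count (no post-hoc scaling). ``fold(g, t)`` is 1 except for
per-type marker genes (fold ``marker_fold``) and planted ligand/receptor
genes in their source/target types.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ClusterAssignment, CountMatrix
from .network import AssociationScoreTable, LRPairTable

__all__ = [
    "PlantedSignal",
    "SimulationSpec",
    "SyntheticDataset",
    "InvalidSpecError",
    "simulate_counts",
    "simulate_null_dataset",
    "make_knowledge_tables",
]


class InvalidSpecError(ValueError):
    """A SimulationSpec field is out of range; the message names the field."""


@dataclasses.dataclass(frozen=True)
class PlantedSignal:
    """One ground-truth directed communication signal.

    The ligand gene's mean is multiplied by ``ligand_fold`` in the source
    type and the receptor gene's mean by ``receptor_fold`` in the target
    type; the pair enters the generated knowledge tables with
    ``assoc_score``.
    """

    ligand_gene: str
    receptor_gene: str
    source_type: str
    target_type: str
    ligand_fold: float = 4.0
    receptor_fold: float = 4.0
    assoc_score: int = 900

    def validate(self, gene_names: Sequence[str], type_names: Sequence[str]) -> None:
        if self.ligand_gene == self.receptor_gene:
            raise InvalidSpecError("planted_signals: ligand_gene == receptor_gene")
        for field, value, universe in (
            ("ligand_gene", self.ligand_gene, gene_names),
            ("receptor_gene", self.receptor_gene, gene_names),
            ("source_type", self.source_type, type_names),
            ("target_type", self.target_type, type_names),
        ):
            if value not in universe:
                raise InvalidSpecError(f"planted_signals: unknown {field} {value!r}")
        if self.ligand_fold < 1 or self.receptor_fold < 1:
            raise InvalidSpecError("planted_signals: folds must be >= 1")
        if not 0 <= self.assoc_score <= 1000:
            raise InvalidSpecError("planted_signals: assoc_score outside [0, 1000]")


@dataclasses.dataclass(frozen=True)
class SimulationSpec:
    """Full parameterization of the synthetic SVF generator.

    Defaults describe a modest droplet run: 4 cell types x 250 cells,
    1,200 genes with log-normal baseline means (median ~0.5 counts/cell,
    ~1,000 total counts and ~450 detected genes per cell), 13
    protein-coding mitochondrial genes at ~10% of counts, moderate NB
    overdispersion (size 2), 30% library-size CV, 5% of cells built to
    violate the standard QC filters, and 30 marker genes per type at
    6-fold enrichment so the types are well separated.
    """

    n_cell_types: int = 4
    cells_per_type: int | tuple[int, ...] = 250
    n_genes: int = 1200
    baseline_log_mean: float = float(np.log(0.5))
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 2.0
    libsize_cv: float = 0.3
    n_mito_genes: int = 13
    mito_mean_frac: float = 0.10
    markers_per_type: int = 30
    marker_fold: float = 6.0
    planted_signals: tuple[PlantedSignal, ...] = ()
    qc_violator_fraction: float = 0.05
    seed: int = 0
    # how violators violate: detected-gene count kept / mito:rest count ratio
    violator_keep_genes: int = 50
    violator_mito_ratio: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_signals", tuple(self.planted_signals))
        if isinstance(self.cells_per_type, (int, np.integer)):
            sizes = (int(self.cells_per_type),) * self.n_cell_types
        else:
            sizes = tuple(int(c) for c in self.cells_per_type)
        object.__setattr__(self, "cells_per_type", sizes)
        self.validate()

    def validate(self) -> None:
        if self.n_cell_types < 1:
            raise InvalidSpecError("n_cell_types must be positive")
        if len(self.cells_per_type) != self.n_cell_types:
            raise InvalidSpecError("cells_per_type length must equal n_cell_types")
        if any(c < 1 for c in self.cells_per_type):
            raise InvalidSpecError("cells_per_type entries must be positive")
        if self.n_genes < 1:
            raise InvalidSpecError("n_genes must be positive")
        if self.baseline_log_sd < 0:
            raise InvalidSpecError("baseline_log_sd must be non-negative")
        if self.nb_dispersion <= 0:
            raise InvalidSpecError("nb_dispersion must be positive")
        if self.libsize_cv < 0:
            raise InvalidSpecError("libsize_cv must be non-negative")
        if not 0 <= self.n_mito_genes < self.n_genes:
            raise InvalidSpecError("n_mito_genes must satisfy 0 <= n_mito_genes < n_genes")
        if not 0 <= self.mito_mean_frac < 1:
            raise InvalidSpecError("mito_mean_frac must be in [0, 1)")
        if self.markers_per_type < 0:
            raise InvalidSpecError("markers_per_type must be non-negative")
        if self.marker_fold < 1:
            raise InvalidSpecError("marker_fold must be >= 1")
        if not 0 <= self.qc_violator_fraction < 1:
            raise InvalidSpecError("qc_violator_fraction must be in [0, 1)")
        n_marked = self.markers_per_type * self.n_cell_types + self.n_mito_genes
        if n_marked > self.n_genes:
            raise InvalidSpecError(
                "markers_per_type * n_cell_types + n_mito_genes exceeds n_genes"
            )
        names = self.gene_names()
        types = self.type_names()
        for sig in self.planted_signals:
            sig.validate(names, types)

    # -- deterministic naming -------------------------------------------
    def type_names(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_cell_types)]

    def gene_names(self) -> pd.Index:
        """Mitochondrial genes first (``mt-`` prefix), then nuclear genes."""
        mito = [f"mt-Gene{i:04d}" for i in range(self.n_mito_genes)]
        rest = [f"Gene{i:04d}" for i in range(self.n_mito_genes, self.n_genes)]
        return pd.Index(mito + rest)

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_type))

    # -- flat config serialization --------------------------------------
    def to_config(self) -> dict:
        cfg = dataclasses.asdict(self)
        cfg["cells_per_type"] = ",".join(str(c) for c in self.cells_per_type)
        cfg["planted_signals"] = ";".join(
            f"{s.ligand_gene}:{s.receptor_gene}:{s.source_type}:{s.target_type}"
            f":{s.ligand_fold}:{s.receptor_fold}:{s.assoc_score}"
            for s in self.planted_signals
        )
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "SimulationSpec":
        kwargs = dict(cfg)
        if "cells_per_type" in kwargs and isinstance(kwargs["cells_per_type"], str):
            kwargs["cells_per_type"] = tuple(
                int(c) for c in kwargs["cells_per_type"].split(",")
            )
        raw = kwargs.pop("planted_signals", "")
        signals = []
        if isinstance(raw, str) and raw:
            for chunk in raw.split(";"):
                lg, rg, st, tt, lf, rf, sc = chunk.split(":")
                signals.append(
                    PlantedSignal(lg, rg, st, tt, float(lf), float(rf), int(sc))
                )
        elif raw:
            signals = list(raw)
        field_names = {f.name for f in dataclasses.fields(cls)}
        typed = {}
        for k, v in kwargs.items():
            if k not in field_names:
                raise InvalidSpecError(f"unknown SimulationSpec field {k!r}")
            ftype = {f.name: f.type for f in dataclasses.fields(cls)}[k]
            if isinstance(v, str) and k not in ("cells_per_type",):
                v = float(v) if ("float" in str(ftype)) else int(v)
            typed[k] = v
        return cls(planted_signals=tuple(signals), **typed)


@dataclasses.dataclass
class SyntheticDataset:
    """A simulated experiment plus its ground truth."""

    counts: CountMatrix
    labels: ClusterAssignment  # true cell types, all cells
    qc_violator: np.ndarray  # True where the cell was built to fail QC
    marker_genes: dict[str, list[str]]
    spec: SimulationSpec


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible substreams per generation stage
    return np.random.default_rng([int(spec_seed), int(stream)])


def _base_means(spec: SimulationSpec) -> np.ndarray:
    rng = _rng(spec.seed, 0)
    base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    if spec.n_mito_genes:
        m = spec.n_mito_genes
        nuclear_sum = base[m:].sum()
        target = spec.mito_mean_frac / (1.0 - spec.mito_mean_frac) * nuclear_sum
        base[:m] *= target / base[:m].sum()
    return base


def _marker_assignment(spec: SimulationSpec) -> dict[str, list[str]]:
    """Disjoint marker-gene sets per type, drawn from non-mitochondrial genes."""
    rng = _rng(spec.seed, 1)
    names = spec.gene_names()
    pool = np.arange(spec.n_mito_genes, spec.n_genes)
    chosen = rng.choice(pool, size=spec.markers_per_type * spec.n_cell_types, replace=False)
    out = {}
    for i, t in enumerate(spec.type_names()):
        idx = chosen[i * spec.markers_per_type : (i + 1) * spec.markers_per_type]
        out[t] = [names[j] for j in sorted(idx)]
    return out


def _fold_matrix(spec: SimulationSpec, markers: dict[str, list[str]]) -> np.ndarray:
    names = spec.gene_names()
    gene_idx = {g: j for j, g in enumerate(names)}
    types = spec.type_names()
    fold = np.ones((spec.n_cell_types, spec.n_genes))
    for i, t in enumerate(types):
        for g in markers[t]:
            fold[i, gene_idx[g]] = spec.marker_fold
    for sig in spec.planted_signals:
        fold[types.index(sig.source_type), gene_idx[sig.ligand_gene]] *= sig.ligand_fold
        fold[types.index(sig.target_type), gene_idx[sig.receptor_gene]] *= sig.receptor_fold
    return fold


def simulate_counts(spec: SimulationSpec) -> SyntheticDataset:
    """Draw one synthetic dataset under ``spec``; fully determined by its seed.

    Returns the raw count matrix, the true cell-type assignment for every
    cell, a per-cell flag marking the deliberately QC-violating cells, and
    the marker-gene ground truth.
    """
    spec.validate()
    names = spec.gene_names()
    types = spec.type_names()
    base = _base_means(spec)
    markers = _marker_assignment(spec)
    fold = _fold_matrix(spec, markers)

    n = spec.n_cells
    type_codes = np.repeat(np.arange(spec.n_cell_types), spec.cells_per_type)

    rng = _rng(spec.seed, 2)
    if spec.libsize_cv > 0:
        sigma2 = np.log1p(spec.libsize_cv**2)
        lib = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)
    else:
        lib = np.ones(n)

    mu = lib[:, None] * (fold[type_codes] * base[None, :])
    size = spec.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int64)

    # plant QC violators: half with too few detected genes, half mito-heavy
    violator = np.zeros(n, dtype=bool)
    n_viol = int(round(spec.qc_violator_fraction * n))
    if n_viol:
        viol_idx = rng.choice(n, size=n_viol, replace=False)
        violator[viol_idx] = True
        n_low = (n_viol + 1) // 2
        mito_mask = np.arange(spec.n_genes) < spec.n_mito_genes
        for rank, i in enumerate(viol_idx):
            if rank < n_low:
                nz = np.flatnonzero(counts[i])
                keep = rng.choice(
                    nz, size=min(spec.violator_keep_genes, len(nz)), replace=False
                )
                row = np.zeros(spec.n_genes, dtype=np.int64)
                row[keep] = counts[i, keep]
                counts[i] = row
            else:
                rest = int(counts[i, ~mito_mask].sum())
                target = max(int(np.ceil(spec.violator_mito_ratio * rest)), 100)
                p = base[:spec.n_mito_genes]
                counts[i, : spec.n_mito_genes] = rng.multinomial(target, p / p.sum())

    barcodes = pd.Index([f"C{i:05d}" for i in range(n)])
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=barcodes,
        gene_names=names,
    )
    labels = ClusterAssignment(
        pd.Series([types[c] for c in type_codes], index=barcodes),
        params={"source": "simulation", "seed": spec.seed},
    )
    return SyntheticDataset(cm, labels, violator, markers, spec)


def simulate_null_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Simulate with no type-dependent signal at all.

    Planted signals are removed and marker folds forced to 1, so every
    gene has the same generative law in every type: the cell-type labels
    are exchangeable and downstream connection p-values should be uniform.
    """
    null_spec = dataclasses.replace(spec, planted_signals=(), marker_fold=1.0)
    return simulate_counts(null_spec)


def make_knowledge_tables(
    spec: SimulationSpec,
    n_decoys: int = 8,
    decoy_score: int = 400,
) -> tuple[LRPairTable, AssociationScoreTable]:
    """Ligand-receptor and association-score tables consistent with ``spec``.

    Every planted (ligand, receptor) appears with its planted association
    score. ``n_decoys`` additional pairs are drawn from background genes —
    genes that are neither mitochondrial, nor markers, nor planted — and
    scored ``decoy_score``; under the generator these decoy pairs carry no
    type-dependent signal, so they behave as true negatives.
    """
    spec.validate()
    if not 0 <= decoy_score <= 1000:
        raise InvalidSpecError("decoy_score outside [0, 1000]")
    names = spec.gene_names()
    markers = _marker_assignment(spec)
    excluded = set()
    for genes in markers.values():
        excluded.update(genes)
    for sig in spec.planted_signals:
        excluded.update((sig.ligand_gene, sig.receptor_gene))
    pool = [g for g in names[spec.n_mito_genes :] if g not in excluded]
    if n_decoys and len(pool) < 2 * n_decoys:
        raise InvalidSpecError("n_decoys too large for the available background genes")

    rows = [
        (s.ligand_gene, s.receptor_gene, s.assoc_score) for s in spec.planted_signals
    ]
    rng = _rng(spec.seed, 3)
    if n_decoys:
        picked = rng.choice(len(pool), size=2 * n_decoys, replace=False)
        for k in range(n_decoys):
            rows.append((pool[picked[2 * k]], pool[picked[2 * k + 1]], decoy_score))

    lr = LRPairTable(
        pd.DataFrame(
            [(l, r) for l, r, _ in rows], columns=["ligand_gene", "receptor_gene"]
        )
    )
    assoc = AssociationScoreTable(
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])
    )
    return lr, assoc
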