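"""Count-matrix I/O, quality control, normalization and clustering-lite.

The QC thresholds default to: genes expressed in fewer than 50 cells are
dropped; cells are kept when the number of expressed genes lies in
[500, 6000], mitochondrial content is strictly below 15% and total counts
strictly below 50,000.  "Expressed" means count > 0 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "QCParams",
    "QCReport",
    "NormalizedMatrix",
    "EmbeddingResult",
    "FormatError",
    "load_counts",
    "write_counts",
    "apply_qc",
    "normalize_log",
    "embed_and_cluster",
]


class FormatError(ValueError):
    """Raised when an on-disk matrix or sidecar file is malformed."""


@dataclass
class CountMatrix:
    """Integer gene x cell count matrix with gene and cell metadata.

    Attributes
    ----------
    values
        CSR sparse matrix of shape (n_genes, n_cells), nonnegative integers.
    gene_meta
        DataFrame with columns ``gene_id``, ``chromosome``, ``start`` and
        ``is_mito``; one row per gene, aligned to matrix rows.
    cell_meta
        DataFrame with columns ``barcode``, ``sample_id`` (plus optional
        label columns); one row per cell, aligned to matrix columns.
    """

    values: sp.csr_matrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape[0] != len(self.gene_meta):
            raise FormatError(
                f"gene_meta has {len(self.gene_meta)} rows but matrix has "
                f"{self.values.shape[0]} genes"
            )
        if self.values.shape[1] != len(self.cell_meta):
            raise FormatError(
                f"cell_meta has {len(self.cell_meta)} rows but matrix has "
                f"{self.values.shape[1]} cells"
            )
        dup_g = self.gene_meta["gene_id"][self.gene_meta["gene_id"].duplicated()]
        if len(dup_g):
            raise FormatError(f"duplicate gene ids: {sorted(set(dup_g))[:5]}")
        dup_b = self.cell_meta["barcode"][self.cell_meta["barcode"].duplicated()]
        if len(dup_b):
            raise FormatError(f"duplicate barcodes: {sorted(set(dup_b))[:5]}")
        if (self.values.data < 0).any():
            raise FormatError("negative entries in count matrix")
        if "is_mito" not in self.gene_meta.columns:
            self.gene_meta = self.gene_meta.copy()
            self.gene_meta["is_mito"] = (
                self.gene_meta["gene_id"].astype(str).str.startswith("MT-")
            )
        self.gene_meta = self.gene_meta.reset_index(drop=True)
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_meta["gene_id"].to_numpy()

    @property
    def barcodes(self) -> np.ndarray:
        return self.cell_meta["barcode"].to_numpy()

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        v = self.values
        gm, cm = self.gene_meta, self.cell_meta
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask)
            v = v[gene_mask, :]
            gm = gm.iloc[gene_mask] if gene_mask.dtype != bool else gm.loc[gene_mask]
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask)
            v = v[:, cell_mask]
            cm = cm.iloc[cell_mask] if cell_mask.dtype != bool else cm.loc[cell_mask]
        return CountMatrix(sp.csr_matrix(v), gm.reset_index(drop=True), cm.reset_index(drop=True))


@dataclass
class QCParams:
    min_cells_per_gene: int = 50
    genes_per_cell_range: tuple[int, int] = (500, 6000)
    max_mito_fraction: float = 0.15
    max_total_counts: int = 50_000

    def __post_init__(self) -> None:
        lo, hi = self.genes_per_cell_range
        if not lo < hi:
            raise ValueError("genes_per_cell_range must satisfy low < high")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    """Per-rule removal counts. Cell-rule counts are evaluated on the
    gene-filtered matrix and may overlap (a cell can fail several rules)."""

    genes_removed: int
    cells_failed_gene_range: int
    cells_failed_mito: int
    cells_failed_total_counts: int
    cells_removed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "gene_min_cells",
                    "cell_gene_range",
                    "cell_mito_fraction",
                    "cell_total_counts",
                    "cells_removed_total",
                ],
                "removed": [
                    self.genes_removed,
                    self.cells_failed_gene_range,
                    self.cells_failed_mito,
                    self.cells_failed_total_counts,
                    self.cells_removed,
                ],
            }
        )


@dataclass
class NormalizedMatrix:
    """log1p(library-size-scaled) expression, genes x cells (dense)."""

    values: np.ndarray
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame
    target_sum: float = 10_000.0

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_meta["gene_id"].to_numpy()

    @property
    def barcodes(self) -> np.ndarray:
        return self.cell_meta["barcode"].to_numpy()


@dataclass
class EmbeddingResult:
    hvg_ids: list[str]
    pc_coordinates: np.ndarray  # cells x n_pcs
    cluster_labels: np.ndarray  # per-cell int
    resolution: float


# ---------------------------------------------------------------------------
# I/O


def load_counts(path_matrix, path_features, path_barcodes) -> CountMatrix:
    """Read a MatrixMarket genes x cells matrix with TSV sidecars.

    ``path_features`` is a headerless TSV with columns (gene_id, chromosome,
    start); ``path_barcodes`` one barcode per line.
    """
    try:
        mat = scipy.io.mmread(str(path_matrix))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"cannot parse MatrixMarket file {path_matrix}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            bad = np.flatnonzero(mat.data != np.round(mat.data))[0]
            raise FormatError(
                f"non-integer entry {mat.data[bad]} at matrix position "
                f"({mat.row[bad] + 1}, {mat.col[bad] + 1})"
            )
        mat = mat.astype(np.int64)
    feats = pd.read_csv(
        path_features, sep="\t", header=None, names=["gene_id", "chromosome", "start"]
    )
    bcs = pd.read_csv(path_barcodes, sep="\t", header=None, names=["barcode"])
    if len(feats) != mat.shape[0]:
        raise FormatError(
            f"features file has {len(feats)} lines but matrix declares "
            f"{mat.shape[0]} rows"
        )
    if len(bcs) != mat.shape[1]:
        raise FormatError(
            f"barcodes file has {len(bcs)} lines but matrix declares "
            f"{mat.shape[1]} columns"
        )
    cell_meta = bcs.copy()
    if "sample_id" not in cell_meta:
        cell_meta["sample_id"] = cell_meta["barcode"].astype(str).str.split("-").str[0]
    return CountMatrix(sp.csr_matrix(mat), feats, cell_meta)


def write_counts(m: CountMatrix, outdir, prefix: str = "") -> dict[str, Path]:
    """Write MTX + features.tsv + barcodes.tsv; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "features": outdir / f"{prefix}features.tsv",
        "barcodes": outdir / f"{prefix}barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(m.values), field="integer")
    m.gene_meta[["gene_id", "chromosome", "start"]].to_csv(
        paths["features"], sep="\t", header=False, index=False
    )
    m.cell_meta[["barcode"]].to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    return paths


# ---------------------------------------------------------------------------
# QC and normalization


def _cell_stats(values: sp.csr_matrix, is_mito: np.ndarray):
    csc = values.tocsc()
    n_genes = csc.getnnz(axis=0)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    mito_totals = np.asarray(csc[is_mito, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)
    return n_genes, totals, mito_frac


def apply_qc(m: CountMatrix, p: QCParams | None = None) -> tuple[CountMatrix, QCReport]:
    """Filter genes then cells.

    Gene rule: keep genes expressed (count > 0) in >= ``min_cells_per_gene``
    cells.  Cell rules (conjunction, evaluated on the gene-filtered matrix):
    expressed-gene count within the inclusive range, mito fraction strictly
    below the cap, total counts strictly below the cap.
    """
    p = p or QCParams()
    expressed_cells = m.values.astype(bool).sum(axis=1)
    gene_keep = np.asarray(expressed_cells).ravel() >= p.min_cells_per_gene
    genes_removed = int((~gene_keep).sum())
    m2 = m.subset(gene_mask=np.flatnonzero(gene_keep))

    is_mito = m2.gene_meta["is_mito"].to_numpy(dtype=bool)
    n_genes, totals, mito_frac = _cell_stats(m2.values, is_mito)
    lo, hi = p.genes_per_cell_range
    ok_range = (n_genes >= lo) & (n_genes <= hi)
    ok_mito = mito_frac < p.max_mito_fraction
    ok_total = totals < p.max_total_counts
    keep = ok_range & ok_mito & ok_total
    report = QCReport(
        genes_removed=genes_removed,
        cells_failed_gene_range=int((~ok_range).sum()),
        cells_failed_mito=int((~ok_mito).sum()),
        cells_failed_total_counts=int((~ok_total).sum()),
        cells_removed=int((~keep).sum()),
    )
    if not keep.any():
        warnings.warn("QC removed every cell; returning an empty matrix", stacklevel=2)
    out = m2.subset(cell_mask=np.flatnonzero(keep))
    return out, report


def normalize_log(m: CountMatrix, target_sum: float = 10_000.0) -> NormalizedMatrix:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    All-zero cells stay all-zero.  value = log(1 + count * target_sum / total).
    """
    dense = np.asarray(m.values.todense(), dtype=float)
    totals = dense.sum(axis=0)
    scale = np.where(totals > 0, target_sum / np.maximum(totals, 1e-300), 0.0)
    vals = np.log1p(dense * scale[None, :])
    return NormalizedMatrix(vals, m.gene_meta.copy(), m.cell_meta.copy(), float(target_sum))


# ---------------------------------------------------------------------------
# Dimensionality reduction + clustering


def select_hvgs(nm: NormalizedMatrix, n_hvg: int = 2000) -> list[str]:
    """Dispersion-ranked highly variable genes (var/mean on de-logged values)."""
    x = np.expm1(nm.values)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros(x.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), -np.inf)
    order = np.argsort(-disp, kind="stable")
    return [nm.gene_ids[i] for i in order[: min(n_hvg, len(order))]]


def embed_and_cluster(
    nm: NormalizedMatrix,
    n_hvg: int = 2000,
    n_pcs: int = 40,
    resolution: float = 0.05,
    seed: int = 0,
    n_neighbors: int = 15,
) -> EmbeddingResult:
    """HVG selection, PCA, kNN graph, seeded modularity clustering."""
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    hvg = select_hvgs(nm, n_hvg)
    idx = pd.Index(nm.gene_ids).get_indexer(hvg)
    x = nm.values[idx, :].T  # cells x genes
    max_pcs = min(x.shape[0] - 1, x.shape[1])
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs reduced from {n_pcs} to {max_pcs} (matrix rank limit)", stacklevel=2)
        n_pcs = max_pcs
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(x)
    k = min(n_neighbors, pcs.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, nbr = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(nbr) for j in row if i != j}
    g = igraph.Graph(n=pcs.shape[0], edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership, dtype=int)
    return EmbeddingResult(hvg, pcs, labels, float(resolution))
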