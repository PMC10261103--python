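"""Per-cell ABC/GCB cell-of-origin classification.

Pipeline: restrict to signature genes -> quantile normalization across cells
-> log2(x + 1) -> per-gene z-score across cells -> per-cell mean z over each
gene set.  A cell is ABC when (abc - gcb) > 0.25 and its GCB score < 0.75,
GCB when (abc - gcb) < -0.25 and its ABC score < 0.75, else Unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qcnorm import CountMatrix

__all__ = [
    "COOGeneSets",
    "COOCall",
    "load_gene_sets",
    "quantile_normalize_cells",
    "coo_scores",
    "coo_classify",
]


@dataclass
class COOGeneSets:
    abc_genes: list[str]
    gcb_genes: list[str]

    def __post_init__(self) -> None:
        if not self.abc_genes or not self.gcb_genes:
            raise ValueError("both gene sets must be nonempty")
        common = set(self.abc_genes) & set(self.gcb_genes)
        if common:
            raise ValueError(f"gene sets must be disjoint; shared: {sorted(common)[:5]}")

    def swapped(self) -> "COOGeneSets":
        return COOGeneSets(list(self.gcb_genes), list(self.abc_genes))


@dataclass
class COOCall:
    scores: pd.DataFrame  # barcode, abc_score, gcb_score, combined_score[, label, sample_id]
    sample_dominant: dict = field(default_factory=dict)


def load_gene_sets(path_abc, path_gcb) -> COOGeneSets:
    """Read two-column TSVs (set_name, gene_id); only the gene column is used."""

    def read(p):
        df = pd.read_csv(p, sep="\t", header=None)
        return df.iloc[:, -1].astype(str).tolist()

    return COOGeneSets(read(path_abc), read(path_gcb))


def quantile_normalize_cells(sub: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (cells) of a genes x cells matrix.

    Each cell's values are replaced by the across-cell mean of order
    statistics at its own ranks; tied values receive the average of the
    reference values at the tied positions.
    """
    sub = np.asarray(sub, dtype=float)
    if sub.ndim != 2:
        raise ValueError("expected a 2-D genes x cells matrix")
    n_genes, n_cells = sub.shape
    if n_cells < 2:
        warnings.warn("quantile normalization of a single cell is the identity", stacklevel=2)
        return sub.copy()
    reference = np.sort(sub, axis=0).mean(axis=1)
    out = np.empty_like(sub)
    for c in range(n_cells):
        col = sub[:, c]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n_genes)
        mapped[order] = reference
        # average reference values over runs of tied input values
        sorted_vals = col[order]
        i = 0
        while i < n_genes:
            j = i
            while j + 1 < n_genes and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            if j > i:
                mapped[order[i : j + 1]] = reference[i : j + 1].mean()
            i = j + 1
        out[:, c] = mapped
    return out


def coo_scores(m: CountMatrix, sets: COOGeneSets) -> COOCall:
    """Compute per-cell ABC/GCB/combined scores on malignant cells."""
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells")
    gidx = pd.Index(m.gene_ids)
    genes = list(sets.abc_genes) + list(sets.gcb_genes)
    present = [g for g in genes if g in gidx]
    if not present:
        raise ValueError(f"none of the signature genes are present: {genes[:10]}")
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing[:10]}", stacklevel=2)
    rows = gidx.get_indexer(present)
    sub = np.asarray(m.values[rows, :].todense(), dtype=float)

    qn = quantile_normalize_cells(sub)
    logged = np.log2(qn + 1.0)
    mu = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True) if logged.shape[1] > 1 else np.ones_like(mu)
    z = np.where(sd > 0, (logged - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    sub_index = pd.Index(present)
    abc_rows = sub_index.get_indexer([g for g in sets.abc_genes if g in sub_index])
    gcb_rows = sub_index.get_indexer([g for g in sets.gcb_genes if g in sub_index])
    if len(abc_rows) == 0 or len(gcb_rows) == 0:
        raise ValueError("one of the gene sets has no genes present in the matrix")
    abc = z[abc_rows, :].mean(axis=0)
    gcb = z[gcb_rows, :].mean(axis=0)
    scores = pd.DataFrame(
        {
            "barcode": m.barcodes,
            "abc_score": abc,
            "gcb_score": gcb,
            "combined_score": abc - gcb,
        }
    )
    if "sample_id" in m.cell_meta.columns:
        scores["sample_id"] = m.cell_meta["sample_id"].to_numpy()
    return COOCall(scores)


def coo_classify(
    call: COOCall,
    combined_threshold: float = 0.25,
    guard_threshold: float = 0.75,
) -> COOCall:
    """Attach per-cell labels and per-sample dominant labels."""
    s = call.scores.copy()
    abc = (s["combined_score"] > combined_threshold) & (s["gcb_score"] < guard_threshold)
    gcb = (s["combined_score"] < -combined_threshold) & (s["abc_score"] < guard_threshold)
    s["label"] = np.select([abc, gcb], ["ABC", "GCB"], default="Unclassified")
    dominant = {}
    if "sample_id" in s.columns:
        for sid, grp in s.groupby("sample_id", sort=True):
            dominant[sid] = grp["label"].mode().iloc[0]
    return COOCall(s, dominant)
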