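"""Clonotype assembly from contig tables and clonality statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity.alpha import berger_parker_d

__all__ = [
    "ClonotypeTable",
    "read_contigs",
    "assemble_clonotypes",
    "expansion_fraction",
    "morisita_horn",
    "berger_parker",
]

TCR_CHAINS = {"TRA", "TRB"}
BCR_CHAINS = {"IGH", "IGK", "IGL"}


@dataclass
class ClonotypeTable:
    """Per-cell clonotype assignment plus clone sizes.

    ``cells`` has columns barcode, clone_id (plus any carried-over metadata);
    ``clone_sizes`` maps clone_id -> number of cells.  ``excluded`` lists
    barcodes removed by the multi-chain filter.
    """

    cells: pd.DataFrame
    clone_sizes: pd.Series
    excluded: list[str]

    def group_counts(self, groups: pd.Series) -> pd.DataFrame:
        """Clone x group count matrix from a barcode -> group mapping."""
        df = self.cells.copy()
        df["group"] = groups.reindex(df["barcode"]).to_numpy()
        return df.pivot_table(
            index="clone_id", columns="group", aggfunc="size", fill_value=0
        )


def read_contigs(path) -> pd.DataFrame:
    """Read a 10x ``filtered_contig_annotations.csv``-dialect table or an
    AIRR rearrangement TSV (cell_id/locus/junction columns)."""
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz")) else ","
    df = pd.read_csv(path, sep=sep)
    if "cell_id" in df.columns and "barcode" not in df.columns:  # AIRR dialect
        df = df.rename(columns={"cell_id": "barcode", "locus": "chain", "junction": "cdr3_nt"})
    required = {"barcode", "chain", "cdr3_nt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contig table lacks required columns: {sorted(missing)}")
    for col, truthy in (("is_cell", "true"), ("high_confidence", "true")):
        if col in df.columns:
            df = df[df[col].astype(str).str.lower().isin([truthy, "1"])]
    return df.reset_index(drop=True)


def assemble_clonotypes(contigs: pd.DataFrame, receptor: str = "TCR") -> ClonotypeTable:
    """Collapse contigs to clonotypes keyed on CDR3 nucleotide sequences.

    Cells with more than one contig of the same chain locus are excluded
    (doublet/multiplet guard); surviving cells are keyed on the sorted set of
    (chain, cdr3_nt) pairs.
    """
    allowed = TCR_CHAINS if receptor.upper() == "TCR" else BCR_CHAINS
    unknown = set(contigs["chain"].unique()) - allowed
    if unknown:
        raise ValueError(f"unknown chain labels for {receptor}: {sorted(unknown)}")
    per_chain = contigs.groupby(["barcode", "chain"]).size()
    bad = per_chain[per_chain > 1].index.get_level_values("barcode").unique().tolist()
    kept = contigs[~contigs["barcode"].isin(bad)]

    keys = (
        kept.sort_values(["barcode", "chain", "cdr3_nt"])
        .groupby("barcode")[["chain", "cdr3_nt"]]
        .apply(lambda g: "|".join(f"{c}:{s}" for c, s in zip(g["chain"], g["cdr3_nt"])))
    )
    clone_ids, uniques = pd.factorize(keys, sort=True)
    cells = pd.DataFrame({"barcode": keys.index, "clone_id": clone_ids})
    sizes = cells.groupby("clone_id").size().rename("clone_size")
    return ClonotypeTable(cells.reset_index(drop=True), sizes, sorted(bad))


def expansion_fraction(
    t: ClonotypeTable, groups: pd.Series | None = None, min_clone: int = 11
) -> pd.Series:
    """Fraction of cells belonging to clones of size >= ``min_clone``
    (clone size measured over the whole table), per group."""
    sizes = t.clone_sizes
    expanded_clones = set(sizes.index[sizes >= min_clone])
    df = t.cells.copy()
    df["expanded"] = df["clone_id"].isin(expanded_clones)
    if groups is None:
        df["group"] = "all"
    else:
        df["group"] = groups.reindex(df["barcode"]).to_numpy()
    out = df.groupby("group")["expanded"].mean()
    return out.rename("expansion_fraction")


def morisita_horn(x, y) -> float:
    """Morisita-Horn overlap of two clone count vectors over aligned clones.

    MH = 2 * sum(x_i * y_i) / ((sum x_i^2 / X^2 + sum y_i^2 / Y^2) * X * Y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must align over the same clones")
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("zero-total clone count vector")
    num = 2.0 * np.sum(x * y)
    den = (np.sum(x**2) / X**2 + np.sum(y**2) / Y**2) * X * Y
    return float(num / den)


def berger_parker(x) -> float:
    """Dominance of the largest clone: max(x) / sum(x)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0 or x.sum() <= 0:
        raise ValueError("empty or zero-total clone count vector")
    return float(berger_parker_d(np.round(x).astype(int)))
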