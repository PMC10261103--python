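"""Malignancy evidence: light-chain allelic exclusion, expression-based CNV
profiles against a reference population, and hypergeometric set overlap."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .qcnorm import NormalizedMatrix

__all__ = [
    "LightChainCall",
    "CNVProfile",
    "OverlapTestResult",
    "allelic_exclusion",
    "cnv_windowed",
    "hypergeometric_overlap",
]


@dataclass
class LightChainCall:
    """Per-cell kappa/lambda dominance and per-cluster restriction labels."""

    per_cell: pd.DataFrame  # barcode, kappa_max, lambda_max, kappa_fraction, cluster
    per_cluster: pd.DataFrame  # cluster, median_fraction, restricted_label, n_cells


@dataclass
class CNVProfile:
    values: np.ndarray  # cells x windows, clipped smoothed log-ratio
    window_table: pd.DataFrame  # chrom, first_gene_start, last_gene_start, window_index, gene_id
    cell_ids: list[str]
    reference_cell_ids: list[str]


@dataclass
class OverlapTestResult:
    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    p_value: float


def allelic_exclusion(
    nm: NormalizedMatrix,
    kappa_genes: list[str],
    lambda_genes: list[str],
    clusters,
    kappa_threshold: float = 0.9,
    lambda_threshold: float = 0.1,
) -> LightChainCall:
    """Light-chain dominance per cell and restriction label per cluster.

    For each cell, take the maximum normalized expression over the kappa
    genes and over the lambda genes; the kappa fraction is
    ``kappa_max / (kappa_max + lambda_max)``.  Cells with both maxima zero
    are flagged missing and excluded from cluster medians.  A cluster is
    called ``kappa`` when its median fraction >= ``kappa_threshold``,
    ``lambda`` when <= ``lambda_threshold``, else ``balanced``.
    """
    gidx = pd.Index(nm.gene_ids)
    ki = gidx.get_indexer(kappa_genes)
    li = gidx.get_indexer(lambda_genes)
    if len(kappa_genes) == 0 or (ki < 0).all():
        raise ValueError("no kappa genes present in the matrix")
    if len(lambda_genes) == 0 or (li < 0).all():
        raise ValueError("no lambda genes present in the matrix")
    ki, li = ki[ki >= 0], li[li >= 0]
    kmax = nm.values[ki, :].max(axis=0)
    lmax = nm.values[li, :].max(axis=0)
    denom = kmax + lmax
    with np.errstate(invalid="ignore"):
        frac = np.where(denom > 0, kmax / np.where(denom > 0, denom, 1.0), np.nan)
    clusters = np.asarray(clusters)
    per_cell = pd.DataFrame(
        {
            "barcode": nm.barcodes,
            "kappa_max": kmax,
            "lambda_max": lmax,
            "kappa_fraction": frac,
            "cluster": clusters,
        }
    )
    rows = []
    for cl, grp in per_cell.groupby("cluster", sort=True):
        med = grp["kappa_fraction"].median(skipna=True)
        if np.isnan(med):
            label = "balanced"
        elif med >= kappa_threshold:
            label = "kappa"
        elif med <= lambda_threshold:
            label = "lambda"
        else:
            label = "balanced"
        rows.append(
            {"cluster": cl, "median_fraction": med, "restricted_label": label, "n_cells": len(grp)}
        )
    return LightChainCall(per_cell, pd.DataFrame(rows))


def cnv_windowed(
    nm: NormalizedMatrix,
    gene_meta: pd.DataFrame | None = None,
    reference_cells: list[str] | np.ndarray = (),
    window: int = 101,
    clip: float = 3.0,
    min_reference: int = 20,
) -> CNVProfile:
    """Smoothed relative-expression CNV profile against reference cells.

    Genes are ordered by (chromosome, start, gene_id); per gene the reference
    mean is subtracted, then a centered moving average of ``window`` genes is
    taken within each chromosome (shrinking at the edges).  Values are
    clipped to ``[-clip, clip]`` and finally centered per cell.  Chromosomes
    with fewer than ``window // 4`` genes are excluded with a warning.
    """
    gene_meta = nm.gene_meta if gene_meta is None else gene_meta
    ref = pd.Index(nm.barcodes).get_indexer(list(reference_cells))
    if (ref < 0).any():
        missing = [b for b, i in zip(reference_cells, ref) if i < 0]
        raise ValueError(f"reference cells not found: {missing[:5]}")
    if len(ref) < min_reference:
        raise ValueError(f"need >= {min_reference} reference cells, got {len(ref)}")

    gm = gene_meta.copy().reset_index(drop=True)
    for col in ("chromosome", "start"):
        if col not in gm.columns:
            raise ValueError(f"gene_meta lacks column {col!r}")
    order = gm.sort_values(["chromosome", "start", "gene_id"]).index.to_numpy()

    rel = nm.values - nm.values[:, ref].mean(axis=1, keepdims=True)
    half = window // 2
    blocks, table_rows = [], []
    widx = 0
    for chrom, sub in gm.iloc[order].groupby("chromosome", sort=True):
        gi = sub.index.to_numpy()
        if len(gi) < max(1, window // 4):
            warnings.warn(
                f"chromosome {chrom} has {len(gi)} genes (< window/4); excluded", stacklevel=2
            )
            continue
        block = rel[gi, :]  # genes_on_chrom x cells
        csum = np.cumsum(block, axis=0)
        n = len(gi)
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half, n - 1)
        upper = csum[hi, :]
        lower = np.where(lo[:, None] > 0, csum[np.maximum(lo - 1, 0), :], 0.0)
        smooth = (upper - lower) / (hi - lo + 1)[:, None]
        blocks.append(smooth)
        starts = sub["start"].to_numpy()
        for j in range(n):
            table_rows.append(
                {
                    "chrom": chrom,
                    "first_gene_start": int(starts[lo[j]]),
                    "last_gene_start": int(starts[hi[j]]),
                    "window_index": widx,
                    "gene_id": sub["gene_id"].iloc[j],
                }
            )
            widx += 1
    if not blocks:
        raise ValueError("no chromosome passed the minimum-gene filter")
    profile = np.vstack(blocks).T  # cells x windows
    profile = np.clip(profile, -clip, clip)
    profile = profile - profile.mean(axis=1, keepdims=True)
    return CNVProfile(
        values=profile,
        window_table=pd.DataFrame(table_rows),
        cell_ids=list(nm.barcodes),
        reference_cell_ids=[nm.barcodes[i] for i in ref],
    )


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_overlap(universe, set_a, set_b) -> OverlapTestResult:
    """Upper-tail hypergeometric P(X >= k) for the overlap of two sets.

    Exact tail summation in log space; N = |universe|, K = |set_a|,
    n = |set_b|, k = |set_a & set_b|.
    """
    universe, set_a, set_b = set(universe), set(set_a), set(set_b)
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    support = np.arange(k, min(K, n) + 1)
    if len(support) == 0 or k == 0:
        p = 1.0
    else:
        logs = _log_binom(K, support) + _log_binom(N - K, n - support) - _log_binom(N, n)
        p = float(np.exp(logsumexp(logs)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return OverlapTestResult(N, K, n, k, p)
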