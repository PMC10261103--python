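"""Expression-program discovery and intratumor-heterogeneity metrics.

Per-sample consensus NMF yields program modules (unit-L2 gene spectra plus
per-cell usages); modules from all samples are clustered on pairwise Pearson
correlation of spectra and clusters recurring in >= ``min_recurrence``
distinct samples are kept as meta-programs.  Signature scoring follows the
binned-control convention: mean expression over the gene set minus the mean
over expression-matched control genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize
import scipy.spatial.distance as ssd
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF

from .qcnorm import NormalizedMatrix

__all__ = [
    "ProgramModule",
    "MetaProgram",
    "SignatureScoreVector",
    "ITHResult",
    "relative_expression",
    "nmf_consensus_sample",
    "build_metaprograms",
    "score_signature",
    "call_mp_cells",
    "depth2",
    "hill_diversity",
]


@dataclass
class ProgramModule:
    sample_id: str
    spectra: pd.Series  # gene -> nonnegative weight, unit L2 norm
    usage: pd.Series  # barcode -> nonnegative weight
    rank_k: int


@dataclass
class MetaProgram:
    mp_id: str
    member_modules: list  # list[ProgramModule]
    recurrence: int
    gene_list: list[str]
    score_threshold: float | None = None

    @property
    def member_samples(self) -> set:
        return {m.sample_id for m in self.member_modules}


@dataclass
class SignatureScoreVector:
    signature_name: str
    scores: pd.Series  # barcode -> score
    n_bins: int
    ctrl_per_gene: int
    seed: int


@dataclass
class ITHResult:
    depth2_scores: pd.Series | None = None
    diversity_profile: dict | None = None
    cluster_frequencies: np.ndarray | None = None


# ---------------------------------------------------------------------------
# consensus NMF


def relative_expression(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Per-gene mean-centered expression with negatives clipped to zero.

    The flat library/baseline component would otherwise dominate one NMF
    factor in every sample and surface as a spurious recurrent program;
    factorizing clipped relative expression suppresses it.
    """
    vals = np.asarray(nm.values, dtype=float)
    vals = np.clip(vals - vals.mean(axis=1, keepdims=True), 0.0, None)
    return NormalizedMatrix(vals, nm.gene_meta, nm.cell_meta, nm.target_sum)


def nmf_consensus_sample(
    nm: NormalizedMatrix,
    k: int,
    n_restarts: int = 50,
    density_quantile: float = 0.25,
    seed: int = 0,
    max_iter: int = 500,
) -> list[ProgramModule]:
    """Consensus NMF on one sample's cells.

    ``n_restarts`` randomly initialised multiplicative-update NMF runs are
    pooled; each run's k spectra are L2-normalized, spectra whose mean
    distance to their nearest neighbours falls in the top ``density_quantile``
    tail are discarded as outliers, the survivors are k-means clustered into
    k groups, and the consensus spectrum of a group is the componentwise
    median (renormalized).  Usages are refit by nonnegative least squares.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(nm.values, dtype=float).T  # cells x genes, nonnegative
    if x.shape[0] < 10 * k:
        warnings.warn(f"only {x.shape[0]} cells for rank {k}; results may be unstable", stacklevel=2)
    sample_id = str(nm.cell_meta["sample_id"].iloc[0]) if "sample_id" in nm.cell_meta else "sample"

    pool = []
    for r in range(n_restarts):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            random_state=seed + r,
            tol=1e-5,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x)
        except Exception as exc:
            warnings.warn(f"NMF restart {r} failed and was dropped: {exc}", stacklevel=2)
            continue
        h = model.components_  # k x genes
        norms = np.linalg.norm(h, axis=1)
        keep = norms > 0
        pool.append(h[keep] / norms[keep, None])
    if not pool:
        raise RuntimeError("all NMF restarts failed")
    spectra = np.vstack(pool)  # (restarts*k) x genes, unit L2 rows

    # outlier pruning by mean distance to nearest neighbours
    if len(spectra) > k and 0.0 < density_quantile < 1.0:
        n_nbr = max(1, len(pool) // 3)
        d = ssd.squareform(ssd.pdist(spectra))
        np.fill_diagonal(d, np.inf)
        mean_nn = np.sort(d, axis=1)[:, :n_nbr].mean(axis=1)
        cutoff = np.quantile(mean_nn, 1.0 - density_quantile)
        keep = mean_nn <= cutoff
        if keep.sum() >= k:
            spectra = spectra[keep]

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(spectra)
    consensus = []
    for c in range(k):
        members = spectra[labels == c]
        if len(members) == 0:
            continue
        med = np.median(members, axis=0)
        nrm = np.linalg.norm(med)
        consensus.append(med / nrm if nrm > 0 else med)
    consensus = np.array(consensus)

    # refit usages by NNLS per cell
    usage = np.empty((x.shape[0], len(consensus)))
    a = consensus.T  # genes x k
    for c in range(x.shape[0]):
        usage[c], _ = scipy.optimize.nnls(a, x[c])

    modules = []
    for j in range(len(consensus)):
        modules.append(
            ProgramModule(
                sample_id=sample_id,
                spectra=pd.Series(consensus[j], index=nm.gene_ids),
                usage=pd.Series(usage[:, j], index=nm.barcodes),
                rank_k=k,
            )
        )
    return modules


def build_metaprograms(
    modules: list[ProgramModule],
    min_recurrence: int = 4,
    top_n_genes: int = 50,
    linkage: str = "average",
    cut_height: float = 0.7,
) -> list[MetaProgram]:
    """Cluster modules across samples into recurrent meta-programs.

    Pearson correlation of spectra over the union gene space (absent genes
    contribute 0); distance 1 - r; the ``linkage`` tree is cut at
    ``cut_height``; clusters spanning fewer than ``min_recurrence`` distinct
    samples are dropped.  The gene list ranks genes by mean within-module
    rank of spectra weight across members.
    """
    if len(modules) < 2:
        return []
    union = sorted(set().union(*(set(m.spectra.index) for m in modules)))
    mat = np.zeros((len(modules), len(union)))
    for i, m in enumerate(modules):
        mat[i, pd.Index(union).get_indexer(m.spectra.index)] = m.spectra.to_numpy()
    r = np.corrcoef(mat)
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = sch.linkage(ssd.squareform(dist, checks=False), method=linkage)
    labels = sch.fcluster(z, t=cut_height, criterion="distance")

    mps = []
    for c in sorted(set(labels)):
        members = [modules[i] for i in np.flatnonzero(labels == c)]
        recurrence = len({m.sample_id for m in members})
        if recurrence < min_recurrence:
            continue
        # rank genes within each member (1 = heaviest), average across members
        from scipy.stats import rankdata

        ranks = np.zeros(len(union))
        for m in members:
            w = np.zeros(len(union))
            w[pd.Index(union).get_indexer(m.spectra.index)] = m.spectra.to_numpy()
            ranks += rankdata(-w, method="average")
        mean_rank = ranks / len(members)
        top = [union[i] for i in np.argsort(mean_rank, kind="stable")[:top_n_genes]]
        mps.append(
            MetaProgram(
                mp_id=f"MP{len(mps) + 1}",
                member_modules=members,
                recurrence=recurrence,
                gene_list=top,
            )
        )
    return mps


# ---------------------------------------------------------------------------
# signature scoring


def score_signature(
    nm: NormalizedMatrix,
    gene_set,
    n_bins: int = 25,
    ctrl_per_gene: int = 50,
    seed: int = 0,
    signature_name: str = "signature",
) -> SignatureScoreVector:
    """Binned-control signature score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins of mean expression
    across cells; for each set gene, ``ctrl_per_gene`` control genes are
    drawn from its bin without replacement (set genes excluded).  The score
    is the per-cell mean over set genes minus the mean over the pooled
    (deduplicated) controls.
    """
    gidx = pd.Index(nm.gene_ids)
    present = [g for g in gene_set if g in gidx]
    absent = [g for g in gene_set if g not in gidx]
    if absent:
        warnings.warn(f"dropping absent signature genes: {absent[:10]}", stacklevel=2)
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if nm.values.shape[0] < n_bins:
        raise ValueError(f"need >= {n_bins} genes for {n_bins} bins")

    means = nm.values.mean(axis=1)
    order = np.argsort(means, kind="stable")
    bins = np.empty(len(means), dtype=int)
    bins[order] = (np.arange(len(means)) * n_bins) // len(means)

    rng = np.random.default_rng(seed)
    set_rows = gidx.get_indexer(present)
    set_mask = np.zeros(len(means), dtype=bool)
    set_mask[set_rows] = True
    controls: list[int] = []
    for g in set_rows:
        candidates = np.flatnonzero((bins == bins[g]) & ~set_mask)
        if len(candidates) == 0:
            continue
        take = min(ctrl_per_gene, len(candidates))
        controls.extend(rng.choice(candidates, size=take, replace=False).tolist())
    controls = sorted(set(controls))
    set_mean = nm.values[set_rows, :].mean(axis=0)
    ctrl_mean = nm.values[controls, :].mean(axis=0) if controls else np.zeros(nm.values.shape[1])
    scores = pd.Series(set_mean - ctrl_mean, index=nm.barcodes, name=signature_name)
    return SignatureScoreVector(signature_name, scores, n_bins, ctrl_per_gene, seed)


def call_mp_cells(
    scores: SignatureScoreVector, threshold: float, samples: pd.Series | None = None
) -> tuple[pd.Index, pd.Series]:
    """Cells with score > threshold, plus per-sample flagged proportions."""
    if not np.isfinite(threshold) and threshold != np.inf:
        raise ValueError("threshold must be finite or +inf")
    flagged = scores.scores.index[scores.scores > threshold]
    if samples is None:
        prop = pd.Series(
            {"all": len(flagged) / len(scores.scores) if len(scores.scores) else np.nan}
        )
    else:
        samples = samples.reindex(scores.scores.index)
        flags = scores.scores > threshold
        prop = flags.groupby(samples).mean()
    return flagged, prop


# ---------------------------------------------------------------------------
# intratumor heterogeneity


def depth2(pseudobulk: pd.DataFrame) -> pd.Series:
    """Heterogeneity score per sample: sd over genes of |z| where z is the
    per-gene z-score across samples (ddof=1; zero-variance genes -> 0)."""
    if pseudobulk.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = pseudobulk.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    scores = np.abs(z).std(axis=0, ddof=1)
    return pd.Series(scores, index=pseudobulk.columns, name="depth2")


def hill_diversity(frequencies, q_grid=(0.0, 1.0, 2.0)) -> dict:
    """Hill numbers D_q over a frequency vector (renormalized; zeros dropped).

    D_q = (sum p_i^q)^(1/(1-q)) for q != 1; D_1 = exp(-sum p_i ln p_i).
    """
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if (p < 0).any():
        raise ValueError("negative frequencies")
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("all frequencies are zero")
    p = p / p.sum()
    out = {}
    for q in q_grid:
        if abs(q - 1.0) < 1e-12:
            out[q] = float(np.exp(-np.sum(p * np.log(p))))
        else:
            out[q] = float(np.sum(p**q) ** (1.0 / (1.0 - q)))
    return out
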