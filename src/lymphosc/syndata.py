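"""Synthetic multi-sample cohort generator with exact ground truth.

Counts are negative-binomial in the mean/theta parameterization
(Var = m + m^2/theta), with per-cell library-size factors, sample-restricted
expression programs acting multiplicatively on gene means, contiguous CNV
blocks in malignant subclones, per-sample kappa-or-lambda light-chain
restriction, per-sample ABC/GCB signature shifts, clone-size-skewed
receptor repertoires and threshold-effect survival times.

All randomness flows from one master seed through named child streams, so
identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .qcnorm import CountMatrix, write_counts

__all__ = [
    "ProgramSpec",
    "CNVBlockSpec",
    "RepertoireSpec",
    "SurvivalSpec",
    "SimConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_cohort",
    "generate_repertoire",
    "generate_survival",
    "write_cohort",
]

KAPPA_GENES = ("IGKC", "IGKC2")
LAMBDA_GENES = ("IGLC1", "IGLC2")
_OFF_CLASS_MEAN = 0.01


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class ProgramSpec:
    name: str
    gene_ids: list[str]
    log_effect: float
    active_fraction: float
    samples_active: list[str]

    def validate(self) -> None:
        if not np.isfinite(self.log_effect):
            raise ConfigurationError(f"program {self.name}: log_effect not finite")
        if not 0.0 < self.active_fraction <= 1.0:
            raise ConfigurationError(f"program {self.name}: active_fraction not in (0, 1]")
        if not self.gene_ids:
            raise ConfigurationError(f"program {self.name}: empty gene set")


@dataclass
class CNVBlockSpec:
    name: str
    chromosome: str
    gene_index_range: tuple[int, int]  # half-open, indices within the chromosome
    fold_change: float
    clone_fraction: float

    def validate(self) -> None:
        lo, hi = self.gene_index_range
        if not lo < hi:
            raise ConfigurationError(f"cnv block {self.name}: degenerate index range")
        if not self.fold_change > 0:
            raise ConfigurationError(f"cnv block {self.name}: fold_change must be > 0")
        if not 0.0 < self.clone_fraction <= 1.0:
            raise ConfigurationError(f"cnv block {self.name}: clone_fraction not in (0, 1]")


@dataclass
class RepertoireSpec:
    n_clones: int = 50
    clone_size_law: str = "geometric"  # or "powerlaw"
    law_param: float = 0.2
    cdr3_length_range: tuple[int, int] = (30, 45)
    multi_chain_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_clones < 1:
            raise ConfigurationError("repertoire: n_clones must be >= 1")
        if self.clone_size_law not in ("geometric", "powerlaw"):
            raise ConfigurationError(f"unknown clone_size_law {self.clone_size_law!r}")
        if not 0.0 <= self.multi_chain_fraction <= 1.0:
            raise ConfigurationError("multi_chain_fraction must be in [0, 1]")


@dataclass
class SurvivalSpec:
    n_patients: int = 100
    true_cutpoint: float = 0.5
    hazard_ratio: float = 2.0
    baseline_scale: float = 10.0
    censor_rate: float = 0.1

    def validate(self) -> None:
        if not self.hazard_ratio > 0:
            raise ConfigurationError("hazard_ratio must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError("censor_rate must be in [0, 1)")


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 2
    genes: int = 500
    cells_per_sample: dict = field(
        default_factory=lambda: {"malignant": 200, "nonmalignant_B": 50, "cd8_T": 50}
    )
    baseline_log_mean: float = -1.0
    baseline_log_sd: float = 1.0
    dispersion: float = 2.0  # NB inverse-dispersion theta
    library_size_log_mean: float = 0.0
    library_size_log_sd: float = 0.25
    programs: list[ProgramSpec] = field(default_factory=list)
    lightchain_restriction: dict = field(default_factory=dict)  # sample -> kappa|lambda
    cnv_blocks: list[CNVBlockSpec] = field(default_factory=list)
    coo_subtype: dict = field(default_factory=dict)  # sample -> ABC|GCB
    coo_effect: float = 1.0
    n_coo_genes: int = 20
    repertoire: RepertoireSpec = field(default_factory=RepertoireSpec)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    mito_fraction: float = 0.05
    n_mito_genes: int = 10
    qc_violators: int = 0

    # -- derived layout ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    def validate(self) -> None:
        if self.n_samples < 1 or self.genes < 1:
            raise ConfigurationError("n_samples and genes must be >= 1")
        if any(v < 0 for v in self.cells_per_sample.values()):
            raise ConfigurationError("cell counts must be >= 0")
        if not (np.isfinite(self.dispersion) and self.dispersion > 0):
            raise ConfigurationError("dispersion (theta) must be finite and > 0")
        if not 0.0 <= self.mito_fraction < 1.0:
            raise ConfigurationError("mito_fraction must be in [0, 1)")
        for ps in self.programs:
            ps.validate()
            unknown = set(ps.samples_active) - set(self.sample_ids)
            if unknown:
                raise ConfigurationError(f"program {ps.name}: unknown samples {sorted(unknown)}")
        for cb in self.cnv_blocks:
            cb.validate()
        for s, lab in self.lightchain_restriction.items():
            if lab not in ("kappa", "lambda"):
                raise ConfigurationError(f"lightchain_restriction[{s}] must be kappa or lambda")
        for s, lab in self.coo_subtype.items():
            if lab not in ("ABC", "GCB"):
                raise ConfigurationError(f"coo_subtype[{s}] must be ABC or GCB")
        self.repertoire.validate()
        self.survival.validate()

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic child generator for a named pipeline stage."""
        ss = np.random.SeedSequence(self.seed)
        child = np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(abs(hash_stable(stream)) % (2**31),)
        )
        return np.random.default_rng(child)

    # -- gene universe -----------------------------------------------------
    def gene_table(self) -> pd.DataFrame:
        """Gene ids with chromosome/start layout.

        Regular genes are split over chr1..chr10 contiguously; the light-chain
        constant genes sit on chr2 (kappa) and chr22 (lambda); mito genes on
        chrM.  Start positions increase within chromosomes.
        """
        n_regular = self.genes
        ids = [f"G{i + 1:05d}" for i in range(n_regular)]
        n_chrom = min(10, max(1, n_regular // 50))
        per = int(np.ceil(n_regular / n_chrom))
        chroms = [f"chr{i // per + 1}" for i in range(n_regular)]
        starts = [1000 * ((i % per) + 1) for i in range(n_regular)]
        rows = list(zip(ids, chroms, starts))
        rows += [(g, "chr2", 10_000_000 + 1000 * i) for i, g in enumerate(KAPPA_GENES)]
        rows += [(g, "chr22", 10_000_000 + 1000 * i) for i, g in enumerate(LAMBDA_GENES)]
        rows += [(f"MT-G{i + 1}", "chrM", 100 * (i + 1)) for i in range(self.n_mito_genes)]
        df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start"])
        df["is_mito"] = df["gene_id"].str.startswith("MT-")
        return df

    def default_coo_sets(self) -> tuple[list[str], list[str]]:
        """Disjoint built-in ABC / GCB marker sets (last regular genes)."""
        n = self.n_coo_genes
        ids = [f"G{i + 1:05d}" for i in range(self.genes)]
        if 2 * n > len(ids):
            raise ConfigurationError("not enough genes for the COO sets")
        return ids[-2 * n : -n], ids[-n:]


@dataclass
class GroundTruth:
    cell_meta: pd.DataFrame  # barcode, sample_id, role, violation
    program_activity: pd.DataFrame  # cells x programs, {0,1}
    lightchain: pd.Series  # per-cell kappa|lambda|both|none
    cnv_blocks: dict  # name -> {"gene_ids": [...], "cells": [...], "fold_change": f}
    coo_labels: dict  # sample -> ABC|GCB
    abc_genes: list[str]
    gcb_genes: list[str]
    program_genes: dict  # program name -> gene ids
    clone_ids: pd.Series | None = None  # per-barcode clone id (repertoire)
    multi_chain: pd.Series | None = None
    survival_groups: pd.Series | None = None


def hash_stable(s: str) -> int:
    """Platform-stable string hash (FNV-1a, 32-bit)."""
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


# ---------------------------------------------------------------------------
# expression cohort


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB(mean, theta) via gamma-Poisson; Var = m + m^2/theta."""
    shape = np.broadcast_to(theta, mean.shape)
    lam = rng.gamma(shape, np.maximum(mean, 0.0) / theta)
    return rng.poisson(lam)


def generate_cohort(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Sample the full gene x cell count matrix plus latent assignments."""
    config.validate()
    genes = config.gene_table()
    gene_index = pd.Index(genes["gene_id"])
    n_genes = len(genes)

    rng_mu = config.rng("baseline")
    mu = rng_mu.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_genes)
    # light-chain and mito means are set explicitly below
    is_mito = genes["is_mito"].to_numpy()
    lc_idx = {g: gene_index.get_loc(g) for g in KAPPA_GENES + LAMBDA_GENES}

    cells = []
    roles = ["malignant", "nonmalignant_B", "cd8_T"]
    for s in config.sample_ids:
        for role in roles:
            for i in range(config.cells_per_sample.get(role, 0)):
                cells.append((f"{s}-{role}-{i + 1}", s, role, "none"))
        for v, vio in enumerate(["low_genes", "high_mito", "high_counts"]):
            for i in range(config.qc_violators):
                cells.append((f"{s}-violator-{vio}-{i + 1}", s, "violator", vio))
    cell_meta = pd.DataFrame(cells, columns=["barcode", "sample_id", "role", "violation"])
    n_cells = len(cell_meta)

    rng_lib = config.rng("library")
    libsize = np.exp(
        rng_lib.normal(config.library_size_log_mean, config.library_size_log_sd, n_cells)
    )

    # per-cell program activity
    rng_prog = config.rng("programs")
    activity = np.zeros((n_cells, len(config.programs)), dtype=int)
    is_malignant = (cell_meta["role"] == "malignant").to_numpy()
    for p, ps in enumerate(config.programs):
        eligible = is_malignant & cell_meta["sample_id"].isin(ps.samples_active).to_numpy()
        draws = rng_prog.random(n_cells) < ps.active_fraction
        activity[:, p] = (eligible & draws).astype(int)

    # log-mean matrix: genes x cells
    log_mean = np.tile(mu[:, None], (1, n_cells))
    for p, ps in enumerate(config.programs):
        gi = gene_index.get_indexer(ps.gene_ids)
        if (gi < 0).any():
            missing = [g for g, j in zip(ps.gene_ids, gi) if j < 0]
            raise ConfigurationError(f"program {ps.name}: unknown genes {missing[:5]}")
        active = activity[:, p] == 1
        log_mean[np.ix_(gi, active)] += ps.log_effect

    # COO shifts on malignant cells
    abc_genes, gcb_genes = config.default_coo_sets()
    abc_idx = gene_index.get_indexer(abc_genes)
    gcb_idx = gene_index.get_indexer(gcb_genes)
    for s, lab in config.coo_subtype.items():
        m = (is_malignant & (cell_meta["sample_id"] == s).to_numpy()).nonzero()[0]
        idx = abc_idx if lab == "ABC" else gcb_idx
        log_mean[np.ix_(idx, m)] += config.coo_effect

    mean = np.exp(log_mean) * libsize[None, :]

    # CNV blocks: multiplicative on malignant subclone means
    rng_cnv = config.rng("cnv")
    cnv_truth: dict = {}
    for cb in config.cnv_blocks:
        chrom_genes = genes.loc[genes["chromosome"] == cb.chromosome].sort_values(
            ["start", "gene_id"]
        )
        lo, hi = cb.gene_index_range
        if hi > len(chrom_genes):
            raise ConfigurationError(
                f"cnv block {cb.name}: range {cb.gene_index_range} exceeds "
                f"{len(chrom_genes)} genes on {cb.chromosome}"
            )
        block_ids = chrom_genes["gene_id"].iloc[lo:hi].tolist()
        gi = gene_index.get_indexer(block_ids)
        carriers = []
        for s in config.sample_ids:
            m = (is_malignant & (cell_meta["sample_id"] == s).to_numpy()).nonzero()[0]
            k = int(round(cb.clone_fraction * len(m)))
            carriers.extend(rng_cnv.choice(m, size=k, replace=False).tolist())
        carriers = sorted(carriers)
        mean[np.ix_(gi, carriers)] *= cb.fold_change
        cnv_truth[cb.name] = {
            "gene_ids": block_ids,
            "cells": cell_meta["barcode"].iloc[carriers].tolist(),
            "fold_change": cb.fold_change,
        }

    # light-chain constant genes
    role = cell_meta["role"].to_numpy()
    lightchain = pd.Series("none", index=cell_meta["barcode"], name="lightchain")
    for g in KAPPA_GENES + LAMBDA_GENES:
        mean[lc_idx[g], :] = _OFF_CLASS_MEAN
    for s in config.sample_ids:
        restrict = config.lightchain_restriction.get(s)
        in_sample = (cell_meta["sample_id"] == s).to_numpy()
        m = (is_malignant & in_sample).nonzero()[0]
        if restrict is not None and len(m):
            on = KAPPA_GENES if restrict == "kappa" else LAMBDA_GENES
            for g in on:
                mean[lc_idx[g], m] = 5.0 * libsize[m]
            lightchain.iloc[m] = restrict
        b = ((role == "nonmalignant_B") & in_sample).nonzero()[0]
        if len(b):
            for g in KAPPA_GENES + LAMBDA_GENES:
                mean[lc_idx[g], b] = 2.0 * libsize[b]
            lightchain.iloc[b] = "both"

    # mito genes carry mito_fraction of each cell's expected mass
    if config.n_mito_genes and config.mito_fraction > 0:
        nonmito_mass = mean[~is_mito, :].sum(axis=0)
        per_gene = (
            config.mito_fraction / (1.0 - config.mito_fraction) * nonmito_mass / config.n_mito_genes
        )
        mean[is_mito, :] = per_gene[None, :]

    rng_counts = config.rng("counts")
    counts = _nb_sample(rng_counts, mean, config.dispersion)

    # deliberate QC violators
    rng_vio = config.rng("violators")
    violation = cell_meta["violation"].to_numpy()
    for c in np.flatnonzero(violation == "low_genes"):
        col = np.zeros(n_genes, dtype=counts.dtype)
        keep = rng_vio.choice(np.flatnonzero(~is_mito), size=min(100, n_genes), replace=False)
        col[keep] = 1
        counts[:, c] = col
    for c in np.flatnonzero(violation == "high_mito"):
        total = counts[:, c].sum()
        boost = max(int(total), 50) // max(config.n_mito_genes, 1) + 1
        counts[is_mito, c] += boost  # pushes mito fraction well above 50%
    for c in np.flatnonzero(violation == "high_counts"):
        g = int(rng_vio.integers(0, n_genes))
        counts[g, c] += 60_000

    cm = CountMatrix(
        sp.csr_matrix(counts),
        genes,
        cell_meta[["barcode", "sample_id", "role", "violation"]].copy(),
    )
    gt = GroundTruth(
        cell_meta=cell_meta,
        program_activity=pd.DataFrame(
            activity, index=cell_meta["barcode"], columns=[p.name for p in config.programs]
        ),
        lightchain=lightchain,
        cnv_blocks=cnv_truth,
        coo_labels=dict(config.coo_subtype),
        abc_genes=abc_genes,
        gcb_genes=gcb_genes,
        program_genes={p.name: list(p.gene_ids) for p in config.programs},
    )
    return cm, gt


# ---------------------------------------------------------------------------
# repertoire

_CODON_AA = None


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    trimmed = nt[: len(nt) - len(nt) % 3]
    return str(Seq(trimmed).translate())


def _clone_probabilities(spec: RepertoireSpec) -> np.ndarray:
    i = np.arange(1, spec.n_clones + 1, dtype=float)
    if spec.clone_size_law == "geometric":
        p = spec.law_param
        w = (1 - p) ** (i - 1) * p
    else:  # powerlaw
        w = i ** (-spec.law_param)
    return w / w.sum()


def generate_repertoire(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a 10x-style filtered-contig table for the cohort's T cells.

    Returns ``(contigs, truth)`` where truth has one row per cell with its
    clone id and a multi-chain flag.  Every clone owns one TRA and one TRB
    CDR3 nucleotide sequence; multi-chain cells receive an extra TRB contig.
    """
    config.validate()
    spec = config.repertoire
    rng = config.rng("repertoire")
    barcodes = [
        f"{s}-cd8_T-{i + 1}"
        for s in config.sample_ids
        for i in range(config.cells_per_sample.get("cd8_T", 0))
    ]
    n_cells = len(barcodes)
    if n_cells == 0:
        raise ConfigurationError("repertoire requires cd8_T cells in the cohort")

    lo, hi = spec.cdr3_length_range
    lengths = [3 * k for k in range(int(np.ceil(lo / 3)), hi // 3 + 1)] or [lo]

    def random_cdr3() -> str:
        L = int(rng.choice(lengths))
        return "".join(rng.choice(list("ACGT"), size=L))

    clone_tra = [random_cdr3() for _ in range(spec.n_clones)]
    clone_trb = [random_cdr3() for _ in range(spec.n_clones)]
    assignment = rng.choice(spec.n_clones, size=n_cells, p=_clone_probabilities(spec))
    multi = rng.random(n_cells) < spec.multi_chain_fraction

    rows = []
    for c, bc in enumerate(barcodes):
        cl = int(assignment[c])
        for chain, cdr3 in (("TRA", clone_tra[cl]), ("TRB", clone_trb[cl])):
            rows.append(
                {
                    "barcode": bc,
                    "is_cell": "True",
                    "contig_id": f"{bc}_contig_{len(rows) + 1}",
                    "chain": chain,
                    "v_gene": f"{chain}V1-1",
                    "j_gene": f"{chain}J1-1",
                    "cdr3": _translate(cdr3),
                    "cdr3_nt": cdr3,
                    "reads": int(rng.integers(200, 2000)),
                    "umis": int(rng.integers(2, 20)),
                }
            )
        if multi[c]:
            extra = random_cdr3()
            rows.append(
                {
                    "barcode": bc,
                    "is_cell": "True",
                    "contig_id": f"{bc}_contig_{len(rows) + 1}",
                    "chain": "TRB",
                    "v_gene": "TRBV2-1",
                    "j_gene": "TRBJ2-1",
                    "cdr3": _translate(extra),
                    "cdr3_nt": extra,
                    "reads": int(rng.integers(200, 2000)),
                    "umis": int(rng.integers(2, 20)),
                }
            )
    contigs = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {"barcode": barcodes, "clone_id": assignment.astype(int), "multi_chain": multi}
    )
    return contigs, truth


# ---------------------------------------------------------------------------
# survival


def generate_survival(config: SimConfig) -> pd.DataFrame:
    """Exponential survival with a hazard step at the true cutpoint.

    Columns: patient_id, time, event, score, true_group.
    """
    config.validate()
    spec = config.survival
    rng = config.rng("survival")
    score = rng.random(spec.n_patients)
    high = score > spec.true_cutpoint
    scale = np.where(high, spec.baseline_scale / spec.hazard_ratio, spec.baseline_scale)
    time = rng.exponential(scale)
    censored = rng.random(spec.n_patients) < spec.censor_rate
    u = rng.random(spec.n_patients)
    time = np.where(censored, time * u, time)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(spec.n_patients)],
            "time": time,
            "event": (~censored).astype(int),
            "score": score,
            "true_group": np.where(high, "high", "low"),
        }
    )


# ---------------------------------------------------------------------------
# output


def write_cohort(config: SimConfig, outdir) -> dict[str, Path]:
    """Generate everything and write the text bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, gt = generate_cohort(config)
    paths = write_counts(cm, outdir)
    cm.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)
    gt.program_activity.to_csv(outdir / "truth_program_activity.tsv", sep="\t")
    gt.lightchain.to_frame().to_csv(outdir / "truth_lightchain.tsv", sep="\t")
    pd.DataFrame(
        [
            {"block": name, "fold_change": d["fold_change"], "gene_ids": ",".join(d["gene_ids"]),
             "cells": ",".join(d["cells"])}
            for name, d in gt.cnv_blocks.items()
        ]
    ).to_csv(outdir / "truth_cnv_blocks.tsv", sep="\t", index=False)
    if config.cells_per_sample.get("cd8_T", 0):
        contigs, ctruth = generate_repertoire(config)
        contigs.to_csv(outdir / "filtered_contig_annotations.csv", index=False)
        ctruth.to_csv(outdir / "truth_clones.tsv", sep="\t", index=False)
        paths["contigs"] = outdir / "filtered_contig_annotations.csv"
    surv = generate_survival(config)
    surv.to_csv(outdir / "survival.csv", index=False)
    paths["survival"] = outdir / "survival.csv"
    return paths
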