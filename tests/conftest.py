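import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lymphosc import qcnorm, syndata


@pytest.fixture(scope="session")
def small_cohort():
    """Two-sample cohort with light-chain restriction and COO shifts."""
    cfg = syndata.SimConfig(
        seed=11,
        n_samples=2,
        genes=300,
        cells_per_sample={"malignant": 120, "nonmalignant_B": 40, "cd8_T": 40},
        lightchain_restriction={"S1": "kappa", "S2": "lambda"},
        coo_subtype={"S1": "ABC", "S2": "GCB"},
        dispersion=5.0,
        baseline_log_mean=-0.5,
        n_coo_genes=30,
    )
    cm, gt = syndata.generate_cohort(cfg)
    return cfg, cm, gt


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    _, cm, _ = small_cohort
    return qcnorm.normalize_log(cm)


def dense_matrix(values, gene_ids=None, barcodes=None, sample_id="S1"):
    """Build a CountMatrix from a dense integer array (test helper)."""
    values = np.asarray(values)
    n_genes, n_cells = values.shape
    gene_ids = gene_ids or [f"G{i + 1:05d}" for i in range(n_genes)]
    barcodes = barcodes or [f"C{j + 1}" for j in range(n_cells)]
    gene_meta = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": ["chr1"] * n_genes,
            "start": 1000 * (np.arange(n_genes) + 1),
        }
    )
    cell_meta = pd.DataFrame({"barcode": barcodes, "sample_id": [sample_id] * n_cells})
    return qcnorm.CountMatrix(sp.csr_matrix(values), gene_meta, cell_meta)


@pytest.fixture
def make_count_matrix():
    return dense_matrix
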