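import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphosc import programs, qcnorm
from lymphosc.programs import ProgramModule


def make_nm(values, gene_ids=None, barcodes=None, sample_id="S1"):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = gene_ids or [f"G{i + 1:05d}" for i in range(n_genes)]
    barcodes = barcodes or [f"c{j}" for j in range(n_cells)]
    gene_meta = pd.DataFrame(
        {"gene_id": gene_ids, "chromosome": "chr1", "start": np.arange(n_genes) + 1}
    )
    cell_meta = pd.DataFrame({"barcode": barcodes, "sample_id": sample_id})
    return qcnorm.NormalizedMatrix(values, gene_meta, cell_meta)


class TestNmfConsensus:
    def test_exact_rank_two_recovery(self):
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(0)
        n_genes, n_cells = 40, 120
        h = np.zeros((2, n_genes))
        h[0, :15] = rng.uniform(1, 3, 15)
        h[1, 20:40] = rng.uniform(1, 3, 20)
        w = rng.uniform(0.1, 2.0, (n_cells, 2))
        x = (w @ h).T  # genes x cells
        nm = make_nm(x)
        mods = programs.nmf_consensus_sample(nm, k=2, n_restarts=8, seed=1)
        assert len(mods) == 2
        truth = h / np.linalg.norm(h, axis=1, keepdims=True)
        est = np.array([m.spectra.to_numpy() for m in mods])
        cos = truth @ est.T
        rows, cols = linear_sum_assignment(-cos)
        assert cos[rows, cols].min() > 0.99

    def test_rank_one_degenerate(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(0.5, 2.0, 30)
        w = rng.uniform(0.1, 1.0, 50)
        x = np.outer(h, w)
        mods = programs.nmf_consensus_sample(make_nm(x), k=1, n_restarts=4, seed=0)
        assert len(mods) == 1
        cos = mods[0].spectra.to_numpy() @ (h / np.linalg.norm(h))
        assert cos > 0.999

    def test_determinism(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 2, (30, 60))
        a = programs.nmf_consensus_sample(make_nm(x), k=3, n_restarts=4, seed=5)
        b = programs.nmf_consensus_sample(make_nm(x), k=3, n_restarts=4, seed=5)
        for ma, mb in zip(a, b):
            pd.testing.assert_series_equal(ma.spectra, mb.spectra)
            pd.testing.assert_series_equal(ma.usage, mb.usage)

    def test_spectra_nonnegative_unit_norm(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 2, (30, 60))
        mods = programs.nmf_consensus_sample(make_nm(x), k=3, n_restarts=4, seed=5)
        for m in mods:
            s = m.spectra.to_numpy()
            assert (s >= 0).all()
            assert np.linalg.norm(s) == pytest.approx(1.0, abs=1e-9)
            assert (m.usage.to_numpy() >= 0).all()


def synthetic_module(sample_id, heavy_genes, all_genes, seed, heavy=5.0):
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.0, 0.3, len(all_genes))
    w[pd.Index(all_genes).get_indexer(heavy_genes)] += heavy
    w /= np.linalg.norm(w)
    return ProgramModule(
        sample_id=sample_id,
        spectra=pd.Series(w, index=all_genes),
        usage=pd.Series(dtype=float),
        rank_k=3,
    )


class TestBuildMetaprograms:
    GENES = [f"G{i:04d}" for i in range(200)]

    def test_shared_program_recurs(self):
        shared = self.GENES[:30]
        mods = []
        for i, s in enumerate([f"S{j}" for j in range(1, 6)]):
            mods.append(synthetic_module(s, shared, self.GENES, seed=i))
            noise = self.GENES[40 + 25 * i : 60 + 25 * i]
            mods.append(synthetic_module(s, noise, self.GENES, seed=100 + i))
        mps = programs.build_metaprograms(mods, min_recurrence=4)
        assert len(mps) == 1
        assert mps[0].recurrence == 5
        assert set(mps[0].gene_list[:30]) == set(shared)

    def test_three_sample_program_dropped(self):
        shared = self.GENES[:30]
        mods = [
            synthetic_module(s, shared, self.GENES, seed=i)
            for i, s in enumerate(["S1", "S2", "S3"])
        ]
        assert programs.build_metaprograms(mods, min_recurrence=4) == []

    def test_orthogonal_modules_no_mps(self):
        mods = []
        for i, s in enumerate([f"S{j}" for j in range(1, 7)]):
            block = self.GENES[30 * i : 30 * (i + 1)]
            w = np.zeros(len(self.GENES))
            w[pd.Index(self.GENES).get_indexer(block)] = 1.0
            w /= np.linalg.norm(w)
            mods.append(
                ProgramModule(s, pd.Series(w, index=self.GENES), pd.Series(dtype=float), 1)
            )
        assert programs.build_metaprograms(mods, min_recurrence=2) == []

    def test_single_module_empty(self):
        mods = [synthetic_module("S1", self.GENES[:10], self.GENES, seed=0)]
        assert programs.build_metaprograms(mods) == []


def signature_oracle(values, gene_ids, gene_set, n_bins, ctrl_per_gene, seed):
    """Independent two-pass bin/sample/subtract reimplementation."""
    gene_ids = list(gene_ids)
    means = values.mean(axis=1)
    order = np.argsort(means, kind="stable")
    bins = np.empty(len(means), dtype=int)
    bins[order] = (np.arange(len(means)) * n_bins) // len(means)
    rng = np.random.default_rng(seed)
    set_rows = [gene_ids.index(g) for g in gene_set if g in gene_ids]
    controls = set()
    for g in set_rows:
        pool = [
            i for i in range(len(gene_ids)) if bins[i] == bins[g] and i not in set_rows
        ]
        take = min(ctrl_per_gene, len(pool))
        controls.update(rng.choice(pool, size=take, replace=False).tolist())
    set_mean = values[set_rows, :].mean(axis=0)
    ctrl_mean = values[sorted(controls), :].mean(axis=0)
    return set_mean - ctrl_mean


class TestScoreSignature:
    def test_constant_matrix_zero(self):
        nm = make_nm(np.full((60, 10), 2.5))
        sv = programs.score_signature(nm, list(nm.gene_ids[:5]), n_bins=5, seed=0)
        np.testing.assert_allclose(sv.scores, 0.0, atol=1e-12)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 4, size=(30, 10))
        nm = make_nm(vals)
        gene_set = list(nm.gene_ids[::7])
        sv = programs.score_signature(nm, gene_set, n_bins=5, ctrl_per_gene=3, seed=11)
        expected = signature_oracle(vals, nm.gene_ids, gene_set, 5, 3, 11)
        np.testing.assert_allclose(sv.scores.to_numpy(), expected, atol=1e-12)

    def test_shifted_set_genes_scored_near_delta(self):
        rng = np.random.default_rng(8)
        n_genes, n_cells, delta = 200, 100, 1.5
        vals = np.full((n_genes, n_cells), 1.0) + rng.normal(0, 0.01, (n_genes, n_cells))
        active = np.arange(n_cells) < 50
        set_rows = np.arange(10)
        vals[np.ix_(set_rows, np.flatnonzero(active))] += delta
        nm = make_nm(vals)
        sv = programs.score_signature(nm, list(nm.gene_ids[:10]), n_bins=10, seed=0)
        s = sv.scores.to_numpy()
        assert abs(s[active].mean() - delta) < 0.1
        assert abs(s[~active].mean()) < 0.1

    def test_absent_genes_warn_and_all_absent_error(self):
        nm = make_nm(np.ones((30, 4)))
        with pytest.warns(UserWarning, match="absent"):
            programs.score_signature(nm, [nm.gene_ids[0], "NOPE"], n_bins=3, seed=0)
        with pytest.raises(ValueError, match="no signature gene"):
            programs.score_signature(nm, ["NOPE"], n_bins=3, seed=0)

    def test_translation_equivariance(self):
        # set genes isolated in the top bin before and after the shift, so the
        # control pool is unchanged and scores shift exactly by the constant
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 1, size=(40, 8))
        vals[:5, :] += 10.0  # set genes dominate the top bin
        nm_a = make_nm(vals)
        shifted = vals.copy()
        shifted[:5, :] += 2.0
        nm_b = make_nm(shifted)
        genes = list(nm_a.gene_ids[:5])
        a = programs.score_signature(nm_a, genes, n_bins=4, ctrl_per_gene=5, seed=3)
        b = programs.score_signature(nm_b, genes, n_bins=4, ctrl_per_gene=5, seed=3)
        np.testing.assert_allclose(b.scores - a.scores, 2.0, atol=1e-10)


class TestCallMpCells:
    def test_fixed_threshold_proportion(self):
        scores = pd.Series(
            np.concatenate([np.full(17, 0.1), np.full(3, 1.5)]),
            index=[f"c{i}" for i in range(20)],
        )
        sv = programs.SignatureScoreVector("mp", scores, 25, 50, 0)
        flagged, prop = programs.call_mp_cells(sv, threshold=0.9)
        assert len(flagged) == 3
        assert prop["all"] == pytest.approx(0.15)

    def test_infinite_threshold_empty(self):
        sv = programs.SignatureScoreVector(
            "mp", pd.Series([1.0, 2.0], index=["a", "b"]), 25, 50, 0
        )
        flagged, prop = programs.call_mp_cells(sv, threshold=np.inf)
        assert len(flagged) == 0
        assert prop["all"] == 0.0

    def test_per_sample_proportions(self):
        scores = pd.Series([2.0, 0.1, 2.0, 2.0], index=list("abcd"))
        samples = pd.Series(["S1", "S1", "S2", "S2"], index=list("abcd"))
        sv = programs.SignatureScoreVector("mp", scores, 25, 50, 0)
        _, prop = programs.call_mp_cells(sv, threshold=0.9, samples=samples)
        assert prop["S1"] == pytest.approx(0.5)
        assert prop["S2"] == pytest.approx(1.0)


class TestDepth2:
    def test_identical_columns_zero(self):
        pb = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        np.testing.assert_allclose(programs.depth2(pb), 0.0)

    def test_hand_example(self):
        pb = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 2.0]})
        np.testing.assert_allclose(programs.depth2(pb), [0.5, 0.5], atol=1e-12)

    def test_per_gene_shift_invariance(self):
        rng = np.random.default_rng(1)
        pb = pd.DataFrame(rng.random((50, 4)), columns=list("abcd"))
        shifted = pb.add(rng.random(50), axis=0)
        np.testing.assert_allclose(programs.depth2(pb), programs.depth2(shifted), atol=1e-10)

    def test_per_gene_affine_invariance(self):
        rng = np.random.default_rng(2)
        pb = pd.DataFrame(rng.random((50, 4)), columns=list("abcd"))
        affine = pb.mul(3.7).add(rng.random(50), axis=0)
        np.testing.assert_allclose(programs.depth2(pb), programs.depth2(affine), atol=1e-10)

    def test_single_sample_error(self):
        with pytest.raises(ValueError):
            programs.depth2(pd.DataFrame({"a": [1.0, 2.0]}))


class TestHillDiversity:
    def test_uniform_equals_richness(self):
        for k in (1, 3, 10):
            d = programs.hill_diversity(np.full(k, 1.0 / k), q_grid=(0, 0.5, 1, 2, 5))
            for v in d.values():
                assert v == pytest.approx(k, rel=1e-9)

    def test_closed_form_example(self):
        d = programs.hill_diversity([0.5, 0.25, 0.25], q_grid=(0, 1, 2))
        assert d[0] == pytest.approx(3.0)
        assert d[1] == pytest.approx(2 ** 1.5, rel=1e-9)
        assert d[2] == pytest.approx(8 / 3, rel=1e-9)

    def test_zero_frequency_clusters_excluded(self):
        d = programs.hill_diversity([0.5, 0.5, 0.0], q_grid=(0,))
        assert d[0] == pytest.approx(2.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            programs.hill_diversity([])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_nonincreasing_in_q(self, weights):
        qs = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)
        d = programs.hill_diversity(weights, q_grid=qs)
        vals = [d[q] for q in qs]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))
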