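"""qpWave rank tests, qpAdm weights and the model-search protocol."""

import numpy as np
import pytest

from sibtrace.formats import GenotypeMatrix, Individual
from sibtrace.fstats import allele_freqs, f4
from sibtrace.qpadm import (F4Matrix, QpAdm, build_f4_matrix, model_search,
                            qpwave_rank)
from conftest import RIGHTS, two_source_genotypes


@pytest.fixture(scope="module")
def two_source(mapped_panel):
    return two_source_genotypes(mapped_panel, seed=20)


class TestBuildF4Matrix:
    def test_entries_match_independent_f4_calls(self, two_source):
        """Cross-module oracle: each cell equals the standalone f4."""
        left = ["T", "S1", "S2"]
        mat = build_f4_matrix(two_source, left, RIGHTS)
        freqs = allele_freqs(two_source)
        for i, li in enumerate(left[1:]):
            for j, rj in enumerate(RIGHTS[1:]):
                expect = f4(freqs, li, left[0], rj, RIGHTS[0]).estimate
                assert mat.x[i, j] == pytest.approx(expect, abs=1e-14)

    def test_allsnps_equals_intersection_on_complete_data(self, two_source):
        a = build_f4_matrix(two_source, ["T", "S1", "S2"], RIGHTS, allsnps=True)
        b = build_f4_matrix(two_source, ["T", "S1", "S2"], RIGHTS, allsnps=False)
        assert np.allclose(a.x, b.x, atol=0)
        assert np.array_equal(a.cell_sites, b.cell_sites)

    def test_self_model_is_noise(self, mapped_panel):
        """Relabelling one population as target and source gives X ~ 0."""
        gm = two_source_genotypes(mapped_panel, seed=21)
        # split S1's individuals into two pseudo-populations
        for ind in gm.individuals:
            if ind.population == "S1" and ind.id.endswith(("0", "1", "2", "3", "4")):
                ind.population = "S1b"
        mat = build_f4_matrix(gm, ["S1", "S1b"], RIGHTS)
        q = mat.jackknife_covariance()
        z = mat.x.reshape(-1) / np.sqrt(np.diag(q))
        assert np.all(np.abs(z) < 4)

    def test_sparse_cells_rejected(self, small_panel):
        gm = two_source_genotypes(small_panel, seed=22)
        with pytest.raises(ValueError, match="usable sites"):
            build_f4_matrix(gm, ["T", "S1"], RIGHTS[:3], min_cell_sites=10**6)


class TestQpWave:
    def test_dof_formula(self, two_source):
        mat = build_f4_matrix(two_source, ["T", "S1", "S2"], RIGHTS)
        _, dof0, _ = qpwave_rank(mat, 0)
        _, dof1, _ = qpwave_rank(mat, 1)
        assert dof0 == 2 * 4 and dof1 == 1 * 3

    def test_dof_counting_example(self):
        # |L| = 6, |R| = 7, r = 4 -> (5-4)(6-4) = 2
        m, n, r = 5, 6, 4
        assert (m - r) * (n - r) == 2

    def test_zero_matrix_chi2_zero(self):
        B, m, n = 12, 2, 4
        mat = F4Matrix(left=["T", "a", "b"], right=list("wxyz") + ["v"],
                       x=np.zeros((m, n)),
                       block_sums=np.random.default_rng(0).normal(
                           0, 1e-12, (B, m, n)),
                       block_counts=np.full((B, m, n), 100),
                       block_weights=np.full(B, 100.0),
                       cell_sites=np.full((m, n), B * 100))
        mat.x[:] = 0.0
        for r in (0, 1):
            chi2, _, p = qpwave_rank(mat, r, seed=0)
            assert chi2 == pytest.approx(0.0, abs=1e-6)
            assert p == pytest.approx(1.0, abs=1e-6)

    def test_two_stream_data_rank_calibration(self, two_source):
        """Rank 0 rejected, rank 1 accepted when two streams are simulated."""
        mat = build_f4_matrix(two_source, ["T", "S1", "S2"], RIGHTS)
        _, _, p0 = qpwave_rank(mat, 0, seed=0)
        _, _, p1 = qpwave_rank(mat, 1, seed=0)
        assert p0 < 0.01
        assert p1 > 0.05

    def test_invalid_rank_rejected(self, two_source):
        mat = build_f4_matrix(two_source, ["T", "S1", "S2"], RIGHTS)
        with pytest.raises(ValueError):
            qpwave_rank(mat, 2)


class TestQpAdmFit:
    def test_weights_sum_to_one_exactly(self, two_source):
        res = QpAdm(two_source, "T", ["S1", "S2"], RIGHTS).fit(seed=0)
        assert abs(res.weights.sum() - 1.0) < 1e-12

    def test_recovers_simulated_alpha(self, two_source):
        res = QpAdm(two_source, "T", ["S1", "S2"], RIGHTS).fit(seed=0)
        assert res.weights[0] == pytest.approx(0.3, abs=3 * res.weight_se[0] + 0.02)
        assert res.p_value > 0.01
        assert res.feasible

    def test_identity_model_not_rejected(self, mapped_panel):
        gm = two_source_genotypes(mapped_panel, seed=23)
        for ind in gm.individuals:
            if ind.population == "S1" and ind.id.endswith(("0", "1", "2", "3", "4")):
                ind.population = "S1b"
        res = QpAdm(gm, "S1", ["S1b"], RIGHTS).fit(seed=0)
        assert res.weights[0] == pytest.approx(1.0)
        assert res.p_value > 0.05

    def test_source_relabelling_permutes_weights(self, two_source):
        r1 = QpAdm(two_source, "T", ["S1", "S2"], RIGHTS).fit(seed=0)
        r2 = QpAdm(two_source, "T", ["S2", "S1"], RIGHTS).fit(seed=0)
        assert r1.weights[0] == pytest.approx(r2.weights[1], abs=1e-9)
        assert r1.weights[1] == pytest.approx(r2.weights[0], abs=1e-9)

    def test_k1_reduces_to_cladality_test(self, two_source):
        res = QpAdm(two_source, "T", ["S1"], RIGHTS).fit(seed=0)
        mat = build_f4_matrix(allele_freqs(two_source), ["T", "S1"], RIGHTS)
        chi2, dof, p = qpwave_rank(mat, 0, seed=0)
        assert res.chi2 == pytest.approx(chi2)
        assert res.dof == dof == len(RIGHTS) - 1
        assert res.p_value == pytest.approx(p)

    def test_underdetermined_rejected(self, two_source):
        with pytest.raises(ValueError, match="under-determined"):
            QpAdm(two_source, "T", ["S1", "S2"], RIGHTS[:2])

    def test_summary_mentions_everything(self, two_source):
        res = QpAdm(two_source, "T", ["S1", "S2"], RIGHTS).fit(seed=0)
        text = res.summary()
        assert "S1" in text and "p =" in text and "weights" in text


class TestModelSearch:
    def test_spurious_source_dropped(self, mapped_panel):
        gm = two_source_genotypes(mapped_panel, seed=24, extra_source=True)
        result = model_search(gm, "T", ["S1", "S2", "S3"],
                              [("OG1", RIGHTS)], seed=0)
        assert result.found
        assert set(result.selected.sources) == {"S1", "S2"}
        assert len(result.ledger) >= 2

    def test_identical_outgroup_sets_order_invariant(self, two_source):
        sets_a = [("OG1", RIGHTS), ("OG2", RIGHTS)]
        sets_b = [("OG2", RIGHTS), ("OG1", RIGHTS)]
        ra = model_search(two_source, "T", ["S1", "S2"], sets_a, seed=0)
        rb = model_search(two_source, "T", ["S1", "S2"], sets_b, seed=0)
        assert np.allclose(ra.selected.weights, rb.selected.weights)

    def test_minimality_prefers_single_source(self, mapped_panel):
        gm = two_source_genotypes(mapped_panel, seed=25)
        for ind in gm.individuals:
            if ind.population == "S1" and ind.id.endswith(("0", "1", "2", "3", "4")):
                ind.population = "S1b"
        # target == S1b, pool offers the equivalent S1 plus an unrelated S2
        result = model_search(gm, "S1b", ["S1", "S2"], [("OG1", RIGHTS)], seed=0)
        assert result.found
        assert result.selected.sources == ["S1"]

    def test_no_model_reports_ledger(self, two_source):
        # impossible target: model T from a single unrelated right-like source
        result = model_search(two_source, "T", ["S1"],
                              [("OG1", RIGHTS)], seed=0)
        assert not result.found
        assert len(result.ledger) == 1

    def test_empty_pool_rejected(self, two_source):
        with pytest.raises(ValueError):
            model_search(two_source, "T", [], [("OG1", RIGHTS)])
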