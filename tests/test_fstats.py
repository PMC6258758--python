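"""f3/f4 estimators, allele frequencies and the weighted block jackknife."""

import numpy as np
import pytest

from sibtrace.formats import MISSING, GenotypeMatrix, Individual
from sibtrace.fstats import (AlleleFreqTable, allele_freqs, assign_blocks,
                             block_jackknife, f3, f4)
from sibtrace.synthetic import (AdmixtureEvent, PopulationModel, default_panel,
                                simulate_freqs, simulate_genotypes)
from conftest import two_source_genotypes


def _table(pops, freq, count):
    return AlleleFreqTable(pops, np.asarray(freq, float),
                           np.asarray(count, int), panel=None)


ONE_BLOCK = np.array([0])


class TestAlleleFreqs:
    def test_single_diploid_het(self, small_panel):
        calls = np.ones((1, len(small_panel)), dtype=np.int8)
        m = GenotypeMatrix(small_panel, [Individual("i", "P")], calls)
        t = allele_freqs(m)
        assert np.all(t.freq[0] == 0.5)
        assert np.all(t.count[0] == 2)

    def test_single_pseudohaploid(self, small_panel):
        calls = np.full((1, len(small_panel)), 2, dtype=np.int8)
        m = GenotypeMatrix(small_panel,
                           [Individual("i", "P", "U", "pseudohaploid")], calls)
        t = allele_freqs(m)
        assert np.all(t.freq[0] == 1.0)
        assert np.all(t.count[0] == 1)
        assert t.all_pseudohaploid["P"]

    def test_brute_force_counting_oracle(self, small_panel):
        """Mixed diploid/pseudohaploid population vs per-site hand counting."""
        rng = np.random.default_rng(8)
        n = len(small_panel)
        inds = [Individual(f"d{i}", "P") for i in range(3)] + \
               [Individual(f"h{i}", "P", "U", "pseudohaploid") for i in range(3)]
        calls = np.zeros((6, n), dtype=np.int8)
        calls[:3] = rng.integers(0, 3, size=(3, n))
        calls[3:] = 2 * rng.integers(0, 2, size=(3, n))
        calls[rng.random((6, n)) < 0.2] = MISSING
        m = GenotypeMatrix(small_panel, inds, calls)
        t = allele_freqs(m)
        for j in rng.choice(n, 50, replace=False):
            copies = tot = 0
            for i in range(6):
                c = calls[i, j]
                if c == MISSING:
                    continue
                if i < 3:
                    copies += c
                    tot += 2
                else:
                    copies += c // 2
                    tot += 1
            assert t.count[0, j] == tot
            if tot:
                assert t.freq[0, j] == pytest.approx(copies / tot)
            else:
                assert np.isnan(t.freq[0, j])

    def test_empty_population_errors(self, small_panel):
        calls = np.ones((1, len(small_panel)), dtype=np.int8)
        m = GenotypeMatrix(small_panel, [Individual("i", "P")], calls)
        with pytest.raises(KeyError):
            allele_freqs(m, populations=["Q"])


class TestHandComputedValues:
    def test_f3_single_site(self):
        t = _table(["C", "A", "B"], [[0.5], [0.1], [0.9]], [[10], [20], [20]])
        r = f3(t, "C", "A", "B", blocks=ONE_BLOCK)
        assert r.estimate == pytest.approx((0.4) * (-0.4) - 0.25 / 9, abs=1e-12)

    def test_f4_single_site(self):
        t = _table(["A", "B", "C", "D"], [[0.8], [0.2], [0.9], [0.1]],
                   [[10]] * 4)
        r = f4(t, "A", "B", "C", "D", blocks=ONE_BLOCK)
        assert r.estimate == pytest.approx(0.48, abs=1e-12)

    def test_f4_identical_cd_zero(self):
        rng = np.random.default_rng(1)
        fr = rng.uniform(0.1, 0.9, (3, 50))
        t = _table(["A", "B", "C"], fr, np.full((3, 50), 20))
        r = f4(t, "A", "B", "C", "C", blocks=np.zeros(50, dtype=int))
        assert r.estimate == 0.0

    def test_f3_coincident_populations_zero_at_large_n(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, 100)
        big = 10**9
        t = _table(["C", "A"], np.stack([p, p]), np.full((2, 100), big))
        r = f3(t, "C", "A", "A", blocks=np.zeros(100, dtype=int))
        assert abs(r.estimate) < 1e-6


@pytest.fixture(scope="module")
def freq_table():
    rng = np.random.default_rng(3)
    fr = rng.uniform(0.05, 0.95, (4, 400))
    blocks = np.repeat(np.arange(8), 50)
    t = _table(["A", "B", "C", "D"], fr, np.full((4, 400), 30))
    return t, blocks


class TestSymmetries:
    def test_f4_antisymmetry_exact(self, freq_table):
        t, blocks = freq_table
        r = f4(t, "A", "B", "C", "D", blocks=blocks)
        r_ab = f4(t, "B", "A", "C", "D", blocks=blocks)
        r_cd = f4(t, "A", "B", "D", "C", blocks=blocks)
        assert np.array_equal(r.block_values, -r_ab.block_values)
        assert np.array_equal(r.block_values, -r_cd.block_values)
        assert r.estimate == -r_ab.estimate == -r_cd.estimate

    def test_f3_source_symmetry_exact(self, freq_table):
        t, blocks = freq_table
        a = f3(t, "A", "B", "C", blocks=blocks)
        b = f3(t, "A", "C", "B", blocks=blocks)
        assert a.estimate == b.estimate
        assert np.array_equal(a.block_values, b.block_values)

    def test_individual_order_invariance(self, mapped_panel):
        gm = two_source_genotypes(mapped_panel, seed=9)
        perm = np.random.default_rng(0).permutation(gm.n_individuals)
        gm2 = GenotypeMatrix(gm.panel, [gm.individuals[i] for i in perm],
                             gm.calls[perm])
        t1, t2 = allele_freqs(gm), allele_freqs(gm2)
        r1 = f4(t1, "S1", "S2", "R1", "R0")
        r2 = f4(t2, "S1", "S2", "R1", "R0")
        assert r1.estimate == r2.estimate
        assert r1.se == r2.se


class TestPseudohaploidCorrection:
    def test_correction_omitted_with_warning(self):
        t = AlleleFreqTable(["C", "A", "B"],
                            np.array([[0.5, 1.0], [0.1, 0.2], [0.9, 0.6]]),
                            np.array([[4, 4], [20, 20], [20, 20]]),
                            panel=None, all_pseudohaploid={"C": True})
        with pytest.warns(UserWarning, match="pseudohaploid"):
            r = f3(t, "C", "A", "B", blocks=np.array([0, 0]))
        expect = np.mean([(0.4) * (-0.4), (0.8) * (0.4)])
        assert r.estimate == pytest.approx(expect, abs=1e-12)


class TestBlockJackknife:
    def test_equal_blocks_match_textbook_delete_one(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=20)
        w = np.full(20, 7.0)
        est, se = block_jackknife(vals, w)
        # textbook delete-1 jackknife of the mean
        n = 20
        loo = (vals.sum() - vals) / (n - 1)
        var = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
        assert est == pytest.approx(vals.mean())
        assert se == pytest.approx(np.sqrt(var), rel=1e-12)

    def test_constant_blocks_zero_se(self):
        est, se = block_jackknife(np.full(10, 3.3), np.arange(1.0, 11.0))
        assert est == pytest.approx(3.3)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_single_block_flagged(self):
        est, se = block_jackknife(np.array([1.0]), np.array([5.0]))
        assert est == 1.0 and np.isnan(se)


class TestAssignBlocks:
    def test_five_cm_blocks_respect_chromosomes(self, mapped_panel):
        blocks = assign_blocks(mapped_panel, block_cm=5.0)
        # contiguous, starting at 0
        assert blocks[0] == 0
        assert np.all(np.diff(blocks) >= 0)
        boundaries = np.flatnonzero(np.diff(mapped_panel.chrom) != 0)
        for b in boundaries:
            assert blocks[b + 1] == blocks[b] + 1
        # 100 cM / 5 cM = 20 windows plus the endpoint site, per chromosome
        assert blocks.max() + 1 == 63

    def test_mapless_fallback_equal_count(self):
        panel = default_panel(1, 100, 1400, seed=0)
        panel.gpos[:] = 0.0
        blocks = assign_blocks(panel)
        counts = np.bincount(blocks)
        assert len(counts) == 700
        assert counts.min() == counts.max() == 2


class TestSimulatedAdmixtureSignal:
    def test_f3_negative_on_admixed_target(self):
        """50/50 admixture of diverged sources gives strongly negative f3."""
        model = PopulationModel(
            populations=[("A", 0.15), ("B", 0.15)],
            admixture_events=[AdmixtureEvent("C", "A", "B", 0.5, 0.0)])
        fr = simulate_freqs(model, 30_000, seed=11)
        panel = default_panel(3, 100, 10_000, seed=2)
        gm = simulate_genotypes(fr, 30, "diploid", 12, panel=panel)
        r = f3(allele_freqs(gm), "C", "A", "B")
        assert r.estimate < 0
        assert r.z < -3

    def test_f3_most_negative_at_closest_source_proxies(self):
        """Scanning candidate sources finds the pair sharing the most drift
        with the (unobserved) true mixing populations.

        Private drift on a proxy's own branch does not enter f3, so the
        informative contrast is between proxies inside the true sources'
        clades (NearA/NearB) and unrelated outsiders (FarA/FarB).
        """
        model = PopulationModel(
            populations=[("AncA", 0.08), ("AncB", 0.08),
                         ("TrueA", 0.02, "AncA"), ("NearA", 0.02, "AncA"),
                         ("TrueB", 0.02, "AncB"), ("NearB", 0.02, "AncB"),
                         ("FarA", 0.15), ("FarB", 0.15)],
            admixture_events=[AdmixtureEvent("C", "TrueA", "TrueB", 0.5, 0.0)])
        fr = simulate_freqs(model, 20_000, seed=13)
        fr = {k: v for k, v in fr.items()
              if k in ("C", "NearA", "NearB", "FarA", "FarB")}
        panel = default_panel(2, 100, 10_000, seed=2)
        gm = simulate_genotypes(fr, 30, "diploid", 14, panel=panel)
        t = allele_freqs(gm)
        results = {(a, b): f3(t, "C", a, b).estimate
                   for a in ("NearA", "FarA") for b in ("NearB", "FarB")}
        assert min(results, key=results.get) == ("NearA", "NearB")
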