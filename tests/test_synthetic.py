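"""Statistical behaviour of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import curve_fit

from sibtrace.synthetic import (AdmixtureEvent, PopulationModel, ReadSimParams,
                                default_panel, haplotypes_from_freqs,
                                simulate_admixture_haplotypes, simulate_freqs,
                                simulate_genotypes, simulate_reads)


class TestSimulateFreqs:
    def test_zero_drift_equals_ancestral(self):
        model = PopulationModel(populations=[("A", 0.0), ("B", 0.0)])
        fr = simulate_freqs(model, 100, seed=0)
        assert np.array_equal(fr["A"], fr["__ancestral__"])
        assert np.array_equal(fr["B"], fr["__ancestral__"])

    def test_alpha_one_copies_source_a(self):
        model = PopulationModel(
            populations=[("A", 0.1), ("B", 0.1)],
            admixture_events=[AdmixtureEvent("C", "A", "B", 1.0, 0.0)])
        fr = simulate_freqs(model, 100, seed=1)
        assert np.array_equal(fr["C"], fr["A"])

    def test_fst_matches_beta_expectation_oracle(self):
        """Hudson-style FST on simulated pop frequencies vs the analytic
        expectation under the Balding-Nichols Beta law.

        Oracle: with p ~ Uniform(a, b) ancestral and pA, pB independent
        Beta draws around p with drift F, E[(pA-pB)^2 | p] = 2 F p(1-p)
        and E[pA(1-pB) + pB(1-pA) | p] = 2 p(1-p); both integrate over the
        ancestral density, so the ratio of expectations is F exactly.  The
        simulated ratio-of-means estimator must land within 10%.
        """
        F = 0.1
        model = PopulationModel(populations=[("A", F), ("B", F)])
        fr = simulate_freqs(model, 50_000, seed=2)
        pa, pb = fr["A"], fr["B"]
        num = np.mean((pa - pb) ** 2)
        den = np.mean(pa * (1 - pb) + pb * (1 - pa))
        fst = num / den
        # independent quadrature of the same two expectations
        from scipy.integrate import quad
        lo, hi = 0.05, 0.95
        e_num = quad(lambda p: 2 * F * p * (1 - p) / (hi - lo), lo, hi)[0]
        e_den = quad(lambda p: 2 * p * (1 - p) / (hi - lo), lo, hi)[0]
        assert fst == pytest.approx(e_num / e_den, rel=0.10)

    def test_nested_parent_must_precede(self):
        with pytest.raises(ValueError, match="precede"):
            PopulationModel(populations=[("A", 0.1, "Z")])


class TestSimulateGenotypes:
    def test_boundary_frequencies(self):
        panel = default_panel(1, 10, 50, seed=0)
        m0 = simulate_genotypes({"p": np.zeros(50)}, 5, "diploid", 1, panel=panel)
        assert np.all(m0.calls == 0)
        m1 = simulate_genotypes({"p": np.ones(50)}, 5, "pseudohaploid", 1,
                                panel=panel)
        assert np.all(m1.calls == 2)

    def test_sample_frequency_within_binomial_ci(self):
        panel = default_panel(1, 100, 2000, seed=1)
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 2000)
        m = simulate_genotypes({"p": p}, 500, "diploid", 4, panel=panel)
        phat = m.calls.mean(axis=0) / 2.0
        bound = 3 * np.sqrt(p * (1 - p) / 1000)
        assert np.mean(np.abs(phat - p) <= bound) >= 0.99

    def test_same_seed_reproduces(self):
        panel = default_panel(1, 10, 100, seed=0)
        p = np.full(100, 0.5)
        a = simulate_genotypes({"p": p}, 10, "diploid", 7, panel=panel)
        b = simulate_genotypes({"p": p}, 10, "diploid", 7, panel=panel)
        assert np.array_equal(a.calls, b.calls)

    def test_different_seeds_statistically_indistinguishable(self):
        panel = default_panel(1, 100, 5000, seed=1)
        model = PopulationModel(populations=[("A", 0.1)])
        f1 = simulate_freqs(model, 5000, seed=10)["A"]
        f2 = simulate_freqs(model, 5000, seed=11)["A"]
        assert stats.ks_2samp(f1, f2).pvalue > 0.01


@pytest.fixture(scope="module")
def pools():
    panel = default_panel(3, 100, 1500, seed=5)
    model = PopulationModel(populations=[("A", 0.2), ("B", 0.2)])
    fr = simulate_freqs(model, len(panel), seed=6)
    pa = haplotypes_from_freqs(fr["A"], 100, panel, seed=7)
    pb = haplotypes_from_freqs(fr["B"], 100, panel, seed=8)
    return panel, pa, pb


class TestAdmixtureHaplotypes:

    def test_g0_tracts_span_chromosomes(self, pools):
        panel, pa, pb = pools
        out = simulate_admixture_haplotypes(pa, pb, 0.5, 0, 50, seed=9)
        # every haplotype is single-ancestry genome-wide before any mating
        assert np.all(out.ancestry.all(axis=1) | (~out.ancestry).any(axis=1))
        per_hap = out.ancestry.mean(axis=1)
        assert set(np.round(per_hap, 6)) <= {0.0, 1.0}

    def test_alpha_zero_is_pure_b(self, pools):
        panel, pa, pb = pools
        out = simulate_admixture_haplotypes(pa, pb, 0.0, 3, 50, seed=10)
        assert not out.ancestry.any()

    def test_ancestry_covariance_decay_rate(self):
        """Local-ancestry covariance decays as exp(-g d).

        Oracle: bin the empirical ancestry covariance by distance and fit
        A exp(-g d) + c directly with scipy; the fitted rate must be the
        simulated generation count within 15%.
        """
        g_true = 17
        panel = default_panel(3, 100, 3000, seed=5)
        model = PopulationModel(populations=[("A", 0.2), ("B", 0.2)])
        fr = simulate_freqs(model, len(panel), seed=6)
        pa = haplotypes_from_freqs(fr["A"], 150, panel, seed=7)
        pb = haplotypes_from_freqs(fr["B"], 150, panel, seed=8)
        out = simulate_admixture_haplotypes(pa, pb, 0.4, g_true, 400, seed=11)
        anc = out.ancestry.astype(float)
        n_bins = 60
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for c in np.unique(panel.chrom):
            idx = np.flatnonzero(panel.chrom == c)
            a = anc[:, idx] - anc[:, idx].mean(0)
            cov = a.T @ a / (anc.shape[0] - 1)
            d = np.abs(panel.gpos[idx][:, None] - panel.gpos[idx][None, :])
            iu = np.triu_indices(len(idx), 1)
            bins = np.minimum((d[iu] * 200).astype(int), n_bins - 1)  # 0.5 cM
            sums += np.bincount(bins, weights=cov[iu], minlength=n_bins)
            counts += np.bincount(bins, minlength=n_bins)
        a_d = sums / counts
        x = (np.arange(n_bins) + 0.5) / 200.0
        sel = (x >= 0.01) & (x <= 0.30)
        popt, _ = curve_fit(lambda d, A, g, c: A * np.exp(-g * d) + c,
                            x[sel], a_d[sel], p0=[0.2, 10.0, 0.0],
                            maxfev=10_000)
        assert popt[1] == pytest.approx(g_true, rel=0.15)


class TestSimulateReads:
    def test_no_error_no_damage_matches_genotype(self):
        panel = default_panel(1, 20, 300, seed=12)
        calls = np.full(len(panel), 2, dtype=np.int8)
        params = ReadSimParams(mean_depth=3, error_rate=0.0,
                               deamination_amplitude=0.0, seed=0)
        sites = simulate_reads(calls, panel, params, seed=13)
        index = {(int(c), int(p)): j for j, (c, p)
                 in enumerate(zip(panel.chrom, panel.ppos))}
        for site in sites:
            j = index[(site.chrom, site.ppos)]
            for o in site.observations:
                assert o.base == panel.allele1[j]

    def test_zero_depth_empty(self):
        panel = default_panel(1, 10, 50, seed=0)
        params = ReadSimParams(mean_depth=0.0, seed=0)
        assert simulate_reads(np.ones(50, np.int8), panel, params, seed=1) == []

    def test_terminal_deamination_rates(self):
        """First-position C->T frequency ~ delta0, second ~ delta0 * k."""
        from sibtrace.genotyping import damage_profile

        panel = default_panel(1, 50, 4000, seed=9)
        panel.allele1[:] = "C"
        panel.allele2[:] = "A"
        calls = np.full(len(panel), 2, dtype=np.int8)
        params = ReadSimParams(mean_depth=15, error_rate=0.001,
                               deamination_amplitude=0.3,
                               deamination_decay=0.5, read_length=10, seed=0)
        sites = simulate_reads(calls, panel, params, seed=14)
        prof = damage_profile(sites, window=5)
        for pos, expect in ((0, 0.30), (1, 0.15)):
            n = prof.n_ct5[pos]
            sigma = np.sqrt(expect * (1 - expect) / n)
            assert abs(prof.ct5[pos] - expect) < 3 * sigma + 0.001
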