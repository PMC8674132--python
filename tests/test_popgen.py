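"""Weir-Cockerham theta, empirical p-values and the FST scan."""

import math

import numpy as np
import pytest

from ighgkit import popgen, synthetic_data
from tests.conftest import make_matrix


def theta_oracle(counts1, counts2):
    """Independently coded variance-components estimator (different algebra:
    arrays and explicit intermediate sums rather than generator expressions)."""
    c = np.array([counts1, counts2], dtype=float)
    n = c.sum(axis=1)
    p = (2 * c[:, 0] + c[:, 1]) / (2 * n)
    h = c[:, 1] / n
    r = 2.0
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - 0.25 * hbar)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    cc = 0.5 * hbar
    denom = a + b + cc
    return math.nan if denom == 0 else a / denom


class TestTheta:
    def test_hand_computed_variance_components(self):
        """Frozen from the published component formulas applied by hand:
        pop1=(30,10,10), pop2=(5,10,35) gives a=0.1222449, b=0.0877551,
        c=0.1, theta=0.3943383805134955."""
        a, b, c = popgen.weir_cockerham_components((30, 10, 10), (5, 10, 35))
        assert a == pytest.approx(0.12224489795918363, abs=1e-12)
        assert b == pytest.approx(0.08775510204081638, abs=1e-12)
        assert c == pytest.approx(0.1, abs=1e-12)
        theta = popgen.weir_cockerham_theta((30, 10, 10), (5, 10, 35))
        assert theta == pytest.approx(0.3943383805134955, abs=1e-12)

    def test_complete_fixation_is_one(self):
        assert popgen.weir_cockerham_theta((10, 0, 0), (0, 0, 10)) == pytest.approx(1.0)

    def test_identical_counts_nonpositive(self):
        assert popgen.weir_cockerham_theta((30, 10, 10), (30, 10, 10)) <= 0

    def test_monomorphic_both_pops_is_nan(self):
        assert math.isnan(popgen.weir_cockerham_theta((20, 0, 0), (15, 0, 0)))

    def test_symmetry_population_and_allele_swap(self):
        c1, c2 = (12, 6, 2), (3, 9, 8)
        t = popgen.weir_cockerham_theta(c1, c2)
        assert popgen.weir_cockerham_theta(c2, c1) == pytest.approx(t, abs=1e-12)
        assert popgen.weir_cockerham_theta(c1[::-1], c2[::-1]) == pytest.approx(
            t, abs=1e-12
        )

    def test_exhaustive_small_grid_matches_oracle(self):
        """All genotype-count tables with <= 12 individuals per population."""
        tables = [
            (a, b, n - a - b)
            for n in range(1, 13)
            for a in range(n + 1)
            for b in range(n - a + 1)
        ]
        for c1 in tables:
            for c2 in tables:
                if sum(c1) == 1 and sum(c2) == 1:
                    continue  # nbar = 1: components genuinely undefined
                t = popgen.weir_cockerham_theta(c1, c2)
                o = theta_oracle(c1, c2)
                if math.isnan(o):
                    assert math.isnan(t)
                else:
                    assert t == pytest.approx(o, abs=1e-12), (c1, c2)


class TestEmpiricalP:
    def test_observed_above_all_null(self):
        null = list(np.linspace(0, 0.5, 1000))
        assert popgen.empirical_p(0.9, null) == pytest.approx(1 / 1001)

    def test_observed_below_all_null(self):
        null = list(np.linspace(0, 0.5, 1000))
        assert popgen.empirical_p(-1.0, null) == 1.0

    def test_observed_at_median_by_direct_count(self):
        rng = np.random.default_rng(7)
        null = sorted(rng.normal(size=1001))
        obs = null[500]  # the median of an odd-length null
        expect = (1 + sum(1 for t in null if t >= obs)) / (1 + len(null))
        assert popgen.empirical_p(obs, null) == pytest.approx(expect)
        assert abs(popgen.empirical_p(obs, null) - 0.5) < 0.01

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            popgen.empirical_p(0.5, [])


class TestBnCalibration:
    def test_f0_mean_theta_near_zero_and_null_tail(self):
        sim = synthetic_data.simulate_bn_pair(500, 0.0, 200, seed=21)
        pairs = list(zip(sim.counts1, sim.counts2))
        assert abs(popgen.multi_locus_theta(pairs)) < 0.02
        thetas = np.array([popgen.weir_cockerham_theta(a, b) for a, b in pairs])
        thetas = thetas[~np.isnan(thetas)]
        q95 = np.quantile(thetas, 0.95)
        frac = (thetas > q95).mean()
        assert 0.03 < frac < 0.07  # ~5% exceed the null 95th percentile

    def test_f06_combined_theta_within_005(self):
        sim = synthetic_data.simulate_bn_pair(500, 0.6, 200, seed=22)
        t = popgen.multi_locus_theta(zip(sim.counts1, sim.counts2))
        assert t == pytest.approx(0.6, abs=0.05)

    def test_estimator_consistency_in_n(self):
        """Per-sample-size convergence of the combined estimator.

        At a fixed number of loci the distance to F saturates at the
        frequency-sampling floor (the realized FST of the drawn population
        frequencies differs from F by ~1/sqrt(loci)), so convergence in n is
        measured against the large-n limit under the same frequency draws
        (common random numbers) and must shrink monotonically through
        n = 20, 80, 320.
        """
        errs = []
        for n in (20, 80, 320):
            ds = []
            for r in range(12):
                s = synthetic_data.simulate_bn_pair(400, 0.3, n, seed=3000 + r)
                ref = synthetic_data.simulate_bn_pair(400, 0.3, 4000, seed=3000 + r)
                t = popgen.multi_locus_theta(zip(s.counts1, s.counts2))
                tref = popgen.multi_locus_theta(zip(ref.counts1, ref.counts2))
                ds.append(abs(t - tref))
            errs.append(np.mean(ds))
        assert errs[0] > errs[1] > errs[2]


class TestFstScan:
    def _matrix(self, toy_snps):
        rows = [["A/A", "T/T"]] * 6 + [["A/G", "T/G"]] * 2
        rows += [["G/G", "G/G"]] * 6 + [["A/G", "T/G"]] * 2
        pops = ["P1"] * 8 + ["P2"] * 8
        return make_matrix(toy_snps, rows, population=pops)

    def test_bonferroni_m_is_snps_times_pairs(self, toy_snps):
        m = self._matrix(toy_snps)
        null = {("P1", "P2"): np.linspace(0, 0.2, 100)}
        res = popgen.fst_scan(m, [toy_snps[0].snp_id], [("P1", "P2")], null)
        assert res[0].n_tests == 1
        # one SNP, three pairs -> m = 3
        null3 = {p: np.linspace(0, 0.2, 100)
                 for p in [("P1", "P2"), ("P1", "P1"), ("P2", "P2")]}
        res3 = popgen.fst_scan(
            m, [toy_snps[0].snp_id],
            [("P1", "P2"), ("P1", "P1"), ("P2", "P2")], null3,
        )
        assert all(r.n_tests == 3 for r in res3)
        assert res3[0].p_bonferroni == pytest.approx(min(1.0, res3[0].empirical_p * 3))

    def test_missing_null_is_error(self, toy_snps):
        m = self._matrix(toy_snps)
        with pytest.raises(popgen.NullSourceError):
            popgen.fst_scan(m, [toy_snps[0].snp_id], [("P1", "P2")], {})

    def test_significance_against_low_null(self, toy_snps):
        m = self._matrix(toy_snps)
        null = {("P1", "P2"): np.full(1000, 0.01)}
        res = popgen.fst_scan(m, [s.snp_id for s in toy_snps], [("P1", "P2")], null)
        assert all(r.theta > 0.3 for r in res)
        assert all(r.significant for r in res)

    def test_trimorphic_site_minor_vs_rest(self, models, panel):
        by_id = {s.snp_id: s for s in panel}
        tri = by_id["G2_CH2_231"]  # V/L/M trimorphism, alleles G/C/A
        rows = [["G/G"]] * 5 + [["G/C"]] * 3 + [["C/C"]] * 2 + [["G/A"]] * 1
        pops = ["P1"] * 6 + ["P2"] * 5
        m = make_matrix([tri], rows, population=pops)
        counts = popgen.pair_genotype_counts(m, tri, ("P1", "P2"))
        # global minor allele is A (1 copy): decomposition is A vs rest
        assert counts[0] == (6, 0, 0)
        assert counts[1] == (4, 1, 0)
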