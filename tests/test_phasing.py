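"""EM haplotype inference: closed forms, likelihood oracle, invariants."""

import numpy as np
import pytest

from ighgkit import phasing, qc, synthetic_data
from tests.conftest import make_matrix


def two_locus_matrix(toy_snps):
    """4 x AB/AB, 4 x ab/ab, 2 x double heterozygotes.

    Locus alleles: A<->'A', a<->'G' at Eu 214; B<->'T', b<->'G' at Eu 356.
    """
    rows = (
        [["A/A", "T/T"]] * 4
        + [["G/G", "G/G"]] * 4
        + [["A/G", "T/G"]] * 2
    )
    return make_matrix(toy_snps, rows)


class TestEmCore:
    def test_single_locus_equals_allele_freqs(self, toy_snps):
        m = make_matrix(toy_snps[:1], [["A/A"], ["A/G"], ["A/G"], ["G/G"]])
        fs = phasing.em_haplotypes(m, toy_snps[:1], seed=0)
        expected = qc.allele_freqs(m, toy_snps[0])
        for allele, f in expected.items():
            assert fs.haplotypes[allele] == pytest.approx(f, abs=1e-9)

    def test_all_homozygous_cohort_is_direct_count(self, toy_snps):
        m = make_matrix(toy_snps, [["A/A", "T/T"]] * 3 + [["G/G", "G/G"]])
        fs = phasing.em_haplotypes(m, toy_snps, seed=0)
        assert fs.haplotypes["AT"] == pytest.approx(0.75, abs=1e-9)
        assert fs.haplotypes["GG"] == pytest.approx(0.25, abs=1e-9)

    def test_two_locus_matches_grid_search_oracle(self, toy_snps):
        """Frozen oracle: dense grid search over the 3-simplex of {AB,ab,Ab,aB}
        puts the global maximum at {AB: 0.5, ab: 0.5} (loglik -12.47665)."""
        m = two_locus_matrix(toy_snps)
        fs = phasing.em_haplotypes(m, toy_snps, seed=0)
        assert fs.haplotypes["AT"] == pytest.approx(0.5, abs=1e-6)
        assert fs.haplotypes["GG"] == pytest.approx(0.5, abs=1e-6)
        assert fs.haplotypes.get("AG", 0.0) == pytest.approx(0.0, abs=1e-6)
        assert fs.loglik == pytest.approx(-12.476649250079015, abs=1e-6)

    def test_loglik_nondecreasing_and_freqs_sum_to_one(self, toy_snps):
        rng = np.random.default_rng(1234)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            rows = []
            for _s in range(n):
                g1 = "/".join(sorted(rng.choice(["A", "G"], 2)))
                g2 = "/".join(sorted(rng.choice(["T", "G"], 2)))
                rows.append([g1, g2])
            m = make_matrix(toy_snps, rows)
            fs = phasing.em_haplotypes(m, toy_snps, seed=int(rng.integers(1 << 30)))
            diffs = np.diff(fs.trace)
            assert (diffs >= -1e-8).all()
            assert sum(fs.haplotypes.values()) == pytest.approx(1.0, abs=1e-9)

    def test_marginals_reproduce_allele_freqs(self, toy_snps):
        m = two_locus_matrix(toy_snps)
        fs = phasing.em_haplotypes(m, toy_snps, seed=0)
        for i, snp in enumerate(toy_snps):
            expected = qc.allele_freqs(m, snp)
            marg = fs.marginal(i)
            for allele, f in expected.items():
                assert marg.get(allele, 0.0) == pytest.approx(f, abs=1e-6)

    def test_missing_expansion_over_observed_alleles(self, toy_snps):
        m = make_matrix(toy_snps[:1], [["A/A"], [None], ["A/G"]])
        fs = phasing.em_haplotypes(m, toy_snps[:1], seed=0)
        assert set(fs.haplotypes) == {"A", "G"}

    def test_locus_bound_raises_expansion_error(self, panel):
        many = [s for s in panel if s.gene == "IGHG3" and s.is_nonsynonymous]
        m = make_matrix(many, [[f"{s.ref_base}/{s.ref_base}" for s in many]])
        with pytest.raises(phasing.EMExpansionError, match="partition-ligation"):
            phasing.em_haplotypes(m, many)


class TestDiplotypes:
    def test_fully_homozygous_unique_pair(self, toy_snps):
        m = make_matrix(toy_snps, [["A/A", "T/T"]])
        fs = phasing.em_haplotypes(m, toy_snps, seed=0)
        [d] = phasing.assign_diplotypes(fs, m)
        assert d.haplotypes == ("AT", "AT")
        assert d.posterior == pytest.approx(1.0)

    def test_single_snp_het(self, toy_snps):
        m = make_matrix(toy_snps[:1], [["A/G"]])
        fs = phasing.em_haplotypes(m, toy_snps[:1], seed=0)
        [d] = phasing.assign_diplotypes(fs, m)
        assert d.haplotypes == ("A", "G")
        assert d.posterior == pytest.approx(1.0)

    def test_double_het_resolved_by_nonzero_frequencies(self, toy_snps):
        m = two_locus_matrix(toy_snps)
        fs = phasing.em_haplotypes(m, toy_snps, seed=0)
        dips = phasing.assign_diplotypes(fs, m)
        double_hets = [d for d in dips if d.sample in {"s9", "s10"}]
        for d in double_hets:
            assert d.haplotypes == ("AT", "GG")
            assert d.posterior == pytest.approx(1.0, abs=1e-6)

    def test_pair_consistent_with_observed_genotypes(self, toy_snps):
        m = two_locus_matrix(toy_snps)
        fs = phasing.em_haplotypes(m, toy_snps, seed=0)
        for d in phasing.assign_diplotypes(fs, m):
            call_pairs = [m.call(d.sample, s.snp_id) for s in toy_snps]
            for i, call in enumerate(call_pairs):
                got = tuple(sorted((d.haplotypes[0][i], d.haplotypes[1][i])))
                assert got == call


class TestMultigene:
    def test_single_gene_degenerate_partition(self, toy_snps):
        m = two_locus_matrix(toy_snps)
        full = phasing.em_haplotypes(m, toy_snps, seed=0)
        pl = phasing.multigene_haplotypes(
            m, toy_snps, threshold=0.0, seed=0, require_nonsynonymous=False
        )
        for hap, f in full.haplotypes.items():
            assert pl.haplotypes.get(hap, 0.0) == pytest.approx(f, abs=1e-9)

    def test_threshold_one_empties_report(self, toy_snps):
        m = two_locus_matrix(toy_snps)
        pl = phasing.multigene_haplotypes(
            m, toy_snps, threshold=1.0, seed=0, require_nonsynonymous=False
        )
        assert pl.haplotypes == {}

    def test_synonymous_loci_rejected_by_default(self, panel):
        syn = [s for s in panel if not s.is_nonsynonymous][:2]
        m = make_matrix(syn, [[f"{s.ref_base}/{s.ref_base}" for s in syn]])
        with pytest.raises(ValueError, match="non-synonymous"):
            phasing.multigene_haplotypes(m, syn)

    def test_four_haplotype_recovery_within_3se(self, models, panel):
        """Three-gene pools at (0.4, 0.3, 0.2, 0.1), N=200: partition-ligation
        recovers every haplotype within 3 binomial standard errors."""
        pool = [
            synthetic_data.PoolHaplotype("IGHG3*01", 4, "IGHG1*02", "IGHG2*03", 0.4),
            synthetic_data.PoolHaplotype("IGHG3*11", 4, "IGHG1*03", "IGHG2*02", 0.3),
            synthetic_data.PoolHaplotype("IGHG3*14", 4, "IGHG1*02", "IGHG2*06", 0.2),
            synthetic_data.PoolHaplotype("IGHG3*03", 3, "IGHG1*03", "IGHG2*03", 0.1),
        ]
        cfg = synthetic_data.SimConfig(
            seed=2024, pools={"P": pool}, cohorts={"P": (200, {"P": 1.0})}
        )
        matrix, _h, truth = synthetic_data.simulate_cohort(cfg, models, panel)
        loci = [s for s in matrix.snps if s.is_nonsynonymous and s.callable]
        fs = phasing.multigene_haplotypes(
            matrix, loci, population="P", threshold=0.01, seed=5, n_restarts=3
        )
        expander = synthetic_data.HaplotypeExpander(loci)
        assert len(fs.haplotypes) == 4
        for hap in pool:
            nt = expander.expand(hap.names)
            se = np.sqrt(hap.freq * (1 - hap.freq) / 400)
            assert fs.haplotypes[nt] == pytest.approx(hap.freq, abs=3 * se)

    def test_recovery_error_shrinks_with_n(self, models, panel):
        """Mean absolute frequency error decreases monotonically with N."""
        pool = [
            synthetic_data.PoolHaplotype("IGHG3*01", 4, "IGHG1*02", "IGHG2*03", 0.5),
            synthetic_data.PoolHaplotype("IGHG3*11", 4, "IGHG1*03", "IGHG2*02", 0.3),
            synthetic_data.PoolHaplotype("IGHG3*14", 4, "IGHG1*02", "IGHG2*06", 0.2),
        ]
        errors = []
        for n in (50, 200, 1000):
            reps = []
            for rep in range(5):
                cfg = synthetic_data.SimConfig(
                    seed=100 * n + rep, pools={"P": pool},
                    cohorts={"P": (n, {"P": 1.0})},
                )
                matrix, _h, _t = synthetic_data.simulate_cohort(cfg, models, panel)
                loci = [s for s in matrix.snps if s.is_nonsynonymous and s.callable]
                fs = phasing.multigene_haplotypes(
                    matrix, loci, population="P", threshold=0.0, seed=3, n_restarts=2
                )
                expander = synthetic_data.HaplotypeExpander(loci)
                reps.append(
                    np.mean(
                        [abs(fs.haplotypes.get(expander.expand(h.names), 0.0) - h.freq)
                         for h in pool]
                    )
                )
            errors.append(np.mean(reps))
        assert errors[0] > errors[1] > errors[2]
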