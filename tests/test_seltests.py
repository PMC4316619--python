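import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from tlrpopgen import seltests
from tlrpopgen.exceptions import UsageError

from conftest import make_alignment


def oracle_fisher_two_sided(a, b, c, d):
    """Exhaustive hypergeometric enumeration over all tables with the
    observed margins (two-sided: sum of point probabilities <= observed)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = hypergeom.pmf(k, n, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestMKTable:
    def test_manual_enumeration_example(self):
        # ingroup TTTGGA x3 + TTCGGA; outgroup TTTGGG:
        # site 2 polymorphic synonymous (Phe), site 5 fixed synonymous (Gly)
        aln = make_alignment(
            ["TTTGGA", "TTTGGA", "TTTGGA", "TTCGGA"], "TTTGGG", coding=True
        )
        t = seltests.build_mk_table(aln)
        assert (t.Pn, t.Ps, t.Dn, t.Ds) == (0, 1, 0, 1)

    def test_monomorphic_identical_to_outgroup(self):
        aln = make_alignment(["TTTGGA"] * 3, "TTTGGA", coding=True)
        t = seltests.build_mk_table(aln)
        assert (t.Pn, t.Ps, t.Dn, t.Ds) == (0, 0, 0, 0)

    def test_fixed_nonsynonymous(self):
        aln = make_alignment(["GAT", "GAT"], "TAT", coding=True)  # Asp vs Tyr
        t = seltests.build_mk_table(aln)
        assert (t.Pn, t.Ps, t.Dn, t.Ds) == (0, 0, 1, 0)

    def test_polymorphic_and_different_counts_as_polymorphic(self):
        # site segregates T/C in ingroup while outgroup has G: polymorphic
        aln = make_alignment(["TTT", "TTC"], "TTG", coding=True)
        t = seltests.build_mk_table(aln)
        assert t.Ps == 1 and t.Ds == 0


class TestFisherExact:
    def test_frozen_example(self):
        p, testable = seltests.fisher_exact_2x2(seltests.MKCounts(2, 8, 8, 2))
        assert testable
        assert p == pytest.approx(0.02301, abs=2e-5)

    def test_balanced_table(self):
        p, _ = seltests.fisher_exact_2x2(seltests.MKCounts(5, 5, 5, 5))
        assert p == 1.0

    def test_zero_margin_convention(self):
        p, testable = seltests.fisher_exact_2x2(seltests.MKCounts(0, 0, 3, 4))
        assert p == 1.0 and not testable

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 15, size=4)
            t = seltests.MKCounts(int(a), int(b), int(c), int(d))
            p, testable = seltests.fisher_exact_2x2(t)
            if testable:
                assert p == pytest.approx(
                    oracle_fisher_two_sided(a, c, b, d), abs=1e-9
                )


class TestNeutralityIndex:
    def test_arithmetic(self):
        assert seltests.neutrality_index(seltests.MKCounts(2, 8, 8, 2)) == \
            pytest.approx(0.0625)

    def test_neutral_expectation(self):
        assert seltests.neutrality_index(seltests.MKCounts(3, 6, 4, 8)) == \
            pytest.approx(1.0)

    def test_undefined_cases(self):
        assert math.isnan(seltests.neutrality_index(seltests.MKCounts(2, 0, 8, 2)))
        assert math.isnan(seltests.neutrality_index(seltests.MKCounts(2, 8, 0, 2)))


class TestHKA:
    def test_single_locus_saturated(self):
        fit = seltests.hka_statistic([seltests.HKALocus("a", 10, 20, 500, 10)])
        assert fit.X2 == pytest.approx(0.0, abs=1e-10)

    def test_perfect_fit_two_loci(self):
        from tlrpopgen.popstats import harmonic

        # S and D exactly at their expectations for theta in ratio 1:2
        T = 5.0
        a = harmonic(10)
        loci = [
            seltests.HKALocus("a", 2 * a, 2 * (T + 1), 500, 10),
            seltests.HKALocus("b", 4 * a, 4 * (T + 1), 1000, 10),
        ]
        fit = seltests.hka_statistic(loci)
        assert fit.X2 == pytest.approx(0.0, abs=1e-8)
        assert fit.T == pytest.approx(T, rel=1e-6)

    def test_outlier_locus_flagged_by_leave_one_out(self):
        from tlrpopgen.popstats import harmonic

        T = 5.0
        a = harmonic(10)
        loci = [
            seltests.HKALocus("a", 3 * a, 3 * (T + 1), 500, 10),
            seltests.HKALocus("b", 3 * a, 3 * (T + 1), 500, 10),
            seltests.HKALocus("c", 3 * a, 6 * (T + 1), 500, 10),  # D doubled
        ]
        fit = seltests.hka_statistic(loci)
        assert fit.X2 > 0
        assert max(fit.contributions, key=fit.contributions.get) == "c"
        # diagnostic consistency: contributions roughly recover X2
        assert sum(fit.contributions.values()) > 0

    def test_null_simulation_pvalue_not_extreme(self, rng):
        """A dataset drawn from the fitted neutral model should not give a
        small p."""
        # simulate observed data under the null, then test it
        loci_cfg = [("a", 16, 3.0), ("b", 16, 5.0), ("c", 16, 2.0)]
        obs = []
        T = 4.0
        for lid, n, theta in loci_cfg:
            S, D = seltests._simulate_locus_SD(n, theta, T, rng)
            obs.append(seltests.HKALocus(lid, S, D, 500, n))
        fit = seltests.hka_statistic(obs)
        p, warned = seltests.hka_simulation_pvalue(obs, fit, nreps=300, rng=rng)
        assert not warned
        assert p > 0.01

    def test_inflated_divergence_detected(self, rng):
        from tlrpopgen.popstats import harmonic

        T = 4.0
        a = harmonic(16)
        loci = [
            seltests.HKALocus("a", 3 * a, 3 * (T + 1), 500, 16),
            seltests.HKALocus("b", 3 * a, 3 * (T + 1), 500, 16),
            seltests.HKALocus("c", 3 * a, 15 * (T + 1), 500, 16),  # 5x divergence
        ]
        fit = seltests.hka_statistic(loci)
        p, _ = seltests.hka_simulation_pvalue(loci, fit, nreps=300, rng=rng)
        assert p < 0.05

    def test_input_from_alignments(self, small_study):
        _, pairs, spec = small_study
        alns = [a for a, t in pairs if a.coding]
        records = seltests.hka_input_from_alignments(alns, lineage="Lm")
        assert len(records) == len(alns)
        for r in records:
            assert r.n == spec.n_lineage_a
            assert r.D > 0  # outgroup divergence present
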