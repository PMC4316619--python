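import math

import numpy as np
import pytest

from tlrpopgen import coalescent as co
from tlrpopgen.exceptions import ModelError, UsageError
from tlrpopgen.popstats import harmonic, tajimas_d_from_sfs


def simulate_many(model, n, reps, rng, rho=0.0, theta=0.0):
    args, tables = [], []
    for _ in range(reps):
        arg = co.simulate_genealogy((n,), model, rho, rng)
        args.append(arg)
        if theta:
            tables.append(co.drop_mutations(arg, theta, 0.0, rng))
    return args, tables


class TestGenealogyMoments:
    def test_pairwise_tmrca(self, rng):
        args, _ = simulate_many(co.constant_model(), 2, 4000, rng)
        t = [a.tmrca() for a in args]
        se = np.std(t) / math.sqrt(len(t))
        assert abs(np.mean(t) - 1.0) < 3 * se

    def test_total_branch_length(self, rng):
        args, _ = simulate_many(co.constant_model(), 10, 4000, rng)
        tot = [a.total_branch_length() for a in args]
        expected = 2 * harmonic(10)
        se = np.std(tot) / math.sqrt(len(tot))
        assert abs(np.mean(tot) - expected) < 3 * se

    def test_recent_crash_shortens_tmrca(self):
        # matched seeds: same random streams under both models
        t_const, t_crash = [], []
        crash = co.crash_recovery_model(0.1, crash_start=1e-9, crash_duration=0.5)
        for seed in range(800):
            t_const.append(
                co.simulate_genealogy((6,), co.constant_model(), 0.0,
                                      np.random.default_rng(seed)).tmrca()
            )
            t_crash.append(
                co.simulate_genealogy((6,), crash, 0.0,
                                      np.random.default_rng(seed)).tmrca()
            )
        assert np.mean(t_crash) < np.mean(t_const)

    def test_noncoalescing_model_is_error(self):
        # two populations, no migration, no join: can never fully coalesce
        model = co.DemographicModel(populations=(1.0, 1.0))
        with pytest.raises(ModelError):
            co.simulate_genealogy((2, 2), model, 0.0, np.random.default_rng(0))


class TestMutations:
    def test_zero_rate_gives_empty_table(self, rng):
        arg = co.simulate_genealogy((5,), co.constant_model(), 0.0, rng)
        muts = co.drop_mutations(arg, 0.0, 0.0, rng)
        assert len(muts) == 0

    def test_watterson_expectation(self, rng):
        _, tables = simulate_many(co.constant_model(), 10, 6000, rng, theta=1.0)
        S = [len(t) for t in tables]
        expected = harmonic(10)  # theta * a1 = 2.829
        se = np.std(S) / math.sqrt(len(S))
        assert abs(np.mean(S) - expected) < 3 * se

    def test_class_labels_bernoulli(self, rng):
        arg = co.simulate_genealogy((20,), co.constant_model(), 0.0, rng)
        muts = co.drop_mutations(arg, 50.0, 50.0, rng)
        frac = muts.is_synonymous.mean()
        assert 0.35 < frac < 0.65

    def test_recombination_reduces_pi_variance(self, rng):
        def pi_values(rho):
            out = []
            for _ in range(1500):
                arg = co.simulate_genealogy((10,), co.constant_model(), rho, rng)
                muts = co.drop_mutations(arg, 5.0, 0.0, rng)
                c = muts.derived_counts()
                out.append(np.sum(2.0 * c * (10 - c) / (10 * 9)))
            return np.asarray(out)

        assert pi_values(20.0).var() < pi_values(0.0).var()

    def test_sfs_counts_match_marginal_trees(self, rng):
        # derived counts recorded on edges equal a fresh traversal count
        arg = co.simulate_genealogy((8,), co.constant_model(), 3.0, rng)
        muts = co.drop_mutations(arg, 5.0, 0.0, rng)
        for i in range(len(muts)):
            child = int(arg.edge_child[muts.edge_index[i]])
            carriers = arg.samples_below(child, float(muts.positions[i]))
            assert len(carriers) == muts.counts[i].sum()


class TestDeterminism:
    def test_bit_identical_given_seed(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            arg = co.simulate_genealogy((12,), co.constant_model(), 2.0, rng)
            muts = co.drop_mutations(arg, 4.0, 1.0, rng)
            return (arg.node_times.tobytes(), muts.positions.tobytes(),
                    muts.counts.tobytes())

        assert run(7) == run(7)
        assert run(7) != run(8)


class TestNullDistributions:
    def test_null_distribution_mean_matches_msprime(self, rng):
        """Cross-simulator oracle: Tajima's D null mean under a constant-size
        model agrees between this engine and msprime at identical settings."""
        import msprime

        n, theta, reps = 15, 5.0, 2500
        config = co.SimulationConfig(n_samples=(n,), theta_syn=theta, nreps=reps)
        null = co.simulate_null_distribution(
            "D", config, co.constant_model(), rng=rng
        )
        ds = []
        seed_rng = np.random.default_rng(99)
        # ploidy 1 with population_size 1 puts msprime on the same clock
        # (pairwise coalescence rate 1, mutation rate theta/2 per branch unit)
        for ts in msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1.0, num_replicates=reps,
            random_seed=99,
        ):
            mts = msprime.sim_mutations(
                ts, rate=theta / 2.0,
                random_seed=int(seed_rng.integers(1, 2**31)),
                discrete_genome=False,
            )
            sfs = mts.allele_frequency_spectrum(
                polarised=True, span_normalise=False
            )[1:n]
            d = tajimas_d_from_sfs(n, sfs)
            if not math.isnan(d):
                ds.append(d)
        se = math.sqrt(
            np.var(null.values) / len(null.values) + np.var(ds) / len(ds)
        )
        assert abs(np.mean(null.values) - np.mean(ds)) < 3 * se

    def test_h_mean_near_zero_under_neutrality(self, rng):
        config = co.SimulationConfig(n_samples=(12,), theta_syn=4.0, nreps=3000)
        null = co.simulate_null_distribution("H", config, co.constant_model(), rng=rng)
        se = np.std(null.values) / math.sqrt(len(null.values))
        assert abs(np.mean(null.values)) < 3 * se

    def test_undefined_replicates_reported(self, rng):
        config = co.SimulationConfig(n_samples=(5,), theta_syn=0.1, nreps=300)
        null = co.simulate_null_distribution("D", config, co.constant_model(), rng=rng)
        assert null.n_undefined > 0

    def test_sweep_merge_depresses_h(self, rng):
        config = co.SimulationConfig(n_samples=(20,), theta_syn=6.0, nreps=800)
        base = co.constant_model()
        null = co.simulate_null_distribution("H", config, base, rng=rng)
        swept = co.simulate_null_distribution(
            "H", config, co.with_sweep(base, 0, 0.9, 0.05), rng=rng
        )
        assert np.mean(swept.values) < np.mean(null.values) - 1.0


class TestEmpiricalPvalue:
    def make_null(self, values):
        return co.NullDistribution(statistic="D", values=np.asarray(values, float))

    def test_observed_below_all(self):
        null = self.make_null(np.arange(999) + 1.0)
        assert co.empirical_pvalue(0.0, null, co.ONE_SIDED_LOW) == pytest.approx(1 / 1000)

    def test_observed_above_all(self):
        null = self.make_null(np.arange(999) + 1.0)
        assert co.empirical_pvalue(1e9, null, co.ONE_SIDED_LOW) == 1.0

    def test_two_sided_at_median(self):
        null = self.make_null(np.linspace(-1, 1, 999))
        assert co.empirical_pvalue(0.0, null, co.TWO_SIDED) == 1.0

    def test_too_few_values_refused(self):
        null = self.make_null(np.arange(50))
        with pytest.raises(UsageError):
            co.empirical_pvalue(0.0, null, co.TWO_SIDED)


class TestSerialization:
    def test_model_json_roundtrip(self):
        model = co.two_population_split_model(2.0, sizes=(1.0, 0.5),
                                              migration=0.3)
        back = co.DemographicModel.from_json(model.to_json())
        assert back == model

    def test_ms_dialect_output(self, tmp_path, rng):
        arg = co.simulate_genealogy((6,), co.constant_model(), 0.0, rng)
        muts = co.drop_mutations(arg, 3.0, 0.0, rng)
        out = tmp_path / "out.ms"
        co.write_ms(out, [muts], 6)
        text = out.read_text()
        assert "//" in text and "segsites:" in text
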