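import numpy as np
import pandas as pd
import pytest

from evotrap import (ExperimentDesign, Genotype, ParameterSet, SimRng,
                     run_generation, run_grid, run_replicate)
from evotrap.engine import GenerationState
from evotrap.host_dynamics import (HostIndividual, KILLED_REPRODUCTIVE,
                                   initialize_hosts, sample_maturation_times,
                                   spawn_offspring)

from conftest import scaled_params


def _fresh_cohorts(p: ParameterSet, rng: SimRng):
    c1 = spawn_offspring(round(p.K1 * np.log(p.r1)), p, 1, rng)
    c2 = spawn_offspring(round(p.K2 * np.log(p.r2)), p, 2, rng)
    return (sample_maturation_times(c1, p.tau_dH1, rng, 1, 0),
            sample_maturation_times(c2, p.tau_dH2, rng, 2, p.n1))


class TestRunGeneration:
    def test_minimal_kill_path(self):
        # one parasitoid, one host in a one-patch-per-species world; the host
        # is vulnerable essentially forever, so the first egg decides
        p = ParameterSet(n1=1, n2=1, K1=10.0, K2=10.0, P0=1, mu_q=0.0, mu_S=0.0)
        rng = SimRng(23)
        host = HostIndividual(1, 0, maturation_time=1e9)
        state = GenerationState([host], [], [Genotype(0.0, 1)], p, rng)
        s1, s2, offspring, tally = run_generation(state)
        assert host.fate == KILLED_REPRODUCTIVE
        assert (s1, s2) == (0, 0)
        assert offspring == [Genotype(0.0, 1)]
        assert tally.emerged[0] == 1 and tally.eggs_laid[0] >= 1

    @pytest.mark.parametrize("scenario", [1, 2])
    def test_every_host_resolves_into_one_bucket(self, scenario):
        p = scaled_params(scenario=scenario, mu_q=0.001)
        rng = SimRng(29)
        hosts1, hosts2 = _fresh_cohorts(p, rng)
        spawned = (len(hosts1), len(hosts2))
        state = GenerationState(hosts1, hosts2, [Genotype(0.0, 1)] * p.P0, p, rng)
        s1, s2, offspring, tally = run_generation(state)
        for i, n in enumerate(spawned):
            killed = tally.reproductive_kills[i] + tally.nonreproductive_kills[i]
            assert killed + tally.survived[i] == n
        assert (s1, s2) == (tally.survived[0], tally.survived[1])
        # solitary development: one emergence per reproductive kill
        assert tally.emerged == tally.reproductive_kills
        if scenario == 1:
            assert tally.nonreproductive_kills == [0, 0]
        assert len(offspring) == sum(tally.emerged)
        assert len(offspring) <= sum(tally.reproductive_kills) + sum(tally.nonreproductive_kills)

    def test_fixed_specialist_population_table_semantics(self):
        # all-S=1, q=0 parasitoids: scenario 1 cannot touch host 2 at all;
        # scenario 2 kills host 2 only non-reproductively
        for scenario, expect_h2_kills in ((1, False), (2, True)):
            p = scaled_params(scenario=scenario, mu_q=0.0, mu_S=0.0, seed=31)
            rng = SimRng(31)
            hosts1, hosts2 = _fresh_cohorts(p, rng)
            state = GenerationState(hosts1, hosts2, [Genotype(0.0, 1)] * p.P0, p, rng)
            *_, tally = run_generation(state)
            assert tally.reproductive_kills[1] == 0
            assert tally.eggs_laid[1] > 0  # host 2 is attacked either way
            if expect_h2_kills:
                assert tally.nonreproductive_kills[1] > 0
            else:
                assert tally.nonreproductive_kills[1] == 0

    def test_matured_host_removal_switch(self):
        p = scaled_params(mu_q=0.0, mu_S=0.0)
        rng = SimRng(37)
        hosts1, hosts2 = _fresh_cohorts(p, rng)
        state = GenerationState(hosts1, hosts2, [Genotype(0.0, 1)] * p.P0, p, rng,
                                remove_matured_hosts=True)
        s1, s2, _, tally = run_generation(state)
        assert tally.reproductive_kills[0] + tally.survived[0] == len(hosts1)
        assert s1 > 0


class TestRunReplicate:
    def test_single_generation_single_record(self):
        res = run_replicate(scaled_params(generations=1))
        assert len(res.records) == 1
        assert res.records[0].generation == 1

    def test_parasitoid_free_dynamics(self):
        res = run_replicate(scaled_params(P0=0, generations=5))
        assert all(r.P == 0 for r in res.records)
        assert all(np.isnan(r.freq_S1) for r in res.records)
        assert all(r.H1 > 0 and r.H2 > 0 for r in res.records)
        assert all(r.eggs_laid_1 == r.eggs_laid_2 == 0 for r in res.records)

    def test_clonal_population_stays_monomorphic_without_mutation(self):
        res = run_replicate(scaled_params(mu_q=0.0, mu_S=0.0, generations=10))
        for r in res.records:
            if r.P > 0:
                assert r.freq_S1 == 1.0
                assert r.mean_q == 0.0

    def test_same_seed_bitwise_identical_series(self):
        p = scaled_params(generations=10, mu_q=0.001)
        a = run_replicate(p)
        b = run_replicate(p)
        pd.testing.assert_frame_equal(a.to_dataframe(), b.to_dataframe())

    def test_different_seeds_diverge(self):
        p = scaled_params(generations=10)
        a = run_replicate(p, seed=1)
        b = run_replicate(p, seed=2)
        assert not a.to_dataframe().equals(b.to_dataframe())

    def test_offspring_never_exceed_hosts_killed(self):
        res = run_replicate(scaled_params(generations=15, scenario=2))
        for prev, curr in zip(res.records, res.records[1:]):
            killed = (prev.repro_kills_1 + prev.nonrepro_kills_1
                      + prev.repro_kills_2 + prev.nonrepro_kills_2)
            assert curr.P <= killed

    def test_strategy_frequencies_sum_to_one(self):
        res = run_replicate(scaled_params(generations=15))
        for r in res.records:
            if r.P > 0:
                assert r.freq_S1 + r.freq_S2 + r.freq_S3 == pytest.approx(1.0)

    def test_extinction_recorded_and_hosts_recover(self):
        # a lethal trap world: only host 2 patches but host-1 specialists,
        # scenario 1 -> no reproduction at all, extinct after generation 1
        p = ParameterSet(n1=1, n2=8, K1=1.0, K2=200.0, r1=1.5, r2=4.0,
                         P0=50, generations=6, mu_q=0.0, mu_S=0.0,
                         scenario=1, tau_s=3.0, seed=5)
        res = run_replicate(p)
        assert res.extinction_generation == 1
        assert all(r.P == 0 for r in res.records[1:])
        assert res.final.H2 > 0


class TestRunGrid:
    def test_grid_shapes_and_standard_errors(self):
        p1 = scaled_params(generations=5, seed=11)
        p2 = scaled_params(generations=5, tau_s=7.0, seed=12)
        design = ExperimentDesign(variants=[("fast", p1), ("slow", p2)], replicates=3)
        summary = run_grid(design)
        assert len(summary.table) == 2
        assert summary.results is not None
        assert sum(len(v) for v in summary.results.values()) == 6
        finals = [r.final.freq_S1 for r in summary.results["fast"]]
        row = summary.table.set_index("variant").loc["fast"]
        assert row["mean_freq_S1"] == pytest.approx(np.mean(finals))
        assert row["se_freq_S1"] == pytest.approx(np.std(finals, ddof=1) / np.sqrt(3))

    def test_variants_are_independent_cells(self):
        p1 = scaled_params(generations=4, seed=21)
        p2 = scaled_params(generations=4, tau_s=11.0, seed=22)
        both = run_grid(ExperimentDesign(variants=[("a", p1), ("b", p2)], replicates=2))
        alone = run_grid(ExperimentDesign(variants=[("a", p1)], replicates=2))
        for ra, rb in zip(both.results["a"], alone.results["a"]):
            pd.testing.assert_frame_equal(ra.to_dataframe(), rb.to_dataframe())
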