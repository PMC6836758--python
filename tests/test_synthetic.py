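import math

import numpy as np
import pytest

from phyloabc.data_model import LocusSpec
from phyloabc.popgen import diversity, tajima_d
from phyloabc.synthetic import (
    MULTILOCUS_SAMPLE_SIZES,
    MergeEvent,
    ParameterDraw,
    PriorSpec,
    PriorSpecificationError,
    SamplingDesign,
    ScenarioSpec,
    builtin_scenarios,
    child_rng,
    default_design,
    default_loci,
    draw_parameters,
    simulate_dataset,
    simulate_locus_matrix,
)


def clade_of(scenario, branch):
    """Populations that have merged into `branch` by the time it merges away
    (or by the root), scanning events in an order consistent with the
    ordering constraints (events as listed are so ordered for the built-ins)."""
    members = {p: {p} for p in scenario.populations}
    for e in scenario.events:
        members[e.dest] |= members[e.source]
        if e.source == branch:
            return members[branch]
    return members[branch]


class TestBuiltinScenarios:
    def test_each_scenario_is_a_rooted_tree(self, scenarios):
        assert len(scenarios) == 4
        for sc in scenarios:
            assert len(sc.events) == 6  # 7 populations -> 6 merges
            sources = {e.source for e in sc.events}
            assert len(sources) == 6
            assert sc.root not in sources

    def test_scenario1_has_nep_clade_joining_pet(self, scenarios):
        s1 = scenarios[0]
        # the branch that merges into PET carries exactly {KOD, COR, JUN}
        ev = next(e for e in s1.events if e.dest == "PET")
        assert clade_of(s1, ev.source) == {"KOD", "COR", "JUN"}

    def test_scenario3_reverses_colonization_direction(self, scenarios):
        s3 = scenarios[2]
        ev = next(e for e in s3.events if e.source == "PET")
        # PET merges INTO the NEP ancestral lineage
        assert ev.dest in {"KOD", "COR", "JUN"}

    def test_scenario2_has_two_independent_mergers_into_pet(self, scenarios):
        s2 = scenarios[1]
        into_pet = [e for e in s2.events if e.dest == "PET"]
        assert len(into_pet) == 2
        assert {e.source for e in into_pet} == {"COR", "KOD"}

    def test_scenario4_nep_clade_joins_at_root(self, scenarios):
        s4 = scenarios[3]
        ev = next(e for e in s4.events if e.source == "COR")
        assert clade_of(s4, "COR") == {"KOD", "COR", "JUN"}
        # the NEP-clade merge is constrained to postdate every NWP merge
        later = {b for a, b in s4.ordering_constraints if b == ev.time_param}
        assert ev.time_param in {b for _, b in s4.ordering_constraints}

    def test_structural_constraints_derived_from_events(self, scenarios):
        s1 = scenarios[0]
        cons = set(s1.all_constraints())
        # NEP members must merge before their ancestor joins PET, which
        # must happen before the PET lineage joins ERI
        assert ("t_a", "t_c") in cons
        assert ("t_b", "t_c") in cons
        assert ("t_c", "t_e") in cons


class TestDrawParameters:
    def test_draws_respect_bounds_and_constraints(self, scenarios):
        sc = scenarios[0]
        for seed in range(20):
            d = draw_parameters(sc, seed)
            for p, v in d.values.items():
                pr = sc.priors[p]
                assert pr.lower <= v <= pr.upper
            for a, b in sc.all_constraints():
                assert d.values[a] < d.values[b]

    def test_fixed_seed_reproduces_draw(self, scenarios):
        d1 = draw_parameters(scenarios[1], 42)
        d2 = draw_parameters(scenarios[1], 42)
        assert d1.values == d2.values

    def test_unsatisfiable_constraints_raise(self):
        sc = ScenarioSpec(
            id="bad",
            populations=("A", "B"),
            events=(MergeEvent("t1", "A", "B"),),
            size_param={"A": "NA_", "B": "NB_"},
            priors={
                "NA_": PriorSpec(1, 10), "NB_": PriorSpec(1, 10),
                "t1": PriorSpec(0, 100), "t2": PriorSpec(200, 300),
            },
            ordering_constraints=(("t2", "t1"),),  # impossible given priors
        )
        # t2 is not a scenario parameter -> prior error paths either way
        with pytest.raises((PriorSpecificationError, KeyError)):
            draw_parameters(sc, 0, max_rejections=100)


class TestCoalescentCalibration:
    def test_pair_coalescence_time_nuclear(self, single_pop_scenario):
        """E[T2] = 2N generations for two nuclear gene copies."""
        N = 500.0
        sc, draw = single_pop_scenario(N)
        # measure T2 through mean pairwise differences at high mutation rate:
        # E[k] = 2 u E[T2]
        locus = LocusSpec("L", 10_000, 1.0, 1e-6, 2)
        u = locus.mu_locus_gen
        rng = np.random.default_rng(11)
        ks = []
        for _ in range(3000):
            mat, _, _ = simulate_locus_matrix(sc, draw, locus, SamplingDesign({"P": 1}), rng)
            ks.append(mat.shape[1])
        mean_k = np.mean(ks)
        se = np.std(ks) / math.sqrt(len(ks))
        assert abs(mean_k - 2 * u * 2 * N) <= 3 * se

    def test_pairwise_differences_mtdna(self, single_pop_scenario):
        """mtDNA theta = 2 * (0.25 * 2N) * u."""
        N = 1000.0
        sc, draw = single_pop_scenario(N)
        locus = LocusSpec("M", 5000, 0.25, 1e-6, 1)
        u = locus.mu_locus_gen
        rng = np.random.default_rng(12)
        ks = []
        for _ in range(3000):
            mat, _, _ = simulate_locus_matrix(sc, draw, locus, SamplingDesign({"P": 2}), rng)
            ks.append(mat.shape[1])
        expect = 2 * (0.25 * 2 * N) * u
        se = np.std(ks) / math.sqrt(len(ks))
        assert abs(np.mean(ks) - expect) <= 3 * se

    def test_neutral_single_population_summaries(self, single_pop_scenario):
        """n=20, theta=5: E[S] = theta*a1, E[k] = theta, mean D near 0."""
        N = 1000.0
        sc, draw = single_pop_scenario(N)
        locus = LocusSpec("L", 2000, 1.0, 5.0 / (4 * N) / 2000, 2)  # theta = 5
        rng = np.random.default_rng(13)
        S, K, D = [], [], []
        for _ in range(1000):
            mat, _, _ = simulate_locus_matrix(sc, draw, locus, SamplingDesign({"P": 10}), rng)
            S.append(mat.shape[1])
            K.append(diversity(mat).k if mat.shape[1] else 0.0)
            d = tajima_d(mat) if mat.shape[1] else math.nan
            if not math.isnan(d):
                D.append(d)
        theta = 5.0
        a1 = sum(1.0 / i for i in range(1, 20))
        se_S = np.std(S) / math.sqrt(len(S))
        se_K = np.std(K) / math.sqrt(len(K))
        assert abs(np.mean(S) - theta * a1) <= 3 * se_S
        assert abs(np.mean(K) - theta) <= 3 * se_K
        assert -0.15 <= np.mean(D) <= 0.15

    def test_zero_split_time_mixes_populations(self):
        """A split at time ~0 leaves between = within pairwise diversity."""
        sc = ScenarioSpec(
            id="split",
            populations=("A", "B"),
            events=(MergeEvent("t1", "A", "B"),),
            size_param={"A": "N_A", "B": "N_B"},
            priors={"N_A": PriorSpec(1, 1e7), "N_B": PriorSpec(1, 1e7),
                    "t1": PriorSpec(0, 1e7)},
        )
        draw = ParameterDraw("split", {"N_A": 1000.0, "N_B": 1000.0, "t1": 1e-9}, 0)
        locus = LocusSpec("L", 2000, 1.0, 1e-6, 2)
        rng = np.random.default_rng(14)
        within, between = [], []
        design = SamplingDesign({"A": 5, "B": 5})
        for _ in range(400):
            mat, pops, _ = simulate_locus_matrix(sc, draw, locus, design, rng)
            if mat.shape[1] == 0:
                within.append(0.0)
                between.append(0.0)
                continue
            X = mat.astype(float)
            d = X @ (1 - X).T
            d = d + d.T
            a = slice(0, 10)
            b = slice(10, 20)
            iu = np.triu_indices(10, k=1)
            within.append((d[a, a][iu].mean() + d[b, b][iu].mean()) / 2)
            between.append(d[a, b].mean())
        diff = np.array(between) - np.array(within)
        se = diff.std() / math.sqrt(len(diff))
        assert abs(diff.mean()) <= 3 * se

    def test_between_population_divergence_monotone_in_split_time(self):
        """Deeper splits cannot decrease expected between-population diversity."""
        locus = LocusSpec("L", 2000, 1.0, 1e-6, 2)
        design = SamplingDesign({"A": 5, "B": 5})
        means = []
        for t_split in [0.0, 2000.0, 20000.0]:
            sc = ScenarioSpec(
                id="split",
                populations=("A", "B"),
                events=(MergeEvent("t1", "A", "B"),),
                size_param={"A": "N_A", "B": "N_B"},
                priors={"N_A": PriorSpec(1, 1e7), "N_B": PriorSpec(1, 1e7),
                        "t1": PriorSpec(0, 1e7)},
            )
            draw = ParameterDraw("split", {"N_A": 1000.0, "N_B": 1000.0,
                                           "t1": t_split + 1e-9}, 0)
            rng = np.random.default_rng(15)
            vals = []
            for _ in range(300):
                mat, _, _ = simulate_locus_matrix(sc, draw, locus, design, rng)
                if mat.shape[1] == 0:
                    vals.append(0.0)
                    continue
                X = mat.astype(float)
                d = X @ (1 - X).T
                d = d + d.T
                vals.append(d[:10, 10:].mean())
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]


class TestSimulateDataset:
    def test_mtdna_record_count_matches_design(self, scenarios, loci, design):
        draw = draw_parameters(scenarios[0], 3)
        panel = simulate_dataset(scenarios[0], draw, loci, design, rng_seed=3)
        assert len(panel.records_for("CYTB")) == sum(MULTILOCUS_SAMPLE_SIZES.values()) == 80
        # nuclear loci carry two phased copies per individual
        assert len(panel.records_for("ATPSa")) == 160

    def test_zero_mutation_rate_gives_identical_sequences(self, scenarios, design):
        loci = [LocusSpec("L", 100, 1.0, 1e-300, 2)]
        draw = draw_parameters(scenarios[0], 5)
        panel = simulate_dataset(scenarios[0], draw, loci, design, rng_seed=5)
        seqs = {r.sequence for r in panel.records_for("L")}
        assert len(seqs) == 1

    def test_same_seed_reproduces_panel(self, scenarios, loci, design):
        draw = draw_parameters(scenarios[1], 8)
        p1 = simulate_dataset(scenarios[1], draw, loci, design, rng_seed=8)
        p2 = simulate_dataset(scenarios[1], draw, loci, design, rng_seed=8)
        for sp in loci:
            assert [r.sequence for r in p1.records_for(sp.name)] == [
                r.sequence for r in p2.records_for(sp.name)
            ]

    def test_design_missing_population_rejected(self, scenarios, loci):
        draw = draw_parameters(scenarios[0], 9)
        with pytest.raises((ValueError, KeyError)):
            simulate_dataset(scenarios[0], draw, loci, SamplingDesign({"ERI": 5}), rng_seed=9)


class TestAgainstMsprime:
    def test_single_population_site_spectrum_matches_msprime(self, single_pop_scenario):
        """(S, k) distribution vs an independent coalescent simulator."""
        msprime = pytest.importorskip("msprime")
        from scipy.stats import ks_2samp

        N = 1000.0
        sc, draw = single_pop_scenario(N)
        locus = LocusSpec("L", 1000, 1.0, 1e-6, 2)
        rng = np.random.default_rng(21)
        n_rep = 600
        S_ours = []
        k_ours = []
        for _ in range(n_rep):
            mat, _, _ = simulate_locus_matrix(sc, draw, locus, SamplingDesign({"P": 8}), rng)
            S_ours.append(mat.shape[1])
            k_ours.append(diversity(mat).k if mat.shape[1] else 0.0)
        S_ms, k_ms = [], []
        reps = msprime.sim_ancestry(
            samples=8, ploidy=2, population_size=N, sequence_length=1000,
            num_replicates=n_rep, random_seed=99,
        )
        for ts in reps:
            mts = msprime.sim_mutations(
                ts, rate=1e-6, model=msprime.BinaryMutationModel(), discrete_genome=False
            )
            S_ms.append(mts.num_sites)
            k_ms.append(mts.diversity(span_normalise=False))
        assert ks_2samp(S_ours, S_ms).pvalue > 0.01
        assert ks_2samp(k_ours, k_ms).pvalue > 0.01


def test_child_rng_counter_scheme_is_stable():
    a = child_rng(7, 3).integers(0, 2**31)
    b = child_rng(7, 3).integers(0, 2**31)
    c = child_rng(7, 4).integers(0, 2**31)
    assert a == b != c
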