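import math
import warnings

import numpy as np
import pytest

from phyloabc import abc as A
from phyloabc.data_model import LocusSpec
from phyloabc.synthetic import (
    SCENARIO1_REFERENCE_PARAMS,
    ParameterDraw,
    SamplingDesign,
    builtin_scenarios,
    child_rng,
    default_design,
    default_loci,
    draw_parameters,
    simulate_dataset,
)


@pytest.fixture(scope="module")
def micro_table(scenarios, loci, design):
    """A deliberately tiny table for contract-level tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return A.build_reference_table(scenarios, loci, design, 60, master_seed=5)


class TestSummaryVector:
    def test_schema_dimension_and_order(self, loci):
        pops = ["A", "B", "C"]
        names = A.summary_names(pops, loci)
        # 2 locus groups x (3 pops x 5 one-sample + 3 pairs x 3 two-sample)
        assert len(names) == 2 * (3 * 5 + 3 * 3)
        assert names[0].startswith("CYTB|A|")
        assert any(n == "nuclear|A-B|fst" for n in names)

    def test_panel_and_matrix_paths_agree(self, scenarios, loci, design):
        draw = draw_parameters(scenarios[0], 6)
        panel = simulate_dataset(scenarios[0], draw, loci, design, rng_seed=6)
        sv = A.summarize_panel(panel, populations=list(scenarios[0].populations))
        assert len(sv.values) == len(sv.names)
        assert np.isfinite(sv.values).all()
        # spot-check one entry against the slow reference implementation
        from phyloabc import popgen

        mat = popgen.records_matrix(panel.records_for("CYTB", "KHO"))
        st = popgen.diversity(mat)
        idx = sv.names.index("CYTB|KHO|k")
        assert sv.values[idx] == pytest.approx(st.k, abs=1e-12)

    def test_undefined_statistics_encoded_as_zero_with_flag(self, scenarios, design):
        loci = [LocusSpec("CYTB", 433, 0.25, 1e-300, 1)]  # no variation at all
        draw = draw_parameters(scenarios[0], 7)
        panel = simulate_dataset(scenarios[0], draw, loci, design, rng_seed=7)
        sv = A.summarize_panel(panel, populations=list(scenarios[0].populations))
        i = sv.names.index("CYTB|ERI|D")
        assert sv.values[i] == 0.0
        assert sv.undefined[i]


class TestReferenceTable:
    def test_balanced_row_counts(self, micro_table):
        assert micro_table.n_rows == 240
        assert np.bincount(micro_table.labels).tolist() == [60] * 4

    def test_same_master_seed_reproduces_table(self, scenarios, loci, design):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1 = A.build_reference_table(scenarios, loci, design, 5, master_seed=9)
            t2 = A.build_reference_table(scenarios, loci, design, 5, master_seed=9)
        assert np.array_equal(t1.stats, t2.stats)
        for sid in t1.scenario_ids:
            assert np.array_equal(t1.params[sid], t2.params[sid])

    def test_constant_column_mad_fallback(self, scenarios, loci, design):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            t = A.build_reference_table(scenarios, loci, design, 3, master_seed=1)
        assert (t.mad > 0).all()

    def test_save_load_round_trip(self, micro_table, tmp_path):
        base = str(tmp_path / "tab")
        A.save_reference_table(micro_table, base)
        t2 = A.load_reference_table(base)
        assert np.array_equal(t2.stats, micro_table.stats)
        assert t2.names == micro_table.names
        assert t2.scenario_ids == micro_table.scenario_ids


class TestReject:
    def test_exact_match_has_zero_distance(self, micro_table):
        row = 17
        obs = A.SummaryVector(
            micro_table.names, micro_table.stats[row].copy(),
            np.zeros(len(micro_table.names), bool),
        )
        rej = A.reject(micro_table, obs, 5)
        assert rej.indices[0] == row
        assert rej.distances[0] == 0.0

    def test_retain_all_rows(self, micro_table):
        obs = A.SummaryVector(
            micro_table.names, micro_table.stats.mean(axis=0),
            np.zeros(len(micro_table.names), bool),
        )
        rej = A.reject(micro_table, obs, micro_table.n_rows)
        assert len(rej.indices) == micro_table.n_rows

    def test_distances_match_hand_computation(self):
        names = ("s1", "s2")
        table = A.ReferenceTable(
            scenario_ids=["a"],
            labels=np.zeros(3, int),
            stats=np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]]),
            params={"a": np.zeros((3, 1))},
            param_names={"a": ("p",)},
            row_within=np.arange(3),
            mad=np.array([1.0, 2.0]),
            names=names,
            master_seed=0,
        )
        obs = A.SummaryVector(names, np.array([0.0, 0.0]), np.zeros(2, bool))
        rej = A.reject(table, obs, 3)
        # distances: 0, sqrt(1 + 0.25), 2
        assert rej.distances == pytest.approx([0.0, math.sqrt(1.25), 2.0])

    def test_prefix_property_of_retention(self, micro_table):
        obs = A.SummaryVector(
            micro_table.names, micro_table.stats.mean(axis=0),
            np.zeros(len(micro_table.names), bool),
        )
        r10 = A.reject(micro_table, obs, 10)
        r50 = A.reject(micro_table, obs, 50)
        assert r50.indices[:10].tolist() == r10.indices.tolist()
        assert r10.distances.max() <= r50.distances.max()

    def test_schema_mismatch_rejected(self, micro_table):
        obs = A.SummaryVector(("x",), np.array([1.0]), np.zeros(1, bool))
        with pytest.raises(ValueError):
            A.reject(micro_table, obs, 5)


class TestModelChoice:
    def _obs(self, table, vec):
        return A.SummaryVector(table.names, vec, np.zeros(len(table.names), bool))

    def test_single_scenario_retained_gets_probability_one(self, micro_table):
        mask = micro_table.labels == 2
        rej = A.RejectionResult(
            indices=np.nonzero(mask)[0][:20],
            distances=np.zeros(20),
            labels=np.full(20, 2),
            stats=micro_table.stats[mask][:20],
        )
        obs = self._obs(micro_table, micro_table.stats[mask][:20].mean(axis=0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = A.model_choice(micro_table, rej, obs, n_boot=0)
        assert res.probabilities[2] == pytest.approx(1.0)
        assert res.selected == "scenario3"

    def test_no_signal_limit_recovers_class_frequencies(self):
        rng = np.random.default_rng(0)
        n, p = 4000, 4
        names = tuple(f"s{i}" for i in range(p))
        table = A.ReferenceTable(
            scenario_ids=["a", "b", "c", "d"],
            labels=np.zeros(n, int),
            stats=np.zeros((n, p)),
            params={k: np.zeros((n, 1)) for k in "abcd"},
            param_names={k: ("x",) for k in "abcd"},
            row_within=np.arange(n),
            mad=np.ones(p),
            names=names,
            master_seed=0,
        )
        labels = rng.integers(0, 4, n)
        stats = rng.normal(size=(n, p))
        rej = A.RejectionResult(np.arange(n), np.ones(n), labels, stats)
        obs = A.SummaryVector(names, np.zeros(p), np.zeros(p, bool))
        res = A.model_choice(table, rej, obs, n_boot=0)
        freqs = np.bincount(labels, minlength=4) / n
        assert np.allclose(res.probabilities, freqs, atol=0.05)

    def test_probabilities_sum_to_one_and_cis_bracket(self, micro_table):
        obs = self._obs(micro_table, micro_table.stats.mean(axis=0))
        rej = A.reject(micro_table, obs, 100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = A.model_choice(micro_table, rej, obs, n_boot=30, rng_seed=1)
        assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.ci_lower <= res.probabilities + 1e-12).all()
        assert (res.ci_upper >= res.probabilities - 1e-12).all()
        assert ((res.ci_lower >= 0) & (res.ci_upper <= 1)).all()


class TestErrorRates:
    def test_oracle_chooser_gives_zero_rates(self, micro_table, scenarios, loci, design, monkeypatch):
        truth = {}

        def fake_choice(table, sv, n_retain):
            return truth["current"]

        monkeypatch.setattr(A, "_choose_for_pod", fake_choice)
        orig = A.simulate_summary

        def tracking_sim(sc, draw, loci_, design_, rng):
            truth["current"] = [s.id for s in scenarios].index(sc.id)
            return orig(sc, draw, loci_, design_, rng)

        monkeypatch.setattr(A, "simulate_summary", tracking_sim)
        er = A.error_rates(
            micro_table, scenarios, loci, design, focal="scenario1",
            n_pods=3, n_retain=20, rng_seed=1,
        )
        assert er.false_positive_rate == 0.0
        assert er.false_negative_rate == 0.0

    def test_point_source_requires_parameters(self, micro_table, scenarios, loci, design):
        with pytest.raises(ValueError):
            A.error_rates(
                micro_table, scenarios, loci, design, focal="scenario1",
                n_pods=1, pod_source="point",
            )


class TestEstimateParameters:
    def test_zero_regressor_returns_rejection_sample(self, micro_table, scenarios):
        sc = scenarios[0]
        mask = micro_table.labels == 0
        obs_vec = micro_table.stats[mask][0].copy()
        # craft a table whose scenario-1 rows all equal the observed vector
        t = A.ReferenceTable(
            scenario_ids=micro_table.scenario_ids,
            labels=micro_table.labels,
            stats=np.where(mask[:, None], obs_vec, micro_table.stats),
            params=micro_table.params,
            param_names=micro_table.param_names,
            row_within=micro_table.row_within,
            mad=micro_table.mad,
            names=micro_table.names,
            master_seed=0,
        )
        obs = A.SummaryVector(t.names, obs_vec, np.zeros(len(t.names), bool))
        post = A.estimate_parameters(t, obs, sc, retain_fraction=0.5)
        raw = t.params[sc.id][:len(post.samples)]
        # with all regressors zero the adjustment leaves draws unchanged
        # (up to the logit clamp at the prior bounds)
        j = post.param_names.index("t_c")
        got = np.sort(post.samples[:, j])
        expect = np.sort(t.params[sc.id][t.row_within[mask]][:len(post.samples), j])
        assert got == pytest.approx(expect, rel=1e-6)

    def test_samples_respect_prior_bounds(self, micro_table, scenarios):
        sc = scenarios[0]
        obs = A.SummaryVector(
            micro_table.names, micro_table.stats.mean(axis=0),
            np.zeros(len(micro_table.names), bool),
        )
        post = A.estimate_parameters(micro_table, obs, sc, retain_fraction=0.5)
        for j, pn in enumerate(post.param_names):
            pr = sc.priors[pn]
            assert (post.samples[:, j] >= pr.lower).all()
            assert (post.samples[:, j] <= pr.upper).all()
            assert post.ci_lower[j] <= post.ci_upper[j]

    def test_linear_model_adjustment_sharpens_posterior(self, scenarios):
        """With stats linear in the parameter, the regression adjustment
        concentrates the posterior on the truth far beyond raw rejection."""
        from phyloabc.synthetic import PriorSpec, ScenarioSpec

        rng = np.random.default_rng(3)
        n = 5000
        x = rng.uniform(0, 1, n)
        stats = (x + rng.normal(0, 0.05, n))[:, None]
        sc = ScenarioSpec(
            id="lin", populations=("P",), events=(),
            size_param={"P": "x"}, priors={"x": PriorSpec(0.0, 1.0)},
        )
        table = A.ReferenceTable(
            scenario_ids=["lin"], labels=np.zeros(n, int), stats=stats,
            params={"lin": x[:, None]}, param_names={"lin": ("x",)},
            row_within=np.arange(n), mad=np.array([np.median(np.abs(x - np.median(x)))]),
            names=("s",), master_seed=0,
        )
        obs = A.SummaryVector(("s",), np.array([0.3]), np.zeros(1, bool))
        post = A.estimate_parameters(table, obs, sc, retain_fraction=0.2)
        assert post.adjusted
        assert abs(post.modes[0] - 0.3) < 0.05
        # raw retained draws span the rejection window; adjustment shrinks it
        raw_width = np.quantile(x, 0.975) - np.quantile(x, 0.025)
        adj_width = post.ci_upper[0] - post.ci_lower[0]
        assert adj_width < raw_width / 2

    def test_equivariant_under_affine_stat_rescaling(self, micro_table, scenarios):
        sc = scenarios[0]
        obs_vec = micro_table.stats.mean(axis=0)
        obs = A.SummaryVector(micro_table.names, obs_vec, np.zeros(len(obs_vec), bool))
        post1 = A.estimate_parameters(micro_table, obs, sc, retain_fraction=0.3)
        scale = np.full(len(obs_vec), 3.0)
        t2 = A.ReferenceTable(
            scenario_ids=micro_table.scenario_ids,
            labels=micro_table.labels,
            stats=micro_table.stats * scale,
            params=micro_table.params,
            param_names=micro_table.param_names,
            row_within=micro_table.row_within,
            mad=micro_table.mad * scale,
            names=micro_table.names,
            master_seed=0,
        )
        obs2 = A.SummaryVector(micro_table.names, obs_vec * scale, np.zeros(len(obs_vec), bool))
        post2 = A.estimate_parameters(t2, obs2, sc, retain_fraction=0.3)
        assert post1.samples == pytest.approx(post2.samples, rel=1e-9)


class TestScaleUnits:
    CYTB = LocusSpec("CYTB", 433, 0.25, 5e-9, 1)

    def test_generations_to_years_identity_generation_time(self):
        assert A.scale_units(20_000, "generations_to_years", self.CYTB) == 20_000

    def test_divergence_rate_implies_per_lineage_site_rate(self):
        cfg = A.ScalingConfig()
        assert cfg.mu_site_year == pytest.approx(5e-9)

    def test_mutation_scaled_time_to_years(self):
        got = A.scale_units(0.2, "t_mut_to_years", self.CYTB)
        assert got == pytest.approx(0.2 / (433 * 5e-9), rel=1e-12)
        assert got == pytest.approx(92_379, rel=1e-3)

    def test_theta_to_population_size(self):
        # theta = 4 N u s: N = theta / (4 u s)
        u = self.CYTB.mu_locus_gen
        got = A.scale_units(1.0, "theta_to_N", self.CYTB)
        assert got == pytest.approx(1.0 / (4 * u * 0.25))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            A.scale_units(1.0, "bogus", self.CYTB)
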