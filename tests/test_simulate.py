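"""Simulator correctness: Peto pooling against a hypergeometric oracle,
criterion identities, determinism, and the selection-bias mechanism."""

import numpy as np
import pytest
from scipy import stats

from nestedloop import (
    FactorialDesign,
    MetaSimConfig,
    ParameterSpec,
    compute_criteria,
    example_config,
    peto_log_or,
    run_simulation_study,
    simulate_one_meta,
    synth_factorial_results,
)
from nestedloop.ordering import nestedloop_reorder, step_series
from nestedloop.simulate import (
    _simulate_scenario,
    scenario_rng,
    treatment_proportion,
)


def hypergeom_oracle(a, n1, c, n0):
    """Per-study O−E and V from scipy's hypergeometric moments."""
    n, m = n1 + n0, a + c
    dist = stats.hypergeom(M=n, n=m, N=n1)
    return a - dist.mean(), dist.var()


class TestPetoPooling:
    def test_identical_arms_give_zero(self):
        est, se = peto_log_or([(5, 10, 5, 10)])
        assert est == pytest.approx(0.0, abs=1e-12)
        assert se > 0

    def test_single_table_matches_hypergeometric_oracle(self):
        # treatment 1/10 events, control 5/10
        a, n1, c, n0 = 1, 10, 5, 10
        o_minus_e, v = hypergeom_oracle(a, n1, c, n0)
        # direct moments: E = 10*6/20, V = 10*10*6*14/(20^2*19)
        assert o_minus_e == pytest.approx(1 - 10 * 6 / 20)
        assert v == pytest.approx(10 * 10 * 6 * 14 / (20**2 * 19))
        est, se = peto_log_or([(a, n1, c, n0)])
        assert est == pytest.approx(o_minus_e / v)
        assert se == pytest.approx(1 / np.sqrt(v))

    @pytest.mark.parametrize("table", [
        (1, 10, 5, 10), (7, 30, 3, 50), (0, 12, 4, 12), (9, 20, 14, 25),
    ])
    def test_pooling_terms_match_oracle(self, table):
        o1, v1 = hypergeom_oracle(*table)
        est, se = peto_log_or([table])
        assert est == pytest.approx(o1 / v1, rel=1e-12)

    def test_pooling_duplicate_tables_keeps_estimate_shrinks_se(self):
        one_est, one_se = peto_log_or([(3, 15, 7, 18)])
        two_est, two_se = peto_log_or([(3, 15, 7, 18)] * 2)
        assert two_est == pytest.approx(one_est)
        assert two_se == pytest.approx(one_se / np.sqrt(2))

    def test_all_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            peto_log_or([(0, 10, 0, 10), (10, 10, 10, 10)])

    def test_zero_cell_tables_tolerated_if_any_margin_informative(self):
        est, se = peto_log_or([(0, 10, 3, 10)])
        assert np.isfinite(est) and np.isfinite(se)


class TestTreatmentProportion:
    def test_null_effect_keeps_control_risk(self):
        assert treatment_proportion(0.0, 0.3) == pytest.approx(0.3)

    def test_odds_transform(self):
        # OR = 0.5 at p_c = 0.2: odds_c = 0.25, odds_t = 0.125
        p_t = treatment_proportion(np.log(0.5), 0.2)
        assert p_t == pytest.approx(0.125 / 1.125)


class TestComputeCriteria:
    def test_perfect_estimates(self):
        crit = compute_criteria([1.0, 1.0, 1.0],
                                [(0.5, 1.5)] * 3, truth=1.0)
        assert (crit.bias, crit.variance, crit.mse, crit.mcse) == (0, 0, 0, 0)
        assert crit.coverage == 1.0

    def test_two_point_example(self):
        crit = compute_criteria([0.0, 2.0], [(-1, 1), (1, 3)], truth=1.0)
        assert crit.bias == pytest.approx(0.0)
        assert crit.variance == pytest.approx(1.0)  # denominator R = 2
        assert crit.mse == pytest.approx(1.0)
        assert crit.coverage == 1.0

    def test_single_repetition_degeneracy(self):
        crit = compute_criteria([0.4], [(0.0, 1.0)], truth=0.1)
        assert crit.variance == 0.0
        assert crit.mse == pytest.approx(crit.bias**2)

    def test_nan_estimates_dropped(self):
        crit = compute_criteria([np.nan, 2.0], [(0, 0), (1, 3)], truth=2.0)
        assert crit.n_reps == 1 and crit.bias == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no non-missing"):
            compute_criteria([np.nan], [(0, 1)], truth=0.0)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        {"k_levels": (1, 5)},
        {"or_levels": (0.0, 1.0)},
        {"p_c_levels": (0.0, 0.3)},
        {"tau2_levels": (-0.1,)},
        {"replications": 0},
        {"retention": {"none": 1.0, "weak": 0.75, "moderate": 0.5,
                       "strong": 0.0}},
    ])
    def test_invalid_settings_rejected(self, bad):
        with pytest.raises(ValueError):
            example_config(**bad)

    def test_yaml_round_trip(self, tmp_path):
        cfg = example_config(replications=7, seed=3)
        path = tmp_path / "cfg.yaml"
        cfg.to_file(path)
        assert MetaSimConfig.from_file(path) == cfg

    def test_example_design_shape(self):
        design = example_config().design()
        assert design.n_scenarios == 768
        assert [p.n_levels for p in design.params] == [4, 4, 4, 4, 3]


class TestSimulateOneMeta:
    def test_deterministic_under_seed(self):
        cfg = example_config()
        a = simulate_one_meta(cfg, 0.75, "moderate", 0.2, 0.05, 10,
                              scenario_rng(5, 0))
        b = simulate_one_meta(cfg, 0.75, "moderate", 0.2, 0.05, 10,
                              scenario_rng(5, 0))
        assert a == b

    def test_null_scenario_is_unbiased(self):
        """OR=1, no selection, symmetric arms: mean estimate near 0."""
        cfg = example_config()
        est, _ = _simulate_scenario(cfg, 1.0, "none", 0.30, 0.0, 10, 2000,
                                    scenario_rng(11, 0))
        mcse = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean()) < 3 * mcse

    def test_strong_selection_biases_null_estimate(self):
        """Retaining mostly significant studies biases the pooled log OR
        away from zero at OR=1 (the motivating failure mode)."""
        cfg = example_config()
        none_est, _ = _simulate_scenario(cfg, 1.0, "none", 0.30, 0.0, 20,
                                         2000, scenario_rng(1, 0))
        strong_est, _ = _simulate_scenario(cfg, 1.0, "strong", 0.30, 0.0, 20,
                                           2000, scenario_rng(1, 1))
        mcse = np.hypot(none_est.std(ddof=1), strong_est.std(ddof=1)) / np.sqrt(2000)
        assert abs(strong_est.mean()) > abs(none_est.mean()) + 3 * mcse


@pytest.fixture(scope="module")
def small_study():
    cfg = example_config(
        or_levels=(1.0, 0.5), selection_levels=("none", "strong"),
        p_c_levels=(0.3,), tau2_levels=(0.0, 0.1), k_levels=(5,),
        replications=40, seed=123)
    return cfg, run_simulation_study(cfg)


class TestRunSimulationStudy:
    def test_one_row_per_scenario(self, small_study):
        cfg, table = small_study
        assert table.n_rows == cfg.design().n_scenarios == 8
        assert table.methods == ["peto"]
        assert "true_log_or" in table.aux_columns()

    def test_mse_identity_every_scenario(self, small_study):
        _, table = small_study
        mse = table.values("mse", "peto")
        bias = table.values("bias", "peto")
        var = table.values("var", "peto")
        assert np.all(np.abs(mse - (bias**2 + var)) < 1e-12)

    def test_coverage_within_unit_interval(self, small_study):
        _, table = small_study
        cov = table.values("coverage", "peto")
        assert np.all((cov >= 0) & (cov <= 1))

    def test_reproducible_and_order_independent_substreams(self, small_study):
        cfg, table = small_study
        again = run_simulation_study(cfg)
        assert again == table
        # re-simulating one scenario in isolation reproduces its row
        row = table.data.iloc[3]
        est, se = _simulate_scenario(
            cfg, row["or"], row["selection"], row["p_c"], row["tau2"],
            int(row["k"]), cfg.replications, scenario_rng(cfg.seed, 3))
        assert est.mean() == pytest.approx(row["est__peto"])

    def test_single_repetition_degeneracy(self):
        cfg = example_config(
            or_levels=(1.0,), selection_levels=("none",), p_c_levels=(0.3,),
            tau2_levels=(0.0,), k_levels=(5,), replications=1, seed=9)
        table = run_simulation_study(cfg)
        assert table.values("var", "peto")[0] == 0.0
        assert table.values("mse", "peto")[0] == pytest.approx(
            table.values("bias", "peto")[0] ** 2)

    def test_halving_reps_inflates_mcse(self):
        """mcse = sd/sqrt(R): quartering R roughly doubles it (seed-averaged)."""
        ratios = []
        for seed in range(4):
            big = example_config(
                or_levels=(1.0,), selection_levels=("none",),
                p_c_levels=(0.3,), tau2_levels=(0.0,), k_levels=(5,),
                replications=1600, seed=seed)
            small = example_config(
                or_levels=(1.0,), selection_levels=("none",),
                p_c_levels=(0.3,), tau2_levels=(0.0,), k_levels=(5,),
                replications=400, seed=seed + 100)
            ratios.append(
                run_simulation_study(small).values("mcse", "peto")[0]
                / run_simulation_study(big).values("mcse", "peto")[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.2)


class TestSynthFactorial:
    def test_zero_noise_matches_closed_form(self):
        design = FactorialDesign([
            ParameterSpec("a", [10, 20]),
            ParameterSpec("b", ["u", "v", "w"]),
        ])
        table = synth_factorial_results(
            design, main_effects={"a": [0.0, 1.0], "b": [0.0, 0.1, 0.2]},
            interactions={("a", "b"): [[0, 0, 0], [0, 0, 0.5]]},
            criteria=["y"], methods=["m"])
        got = dict(zip(map(tuple, table.data[["a", "b"]].itertuples(index=False)),
                       table.data["y__m"]))
        assert got[(20, "w")] == pytest.approx(1.0 + 0.2 + 0.5)
        assert got[(10, "u")] == 0.0
        assert got[(20, "u")] == pytest.approx(1.0)

    def test_same_seed_identical_tables(self, meta_design):
        kwargs = dict(main_effects={"or": [0, 1, 2, 3]}, noise_sd=0.3)
        a = synth_factorial_results(meta_design, seed=5, **kwargs)
        b = synth_factorial_results(meta_design, seed=5, **kwargs)
        assert a == b

    def test_outer_main_effect_yields_pure_step_function(self, meta_design):
        table = synth_factorial_results(
            meta_design, main_effects={"or": [0.0, 1.0, 2.0, 3.0]})
        ordered, layout = nestedloop_reorder(table)
        y = ordered.values("y", "m")
        runs = np.flatnonzero(np.diff(y) != 0) + 1
        assert list(runs) == [192, 384, 576]
        assert len(step_series(layout, "or")) == 4

    def test_unknown_parameter_in_effects_rejected(self, meta_design):
        with pytest.raises(KeyError, match="unknown parameter"):
            synth_factorial_results(meta_design, main_effects={"zz": [1]})
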