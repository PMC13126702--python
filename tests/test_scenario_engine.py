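"""Schedules, the day loop, replicates, summaries, and scenario comparison."""

import numpy as np
import pandas as pd
import pytest

from lockdownsim import (
    ScenarioConfig,
    build_schedule,
    compare_scenarios,
    run_replicate,
    run_scenario,
    sample_population,
)
from lockdownsim.scenario_engine import ACTUAL_SEGMENTS
from lockdownsim.synthetic_fixtures import FixtureSpec, generate_case_curve


def small_config(**kw):
    base = dict(n_agents=200, replicates=4, seed=5,
                start_date="2020-06-11", end_date="2020-09-18",
                preset="partial_only")
    base.update(kw)
    return ScenarioConfig(**base)


def clipped_inputs(fixture_inputs, days):
    """Fixture inputs with the case series clipped to the run length."""
    import dataclasses

    cases = fixture_inputs.cases
    from lockdownsim import CaseSeries

    clipped = CaseSeries(
        dates=cases.dates[:days],
        new_cases=cases.new_cases[:days],
        real_population_n=cases.real_population_n,
    )
    return dataclasses.replace(fixture_inputs, cases=clipped)


class TestBuildSchedule:
    def test_actual_preset_reproduces_dated_segments(self):
        sched = build_schedule("actual", "2020-06-11", "2021-06-11")
        got = [(str(s.start.date()), str(s.end.date()), s.kind)
               for s in sched.segments]
        assert got == [list(x) and x for x in ACTUAL_SEGMENTS] == [
            ("2020-06-11", "2020-11-03", "partial"),
            ("2020-11-04", "2021-03-25", "full"),
            ("2021-03-26", "2021-06-11", "partial"),
        ]

    def test_single_segment_presets(self):
        sched = build_schedule("partial_only", "2020-06-11", "2021-06-10")
        assert len(sched.segments) == 1
        assert sched.days == 365
        assert set(sched.day_types()) == {"partial"}

    def test_segment_day_counts_cover_window(self):
        sched = build_schedule("actual", "2020-06-11", "2021-06-11")
        assert sum(s.days for s in sched.segments) == sched.days == 366

    def test_window_outside_actual_dates_rejected(self):
        with pytest.raises(ValueError, match="not covered"):
            build_schedule("actual", "2020-01-01", "2021-06-11")

    def test_actual_preset_clips_to_window(self):
        sched = build_schedule("actual", "2020-10-01", "2020-12-01")
        assert [s.kind for s in sched.segments] == ["partial", "full"]
        assert str(sched.segments[0].end.date()) == "2020-11-03"


class TestRunReplicate:
    @pytest.mark.parametrize("action_beta, label", [
        (0.0, "cancelled"), (1e-9, "flat"),
    ])
    def test_flat_coefficient_pathologies(self, fixture_inputs, action_beta,
                                          label):
        """Two degenerate coefficient regimes: an all-zero depression matrix
        cancels every action pattern out exactly, so the whole population
        falls back to the ~0.002 baseline draw; a vanishingly small nonzero
        coefficient instead rides the sigmoid, pinning every agent who took
        any action at sigmoid(~0) = 0.5."""
        import dataclasses

        from lockdownsim.parameters import ACTION_COL, INTERCEPT, BetaMatrix

        schema, catalog = fixture_inputs.schema, fixture_inputs.catalog
        params = {}
        for ld in ("partial", "full"):
            ac = pd.DataFrame(0.0, index=list(catalog.actions),
                              columns=[INTERCEPT, *schema.onehot_columns])
            de = pd.DataFrame(0.0, index=list(catalog.actions),
                              columns=[INTERCEPT, ACTION_COL,
                                       *schema.onehot_columns])
            de[ACTION_COL] = action_beta
            params[("action_choice", ld)] = BetaMatrix(
                "action_choice", ld, ac).validate(schema, catalog)
            params[("depression_effect", ld)] = BetaMatrix(
                "depression_effect", ld, de).validate(schema, catalog)
        days = 30
        inputs = clipped_inputs(
            dataclasses.replace(fixture_inputs, params=params), days
        )
        inputs.cases.new_cases[:] = 0
        sched = build_schedule("partial_only", "2020-06-11", "2020-07-10")
        agents = sample_population(inputs.weights, 400,
                                   np.random.default_rng(1))
        df = run_replicate(agents, sched, inputs, np.random.default_rng(2))
        assert df["infected"].sum() == 0
        if label == "cancelled":
            expected, tol = 0.002, 0.001
        else:
            p_no_action = 0.5 ** 9  # each of 9 actions taken with p=0.5
            expected = (1 - p_no_action) * 0.5 + p_no_action * 0.002
            tol = 0.02
        assert df["mean_probability"].mean() == pytest.approx(expected, abs=tol)

    def test_zero_cases_means_no_one_forced_home(self, fixture_inputs):
        days = 50
        inputs = clipped_inputs(fixture_inputs, days)
        inputs.cases.new_cases[:] = 0
        sched = build_schedule("partial_only", "2020-06-11", "2020-07-30")
        agents = sample_population(inputs.weights, 300,
                                   np.random.default_rng(3))
        df = run_replicate(agents, sched, inputs, np.random.default_rng(4))
        assert df["infected"].sum() == 0
        assert df["new_infections"].sum() == 0

    def test_same_seed_identical_output(self, fixture_inputs):
        days = 40
        inputs = clipped_inputs(fixture_inputs, days)
        sched = build_schedule("full_only", "2020-06-11", "2020-07-20")
        agents = sample_population(inputs.weights, 250,
                                   np.random.default_rng(6))
        a = run_replicate(agents, sched, inputs, np.random.default_rng(9))
        b = run_replicate(agents, sched, inputs, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_case_series_length_must_match(self, fixture_inputs):
        sched = build_schedule("partial_only", "2020-06-11", "2020-06-20")
        agents = sample_population(fixture_inputs.weights, 50,
                                   np.random.default_rng(6))
        with pytest.raises(ValueError, match="length"):
            run_replicate(agents, sched, fixture_inputs,
                          np.random.default_rng(0))


class TestRunScenario:
    def test_end_to_end_determinism(self, fixture_inputs):
        cfg = small_config()
        inputs = clipped_inputs(fixture_inputs, 100)
        r1 = run_scenario(cfg, inputs)
        r2 = run_scenario(cfg, inputs)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)
        for a, b in zip(r1.replicates, r2.replicates):
            pd.testing.assert_frame_equal(a, b)

    def test_summary_shape_and_ci_ordering(self, fixture_inputs):
        cfg = small_config(replicates=6)
        res = run_scenario(cfg, clipped_inputs(fixture_inputs, 100))
        assert res.n_replicates == 6
        assert len(res.summary) == 100
        assert (res.summary["ci_low"] <= res.summary["mean"]).all()
        assert (res.summary["mean"] <= res.summary["ci_high"]).all()
        assert ((res.summary["mean"] >= 0) & (res.summary["mean"] <= 1)).all()

    def test_ci_width_shrinks_with_replicates(self, fixture_inputs):
        """Quadrupling R should roughly halve the CI width (CLT scaling)."""
        inputs = clipped_inputs(fixture_inputs, 60)
        widths = {}
        for reps in (8, 32):
            cfg = small_config(
                replicates=reps, end_date="2020-08-09", n_agents=150
            )
            res = run_scenario(cfg, inputs)
            w = (res.summary["ci_high"] - res.summary["ci_low"]).tail(30).mean()
            widths[reps] = w
        ratio = widths[8] / widths[32]
        assert ratio == pytest.approx(2.0, rel=0.35)

    def test_results_written_to_disk(self, fixture_inputs, tmp_path):
        cfg = small_config(replicates=3, output_dir=str(tmp_path / "out"))
        run_scenario(cfg, clipped_inputs(fixture_inputs, 100))
        assert (tmp_path / "out" / "summary.csv").exists()
        assert (tmp_path / "out" / "replicate_000.csv").exists()
        df = pd.read_csv(tmp_path / "out" / "replicate_000.csv")
        assert {"day", "symptomatic_share", "mean_probability", "infected",
                "recovered"} <= set(df.columns)

    def test_larger_population_agrees_within_monte_carlo_error(
        self, fixture_inputs
    ):
        """A 10x larger population should reproduce the final prevalence of
        the small run within Monte-Carlo error (scale robustness)."""
        inputs = clipped_inputs(fixture_inputs, 120)
        cfg_small = small_config(n_agents=1000, replicates=8,
                                 end_date="2020-10-08")
        cfg_big = small_config(n_agents=10_000, replicates=2, seed=6,
                               end_date="2020-10-08")
        res_small = run_scenario(cfg_small, inputs)
        res_big = run_scenario(cfg_big, inputs)
        assert res_big.final["mean"] == pytest.approx(
            res_small.final["mean"], abs=0.02
        )

    def test_isolation_beta_monotonicity(self, fixture_inputs):
        """Final prevalence weakly increases in the feel-isolated depression
        coefficient, everything else fixed."""
        import dataclasses

        inputs = clipped_inputs(fixture_inputs, 60)
        finals = []
        for beta in (-1.0, 0.68, 3.0):
            params = {}
            for key, bm in inputs.params.items():
                table = bm.table.copy()
                if key[0] == "depression_effect":
                    table.loc["feel_isolated", "action"] = beta
                params[key] = dataclasses.replace(bm, table=table)
            mod = dataclasses.replace(inputs, params=params)
            cfg = small_config(n_agents=400, replicates=6,
                               end_date="2020-08-09")
            finals.append(run_scenario(cfg, mod).final["mean"])
        assert finals[0] <= finals[1] <= finals[2]


class TestCompareScenarios:
    def test_identical_inputs_overlap_everywhere(self, fixture_inputs):
        inputs = clipped_inputs(fixture_inputs, 60)
        cfg = small_config(end_date="2020-08-09")
        res = run_scenario(cfg, inputs)
        table = compare_scenarios({"a": res, "b": res})
        assert (table["distinct_from"] == "").all()

    def test_report_has_one_row_per_scenario(self, fixture_inputs):
        inputs = clipped_inputs(fixture_inputs, 60)
        results = {}
        for i, preset in enumerate(["partial_only", "full_only", "actual"]):
            end = "2020-08-09"
            cfg = small_config(preset=preset, end_date=end, seed=20 + i)
            results[preset] = run_scenario(cfg, inputs)
        table = compare_scenarios(results)
        assert len(table) == 3
        assert set(table["scenario"]) == set(results)

    def test_mismatched_horizons_rejected(self, fixture_inputs):
        a = run_scenario(small_config(end_date="2020-08-09"),
                         clipped_inputs(fixture_inputs, 60))
        b = run_scenario(small_config(end_date="2020-07-10"),
                         clipped_inputs(fixture_inputs, 30))
        with pytest.raises(ValueError, match="horizon"):
            compare_scenarios({"a": a, "b": b})

    def test_full_lockdown_final_prevalence_at_least_partial(
        self, fixture_inputs
    ):
        """Directional finding: with the published effect coefficients, a
        year of full lockdown yields at least the final prevalence of a year
        of partial lockdown."""
        res = {}
        for preset in ("partial_only", "full_only"):
            cfg = ScenarioConfig(n_agents=500, replicates=10, seed=31,
                                 preset=preset, start_date="2020-06-11",
                                 end_date="2021-06-10")
            res[preset] = run_scenario(cfg, clipped_inputs(fixture_inputs, 365))
        assert res["full_only"].final["mean"] >= res["partial_only"].final["mean"]
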