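import numpy as np
import pandas as pd
import pytest

from swgee.sim_study import (
    AnalysisMethod,
    Scenario,
    default_methods,
    phase1_grid,
    phase2_grid,
    run_scenario,
    run_study,
    summarise,
)


class TestGrids:
    def test_phase_one_size_and_constraints(self):
        grid = phase1_grid()
        assert len(grid) == 64
        assert all(s.n_clusters == 18 for s in grid)
        assert len({s.scenario_id for s in grid}) == 64

    def test_phase_two_size_and_footnote_restrictions(self):
        grid = phase2_grid()
        assert len(grid) == 690
        big = [s for s in grid if s.cluster_size == 300]
        assert len(big) == 18
        assert all(s.structure == "exchangeable" for s in big)
        assert all(s.cv == 0.0 for s in big)
        assert all(s.n_clusters in (12, 24, 42) for s in big)
        assert len({s.scenario_id for s in grid}) == 690

    def test_ids_stable(self):
        a = [s.scenario_id for s in phase1_grid()]
        b = [s.scenario_id for s in phase1_grid()]
        assert a == b


@pytest.fixture(scope="module")
def tiny_run():
    sc = Scenario(1, 3, 12, "exchangeable", 0.05, 24, 0.0)
    methods = [
        AnalysisMethod("independence", "LZ", "Inf"),
        AnalysisMethod("independence", "FG", "FG"),
        AnalysisMethod("exchangeable", "FG", "C-P"),
        AnalysisMethod("independence", "MD", "PW"),
    ]
    return sc, methods, run_scenario(sc, methods, 40, seed=2)


class TestRunScenario:
    def test_metric_ranges(self, tiny_run):
        _, _, results = tiny_run
        for r in results:
            assert 0 <= r.coverage <= 1
            assert 0 <= r.power <= 1
            assert 0 < r.n_fit_converged <= r.n_reps
            assert r.sd_est > 0

    def test_reproducible(self, tiny_run):
        sc, methods, results = tiny_run
        again = run_scenario(sc, methods, 40, seed=2)
        for a, b in zip(results, again):
            assert a.rel_se_error == b.rel_se_error
            assert a.coverage == b.coverage

    def test_seed_changes_results(self, tiny_run):
        sc, methods, results = tiny_run
        other = run_scenario(sc, methods, 40, seed=3)
        assert any(a.mean_est != b.mean_est for a, b in zip(results, other))

    def test_estimate_shared_across_corrections(self, tiny_run):
        _, _, results = tiny_run
        ind = [r for r in results if r.method.working == "independence"]
        assert len({round(r.mean_est, 12) for r in ind}) == 1

    def test_rejects_single_rep(self, tiny_run):
        sc, methods, _ = tiny_run
        with pytest.raises(ValueError):
            run_scenario(sc, methods, 1, seed=2)


class TestRunStudyAndSummarise:
    def test_frame_layout_and_order_independence(self):
        scenarios = [
            Scenario(1, 3, 12, "exchangeable", 0.05, 24, 0.0),
            Scenario(1, 3, 12, "ar1_0.6", 0.05, 24, 0.0),
        ]
        methods = [AnalysisMethod("independence", "LZ", "Inf")]
        df = run_study(scenarios, methods, 20, seed=4)
        df_rev = run_study(scenarios[::-1], methods, 20, seed=4)
        assert len(df) == 2
        merged = df.merge(df_rev, on="scenario", suffixes=("", "_r"))
        assert (merged["rel_se_error"] == merged["rel_se_error_r"]).all()

    def test_summarise_bands(self):
        rows = []
        for cov in (0.92, 0.95, 0.97):
            rows.append(
                {
                    "working": "independence",
                    "correction": "LZ",
                    "df": "Inf",
                    "std_bias": 0.0,
                    "rel_se_error": -0.05,
                    "coverage": cov,
                    "power": 0.5,
                    "conv_prop": 1.0,
                }
            )
        out = summarise(pd.DataFrame(rows))
        assert out.loc[0, "n_scenarios"] == 3
        assert out.loc[0, "n_low_coverage"] == 1
        assert out.loc[0, "n_high_coverage"] == 1
        assert out.loc[0, "coverage"] == pytest.approx(np.mean([0.92, 0.95, 0.97]))

    def test_default_method_sets(self):
        assert len(default_methods(1)) == 14
        assert all(m.df in ("FG", "C-P") for m in default_methods(2))
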