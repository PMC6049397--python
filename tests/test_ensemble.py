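"""Ensemble aggregation, exclusion rules, survival of mosaicism, presets."""

import numpy as np
import pytest
import scipy.stats

from ringdrift import (
    ConfigError,
    SimConfig,
    SurvivalTable,
    experiment_grid,
    logrank_mosaicism,
    run_ensemble,
    survival_of_mosaicism,
)


class TestAggregation:
    def test_single_replicate_means_equal_trace_values(self):
        cfg = SimConfig(n_cells=20, generations=10, p_replace=0.2, replicates=1, seed=1)
        result = run_ensemble(cfg, keep_traces=True)
        trace = result.traces[0]
        for g, s in enumerate(trace.summaries):
            row = result.per_generation.iloc[g]
            assert row["pct_blue_mean"] == pytest.approx(s.pct_blue)
            assert np.isnan(row["pct_blue_ci95"])  # CI undefined for one replicate

    def test_confidence_interval_matches_hand_computed_t_interval(self):
        """95% CI half-widths agree with a direct t-interval on the raw replicate values."""
        cfg = SimConfig(n_cells=40, generations=5, p_replace=0.3, replicates=8, seed=2)
        result = run_ensemble(cfg, keep_traces=True)
        g = 5
        values = np.array(
            [t.summaries[g].corrected_stripes for t in result.traces], dtype=float
        )
        values = values[~np.isnan(values)]
        n = values.size
        expected_half = scipy.stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n)
        row = result.per_generation.iloc[g]
        assert row["corrected_mean"] == pytest.approx(values.mean())
        assert row["corrected_ci95"] == pytest.approx(expected_half)
        assert row["corrected_n"] == n

    def test_fixed_replicates_excluded_from_corrected_but_not_pct(self):
        """After fixation a replicate still reports 0/100% and 1 stripe, never a
        corrected stripe number; an emptied replicate reports nothing."""
        cfg = SimConfig(n_cells=6, generations=60, p_loss=0.3, replicates=30, seed=3)
        result = run_ensemble(cfg, keep_traces=True)
        saw_fixation = saw_empty = False
        for g in range(cfg.generations + 1):
            row = result.per_generation.iloc[g]
            n_alive = sum(t.summaries[g].n_total > 0 for t in result.traces)
            n_mosaic = sum(t.summaries[g].mosaic for t in result.traces)
            assert row["pct_blue_n"] == n_alive
            assert row["uncorrected_n"] == n_alive
            assert row["corrected_n"] == n_mosaic
            saw_fixation |= n_mosaic < n_alive
            saw_empty |= n_alive < 30
            for t in result.traces:
                s = t.summaries[g]
                if s.n_total > 0 and not s.mosaic:
                    assert s.uncorrected_stripes == 1
                    assert s.pct_blue in (0.0, 100.0)
                    assert s.corrected_stripes is None
        assert saw_fixation and saw_empty

    def test_per_replicate_half_life_uses_own_baseline(self):
        cfg = SimConfig(n_cells=120, generations=50, p_loss=0.05, replicates=5, seed=4)
        result = run_ensemble(cfg, keep_traces=True)
        from ringdrift.stats import half_life

        for trace, hl in zip(result.traces, result.per_replicate_half_life):
            series = [s.corrected_stripes for s in trace.summaries]
            assert hl.value == half_life(series).value
            assert hl.mode == "per-replicate"


class TestSurvival:
    def test_median_of_explicit_loss_generations(self):
        table = SurvivalTable(loss_generation=[7, 7, 8], horizon=100)
        assert table.median_survival() == 7

    def test_all_censored_reports_exceeds_horizon(self):
        table = SurvivalTable(loss_generation=[None] * 20, horizon=1000)
        assert table.median_survival() == ">1000"

    def test_majority_censored_reports_exceeds_horizon(self):
        table = SurvivalTable(loss_generation=[5] * 9 + [None] * 11, horizon=200)
        assert table.median_survival() == ">200"

    def test_kaplan_meier_median_matches_empirical(self):
        table = SurvivalTable(
            loss_generation=[3, 5, 5, 8, 12, None, None], horizon=50
        )
        # ceil(7/2)=4th event time = 8 under both conventions
        assert table.median_survival("empirical") == 8
        assert table.median_survival("km") == 8

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            SurvivalTable([1], 10).median_survival("banana")

    def test_non_mosaic_start_rejected(self):
        cfg = SimConfig(n_cells=6, generations=2, p_blue=1.0, seed=5)
        from ringdrift import run_simulation

        with pytest.raises(ValueError):
            survival_of_mosaicism([run_simulation(cfg)])

    def test_loss_generation_matches_trace_fixation(self):
        cfg = SimConfig(n_cells=6, generations=300, p_replace=0.5, replicates=10, seed=6)
        result = run_ensemble(cfg, keep_traces=True)
        for trace, g in zip(result.traces, result.survival.loss_generation):
            mosaic = [s.mosaic for s in trace.summaries]
            if g is None:
                assert all(mosaic)
            else:
                assert mosaic[g - 1] and not mosaic[g]

    def test_logrank_smoke(self):
        small = SurvivalTable(loss_generation=[3, 4, 5, 6, 7, 8, 9, 10], horizon=100)
        large = SurvivalTable(loss_generation=[None] * 8, horizon=100)
        p = logrank_mosaicism([small, large])
        assert 0 < p < 0.05
        mid = SurvivalTable(loss_generation=[20, 30, 40, None, None, None, None, None], horizon=100)
        p_trend = logrank_mosaicism([small, mid, large], trend=True)
        assert 0 < p_trend < 1


class TestExperimentGrid:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError):
            experiment_grid("no-such-grid")

    def test_grid_is_reproducible_from_master_seed(self):
        a = experiment_grid("half-life-basic", seed=7, replicates=2)
        b = experiment_grid("half-life-basic", seed=7, replicates=2)
        assert len(a) == len(b) == 12
        for ra, rb in zip(a, b):
            assert ra.label == rb.label
            assert ra.config == rb.config
            assert ra.survival.median_survival() == rb.survival.median_survival()
            assert (
                ra.per_generation["corrected_mean"].to_numpy()
                == rb.per_generation["corrected_mean"].to_numpy()
            ).all(where=~np.isnan(ra.per_generation["corrected_mean"].to_numpy()))
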