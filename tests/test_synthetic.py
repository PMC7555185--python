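"""Synthetic study generator: determinism, calibration, closed loops."""

import numpy as np
import pandas as pd
import pytest

from rancistab import (
    MarkerSpec,
    SimulationConfig,
    TraceParams,
    compute_q10,
    correlation_matrix,
    detect_induction_tangent,
    pearson,
    simulate_osi_study,
    simulate_quality_panel,
    simulate_storage_osi,
    simulate_study,
    simulate_trace,
    summarize_osi,
)
from rancistab.errors import InvalidConfig


class TestSimulateTrace:
    def test_noise_free_detection_recovers_induction_time(self):
        trace = simulate_trace(10.0, TraceParams(noise_sd=0.0), 0)
        res = detect_induction_tangent(trace)
        assert res.osi == pytest.approx(10.0, rel=5e-3)

    def test_trace_covers_induction_time(self):
        trace = simulate_trace(4.0, TraceParams(), 1)
        assert trace.time[-1] >= 1.5 * 4.0

    def test_seed_contract(self):
        p = TraceParams(noise_sd=0.5)
        t1 = simulate_trace(8.0, p, 11)
        t2 = simulate_trace(8.0, p, 12)
        t3 = simulate_trace(8.0, p, 11)
        assert not np.array_equal(t1.conductivity, t2.conductivity)
        assert np.array_equal(t1.conductivity, t3.conductivity)
        assert np.array_equal(t1.time, t2.time)  # same generative induction

    def test_rejects_nonpositive_induction(self):
        with pytest.raises(InvalidConfig):
            simulate_trace(0.0, TraceParams(), 0)


class TestOsiStudy:
    def test_byte_identical_under_same_seed(self):
        cfg = SimulationConfig(seed=42)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        pd.testing.assert_frame_equal(a.osi_truth, b.osi_truth)
        pd.testing.assert_frame_equal(a.panels, b.panels)
        assert all(
            np.array_equal(x.conductivity, y.conductivity)
            for x, y in zip(a.traces, b.traces)
        )

    def test_zero_cv_gives_zero_cell_cv(self):
        cfg = SimulationConfig(seed=0, replicate_cv=0.0)
        ds = simulate_osi_study(cfg, render_traces=False)
        out = summarize_osi(ds.osi_truth)
        assert (out["cv_pct"] == 0.0).all()

    def test_exact_halving_gives_q10_of_two(self):
        """kinetic_a = log10(2)/10 per degree halves OSI every 10 C."""
        cfg = SimulationConfig(seed=0, kinetic_a=-np.log10(2) / 10, replicate_cv=0.0)
        ds = simulate_osi_study(cfg, render_traces=False)
        cell = summarize_osi(ds.osi_truth)
        pts = cell.groupby("temperature_C")["mean_osi_h"].mean().reset_index()
        q10 = compute_q10(list(zip(pts["temperature_C"], pts["mean_osi_h"])))
        assert q10 == pytest.approx(2.0, rel=1e-9)

    def test_replicate_cv_calibration(self):
        """Lognormal scatter reproduces the requested CV (10% tolerance at
        a large replicate count)."""
        cfg = SimulationConfig(seed=3, replicate_cv=8.0, replicates_per_cell=2000,
                               temperatures=(110.0,), airflows=(25.0,))
        ds = simulate_osi_study(cfg, render_traces=False)
        out = summarize_osi(ds.osi_truth)
        assert out.loc[0, "cv_pct"] == pytest.approx(8.0, rel=0.1)

    def test_traces_match_truth_grid(self):
        cfg = SimulationConfig(seed=1, replicates_per_cell=2,
                               temperatures=(110.0, 120.0), airflows=(25.0,))
        ds = simulate_osi_study(cfg, render_traces=True)
        assert len(ds.traces) == len(ds.osi_truth)
        for trace, row in zip(ds.traces, ds.osi_truth.itertuples()):
            assert trace.temperature == row.temperature_C
            assert trace.time[-1] > row.osi_h  # truth inside the time range


class TestQualityPanel:
    @staticmethod
    def storage_structured_osi(n_lots: int, seed: int) -> pd.DataFrame:
        """Kernel OSI with the generator's storage structure: harvest level
        from the log-linear law, 0.85x decay per month, 8% lognormal
        scatter; one row per lot per storage time."""
        rng = np.random.default_rng(seed)
        n = 3 * n_lots
        months = np.tile([0.0, 4.0, 6.0], n_lots)
        sigma = np.sqrt(np.log1p(0.08**2))
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "storage_months": months,
                "osi_h": 10 ** (-0.037 * 110 + 5.181)
                * 0.85**months
                * rng.lognormal(-0.5 * sigma**2, sigma, n),
            }
        )

    def test_target_correlation_recovered_at_large_n(self):
        """Target r = -0.8 at n ~ 500 lands inside (-0.85, -0.75), the
        Fisher-z 95% interval being well inside that window at this n."""
        osi = self.storage_structured_osi(167, seed=0)  # n = 501
        panel = simulate_quality_panel(SimulationConfig(seed=9), osi)
        r = pearson(osi["osi_h"], panel["pv"]).r
        assert -0.85 < r < -0.75

    def test_moisture_uncorrelated(self):
        """Moisture's |r| stays below the 95% null quantile in >= 90% of
        50 seeds (two-sided null: |r| < r_crit at p=0.05)."""
        from scipy import stats

        n = 24
        base = np.random.default_rng(123)
        hits = 0
        t_crit = stats.t.ppf(0.975, n - 2)
        r_crit = np.sqrt(t_crit**2 / (t_crit**2 + n - 2))
        for seed in range(50):
            osi = pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(n)],
                    "storage_months": np.tile([0.0, 4.0, 6.0], 8),
                    "osi_h": base.lognormal(2.5, 0.3, n),
                }
            )
            panel = simulate_quality_panel(SimulationConfig(seed=seed), osi)
            if abs(pearson(osi["osi_h"], panel["moisture_pct"]).r) < r_crit:
                hits += 1
        assert hits >= 45

    def test_zero_residual_unit_correlation(self):
        cfg = SimulationConfig(
            seed=0,
            markers={"rancidity": MarkerSpec(5.0, 0.0, 0.0, -1.0, 0.0, 10.0)},
        )
        osi = simulate_storage_osi(cfg)
        panel = simulate_quality_panel(cfg, osi)
        out = correlation_matrix(
            osi.assign(label="ref"), panel, markers=["rancidity"]
        )
        assert out.loc[0, "r"] == pytest.approx(-1.0, abs=1e-12)

    def test_sign_pattern_matches_oxidation_chemistry(self):
        """Oil OSI correlates positively with kernel OSI; PV, K232, K268,
        hexanal and rancidity negatively."""
        ds = simulate_study(SimulationConfig(seed=4), render_traces=False)
        out = correlation_matrix(ds.storage_osi.assign(label="ref"), ds.panels)
        out = out.set_index("marker")
        assert out.loc["oil_osi_h", "r"] > 0
        for marker in ("pv", "k232", "k268", "hexanal_mg_kg", "rancidity"):
            assert out.loc[marker, "r"] < 0

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(InvalidConfig):
            MarkerSpec(1.0, 0.0, 0.5, -1.0)

    def test_markers_clipped_to_physical_ranges(self):
        ds = simulate_study(SimulationConfig(seed=8), render_traces=False)
        p = ds.panels
        assert p["rancidity"].between(0, 10).all()
        assert p["moisture_pct"].between(0, 100).all()
        assert (p[["pv", "hexanal_mg_kg", "oil_osi_h"]] >= 0).all().all()


class TestClosedLoop:
    def test_detect_summarize_fit_recovers_kinetics(self):
        """Trace rendering -> detection -> cell means -> log-linear fit
        recovers the generative slope within its standard error on most
        seeds (10 seeds here; the acceptance suite runs 50)."""
        from rancistab import fit_log_linear

        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, replicate_cv=5.0)
            ds = simulate_osi_study(cfg, render_traces=True)
            rows = [
                {
                    "temperature_C": tr.temperature,
                    "airflow_L_h": tr.airflow,
                    "replicate": tr.replicate,
                    "osi_h": detect_induction_tangent(tr).osi,
                }
                for tr in ds.traces
            ]
            cell = summarize_osi(pd.DataFrame(rows))
            pts = cell.groupby("temperature_C")["mean_osi_h"].mean().reset_index()
            fit = fit_log_linear(list(zip(pts["temperature_C"], pts["mean_osi_h"])))
            if abs(fit.a - cfg.kinetic_a) <= max(2 * fit.se_a, 0.004):
                hits += 1
        assert hits >= 9
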