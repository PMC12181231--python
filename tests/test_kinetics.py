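"""Time-series assembly and exponential-plateau decay fitting."""

import numpy as np
import pytest

import dropcascade as dc
from dropcascade.acc_detect import TimePointCount


def tp(loc, step, t, n_acc, n_total, n_v=0, n_c=0):
    return TimePointCount(location_id=loc, timestep_index=step,
                          mean_time_min=t, time_span_min=(t, t),
                          n_droplets=n_total, n_vaterite_droplets=n_v,
                          n_calcite_droplets=n_c, n_acc=n_acc)


class TestAssembleTimeseries:
    def test_two_locations_pooled(self):
        series = dc.assemble_timeseries([tp(0, 0, 10.0, 30, 50),
                                         tp(1, 0, 12.0, 31, 50)])
        assert series.times[0] == pytest.approx(11.0)
        assert series.n_acc[0] == 61
        assert series.spans[0] == (10.0, 12.0)

    def test_single_location_span_collapses(self):
        series = dc.assemble_timeseries([tp(0, 0, 25.0, 10, 10)])
        assert series.spans[0] == (25.0, 25.0)

    def test_order_invariance(self):
        rows = [tp(loc, step, 10.0 * step + loc, 40 - step, 50)
                for loc in range(3) for step in range(4)]
        a = dc.assemble_timeseries(rows)
        b = dc.assemble_timeseries(rows[::-1])
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.n_acc, b.n_acc)

    def test_pooled_equals_sum_of_locations(self):
        rows = [tp(loc, 0, 5.0, 7 + loc, 10) for loc in range(4)]
        series = dc.assemble_timeseries(rows)
        assert series.n_acc[0] == sum(7 + loc for loc in range(4))
        assert series.n_total[0] == 40

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no count rows"):
            dc.assemble_timeseries([])


class TestFitDecay:
    def test_noiseless_recovery_of_count_model(self):
        """The fitter recovers (A, k, C) = (65.63, 0.027, 596.0) from its own
        noiseless curve to better than 1e-6 relative."""
        t = np.linspace(0, 360, 17)
        y = 65.63 * np.exp(-0.027 * t) + 596.0
        fit = dc.fit_decay(t, y, form="count")
        assert fit.A == pytest.approx(65.63, rel=1e-6)
        assert fit.k == pytest.approx(0.027, rel=1e-6)
        assert fit.C == pytest.approx(596.0, rel=1e-6)

    def test_constant_series_flags_no_decay(self):
        fit = dc.fit_decay([0, 10, 20, 30], [5.0, 5.0, 5.0, 5.0])
        assert fit.no_decay
        assert fit.C == pytest.approx(5.0, abs=1e-6)
        assert abs(fit.A) < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            dc.fit_decay([0, 1, 2], [3, 2, 1])

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            dc.fit_decay([-1, 0, 1, 2], [4, 3, 2, 1])

    def test_nan_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            dc.fit_decay([0, 1, 2, 3], [1.0, np.nan, 0.5, 0.4])

    def test_stochastic_rate_recovery(self):
        """Median fitted k over 30 seeded simulations (~660 droplets, 16
        timesteps) lands within 25% of the generating rate 0.027/min."""
        scene = dc.SceneSpec(droplets_per_frame=55)
        kin = dc.KineticsSpec(k_true=0.027, labile_fraction=0.1,
                              timesteps=list(np.linspace(0, 360, 16)),
                              n_locations=12)
        ks = []
        for seed in range(30):
            tl = dc.generate_timelapse(scene, kin, seed=seed, render=False)
            counts = [
                tp(int(r.location_id), int(r.timestep_index),
                   float(r.acquisition_time_min), int(r.n_acc),
                   int(r.n_droplets), int(r.n_vaterite_droplets),
                   int(r.n_calcite_droplets))
                for _, r in tl.true_counts.iterrows()
            ]
            series = dc.assemble_timeseries(counts)
            ks.append(dc.fit_decay(series.times, series.ratios(),
                                   form="ratio").k)
        assert abs(np.median(ks) - 0.027) / 0.027 < 0.25


class TestEvaluateFit:
    RATIO = dc.DecayFit("ratio", 0.099, 0.027, 0.898, 0.0, 17)

    def test_at_time_zero_is_amplitude_plus_plateau(self):
        assert dc.evaluate_fit(self.RATIO, 0.0) == pytest.approx(0.997)

    def test_end_of_run_value(self):
        assert dc.evaluate_fit(self.RATIO, 360.0) == pytest.approx(0.898,
                                                                   abs=5e-4)

    def test_long_time_limit_is_plateau(self):
        assert dc.evaluate_fit(self.RATIO, 1e9) == pytest.approx(0.898)

    def test_monotone_decreasing_for_positive_rate(self):
        ts = np.linspace(0, 500, 40)
        vals = [dc.evaluate_fit(self.RATIO, t) for t in ts]
        assert np.all(np.diff(vals) < 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            dc.evaluate_fit(self.RATIO, -1.0)


class TestAccFraction:
    def test_manual_count_ratio(self):
        assert dc.acc_fraction(443, 653) == 0.678

    def test_extremes(self):
        assert dc.acc_fraction(0, 10) == 0.0
        assert dc.acc_fraction(653, 653) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dc.acc_fraction(5, 0)
        with pytest.raises(ValueError):
            dc.acc_fraction(11, 10)


class TestHalfLife:
    def test_empirical_lower_bound(self):
        hl = dc.half_life_bound(empirical=[(1440.0, 0.678)])
        assert hl.kind == "lower_bound"
        assert hl.value_min == 1440.0

    def test_plateau_above_half_is_unreachable(self):
        fit = dc.DecayFit("ratio", 0.099, 0.027, 0.898, 0.0, 17)
        assert dc.half_life_bound(fit=fit).kind == "unreachable"

    def test_exact_half_life_closed_form(self):
        fit = dc.DecayFit("ratio", 1.0, 0.1, 0.0, 0.0, 10)
        hl = dc.half_life_bound(fit=fit)
        assert hl.kind == "exact"
        assert hl.value_min == pytest.approx(np.log(2) / 0.1)

    def test_count_form_fit_rejected(self):
        fit = dc.DecayFit("count", 65.63, 0.027, 596.0, 0.0, 17)
        with pytest.raises(ValueError, match="ratio-form"):
            dc.half_life_bound(fit=fit)


class TestBootstrap:
    def test_interval_brackets_generating_rate(self):
        rng = np.random.default_rng(0)
        t_grid = np.linspace(0, 360, 12)
        rows = []
        for loc in range(6):
            n = 50
            for step, t in enumerate(t_grid):
                p = 0.9 + 0.1 * np.exp(-0.03 * t)
                n_acc = int(rng.binomial(n, p))
                rows.append(tp(loc, step, float(t), n_acc, n))
        lo, hi = dc.bootstrap_rate_ci(rows, n_boot=50, seed=1)
        assert lo <= 0.03 <= hi
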