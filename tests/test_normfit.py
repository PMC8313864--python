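"""Tests for normalization, opto-model fitting and AIC comparison."""

import numpy as np
import pytest

import optorelease as opt
from optorelease.kinetics import NoiseSpec
from optorelease.normfit import subtract_background
from optorelease.result import aic_gaussian, akaike_weights


def _noisy_normalized(rates, schedule, seed, frac=0.01):
    trace = opt.simulate_trace(rates, schedule, noise=NoiseSpec(frac=frac), seed=seed)
    return opt.renormalise_per_frame(trace)


class TestBackground:
    def test_zero_background_is_identity(self, standard_rates, standard_schedule):
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        out, floored = subtract_background(trace, np.zeros(10))
        assert floored == 0
        assert np.allclose(out.stacked(), trace.stacked())

    def test_scalar_mean_subtracted(self, standard_schedule):
        n = standard_schedule.n_frames
        trace = opt.CompartmentTrace(
            standard_schedule, np.full(n, 10.0), np.full(n, 8.0), np.full(n, 6.0)
        )
        out, floored = subtract_background(trace, np.array([3.0, 5.0]))
        assert np.allclose(out.M, 6.0)
        assert floored == 0

    def test_negative_results_floored_and_counted(self, standard_schedule):
        n = standard_schedule.n_frames
        trace = opt.CompartmentTrace(
            standard_schedule, np.full(n, 2.0), np.full(n, 8.0), np.full(n, 6.0)
        )
        out, floored = subtract_background(trace, np.array([4.0]))
        assert np.allclose(out.M, 0.0)
        assert floored == n


class TestBilinearNormalise:
    def test_flat_total_divides_exactly(self, standard_rates, standard_schedule):
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        scaled = trace.scaled(500.0)
        out = opt.bilinear_normalise(scaled)
        assert out.normalized
        assert np.max(np.abs(out.total - 1.0)) <= 1e-6
        assert np.allclose(out.stacked(), trace.stacked(), atol=1e-9)

    def test_inverts_applied_linear_decay(self, standard_rates, standard_schedule):
        """Per-phase linear bleaching applied by the generator is removed."""
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        bleach = np.ones(standard_schedule.n_frames)
        level = 1.0
        for start, stop, lit in standard_schedule.phases():
            slope = 4e-4 if lit else 1e-4
            k = np.arange(stop - start)
            bleach[start:stop] = level - slope * k
            level = bleach[stop - 1] - slope
        bleached = opt.CompartmentTrace(
            standard_schedule, trace.M * bleach, trace.C * bleach, trace.N * bleach
        )
        out = opt.bilinear_normalise(bleached)
        assert np.max(np.abs(out.stacked() - trace.stacked())) <= 1e-6

    def test_needs_both_phases(self, standard_rates):
        sched = opt.LightSchedule.from_blocks([(40, False)])
        trace = opt.simulate_trace(standard_rates, sched)
        with pytest.raises(ValueError):
            opt.bilinear_normalise(trace)

    def test_short_phase_rejected(self, standard_rates):
        sched = opt.LightSchedule.from_blocks([(2, False), (40, True)])
        trace = opt.simulate_trace(standard_rates, sched, init=(0.4, 0.3, 0.3))
        with pytest.raises(ValueError, match="usable frames"):
            opt.bilinear_normalise(trace)


class TestOptoFit:
    def test_noiseless_round_trip_within_one_percent(
        self, standard_rates, standard_schedule
    ):
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        fit = opt.fit_opto_model(trace, n_starts=1)
        for name in (
            "k_imp", "k_exp", "k_on_unlit", "k_off_unlit", "k_on_lit", "k_off_lit"
        ):
            assert fit.params[name] == pytest.approx(
                getattr(standard_rates, name), rel=0.01
            )

    def test_reported_dark_state_binding_medians_recovered(self, standard_schedule):
        """Traces generated at the dark-state binding medians (0.027 / 0.019
        s^-1) return those constants from the dual-rate fit."""
        rates = opt.RateParams(0.002, 0.002, 0.027, 0.019, 0.027, 0.085)
        trace = opt.simulate_trace(rates, standard_schedule)
        fit = opt.fit_opto_model(trace, n_starts=1)
        assert fit.params["k_on_unlit"] == pytest.approx(0.027, rel=0.02)
        assert fit.params["k_off_unlit"] == pytest.approx(0.019, rel=0.02)

    def test_all_dark_trace_flags_lit_rates(self, standard_rates):
        sched = opt.LightSchedule.from_blocks([(60, False)])
        trace = opt.simulate_trace(standard_rates, sched)
        fit = opt.fit_opto_model(trace, n_starts=1)
        assert any("k_on_lit" in f for f in fit.flags)
        assert any("k_off_lit" in f for f in fit.flags)

    def test_unnormalized_trace_rejected(self, standard_rates, standard_schedule):
        trace = opt.simulate_trace(
            standard_rates, standard_schedule, noise=NoiseSpec(0.01), seed=0
        )
        with pytest.raises(ValueError):
            opt.fit_opto_model(trace)

    def test_noisy_recovery_median_error(self, standard_rates, standard_schedule):
        """Across seeds at 1% noise the median relative error stays small."""
        errs = []
        for seed in range(8):
            trace = _noisy_normalized(standard_rates, standard_schedule, seed)
            fit = opt.fit_opto_model(trace, n_starts=1)
            errs.append(
                [
                    abs(fit.params[n] - getattr(standard_rates, n))
                    / getattr(standard_rates, n)
                    for n in (
                        "k_imp", "k_exp", "k_on_unlit", "k_off_unlit",
                        "k_on_lit", "k_off_lit",
                    )
                ]
            )
        med = np.median(np.array(errs), axis=0)
        assert np.all(med <= 0.10)

    def test_expression_scale_invariance(self, standard_rates, standard_schedule):
        """Uniform scaling of all compartments (expression level) leaves the
        fitted rates unchanged."""
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        raw = trace.scaled(1234.5)
        norm = opt.bilinear_normalise(raw)
        fit_scaled = opt.fit_opto_model(norm, n_starts=1)
        fit_ref = opt.fit_opto_model(trace, n_starts=1)
        for name in fit_ref.params:
            assert fit_scaled.params[name] == pytest.approx(
                fit_ref.params[name], rel=1e-6
            )

    def test_single_compartment_gain_sensitivity_bounded(
        self, standard_rates, standard_schedule
    ):
        """A small gain miscalibration of one compartment's signal perturbs
        the bilinear total, so rate estimates shift, but the shift stays of
        the same order as the miscalibration itself (all three compartments
        share one detector, so only small relative errors are physical)."""
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        skewed = opt.CompartmentTrace(
            standard_schedule, trace.M * 1.05, trace.C, trace.N
        )
        norm = opt.renormalise_per_frame(opt.bilinear_normalise(skewed))
        fit = opt.fit_opto_model(norm, n_starts=1)
        for name in ("k_on_unlit", "k_off_unlit", "k_imp", "k_exp"):
            assert fit.params[name] == pytest.approx(
                getattr(standard_rates, name), rel=0.10
            )

    def test_fixed_dark_rate_variant_uses_given_values(
        self, standard_rates, standard_schedule
    ):
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        variant = opt.ModelVariant(
            on_rate_mode="dual", dark_rate_mode="fixed_values",
            fixed_k_on_unlit=0.027, fixed_k_off_unlit=0.019,
        )
        fit = opt.fit_opto_model(trace, variant, n_starts=1)
        assert "k_on_unlit" not in fit.params
        assert fit.extra["rates"].k_on_unlit == 0.027


class TestPhaseRestriction:
    def test_both_phase_intervals_are_narrowest(
        self, standard_rates, standard_schedule
    ):
        """Using release and recovery together tightens every shared
        parameter's interval relative to either phase alone (median over
        seeded noisy simulations)."""
        params = ["k_imp", "k_exp", "k_on_unlit", "k_off_unlit"]
        widths = {p: {"both": [], "release": [], "recovery": []} for p in params}
        for seed in range(6):
            trace = _noisy_normalized(standard_rates, standard_schedule, seed)
            for ph in ("both", "release", "recovery"):
                fit = opt.phase_restricted_ci(trace, phases=ph, n_starts=1)
                for p in params:
                    widths[p][ph].append(fit.ci_width(p))
        for p in params:
            med = {ph: np.median(widths[p][ph]) for ph in widths[p]}
            assert med["both"] <= med["release"]
            assert med["both"] <= med["recovery"]

    def test_noiseless_intervals_near_zero(self, standard_rates, standard_schedule):
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        fit = opt.phase_restricted_ci(trace, phases="both", n_starts=1)
        for name in ("k_imp", "k_exp", "k_on_unlit", "k_off_unlit"):
            assert fit.ci_width(name) < 1e-6

    def test_recovery_only_flags_lit_rates(self, standard_rates, standard_schedule):
        trace = _noisy_normalized(standard_rates, standard_schedule, 0)
        fit = opt.phase_restricted_ci(trace, phases="recovery", n_starts=1)
        assert any("k_on_lit" in f for f in fit.flags)
        assert any("k_off_lit" in f for f in fit.flags)


class TestAic:
    def test_equal_fits_share_weight(self):
        w = akaike_weights(np.array([10.0, 10.0]))
        assert np.allclose(w, [0.5, 0.5])

    def test_two_point_penalty_gives_weight_ratio_e(self):
        a1 = aic_gaussian(rss=1.0, n=300, k=6)
        a2 = aic_gaussian(rss=1.0, n=300, k=7)
        assert a2 - a1 == pytest.approx(2.0)
        w = akaike_weights(np.array([a1, a2]))
        assert w[0] / w[1] == pytest.approx(np.e)

    def test_weights_sum_to_one(self):
        w = akaike_weights(np.array([3.0, 9.0, 1.0, 4.5]))
        assert w.sum() == pytest.approx(1.0)

    def test_distinct_on_rates_prefer_dual_variant(self, standard_schedule):
        rates = opt.RateParams(0.002, 0.002, 0.027, 0.019, 0.010, 0.085)
        variants = [
            opt.ModelVariant(on_rate_mode="single"),
            opt.ModelVariant(on_rate_mode="dual"),
        ]
        wins = 0
        for seed in range(10):
            trace = _noisy_normalized(rates, standard_schedule, seed)
            res = opt.compare_models_aic(trace, variants, n_starts=1, seed=seed)
            w_dual = next(
                r.akaike_weight for r in res if r.variant.startswith("dual")
            )
            wins += w_dual is not None and w_dual > 0.9
        assert wins >= 9

    def test_needs_two_variants(self, standard_rates, standard_schedule):
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        with pytest.raises(ValueError):
            opt.compare_models_aic(trace, [opt.ModelVariant()])


class TestExpressionCohort:
    def test_no_correlation_with_expression_level(
        self, standard_rates, standard_schedule
    ):
        """Fitted rates show no trend against total fluorescence across a
        cohort with varied expression scaling."""
        from scipy.stats import spearmanr

        scales, k_imps, k_ons = [], [], []
        rng = np.random.default_rng(11)
        for seed in range(30):
            scale = float(rng.uniform(200.0, 5000.0))
            trace = opt.simulate_trace(
                standard_rates, standard_schedule,
                noise=NoiseSpec(frac=0.01), seed=seed,
            )
            raw = trace.scaled(scale)
            norm = opt.renormalise_per_frame(opt.bilinear_normalise(raw))
            fit = opt.fit_opto_model(norm, n_starts=1)
            scales.append(scale)
            k_imps.append(fit.params["k_imp"])
            k_ons.append(fit.params["k_on_unlit"])
        for vals in (k_imps, k_ons):
            rho = abs(spearmanr(scales, vals).statistic)
            assert rho < 0.2
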