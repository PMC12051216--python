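import numpy as np
import pytest
from scipy import integrate, stats

from trajrecur import (
    EventWindow,
    cumulative_intensity,
    fit_nhpp,
    hazard_ratios,
    mean_survival_curve,
    simulate_events,
    survival_first_event,
    transform_residuals,
    window_loglik,
)
from trajrecur.nhpp import NHPPFit, NHPPParams, residual_mean


def _lam(t, params, xg=0.0):
    e, b = params.eta, params.beta_shape
    return (b / e) * (t / e) ** (b - 1) * np.exp(xg)


class TestCumulativeIntensity:
    def test_zero_at_origin(self):
        p = NHPPParams(100.0, 2.0)
        assert cumulative_intensity(0.0, [], p) == 0.0

    def test_closed_form(self):
        p = NHPPParams(100.0, 2.0)
        assert cumulative_intensity(100.0, [], p) == pytest.approx(1.0)

    @pytest.mark.parametrize("eta,beta,xg", [(400.0, 1.3, 0.0), (50.0, 0.8, 0.7)])
    def test_matches_quadrature_of_intensity(self, eta, beta, xg):
        p = NHPPParams(eta, beta, [xg])
        x = [1.0]
        for t in (10.0, 200.0, 900.0):
            quad, _ = integrate.quad(_lam, 0, t, args=(p, xg), points=[1e-9])
            assert cumulative_intensity(t, x, p) == pytest.approx(quad, rel=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cumulative_intensity(-1.0, [], NHPPParams(100.0, 1.0))

    def test_strictly_increasing(self):
        p = NHPPParams(300.0, 1.3)
        t = np.linspace(0, 2000, 100)
        assert np.all(np.diff(cumulative_intensity(t, [], p)) > 0)


class TestWindowLoglik:
    def test_hand_evaluated_example(self):
        """Window (0,100], events {40, 80}, beta=2, eta=100:
        log(0.008) + log(0.016) - 1."""
        p = NHPPParams(100.0, 2.0)
        w = EventWindow("a", 0.0, 100.0, np.array([40.0, 80.0]))
        expected = np.log(0.008) + np.log(0.016) - 1.0
        assert window_loglik(p, [w]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-9.9635, abs=5e-5)

    def test_no_events_is_minus_lambda_gap(self):
        p = NHPPParams(200.0, 1.5, [0.3])
        w = EventWindow("a", 50.0, 400.0, np.array([]), np.array([1.0]))
        gap = cumulative_intensity(400.0, [1.0], p) - cumulative_intensity(
            50.0, [1.0], p
        )
        assert window_loglik(p, [w]) == pytest.approx(-gap)

    def test_doubling_cohort_doubles_loglik(self):
        p = NHPPParams(150.0, 1.2, [0.5])
        ws = [
            EventWindow("a", 0.0, 300.0, np.array([100.0, 250.0]), np.array([1.0])),
            EventWindow("b", 20.0, 500.0, np.array([60.0]), np.array([0.0])),
        ]
        assert window_loglik(p, ws + ws) == pytest.approx(2 * window_loglik(p, ws))

    def test_splitting_window_leaves_loglik_unchanged(self):
        p = NHPPParams(150.0, 1.4, [0.2])
        x = np.array([1.0])
        whole = [EventWindow("a", 0.0, 100.0, np.array([30.0, 70.0]), x)]
        split = [
            EventWindow("a1", 0.0, 50.0, np.array([30.0]), x),
            EventWindow("a2", 50.0, 100.0, np.array([70.0]), x),
        ]
        assert window_loglik(p, split) == pytest.approx(window_loglik(p, whole))


class TestFitNHPP:
    def test_hpp_closed_form_rate(self):
        """With beta pinned to 1 the scale MLE is exposure per event."""
        ws = [EventWindow("a", 0.0, 300.0, np.array([50.0, 150.0, 250.0]))]
        fit = fit_nhpp(ws, fix_beta=1.0)
        assert fit.params.eta == pytest.approx(100.0, rel=1e-5)
        assert fit.params.beta_shape == 1.0

    def test_zero_events_rejected(self):
        ws = [EventWindow("a", 0.0, 300.0, np.array([]))]
        with pytest.raises(ValueError, match="unidentified"):
            fit_nhpp(ws)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(0)
        ws = []
        for i in range(30):
            z = float(i % 2)
            ws.append(
                EventWindow(
                    str(i), 0.0, 400.0,
                    simulate_events(NHPPParams(200.0, 1.0), [], 0, 400, rng),
                    np.array([z, 2 * z]),
                )
            )
        with pytest.raises(ValueError, match="rank"):
            fit_nhpp(ws)

    def test_parameter_recovery_within_3se(self):
        truth = NHPPParams(400.0, 1.3, [np.log(2.0)])
        rng = np.random.default_rng(12)
        ws = []
        for i in range(1500):
            x = np.array([float(rng.random() < 0.3)])
            ev = simulate_events(truth, x, 0.0, 520.0, rng)
            ws.append(EventWindow(str(i), 0.0, 520.0, ev, x))
        fit = fit_nhpp(ws)
        est = np.r_[np.log(fit.params.eta), np.log(fit.params.beta_shape),
                    fit.params.gamma]
        true = np.r_[np.log(400.0), np.log(1.3), np.log(2.0)]
        se = np.sqrt(np.diag(fit.vcov))
        assert np.all(np.abs(est - true) < 3 * se)
        assert fit.loglik >= window_loglik(truth, ws) - 1e-6

    def test_vcov_symmetric_psd(self):
        rng = np.random.default_rng(5)
        truth = NHPPParams(300.0, 1.2)
        ws = [
            EventWindow(str(i), 0.0, 600.0,
                        simulate_events(truth, [], 0, 600, rng))
            for i in range(300)
        ]
        fit = fit_nhpp(ws)
        assert np.allclose(fit.vcov, fit.vcov.T)
        assert np.all(np.linalg.eigvalsh(fit.vcov) > -1e-10)


class TestHazardRatios:
    def test_wald_arithmetic(self):
        fit = NHPPFit(
            params=NHPPParams(100.0, 1.0, [np.log(2.0)]),
            vcov=np.diag([0.01, 0.01, 0.01]),   # SE(gamma) = 0.1
            loglik=0.0, converged=True, n_events=10, total_exposure=100.0,
            covariate_names=["flag"],
        )
        tab = hazard_ratios(fit)
        assert tab.loc[0, "HR"] == pytest.approx(2.0)
        assert tab.loc[0, "CI_low"] == pytest.approx(2 * np.exp(-1.96 * 0.1), rel=1e-6)
        assert tab.loc[0, "CI_high"] == pytest.approx(2 * np.exp(1.96 * 0.1), rel=1e-6)
        assert tab.loc[0, "CI_low"] == pytest.approx(1.644, abs=5e-3)
        assert tab.loc[0, "CI_high"] == pytest.approx(2.433, abs=5e-3)

    def test_null_effect_ci_contains_one(self):
        fit = NHPPFit(
            params=NHPPParams(100.0, 1.0, [0.0]),
            vcov=np.diag([0.01, 0.01, 0.04]),
            loglik=0.0, converged=True, n_events=10, total_exposure=100.0,
        )
        tab = hazard_ratios(fit)
        assert tab.loc[0, "HR"] == 1.0
        assert tab.loc[0, "CI_low"] < 1.0 < tab.loc[0, "CI_high"]
        assert tab.loc[0, "p"] == pytest.approx(1.0)


class TestSurvival:
    def test_unit_at_zero_and_exponential_closed_form(self):
        p = NHPPParams(100.0, 1.0)
        assert survival_first_event(p, [], 0.0, 0.0) == 1.0
        assert survival_first_event(p, [], 0.0, 50.0) == pytest.approx(
            np.exp(-0.5), rel=1e-12
        )

    def test_matches_empirical_first_event_survival(self):
        """Simulated first-event times reproduce S(t) within 0.02."""
        p = NHPPParams(400.0, 1.3, [0.4])
        x, L = [1.0], 100.0
        rng = np.random.default_rng(3)
        n = 20_000
        # first event after L: Lambda gap to first event is Exp(1)
        first = []
        for _ in range(n):
            ev = simulate_events(p, x, L, 800.0, rng)   # grid stays inside R - L
            first.append(ev[0] - L if len(ev) else np.inf)
        first = np.asarray(first)
        grid = np.array([26.0, 52.0, 104.0, 208.0, 416.0])
        emp = np.array([(first > t).mean() for t in grid])
        model = survival_first_event(p, x, L, grid)
        assert np.all(np.abs(emp - model) < 0.02)

    def test_mean_curve_of_identical_subjects_is_individual_curve(self):
        p = NHPPParams(300.0, 1.2, [0.5])
        w = EventWindow("a", 50.0, 400.0, np.array([]), np.array([1.0]))
        grid = np.linspace(0, 200, 21)
        single = survival_first_event(p, w.x, w.L, grid)
        assert np.allclose(mean_survival_curve(p, [w, w, w], grid), single)

    def test_higher_risk_class_has_lower_curve(self):
        p = NHPPParams(300.0, 1.2, [0.8])
        lo = EventWindow("a", 0.0, 400.0, np.array([]), np.array([0.0]))
        hi = EventWindow("b", 0.0, 400.0, np.array([]), np.array([1.0]))
        grid = np.linspace(1, 300, 30)
        assert np.all(
            mean_survival_curve(p, [hi], grid) < mean_survival_curve(p, [lo], grid)
        )

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            mean_survival_curve(NHPPParams(100.0, 1.0), [], [0.0, 1.0])


class TestResidualsAndSimulation:
    def test_single_event_gap_definition(self):
        p = NHPPParams(200.0, 1.5, [0.2])
        w = EventWindow("a", 30.0, 400.0, np.array([120.0]), np.array([1.0]))
        gap = transform_residuals(p, w)
        expected = cumulative_intensity(120.0, w.x, p) - cumulative_intensity(
            30.0, w.x, p
        )
        assert gap == pytest.approx([expected])

    def test_beta_one_gaps_are_scaled_raw_times(self):
        p = NHPPParams(100.0, 1.0, [np.log(2.0)])
        w = EventWindow("a", 0.0, 500.0, np.array([50.0, 125.0]), np.array([1.0]))
        gaps = transform_residuals(p, w)
        assert np.allclose(gaps, np.diff([0.0, 50.0, 125.0]) / 100.0 * 2.0)

    def test_simulate_transform_round_trip_is_exp1(self):
        """In an effectively untruncated regime the transformed gaps are
        standard exponential (KS) with mean 1."""
        p = NHPPParams(400.0, 1.3)
        R = 400.0 * 40 ** (1 / 1.3)    # expected ~40 events per window
        rng = np.random.default_rng(7)
        gaps = []
        for i in range(400):
            ev = simulate_events(p, [], 0.0, R, rng)
            w = EventWindow(str(i), 0.0, R, ev, [])
            gaps.append(transform_residuals(p, w)[:5])   # early gaps: no truncation
        gaps = np.concatenate(gaps)
        assert gaps.mean() == pytest.approx(1.0, abs=0.05)
        assert stats.kstest(gaps, "expon").pvalue > 0.01

    def test_censoring_aware_residual_mean_is_one_under_truncation(self):
        """Total transformed exposure / events = 1 even on short windows."""
        p = NHPPParams(400.0, 1.3)
        rng = np.random.default_rng(5)
        ws = [
            EventWindow(str(i), 0.0, 800.0,
                        simulate_events(p, [], 0.0, 800.0, rng))
            for i in range(2000)
        ]
        assert residual_mean(p, ws) == pytest.approx(1.0, abs=0.05)

    def test_empty_window_limit_gives_no_events(self):
        p = NHPPParams(100.0, 1.0)
        assert len(simulate_events(p, [], 100.0, 100.0 + 1e-12, seed=0)) == 0

    def test_event_counts_are_poisson(self):
        """Counts over replicates follow Poisson(Lambda gap) (chi-square GOF)
        and their mean matches the gap."""
        p = NHPPParams(100.0, 1.0)
        rng = np.random.default_rng(10)
        counts = np.array(
            [len(simulate_events(p, [], 0.0, 1000.0, rng)) for _ in range(10_000)]
        )
        assert counts.mean() == pytest.approx(10.0, abs=0.1)
        kmax = 25
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax + 1), 10.0)
        pmf[kmax] = stats.poisson.sf(kmax - 1, 10.0)
        keep = pmf * len(counts) >= 5
        chi = stats.chisquare(obs[keep], pmf[keep] / pmf[keep].sum() * obs[keep].sum())
        assert chi.pvalue > 0.01

    def test_seeded_determinism(self):
        p = NHPPParams(200.0, 1.3, [0.5])
        a = simulate_events(p, [1.0], 0.0, 1000.0, seed=42)
        b = simulate_events(p, [1.0], 0.0, 1000.0, seed=42)
        assert np.array_equal(a, b)
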