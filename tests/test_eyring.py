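"""Modified Eyring kinetics: exact solution, scaling, asymptotics, fitting
and dynamic-class assignment."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from micellex.eyring import (
    EyringParams,
    FitError,
    RegimeError,
    asymptotics,
    classify_and_collapse,
    eyring_rhs,
    eyring_solution,
    fit,
    inverse_scale_transform,
    scale_transform,
)
from micellex.series import CorrelationSeries
from micellex.synthetic import synth_curve

TABLE_SIM = {
    "flexible": EyringParams(2.6e-2, 1.0e-8, 6.8e5),
    "semiflexible": EyringParams(2.0e-2, 1.0e-13, 4.1e5),
    "rigid": EyringParams(1.9e-2, 1.0e-14, 4.3e5),
}


def ode_reference(p, tgrid):
    """Independent oracle: stiff numerical integration of the rate equation."""
    sol = solve_ivp(
        lambda t, F: [eyring_rhs(F[0], p)],
        (0.0, tgrid[-1] * (1 + 1e-9)),
        [1.0],
        t_eval=tgrid,
        method="Radau",
        rtol=1e-12,
        atol=1e-13,
    )
    assert sol.success
    return sol.y[0]


class TestSolution:
    def test_initial_value(self):
        for p in TABLE_SIM.values():
            assert eyring_solution(np.array([0.0]), p)[0] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_nonincreasing_and_bounded(self):
        p = TABLE_SIM["flexible"]
        t = np.geomspace(1e-14, 1e-2, 500)
        F = eyring_solution(t, p)
        assert np.all(np.diff(F) <= 1e-15)
        assert F[-1] >= -1e-12  # stationary state is complete mixing, F = 0

    def test_closed_form_matches_ode_integration(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(12):
            eps = rng.uniform(0.01, 0.1)
            k2 = 10 ** rng.uniform(-2, 6)
            gamma = 10 ** rng.uniform(-14, 3)
            p = EyringParams(eps, gamma * k2, k2)
            d = p.derived()
            tgrid = np.geomspace(min(d.tau1, d.tau2) * 1e-2, 5 * d.tau2, 80)
            worst = max(worst, np.max(np.abs(ode_reference(p, tgrid) - eyring_solution(tgrid, p))))
        assert worst < 1e-8

    def test_rhs_matches_solution_derivative(self):
        p = EyringParams(0.03, 1e-4, 1e3)
        d = p.derived()
        t = np.geomspace(d.tau1 * 10, d.tau2, 20)
        h = t * 1e-6
        dF_num = (eyring_solution(t + h, p) - eyring_solution(t - h, p)) / (2 * h)
        dF_ana = eyring_rhs(eyring_solution(t, p), p)
        np.testing.assert_allclose(dF_num, dF_ana, rtol=1e-6)

    def test_rhs_negative_above_stationary_value(self):
        p = TABLE_SIM["semiflexible"]
        assert np.all(eyring_rhs(np.linspace(0.01, 1.0, 50), p) < 0)
        # initial rate is k1-dominated: |dF/dt| at F=1 ~ k1 e^{1/eps}
        rate0 = -eyring_rhs(1.0, p)
        assert rate0 == pytest.approx(p.k1 * np.exp(1.0 / p.eps), rel=1e-2)
        # and exactly so in the k2 -> 0 limit
        p0 = EyringParams(p.eps, p.k1, p.k1 * 1e-8)
        assert -eyring_rhs(1.0, p0) == pytest.approx(p0.k1 * np.exp(1.0 / p0.eps), rel=1e-7)


class TestScaling:
    def test_round_trip(self):
        p = TABLE_SIM["flexible"]
        t = np.geomspace(1e-12, 1e-4, 200)
        curve = CorrelationSeries(t, eyring_solution(t, p))
        back = inverse_scale_transform(scale_transform(curve, p), p)
        np.testing.assert_allclose(back.times, curve.times, rtol=1e-12)
        np.testing.assert_allclose(back.F, curve.F, atol=1e-12)

    def test_intermediate_slope_minus_one(self):
        p = EyringParams(0.025, 1e-6 * 4e5, 4e5)
        d = p.derived()
        t = np.geomspace(d.tau1 * 10, d.a, 500)
        s = scale_transform(CorrelationSeries(t, eyring_solution(t, p)), p)
        lo = 100 * np.exp(-1.0 / p.eps) / d.gamma
        m = (s.t_star > lo) & (s.t_star < 0.02)
        slope = np.polyfit(np.log(s.t_star[m]), s.log_y_star[m], 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.02)

    def test_type_b_master_curve_collapse(self):
        pa = EyringParams(0.025, 1e-6 * 4e5, 4e5)
        pb = EyringParams(0.02, 1e-8 * 7e5, 7e5)
        ts = np.geomspace(1e-5, 1.0, 300)
        gaps = []
        sa = scale_transform(
            CorrelationSeries(ts * pa.derived().a, eyring_solution(ts * pa.derived().a, pa)), pa
        )
        sb = scale_transform(
            CorrelationSeries(ts * pb.derived().a, eyring_solution(ts * pb.derived().a, pb)), pb
        )
        gap = np.max(np.abs(sa.y_star - sb.y_star) / sb.y_star)
        assert gap <= 0.02


class TestAsymptotics:
    def test_tau1_on_printed_simulation_parameters(self):
        d = TABLE_SIM["flexible"].derived()
        # logarithmic onset ~5e-11 s, consistent with a log regime from 1e-10 s
        assert d.tau1 == pytest.approx(5.1e-11, rel=0.05)
        assert d.gamma == pytest.approx(1.47e-14, rel=0.01)

    def test_logarithmic_window_accuracy(self):
        p = EyringParams(0.03, 1e-6 * 1e5, 1e5)
        d = p.derived()
        t = np.geomspace(10 * d.tau1, d.a / 10, 200)
        err = np.abs(asymptotics(p, "logarithmic")(t) - eyring_solution(t, p))
        assert err.max() <= 0.01

    def test_matched_form_global_accuracy_small_gamma(self):
        p = EyringParams(0.02, 1e-6 * 4e5, 4e5)
        d = p.derived()
        t = np.geomspace(d.tau1 * 0.01, 12 * d.a, 400)
        err = np.abs(asymptotics(p, "matched")(t) - eyring_solution(t, p))
        assert err.max() <= 0.01

    def test_terminal_type_a_tracks_exact_solution(self):
        p = EyringParams(0.05, 50.0, 1.0)  # gamma = 50, type a
        d = p.derived()
        t = np.geomspace(10 * d.tau1, 3 * d.tau2, 200)
        err = np.abs(asymptotics(p, "terminal")(t) - eyring_solution(t, p))
        assert err.max() <= 5 * p.eps  # matched amplitude is O(eps) accurate

    def test_regime_class_errors(self):
        type_b = TABLE_SIM["flexible"]
        type_a = EyringParams(0.05, 50.0, 1.0)
        with pytest.raises(RegimeError):
            asymptotics(type_b, "terminal")
        with pytest.raises(RegimeError):
            asymptotics(type_a, "second-intermediate")
        with pytest.raises(RegimeError):
            asymptotics(type_a, "matched")

    def test_tau1_predicts_plateau_departure(self):
        # F has dropped by eps*ln(2) at t = tau1: departure within a factor 2
        for p in TABLE_SIM.values():
            d = p.derived()
            drop = 1.0 - eyring_solution(np.array([d.tau1]), p)[0]
            assert 0.5 * p.eps * np.log(2) < drop < 2 * p.eps * np.log(2)


class TestFit:
    def test_noiseless_recovery_within_one_percent(self):
        p = EyringParams(0.02, 1e-13, 4e5)
        curve = synth_curve(p, noise=0.0)
        res = fit(curve)
        assert res.params.eps == pytest.approx(p.eps, rel=0.01)
        assert res.params.k1 == pytest.approx(p.k1, rel=0.01)
        assert res.params.k2 == pytest.approx(p.k2, rel=0.01)
        assert res.r2 > 0.9999

    def test_noisy_recovery_experimental_regime(self):
        # identifiable (type-b, eps ~ 7e-2) parameter regime at 1% noise
        p = EyringParams(7.2e-2, 4.1e-10, 2.4e-9)
        rng = np.random.default_rng(42)
        res = fit(synth_curve(p, noise=0.01, rng=rng), seed=1)
        assert res.params.eps == pytest.approx(p.eps, rel=0.10)
        assert res.params.k1 == pytest.approx(p.k1, rel=0.10)
        assert res.params.k2 == pytest.approx(p.k2, rel=0.10)
        assert res.r2 >= 0.98

    def test_flat_curve_rejected(self):
        t = np.geomspace(1e-9, 1e-3, 50)
        with pytest.raises(FitError):
            fit(CorrelationSeries(t, np.ones_like(t)))

    def test_too_few_points_rejected(self):
        p = TABLE_SIM["flexible"]
        t = np.geomspace(1e-10, 1e-6, 8)
        with pytest.raises(FitError):
            fit(CorrelationSeries(t, eyring_solution(t, p)))

    def test_parameter_bias_vanishes_with_noise(self):
        p = EyringParams(7.2e-2, 4.1e-10, 2.4e-9)
        biases = []
        for noise in (0.02, 0.002):
            errs = []
            for s in range(4):
                rng = np.random.default_rng(100 + s)
                res = fit(synth_curve(p, noise=noise, rng=rng, points_per_decade=100), seed=s)
                errs.append(abs(np.log(res.params.k2 / p.k2)))
            biases.append(np.mean(errs))
        assert biases[1] < biases[0]


class TestClassification:
    def test_printed_experimental_row_is_type_b(self):
        p = EyringParams(7.2e-2, 4.1e-10, 2.4e-9)
        assert p.gamma == pytest.approx(0.1708, rel=1e-3)
        t = np.geomspace(1e-2, 1e10, 100)
        curve = CorrelationSeries(t, eyring_solution(t, p))
        (c,) = classify_and_collapse([(curve, p)])
        assert c.dynamic_class == "b"

    def test_simulation_fits_all_type_b(self):
        for p in TABLE_SIM.values():
            assert p.gamma < 1

    def test_truncated_curve_flags_k2_unreliable(self):
        p = TABLE_SIM["flexible"]
        d = p.derived()
        # data ending deep inside the logarithmic window (t* < 0.1)
        t = np.geomspace(10 * d.tau1, 0.05 * d.a, 60)
        curve = CorrelationSeries(t, eyring_solution(t, p))
        (c,) = classify_and_collapse([(curve, p)])
        assert not c.k2_reliable
        t2 = np.geomspace(10 * d.tau1, 3 * d.a, 80)
        (c2,) = classify_and_collapse([(CorrelationSeries(t2, eyring_solution(t2, p)), p)])
        assert c2.k2_reliable
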