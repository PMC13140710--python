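"""Boltzmann fitting, kinetic summaries, protection, event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phasekin as pk
from phasekin import synth, tht


def _noiseless_trace(Fi=100.0, Ff=1100.0, t50=3600.0, k=400.0):
    truth = synth.ThTTruth(Fi=Fi, Ff=Ff, t50_s=t50, k_s=k, noise_sd=0.0, lag_cv=0.0)
    plate, _ = synth.gen_tht_plate(truth, n_wells=1, seed=0)
    return plate.traces[0]


def test_noiseless_fit_recovers_parameters_to_1e6():
    fit = tht.fit_boltzmann(_noiseless_trace())
    assert fit.converged
    assert fit.Fi == pytest.approx(100.0, rel=1e-6)
    assert fit.Ff == pytest.approx(1100.0, rel=1e-6)
    assert fit.t50_s == pytest.approx(3600.0, rel=1e-6)
    assert fit.k_s == pytest.approx(400.0, rel=1e-6)
    assert fit.r2 > 1 - 1e-12


def test_decreasing_trace_fits_with_negative_amplitude():
    t = np.arange(181) * 350.0
    y = tht.boltzmann(t, 1100.0, 100.0, 3600.0, 400.0)
    falling = pk.ThTTrace(well_id="A1", time_s=t, intensity=y)
    fit = tht.fit_boltzmann(falling)
    assert fit.converged
    assert fit.Ff - fit.Fi == pytest.approx(-1000.0, rel=1e-5)


def test_flat_trace_reports_no_transition():
    t = np.arange(20) * 350.0
    tr = pk.ThTTrace(well_id="A1", time_s=t, intensity=np.full(20, 100.0))
    fit = tht.fit_boltzmann(tr)
    assert not fit.converged
    assert fit.reason == "no transition"
    with pytest.raises(ValueError):
        tht.kinetic_summary(fit, tr)


def test_noisy_flat_trace_fails_r2_gate(rng):
    t = np.arange(180) * 350.0
    tr = pk.ThTTrace(well_id="A1", time_s=t, intensity=100 + rng.normal(0, 5, 180))
    fit = tht.fit_boltzmann(tr)
    assert not fit.converged


def test_kinetic_summary_printed_formulas():
    tr = _noiseless_trace()
    fit = tht.BoltzmannFit(Fi=100.0, Ff=1100.0, t50_s=3600.0, k_s=400.0,
                           r2=1.0, converged=True)
    s = tht.kinetic_summary(fit, tr)
    assert s.elongation_rate == pytest.approx(0.625)
    assert s.t_lag_tangent_s == pytest.approx(2800.0)
    assert s.t_lag_baseline_s == pytest.approx(2960.0)
    assert s.delta_I == pytest.approx(1000.0)

    zero_base = tht.BoltzmannFit(Fi=0.0, Ff=400.0, t50_s=1000.0, k_s=10.0,
                                 r2=1.0, converged=True)
    s0 = tht.kinetic_summary(zero_base, tr)
    assert s0.elongation_rate == pytest.approx(10.0)
    assert s0.t_lag_baseline_s == pytest.approx(980.0)
    assert s0.t_lag_tangent_s == pytest.approx(980.0)

    degenerate = tht.BoltzmannFit(Fi=5.0, Ff=5.0, t50_s=10.0, k_s=1.0,
                                  r2=1.0, converged=True)
    with pytest.raises(ZeroDivisionError):
        tht.kinetic_summary(degenerate, tr)


def test_endpoint_is_mean_of_final_three_raw_points():
    tr = _noiseless_trace()
    fit = tht.fit_boltzmann(tr)
    s = tht.kinetic_summary(fit, tr)
    assert s.endpoint == pytest.approx(float(np.mean(tr.intensity[-3:])))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    Ff=st.floats(1.0, 1e6),
    t50=st.floats(10.0, 1e5),
    k=st.floats(1e-3, 1e4),
)
def test_lag_formulas_coincide_when_baseline_is_zero(Ff, t50, k):
    baseline = tht.lag_time_baseline(0.0, Ff, t50, k)
    tangent = tht.lag_time_tangent(t50, k)
    assert abs(baseline - tangent) < 1e-9 * max(1.0, abs(tangent))


def test_elongation_rate_equals_numerical_derivative_at_midpoint():
    Fi, Ff, t50, k = 100.0, 1100.0, 3600.0, 400.0
    h = 1e-3
    num = (tht.boltzmann(t50 + h, Fi, Ff, t50, k)
           - tht.boltzmann(t50 - h, Fi, Ff, t50, k)) / (2 * h)
    assert tht.elongation_rate(Fi, Ff, k) == pytest.approx(float(num), rel=1e-6)


def test_parameter_recovery_under_noise_is_unbiased():
    """200 wells at 2% amplitude noise: median |t50 error| < 2%,
    elongation-rate bias < 1%, t50 RMSE < 2%."""
    truth = synth.ThTTruth(Fi=100.0, Ff=1100.0, t50_s=3600.0, k_s=400.0,
                           lag_cv=0.0, noise_sd=20.0)
    plate, _ = synth.gen_tht_plate(truth, n_wells=200, seed=2024)
    t50_err, rate_err = [], []
    true_rate = tht.elongation_rate(truth.Fi, truth.Ff, truth.k_s)
    for tr in plate.traces:
        fit = tht.fit_boltzmann(tr)
        assert fit.converged
        t50_err.append(fit.t50_s / truth.t50_s - 1)
        rate_err.append(tht.elongation_rate(fit.Fi, fit.Ff, fit.k_s) / true_rate - 1)
    assert np.median(np.abs(t50_err)) < 0.02
    assert abs(np.mean(rate_err)) < 0.01
    assert np.sqrt(np.mean(np.square(t50_err))) < 0.02


def test_percent_protection_values_and_properties():
    assert tht.percent_protection(1000.0, 0.0) == pytest.approx(100.0)
    assert tht.percent_protection(1000.0, 1000.0) == pytest.approx(0.0)
    assert tht.percent_protection(1000.0, 1500.0) == pytest.approx(-50.0)
    with pytest.raises(ZeroDivisionError):
        tht.percent_protection(0.0, 5.0)
    # antitone in the chaperone amplitude; exact linear identity
    chap = np.linspace(0, 3000, 13)
    vals = [tht.percent_protection(1000.0, c) for c in chap]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    np.testing.assert_allclose(vals, 100 - 100 * chap / 1000.0, atol=1e-12)


def test_detect_event_flat_noise_trace_censors_at_assay_end(rng):
    t = np.arange(180) * 350.0
    tr = pk.ThTTrace(well_id="B2", time_s=t, intensity=100 + rng.normal(0, 5, 180))
    rec = tht.detect_event(tr, tht.fit_boltzmann(tr))
    assert rec.event == 0
    assert rec.time_s == t[-1]


def test_detect_event_recovers_true_lag_within_5pct():
    truth = synth.ThTTruth(Fi=100.0, Ff=1100.0, t50_s=7000.0, k_s=400.0,
                           noise_sd=10.0)  # amplitude 100x baseline sd
    plate, table = synth.gen_tht_plate(truth, n_wells=20, seed=5,
                                       duration_s=40 * 350.0)
    for tr, true_lag in zip(plate.traces, table["t_lag_baseline_s"]):
        rec = tht.detect_event(tr, tht.fit_boltzmann(tr))
        assert rec.event == 1
        assert rec.time_s == pytest.approx(true_lag, rel=0.05)


def test_detect_event_censored_fraction_tracks_truth():
    # lag of hours against 350 s cycles, as in a real plate assay
    truth = synth.ThTTruth(t50_s=14400.0, k_s=1000.0, nonaggregating_frac=0.3,
                           noise_sd=10.0, lag_cv=0.1)
    plate, table = synth.gen_tht_plate(truth, n_wells=100, seed=77)
    censored = 0
    for tr in plate.traces:
        rec = tht.detect_event(tr, tht.fit_boltzmann(tr))
        censored += 1 - rec.event
    # detector must agree with the generator's own labels...
    assert censored == int((1 - table["event"]).sum())
    # ...and that count sits inside the binomial 99% interval around 30
    assert 18 <= censored <= 42


def test_event_lag_formula_selectable():
    tr = _noiseless_trace()
    fit = tht.fit_boltzmann(tr)
    baseline = tht.detect_event(tr, fit, tht.EventCriteria(lag_formula="baseline"))
    tangent = tht.detect_event(tr, fit, tht.EventCriteria(lag_formula="tangent"))
    assert baseline.time_s == pytest.approx(2960.0, rel=1e-4)
    assert tangent.time_s == pytest.approx(2800.0, rel=1e-4)
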