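"""Boltzmann fitting, energetics and kinetics metrics against closed-form
oracles."""

import math

import numpy as np
import pytest

from iksim import (
    NoiseModel,
    delta_delta_g,
    extract_tail_gv,
    fit_boltzmann,
    fit_boltzmann_shared_slope,
    fit_double_boltzmann,
    fit_exponentials,
    gating_charge,
    generate_recording,
    gv_curve,
    standard_protocol,
    t50_close,
    t50_open,
    tau_ratio,
)
from iksim.analysis import FitError, boltzmann


# -- single Boltzmann -------------------------------------------------------


def test_boltzmann_fit_recovers_exact_parameters():
    v = np.arange(-80.0, 61.0, 10.0)
    y = boltzmann(v, 1.0, -20.0, 12.5)
    fit = fit_boltzmann(v, y)
    assert fit.gmax == pytest.approx(1.0, abs=1e-6)
    assert fit.v50 == pytest.approx(-20.0, abs=1e-6)
    assert fit.s == pytest.approx(12.5, abs=1e-6)
    assert fit(np.array([fit.v50]))[0] == pytest.approx(fit.gmax / 2, rel=1e-9)


def test_boltzmann_fit_translation_equivariance():
    v = np.arange(-80.0, 61.0, 10.0)
    y = boltzmann(v, 1.0, -20.0, 12.5)
    fit = fit_boltzmann(v + 10.0, y)
    assert fit.v50 == pytest.approx(-10.0, abs=1e-6)
    assert fit.s == pytest.approx(12.5, abs=1e-6)


def test_boltzmann_fit_flags_nonsaturating_curve():
    v = np.arange(-80.0, 1.0, 10.0)  # stop well below the plateau
    y = boltzmann(v, 1.0, 10.0, 15.0)
    fit = fit_boltzmann(v, y)
    assert not fit.saturating
    assert "approximation" in fit.flags


def test_boltzmann_monte_carlo_bias_and_coverage():
    """Gaussian noise sigma = 0.02*Gmax: mean V50 error < 1 mV and ~95% of
    fits cover the truth within +/-2 SE."""
    v = np.arange(-80.0, 61.0, 10.0)
    truth = boltzmann(v, 1.0, -20.0, 12.5)
    rng = np.random.default_rng(42)
    v50s, covered = [], 0
    n_rep = 200
    for _ in range(n_rep):
        fit = fit_boltzmann(v, truth + rng.normal(0.0, 0.02, size=v.shape))
        v50s.append(fit.v50)
        if fit.v50_se and abs(fit.v50 - (-20.0)) <= 2.0 * fit.v50_se:
            covered += 1
    assert abs(np.mean(v50s) + 20.0) < 1.0
    assert 0.85 <= covered / n_rep <= 1.0


def test_shared_slope_fit_ties_slopes():
    v = np.arange(-80.0, 61.0, 10.0)
    curves = {
        "ctrl": (v, boltzmann(v, 1.0, -20.0, 12.5)),
        "treated": (v, boltzmann(v, 0.8, -45.0, 12.5)),
    }
    fits = fit_boltzmann_shared_slope(curves)
    assert fits["ctrl"].s == fits["treated"].s
    assert fits["ctrl"].v50 == pytest.approx(-20.0, abs=1e-4)
    assert fits["treated"].v50 == pytest.approx(-45.0, abs=1e-4)


def test_boltzmann_fit_input_validation():
    with pytest.raises(FitError):
        fit_boltzmann(np.arange(3.0), np.arange(3.0))
    with pytest.raises(FitError):
        fit_boltzmann(np.arange(-40.0, 41.0, 10.0), np.ones(9))


# -- double Boltzmann -------------------------------------------------------


def test_double_boltzmann_recovers_two_components():
    v = np.arange(-160.0, 81.0, 20.0)
    y = boltzmann(v, 1.0, -120.0, 15.0) + boltzmann(v, 1.0, 20.0, 15.0)
    fit = fit_double_boltzmann(v, y)
    assert fit.v50_1 == pytest.approx(-120.0, abs=0.1)
    assert fit.v50_2 == pytest.approx(20.0, abs=0.1)
    assert fit.v50_1 <= fit.v50_2


def test_double_boltzmann_flags_single_component_input():
    v = np.arange(-80.0, 81.0, 10.0)
    y = boltzmann(v, 1.0, 0.0, 12.0)
    fit = fit_double_boltzmann(v, y)
    assert "degenerate_component" in fit.flags


def test_double_boltzmann_needs_eight_points():
    v = np.arange(-60.0, 10.0, 10.0)
    with pytest.raises(FitError):
        fit_double_boltzmann(v, boltzmann(v, 1.0, -30.0, 10.0))


# -- energetics -------------------------------------------------------------


@pytest.mark.parametrize("s, z", [(25.0, 1.0), (12.5, 2.0), (13.3, 25.0 / 13.3)])
def test_gating_charge_from_slope(s, z):
    assert gating_charge(s) == pytest.approx(z, rel=1e-12)


def test_delta_delta_g_worked_examples():
    assert delta_delta_g(2.0, 0.0) == 0.0
    # 2 * 0.0259 V * 96485 C/mol = 4998 J/mol
    assert delta_delta_g(2.0, 25.9) == pytest.approx(4.998, abs=0.005)
    assert delta_delta_g(25.0 / 13.3, 27.0) == pytest.approx(4.9, abs=0.05)


def test_delta_delta_g_antisymmetric_and_linear():
    rng = np.random.default_rng(3)
    for z, dv in rng.uniform(0.5, 3.0, size=(20, 2)):
        assert delta_delta_g(z, -dv) == pytest.approx(-delta_delta_g(z, dv), rel=1e-12)
        assert delta_delta_g(2 * z, dv) == pytest.approx(2 * delta_delta_g(z, dv), rel=1e-12)


# -- T50 metrics ------------------------------------------------------------


def test_t50_open_closed_form_single_exponential():
    tau = 500.0
    t = np.arange(0.0, 3000.1, 1.0)
    i = 1.0 - np.exp(-t / tau)
    # half of the end level 1-e^-6: first crossing at -tau*ln(1 - 0.5*(1-e^-6))
    expected = -tau * math.log(1.0 - 0.5 * (1.0 - math.exp(-6.0)))
    assert t50_open(t, i) == pytest.approx(expected, abs=0.01)
    assert expected == pytest.approx(345.4, abs=0.1)
    # doubling tau doubles T50 for a pure exponential (same relative end level)
    t2 = np.arange(0.0, 6000.1, 1.0)
    i2 = 1.0 - np.exp(-t2 / (2 * tau))
    assert t50_open(t2, i2) == pytest.approx(2 * expected, abs=0.02)


def test_t50_open_gain_invariance_and_dense_oracle(iks):
    from iksim import current_observable, propagate, VoltageSegment

    trace = propagate(
        iks, [VoltageSegment(40.0, 5000.0)], initial="holding", holding_mv=-80.0,
        sample_interval_ms=2.0,
    )
    i = current_observable(trace, iks.gmax_us, iks.e_rev_mv)
    t = trace.time_ms
    res = t50_open(t, i)
    assert t50_open(t, 7.3 * i) == pytest.approx(res, rel=1e-12)  # gain-free
    # brute-force crossing on 10x denser sampling agrees within one interval
    dense = propagate(
        iks, [VoltageSegment(40.0, 5000.0)], initial="holding", holding_mv=-80.0,
        sample_interval_ms=0.2,
    )
    i_d = current_observable(dense, iks.gmax_us, iks.e_rev_mv)
    end = i_d[-1]
    idx = np.argmax(i_d >= 0.5 * end)
    assert abs(res - dense.time_ms[idx]) < 2.0


def test_t50_close_closed_form_and_offset_invariance():
    tau = 967.0
    # window long enough that the final samples sit on the true plateau
    t = np.arange(0.0, 10000.1, 1.0)
    i = 0.2 + 0.8 * np.exp(-t / tau)
    expected = tau * math.log(2.0)
    assert t50_close(t, i) == pytest.approx(expected, abs=0.1)
    assert expected == pytest.approx(670.3, abs=0.2)
    assert t50_close(t, i + 5.0) == pytest.approx(expected, abs=0.1)
    with pytest.raises(FitError):
        t50_close(t, np.full_like(t, 0.3))  # no relaxation


# -- exponential fits -------------------------------------------------------


def test_single_exponential_fit_exact():
    t = np.arange(0.0, 2000.0, 2.0)
    y = 0.1 + 0.9 * np.exp(-t / 300.0)
    res = fit_exponentials(t, y, n_components=1)
    assert res.tau_slow_ms == pytest.approx(300.0, abs=1e-6)


def test_double_exponential_fit_recovers_both_taus():
    t = np.arange(0.0, 4000.0, 2.0)
    y = 0.5 * np.exp(-t / 50.0) + 0.5 * np.exp(-t / 800.0)
    rng = np.random.default_rng(11)
    res = fit_exponentials(t, y + rng.normal(0, 0.002, t.shape), n_components=2)
    assert res.tau_fast_ms == pytest.approx(50.0, rel=0.02)
    assert res.tau_slow_ms == pytest.approx(800.0, rel=0.02)
    assert res.tau_fast_ms <= res.tau_slow_ms


def test_two_component_fit_on_single_exponential_flags_degenerate():
    t = np.arange(0.0, 2000.0, 2.0)
    y = np.exp(-t / 400.0)
    res = fit_exponentials(t, y, n_components=2)
    amps = np.abs(np.asarray(res.amplitudes))
    assert "degenerate_component" in res.flags or amps.min() / amps.sum() < 0.02


def test_fit_window_validation():
    t = np.arange(0.0, 100.0, 1.0)
    with pytest.raises(ValueError):
        fit_exponentials(t, np.exp(-t / 10.0), window_ms=(0.0, 500.0))


# -- tau ratios -------------------------------------------------------------


def test_tau_ratio_definitions():
    assert tau_ratio({"a": (300.0, 300.0)})["a"] == 1.0
    assert tau_ratio({"a": (400.0, 200.0)})["a"] == 0.5
    with pytest.raises(ValueError):
        tau_ratio({"a": (0.0, 1.0)})


# -- tail extraction round trip ---------------------------------------------


def test_extract_tail_gv_round_trip(iks):
    proto = standard_protocol("vcf_iks", sample_interval_ms=5.0)
    noiseless = NoiseModel(current_sd_ua=0.0, fluorescence_sd=0.0, seed=1)
    rec = generate_recording(iks, proto, noiseless)
    v_rec, i_rec = extract_tail_gv(rec, proto, delay_ms=5.0)
    v_sim, i_sim = gv_curve(iks, proto, method="tail", tail_delay_ms=5.0)
    np.testing.assert_allclose(v_rec, v_sim)
    np.testing.assert_allclose(i_rec, i_sim, rtol=1e-9, atol=1e-12)
    assert (np.diff(v_rec) > 0).all()
    with pytest.raises(ValueError):
        extract_tail_gv(rec, proto, delay_ms=5000.0)
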