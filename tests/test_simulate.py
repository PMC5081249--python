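"""Propagation correctness and observable definitions."""

import numpy as np
import pytest

from iksim import (
    PerturbationSpec,
    VoltageSegment,
    apply_perturbation,
    current_observable,
    default_params,
    fluorescence_observable,
    fv_curve,
    gv_curve,
    propagate,
    simulate_protocol,
    standard_protocol,
    steady_state,
)
from iksim.schemes import build_iks_scheme

from conftest import analytic_iks_po


def test_long_single_segment_reaches_steady_state(iks):
    v = 0.0
    trace = propagate(
        iks, [VoltageSegment(v, 60000.0)], initial="holding", holding_mv=-80.0,
        sample_interval_ms=50.0,
    )
    assert np.abs(trace.occupancies[-1] - steady_state(iks, v)).max() < 1e-8


def test_expm_and_ode_paths_agree(iks, vcf_iks_fast):
    segments = vcf_iks_fast.sweeps[8]  # 0 mV test sweep
    kw = dict(initial="holding", holding_mv=-80.0, sample_interval_ms=5.0)
    t_expm = propagate(iks, segments, method="expm", **kw)
    t_ode = propagate(iks, segments, method="ode", **kw)
    assert np.abs(t_expm.occupancies - t_ode.occupancies).max() < 1e-6


def test_splitting_a_segment_changes_nothing(iks):
    kw = dict(initial="holding", holding_mv=-80.0, sample_interval_ms=10.0)
    whole = propagate(iks, [VoltageSegment(20.0, 1000.0)], **kw)
    split = propagate(iks, [VoltageSegment(20.0, 400.0), VoltageSegment(20.0, 600.0)], **kw)
    assert np.abs(whole.occupancies - split.occupancies).max() < 1e-9
    np.testing.assert_allclose(whole.time_ms, split.time_ms)


def test_occupancies_bounded_everywhere(kv71):
    proto = standard_protocol("vcf_kv71", sample_interval_ms=10.0)
    trace = propagate(
        kv71, proto.sweeps[-1], initial="holding", holding_mv=-80.0, sample_interval_ms=10.0
    )
    assert trace.occupancies.min() > -1e-12
    assert trace.occupancies.max() < 1 + 1e-12


def test_propagate_rejects_bad_input(iks):
    with pytest.raises(ValueError):
        propagate(iks, [], initial="holding", holding_mv=-80.0)
    with pytest.raises(ValueError):
        VoltageSegment(0.0, -5.0)
    with pytest.raises(ValueError):
        propagate(iks, [VoltageSegment(0.0, 10.0)], initial=np.zeros(6))


def test_current_observable_definitions(iks):
    from iksim import SimulationTrace

    # occupancy entirely in closed states carries no current, exactly
    occ = np.zeros((3, 6))
    occ[:, :5] = 0.2
    closed_trace = SimulationTrace(
        time_ms=np.arange(3.0),
        voltage_mv=np.full(3, 40.0),
        occupancies=occ,
        state_ids=[s.id for s in iks.states],
        conducting_mask=iks.conducting_mask,
        fluor_weights=iks.fluor_weights,
        segment_bounds=[(0.0, 3.0, 40.0)],
    )
    assert np.abs(current_observable(closed_trace, 10.0, -95.0)).max() == 0.0
    # zero driving force: V = E_rev
    trace2 = propagate(
        iks, [VoltageSegment(40.0, 2000.0)], initial="holding", holding_mv=-80.0,
        sample_interval_ms=500.0,
    )
    assert np.abs(current_observable(trace2, 10.0, 40.0)).max() < 1e-12
    with pytest.raises(ValueError):
        current_observable(trace2, -1.0, -95.0)


def test_observables_match_hand_dot_product(iks):
    trace = propagate(
        iks, [VoltageSegment(20.0, 3.0)], initial="holding", holding_mv=-80.0,
        sample_interval_ms=1.0,
    )
    occ = trace.occupancies
    mask = iks.conducting_mask
    expect_i = 5.0 * occ[:, mask].sum(axis=1) * (20.0 - (-95.0)) * 1e-3
    np.testing.assert_allclose(current_observable(trace, 5.0, -95.0), expect_i, rtol=1e-12)
    expect_f = occ @ iks.fluor_weights
    np.testing.assert_allclose(fluorescence_observable(trace), expect_f, rtol=1e-12)


def test_fluorescence_extremes(iks):
    resting = propagate(
        iks, [VoltageSegment(-500.0, 100.0)], initial="holding", holding_mv=-500.0,
        sample_interval_ms=50.0,
    )
    assert fluorescence_observable(resting).max() < 1e-3  # essentially all in C0
    # all channels driven open: fluorescence approaches 4*f1 + f2
    open_all = propagate(
        iks, [VoltageSegment(400.0, 60000.0)], initial="holding", holding_mv=400.0,
        sample_interval_ms=30000.0,
    )
    top = 4 * iks.f1 + iks.f2
    assert fluorescence_observable(open_all)[-1] == pytest.approx(top, rel=1e-2)


def test_flat_fluorescence_scheme_is_zero():
    params = default_params("iks_6state")
    params["f1"] = 0.0
    params["f2"] = 0.0
    flat = build_iks_scheme(params)
    proto = standard_protocol("vcf_iks", sample_interval_ms=200.0)
    _, f = fv_curve(flat, proto)
    assert np.abs(f).max() == 0.0


def test_steady_state_gv_matches_partition_function(iks):
    vs, g = gv_curve(iks, method="steady_state", voltages=np.arange(-120.0, 81.0, 20.0))
    expected = np.array([analytic_iks_po(iks, v) for v in vs]) * iks.gmax_us
    np.testing.assert_allclose(g, expected, atol=1e-8 * iks.gmax_us)


def test_tail_method_biased_right_of_steady_state_for_slow_channels(iks):
    """With slow activation a finite test pulse undersamples equilibrium at
    mid-range voltages, pushing the fitted tail V50 rightward."""
    from iksim import fit_boltzmann

    slow = iks.copy()
    for t in slow.transitions:
        if t.kind == "opening":
            t.law.k0 *= 0.3
    proto = standard_protocol("vcf_iks", sample_interval_ms=5.0)
    v_t, g_t = gv_curve(slow, proto, method="tail")
    v_s, g_s = gv_curve(slow, method="steady_state", voltages=v_t)
    assert fit_boltzmann(v_t, g_t).v50 > fit_boltzmann(v_s, g_s).v50


def test_global_shift_translates_curves(iks):
    delta = 25.0
    pert = apply_perturbation(iks, PerturbationSpec("all", delta_v=delta))
    vs = np.arange(-120.0, 81.0, 20.0)
    _, g0 = gv_curve(iks, method="steady_state", voltages=vs)
    _, g1 = gv_curve(pert, method="steady_state", voltages=vs + delta)
    np.testing.assert_allclose(g1, g0, rtol=1e-9)
    _, f0 = fv_curve(iks, method="steady_state", voltages=vs)
    _, f1 = fv_curve(pert, method="steady_state", voltages=vs + delta)
    np.testing.assert_allclose(f1, f0, rtol=1e-9)


def test_train_protocol_accumulates_current(iks):
    """Chained 1 Hz pulses: peak current per sweep is nondecreasing early on
    (incomplete deactivation at the holding voltage between pulses)."""
    proto = standard_protocol("train_1hz", sample_interval_ms=5.0)
    traces = simulate_protocol(iks, proto)
    peaks = []
    for tr in traces[:10]:
        sl = tr.segment_slice(0)
        peaks.append(current_observable(tr, iks.gmax_us, iks.e_rev_mv)[sl].max())
    assert all(b >= a - 1e-12 for a, b in zip(peaks, peaks[1:]))
    assert peaks[-1] > peaks[0] * 1.02
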