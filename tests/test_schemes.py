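"""Structure, thermodynamic consistency and perturbation semantics of the
gating schemes."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from iksim import (
    PerturbationSpec,
    apply_perturbation,
    build_iks_scheme,
    build_kv71_scheme,
    default_params,
    rate_matrix,
    steady_state,
)
from iksim.schemes import DegenerateModelError, ParameterError

from conftest import analytic_iks_po


def test_kv71_topology(kv71):
    assert kv71.n_states == 10
    undirected = {tuple(sorted(e)) for e in kv71.edges()}
    assert len(undirected) == 13  # 4 horizontal per row + 5 vertical
    assert len(kv71.edges()) == 26  # every edge bidirectional
    assert [s.id for s in kv71.states] == [f"C{n}" for n in range(5)] + [f"O{n}" for n in range(5)]
    assert sum(s.conducting for s in kv71.states) == 5


def test_iks_topology(iks):
    assert iks.n_states == 6
    assert len({tuple(sorted(e)) for e in iks.edges()}) == 5
    o = iks.states[-1]
    assert o.conducting and o.n_activated == 4
    assert o.fluor_weight == pytest.approx(4 * iks.f1 + iks.f2)


def test_fluor_weights_follow_state_composition(kv71, iks):
    for scheme in (kv71, iks):
        for s in scheme.states:
            expected = s.n_activated * scheme.f1 + (scheme.f2 if s.conducting else 0.0)
            assert s.fluor_weight == pytest.approx(expected)


def test_uncoupled_scheme_has_uniform_opening_equilibrium():
    params = default_params("kv71_10state")
    params["allosteric_factor"] = 1.0
    scheme = build_kv71_scheme(params)
    kt = scheme.kt_mv
    laws = {(t.source, t.target): t.law for t in scheme.transitions}
    eq = [
        laws[(f"C{n}", f"O{n}")].rate(0.0, kt) / laws[(f"O{n}", f"C{n}")].rate(0.0, kt)
        for n in range(5)
    ]
    assert np.allclose(eq, eq[0], rtol=1e-12)


@pytest.mark.parametrize("v", [-120.0, 0.0, 80.0])
def test_detailed_balance_on_elementary_cycles(kv71, v):
    """Brute-force product of equilibrium constants around each of the four
    elementary squares of the 10-state grid equals 1."""
    kt = kv71.kt_mv
    laws = {(t.source, t.target): t.law for t in kv71.transitions}

    def k_eq(a, b):
        return laws[(a, b)].rate(v, kt) / laws[(b, a)].rate(v, kt)

    for n in range(4):
        cycle = k_eq(f"C{n}", f"C{n+1}") * k_eq(f"C{n+1}", f"O{n+1}")
        cycle *= k_eq(f"O{n+1}", f"O{n}") * k_eq(f"O{n}", f"C{n}")
        assert abs(cycle - 1.0) < 1e-10


def test_rate_matrix_columns_conserve_probability(kv71, iks):
    for scheme in (kv71, iks):
        for v in (-160.0, -40.0, 60.0):
            q = rate_matrix(scheme, v)
            assert np.abs(q.sum(axis=0)).max() < 1e-12
            off = q[~np.eye(scheme.n_states, dtype=bool)]
            assert (off >= 0).all()


def test_rate_matrix_entry_carries_multiplicity(iks):
    v = 20.0
    q = rate_matrix(iks, v)
    law = next(t.law for t in iks.transitions if (t.source, t.target) == ("C0", "C1"))
    expected = 4 * law.k0 * math.exp(law.z * v / iks.kt_mv)
    assert q[iks.state_index("C1"), iks.state_index("C0")] == pytest.approx(expected, rel=1e-12)


def test_globally_shifted_matrix_is_translated(iks):
    delta = 35.0
    pert = apply_perturbation(iks, PerturbationSpec("all", delta_v=delta))
    for v in (-60.0, 10.0):
        assert np.allclose(rate_matrix(pert, v), rate_matrix(iks, v - delta), rtol=1e-12)


def test_steady_state_normalized_and_resting_at_hyperpolarization(kv71, iks):
    for scheme in (kv71, iks):
        for v in np.arange(-160.0, 101.0, 20.0):
            p = steady_state(scheme, v)
            assert abs(p.sum() - 1.0) < 1e-10
            assert (p >= 0).all()
    # deep hyperpolarization parks everything in C0 (the shallow IKs sensor
    # needs a stronger hyperpolarization to saturate)
    assert steady_state(kv71, -200.0)[kv71.state_index("C0")] > 0.99
    assert steady_state(iks, -400.0)[iks.state_index("C0")] > 0.99


def test_steady_state_matches_long_time_propagation(iks):
    """Null-space steady state equals expm(Q t) p0 for t = 1e6 ms, any p0."""
    v = -20.0
    q = rate_matrix(iks, v)
    p_inf = steady_state(iks, v)
    rng = np.random.default_rng(7)
    p0 = rng.dirichlet(np.ones(iks.n_states))
    p_long = expm(q * 1e6) @ p0
    assert np.abs(p_long - p_inf).max() < 1e-8


def test_iks_steady_state_matches_partition_function(iks):
    for v in np.arange(-120.0, 81.0, 20.0):
        po = steady_state(iks, v)[iks.conducting_mask].sum()
        assert abs(po - analytic_iks_po(iks, v)) < 1e-10


def test_iks_open_probability_limit_is_opening_equilibrium(iks):
    """As V -> +inf all sensors are activated and Po -> L/(1+L)."""
    v = 400.0
    laws = {(t.source, t.target): t.law for t in iks.transitions}
    op, cl = laws[("C4", "O")], laws[("O", "C4")]
    l_eq = (op.k0 / cl.k0) * math.exp((op.z * v - cl.z * v) / iks.kt_mv)
    po = analytic_iks_po(iks, v)
    assert abs(po - l_eq / (1.0 + l_eq)) < 1e-8


def test_perturbation_identity_and_equilibrium_shift(iks):
    ident = apply_perturbation(iks, PerturbationSpec("s4_movement", 0.0))
    for v in (-80.0, 0.0):
        assert np.allclose(rate_matrix(ident, v), rate_matrix(iks, v), rtol=1e-14)

    delta = 40.0
    pert = apply_perturbation(iks, PerturbationSpec("opening", delta_v=delta))
    kt = iks.kt_mv
    for v in (-30.0, 20.0):
        law = {(t.source, t.target): t.law for t in pert.transitions}
        l_pert = law[("C4", "O")].rate(v, kt) / law[("O", "C4")].rate(v, kt)
        law0 = {(t.source, t.target): t.law for t in iks.transitions}
        l_ref = law0[("C4", "O")].rate(v - delta, kt) / law0[("O", "C4")].rate(v - delta, kt)
        assert l_pert == pytest.approx(l_ref, rel=1e-12)


def test_perturbation_leaves_other_classes_untouched(iks):
    pert = apply_perturbation(iks, PerturbationSpec("opening", delta_v=140.0))
    for t, t0 in zip(pert.transitions, iks.transitions):
        if t.kind == "s4_movement":
            assert t.law.dv == t0.law.dv and t.law.k0 == t0.law.k0


def test_parameter_validation_errors():
    params = default_params("kv71_10state")
    params["allosteric_factor"] = 0.5
    with pytest.raises(ParameterError):
        build_kv71_scheme(params)
    params = default_params("iks_6state")
    params["rates"]["opening"]["k0"] = -1.0
    with pytest.raises(ParameterError):
        build_iks_scheme(params)
    with pytest.raises(ParameterError):
        PerturbationSpec("pore_collapse", 10.0)


def test_rate_overflow_raises_not_nan(iks):
    with pytest.raises((DegenerateModelError, ParameterError, OverflowError)):
        steady_state(iks, 1e6)


def test_temperature_scaling_q10(iks):
    warm = iks.with_temperature(301.0, q10=5.0)
    scale = 5.0 ** ((301.0 - 295.0) / 10.0)
    assert warm.transitions[0].law.k0 == pytest.approx(iks.transitions[0].law.k0 * scale)
    assert warm.kt_mv > iks.kt_mv
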