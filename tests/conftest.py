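import numpy as np
import pytest

from iksim import default_scheme, standard_protocol


@pytest.fixture(scope="session")
def kv71():
    """Wild-type 10-state KV7.1 scheme (packaged calibrated stand-in)."""
    return default_scheme("kv71_10state")


@pytest.fixture(scope="session")
def iks():
    """Wild-type 6-state KV7.1+KCNE1 scheme."""
    return default_scheme("iks_6state")


@pytest.fixture(scope="session")
def vcf_iks_fast():
    """The IKs VCF protocol at a coarse 5 ms sample interval (test speed)."""
    return standard_protocol("vcf_iks", sample_interval_ms=5.0)


def analytic_iks_po(scheme, v):
    """Closed-form 6-state steady-state open probability.

    Independent oracle: with per-sensor equilibrium K(V) and opening
    equilibrium L(V), Po = L*K^4 / (sum_n C(4,n) K^n + L*K^4).
    """
    from math import comb

    kt = scheme.kt_mv
    laws = {}
    for t in scheme.transitions:
        laws[(t.source, t.target)] = t.law
    fwd, bwd = laws[("C0", "C1")], laws[("C1", "C0")]
    k_eq = (fwd.k0 / bwd.k0) * np.exp(
        (fwd.z * (v - fwd.dv) - bwd.z * (v - bwd.dv)) / kt
    )
    op, cl = laws[("C4", "O")], laws[("O", "C4")]
    l_eq = (op.k0 / cl.k0) * np.exp((op.z * (v - op.dv) - cl.z * (v - cl.dv)) / kt)
    z = sum(comb(4, n) * k_eq**n for n in range(5)) + l_eq * k_eq**4
    return l_eq * k_eq**4 / z
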