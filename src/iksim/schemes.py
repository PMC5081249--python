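"""Allosteric Markov gating schemes for KV7.1 and KV7.1+KCNE1 (IKs) channels.

Two scheme topologies are provided:

* a 10-state allosteric scheme for KV7.1 alone: a 5x2 grid of closed states
  C0..C4 and open states O0..O4, where the column index counts activated S4
  voltage sensors.  Horizontal transitions are independent S4 movements,
  vertical transitions are pore opening, allowed from every column and biased
  by an allosteric coupling factor ``f`` per activated sensor.
* a 6-state scheme for KV7.1+KCNE1: a linear chain C0..C4 followed by a single
  concerted opening step C4 <-> O, i.e. opening requires all four sensors.

Every transition rate follows a single-exponential (Eyring) voltage
dependence ``k(V) = multiplicity * k0 * exp(z * (V - dV) * F / (R * T))``
with a signed partial charge ``z`` and a voltage offset ``dV`` that
perturbations (mutations, drugs) act on.

Convention: the generator matrix ``Q`` returned by :func:`rate_matrix` acts on
column occupancy vectors, ``dp/dt = Q @ p``; its columns sum to zero and
``Q[i, j]`` (i != j) is the rate of the ``j -> i`` transition.  State order is
C0..C4 then O0..O4 (10-state) or C0..C4 then O (6-state).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
from scipy.linalg import null_space

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

PARAM_SCHEMA_VERSION = 1

S4_MOVEMENT = "s4_movement"
OPENING = "opening"
TRANSITION_CLASSES = (S4_MOVEMENT, OPENING)


class ParameterError(ValueError):
    """Invalid rate / scheme parameter."""


class DegenerateModelError(RuntimeError):
    """Numerical failure while solving for a steady state."""


def thermal_voltage_mv(temperature_k: float) -> float:
    """RT/F in millivolts (about 25.4 mV at 295 K)."""
    return 1000.0 * GAS_CONSTANT * temperature_k / FARADAY


@dataclass(frozen=True)
class StateSpec:
    """A single channel conformation.

    ``n_activated`` counts outward (activated) S4 sensors; ``fluor_weight`` is
    the state's fluorescence level, ``n_activated * f1`` plus ``f2`` if the
    gate is open (each activated sensor contributes the F1 increment, opening
    the additional F2 increment).
    """

    id: str
    n_activated: int
    conducting: bool
    fluor_weight: float

    def __post_init__(self) -> None:
        if self.n_activated not in (0, 1, 2, 3, 4):
            raise ParameterError(f"n_activated must be in 0..4, got {self.n_activated}")


@dataclass
class RateLaw:
    """Exponential voltage dependence of a unimolecular transition rate.

    k(V) = multiplicity * k0 * exp(z * (V - dv) / (RT/F))

    with ``k0`` in 1/ms at ``V = dv``, ``z`` the signed partial gating charge
    moved to the barrier (elementary charges) and ``multiplicity`` the
    statistical factor for independent, identical sensors.
    """

    k0: float
    z: float
    dv: float = 0.0
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ParameterError(f"rate k0 must be positive, got {self.k0}")
        if self.multiplicity < 1:
            raise ParameterError("multiplicity must be >= 1")

    def rate(self, v_mv: float, kt_mv: float) -> float:
        return self.multiplicity * self.k0 * math.exp(self.z * (v_mv - self.dv) / kt_mv)


@dataclass
class Transition:
    """One direction of a bidirectional edge in the scheme graph."""

    source: str
    target: str
    law: RateLaw
    kind: str  # one of TRANSITION_CLASSES
    forward: bool  # True for activating / opening direction


@dataclass
class PerturbationSpec:
    """A transition-class-targeted modification of a scheme.

    ``delta_v`` shifts the voltage dependence of both directions of every
    targeted transition (positive = stronger depolarization required); the
    equilibrium constant of a shifted transition at voltage ``V`` equals the
    unshifted one at ``V - delta_v``.  ``rate_scale_forward`` /
    ``rate_scale_backward`` multiply the corresponding k0 values (kinetic
    effect with no equilibrium-shift interpretation of their ratio removed).
    """

    target_class: str  # "s4_movement" | "opening" | "all"
    delta_v: float = 0.0
    rate_scale_forward: float = 1.0
    rate_scale_backward: float = 1.0

    def __post_init__(self) -> None:
        if self.target_class not in TRANSITION_CLASSES + ("all",):
            raise ParameterError(f"unknown transition class {self.target_class!r}")
        if self.rate_scale_forward <= 0 or self.rate_scale_backward <= 0:
            raise ParameterError("rate scale factors must be positive")


@dataclass
class GatingScheme:
    """A labeled state graph with voltage-dependent transition rates."""

    name: str
    states: list[StateSpec]
    transitions: list[Transition]
    f1: float
    f2: float
    allosteric_factor: float | None = None
    temperature_k: float = 295.0
    gmax_us: float = 10.0
    e_rev_mv: float = -95.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.states]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate state ids")
        self._index = {s: i for i, s in enumerate(ids)}
        for t in self.transitions:
            if t.source not in self._index or t.target not in self._index:
                raise ParameterError(f"transition references unknown state {t.source}->{t.target}")
        self._check_reversibility()

    # -- structure ---------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state_id: str) -> int:
        return self._index[state_id]

    @property
    def conducting_mask(self) -> np.ndarray:
        return np.array([s.conducting for s in self.states], dtype=bool)

    @property
    def fluor_weights(self) -> np.ndarray:
        return np.array([s.fluor_weight for s in self.states], dtype=float)

    @property
    def kt_mv(self) -> float:
        return thermal_voltage_mv(self.temperature_k)

    def edges(self) -> set[tuple[str, str]]:
        return {(t.source, t.target) for t in self.transitions}

    def _check_reversibility(self) -> None:
        edges = self.edges()
        for s, t in edges:
            if (t, s) not in edges:
                raise ParameterError(f"transition {s}->{t} has no reverse transition")

    def copy(self) -> "GatingScheme":
        return copy.deepcopy(self)

    def with_temperature(self, temperature_k: float, q10: float = 1.0) -> "GatingScheme":
        """Return a copy at a new bath temperature.

        All k0 values are scaled by ``q10 ** ((T - T_ref) / 10)``; the thermal
        voltage RT/F is updated as well.  Q10 for IKs gating is high
        (reported values cluster around 5-7.5); the default of 1 applies no
        kinetic scaling so temperature handling stays explicit.
        """
        out = self.copy()
        scale = q10 ** ((temperature_k - self.temperature_k) / 10.0)
        for t in out.transitions:
            t.law.k0 *= scale
        out.temperature_k = temperature_k
        return out


# ---------------------------------------------------------------------------
# scheme builders
# ---------------------------------------------------------------------------


def _rates_block(params: dict, key: str) -> tuple[float, float]:
    try:
        blk = params["rates"][key]
        return float(blk["k0"]), float(blk["z"])
    except KeyError as exc:
        raise ParameterError(f"missing rate block {key!r}") from exc


def build_kv71_scheme(params: dict) -> GatingScheme:
    """Build the 10-state allosteric KV7.1 scheme.

    ``params`` carries blocks ``rates.s4_forward``, ``rates.s4_backward``,
    ``rates.opening``, ``rates.closing`` (each ``{k0, z}``; z of backward /
    closing rates should be negative), the allosteric coupling
    ``allosteric_factor`` (f >= 1), an ``allosteric_split`` exponent x in
    [0, 1] (fraction of f**n applied to the opening rate of column n, the
    remainder lowering the closing rate; default 1, i.e. coupling speeds up
    opening), fluorescence increments ``f1``/``f2`` and optional
    ``temperature_K``, ``gmax_uS``, ``e_rev_mV``.

    Detailed balance around every elementary 4-cycle of the grid holds by
    construction: open-row S4 equilibria exceed closed-row ones by exactly f,
    and the opening equilibrium gains a factor f per activated sensor.
    """
    a0, za = _rates_block(params, "s4_forward")
    b0, zb = _rates_block(params, "s4_backward")
    ko0, zo = _rates_block(params, "opening")
    kc0, zc = _rates_block(params, "closing")
    f = float(params["allosteric_factor"])
    split = float(params.get("allosteric_split", 1.0))
    f1 = float(params["f1"])
    f2 = float(params["f2"])
    if f < 1:
        raise ParameterError(f"allosteric factor must be >= 1, got {f}")
    if not 0.0 <= split <= 1.0:
        raise ParameterError("allosteric_split must lie in [0, 1]")

    states = [StateSpec(f"C{n}", n, False, n * f1) for n in range(5)]
    states += [StateSpec(f"O{n}", n, True, n * f1 + f2) for n in range(5)]

    transitions: list[Transition] = []
    # horizontal S4 steps, closed row: independent sensors, multiplicities 4-n / n+1
    for n in range(4):
        transitions.append(
            Transition(f"C{n}", f"C{n+1}", RateLaw(a0, za, multiplicity=4 - n), S4_MOVEMENT, True)
        )
        transitions.append(
            Transition(f"C{n+1}", f"C{n}", RateLaw(b0, zb, multiplicity=n + 1), S4_MOVEMENT, False)
        )
    # horizontal S4 steps, open row: equilibrium biased by f (sensor activation
    # is stabilized in the open conformation; the bias slows the backward rate)
    for n in range(4):
        transitions.append(
            Transition(f"O{n}", f"O{n+1}", RateLaw(a0, za, multiplicity=4 - n), S4_MOVEMENT, True)
        )
        transitions.append(
            Transition(f"O{n+1}", f"O{n}", RateLaw(b0 / f, zb, multiplicity=n + 1), S4_MOVEMENT, False)
        )
    # vertical opening steps: equilibrium L_n = (ko0/kc0) * f**n, split between
    # the two directions by the configurable exponent
    for n in range(5):
        transitions.append(
            Transition(f"C{n}", f"O{n}", RateLaw(ko0 * f ** (split * n), zo), OPENING, True)
        )
        transitions.append(
            Transition(f"O{n}", f"C{n}", RateLaw(kc0 * f ** (-(1.0 - split) * n), zc), OPENING, False)
        )

    return GatingScheme(
        name="kv71_10state",
        states=states,
        transitions=transitions,
        f1=f1,
        f2=f2,
        allosteric_factor=f,
        temperature_k=float(params.get("temperature_K", 295.0)),
        gmax_us=float(params.get("gmax_uS", 10.0)),
        e_rev_mv=float(params.get("e_rev_mV", -95.0)),
        meta={"params": copy.deepcopy(params)},
    )


def build_iks_scheme(params: dict) -> GatingScheme:
    """Build the 6-state KV7.1+KCNE1 (IKs) scheme: C0..C4 chain plus one
    concerted opening step C4 <-> O.  Only O conducts; its fluorescence level
    is ``4*f1 + f2``.  The opening step may carry gating charge through the z
    of the ``opening`` / ``closing`` rate blocks."""
    a0, za = _rates_block(params, "s4_forward")
    b0, zb = _rates_block(params, "s4_backward")
    ko0, zo = _rates_block(params, "opening")
    kc0, zc = _rates_block(params, "closing")
    f1 = float(params["f1"])
    f2 = float(params["f2"])

    states = [StateSpec(f"C{n}", n, False, n * f1) for n in range(5)]
    states.append(StateSpec("O", 4, True, 4 * f1 + f2))

    transitions: list[Transition] = []
    for n in range(4):
        transitions.append(
            Transition(f"C{n}", f"C{n+1}", RateLaw(a0, za, multiplicity=4 - n), S4_MOVEMENT, True)
        )
        transitions.append(
            Transition(f"C{n+1}", f"C{n}", RateLaw(b0, zb, multiplicity=n + 1), S4_MOVEMENT, False)
        )
    transitions.append(Transition("C4", "O", RateLaw(ko0, zo), OPENING, True))
    transitions.append(Transition("O", "C4", RateLaw(kc0, zc), OPENING, False))

    return GatingScheme(
        name="iks_6state",
        states=states,
        transitions=transitions,
        f1=f1,
        f2=f2,
        allosteric_factor=None,
        temperature_k=float(params.get("temperature_K", 295.0)),
        gmax_us=float(params.get("gmax_uS", 10.0)),
        e_rev_mv=float(params.get("e_rev_mV", -95.0)),
        meta={"params": copy.deepcopy(params)},
    )


_BUILDERS = {"kv71_10state": build_kv71_scheme, "iks_6state": build_iks_scheme}


def build_scheme(params: dict) -> GatingScheme:
    """Dispatch on ``params['scheme']`` (kv71_10state or iks_6state)."""
    try:
        builder = _BUILDERS[params["scheme"]]
    except KeyError as exc:
        raise ParameterError(f"unknown scheme {params.get('scheme')!r}") from exc
    return builder(params)


def load_params(path) -> dict:
    with open(path) as fh:
        params = json.load(fh)
    version = params.get("schema_version", PARAM_SCHEMA_VERSION)
    if version != PARAM_SCHEMA_VERSION:
        raise ParameterError(f"unsupported parameter schema version {version}")
    return params


def default_params(scheme: str) -> dict:
    """Load the packaged wild-type parameter file for a scheme.

    The shipped values are a synthetic, calibrated stand-in for the original
    model rate constants (which are not republished here): they were fitted to
    reproduce the published wild-type G(V)/F(V) relationships and the
    documented responses to S4-movement and opening-transition voltage shifts.
    Replace with your own transcription or fit via ``load_params``.
    """
    fname = {"kv71_10state": "kv71_10state_wt_synthetic.json",
             "iks_6state": "iks_6state_wt_synthetic.json"}.get(scheme)
    if fname is None:
        raise ParameterError(f"no default parameters for scheme {scheme!r}")
    text = resources.files("iksim.params").joinpath(fname).read_text()
    return json.loads(text)


def default_scheme(scheme: str) -> GatingScheme:
    return build_scheme(default_params(scheme))


# ---------------------------------------------------------------------------
# generator matrix / steady state / perturbation
# ---------------------------------------------------------------------------


def rate_matrix(scheme: GatingScheme, v_mv: float) -> np.ndarray:
    """Generator matrix Q (1/ms) at membrane voltage ``v_mv``.

    Column convention: ``dp/dt = Q @ p``; every column sums to zero and
    ``Q[i, j]`` for i != j is the rate from state j to state i.
    """
    if not math.isfinite(v_mv):
        raise ParameterError("voltage must be finite")
    n = scheme.n_states
    kt = scheme.kt_mv
    q = np.zeros((n, n))
    for t in scheme.transitions:
        i, j = scheme.state_index(t.target), scheme.state_index(t.source)
        q[i, j] += t.law.rate(v_mv, kt)
    q[np.diag_indices(n)] -= q.sum(axis=0)
    return q


def steady_state(scheme: GatingScheme, v_mv: float) -> np.ndarray:
    """Equilibrium occupancy vector at a holding voltage.

    The schemes built here satisfy detailed balance, so the equilibrium is a
    Boltzmann distribution whose log-weights accumulate along any spanning
    tree of the state graph.  Working in log space keeps the computation
    stable at voltages where the generator itself is numerically singular
    (the result is the null-space direction of the generator; a residual
    check enforces that).  Raises :class:`DegenerateModelError` on failure
    rather than returning NaNs silently.
    """
    if not math.isfinite(v_mv):
        raise ParameterError("voltage must be finite")
    kt = scheme.kt_mv
    log_rates: dict[tuple[int, int], float] = {}
    for t in scheme.transitions:
        key = (scheme.state_index(t.source), scheme.state_index(t.target))
        if key in log_rates:
            # parallel directed edges break the spanning-tree shortcut
            return _steady_state_nullspace(scheme, v_mv)
        log_rates[key] = (
            math.log(t.law.multiplicity * t.law.k0) + t.law.z * (v_mv - t.law.dv) / kt
        )
    n = scheme.n_states
    logw = np.full(n, np.nan)
    logw[0] = 0.0
    frontier = [0]
    while frontier:
        nxt = []
        for i in frontier:
            for (a, b), lr in log_rates.items():
                if a == i and np.isnan(logw[b]):
                    logw[b] = logw[a] + lr - log_rates[(b, a)]
                    nxt.append(b)
        frontier = nxt
    if np.isnan(logw).any():
        raise DegenerateModelError("scheme graph is not connected")
    p = np.exp(logw - logw.max())
    p /= p.sum()
    q = rate_matrix(scheme, v_mv)
    if not np.isfinite(q).all():
        raise DegenerateModelError(f"rate matrix overflow at V={v_mv} mV")
    resid = np.abs(q @ p).max() / max(np.abs(q).max(), 1e-300)
    if not np.isfinite(resid) or resid > 1e-6:
        raise DegenerateModelError(
            f"steady state violates the generator null-space condition at V={v_mv} mV"
        )
    return p


def _steady_state_nullspace(scheme: GatingScheme, v_mv: float) -> np.ndarray:
    """SVD null-space fallback for schemes with parallel directed edges."""
    q = rate_matrix(scheme, v_mv)
    if not np.isfinite(q).all():
        raise DegenerateModelError(f"rate matrix overflow at V={v_mv} mV")
    ns = null_space(q)
    if ns.shape[1] != 1:
        raise DegenerateModelError(
            f"generator null space has dimension {ns.shape[1]} at V={v_mv} mV"
        )
    p = ns[:, 0]
    p = p * np.sign(p.sum())
    if (p < -1e-8 * np.abs(p).max()).any():
        raise DegenerateModelError(f"negative steady-state occupancy at V={v_mv} mV")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def open_probability(scheme: GatingScheme, v_mv: float) -> float:
    return float(steady_state(scheme, v_mv)[scheme.conducting_mask].sum())


def mean_fluorescence(scheme: GatingScheme, v_mv: float) -> float:
    return float(steady_state(scheme, v_mv) @ scheme.fluor_weights)


def apply_perturbation(scheme: GatingScheme, spec: PerturbationSpec) -> GatingScheme:
    """Return a new scheme with the targeted transition class modified.

    Shifting by ``delta_v`` adds the offset to the dV of both directions of
    every targeted transition, translating that step's equilibrium along the
    voltage axis; rate scale factors multiply k0 of the forward (activating /
    opening) and backward directions respectively.  A spec with ``delta_v=0``
    and unit scales is an exact identity.
    """
    out = scheme.copy()
    hit = False
    for t in out.transitions:
        if spec.target_class not in ("all", t.kind):
            continue
        hit = True
        t.law.dv += spec.delta_v
        t.law.k0 *= spec.rate_scale_forward if t.forward else spec.rate_scale_backward
    if not hit:
        raise ParameterError(
            f"scheme {scheme.name!r} has no transitions of class {spec.target_class!r}"
        )
    out.meta = dict(out.meta)
    out.meta.setdefault("perturbations", []).append(
        {
            "target_class": spec.target_class,
            "delta_v": spec.delta_v,
            "rate_scale_forward": spec.rate_scale_forward,
            "rate_scale_backward": spec.rate_scale_backward,
        }
    )
    return out


def detailed_balance_deviation(scheme: GatingScheme, v_mv: float) -> float:
    """Maximum |log product of equilibrium-constant ratios| over all simple
    cycles of the scheme graph at one voltage (0 for a thermodynamically
    consistent scheme).  Uses a cycle basis of the undirected graph."""
    import networkx as nx

    kt = scheme.kt_mv
    rates: dict[tuple[str, str], float] = {}
    for t in scheme.transitions:
        rates[(t.source, t.target)] = rates.get((t.source, t.target), 0.0) + t.law.rate(v_mv, kt)
    g = nx.Graph()
    g.add_edges_from({tuple(sorted(e)) for e in rates})
    worst = 0.0
    for cycle in nx.cycle_basis(g):
        log_prod = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            log_prod += math.log(rates[(a, b)]) - math.log(rates[(b, a)])
        worst = max(worst, abs(log_prod))
    return worst
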