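"""Propagation of gating schemes through voltage protocols and observables.

Within each constant-voltage segment the master equation ``dp/dt = Q p`` is
linear with a constant generator, so occupancies are propagated exactly by
repeated application of ``expm(Q * dt)``; a stiff-ODE path (``method='ode'``)
is provided as an independent numerical cross-check.  Current and
fluorescence are memoryless functions of the occupancy vector:

    I(t) = Gmax * sum_open p(t) * (V(t) - E_rev)        [uA, with Gmax in uS]
    F(t) = sum_states p(t) * fluor_weight(state)        [arbitrary units]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .protocols import VoltageProtocol, VoltageSegment
from .schemes import GatingScheme, rate_matrix, steady_state

_OCC_TOL = 1e-9


class PropagationError(RuntimeError):
    pass


@dataclass
class SimulationTrace:
    """Time-aligned voltage, occupancy and observable vectors for one sweep."""

    time_ms: np.ndarray
    voltage_mv: np.ndarray
    occupancies: np.ndarray  # (n_samples, n_states)
    state_ids: list[str]
    conducting_mask: np.ndarray
    fluor_weights: np.ndarray
    segment_bounds: list[tuple[float, float, float]]  # (t0, t1, level)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        if not (len(self.voltage_mv) == n and self.occupancies.shape[0] == n):
            raise ValueError("trace vectors must have equal length")
        err = np.abs(self.occupancies.sum(axis=1) - 1.0).max()
        if err > _OCC_TOL:
            raise PropagationError(f"occupancy conservation violated: |sum-1| = {err:.2e}")

    @property
    def open_probability(self) -> np.ndarray:
        return self.occupancies[:, self.conducting_mask].sum(axis=1)

    def segment_slice(self, index: int) -> slice:
        t0, t1, _ = self.segment_bounds[index]
        i0 = int(np.searchsorted(self.time_ms, t0 - 1e-9))
        i1 = int(np.searchsorted(self.time_ms, t1 + 1e-9))
        return slice(i0, i1)


def _segment_times(duration: float, dt: float) -> np.ndarray:
    """Local sample offsets within a segment: dt, 2dt, ..., plus the exact
    segment end when the duration is not a multiple of dt."""
    n_full = int(np.floor(duration / dt + 1e-9))
    times = dt * np.arange(1, n_full + 1)
    if n_full == 0 or duration - times[-1] > 1e-9 * max(1.0, duration):
        times = np.append(times, duration)
    return times


def propagate(
    scheme: GatingScheme,
    segments: list[VoltageSegment],
    initial: np.ndarray | str = "holding",
    holding_mv: float | None = None,
    sample_interval_ms: float = 1.0,
    method: str = "expm",
) -> SimulationTrace:
    """Propagate occupancies through a list of constant-voltage segments.

    ``initial`` is an occupancy vector or the string ``"holding"``, in which
    case the steady state at ``holding_mv`` is used.  The first sample is at
    t = 0 with the initial occupancy; occupancies are continuous across
    segment boundaries.
    """
    if not segments:
        raise ValueError("empty segment list")
    if isinstance(initial, str):
        if initial != "holding":
            raise ValueError(f"unknown initial condition {initial!r}")
        if holding_mv is None:
            raise ValueError("holding_mv required for initial='holding'")
        p = steady_state(scheme, holding_mv)
    else:
        p = np.asarray(initial, dtype=float)
        if p.shape != (scheme.n_states,):
            raise ValueError("initial occupancy has wrong length")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("initial occupancies must sum to 1")
        p = p / p.sum()

    dt = sample_interval_ms
    times = [0.0]
    volts = [segments[0].level_mv]
    occs = [p.copy()]
    bounds = []
    t_offset = 0.0
    for seg in segments:
        q = rate_matrix(scheme, seg.level_mv)
        local = _segment_times(seg.duration_ms, dt)
        if method == "expm":
            prop_dt = expm(q * dt)
            prev_t = 0.0
            for t_loc in local:
                step = t_loc - prev_t
                if abs(step - dt) < 1e-9:
                    p = prop_dt @ p
                else:
                    p = expm(q * step) @ p
                prev_t = t_loc
                times.append(t_offset + t_loc)
                volts.append(seg.level_mv)
                occs.append(p)
            # numerical guard: renormalize drift far below the reporting tol
            p = np.clip(p, 0.0, None)
            p = p / p.sum()
        elif method == "ode":
            sol = solve_ivp(
                lambda t, y: q @ y,
                (0.0, seg.duration_ms),
                p,
                method="BDF",
                t_eval=local,
                rtol=1e-8,
                atol=1e-12,
                jac=lambda t, y: q,
            )
            if not sol.success:
                raise PropagationError(f"ODE solve failed in segment at {seg.level_mv} mV: {sol.message}")
            for t_loc, col in zip(sol.t, sol.y.T):
                times.append(t_offset + t_loc)
                volts.append(seg.level_mv)
                occs.append(col)
            p = sol.y[:, -1]
            p = np.clip(p, 0.0, None)
            p = p / p.sum()
        else:
            raise ValueError(f"unknown propagation method {method!r}")
        bounds.append((t_offset, t_offset + seg.duration_ms, seg.level_mv))
        t_offset += seg.duration_ms

    occ = np.vstack(occs)
    # exact-propagation roundoff accumulates slowly; renormalize rows that are
    # within tolerance, error out on anything worse
    row_sums = occ.sum(axis=1)
    if np.abs(row_sums - 1.0).max() > 1e-7:
        raise PropagationError(
            f"occupancy drift {np.abs(row_sums - 1.0).max():.2e} exceeds tolerance"
        )
    occ = occ / row_sums[:, None]
    return SimulationTrace(
        time_ms=np.asarray(times),
        voltage_mv=np.asarray(volts),
        occupancies=occ,
        state_ids=[s.id for s in scheme.states],
        conducting_mask=scheme.conducting_mask,
        fluor_weights=scheme.fluor_weights,
        segment_bounds=bounds,
        meta={"scheme": scheme.name, "method": method},
    )


def simulate_protocol(
    scheme: GatingScheme, protocol: VoltageProtocol, method: str = "expm"
) -> list[SimulationTrace]:
    """Simulate every sweep of a protocol.

    Independent sweeps each start from the holding-voltage steady state;
    chained protocols (1 Hz trains) carry the final occupancy of one sweep
    into the next, which is what produces use-dependent current accumulation.
    """
    p0 = steady_state(scheme, protocol.holding_mv)
    traces = []
    p = p0
    for k, segments in enumerate(protocol.sweeps):
        trace = propagate(
            scheme,
            segments,
            initial=p,
            sample_interval_ms=protocol.sample_interval_ms,
            method=method,
        )
        trace.meta.update({"protocol": protocol.name, "sweep": k})
        if protocol.test_voltages is not None:
            trace.meta["test_voltage"] = float(protocol.test_voltages[k])
        traces.append(trace)
        p = trace.occupancies[-1] if protocol.chained else p0
    return traces


def current_observable(
    trace: SimulationTrace, gmax_us: float, e_rev_mv: float
) -> np.ndarray:
    """Macroscopic current in uA: Gmax * Po(t) * (V(t) - E_rev)."""
    if gmax_us <= 0:
        raise ValueError("gmax must be positive")
    return gmax_us * trace.open_probability * (trace.voltage_mv - e_rev_mv) * 1e-3


def fluorescence_observable(trace: SimulationTrace) -> np.ndarray:
    """Total fluorescence: occupancy-weighted sum of per-state levels."""
    return trace.occupancies @ trace.fluor_weights


def _interp_at(trace: SimulationTrace, values: np.ndarray, t: float) -> float:
    return float(np.interp(t, trace.time_ms, values))


def gv_curve(
    scheme: GatingScheme,
    protocol: VoltageProtocol | None = None,
    method: str = "tail",
    tail_delay_ms: float = 5.0,
    voltages: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conductance-voltage relation.

    ``method='tail'`` runs the protocol and reads the tail current shortly
    (``tail_delay_ms``) after tail onset, one point per sweep, mirroring the
    experimental tail-current analysis (at a fixed tail voltage the driving
    force is constant, so the instantaneous tail current is proportional to
    the open probability at the end of the test pulse).  ``method='steady_state'``
    returns ``Gmax * Po_inf(V)`` on ``voltages`` (or the protocol's test
    family) and involves no kinetics.
    """
    if method == "steady_state":
        if voltages is None:
            if protocol is None or protocol.test_voltages is None:
                raise ValueError("steady_state method needs voltages or a sweep-family protocol")
            voltages = protocol.test_voltages
        vs = np.asarray(voltages, dtype=float)
        g = np.array([scheme.gmax_us * steady_state(scheme, v)[scheme.conducting_mask].sum() for v in vs])
        return vs, g
    if method != "tail":
        raise ValueError(f"unknown G(V) method {method!r}")
    if protocol is None or protocol.tail_index is None or protocol.test_voltages is None:
        raise ValueError("tail method needs a sweep-family protocol with a tail segment")
    traces = simulate_protocol(scheme, protocol)
    tail_seg = protocol.sweeps[0][protocol.tail_index]
    if tail_delay_ms >= tail_seg.duration_ms:
        raise ValueError("tail delay exceeds tail segment duration")
    points = []
    for trace in traces:
        t0, _, _ = trace.segment_bounds[protocol.tail_index]
        current = current_observable(trace, scheme.gmax_us, scheme.e_rev_mv)
        # interpolate strictly inside the tail segment: the sample at the
        # boundary still carries the test-voltage driving force
        mask = trace.time_ms > t0 + 1e-9
        points.append(float(np.interp(t0 + tail_delay_ms, trace.time_ms[mask], current[mask])))
    return protocol.test_voltages.copy(), np.asarray(points)


def fv_curve(
    scheme: GatingScheme,
    protocol: VoltageProtocol | None = None,
    method: str = "end_of_pulse",
    voltages: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fluorescence-voltage relation: fluorescence at the end of the test
    pulse versus test voltage (or the steady-state fluorescence when
    ``method='steady_state'``)."""
    if method == "steady_state":
        if voltages is None:
            if protocol is None or protocol.test_voltages is None:
                raise ValueError("steady_state method needs voltages or a sweep-family protocol")
            voltages = protocol.test_voltages
        vs = np.asarray(voltages, dtype=float)
        f = np.array([steady_state(scheme, v) @ scheme.fluor_weights for v in vs])
        return vs, f
    if method != "end_of_pulse":
        raise ValueError(f"unknown F(V) method {method!r}")
    if protocol is None or protocol.test_index is None or protocol.test_voltages is None:
        raise ValueError("end_of_pulse method needs a sweep-family protocol")
    traces = simulate_protocol(scheme, protocol)
    points = []
    for trace in traces:
        _, t1, _ = trace.segment_bounds[protocol.test_index]
        fl = fluorescence_observable(trace)
        points.append(_interp_at(trace, fl, t1))
    return protocol.test_voltages.copy(), np.asarray(points)
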