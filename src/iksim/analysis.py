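"""Quantitative analysis of voltage-clamp recordings.

Implements the standard tail-current G(V) workflow for KV7.1 / IKs data:

* tail-current extraction shortly after the tail-voltage onset,
* single Boltzmann fits  G(V) = Gmax / (1 + exp((V50 - V)/s)),
* double Boltzmann fits for two-component F(V) curves (F1 / F2),
* gating charge from the slope factor, z = 25/s,
* opening free-energy perturbation  ddG0 = z * dV50 * F (reported in kJ/mol),
* T50 activation / deactivation metrics and single/double exponential fits.

The 25 mV constant in z = 25/s is the conventional value used with these
recordings and is deliberately not recomputed from temperature.  z derived
this way assumes a two-state channel and tends to underestimate the true
gating charge; results carry that caveat in their metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .schemes import FARADAY

Z_SLOPE_CONSTANT_MV = 25.0


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# tail-current G(V) extraction
# ---------------------------------------------------------------------------


def extract_tail_gv(recording, protocol, delay_ms: float = 5.0, average_window_ms: float = 0.0):
    """Tail-current amplitudes versus test voltage from a recording.

    For every sweep the current is read ``delay_ms`` after the onset of the
    protocol's tail segment (linear interpolation between samples) and paired
    with that sweep's test voltage.  ``average_window_ms > 0`` instead
    averages the samples in ``[delay, delay + window]`` after tail onset — a
    noise-robust read-out whose small decay bias is identical across sweeps
    and therefore cancels in the normalized curve.  No leak subtraction is
    applied — the recordings these curves come from are conventionally not
    leak corrected.  Returns ``(test_voltages, tail_currents)``.
    """
    if protocol.tail_index is None or protocol.test_voltages is None:
        raise ValueError("protocol has no tail segment / test family")
    bounds = protocol.segment_bounds(0)
    t_tail, t_end = bounds[protocol.tail_index]
    if delay_ms < 0 or t_tail + delay_ms + average_window_ms > t_end:
        raise ValueError(
            f"tail read-out window ({delay_ms}+{average_window_ms} ms) outside the "
            f"tail segment ({t_end - t_tail:.0f} ms long)"
        )
    vs, amps = [], []
    for k in range(recording.n_sweeps):
        sw = recording.sweep(k)
        t = sw["time_ms"].to_numpy()
        i = sw["current_uA"].to_numpy()
        # samples strictly inside the tail segment only: the boundary sample
        # still carries the test-voltage driving force
        mask = t > t_tail + 1e-9
        if average_window_ms > 0:
            win = (t >= t_tail + delay_ms) & (t <= t_tail + delay_ms + average_window_ms) & mask
            if not win.any():
                raise ValueError("no samples inside the tail averaging window")
            amps.append(float(i[win].mean()))
        else:
            amps.append(float(np.interp(t_tail + delay_ms, t[mask], i[mask])))
        vs.append(float(protocol.test_voltages[k]))
    return np.asarray(vs), np.asarray(amps)


# ---------------------------------------------------------------------------
# Boltzmann fits
# ---------------------------------------------------------------------------


def boltzmann(v, gmax, v50, s):
    v = np.asarray(v, dtype=float)
    return gmax / (1.0 + np.exp((v50 - v) / s))


@dataclass
class BoltzmannFit:
    gmax: float
    v50: float
    s: float
    gmax_se: float | None = None
    v50_se: float | None = None
    s_se: float | None = None
    residual_norm: float = 0.0
    saturating: bool = True
    flags: list[str] = field(default_factory=list)

    def __call__(self, v):
        return boltzmann(v, self.gmax, self.v50, self.s)

    def normalized(self, y):
        """Divide data by the fitted Gmax (the conventional normalization)."""
        return np.asarray(y, dtype=float) / self.gmax


@dataclass
class DoubleBoltzmannFit:
    baseline: float
    amp1: float
    v50_1: float
    s1: float
    amp2: float
    v50_2: float
    s2: float
    residual_norm: float = 0.0
    flags: list[str] = field(default_factory=list)

    def __call__(self, v):
        return (
            self.baseline
            + boltzmann(v, self.amp1, self.v50_1, self.s1)
            + boltzmann(v, self.amp2, self.v50_2, self.s2)
        )


def _check_points(v, y, minimum):
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("voltage and response arrays must be 1-D and equal length")
    if len(v) < minimum:
        raise FitError(f"need at least {minimum} points, got {len(v)}")
    order = np.argsort(v)
    return v[order], y[order]


def fit_boltzmann(v, y, init: dict | None = None) -> BoltzmannFit:
    """Least-squares single Boltzmann fit.

    A fit whose midpoint plus two slope factors lies beyond the sampled
    voltage range is tagged non-saturating ("approximation"/lowest-estimate,
    mirroring how non-saturating experimental curves are reported).
    """
    v, y = _check_points(v, y, 4)
    span = float(y.max() - y.min())
    if span <= 0:
        raise FitError("response has no dynamic range")
    params = Parameters()
    init = init or {}
    params.add("gmax", value=init.get("gmax", y.max()), min=1e-12 * max(abs(y).max(), 1.0))
    params.add("v50", value=init.get("v50", _half_rise_voltage(v, y)))
    params.add("s", value=init.get("s", max((v.max() - v.min()) / 10.0, 1.0)), min=1e-3)

    def resid(p):
        return boltzmann(v, p["gmax"], p["v50"], p["s"]) - y

    out = minimize(resid, params, method="leastsq")
    if not out.success:
        raise FitError(f"Boltzmann fit did not converge: {out.message}")
    p = out.params
    fit = BoltzmannFit(
        gmax=p["gmax"].value,
        v50=p["v50"].value,
        s=p["s"].value,
        gmax_se=p["gmax"].stderr,
        v50_se=p["v50"].stderr,
        s_se=p["s"].stderr,
        residual_norm=float(np.linalg.norm(out.residual)),
    )
    if fit.v50 + 2.0 * fit.s > v.max():
        fit.saturating = False
        fit.flags.append("approximation")  # lowest estimate: curve top not sampled
    return fit


def fit_boltzmann_shared_slope(curves: dict) -> dict:
    """Jointly fit several curves with one shared slope factor.

    ``curves`` maps a label to ``(v, y)``; used for paired control / treated
    G(V) curves from the same cell.  Returns label -> BoltzmannFit with a
    common ``s``.
    """
    if len(curves) < 2:
        raise FitError("shared-slope fitting needs at least two curves")
    data = {k: _check_points(v, y, 4) for k, (v, y) in curves.items()}
    params = Parameters()
    params.add("s", value=10.0, min=1e-3)
    for i, (k, (v, y)) in enumerate(data.items()):
        params.add(f"gmax_{i}", value=float(np.max(y)), min=1e-12)
        params.add(f"v50_{i}", value=_half_rise_voltage(v, y))

    keys = list(data)

    def resid(p):
        out = []
        for i, k in enumerate(keys):
            v, y = data[k]
            out.append(boltzmann(v, p[f"gmax_{i}"], p[f"v50_{i}"], p["s"]) - y)
        return np.concatenate(out)

    out = minimize(resid, params, method="leastsq")
    if not out.success:
        raise FitError(f"shared-slope fit did not converge: {out.message}")
    fits = {}
    for i, k in enumerate(keys):
        v, y = data[k]
        fit = BoltzmannFit(
            gmax=out.params[f"gmax_{i}"].value,
            v50=out.params[f"v50_{i}"].value,
            s=out.params["s"].value,
            v50_se=out.params[f"v50_{i}"].stderr,
            s_se=out.params["s"].stderr,
            residual_norm=float(np.linalg.norm(out.residual)),
        )
        if fit.v50 + 2.0 * fit.s > v.max():
            fit.saturating = False
            fit.flags.append("approximation")
        fits[k] = fit
    return fits


def _half_rise_voltage(v, y, quantile=0.5):
    """Voltage at which the normalized rise crosses a quantile (fit seed)."""
    y0, y1 = float(np.min(y)), float(np.max(y))
    if y1 <= y0:
        return float(np.median(v))
    yn = (np.asarray(y) - y0) / (y1 - y0)
    idx = np.argmax(yn >= quantile)
    return float(v[idx])


def fit_double_boltzmann(v, y) -> DoubleBoltzmannFit:
    """Sum-of-two-Boltzmanns fit with a baseline, components ordered so that
    v50_1 <= v50_2.

    Midpoints are initialized at the voltages where the normalized rise
    crosses its 25th and 75th percentiles — a deterministic, seed-free
    heuristic.  A fit whose two components collapse (vanishing amplitude or
    indistinguishable midpoints) is flagged ``degenerate_component``.
    """
    v, y = _check_points(v, y, 8)
    span = float(y.max() - y.min())
    if span <= 0:
        raise FitError("response has no dynamic range")
    params = Parameters()
    params.add("baseline", value=float(y.min()), min=float(y.min()) - span, max=float(y.max()))
    params.add("amp1", value=0.5 * span, min=0.0, max=3.0 * span)
    params.add("amp2", value=0.5 * span, min=0.0, max=3.0 * span)
    vspan = v.max() - v.min()
    # midpoints confined to a margin around the sampled range; a component
    # whose true midpoint lies far outside is reported at the bound and
    # flagged degenerate rather than diverging
    params.add("v1", value=_half_rise_voltage(v, y, 0.25), min=v.min() - vspan, max=v.max() + vspan)
    params.add("v2", value=_half_rise_voltage(v, y, 0.75), min=v.min() - vspan, max=v.max() + vspan)
    s_seed = max(vspan / 15.0, 1.0)
    params.add("s1", value=s_seed, min=1e-3, max=5 * vspan)
    params.add("s2", value=s_seed, min=1e-3, max=5 * vspan)

    def resid(p):
        model = (
            p["baseline"]
            + boltzmann(v, p["amp1"], p["v1"], p["s1"])
            + boltzmann(v, p["amp2"], p["v2"], p["s2"])
        )
        return model - y

    # deterministic multi-start over rise-quantile midpoint seeds; curves with
    # one component mostly outside the sampled range are prone to local minima
    out = None
    for q1, q2 in ((0.25, 0.75), (0.10, 0.60), (0.40, 0.90), (0.15, 0.95)):
        params["v1"].value = _half_rise_voltage(v, y, q1)
        params["v2"].value = _half_rise_voltage(v, y, q2)
        try:
            cand = minimize(resid, params, method="leastsq")
            if not cand.success:
                cand = minimize(resid, params, method="least_squares")
        except Exception:
            continue
        if cand.success and (out is None or cand.chisqr < out.chisqr):
            out = cand
    if out is None:
        raise FitError("double Boltzmann fit did not converge")
    p = out.params
    comps = sorted(
        [(p["v1"].value, p["amp1"].value, p["s1"].value), (p["v2"].value, p["amp2"].value, p["s2"].value)]
    )
    fit = DoubleBoltzmannFit(
        baseline=p["baseline"].value,
        amp1=comps[0][1],
        v50_1=comps[0][0],
        s1=comps[0][2],
        amp2=comps[1][1],
        v50_2=comps[1][0],
        s2=comps[1][2],
        residual_norm=float(np.linalg.norm(out.residual)),
    )
    total = fit.amp1 + fit.amp2
    if total <= 0:
        raise FitError("double Boltzmann fit collapsed to zero amplitude")
    overlap = abs(fit.v50_2 - fit.v50_1) < 0.5 * (fit.s1 + fit.s2)
    if min(fit.amp1, fit.amp2) / total < 0.02 or overlap:
        fit.flags.append("degenerate_component")
    return fit


# ---------------------------------------------------------------------------
# energetics
# ---------------------------------------------------------------------------


@dataclass
class EnergyResult:
    z: float
    delta_v50_mv: float
    ddg_kj_mol: float
    notes: tuple[str, ...] = ("z from 25/s underestimates the true gating charge",)


def gating_charge(s_mv: float) -> float:
    """Apparent gating charge from a Boltzmann slope factor: z = 25/s."""
    if s_mv <= 0:
        raise ValueError("slope factor must be positive")
    return Z_SLOPE_CONSTANT_MV / s_mv


def delta_delta_g(z: float, delta_v50_mv: float) -> float:
    """Opening free-energy change in kJ/mol for a V50 shift at gating charge z.

    ddG0 = z * dV50 * F, with dV50 converted to volts and the result to
    kJ/mol; positive shifts at positive z cost energy.
    """
    if not (np.isfinite(z) and np.isfinite(delta_v50_mv)):
        raise ValueError("inputs must be finite")
    return z * (delta_v50_mv * 1e-3) * FARADAY * 1e-3


def energy_from_fits(fit_a: BoltzmannFit, fit_b: BoltzmannFit) -> EnergyResult:
    """ddG0 of condition b relative to a, using the mean apparent z of the
    two fits (they share s when fitted with a shared slope)."""
    z = 0.5 * (gating_charge(fit_a.s) + gating_charge(fit_b.s))
    dv = fit_b.v50 - fit_a.v50
    return EnergyResult(z=z, delta_v50_mv=dv, ddg_kj_mol=delta_delta_g(z, dv))


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


@dataclass
class KineticsResult:
    t50_open_ms: float | None = None
    t50_close_ms: float | None = None
    tau_fast_ms: float | None = None
    tau_slow_ms: float | None = None
    amplitudes: tuple = ()
    offset: float | None = None
    window_ms: tuple | None = None
    flags: list[str] = field(default_factory=list)


# samples averaged for the end-of-pulse / steady-state level; kept small so
# the estimate tracks the final level rather than the approach to it (noisy
# recordings should use the median smoothing instead)
_END_WINDOW = 5


def _median_smooth(y, window):
    if window <= 1:
        return y
    from scipy.ndimage import median_filter

    return median_filter(y, size=window, mode="nearest")


def _first_crossing(t, y, level, rising):
    y = np.asarray(y)
    above = y >= level if rising else y <= level
    idx = np.argmax(above)
    if not above.any() or (idx == 0 and not above[0]):
        raise FitError("signal never crosses the half-amplitude level")
    if idx == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[idx - 1], t[idx], y[idx - 1], y[idx]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def t50_open(time_ms, current, smooth_window: int = 1) -> float:
    """Time to reach 50% of the end-of-pulse current, by linear interpolation.

    ``time_ms``/``current`` cover the test pulse, with t = 0 at pulse onset.
    A small median filter (``smooth_window`` samples, default off) can tame
    non-monotone noise before the crossing search.
    """
    t = np.asarray(time_ms, dtype=float)
    y = _median_smooth(np.asarray(current, dtype=float), smooth_window)
    end_level = float(np.mean(y[-_END_WINDOW:]))
    start = float(y[0])
    if end_level <= start:
        raise FitError("current does not rise during the test pulse")
    half = start + 0.5 * (end_level - start)
    return _first_crossing(t - t[0], y, half, rising=True)


def t50_close(time_ms, current, smooth_window: int = 1) -> float:
    """Time for the tail-current amplitude (instantaneous minus steady-state
    level) to decay by 50%, measured from tail onset."""
    t = np.asarray(time_ms, dtype=float)
    y = _median_smooth(np.asarray(current, dtype=float), smooth_window)
    inst = float(y[0])
    ss = float(np.mean(y[-_END_WINDOW:]))
    amp = inst - ss
    if abs(amp) < 1e-12 * max(abs(inst), 1.0):
        raise FitError("tail current shows no relaxation (instantaneous == steady state)")
    half = ss + 0.5 * amp
    return _first_crossing(t - t[0], y, half, rising=amp < 0)


def fit_exponentials(time_ms, y, n_components: int = 1, window_ms: tuple | None = None) -> KineticsResult:
    """Least-squares fit of ``c + sum_i a_i * exp(-t/tau_i)`` with 1 or 2
    components; for two components tau_fast <= tau_slow on output."""
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    t = np.asarray(time_ms, dtype=float)
    y = np.asarray(y, dtype=float)
    if window_ms is not None:
        lo, hi = window_ms
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            raise ValueError("fit window outside trace")
        mask = (t >= lo) & (t <= hi)
        t, y = t[mask], y[mask]
    t = t - t[0]
    span = t[-1] - t[0]
    if span <= 0 or len(t) < 3 + 2 * n_components:
        raise FitError("too few samples in fit window")

    params = Parameters()
    params.add("c", value=float(y[-1]))
    amp0 = float(y[0] - y[-1])
    if n_components == 1:
        params.add("a1", value=amp0)
        params.add("tau1", value=span / 5.0, min=1e-6)
    else:
        params.add("a1", value=0.5 * amp0)
        params.add("a2", value=0.5 * amp0)
        params.add("tau1", value=span / 20.0, min=1e-6)
        params.add("tau2", value=span / 2.0, min=1e-6)

    def model(p):
        out = p["c"] + p["a1"] * np.exp(-t / p["tau1"])
        if n_components == 2:
            out = out + p["a2"] * np.exp(-t / p["tau2"])
        return out

    out = minimize(lambda p: model(p) - y, params, method="leastsq")
    if not out.success:
        raise FitError(f"exponential fit did not converge: {out.message}")
    p = out.params
    if n_components == 1:
        res = KineticsResult(
            tau_fast_ms=p["tau1"].value,
            tau_slow_ms=p["tau1"].value,
            amplitudes=(p["a1"].value,),
            offset=p["c"].value,
            window_ms=window_ms,
        )
    else:
        comps = sorted([(p["tau1"].value, p["a1"].value), (p["tau2"].value, p["a2"].value)])
        res = KineticsResult(
            tau_fast_ms=comps[0][0],
            tau_slow_ms=comps[1][0],
            amplitudes=(comps[0][1], comps[1][1]),
            offset=p["c"].value,
            window_ms=window_ms,
        )
        total = abs(comps[0][1]) + abs(comps[1][1])
        if total > 0 and min(abs(comps[0][1]), abs(comps[1][1])) / total < 0.02:
            res.flags.append("degenerate_component")
    return res


def tau_ratio(pairs: dict) -> dict:
    """Per-cell treated/control time-constant ratios.

    ``pairs`` maps a cell id to ``(tau_control, tau_treated)``; the returned
    ratios feed the one-sample t-test against a hypothetical value of 1.
    """
    out = {}
    for cell, (tau_ctrl, tau_treat) in pairs.items():
        if tau_ctrl <= 0 or tau_treat <= 0:
            raise ValueError(f"non-positive time constant for cell {cell!r}")
        out[cell] = tau_treat / tau_ctrl
    return out
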