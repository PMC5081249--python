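"""Synthetic surrogate recordings for pipeline testing.

No public deposits of the oocyte recordings this kind of analysis targets
exist, so the package generates its own: model current plus an ohmic leak and
Gaussian amplifier noise, model fluorescence under exponential photobleaching
plus Gaussian shot/readout noise, lognormal cell-to-cell expression (Gmax)
variability, optional per-cell voltage-dependence jitter, and homozygous or
heterozygous (two-population current mixture) expression modes.

Heterozygous expression is modeled as a linear mixture of two homomeric
channel populations, ``I = p * I_wt + (1 - p) * I_mut`` — not as random
subunit co-assembly, whose intermediate phenotypes are not constrained by
available data.

Randomness policy: every generator takes one root seed; per-cell and
per-signal child generators are spawned deterministically from it, so a
dataset is bit-stable given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .protocols import VoltageProtocol
from .schemes import GatingScheme, PerturbationSpec, apply_perturbation
from .simulate import current_observable, fluorescence_observable, simulate_protocol


@dataclass
class NoiseModel:
    """Measurement-noise and artifact parameters for one recording."""

    current_sd_ua: float = 0.05
    fluorescence_sd: float = 0.01
    bleach_rate_per_s: float = 0.0  # exponential fluorescence baseline decay
    leak_conductance_us: float = 0.0
    leak_reversal_mv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.current_sd_ua < 0 or self.fluorescence_sd < 0 or self.bleach_rate_per_s < 0:
            raise ValueError("noise standard deviations and bleach rate must be >= 0")


@dataclass
class CellPopulationSpec:
    """Cell-to-cell variability for a simulated batch of oocytes.

    Gmax is lognormal (median ``gmax_median_us``, shape ``gmax_sigma`` on the
    log scale, about 25% spread by default); ``v50_jitter_mv_sd`` jitters each
    cell's voltage dependence by a global shift.  ``expression_mode`` selects
    homozygous channels or a heterozygous two-population mixture with
    wild-type fraction ``mixture_fraction``.
    """

    n_cells: int = 8
    gmax_median_us: float = 10.0
    gmax_sigma: float = 0.25
    v50_jitter_mv_sd: float = 0.0
    expression_mode: str = "homozygous"
    mixture_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.mixture_fraction <= 1.0:
            raise ValueError("mixture_fraction must lie in [0, 1]")
        if self.expression_mode not in ("homozygous", "heterozygous_mixture"):
            raise ValueError(f"unknown expression mode {self.expression_mode!r}")


@dataclass
class Recording:
    """A tabular surrogate recording: one row per sample, long format."""

    data: pd.DataFrame  # sweep, time_ms, voltage_mV, current_uA[, fluorescence_au]
    meta: dict = field(default_factory=dict)

    def sweep(self, k: int) -> pd.DataFrame:
        return self.data[self.data["sweep"] == k]

    @property
    def n_sweeps(self) -> int:
        return int(self.data["sweep"].max()) + 1

    def to_csv(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        with open(path.with_suffix(".meta.json"), "w") as fh:
            json.dump(self.meta, fh, indent=2, default=float)

    @classmethod
    def from_csv(cls, path) -> "Recording":
        path = Path(path)
        data = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(data=data, meta=meta)


def _noisy_observables(traces, scheme, noise, rng, gmax_us=None, include_fluorescence=True):
    """Assemble per-sweep observable frames with leak, bleach and noise."""
    gmax = scheme.gmax_us if gmax_us is None else gmax_us
    frames = []
    t_global = 0.0
    for k, trace in enumerate(traces):
        current = current_observable(trace, gmax, scheme.e_rev_mv)
        current = current + noise.leak_conductance_us * (
            trace.voltage_mv - noise.leak_reversal_mv
        ) * 1e-3
        if noise.current_sd_ua > 0:
            current = current + rng.normal(0.0, noise.current_sd_ua, size=current.shape)
        cols = {
            "sweep": k,
            "time_ms": trace.time_ms,
            "voltage_mV": trace.voltage_mv,
            "current_uA": current,
        }
        if include_fluorescence:
            fl = fluorescence_observable(trace)
            if noise.bleach_rate_per_s > 0:
                # bleaching acts on cumulative illumination time across sweeps
                fl = fl * np.exp(-noise.bleach_rate_per_s * (t_global + trace.time_ms) * 1e-3)
            if noise.fluorescence_sd > 0:
                fl = fl + rng.normal(0.0, noise.fluorescence_sd, size=fl.shape)
            cols["fluorescence_au"] = fl
        frames.append(pd.DataFrame(cols))
        t_global += trace.time_ms[-1]
    return pd.concat(frames, ignore_index=True)


def generate_recording(
    scheme: GatingScheme,
    protocol: VoltageProtocol,
    noise: NoiseModel,
    gmax_us: float | None = None,
    include_fluorescence: bool = True,
) -> Recording:
    """Simulate one cell's recording under a protocol with the given noise.

    Deterministic given ``noise.seed``.  With all noise parameters zero the
    current and fluorescence equal the clean simulation output.
    """
    rng = np.random.default_rng(noise.seed)
    traces = simulate_protocol(scheme, protocol)
    data = _noisy_observables(traces, scheme, noise, rng, gmax_us, include_fluorescence)
    meta = {
        "scheme": scheme.name,
        "protocol": protocol.name,
        "test_voltages": None
        if protocol.test_voltages is None
        else [float(v) for v in protocol.test_voltages],
        "noise": asdict(noise),
        "gmax_uS": float(scheme.gmax_us if gmax_us is None else gmax_us),
        "e_rev_mV": scheme.e_rev_mv,
    }
    return Recording(data=data, meta=meta)


def _mixture_recording(scheme_wt, scheme_mut, p_wt, protocol, noise, rng, gmax_us):
    traces_wt = simulate_protocol(scheme_wt, protocol)
    traces_mut = simulate_protocol(scheme_mut, protocol)
    frames = []
    for k, (tw, tm) in enumerate(zip(traces_wt, traces_mut)):
        i_wt = current_observable(tw, gmax_us, scheme_wt.e_rev_mv)
        i_mut = current_observable(tm, gmax_us, scheme_mut.e_rev_mv)
        current = p_wt * i_wt + (1.0 - p_wt) * i_mut
        current = current + noise.leak_conductance_us * (
            tw.voltage_mv - noise.leak_reversal_mv
        ) * 1e-3
        if noise.current_sd_ua > 0:
            current = current + rng.normal(0.0, noise.current_sd_ua, size=current.shape)
        fl = p_wt * fluorescence_observable(tw) + (1.0 - p_wt) * fluorescence_observable(tm)
        if noise.fluorescence_sd > 0:
            fl = fl + rng.normal(0.0, noise.fluorescence_sd, size=fl.shape)
        frames.append(
            pd.DataFrame(
                {
                    "sweep": k,
                    "time_ms": tw.time_ms,
                    "voltage_mV": tw.voltage_mv,
                    "current_uA": current,
                    "fluorescence_au": fl,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_population(
    scheme_wt: GatingScheme,
    scheme_mut: GatingScheme | None,
    spec: CellPopulationSpec,
    protocol: VoltageProtocol,
    noise: NoiseModel,
) -> list[Recording]:
    """Generate a batch of per-cell recordings.

    Homozygous cells carry only ``scheme_mut`` channels (or ``scheme_wt`` if
    no mutant is given); heterozygous cells mix wild-type and mutant currents
    linearly with wild-type fraction ``spec.mixture_fraction``.  Per-cell Gmax
    is lognormal and an optional per-cell global voltage shift emulates
    cell-to-cell V50 scatter.
    """
    if spec.expression_mode == "heterozygous_mixture" and scheme_mut is None:
        raise ValueError("heterozygous_mixture needs a mutant scheme")
    root = np.random.SeedSequence(noise.seed)
    children = root.spawn(spec.n_cells)
    recordings = []
    for cell, child in enumerate(children):
        rng = np.random.default_rng(child)
        gmax = spec.gmax_median_us * np.exp(rng.normal(0.0, spec.gmax_sigma))
        jitter = rng.normal(0.0, spec.v50_jitter_mv_sd) if spec.v50_jitter_mv_sd > 0 else 0.0
        wt = scheme_wt
        mut = scheme_mut
        if jitter != 0.0:
            shift = PerturbationSpec("all", delta_v=jitter)
            wt = apply_perturbation(wt, shift)
            mut = apply_perturbation(mut, shift) if mut is not None else None
        if spec.expression_mode == "heterozygous_mixture":
            data = _mixture_recording(wt, mut, spec.mixture_fraction, protocol, noise, rng, gmax)
            scheme_label = f"{scheme_wt.name}+{scheme_mut.name}"
        else:
            target = mut if mut is not None else wt
            traces = simulate_protocol(target, protocol)
            data = _noisy_observables(traces, target, noise, rng, gmax)
            scheme_label = target.name
        meta = {
            "cell": cell,
            "scheme": scheme_label,
            "protocol": protocol.name,
            "test_voltages": None
            if protocol.test_voltages is None
            else [float(v) for v in protocol.test_voltages],
            "gmax_uS": float(gmax),
            "v50_jitter_mV": float(jitter),
            "expression_mode": spec.expression_mode,
            "mixture_fraction": spec.mixture_fraction,
            "noise": asdict(noise),
            "cell_seed": [int(s) for s in child.generate_state(4)],
            "e_rev_mV": scheme_wt.e_rev_mv,
        }
        recordings.append(Recording(data=data, meta=meta))
    return recordings


def emulate_treatment(
    scheme: GatingScheme,
    delta_v: float = -30.0,
    opening_speed_factor: float = 1.0,
    closing_slow_factor: float = 1.0,
) -> GatingScheme:
    """Emulate an activator / drug effect for paired-dataset testing.

    The emulation is phenomenological: a global voltage-dependence shift
    (negative = easier activation) plus optional kinetic scaling that speeds
    opening and slows closing.  It makes no claim about molecular mechanism —
    it exists so the paired control/treated analysis pipeline has structured
    input.
    """
    out = scheme
    if delta_v != 0.0:
        out = apply_perturbation(out, PerturbationSpec("all", delta_v=delta_v))
    if opening_speed_factor != 1.0 or closing_slow_factor != 1.0:
        out = apply_perturbation(
            out,
            PerturbationSpec(
                "opening",
                rate_scale_forward=opening_speed_factor,
                rate_scale_backward=1.0 / closing_slow_factor,
            ),
        )
    return out


def write_dataset(recordings: list[Recording], out_dir, manifest_extra: dict | None = None) -> Path:
    """Write one CSV per cell plus a manifest JSON; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        cell = rec.meta.get("cell", 0)
        fname = f"cell{cell:03d}.csv"
        rec.to_csv(out_dir / fname)
        entries.append({"file": fname, **{k: v for k, v in rec.meta.items() if k != "noise"}})
    manifest = {"cells": entries}
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest_path
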