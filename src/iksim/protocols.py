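"""Piecewise-constant command-voltage protocols for TEVC and VCF experiments.

A :class:`VoltageProtocol` is a family of sweeps; every sweep is an ordered
list of constant-voltage segments.  The standard protocols used throughout
the package mirror the classic two-electrode voltage-clamp conventions for
KV7.1 / IKs work in oocytes: holding at -80 mV, a hyperpolarizing pre-pulse
that resets the voltage sensors, a long depolarizing test-pulse family, and a
fixed tail voltage whose instantaneous current indexes the open probability
reached during the test pulse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoltageSegment:
    level_mv: float
    duration_ms: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.duration_ms > 0:
            raise ValueError(f"segment duration must be positive, got {self.duration_ms}")


@dataclass
class VoltageProtocol:
    """A sweep family.

    ``sweeps[k]`` is the segment list of the k-th sweep.  For protocols built
    from a test-voltage family, ``test_voltages[k]`` is the test level of
    sweep k and ``test_index`` / ``tail_index`` locate the test and tail
    segments inside each sweep.  ``chained`` marks protocols whose sweeps run
    back-to-back from the final state of the previous sweep (1 Hz trains)
    instead of starting from the holding-voltage equilibrium.
    """

    name: str
    holding_mv: float
    sweeps: list[list[VoltageSegment]]
    sample_interval_ms: float = 1.0
    test_voltages: np.ndarray | None = None
    test_index: int | None = None
    tail_index: int | None = None
    chained: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sweeps or any(len(s) == 0 for s in self.sweeps):
            raise ValueError("protocol needs at least one sweep with at least one segment")
        if self.sample_interval_ms <= 0:
            raise ValueError("sample interval must be positive")
        if self.test_voltages is not None:
            self.test_voltages = np.asarray(self.test_voltages, dtype=float)
            dv = np.diff(self.test_voltages)
            # ramp families must be strictly monotone; constant families
            # (repetitive trains) are allowed
            if len(dv) and not ((dv > 0).all() or (dv < 0).all() or (dv == 0).all()):
                raise ValueError("test voltages must be strictly monotone")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def segment_bounds(self, sweep: int) -> list[tuple[float, float]]:
        """(start, end) times in ms of each segment of one sweep."""
        t = 0.0
        bounds = []
        for seg in self.sweeps[sweep]:
            bounds.append((t, t + seg.duration_ms))
            t += seg.duration_ms
        return bounds

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "holding_mv": self.holding_mv,
            "sample_interval_ms": self.sample_interval_ms,
            "chained": self.chained,
            "test_voltages": None if self.test_voltages is None else list(self.test_voltages),
            "test_index": self.test_index,
            "tail_index": self.tail_index,
            "sweeps": [
                [
                    {"level_mv": s.level_mv, "duration_ms": s.duration_ms, "label": s.label}
                    for s in sweep
                ]
                for sweep in self.sweeps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        return cls(
            name=d["name"],
            holding_mv=d["holding_mv"],
            sweeps=[
                [VoltageSegment(s["level_mv"], s["duration_ms"], s.get("label", "")) for s in sw]
                for sw in d["sweeps"]
            ],
            sample_interval_ms=d.get("sample_interval_ms", 1.0),
            test_voltages=d.get("test_voltages"),
            test_index=d.get("test_index"),
            tail_index=d.get("tail_index"),
            chained=d.get("chained", False),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "VoltageProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _sweep_family(
    name: str,
    holding: float,
    pre: tuple[float, float] | None,
    v_start: float,
    v_stop: float,
    v_step: float,
    test_ms: float,
    tail_mv: float,
    tail_ms: float,
    dt: float,
    extra_after_test: tuple[float, float] | None = None,
) -> VoltageProtocol:
    tests = np.arange(v_start, v_stop + 0.5 * v_step, v_step)
    sweeps = []
    for v in tests:
        segs = []
        if pre is not None:
            segs.append(VoltageSegment(pre[0], pre[1], "pre"))
        segs.append(VoltageSegment(float(v), test_ms, "test"))
        if extra_after_test is not None:
            segs.append(VoltageSegment(extra_after_test[0], extra_after_test[1], "interpulse"))
        segs.append(VoltageSegment(tail_mv, tail_ms, "tail"))
        sweeps.append(segs)
    test_index = 1 if pre is not None else 0
    tail_index = len(sweeps[0]) - 1
    return VoltageProtocol(
        name=name,
        holding_mv=holding,
        sweeps=sweeps,
        sample_interval_ms=dt,
        test_voltages=tests,
        test_index=test_index,
        tail_index=tail_index,
    )


def activation_family(
    v_start: float,
    v_stop: float,
    v_step: float,
    test_ms: float = 5000.0,
    tail_mv: float = -40.0,
    tail_ms: float = 2000.0,
    pre: tuple[float, float] | None = (-160.0, 5000.0),
    holding_mv: float = -80.0,
    sample_interval_ms: float = 1.0,
    name: str = "activation_family",
) -> VoltageProtocol:
    """Custom activation sweep family (pre-pulse, test range, tail).

    Useful when a strongly shifted variant needs a wider test-voltage window
    than the standard protocols cover."""
    return _sweep_family(
        name, holding_mv, pre, v_start, v_stop, v_step, test_ms, tail_mv, tail_ms,
        sample_interval_ms,
    )


def standard_protocol(name: str, sample_interval_ms: float = 1.0) -> VoltageProtocol:
    """Build one of the standard protocols.

    * ``activation_tevc`` — hold -80 mV; tests -110..+60 mV, 10 mV steps,
      3 s; tail -20 mV, 5 s (long enough for deactivation kinetics).
    * ``vcf_kv71`` — hold -80; pre-pulse -120 mV 2 s; tests -140..+80 mV,
      20 mV steps, 3 s; tail -80 mV 2 s.
    * ``vcf_iks`` — hold -80; pre-pulse -160 mV 5 s; tests -160..+80 mV,
      20 mV steps, 5 s; tail -40 mV 2 s.
    * ``train_1hz`` — 20 chained sweeps: 300 ms at +40 mV, 700 ms at the
      -80 mV holding voltage (1 s period).
    * ``triple_pulse`` — activation family with a brief -140 mV / 20 ms
      hyperpolarizing interpulse between test and tail, used to relieve
      inactivation before the tail measurement.
    """
    dt = sample_interval_ms
    if name == "activation_tevc":
        return _sweep_family("activation_tevc", -80, None, -110, 60, 10, 3000, -20, 5000, dt)
    if name == "vcf_kv71":
        return _sweep_family("vcf_kv71", -80, (-120, 2000), -140, 80, 20, 3000, -80, 2000, dt)
    if name == "vcf_iks":
        return _sweep_family("vcf_iks", -80, (-160, 5000), -160, 80, 20, 5000, -40, 2000, dt)
    if name == "train_1hz":
        sweeps = [
            [VoltageSegment(40, 300, "test"), VoltageSegment(-80, 700, "tail")] for _ in range(20)
        ]
        return VoltageProtocol(
            name="train_1hz",
            holding_mv=-80,
            sweeps=sweeps,
            sample_interval_ms=dt,
            test_voltages=np.full(20, 40.0),
            test_index=0,
            tail_index=1,
            chained=True,
        )
    if name == "triple_pulse":
        return _sweep_family(
            "triple_pulse", -80, None, -80, 40, 20, 3000, -20, 5000, dt,
            extra_after_test=(-140, 20),
        )
    raise ValueError(f"unknown protocol {name!r}")
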