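"""Pacing-trace containers and early-afterdepolarization (EAD) detection.

An EAD is a secondary depolarization during the repolarization phase of
the action potential.  Detection uses a slope criterion on a uniformly
sampled voltage trace: an EAD is present when the forward finite-difference
slope exceeds 0.1 mV/ms at any sample whose offset from the cycle's
stimulus lies within [50, 1000] ms, in either of the last two recorded
cycles.  Only positive (depolarizing) slopes count; repolarization itself
has a large negative slope.

Cell models are pluggable: anything exposing
``simulate(block, protocol, seed) -> VoltageTrace`` and honouring the
pore-block conductance scaling ``I_drug = (1 - beta) * I`` satisfies the
contract.  The package ships a deterministic synthetic EAD model (see
:mod:`cardiorisk.fixtures`); externally obtained biophysical models (e.g.
an O'Hara-Rudy implementation) can be registered through the same
interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = [
    "CHANNELS",
    "VoltageTrace",
    "PacingProtocol",
    "BlockVector",
    "CellModel",
    "EADSimulationError",
    "detect_ead",
    "run_ead_sim",
    "write_trace",
    "read_trace",
]

#: The seven channels screened in the sensitivity analysis, fixed order.
CHANNELS = ("I_CaL", "I_K1", "I_Kr", "I_Ks", "I_NaL", "I_NaP", "I_to")

#: Upper bound of fractional block per channel in the screening design.
MAX_BLOCK = 0.95


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled transmembrane potential for a pacing run.

    ``values`` are mV on a grid of step ``dt`` ms starting at t=0;
    ``cycle_starts`` are the stimulus onset times in ms.
    """

    dt: float
    values: np.ndarray
    cycle_starts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "cycle_starts", np.asarray(self.cycle_starts, dtype=float))
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voltage values must be finite")
        if self.cycle_starts.size == 0:
            raise ValueError("at least one cycle start required")
        if np.any(np.diff(self.cycle_starts) <= 0):
            raise ValueError("cycle_starts must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_starts.size)


@dataclass(frozen=True)
class PacingProtocol:
    """Steady-state pacing: 600 cycles at 1 Hz, last two cycles recorded."""

    n_cycles: int = 600
    frequency: float = 1.0
    record_last: int = 2

    def __post_init__(self) -> None:
        if self.record_last < 2:
            raise ValueError("record_last must be >= 2 for EAD evaluation")
        if self.n_cycles < self.record_last:
            raise ValueError("n_cycles must be >= record_last")
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")

    @property
    def cycle_length_ms(self) -> float:
        return 1000.0 / self.frequency


@dataclass(frozen=True)
class BlockVector:
    """Fractional block of the seven screened channels, each in [0, 0.95]."""

    cal: float = 0.0
    k1: float = 0.0
    kr: float = 0.0
    ks: float = 0.0
    nal: float = 0.0
    nap: float = 0.0
    to: float = 0.0

    def __post_init__(self) -> None:
        for name, v in zip(CHANNELS, self.as_array()):
            if not (0.0 <= v <= MAX_BLOCK):
                raise ValueError(f"{name} block {v} outside [0, {MAX_BLOCK}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.cal, self.k1, self.kr, self.ks, self.nal, self.nap, self.to])

    @classmethod
    def from_array(cls, arr) -> "BlockVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(CHANNELS),):
            raise ValueError(f"expected {len(CHANNELS)} block fractions, got shape {arr.shape}")
        return cls(*arr)


@runtime_checkable
class CellModel(Protocol):
    """Contract for pluggable paced cell models.

    Implementations must be deterministic given (block, protocol, seed),
    return the last ``protocol.record_last`` cycles at a stated dt, and
    scale each screened current's conductance by (1 - beta).
    """

    def simulate(self, block: BlockVector, protocol: PacingProtocol, seed: int | None = None) -> VoltageTrace:
        ...


class EADSimulationError(RuntimeError):
    """Cell-model failure, carrying the offending block vector."""

    def __init__(self, block: BlockVector, cause: Exception):
        super().__init__(f"cell model failed at block {block}: {cause}")
        self.block = block
        self.cause = cause


def detect_ead(
    trace: VoltageTrace,
    window_start: float = 50.0,
    window_end: float = 1000.0,
    slope_threshold: float = 0.1,
    n_last_cycles: int = 2,
) -> bool:
    """Decide EAD presence by the positive-slope criterion.

    Returns True iff, in any of the last ``n_last_cycles`` cycles, the
    forward finite-difference slope (V[k+1]-V[k])/dt exceeds
    ``slope_threshold`` (mV/ms) at some sample whose time offset from
    that cycle's stimulus lies in [window_start, window_end].  The window
    is clipped at the next stimulus (an EAD-prolonged cycle does not leak
    into its successor).
    """
    if trace.n_cycles < n_last_cycles:
        raise ValueError(
            f"trace has {trace.n_cycles} cycles, need >= {n_last_cycles}"
        )
    v = trace.values
    dt = trace.dt
    slopes = np.diff(v) / dt  # slope at sample k uses (k, k+1)
    t = trace.times[:-1]
    starts = trace.cycle_starts
    for ci in range(trace.n_cycles - n_last_cycles, trace.n_cycles):
        start = starts[ci]
        in_win = (t >= start + window_start) & (t <= start + window_end)
        if ci + 1 < trace.n_cycles:
            # clip at the next stimulus so the following upstroke never counts
            in_win &= t < starts[ci + 1]
        if np.any(slopes[in_win] > slope_threshold):
            return True
    return False


def run_ead_sim(
    model: CellModel,
    block: BlockVector,
    protocol: PacingProtocol | None = None,
    seed: int | None = None,
    **detect_kwargs,
) -> bool:
    """Pace ``model`` under ``block`` and test the recorded trace for EADs."""
    protocol = protocol or PacingProtocol()
    try:
        trace = model.simulate(block, protocol, seed=seed)
    except Exception as exc:  # surface with the offending block attached
        raise EADSimulationError(block, exc) from exc
    return detect_ead(trace, n_last_cycles=min(protocol.record_last, trace.n_cycles), **detect_kwargs)


def write_trace(trace: VoltageTrace, path) -> None:
    """Write a trace as two-column CSV (`t_ms,v_mV`) plus a JSON sidecar."""
    path = Path(path)
    t = trace.times
    with open(path, "w") as fh:
        fh.write("t_ms,v_mV\n")
        for ti, vi in zip(t, trace.values):
            fh.write(f"{ti:.6g},{vi:.9g}\n")
    sidecar = {"dt": trace.dt, "cycle_starts": trace.cycle_starts.tolist()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_trace(path) -> VoltageTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return VoltageTrace(dt=float(meta["dt"]), values=data[:, 1], cycle_starts=np.array(meta["cycle_starts"]))
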