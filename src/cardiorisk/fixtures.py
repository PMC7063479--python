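"""Synthetic fixtures: EAD-capable cell model, boundary oracles, drug table.

These generators stand in for the expensive parts of the pipeline — a
biophysical ventricular myocyte model and a whole-heart arrhythmia
oracle — with deterministic, analytically known behaviour, so that every
downstream component (EAD detection, sensitivity analysis, boundary
learning, stratification) can be tested against an exact ground truth.

The synthetic cell model is explicitly NOT biophysical.  Its contract is
a sign structure consistent with the known physiology (I_Kr block
promotes EADs, I_CaL block prevents them) and a sharp, closed-form EAD
region: a linear score over the seven channel blocks,

    s(block) = 4*b_Kr - 4*b_CaL + b_K1 + b_Ks + 0.5*b_NaL,

triggers an EAD bump in the trace iff s > 2.  The bump's rising slope is
0.2*sigmoid(s - 2) mV/ms, which crosses the 0.1 mV/ms detection
threshold exactly at s = 2, so the detected region equals {s > 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np

from .ead import CHANNELS, BlockVector, PacingProtocol, VoltageTrace

__all__ = [
    "SyntheticEADModel",
    "make_trace",
    "make_oracle",
    "write_drug_table",
]

#: Ground-truth channel weights of the synthetic score, in CHANNELS order.
DEFAULT_WEIGHTS = {
    "I_CaL": -4.0,
    "I_K1": 1.0,
    "I_Kr": 4.0,
    "I_Ks": 1.0,
    "I_NaL": 0.5,
    "I_NaP": 0.0,
    "I_to": 0.0,
}


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SyntheticEADModel:
    """Deterministic stylized cell model with a closed-form EAD region.

    Each paced cycle is a stylized action potential (rest -85 mV, 2 ms
    upstroke to +30 mV, smooth repolarization complete by 350 ms).  When
    the linear block score exceeds ``s0``, a triangular bump with rising
    slope ``bump_gain * sigmoid(score - s0)`` mV/ms is injected at
    ``bump_time`` ms post-stimulus — inside the [50, 1000] ms detection
    window and on the flat diastolic baseline, so the measured
    finite-difference slope equals the nominal bump slope exactly.
    """

    weights: tuple[float, ...] = tuple(DEFAULT_WEIGHTS[c] for c in CHANNELS)
    s0: float = 2.0
    bump_gain: float = 0.2
    bump_time: float = 400.0
    dt: float = 1.0

    def score(self, block: BlockVector) -> float:
        return float(np.dot(self.weights, block.as_array()))

    def has_ead(self, block: BlockVector) -> bool:
        """Analytic ground truth: the detected EAD region is {score > s0}."""
        return self.score(block) > self.s0

    def simulate(
        self, block: BlockVector, protocol: PacingProtocol | None = None, seed: int | None = None
    ) -> VoltageTrace:
        return make_trace(self, block, protocol, seed)


def _ap_cycle(n: int, dt: float) -> np.ndarray:
    """Stylized action potential over one cycle of n samples."""
    t = np.arange(n) * dt
    v = np.full(n, -85.0)
    up = t < 2.0
    v[up] = -85.0 + 115.0 * t[up] / 2.0
    repol = (t >= 2.0) & (t < 350.0)
    # smooth monotone repolarization from +30 back to rest
    v[repol] = -85.0 + 115.0 * 0.5 * (1.0 + np.cos(np.pi * (t[repol] - 2.0) / 348.0))
    return v


def _bump(n: int, dt: float, center: float, slope: float) -> np.ndarray:
    """Triangular depolarizing bump: linear rise at `slope` over 40 ms from
    center-20, then linear fall back to baseline over 80 ms."""
    t = np.arange(n) * dt
    rise_t0, rise_t1 = center - 20.0, center + 20.0
    fall_t1 = rise_t1 + 80.0
    amp = slope * (rise_t1 - rise_t0)
    b = np.zeros(n)
    rising = (t >= rise_t0) & (t < rise_t1)
    b[rising] = slope * (t[rising] - rise_t0)
    falling = (t >= rise_t1) & (t < fall_t1)
    b[falling] = amp * (fall_t1 - t[falling]) / (fall_t1 - rise_t1)
    return b


def make_trace(
    model: SyntheticEADModel,
    block: BlockVector,
    protocol: PacingProtocol | None = None,
    seed: int | None = None,
) -> VoltageTrace:
    """Generate the recorded cycles of a pacing run of the synthetic model.

    The model is stationary by construction, so only the last
    ``protocol.record_last`` cycles are materialized; ``seed`` is part of
    the cell-model contract but unused (the fixture is noise-free).
    """
    protocol = protocol or PacingProtocol()
    dt = model.dt
    cycle_len = protocol.cycle_length_ms
    n_per = int(round(cycle_len / dt))
    cycle = _ap_cycle(n_per, dt)
    s = model.score(block)
    if s > model.s0:
        slope = model.bump_gain * _sigmoid(s - model.s0)
        cycle = cycle + _bump(n_per, dt, model.bump_time, slope)
    values = np.tile(cycle, protocol.record_last)
    cycle_starts = np.arange(protocol.record_last) * cycle_len
    return VoltageTrace(dt=dt, values=values, cycle_starts=cycle_starts)


def make_oracle(name: str, **params) -> Callable:
    """Named analytic arrhythmic/safe region over the unit block square.

    Oracles map a point (cal_block, kr_block) to 1 (arrhythmic) or 0
    (safe):

    - ``linear``: arrhythmic iff kr_block > c (default c=0.7).
    - ``circular``: arrhythmic iff within `radius` of `center`
      (defaults: center (0, 1), radius 0.5).
    - ``surrogate-paper``: the anchor-calibrated piecewise-linear
      boundary with its I_CaL safe wall (see
      :func:`cardiorisk.boundary.surrogate_boundary`).
    """
    if name == "linear":
        c = params.get("c", 0.7)

        def oracle(point) -> int:
            return int(point[1] > c)

        return oracle
    if name == "circular":
        center = np.asarray(params.get("center", (0.0, 1.0)), dtype=float)
        radius = params.get("radius", 0.5)

        def oracle(point) -> int:
            return int(np.hypot(point[0] - center[0], point[1] - center[1]) < radius)

        return oracle
    if name == "surrogate-paper":
        from .boundary import surrogate_boundary

        boundary = surrogate_boundary()

        def oracle(point) -> int:
            return int(boundary.region(point))

        return oracle
    raise ValueError(f"unknown oracle {name!r}; choose linear, circular, or surrogate-paper")


def write_drug_table(path) -> Path:
    """Write the bundled 23-drug IC50/Cmax table to ``path``, byte-stable."""
    path = Path(path)
    ref = resources.files("cardiorisk.data").joinpath("drug_table.csv")
    path.write_bytes(ref.read_bytes())
    return path
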