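"""Hill pore-block model of drug-channel interaction.

A drug at free concentration ``C`` (nM) blocks an ionic current with
half-maximal blocking concentration ``IC50`` according to the unit-Hill
pore-block relation

    beta = C / (C + IC50),

so the current is scaled by ``(1 - beta)``.  Applied per channel, a drug
and a concentration (expressed as a multiple of its effective free
therapeutic plasma concentration Cmax) map to a point in the
(I_CaL block, I_Kr block) unit square; sweeping the concentration traces
a monotone trajectory in that plane.

A drug with no measurable block of a channel at any tested concentration
carries a missing IC50 for that channel and is assigned block 0 there
(a vertical/horizontal trajectory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DrugRecord",
    "BlockPoint",
    "Trajectory",
    "hill_block",
    "block_pair",
    "trajectory",
    "load_drug_table",
    "bundled_drug_table",
]


def _valid_conc(x: Optional[float]) -> bool:
    return x is None or (math.isfinite(x) and x > 0)


@dataclass(frozen=True)
class DrugRecord:
    """One drug's IC50 pair (nM) and effective free therapeutic Cmax (nM).

    ``ic50_cal`` / ``ic50_kr`` may be ``None`` when the channel shows no
    measurable block.
    """

    name: str
    ic50_cal: Optional[float]
    ic50_kr: Optional[float]
    cmax: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("drug name must be nonempty")
        if not _valid_conc(self.ic50_cal):
            raise ValueError(f"{self.name}: ic50_cal must be positive or missing")
        if not _valid_conc(self.ic50_kr):
            raise ValueError(f"{self.name}: ic50_kr must be positive or missing")
        if not (math.isfinite(self.cmax) and self.cmax > 0):
            raise ValueError(f"{self.name}: cmax must be strictly positive")


@dataclass(frozen=True)
class BlockPoint:
    """Fractional (I_CaL, I_Kr) block, each in [0, 1)."""

    cal_block: float
    kr_block: float

    def __post_init__(self) -> None:
        for v, nm in ((self.cal_block, "cal_block"), (self.kr_block, "kr_block")):
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{nm}={v} outside [0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.cal_block, self.kr_block])


@dataclass(frozen=True)
class Trajectory:
    """Block points of one drug along increasing concentration multiples."""

    name: str
    multiples: np.ndarray
    points: tuple[BlockPoint, ...] = field(repr=False)

    @property
    def cal_block(self) -> np.ndarray:
        return np.array([p.cal_block for p in self.points])

    @property
    def kr_block(self) -> np.ndarray:
        return np.array([p.kr_block for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


def hill_block(concentration: float, ic50: Optional[float], hill: float = 1.0) -> float:
    """Fractional current block at `concentration` for a channel with `ic50`.

    Parameters
    ----------
    concentration : float
        Free drug concentration, nM. Must be >= 0.
    ic50 : float or None
        Half-block concentration, nM. ``None`` (no measurable block)
        gives block 0 at every concentration.
    hill : float
        Hill exponent; 1 for the memoryless pore-block model. The block
        equals 0.5 at C = IC50 for any exponent.

    Returns
    -------
    float
        Block fraction C^h / (C^h + IC50^h) in [0, 1).
    """
    if not (math.isfinite(concentration) and concentration >= 0):
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if ic50 is None or (isinstance(ic50, float) and math.isnan(ic50)):
        return 0.0
    if not (math.isfinite(ic50) and ic50 > 0):
        raise ValueError(f"ic50 must be strictly positive, got {ic50}")
    if hill <= 0:
        raise ValueError(f"hill exponent must be positive, got {hill}")
    if concentration == 0.0:
        return 0.0
    # work with the ratio to avoid overflow for extreme C/IC50
    r = (ic50 / concentration) ** hill
    return 1.0 / (1.0 + r)


def block_pair(drug: DrugRecord, multiple: float, hill: float = 1.0) -> BlockPoint:
    """Map a drug at ``multiple`` x Cmax to its (I_CaL, I_Kr) block point."""
    if multiple < 0:
        raise ValueError(f"multiple must be >= 0, got {multiple}")
    c = multiple * drug.cmax
    return BlockPoint(
        cal_block=hill_block(c, drug.ic50_cal, hill),
        kr_block=hill_block(c, drug.ic50_kr, hill),
    )


def trajectory(drug: DrugRecord, multiples: Sequence[float], hill: float = 1.0) -> Trajectory:
    """Evaluate a drug's block trajectory along a grid of Cmax multiples.

    The grid must be strictly increasing and positive; both block
    coordinates are nondecreasing along the trajectory.
    """
    m = np.asarray(multiples, dtype=float)
    if m.size == 0:
        raise ValueError("multiples grid must be nonempty")
    if np.any(m <= 0):
        raise ValueError("multiples must be strictly positive")
    if np.any(np.diff(m) <= 0):
        raise ValueError("multiples must be strictly increasing")
    pts = tuple(block_pair(drug, mi, hill) for mi in m)
    return Trajectory(name=drug.name, multiples=m, points=pts)


def _records_from_frame(df: pd.DataFrame) -> list[DrugRecord]:
    required = ["name", "ic50_cal_nM", "ic50_kr_nM", "cmax_nM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"drug table missing columns: {missing}")
    names = df["name"].astype(str)
    if names.duplicated().any():
        dupes = sorted(names[names.duplicated()].unique())
        raise ValueError(f"duplicate drug names: {dupes}")
    records = []
    for _, row in df.iterrows():
        records.append(
            DrugRecord(
                name=str(row["name"]),
                ic50_cal=None if pd.isna(row["ic50_cal_nM"]) else float(row["ic50_cal_nM"]),
                ic50_kr=None if pd.isna(row["ic50_kr_nM"]) else float(row["ic50_kr_nM"]),
                cmax=float(row["cmax_nM"]),
            )
        )
    return records


def load_drug_table(path) -> list[DrugRecord]:
    """Read a drug table CSV (`name,ic50_cal_nM,ic50_kr_nM,cmax_nM`).

    Missing IC50s are encoded as empty fields or ``NA``.
    """
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True)
    return _records_from_frame(df)


def bundled_drug_table() -> list[DrugRecord]:
    """The 23-drug IC50/Cmax table shipped with the package."""
    ref = resources.files("cardiorisk.data").joinpath("drug_table.csv")
    with ref.open("r") as fh:
        return load_drug_table(fh)


def drug_by_name(drugs: Sequence[DrugRecord], name: str) -> DrugRecord:
    """Case-insensitive lookup of one drug in a record list."""
    key = name.strip().lower()
    for d in drugs:
        if d.name.lower() == key:
            return d
    raise KeyError(f"drug {name!r} not in table")
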