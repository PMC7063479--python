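"""Critical drug concentrations and high/low risk stratification.

A drug's block-concentration characteristics trace a trajectory through
the (I_CaL block, I_Kr block) plane; the smallest Cmax multiple at which
the trajectory enters the arrhythmic region of a classification boundary
is the drug's critical concentration.  Trajectories that never enter the
region within the scan cap mark a safe drug.  Drugs are stratified as
high risk when their critical multiple is at or below a threshold.

Two boundary flavours are supported: a model boundary wrapping a fitted
GP classifier (region = predicted arrhythmia probability >= 0.5), and an
analytic surrogate calibrated so that seven reference drugs cross it at
their known critical multiples, with two structural features: risk onset
at ~70% I_Kr block for a pure I_Kr blocker and a safe wall beyond 60%
I_CaL block, past which no I_Kr block is arrhythmogenic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .drugs import DrugRecord, BlockPoint, block_pair, bundled_drug_table
from .gp import BoundaryModel, fit as gp_fit

__all__ = [
    "ClassificationBoundary",
    "SurrogateBoundary",
    "GPBoundary",
    "CriticalConcentration",
    "ANCHOR_MULTIPLES",
    "surrogate_boundary",
    "critical_concentration",
    "stratify",
    "loo_validate",
]

#: Printed critical Cmax multiples of the seven calibration drugs.
ANCHOR_MULTIPLES = {
    "thioridazine": 0.1,
    "quinidine": 0.3,
    "terfenadine": 4.4,
    "bepridil": 4.9,
    "chlorpromazine": 154.9,
    "amiodarone": 282.6,
    "propranolol": 474.6,
}

#: I_CaL block beyond which no I_Kr block is arrhythmogenic (safe wall).
CAL_SAFE_WALL = 0.60

#: Default high/low risk threshold on the critical multiple (x Cmax).
RISK_THRESHOLD = 350.0

#: Default scan cap defining "never crosses" (x Cmax).
SCAN_CAP = 1000.0


@runtime_checkable
class ClassificationBoundary(Protocol):
    """Total arrhythmic/safe predicate over the unit block square."""

    def region(self, point) -> bool:
        """True iff ``point`` = (cal_block, kr_block) is arrhythmic."""
        ...


@dataclass(frozen=True)
class SurrogateBoundary:
    """Piecewise-linear threshold curve B(x) with an I_CaL safe wall.

    Arrhythmic iff cal_block < ``x_wall`` and kr_block >= B(cal_block).
    ``xs``/``ys`` are the sorted anchor vertices of B.
    """

    xs: np.ndarray
    ys: np.ndarray
    x_wall: float = CAL_SAFE_WALL

    def threshold(self, x) -> np.ndarray:
        """Critical I_Kr block B(x) at I_CaL block x."""
        return np.interp(np.asarray(x, dtype=float), self.xs, self.ys)

    def region(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        return bool((p[0] < self.x_wall) & (p[1] >= self.threshold(p[0])))

    def region_many(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p[:, 0] < self.x_wall) & (p[:, 1] >= self.threshold(p[:, 0]))


@dataclass(frozen=True)
class GPBoundary:
    """Boundary view of a fitted GP classifier (arrhythmic iff p >= 0.5)."""

    model: BoundaryModel

    def region(self, point) -> bool:
        return bool(self.model.predict_prob(np.atleast_2d(point))[0] >= 0.5)

    def region_many(self, points) -> np.ndarray:
        return self.model.predict_prob(points) >= 0.5


@dataclass(frozen=True)
class CriticalConcentration:
    """Smallest arrhythmic Cmax multiple of one drug (None = never)."""

    name: str
    multiple: Optional[float]
    crossing: Optional[BlockPoint]

    @property
    def never_crosses(self) -> bool:
        return self.multiple is None


def surrogate_boundary(drugs: Sequence[DrugRecord] | None = None) -> SurrogateBoundary:
    """Anchor-calibrated analytic stand-in for the learned boundary.

    Each calibration drug's block point at its known critical multiple
    must lie on the boundary; the curve is the piecewise-linear
    interpolant through those anchors (sorted by I_CaL block), extended
    linearly from the last anchor to (0.60, 1.0) where it meets the
    I_CaL safe wall.
    """
    drugs = list(drugs) if drugs is not None else bundled_drug_table()
    by_name = {d.name.lower(): d for d in drugs}
    missing = sorted(set(ANCHOR_MULTIPLES) - set(by_name))
    if missing:
        raise ValueError(f"drug table lacks calibration drugs: {missing}")
    anchors = []
    for name, mult in ANCHOR_MULTIPLES.items():
        bp = block_pair(by_name[name], mult)
        anchors.append((bp.cal_block, bp.kr_block))
    anchors.sort()
    anchors.append((CAL_SAFE_WALL, 1.0))
    xs, ys = map(np.array, zip(*anchors))
    return SurrogateBoundary(xs=xs, ys=ys)


def _first_crossing(drug: DrugRecord, boundary: ClassificationBoundary, multiples: np.ndarray):
    """Index of the first arrhythmic multiple on a grid, or None."""
    pts = np.array(
        [[block_pair(drug, m).cal_block, block_pair(drug, m).kr_block] for m in multiples]
    )
    if hasattr(boundary, "region_many"):
        flags = np.asarray(boundary.region_many(pts), dtype=bool)
    else:
        flags = np.array([boundary.region(p) for p in pts], dtype=bool)
    idx = np.flatnonzero(flags)
    return int(idx[0]) if idx.size else None


def critical_concentration(
    drug: DrugRecord,
    boundary: ClassificationBoundary,
    scan_lo: float = 0.01,
    scan_hi: float = SCAN_CAP,
    n_scan: int = 601,
    refine_tol: float = 1e-3,
) -> CriticalConcentration:
    """Critical concentration of ``drug`` against ``boundary``.

    A coarse log-spaced scan of [scan_lo, scan_hi] locates the first
    entry into the arrhythmic region; bisection between the last safe
    and first arrhythmic grid point refines it to ``refine_tol``
    relative width.  Returns a never-crossing record when no scanned
    multiple is arrhythmic.
    """
    if scan_lo <= 0 or scan_hi <= scan_lo:
        raise ValueError(f"invalid scan bounds [{scan_lo}, {scan_hi}]")
    if n_scan < 2:
        raise ValueError("scan grid needs at least 2 points")
    grid = np.logspace(np.log10(scan_lo), np.log10(scan_hi), n_scan)
    i = _first_crossing(drug, boundary, grid)
    if i is None:
        return CriticalConcentration(name=drug.name, multiple=None, crossing=None)
    if i == 0:
        m = grid[0]
    else:
        lo, hi = grid[i - 1], grid[i]
        while (hi - lo) / hi > refine_tol:
            mid = np.sqrt(lo * hi)
            bp = block_pair(drug, mid)
            if boundary.region((bp.cal_block, bp.kr_block)):
                hi = mid
            else:
                lo = mid
        m = hi
    return CriticalConcentration(name=drug.name, multiple=float(m), crossing=block_pair(drug, m))


def stratify(
    drugs: Sequence[DrugRecord],
    boundary: ClassificationBoundary,
    threshold: float = RISK_THRESHOLD,
    scan_hi: float = SCAN_CAP,
    **scan_kwargs,
) -> pd.DataFrame:
    """Stratify a drug table into high/low risk by critical multiple.

    High risk iff the critical multiple exists and is <= ``threshold``.
    The report is sorted by critical multiple, never-crossing drugs last.
    """
    rows = []
    for d in drugs:
        cc = critical_concentration(d, boundary, scan_hi=scan_hi, **scan_kwargs)
        rows.append(
            {
                "name": d.name,
                "critical_multiple": cc.multiple if cc.multiple is not None else np.nan,
                "crossing_cal_block": cc.crossing.cal_block if cc.crossing else np.nan,
                "crossing_kr_block": cc.crossing.kr_block if cc.crossing else np.nan,
                "category": (
                    "high" if cc.multiple is not None and cc.multiple <= threshold else "low"
                ),
            }
        )
    df = pd.DataFrame(rows, columns=[
        "name", "critical_multiple", "crossing_cal_block", "crossing_kr_block", "category",
    ])
    return df.sort_values("critical_multiple", na_position="last").reset_index(drop=True)


def loo_validate(
    multiples: Sequence[Optional[float]],
    labels: Sequence[int],
    cap: float = SCAN_CAP,
    length_scale_bounds: tuple[float, float] = (0.05, 2.0),
    seed: int | None = None,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out GP classification of risk labels from critical multiples.

    Each drug is held out in turn; a 1-D GP classifier on log10 critical
    multiples (never-crossing encoded as the scan cap) is trained on the
    remaining drugs and predicts the held-out label.  Returns (fraction
    correct among evaluated folds, per-drug predictions).  Folds whose
    training labels collapse to one class are skipped with a warning.
    """
    multiples = list(multiples)
    labels = np.asarray(labels, dtype=int)
    if len(multiples) != labels.size:
        raise ValueError("features and labels must align")
    logm = np.log10([cap if m is None or not np.isfinite(m) else m for m in multiples])
    # affine map of log10 multiples from [log10(0.01), log10(cap)] onto [0, 1]
    lo, hi = np.log10(0.01), np.log10(cap)
    x = np.clip((logm - lo) / (hi - lo), 0.0, 1.0).reshape(-1, 1)
    preds = []
    for i in range(labels.size):
        mask = np.ones(labels.size, dtype=bool)
        mask[i] = False
        ytr = labels[mask]
        if np.unique(ytr).size < 2:
            warnings.warn(f"fold {i}: single-class training labels, skipped")
            preds.append(np.nan)
            continue
        model = gp_fit((x[mask], ytr), length_scale_bounds=length_scale_bounds, seed=seed)
        p = model.predict_prob(x[i : i + 1])
        preds.append(int(p[0] >= 0.5))
    preds = np.asarray(preds, dtype=float)
    ok = ~np.isnan(preds)
    accuracy = float(np.mean(preds[ok] == labels[ok])) if ok.any() else float("nan")
    report = pd.DataFrame(
        {
            "log10_multiple": logm,
            "label": labels,
            "predicted": preds,
            "correct": np.where(ok, preds == labels, np.nan),
        }
    )
    return accuracy, report
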