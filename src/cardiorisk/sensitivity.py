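"""Latin hypercube screening of channel-block space and marginal effects.

The screening asks which of seven ionic currents most strongly modulate
early afterdepolarizations: 500 pacing simulations are run at channel
blocks drawn from a Latin hypercube over [0, 0.95]^7, each labeled by
EAD presence, a logistic regression is fitted to the labels, and the
average marginal effect of each channel — the derivative of the fitted
EAD probability with respect to that channel's block, averaged over the
design — is reported, normalized by the largest magnitude.  A positive
effect means blocking the channel promotes EADs; negative means it
protects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import qmc
from sklearn.linear_model import LogisticRegression

from .ead import CHANNELS, MAX_BLOCK, BlockVector, CellModel, PacingProtocol, run_ead_sim

__all__ = [
    "DesignMatrix",
    "LogisticFit",
    "SensitivityResult",
    "lhs_design",
    "run_screen",
    "fit_logistic",
    "marginal_effects",
    "sensitivity_analysis",
]


@dataclass(frozen=True)
class DesignMatrix:
    """LHS block vectors (rows) with their binary EAD labels."""

    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X rows and labels must align")


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic coefficients p = sigmoid(b + X @ w)."""

    intercept: float
    weights: np.ndarray
    channels: tuple[str, ...] = CHANNELS


@dataclass(frozen=True)
class SensitivityResult:
    """Per-channel (normalized) average marginal effects."""

    effects: np.ndarray
    channels: tuple[str, ...] = CHANNELS
    normalized: bool = True

    def as_dict(self) -> dict[str, float]:
        return {c: float(e) for c, e in zip(self.channels, self.effects)}


def lhs_design(n: int, d: int, lower, upper, seed: int | None = None) -> np.ndarray:
    """Latin hypercube sample of ``n`` points in ``d`` dimensions.

    Each dimension is stratified into ``n`` equal-width strata of
    [lower, upper] with exactly one point per stratum; reproducible
    under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lower = np.broadcast_to(np.asarray(lower, dtype=float), (d,))
    upper = np.broadcast_to(np.asarray(upper, dtype=float), (d,))
    if np.any(lower >= upper):
        raise ValueError("lower must be < upper elementwise")
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, lower, upper)


def run_screen(
    model: CellModel,
    n: int = 500,
    seed: int | None = None,
    protocol: PacingProtocol | None = None,
    max_block: float = MAX_BLOCK,
) -> DesignMatrix:
    """Run the LHS screening: n paced simulations over [0, max_block]^7."""
    X = lhs_design(n, len(CHANNELS), 0.0, max_block, seed=seed)
    protocol = protocol or PacingProtocol()
    labels = np.array(
        [run_ead_sim(model, BlockVector.from_array(row), protocol, seed=seed) for row in X],
        dtype=int,
    )
    return DesignMatrix(X=X, labels=labels)


def fit_logistic(design: DesignMatrix, ridge: float = 1e-6, max_iter: int = 5000) -> LogisticFit:
    """Fit p = sigmoid(b + w . block) by (ridge-stabilized) maximum likelihood.

    The tiny ridge penalty keeps the fit finite when the design is
    perfectly separable, which it is for a deterministic EAD rule.
    """
    y = np.asarray(design.labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"degenerate fit: labels contain a single class ({classes.tolist()}); "
            "both EAD outcomes are required"
        )
    clf = LogisticRegression(C=1.0 / ridge, max_iter=max_iter, tol=1e-8)
    clf.fit(design.X, y)
    return LogisticFit(intercept=float(clf.intercept_[0]), weights=clf.coef_[0].copy())


def marginal_effects(
    fit: LogisticFit, design: DesignMatrix, normalize: bool = True
) -> SensitivityResult:
    """Average marginal effect of each channel on EAD probability.

    For the logistic model the derivative dp/dbeta_i = p(1-p) w_i; the
    average marginal effect is its mean over the design rows.  With
    ``normalize`` the effects are divided by the maximal value — the
    largest (positive) effect, so the strongest EAD-promoting channel
    reads exactly 1 and signs are preserved.  If no effect is positive,
    the maximum absolute effect is used instead.
    """
    if design.X.shape[0] == 0:
        raise ValueError("empty design")
    eta = fit.intercept + design.X @ fit.weights
    p = expit(eta)
    effects = np.mean(p * (1.0 - p)) * fit.weights
    if normalize:
        scale = np.max(effects)
        if scale <= 0:
            scale = np.max(np.abs(effects))
        if scale > 0:
            effects = effects / scale
    return SensitivityResult(effects=effects, channels=fit.channels, normalized=normalize)


def sensitivity_analysis(
    model: CellModel,
    n: int = 500,
    seed: int | None = None,
    protocol: PacingProtocol | None = None,
) -> tuple[DesignMatrix, LogisticFit, SensitivityResult]:
    """Full screening pipeline: LHS design -> EAD labels -> logistic fit ->
    normalized average marginal effects."""
    design = run_screen(model, n=n, seed=seed, protocol=protocol)
    fit = fit_logistic(design)
    return design, fit, marginal_effects(fit, design)
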