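"""Gaussian-process classification of the arrhythmic/safe boundary.

The arrhythmia oracle (in the full pipeline, a whole-heart simulation;
here, any user-supplied predicate over the unit block square) is far too
expensive to query on a grid.  Instead a Bernoulli-likelihood Gaussian
process classifier (squared-exponential kernel, Laplace approximation,
logistic link) is fitted to a handful of labeled points, and new queries
are placed at the point of maximal predictive entropy — the location
where the classifier is least certain, which concentrates samples along
the classification boundary.  Ten initial Latin-hypercube queries plus
thirty adaptive queries suffice to recover the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage import measure
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .sensitivity import lhs_design

__all__ = [
    "LabeledSample",
    "BoundaryModel",
    "fit",
    "predict_prob",
    "entropy",
    "next_sample",
    "active_learning_loop",
    "extract_boundary",
    "unit_grid",
]

#: Length-scale bounds preventing degenerate (needle or flat) contours.
LENGTH_SCALE_BOUNDS = (0.05, 2.0)


@dataclass(frozen=True)
class LabeledSample:
    """A block-space point with its binary arrhythmic (1) / safe (0) label."""

    point: np.ndarray
    label: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class BoundaryModel:
    """Fitted GP classifier over block space.

    When both classes are present, ``_gpc`` holds a Laplace-approximate
    GP classifier with marginal-likelihood-optimized hyperparameters.
    With a single observed class no latent GP is identifiable; the
    predictive probability then shades from near-certainty at the data
    toward 0.5 far away (in kernel distance), which both keeps the
    prediction on the observed side of 0.5 everywhere and makes the
    entropy acquisition explore the point farthest from the data.
    """

    X: np.ndarray
    y: np.ndarray
    _gpc: GaussianProcessClassifier | None = field(default=None, repr=False)
    single_class: int | None = None
    fallback_length_scale: float = 0.3
    ndim: int = 2

    def predict_prob(self, points) -> np.ndarray:
        """Arrhythmia probability at each point; strictly inside (0, 1)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.ndim:
            raise ValueError(f"expected {self.ndim}-d points, got shape {pts.shape}")
        if np.any(pts < 0) or np.any(pts > 1):
            raise ValueError("points must lie in the unit hypercube")
        if self._gpc is not None:
            p = self._gpc.predict_proba(pts)[:, list(self._gpc.classes_).index(1)]
        else:
            # kernel proximity to the nearest training point
            d2 = ((pts[:, None, :] - self.X[None, :, :]) ** 2).sum(axis=2)
            k = np.exp(-0.5 * d2 / self.fallback_length_scale**2).max(axis=1)
            sign = 1.0 if self.single_class == 1 else -1.0
            p = 0.5 + sign * 0.49 * k
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    @property
    def kernel_(self):
        return self._gpc.kernel_ if self._gpc is not None else None


def fit(
    samples: Sequence[LabeledSample] | tuple[np.ndarray, np.ndarray],
    length_scale_bounds: tuple[float, float] = LENGTH_SCALE_BOUNDS,
    seed: int | None = None,
    optimize: bool = True,
) -> BoundaryModel:
    """Fit the Bernoulli-GP boundary classifier to labeled samples.

    Hyperparameters (signal variance and a shared length scale, bounded
    to avoid degenerate contours) are chosen by marginal-likelihood
    maximization unless ``optimize`` is False.
    """
    if isinstance(samples, tuple):
        X, y = samples
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
    else:
        X = np.vstack([s.point for s in samples])
        y = np.array([s.label for s in samples], dtype=int)
    if X.shape[0] < 1:
        raise ValueError("at least one sample required")
    if length_scale_bounds[0] <= 0 or length_scale_bounds[0] >= length_scale_bounds[1]:
        raise ValueError(f"degenerate kernel bounds {length_scale_bounds}")
    ndim = X.shape[1]
    classes = np.unique(y)
    if classes.size == 1:
        return BoundaryModel(X=X, y=y, single_class=int(classes[0]), ndim=ndim)
    # amplitude bounded to [1, 1e3]: below unit logit scale ML-II collapses
    # into a flat p=0.5 solution; far above ~30 the Laplace approximation
    # degrades badly on separable labels
    kernel = ConstantKernel(1.0, (1.0, 1e3)) * RBF(
        length_scale=0.3, length_scale_bounds=length_scale_bounds
    )
    # marginal-likelihood optimization is ill-posed for a handful of
    # points (it collapses to spiky length scales); keep the default
    # kernel there and optimize once the data can support it
    optimize = optimize and X.shape[0] >= 8
    gpc = GaussianProcessClassifier(
        kernel=kernel,
        optimizer="fmin_l_bfgs_b" if optimize else None,
        # restarts escape the local ML-II optimum where the amplitude
        # collapses and the predictive probability flattens to 0.5
        n_restarts_optimizer=2 if optimize else 0,
        random_state=seed,
    )
    gpc.fit(X, y)
    return BoundaryModel(X=X, y=y, _gpc=gpc, ndim=ndim)


def predict_prob(model: BoundaryModel, point) -> float:
    """Arrhythmia probability at a single block point."""
    return float(model.predict_prob(np.atleast_2d(point))[0])


def entropy(p) -> np.ndarray | float:
    """Bernoulli predictive entropy in nats, with 0*ln(0) = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) - np.where(p < 1, (1 - p) * np.log(1 - p), 0.0)
    return h if h.ndim else float(h)


def unit_grid(resolution: int = 101, ndim: int = 2) -> np.ndarray:
    """Uniform candidate grid over the unit square (row-major points)."""
    axes = [np.linspace(0.0, 1.0, resolution)] * ndim
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def next_sample(model: BoundaryModel, candidates, seed: int | None = None) -> np.ndarray:
    """Candidate of maximal predictive entropy; ties broken by lowest
    index after a seeded shuffle."""
    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    if cand.shape[0] == 0:
        raise ValueError("candidate set must be nonempty")
    h = entropy(model.predict_prob(cand))
    perm = np.random.default_rng(seed).permutation(cand.shape[0])
    best = perm[int(np.argmax(h[perm]))]
    return cand[best]


@dataclass
class ActiveLearningResult:
    """Samples, final model, and per-query audit log of a learning run."""

    X: np.ndarray
    y: np.ndarray
    model: BoundaryModel
    audit: list[dict]
    error: str | None = None


def active_learning_loop(
    oracle: Callable,
    n_init: int = 10,
    n_adapt: int = 30,
    seed: int | None = None,
    candidates: np.ndarray | None = None,
    ndim: int = 2,
) -> ActiveLearningResult:
    """Learn the arrhythmic/safe boundary from an expensive binary oracle.

    ``n_init`` Latin-hypercube points are queried up front, then
    ``n_adapt`` rounds of fit -> maximal-entropy point -> query.  The
    oracle maps a point in the unit square to label 1 (arrhythmic) or
    0 (safe).  Oracle failure halts the loop and returns the partial
    samples with an error flag set.
    """
    if candidates is None:
        candidates = unit_grid(101, ndim)
    rng_seed = None if seed is None else int(seed)
    X = lhs_design(n_init, ndim, 0.0, 1.0, seed=rng_seed)
    ys: list[int] = []
    audit: list[dict] = []
    error = None

    def query(pt, phase, i):
        label = int(oracle(np.asarray(pt, dtype=float)))
        audit.append({"phase": phase, "iteration": i, "point": list(map(float, pt)), "label": label})
        return label

    try:
        for i, pt in enumerate(X):
            ys.append(query(pt, "init", i))
    except Exception as exc:
        model = fit((X[: len(ys)], np.array(ys, dtype=int)), seed=rng_seed) if ys else None
        return ActiveLearningResult(X[: len(ys)], np.array(ys, dtype=int), model, audit, error=str(exc))

    model = fit((X, np.array(ys, dtype=int)), seed=rng_seed)
    for i in range(n_adapt):
        pt = next_sample(model, candidates, seed=None if rng_seed is None else rng_seed + i)
        try:
            label = query(pt, "adapt", i)
        except Exception as exc:
            error = str(exc)
            break
        X = np.vstack([X, pt])
        ys.append(label)
        model = fit((X, np.array(ys, dtype=int)), seed=rng_seed)
    return ActiveLearningResult(X, np.array(ys, dtype=int), model, audit, error=error)


def extract_boundary(model: BoundaryModel, resolution: int = 101) -> list[np.ndarray]:
    """0.5-probability contour polylines on a resolution^2 grid.

    Uses marching-squares interpolation; returns an empty list when the
    prediction never crosses 0.5 (single-class prediction).
    """
    grid = unit_grid(resolution, model.ndim)
    p = model.predict_prob(grid).reshape(resolution, resolution)
    contours = measure.find_contours(p, 0.5)
    # grid index -> unit-square coordinates (axis 0 = first coordinate)
    return [c / (resolution - 1) for c in contours]
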