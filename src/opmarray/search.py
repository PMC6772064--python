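"""Metropolis search over rigid-array pose and Bayesian model averaging.

Given field data, a source space and a head model, the position (and
optionally orientation) of a rigid sensor array is treated as an unknown
model parameter h.  Free energy F(h) approximates the log evidence of the
geometry, so Metropolis-Hastings with acceptance min(1, exp(F_prop - F_cur))
draws samples from the posterior over poses under a flat prior box.  Chains
use adaptive Gaussian proposals (tuned toward ~30% acceptance during
burn-in, then frozen, preserving detailed balance for the retained samples).

Bayesian model averaging then combines the source estimates of the sampled
geometries, weighting each by its evidence, which yields both a robust
current estimate and posterior confidence ellipsoids on the array location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .evidence import score_geometry
from .forward import HeadModel, SourceSpace
from .geometry import RigidTransform, SensorArray, apply_pose
from .inversion import DataMatrix, SourceEstimate

__all__ = [
    "PoseSample",
    "Ellipsoid",
    "PosteriorSummary",
    "metropolis",
    "metropolis_pose_search",
    "bma_sources",
    "confidence_ellipsoid",
    "central_sensor_index",
]


@dataclass(frozen=True)
class PoseSample:
    """One evaluated pose in a Metropolis chain."""

    pose: RigidTransform
    F: float
    iteration: int
    chain_id: int
    accepted: bool


@dataclass(frozen=True)
class Ellipsoid:
    """Confidence ellipsoid of a 3D posterior point cloud."""

    centre: np.ndarray
    cov: np.ndarray
    level: float
    degenerate: bool = False

    @property
    def semi_axes(self) -> np.ndarray:
        if self.level <= 0:
            return np.zeros(3)
        eig = np.linalg.eigvalsh(self.cov)
        eig = np.clip(eig, 0.0, None)
        return np.sqrt(chi2.ppf(self.level, df=3) * eig)

    @property
    def volume(self) -> float:
        """Volume in cubic metres."""
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))

    @property
    def volume_cm3(self) -> float:
        return self.volume * 1e6


@dataclass(frozen=True)
class PosteriorSummary:
    """Weighted posterior over poses from a Metropolis run."""

    mean_pose: RigidTransform
    ellipsoid: Ellipsoid
    samples: tuple[PoseSample, ...]
    weights: np.ndarray
    collapsed: bool = False

    @property
    def volume_cm3(self) -> float:
        return self.ellipsoid.volume_cm3


def evidence_weights(F) -> np.ndarray:
    """Normalised posterior model weights w_k ∝ exp(F_k − max F)."""
    F = np.asarray(F, float)
    w = np.exp(F - F.max())
    return w / w.sum()


def _metropolis_accept(delta_F: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(delta_F))."""
    if delta_F >= 0:
        return True
    return rng.random() < np.exp(delta_F)


def metropolis(objective, bounds: np.ndarray, n_chains: int, n_iter: int,
               rng: np.random.Generator, target_acceptance: float = 0.3,
               adapt_fraction: float = 0.4,
               initial=None) -> list[tuple[np.ndarray, float, int, int, bool]]:
    """Generic adaptive Metropolis sampler over a box-bounded parameter space.

    ``objective`` maps a parameter vector to a free energy (log evidence);
    failures may return -inf.  Proposals are Gaussian with per-parameter
    step sizes, initialised at a tenth of the box width and adapted toward
    ``target_acceptance`` during the first ``adapt_fraction`` of iterations,
    then frozen.  Out-of-bounds proposals are rejected.

    Returns a list of (params, F, iteration, chain_id, accepted) for every
    evaluated state, including the initial draw of each chain.
    """
    bounds = np.asarray(bounds, float)
    width = bounds[:, 1] - bounds[:, 0]
    burn_end = int(adapt_fraction * n_iter)
    out = []
    for chain in range(n_chains):
        if initial is not None:
            x = np.asarray(initial, float).copy()
        else:
            x = rng.uniform(bounds[:, 0], bounds[:, 1])
        f = objective(x)
        if not np.isfinite(f):
            warnings.warn("objective failed at the initial pose", stacklevel=2)
            f = -np.inf
        out.append((x.copy(), f, 0, chain, True))
        step = width / 10.0
        for it in range(1, n_iter + 1):
            prop = x + step * rng.normal(size=x.size)
            in_bounds = np.all((prop >= bounds[:, 0]) & (prop <= bounds[:, 1]))
            if in_bounds:
                f_prop = objective(prop)
                if not np.isfinite(f_prop):
                    warnings.warn("objective failed at a proposal; rejected",
                                  stacklevel=2)
                    f_prop = -np.inf
                accepted = _metropolis_accept(f_prop - f, rng)
            else:
                f_prop, accepted = -np.inf, False
            if accepted:
                x, f = prop, f_prop
            out.append((prop.copy(), f_prop, it, chain, accepted))
            if it <= burn_end:
                step = step * np.exp(0.05 * ((1.0 if accepted else 0.0)
                                             - target_acceptance))
    return out


def metropolis_pose_search(data: DataMatrix, array: SensorArray,
                           sources: SourceSpace, head: HeadModel,
                           prior_half_width_m: float = 0.020,
                           n_chains: int = 4, n_iter: int = 600,
                           rng_seed: int = 0, mode: str = "translation",
                           axis=None, pivot=None,
                           **inversion_kwargs) -> list[PoseSample]:
    """Posterior sampling of the rigid-array pose given the field data.

    The prior is flat over a box of half-width ``prior_half_width_m`` on each
    translation axis (default 20 mm, a 4 x 4 x 4 cm^3 volume), centred on the
    nominal array position.  ``mode`` selects the searched parameters:

    * ``"translation"`` (default): the 3 translation parameters of the array.
    * ``"axis"``: a single translation along ``axis`` (1D search).
    * ``"rigid"``: all 6 pose parameters; rotations get a +-0.35 rad prior.

    Each proposal is scored by the full lead-field -> EBB -> free-energy
    pipeline; forward-model failures are treated as F = -inf (rejected).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if pivot is None:
        pivot = array.positions.mean(axis=0)
    h = prior_half_width_m
    if mode == "translation":
        bounds = np.array([[-h, h]] * 3)

        def to_pose(p):
            return RigidTransform(np.zeros(3), p)
    elif mode == "axis":
        u = np.asarray(axis if axis is not None else (0.0, 1.0, 0.0), float)
        u = u / np.linalg.norm(u)
        bounds = np.array([[-h, h]])

        def to_pose(p):
            return RigidTransform(np.zeros(3), p[0] * u)
    elif mode == "rigid":
        bounds = np.array([[-0.35, 0.35]] * 3 + [[-h, h]] * 3)

        def to_pose(p):
            return RigidTransform(p[:3], p[3:])
    else:
        raise ValueError(f"unknown search mode {mode!r}")

    def objective(p):
        pose = to_pose(p)
        try:
            moved = apply_pose(array, pose, pivot)
            return score_geometry(data, moved, sources, head,
                                  **inversion_kwargs).F
        except (np.linalg.LinAlgError, ValueError) as err:
            warnings.warn(f"forward/inverse failure at pose {p}: {err}",
                          stacklevel=2)
            return -np.inf

    raw = metropolis(objective, bounds, n_chains, n_iter, rng)
    return [PoseSample(to_pose(p), f, it, chain, acc)
            for p, f, it, chain, acc in raw]


def central_sensor_index(array: SensorArray) -> int:
    """Index of the sensor closest to the array centroid."""
    pos = array.positions
    return int(np.argmin(np.linalg.norm(pos - pos.mean(axis=0), axis=1)))


def _chain_states(samples, burn_in: float):
    """Accepted-state trajectory after burn-in, one state per iteration."""
    states = []
    by_chain = {}
    for s in samples:
        by_chain.setdefault(s.chain_id, []).append(s)
    for chain in sorted(by_chain):
        chain_samples = sorted(by_chain[chain], key=lambda s: s.iteration)
        n_iter = chain_samples[-1].iteration
        start = int(burn_in * n_iter)
        current = chain_samples[0]
        for s in chain_samples:
            if s.accepted:
                current = s
            if s.iteration >= start:
                states.append(current)
    return states


def confidence_ellipsoid(points: np.ndarray, weights: np.ndarray | None = None,
                         level: float = 0.95) -> Ellipsoid:
    """Weighted Gaussian confidence ellipsoid of a 3D sample cloud."""
    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[0] < 4:
        raise ValueError("confidence ellipsoid needs at least 4 samples")
    if weights is None:
        weights = np.ones(points.shape[0])
    w = np.asarray(weights, float)
    w = w / w.sum()
    mean = w @ points
    d = points - mean
    cov = (w[:, None] * d).T @ d
    eig = np.linalg.eigvalsh(cov)
    degenerate = bool(eig.min() <= 1e-30)
    return Ellipsoid(mean, cov, level, degenerate=degenerate)


def bma_sources(samples: list[PoseSample], data: DataMatrix,
                array: SensorArray, sources: SourceSpace, head: HeadModel,
                burn_in: float = 0.4, n_models: int = 30,
                rng_seed: int = 0, level: float = 0.95, pivot=None,
                **inversion_kwargs) -> tuple[SourceEstimate, PosteriorSummary]:
    """Bayesian model averaging of source estimates over posterior poses.

    ``n_models`` geometries are drawn from the post-burn-in chain states
    with probabilities proportional to exp(F - max F); each drawn geometry
    is inverted and the current estimates are averaged with those weights.
    The posterior summary (mean pose and the confidence ellipsoid of the
    central sensor's position) uses the full weighted post-burn-in cloud.
    """
    if pivot is None:
        pivot = array.positions.mean(axis=0)
    states = _chain_states(samples, burn_in)
    if len(states) < n_models:
        raise ValueError("fewer post-burn-in samples than requested models")
    F = np.array([s.F for s in states])
    w = evidence_weights(F)
    params = np.array([s.pose.params for s in states])
    mean_params = w @ params
    spread = np.sqrt(w @ (params - mean_params) ** 2)
    collapsed = bool(np.max(spread) < 1e-12)

    rng = np.random.default_rng(rng_seed)
    if collapsed:
        idx = np.array([int(np.argmax(w))])
        counts = np.array([n_models])
        warnings.warn("posterior collapsed onto a single pose sample",
                      stacklevel=2)
    else:
        drawn = rng.choice(len(states), size=n_models, replace=True, p=w)
        idx, counts = np.unique(drawn, return_counts=True)

    J_avg = None
    for i, cnt in zip(idx, counts):
        pose = states[i].pose
        moved = apply_pose(array, pose, pivot)
        from .forward import compute_leadfield
        from .inversion import EmpiricalBayesBeamformer
        lf = compute_leadfield(moved, sources, head)
        est = EmpiricalBayesBeamformer(data, lf, **inversion_kwargs).fit() \
            .source_estimate(data)
        contrib = (cnt / n_models) * est.J
        J_avg = contrib if J_avg is None else J_avg + contrib
    avg = SourceEstimate(J_avg)

    # posterior pose cloud
    mean_pose = RigidTransform.from_params(mean_params)
    ci = central_sensor_index(array)
    tracked = np.array([
        apply_pose(array, s.pose, pivot).positions[ci] for s in states])
    ell = confidence_ellipsoid(tracked, w, level)
    summary = PosteriorSummary(mean_pose, ell, tuple(states), w,
                               collapsed=collapsed)
    return avg, summary
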