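"""Free-energy scoring of sensor geometries and perturbation curves.

The variational free energy F of a fitted covariance model is a lower bound
on the log model evidence and decomposes as

    F = accuracy - complexity

where accuracy is the Gaussian log likelihood of the data under the implied
sensor covariance and complexity is the Occam penalty on the hyperparameters
(quadratic divergence from their prior plus the log volume ratio of posterior
to prior).  Differences in F between two geometries are log evidence ratios:
dF = -3 means a geometry is about exp(3) ~ 20 times less likely than the
best one, the conventional rejection threshold.

A *perturbation curve* scores the same data under increasingly wrong sensor
geometries (orientation error per sensor, or rigid arc displacement of the
whole array).  Its width at dF = -3 measures how much geometric error a
measurement system can hide: sharper models (better data and forward models)
give narrower curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .forward import HeadModel, SourceSpace, compute_leadfield
from .geometry import SensorArray, apply_gain_error, displace_arc, \
    perturb_orientations
from .inversion import CovarianceModel, DataMatrix, EmpiricalBayesBeamformer, \
    sample_covariance

__all__ = [
    "EvidenceResult",
    "PerturbationCurve",
    "ThresholdWidth",
    "free_energy",
    "score_geometry",
    "perturbation_curve",
    "width_at_threshold",
    "plot_curve",
]


@dataclass(frozen=True)
class EvidenceResult:
    """Free energy and its decomposition for one scored geometry."""

    F: float
    accuracy: float
    complexity: float
    lambda_hat: np.ndarray
    Sigma_lambda: np.ndarray
    converged: bool = True

    def __post_init__(self):
        if abs(self.F - (self.accuracy - self.complexity)) > 1e-9 * max(
                1.0, abs(self.F)):
            raise ValueError("F must equal accuracy - complexity")


@dataclass(frozen=True)
class PerturbationCurve:
    """Free energy versus injected geometric error.

    ``F_values`` has shape (n_offsets, n_repeats); offsets are degrees for
    orientation curves and millimetres for arc curves.
    """

    offsets: np.ndarray
    F_values: np.ndarray
    kind: str
    seed: int | None = None

    def __post_init__(self):
        off = np.asarray(self.offsets, float)
        F = np.atleast_2d(np.asarray(self.F_values, float))
        if F.shape[0] != off.size:
            raise ValueError("F_values first axis must match offsets")
        if np.any(np.diff(off) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if not np.isfinite(F).all():
            raise ValueError("curve contains non-finite free energies")
        object.__setattr__(self, "offsets", off)
        object.__setattr__(self, "F_values", F)

    @property
    def n_repeats(self) -> int:
        return self.F_values.shape[1]

    @property
    def mean_F(self) -> np.ndarray:
        return self.F_values.mean(axis=1)

    @property
    def relative_F(self) -> np.ndarray:
        """Mean F normalised to the curve maximum (<= 0 everywhere)."""
        m = self.mean_F
        return m - m.max()


@dataclass(frozen=True)
class ThresholdWidth:
    """Signed crossings of a relative-F curve through a threshold."""

    negative: float
    positive: float
    open_negative: bool = False
    open_positive: bool = False

    @property
    def half_width(self) -> float:
        """Mean of the two absolute crossing distances."""
        return 0.5 * (abs(self.negative) + abs(self.positive))


def free_energy(data, cov: CovarianceModel, n_samples: int | None = None
                ) -> EvidenceResult:
    """Free energy of a fitted covariance model on the given data.

    ``data`` may be a :class:`DataMatrix`, a raw (Nc, Nt) array or a
    precomputed sample covariance (then ``n_samples`` is required).
    """
    if isinstance(data, DataMatrix):
        C_Y, nt = sample_covariance(data), data.n_samples
    else:
        data = np.atleast_2d(np.asarray(data, float))
        if data.shape[0] == data.shape[1] and np.allclose(data, data.T):
            if n_samples is None:
                raise ValueError("n_samples is required with a covariance input")
            C_Y, nt = data, n_samples
        else:
            C_Y, nt = sample_covariance(data), data.shape[1]
    C = cov.C_model
    nc = C.shape[0]
    try:
        cf = linalg.cho_factor(C)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("model covariance is not positive "
                                    "definite") from err
    tr = np.trace(linalg.cho_solve(cf, C_Y))
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    accuracy = -0.5 * nt * (tr + logdet) - 0.5 * nc * nt * np.log(2 * np.pi)
    eta = np.log(cov.lambda_)
    d = eta - cov.prior_mean
    _, logdet_sp = np.linalg.slogdet(cov.log_lambda_cov @ cov.prior_precision)
    complexity = 0.5 * d @ cov.prior_precision @ d - 0.5 * logdet_sp
    return EvidenceResult(accuracy - complexity, accuracy, complexity,
                          cov.lambda_, cov.log_lambda_cov)


def score_geometry(data: DataMatrix, array: SensorArray,
                   sources: SourceSpace, head: HeadModel,
                   **inversion_kwargs) -> EvidenceResult:
    """Score one candidate sensor geometry against fixed data.

    Pipeline: lead field for the candidate geometry -> EBB prior -> ReML
    hyperparameter optimisation -> free energy.  Deterministic given data
    and geometry.
    """
    lf = compute_leadfield(array, sources, head)
    res = EmpiricalBayesBeamformer(data, lf, **inversion_kwargs).fit()
    return EvidenceResult(res.free_energy, res.accuracy, res.complexity,
                          res.params, res.cov_params, res.converged)


def perturbation_curve(data: DataMatrix, array: SensorArray,
                       sources: SourceSpace, head: HeadModel, kind: str,
                       offsets, n_repeats: int = 30, rng_seed: int = 0,
                       gain_error: float = 0.0, arc_centre=None,
                       arc_axis=(1.0, 0.0, 0.0),
                       **inversion_kwargs) -> PerturbationCurve:
    """Score perturbed copies of ``array`` over a grid of offsets.

    kind "orientation": each sensor independently rotated by the offset (deg)
    about a random frame axis, ``n_repeats`` random draws per offset.
    kind "arc": the whole rigid array displaced along an arc (offset in mm)
    about ``arc_centre`` (default: the head-model centre); the displacement
    is deterministic, so repeats only differ when ``gain_error`` > 0.

    ``gain_error`` additionally multiplies each channel's gain by an
    independent Normal(1, gain_error^2) draw, emulating un-modelled
    calibration error.  Gain draws are paired across offsets (repeat r uses
    the same gain realisation at every offset) so that the constant part of
    the gain penalty cancels from the relative curve; orientation draws are
    fresh for every (offset, repeat) model.
    """
    offsets = np.asarray(offsets, float)
    if 0.0 not in offsets:
        raise ValueError("offsets must include 0")
    if kind not in ("orientation", "arc"):
        raise ValueError(f"unknown perturbation kind {kind!r}")
    if arc_centre is None:
        arc_centre = head.centre
    ss = np.random.SeedSequence(rng_seed)
    deterministic = kind == "arc" and gain_error == 0.0
    n_rep = 1 if deterministic else n_repeats
    rep_seeds = ss.spawn(n_rep)
    F = np.empty((offsets.size, n_rep))
    for rep, rep_ss in enumerate(rep_seeds):
        gain_seed = int(rep_ss.generate_state(1)[0])
        model_seeds = rep_ss.spawn(offsets.size)
        for i, off in enumerate(offsets):
            if kind == "orientation":
                pert = perturb_orientations(
                    array, off, int(model_seeds[i].generate_state(1)[0]))
            else:
                pert = displace_arc(array, off, arc_centre, arc_axis)
            if gain_error > 0:
                pert = apply_gain_error(pert, gain_error, gain_seed)
            F[i, rep] = score_geometry(data, pert, sources, head,
                                       **inversion_kwargs).F
    return PerturbationCurve(offsets, F, kind, seed=rng_seed)


def width_at_threshold(curve: PerturbationCurve,
                       delta_F: float = -3.0) -> ThresholdWidth:
    """Offsets (relative to the argmax) where mean relative F crosses delta_F.

    Linear interpolation on each side of the curve maximum.  The evidence
    ratio at the crossing is exp(delta_F) (~1/20 for the default -3).  A side
    that never reaches the threshold within the scanned range is flagged
    open-ended and reported at the range edge.
    """
    if curve.offsets.size < 3:
        raise ValueError("curve needs at least 3 offsets")
    if delta_F > 0:
        raise ValueError("delta_F must be <= 0 (relative to the maximum)")
    rel = curve.relative_F
    if rel.max() < delta_F:
        raise ValueError("curve lies entirely below the threshold")
    i_max = int(np.argmax(rel))
    x0 = curve.offsets[i_max]

    def cross(idx_range):
        prev = i_max
        for i in idx_range:
            if rel[i] <= delta_F:
                # interpolate between prev and i
                x = np.interp(delta_F, [rel[i], rel[prev]],
                              [curve.offsets[i], curve.offsets[prev]])
                return x - x0, False
            prev = i
        edge = curve.offsets[idx_range[-1]] if len(idx_range) else x0
        return edge - x0, True

    neg, open_neg = cross(list(range(i_max - 1, -1, -1)))
    pos, open_pos = cross(list(range(i_max + 1, curve.offsets.size)))
    if open_neg or open_pos:
        warnings.warn("relative-F curve does not reach the threshold on "
                      "both sides of its maximum", stacklevel=2)
    return ThresholdWidth(neg, pos, open_neg, open_pos)


def plot_curve(curve: PerturbationCurve, threshold: float = -3.0, ax=None,
               label: str | None = None, show_repeats: bool = True):
    """Normalised perturbation curve with the rejection threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rel = curve.relative_F
    if show_repeats and curve.n_repeats > 1:
        spread = curve.F_values - curve.mean_F[:, None] + rel[:, None]
        ax.plot(curve.offsets, spread, color="0.8", lw=0.5, zorder=1)
    ax.plot(curve.offsets, rel, "o-", label=label, zorder=2)
    ax.axhline(threshold, color="k", lw=1)
    unit = "deg" if curve.kind == "orientation" else "mm"
    ax.set_xlabel(f"{curve.kind} offset ({unit})")
    ax.set_ylabel("relative free energy (nats)")
    if label:
        ax.legend()
    return ax
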