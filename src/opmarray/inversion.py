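"""Empirical Bayes Beamformer (EBB) source inversion.

The generative model is the standard MEG general linear model

    Y = L J + eps,   eps ~ N(0, Q_eps),   J ~ N(0, Q)

with ``Y`` the (Nc, Nt) sensor data, ``L`` the lead field and ``J`` the
source currents.  The noise prior is white, ``Q_eps = lambda_1 I``; the
source prior is the empirical beamformer prior ``Q = lambda_2 diag(Gamma)``
where ``Gamma_d = 1 / (l_d' C_Y^{-1} l_d)`` is the per-source beamformer
power estimate (valid when no sources are correlated at zero lag).

The two hyperparameters are optimised by restricted maximum likelihood
(Fisher scoring on log-hyperparameters), maximising the variational free
energy of the implied sensor covariance ``C = lambda_1 I + lambda_2 L G L'``.
The conditional source estimate is the posterior mean

    J_hat = Q L' (Q_eps + L Q L')^{-1} Y.

:class:`EmpiricalBayesBeamformer` follows the Model/Results pattern: build
it from data and a lead field, call :meth:`~EmpiricalBayesBeamformer.fit`,
and read estimates and evidence off the returned :class:`EBBResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .forward import LeadField

__all__ = [
    "DataMatrix",
    "CovarianceModel",
    "SourceEstimate",
    "EmpiricalBayesBeamformer",
    "EBBResults",
    "sample_covariance",
    "ebb_prior",
    "estimate_sources",
    "bandpass",
]


@dataclass(frozen=True)
class DataMatrix:
    """Multichannel field data: (Nc, Nt) values in tesla."""

    values: np.ndarray
    sample_rate: float
    channel_labels: tuple[str, ...] = ()
    window: tuple[float, float] | None = None

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, float))
        if v.ndim != 2 or v.size == 0:
            raise ValueError("data must be a non-empty (Nc, Nt) matrix")
        if self.channel_labels and len(self.channel_labels) != v.shape[0]:
            raise ValueError("channel_labels length must equal Nc")
        if v.shape[1] < v.shape[0]:
            warnings.warn(
                f"Nt={v.shape[1]} < Nc={v.shape[0]}: sample covariance will "
                "be rank deficient", stacklevel=2)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        t = np.arange(self.n_samples) / self.sample_rate
        return t + (self.window[0] if self.window else 0.0)

    def crop(self, start: float, stop: float) -> "DataMatrix":
        """Restrict to the [start, stop] window in seconds."""
        t = self.times
        keep = (t >= start) & (t <= stop)
        return DataMatrix(self.values[:, keep], self.sample_rate,
                          self.channel_labels, (start, stop))


def bandpass(data: DataMatrix, low: float, high: float,
             order: int = 4) -> DataMatrix:
    """Zero-phase Butterworth band-pass, applied per channel."""
    sos = signal.butter(order, [low, high], btype="band", output="sos",
                        fs=data.sample_rate)
    v = signal.sosfiltfilt(sos, data.values, axis=1)
    return DataMatrix(v, data.sample_rate, data.channel_labels, data.window)


@dataclass(frozen=True)
class CovarianceModel:
    """Fitted sensor-covariance model ``C = l1 I + l2 L diag(Gamma) L'``."""

    lambda_: np.ndarray            # hyperparameters, native scale
    gamma: np.ndarray | None       # Nd source prior weights (None: noise-only)
    C_model: np.ndarray            # Nc x Nc implied covariance
    log_lambda_cov: np.ndarray     # posterior covariance of log-hyperparameters
    prior_mean: np.ndarray         # prior mean of log-hyperparameters
    prior_precision: np.ndarray    # prior precision of log-hyperparameters

    def __post_init__(self):
        C = np.asarray(self.C_model, float)
        if not np.allclose(C, C.T, atol=1e-12 * max(1.0, np.abs(C).max())):
            raise ValueError("C_model must be symmetric")
        object.__setattr__(self, "C_model", 0.5 * (C + C.T))


@dataclass(frozen=True)
class SourceEstimate:
    """Posterior mean currents: (Nd, Nt) in ampere-metres."""

    J: np.ndarray
    power: np.ndarray = None

    def __post_init__(self):
        J = np.atleast_2d(np.asarray(self.J, float))
        if not np.isfinite(J).all():
            raise ValueError("source estimate contains non-finite values")
        power = self.power
        if power is None:
            power = np.mean(J**2, axis=1)
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "power", np.asarray(power, float))

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.power))


def sample_covariance(data, normalizer: str = "Nt") -> np.ndarray:
    """Sample covariance Y Y' / N of a data matrix.

    ``normalizer`` selects the divisor: the number of time samples (``"Nt"``,
    the conventional estimator, default) or the number of channels (``"Nc"``).
    A global scale does not affect model *rankings*, which is what geometry
    comparison uses.
    """
    Y = data.values if isinstance(data, DataMatrix) else np.atleast_2d(
        np.asarray(data, float))
    if Y.size == 0:
        raise ValueError("empty data matrix")
    n = Y.shape[1] if normalizer == "Nt" else Y.shape[0]
    C = (Y @ Y.T) / n
    return 0.5 * (C + C.T)


def ebb_prior(leadfield, C_Y: np.ndarray, regularization: float = 0.0,
              normalize: str = "mean") -> np.ndarray:
    """Beamformer source-power prior Gamma.

    ``Gamma_d = 1 / (l_d' (C_Y + reg * tr(C_Y)/Nc * I)^{-1} l_d)`` for each
    lead-field column, rescaled to unit mean.  ``regularization`` defaults to
    0 (no diagonal loading).
    """
    L = leadfield.matrix if isinstance(leadfield, LeadField) else np.asarray(
        leadfield, float)
    nc = C_Y.shape[0]
    C = C_Y + regularization * np.trace(C_Y) / nc * np.eye(nc)
    try:
        cf = linalg.cho_factor(C)
        CiL = linalg.cho_solve(cf, L)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "regularized data covariance is singular; raise the "
            "regularization fraction") from err
    quad = np.einsum("cd,cd->d", L, CiL)
    if np.any(quad <= 0):
        raise np.linalg.LinAlgError(
            "data covariance is not positive definite for the EBB prior; "
            "raise the regularization fraction")
    gamma = 1.0 / quad
    if normalize == "mean":
        gamma = gamma / gamma.mean()
    elif normalize == "trace":
        gamma = gamma / gamma.sum()
    return gamma


def estimate_sources(data, cov: CovarianceModel, leadfield) -> SourceEstimate:
    """Posterior mean currents J_hat = Q L' C^{-1} Y."""
    Y = data.values if isinstance(data, DataMatrix) else np.atleast_2d(
        np.asarray(data, float))
    L = leadfield.matrix if isinstance(leadfield, LeadField) else np.asarray(
        leadfield, float)
    if Y.shape[0] != L.shape[0] or Y.shape[0] != cov.C_model.shape[0]:
        raise ValueError("channel dimensions of data, lead field and "
                         "covariance model do not match")
    if cov.gamma is None:
        raise ValueError("covariance model has no source component")
    cf = linalg.cho_factor(cov.C_model)
    CiY = linalg.cho_solve(cf, Y)
    lam2 = cov.lambda_[-1]
    J = (lam2 * cov.gamma)[:, None] * (L.T @ CiY)
    return SourceEstimate(J)


# ---------------------------------------------------------------------------
# Model / Results


class EmpiricalBayesBeamformer:
    """EBB source-inversion model for one (data, lead field) pair.

    Parameters
    ----------
    data : DataMatrix or (Nc, Nt) array
        Sensor measurements in tesla.
    leadfield : LeadField or (Nc, Nd) array
        Forward model for the candidate sensor geometry.
    gamma : (Nd,) array, optional
        Source prior weights.  Default: the EBB beamformer-power prior
        estimated from the sample covariance.
    regularization : float
        Diagonal-loading fraction used when forming the EBB prior (0 by
        default).
    normalizer : {"Nt", "Nc"}
        Divisor convention for the sample covariance.
    prior_mean, prior_precision : float
        Gaussian prior on the *log* hyperparameters (non-informative by
        default: zero mean, precision 1e-6).
    noise_only : bool
        Drop the source component and fit ``C = lambda_1 I`` only (null
        model for evidence comparisons).
    n_eff : int, None or "auto"
        Effective number of independent temporal observations entering the
        evidence.  Band-limited evoked responses have far fewer independent
        degrees of freedom than raw samples; standard practice projects the
        data onto a small set of dominant temporal modes and counts those
        as observations.  ``"auto"`` (default) caps the count at 16 modes,
        ``None`` uses the raw sample count.  The hyperparameter *estimates*
        are invariant to this scale; free-energy differences are
        proportional to it.
    """

    def __init__(self, data, leadfield, *, gamma=None, regularization=0.0,
                 normalizer="Nt", prior_mean=0.0, prior_precision=1e-6,
                 noise_only=False, n_eff="auto"):
        self.data = data if isinstance(data, DataMatrix) else DataMatrix(
            np.asarray(data, float), sample_rate=1.0)
        self.leadfield = leadfield if isinstance(leadfield, LeadField) else \
            LeadField(np.asarray(leadfield, float))
        if self.data.n_channels != self.leadfield.n_channels:
            raise ValueError("data and lead field disagree on Nc")
        self.n_channels = self.data.n_channels
        self.n_samples = self.data.n_samples
        if n_eff == "auto":
            self.n_eff = min(self.n_samples, 16)
        elif n_eff is None:
            self.n_eff = self.n_samples
        else:
            self.n_eff = int(n_eff)
        self.C_Y = sample_covariance(self.data, normalizer)
        self.noise_only = noise_only
        if noise_only:
            self.gamma = None
        elif gamma is not None:
            self.gamma = np.asarray(gamma, float)
        else:
            self.gamma = ebb_prior(self.leadfield, self.C_Y, regularization)
        # covariance components
        self.components = [np.eye(self.n_channels)]
        if self.gamma is not None:
            L = self.leadfield.matrix
            self.components.append((L * self.gamma) @ L.T)
        k = len(self.components)
        self.prior_mean = np.full(k, float(prior_mean))
        self.prior_precision = np.eye(k) * float(prior_precision)

    # -- restricted-likelihood machinery ------------------------------------

    def _initial_log_lambda(self) -> np.ndarray:
        scale = np.trace(self.C_Y) / self.n_channels
        lam = []
        for Q in self.components:
            qscale = np.trace(Q) / self.n_channels
            lam.append(scale / (len(self.components) * qscale))
        return np.log(np.maximum(lam, 1e-300))

    def _implied_cov(self, log_lambda: np.ndarray) -> np.ndarray:
        lam = np.exp(log_lambda)
        C = np.zeros_like(self.C_Y)
        for li, Q in zip(lam, self.components):
            C += li * Q
        return C

    def _log_likelihood(self, C: np.ndarray) -> float:
        """Gaussian log evidence term -N/2 [tr(C_Y C^-1) + log|C|] + const."""
        nt, nc = self.n_eff, self.n_channels
        cf = linalg.cho_factor(C)
        tr = np.trace(linalg.cho_solve(cf, self.C_Y))
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return -0.5 * nt * (tr + logdet) - 0.5 * nc * nt * np.log(2 * np.pi)

    def fit(self, maxiter: int = 128, tol: float = 1e-4) -> "EBBResults":
        """Maximise free energy over log-hyperparameters by Fisher scoring.

        ``tol`` is the absolute change (nats) in the penalised likelihood at
        which the iteration stops.
        """
        nt = self.n_eff
        eta = self._initial_log_lambda()
        nu, Pi = self.prior_mean, self.prior_precision
        k = len(self.components)

        def objective(eta):
            C = self._implied_cov(eta)
            d = eta - nu
            return self._log_likelihood(C) - 0.5 * d @ Pi @ d

        obj = objective(eta)
        converged = False
        H = Pi.copy()
        for it in range(1, maxiter + 1):
            lam = np.exp(eta)
            C = self._implied_cov(eta)
            cf = linalg.cho_factor(C)
            Ci = linalg.cho_solve(cf, np.eye(self.n_channels))
            CiCYCi = Ci @ self.C_Y @ Ci
            G = [lam[i] * self.components[i] for i in range(k)]
            grad = np.array([
                0.5 * nt * np.sum((CiCYCi - Ci) * G[i]) for i in range(k)
            ]) - Pi @ (eta - nu)
            # stationary point: moving any log-hyperparameter by a full
            # log-unit would change the objective by less than tol
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
            CiG = [Ci @ G[i] for i in range(k)]
            H = np.empty((k, k))
            for i in range(k):
                for j in range(i, k):
                    H[i, j] = H[j, i] = 0.5 * nt * np.sum(CiG[i] * CiG[j].T)
            H += Pi
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = grad / np.diag(H)
            # damped update: halve until the objective does not decrease
            step = np.clip(step, -8.0, 8.0)
            new_obj, new_eta = -np.inf, eta
            for _ in range(16):
                cand = eta + step
                try:
                    cand_obj = objective(cand)
                except linalg.LinAlgError:
                    cand_obj = -np.inf
                if cand_obj >= obj - 1e-12:
                    new_obj, new_eta = cand_obj, cand
                    break
                step *= 0.5
            if not np.isfinite(new_obj):
                break
            d_obj = new_obj - obj
            eta, obj = new_eta, new_obj
            if abs(d_obj) < tol:
                converged = True
                break
        else:
            it = maxiter

        if not converged:
            warnings.warn("hyperparameter optimisation did not converge; "
                          "returning best iterate", stacklevel=2)
        Sigma = np.linalg.inv(H)
        lam = np.exp(eta)
        C = self._implied_cov(eta)
        cov = CovarianceModel(
            lambda_=lam, gamma=self.gamma, C_model=C,
            log_lambda_cov=Sigma, prior_mean=nu, prior_precision=Pi)
        accuracy = self._log_likelihood(C)
        d = eta - nu
        sign, logdet_sp = np.linalg.slogdet(Sigma @ Pi)
        complexity = 0.5 * d @ Pi @ d - 0.5 * logdet_sp
        return EBBResults(self, cov, eta, accuracy=accuracy,
                          complexity=complexity, converged=converged,
                          n_iter=it)


class EBBResults:
    """Fitted EBB model: hyperparameters, evidence decomposition, sources."""

    def __init__(self, model, cov_model, log_lambda, accuracy, complexity,
                 converged, n_iter):
        self.model = model
        self.cov_model = cov_model
        self.log_lambda = log_lambda
        self.accuracy = float(accuracy)
        self.complexity = float(complexity)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)

    @property
    def params(self) -> np.ndarray:
        """Hyperparameters (lambda_1[, lambda_2]) on the native scale."""
        return self.cov_model.lambda_

    @property
    def cov_params(self) -> np.ndarray:
        """Posterior covariance of the log-hyperparameters."""
        return self.cov_model.log_lambda_cov

    @property
    def free_energy(self) -> float:
        """Negative variational free energy F = accuracy - complexity."""
        return self.accuracy - self.complexity

    def source_estimate(self, data=None) -> SourceEstimate:
        """Posterior mean currents for ``data`` (default: the fitted data)."""
        data = self.model.data if data is None else data
        return estimate_sources(data, self.cov_model, self.model.leadfield)

    def summary(self) -> str:
        lam = self.params
        se = np.sqrt(np.diag(self.cov_params))
        names = ["lambda_1 (noise)", "lambda_2 (source)"][: len(lam)]
        lines = [
            "Empirical Bayes Beamformer results",
            "=" * 54,
            f"channels: {self.model.n_channels:6d}    samples: "
            f"{self.model.n_samples:6d}",
            f"free energy: {self.free_energy:16.3f} nats",
            f"  accuracy:  {self.accuracy:16.3f}",
            f"  complexity:{self.complexity:16.3f}",
            f"converged: {self.converged} ({self.n_iter} iterations)",
            "-" * 54,
            f"{'hyperparameter':<20}{'estimate':>16}{'se(log)':>12}",
        ]
        for name, l, s in zip(names, lam, se):
            lines.append(f"{name:<20}{l:>16.6e}{s:>12.4f}")
        return "\n".join(lines)
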