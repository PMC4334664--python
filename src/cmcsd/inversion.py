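"""Variational Laplace inversion of the spectral forward model.

The observed complex cross-spectral density is rearranged into a real
feature vector (real and imaginary parts of the upper-triangular entries
across frequencies; diagonals contribute real parts only).  Under a
Gaussian likelihood with diagonal precision ``Pi`` — one log-precision
hyperparameter per channel-pair feature block — the scheme maximizes the
variational free energy

    F = accuracy - complexity
      = E_q[ln p(y | theta, lambda)] - KL(q(theta) || p(theta))
                                     - KL(q(lambda) || p(lambda))

by Gauss-Newton ascent on the posterior mean with Levenberg-Marquardt
damping (backtracking whenever a candidate step decreases F), and a
closed-form Newton M-step on the noise log-precisions.  F is a lower
bound on the log model evidence and is the model-comparison statistic;
the accuracy-only ("reduced") log evidence of a channel pair,

    F_ij = -1/2 e' Pi e + 1/2 ln|Pi|,    e = y_ij - g(mu)_ij,

is used when competing models share the same complexity.  A log-evidence
difference of 3 corresponds to odds of exp(3) ~ 20:1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np

from .network import CMCParameters, PriorDensity, VERIDICAL, REVERSED
from .spectral import (
    CrossSpectralData,
    UnstableModelError,
    predict_csd,
)

__all__ = [
    "FeatureVector",
    "features_from_csd",
    "features_to_csd",
    "log_likelihood",
    "log_evidence_to_odds",
    "GaussianFeatureProblem",
    "VLResult",
    "vl_fit",
    "ModelFit",
    "fit",
    "reduced_log_evidence",
    "ComparisonReport",
    "compare_models",
    "pool_comparisons",
]

LN2PI = float(np.log(2.0 * np.pi))

#: Free-energy differences smaller than this are reported as a tie.
TIE_TOLERANCE = 1e-6


# ---------------------------------------------------------------------------
# feature representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """Real-valued data features of a complex CSD.

    Ordering: channel pairs ``(i, j)`` with ``i <= j`` in lexicographic
    order; within each pair, the real parts across all frequencies, then
    (off-diagonal pairs only) the imaginary parts across all frequencies.
    Length is ``F*C(C+1)/2*2 - F*C``.
    """

    values: np.ndarray
    block_labels: tuple[str, ...]
    block_slices: tuple[slice, ...]
    pairs: tuple[tuple[int, int], ...]
    n_freqs: int

    def block(self, label: str) -> np.ndarray:
        return self.values[self.block_slices[self.block_labels.index(label)]]


def _pair_blocks(n_channels: int, n_freqs: int):
    pairs, labels, slices = [], [], []
    start = 0
    for i in range(n_channels):
        for j in range(i, n_channels):
            size = n_freqs if i == j else 2 * n_freqs
            pairs.append((i, j))
            labels.append(f"auto_{i}" if i == j else f"cross_{i}_{j}")
            slices.append(slice(start, start + size))
            start += size
    return tuple(pairs), tuple(labels), tuple(slices), start


def features_from_csd(data: CrossSpectralData) -> FeatureVector:
    """Concatenate the unique real degrees of freedom of a Hermitian CSD."""
    F, C = data.freqs.size, data.n_channels
    pairs, labels, slices, total = _pair_blocks(C, F)
    values = np.empty(total)
    for (i, j), sl in zip(pairs, slices):
        if i == j:
            values[sl] = data.csd[:, i, i].real
        else:
            values[sl] = np.concatenate([data.csd[:, i, j].real, data.csd[:, i, j].imag])
    return FeatureVector(values, labels, slices, pairs, F)


def features_to_csd(
    values: np.ndarray, freqs: np.ndarray, n_channels: int
) -> np.ndarray:
    """Inverse of :func:`features_from_csd`; returns the (F, C, C) array."""
    F = np.asarray(freqs).size
    pairs, _labels, slices, total = _pair_blocks(n_channels, F)
    if values.size != total:
        raise ValueError(f"expected {total} features, got {values.size}")
    csd = np.zeros((F, n_channels, n_channels), dtype=complex)
    for (i, j), sl in zip(pairs, slices):
        block = values[sl]
        if i == j:
            csd[:, i, i] = block
        else:
            csd[:, i, j] = block[:F] + 1j * block[F:]
            csd[:, j, i] = np.conj(csd[:, i, j])
    return csd


# ---------------------------------------------------------------------------
# Gaussian likelihood
# ---------------------------------------------------------------------------

def log_likelihood(
    features_obs: np.ndarray,
    features_pred: np.ndarray,
    noise_precision: np.ndarray,
    *,
    include_const: bool = True,
) -> float:
    """Gaussian log-density of the residuals under precision ``Pi``.

    ``Pi`` may be a vector (diagonal precision) or a full SPD matrix.
    The ``-(n/2) ln 2pi`` constant is included by default; the printed-form
    reduced evidence omits it (it cancels between models of equal size).
    """
    y = np.asarray(features_obs, dtype=float)
    g = np.asarray(features_pred, dtype=float)
    if y.shape != g.shape:
        raise ValueError("observed and predicted features must have equal shape")
    eps = y - g
    Pi = np.asarray(noise_precision, dtype=float)
    if Pi.ndim == 1:
        if np.any(Pi <= 0):
            raise np.linalg.LinAlgError("singular (nonpositive) precision")
        quad = float(eps @ (Pi * eps))
        logdet = float(np.sum(np.log(Pi)))
    else:
        sign, logdet = np.linalg.slogdet(Pi)
        if sign <= 0:
            raise np.linalg.LinAlgError("precision matrix is not positive definite")
        quad = float(eps @ Pi @ eps)
    out = -0.5 * quad + 0.5 * logdet
    if include_const:
        out -= 0.5 * eps.size * LN2PI
    return out


def log_evidence_to_odds(delta_f: float) -> float:
    """Posterior odds ratio implied by a log-evidence difference."""
    if delta_f > 700.0:  # exp overflows; the odds are effectively infinite
        return float("inf")
    return float(np.exp(delta_f))


# ---------------------------------------------------------------------------
# generic variational Laplace on Gaussian feature models
# ---------------------------------------------------------------------------

@dataclass
class GaussianFeatureProblem:
    """A nonlinear-regression problem ``y = g(theta) + e`` for VL.

    ``forward`` returns the predicted feature vector, or None if the
    parameter draw is invalid (e.g. dynamically unstable) — such draws are
    rejected during the line search.  ``block_slices`` partitions the
    features; each block has its own noise log-precision with Gaussian
    hyperprior ``N(hyper_mean, hyper_var)``.
    """

    forward: Callable[[np.ndarray], np.ndarray | None]
    prior_mean: np.ndarray
    prior_var: np.ndarray
    block_slices: Sequence[slice]
    hyper_mean: float = 6.0
    hyper_var: float = 1.0 / 128.0


@dataclass
class VLResult:
    mu: np.ndarray
    Sigma: np.ndarray
    lambdas: np.ndarray           # posterior means of the log precisions
    lambda_vars: np.ndarray
    free_energy: float
    accuracy: float
    complexity: float
    trace: list[float]
    converged: bool
    n_iter: int
    predicted: np.ndarray


def _fd_jacobian(forward, theta, f0, step):
    d = theta.size
    J = np.zeros((f0.size, d))
    for i in range(d):
        e = np.zeros(d)
        e[i] = step
        fp = forward(theta + e)
        fm = forward(theta - e)
        if fp is not None and fm is not None:
            J[:, i] = (fp - fm) / (2 * step)
        elif fp is not None:
            J[:, i] = (fp - f0) / step
        elif fm is not None:
            J[:, i] = (f0 - fm) / step
        # both unstable: leave the column at zero
    return J


def _mstep(eps, J, Sigma, block_slices, lambdas, hyper_mean, hyper_var):
    """Newton updates of the block log-precisions; returns (lambdas, vars, qt)."""
    n_b = len(block_slices)
    qt = np.empty(n_b)
    for b, sl in enumerate(block_slices):
        Jb = J[sl]
        qt[b] = float(eps[sl] @ eps[sl] + np.sum((Jb @ Sigma) * Jb))
    lam = lambdas.copy()
    for _ in range(8):
        e_lam = np.exp(lam)
        grad = 0.5 * np.array([sl.stop - sl.start for sl in block_slices]) \
            - 0.5 * e_lam * qt - (lam - hyper_mean) / hyper_var
        hess = -0.5 * e_lam * qt - 1.0 / hyper_var
        lam = lam - grad / hess
    lam_var = 1.0 / (0.5 * np.exp(lam) * qt + 1.0 / hyper_var)
    return lam, lam_var, qt


def _free_energy_parts(eps, J, Sigma, mu, problem, lambdas, lam_vars):
    sls = problem.block_slices
    n = eps.size
    acc = -0.5 * n * LN2PI
    for b, sl in enumerate(sls):
        Jb = J[sl]
        qt = float(eps[sl] @ eps[sl] + np.sum((Jb @ Sigma) * Jb))
        acc += -0.5 * np.exp(lambdas[b]) * qt + 0.5 * (sl.stop - sl.start) * lambdas[b]
    dmu = mu - problem.prior_mean
    V0 = problem.prior_var
    sign, logdet_S = np.linalg.slogdet(Sigma)
    kl_theta = 0.5 * (
        float(np.sum(np.diag(Sigma) / V0))
        + float(dmu @ (dmu / V0))
        - mu.size
        + float(np.sum(np.log(V0)))
        - logdet_S
    )
    kl_lambda = 0.5 * float(
        np.sum(
            lam_vars / problem.hyper_var
            + (lambdas - problem.hyper_mean) ** 2 / problem.hyper_var
            - 1.0
            + np.log(problem.hyper_var)
            - np.log(lam_vars)
        )
    )
    complexity = kl_theta + kl_lambda
    return acc, complexity, acc - complexity


def _evaluate(theta, y, problem, lambdas, fd_step):
    """Full evaluation at theta: prediction, Jacobian, M-step, Sigma, F."""
    g = problem.forward(theta)
    if g is None:
        return None
    eps = y - g
    J = _fd_jacobian(problem.forward, theta, g, fd_step)
    P0 = 1.0 / problem.prior_var
    # first pass with incoming lambdas to get Sigma, then one M-step refresh
    lam = lambdas
    for _ in range(2):
        Pi = np.empty(y.size)
        for b, sl in enumerate(problem.block_slices):
            Pi[sl] = np.exp(lam[b])
        H = (J.T * Pi) @ J + np.diag(P0)
        Sigma = np.linalg.inv(H)
        lam, lam_vars, _ = _mstep(
            eps, J, Sigma, problem.block_slices, lam,
            problem.hyper_mean, problem.hyper_var,
        )
    acc, comp, F = _free_energy_parts(eps, J, Sigma, theta, problem, lam, lam_vars)
    return {
        "g": g, "eps": eps, "J": J, "Pi": Pi, "H": H, "Sigma": Sigma,
        "lambdas": lam, "lambda_vars": lam_vars,
        "accuracy": acc, "complexity": comp, "F": F,
    }


def vl_fit(
    problem: GaussianFeatureProblem,
    y: np.ndarray,
    *,
    max_iter: int = 128,
    tol: float = 1e-2,
    fd_step: float = 1e-3,
    init: np.ndarray | None = None,
    max_backtracks: int = 8,
) -> VLResult:
    """Variational Laplace with Gauss-Newton / Levenberg-Marquardt updates.

    The free-energy trace over accepted iterations is nondecreasing by
    construction: candidate steps that lower F are rejected and the
    damping is increased instead.
    """
    y = np.asarray(y, dtype=float)
    mu = problem.prior_mean.copy() if init is None else np.asarray(init, float).copy()
    if np.any(problem.prior_var <= 0):
        raise ValueError("vl_fit requires strictly positive prior variances")
    lambdas = np.full(len(problem.block_slices), problem.hyper_mean)

    state = _evaluate(mu, y, problem, lambdas, fd_step)
    if state is None:
        raise UnstableModelError("forward model invalid at the initial point")
    trace = [state["F"]]
    damping = 1e-4
    converged = False
    n_iter = 0
    P0 = 1.0 / problem.prior_var

    for n_iter in range(1, max_iter + 1):
        J, Pi, eps = state["J"], state["Pi"], state["eps"]
        grad = J.T @ (Pi * eps) - P0 * (mu - problem.prior_mean)
        H = state["H"]
        accepted = False
        for _ in range(max_backtracks):
            step_mat = H + damping * np.diag(np.diag(H))
            try:
                dmu = np.linalg.solve(step_mat, grad)
            except np.linalg.LinAlgError:
                damping *= 8.0
                continue
            cand = _evaluate(mu + dmu, y, problem, state["lambdas"], fd_step)
            if cand is not None and cand["F"] > state["F"]:
                dF = cand["F"] - state["F"]
                mu = mu + dmu
                state = cand
                trace.append(state["F"])
                damping = max(damping / 2.0, 1e-8)
                accepted = True
                break
            damping *= 8.0
        if not accepted:
            converged = True  # no ascent direction improves F: local maximum
            break
        if dF < tol:
            converged = True
            break

    return VLResult(
        mu=mu,
        Sigma=state["Sigma"],
        lambdas=state["lambdas"],
        lambda_vars=state["lambda_vars"],
        free_energy=state["F"],
        accuracy=state["accuracy"],
        complexity=state["complexity"],
        trace=trace,
        converged=converged,
        n_iter=n_iter,
        predicted=state["g"],
    )


# ---------------------------------------------------------------------------
# CMC model fit
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Posterior density, free energy and predictions of one inversion.

    Parameters with zero prior variance are clamped at their prior mean;
    ``mu``/``Sigma`` cover the full parameter vector with zero rows and
    columns for the clamped entries.  ``data_scale`` is the factor the
    observed CSD was multiplied by before fitting (so that its mean
    autospectral power is one); predictions are in the scaled units.
    """

    prior: PriorDensity
    direction: str
    freqs: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    lambdas: np.ndarray
    block_labels: tuple[str, ...]
    free_energy: float
    accuracy: float
    complexity: float
    trace: list[float]
    converged: bool
    n_iter: int
    data_scale: float
    predicted_csd: CrossSpectralData

    def posterior_params(self) -> CMCParameters:
        return CMCParameters(self.mu, self.prior)

    def credible_interval(self, name: str, level: float = 0.90) -> tuple[float, float]:
        from scipy.stats import norm

        i = self.prior.index(name)
        half = norm.ppf(0.5 + level / 2.0) * np.sqrt(self.Sigma[i, i])
        return (self.mu[i] - half, self.mu[i] + half)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "direction": self.direction,
            "free_energy": self.free_energy,
            "accuracy": self.accuracy,
            "complexity": self.complexity,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "data_scale": self.data_scale,
            "names": list(self.prior.names),
            "mu": self.mu.tolist(),
            "sigma_diag": np.diag(self.Sigma).tolist(),
            "lambdas": self.lambdas.tolist(),
            "block_labels": list(self.block_labels),
            "trace": list(self.trace),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mu", data=self.mu)
            f.create_dataset("Sigma", data=self.Sigma)
            f.create_dataset("lambdas", data=self.lambdas)
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("predicted_re", data=self.predicted_csd.csd.real)
            f.create_dataset("predicted_im", data=self.predicted_csd.csd.imag)
            f.attrs["meta"] = json.dumps(
                {
                    "direction": self.direction,
                    "free_energy": self.free_energy,
                    "accuracy": self.accuracy,
                    "complexity": self.complexity,
                    "converged": self.converged,
                    "data_scale": self.data_scale,
                }
            )


def _normalization_scale(data: CrossSpectralData) -> float:
    power = np.mean(np.diagonal(data.csd, axis1=1, axis2=2).real)
    if power <= 0:
        raise ValueError("observed CSD has nonpositive mean autospectral power")
    return 1.0 / power


def fit(
    data: CrossSpectralData,
    prior: PriorDensity | None = None,
    direction: str = VERIDICAL,
    *,
    max_iter: int = 128,
    tol: float = 1e-2,
    fd_step: float = 1e-3,
    hyper_mean: float = 6.0,
    hyper_var: float = 1.0 / 128.0,
    normalize: bool = True,
    init_jitter: float = 0.0,
    seed: int | None = None,
    n_starts: int = 1,
) -> ModelFit:
    """Invert the CMC spectral model on an observed cross-spectral density.

    ``init_jitter`` perturbs the Gauss-Newton starting point with Gaussian
    noise of that standard deviation in log space (seeded), which is how
    repeated fits of the same data are decorrelated.  With ``n_starts > 1``
    the optimization restarts from additional jittered initializations
    (jitter 0.1 if ``init_jitter`` is 0) and the fit with the highest free
    energy is returned — free-energy ascent is local, and occasional poor
    maxima are best escaped by restarting.
    """
    if n_starts > 1:
        jitter = init_jitter if init_jitter > 0 else 0.1
        base = 0 if seed is None else seed
        fits = [
            fit(
                data, prior, direction,
                max_iter=max_iter, tol=tol, fd_step=fd_step,
                hyper_mean=hyper_mean, hyper_var=hyper_var,
                normalize=normalize,
                init_jitter=0.0 if k == 0 else jitter,
                seed=base + 7919 * k, n_starts=1,
            )
            for k in range(n_starts)
        ]
        return max(fits, key=lambda f: f.free_energy)
    # noisy observed autospectra may dip below zero at low SNR, so only
    # conjugate symmetry and a real diagonal are required of the data
    herm_err = np.abs(data.csd - np.conj(np.swapaxes(data.csd, 1, 2))).max()
    if herm_err > 1e-8:
        raise ValueError("observed CSD must be Hermitian with real diagonal")
    prior = prior or PriorDensity.default()
    freqs = data.freqs
    scale = _normalization_scale(data) if normalize else 1.0
    scaled = CrossSpectralData(
        csd=data.csd * scale, freqs=freqs,
        n_epochs=data.n_epochs, fs=data.fs, channel_labels=data.channel_labels,
    )
    obs = features_from_csd(scaled)

    free = prior.variances > 0
    theta_full = prior.zero_theta()

    def forward_free(theta_free: np.ndarray) -> np.ndarray | None:
        th = theta_full.copy()
        th[free] = theta_free
        try:
            pred = predict_csd(CMCParameters(th, prior), freqs, direction)
        except UnstableModelError:
            return None
        return features_from_csd(pred).values

    n_free = int(free.sum())
    if n_free == 0:
        # degenerate prior: the posterior is the prior point mass
        pred = predict_csd(CMCParameters(theta_full, prior), freqs, direction)
        n_feats = obs.values.size
        return ModelFit(
            prior=prior, direction=direction, freqs=freqs,
            mu=theta_full, Sigma=np.zeros((prior.n_params,) * 2),
            lambdas=np.full(len(obs.block_labels), hyper_mean),
            block_labels=obs.block_labels,
            free_energy=log_likelihood(
                obs.values, features_from_csd(pred).values,
                np.full(n_feats, np.exp(hyper_mean)),
            ),
            accuracy=0.0, complexity=0.0, trace=[], converged=True, n_iter=0,
            data_scale=scale, predicted_csd=pred,
        )

    init = np.zeros(n_free)
    if init_jitter > 0:
        rng = np.random.default_rng(seed)
        init = init + rng.normal(0.0, init_jitter, size=n_free)
        if forward_free(init) is None:  # jittered start unstable: fall back
            init = np.zeros(n_free)

    problem = GaussianFeatureProblem(
        forward=forward_free,
        prior_mean=np.zeros(n_free),
        prior_var=prior.variances[free],
        block_slices=obs.block_slices,
        hyper_mean=hyper_mean,
        hyper_var=hyper_var,
    )
    res = vl_fit(
        problem, obs.values, max_iter=max_iter, tol=tol, fd_step=fd_step, init=init
    )

    mu_full = theta_full.copy()
    mu_full[free] = res.mu
    Sigma_full = np.zeros((prior.n_params, prior.n_params))
    ix = np.flatnonzero(free)
    Sigma_full[np.ix_(ix, ix)] = res.Sigma

    predicted = CrossSpectralData(
        csd=features_to_csd(res.predicted, freqs, data.n_channels), freqs=freqs
    )
    return ModelFit(
        prior=prior, direction=direction, freqs=freqs,
        mu=mu_full, Sigma=Sigma_full,
        lambdas=res.lambdas, block_labels=obs.block_labels,
        free_energy=res.free_energy, accuracy=res.accuracy,
        complexity=res.complexity, trace=res.trace,
        converged=res.converged, n_iter=res.n_iter,
        data_scale=scale, predicted_csd=predicted,
    )


def reduced_log_evidence(
    fit_result: ModelFit,
    data: CrossSpectralData,
    channel_pair: tuple[int, int],
) -> float:
    """Accuracy-based log evidence of one channel pair at the posterior mean.

    Evaluates ``F_ij = -1/2 e' Pi e + 1/2 ln|Pi|`` on the features of the
    requested pair, with the fitted block precision.  The Gaussian constant
    is omitted (it is shared by models of equal feature dimension).
    """
    if not fit_result.converged:
        raise ValueError("reduced_log_evidence requires a converged fit")
    i, j = sorted(channel_pair)
    if not (0 <= i < data.n_channels and 0 <= j < data.n_channels):
        raise ValueError(f"invalid channel pair {channel_pair}")
    label = f"auto_{i}" if i == j else f"cross_{i}_{j}"
    scaled = CrossSpectralData(
        csd=data.csd * fit_result.data_scale, freqs=data.freqs,
        n_epochs=data.n_epochs, fs=data.fs,
    )
    obs = features_from_csd(scaled)
    pred = features_from_csd(fit_result.predicted_csd)
    b = fit_result.block_labels.index(label)
    sl = obs.block_slices[obs.block_labels.index(label)]
    prec = np.full(sl.stop - sl.start, np.exp(fit_result.lambdas[b]))
    return log_likelihood(
        obs.values[sl], pred.values[sl], prec, include_const=False
    )


@dataclass
class ComparisonReport:
    """Free energies and reduced evidences of the two candidate hierarchies."""

    free_energy: dict[str, float]
    accuracy: dict[str, float]
    complexity: dict[str, float]
    reduced_cross: dict[str, float]
    converged: dict[str, bool]
    delta_free_energy: float          # veridical - reversed
    delta_reduced_cross: float
    selected: str                     # 'veridical' | 'reversed' | 'indistinguishable'
    odds_ratio: float
    partial: bool                     # True if either fit failed to converge

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=float))


def compare_models(
    data: CrossSpectralData,
    prior: PriorDensity | None = None,
    *,
    directions: tuple[str, str] = (VERIDICAL, REVERSED),
    cross_pair: tuple[int, int] = (0, 1),
    **fit_kwargs,
) -> ComparisonReport:
    """Fit both hierarchies to the same data and compare their evidence.

    Selection is by full free energy; differences below ``TIE_TOLERANCE``
    are reported as indistinguishable.  Reduced (accuracy-only) evidence on
    the cross-spectral block is reported alongside.
    """
    fits = {d: fit(data, prior, d, **fit_kwargs) for d in directions}
    red = {}
    for d, f in fits.items():
        try:
            red[d] = reduced_log_evidence(f, data, cross_pair)
        except ValueError:
            red[d] = float("nan")
    d0, d1 = directions
    dF = fits[d0].free_energy - fits[d1].free_energy
    if abs(dF) < TIE_TOLERANCE:
        selected = "indistinguishable"
    else:
        selected = d0 if dF > 0 else d1
    return ComparisonReport(
        free_energy={d: fits[d].free_energy for d in directions},
        accuracy={d: fits[d].accuracy for d in directions},
        complexity={d: fits[d].complexity for d in directions},
        reduced_cross=red,
        converged={d: fits[d].converged for d in directions},
        delta_free_energy=dF,
        delta_reduced_cross=red[d0] - red[d1],
        selected=selected,
        odds_ratio=log_evidence_to_odds(abs(dF)),
        partial=not all(fits[d].converged for d in directions),
    )


def pool_comparisons(reports: Sequence[ComparisonReport]) -> dict:
    """Pool evidence across datasets by summing log evidences."""
    directions = list(reports[0].free_energy)
    total_F = {d: float(sum(r.free_energy[d] for r in reports)) for d in directions}
    total_red = {d: float(sum(r.reduced_cross[d] for r in reports)) for d in directions}
    dF = total_F[directions[0]] - total_F[directions[1]]
    if abs(dF) < TIE_TOLERANCE:
        selected = "indistinguishable"
    else:
        selected = directions[0] if dF > 0 else directions[1]
    n_correct = sum(r.selected == directions[0] for r in reports)
    return {
        "pooled_free_energy": total_F,
        "pooled_reduced_cross": total_red,
        "delta_free_energy": dF,
        "selected": selected,
        "n_selected_first": n_correct,
        "n_datasets": len(reports),
    }
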