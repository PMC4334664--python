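"""Synthetic data with the statistical structure the analysis assumes.

Two generators are provided:

* CSD-level datasets — the spectral forward prediction mixed with complex,
  Hermitian-preserving Gaussian noise whose total variance is set by a log
  precision ``lambda``: signal variance / noise variance = exp(lambda)
  (so log precision plays the role of a signal-to-noise ratio in nats).
* time-domain simulations — Euler-Maruyama integration of the linearized
  (or, optionally, full nonlinear) stochastic dynamics driven by colored
  endogenous fluctuations with the parameterized spectra.  These serve as
  an independent oracle for the analytic spectral predictions, which rest
  on an expansion around the fixed point.

Colored drives are produced by frequency-domain amplitude shaping of
white Gaussian noise (circulant embedding), so their one-sided power
spectral densities match the parameterized forms exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import EpochedTimeSeries
from .inversion import features_from_csd, features_to_csd
from .network import (
    N_POP,
    N_SOURCES,
    CMCParameters,
    Population,
    PriorDensity,
    VERIDICAL,
    build_network,
    sigmoid_rate,
)
from .spectral import (
    SPECTRAL_FLOOR,
    CrossSpectralData,
    UnstableModelError,
    is_stable,
    observation_matrix,
    predict_csd,
)

__all__ = [
    "SyntheticDataset",
    "sample_prior",
    "generate_dataset",
    "colored_noise",
    "simulate_timeseries",
]

#: Log precisions at or above this cap are treated as exactly noiseless.
LOG_PRECISION_CAP = 30.0


@dataclass
class SyntheticDataset:
    """A noisy synthetic CSD together with its generative description."""

    params: CMCParameters
    direction: str
    data: CrossSpectralData
    log_precision: float
    seed: int

    def noiseless(self) -> CrossSpectralData:
        """Recompute the noise-free prediction from the stored parameters."""
        return predict_csd(self.params, self.data.freqs, self.direction)


def sample_prior(
    prior: PriorDensity,
    seed: int | None = None,
    *,
    direction: str = VERIDICAL,
    max_attempts: int = 100,
    rng: np.random.Generator | None = None,
) -> CMCParameters:
    """Draw ``theta ~ N(0, v)``, rejecting dynamically unstable draws."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    sd = np.sqrt(prior.variances)
    for _ in range(max_attempts):
        theta = rng.normal(0.0, 1.0, size=prior.n_params) * sd
        params = CMCParameters(theta, prior)
        if is_stable(params, direction):
            return params
    raise UnstableModelError(
        f"no stable prior draw within {max_attempts} attempts"
    )


def generate_dataset(
    params: CMCParameters,
    freqs: np.ndarray,
    log_precision: float,
    seed: int | None = None,
    *,
    direction: str = VERIDICAL,
) -> SyntheticDataset:
    """Model prediction plus complex noise at the stated log precision.

    The noise is Gaussian on the real data features (which preserves the
    Hermitian structure of the matrices), with total variance equal to the
    total signal variance divided by ``exp(log_precision)``.  Per-feature
    variance is allocated proportionally to the mean signal power at that
    feature's frequency, so relative SNR is roughly constant across the
    spectrum.
    """
    if np.isnan(log_precision) or log_precision == -np.inf:
        raise ValueError("log precision must be finite or +inf")
    clean = predict_csd(params, freqs, direction)
    if log_precision >= LOG_PRECISION_CAP:
        return SyntheticDataset(
            params=params, direction=direction,
            data=CrossSpectralData(csd=clean.csd.copy(), freqs=clean.freqs),
            log_precision=float(log_precision),
            seed=-1 if seed is None else int(seed),
        )
    feats = features_from_csd(clean)
    rng = np.random.default_rng(seed)

    signal_var = float(np.sum(feats.values**2))
    noise_var_total = signal_var / np.exp(log_precision)

    # per-frequency mean signal power, broadcast to the feature layout
    power_f = np.mean(np.abs(clean.csd) ** 2, axis=(1, 2))  # (F,)
    weights = np.empty_like(feats.values)
    F = feats.n_freqs
    for (i, j), sl in zip(feats.pairs, feats.block_slices):
        w = power_f
        weights[sl] = w if i == j else np.concatenate([w, w])
    weights = weights / weights.sum()
    sd = np.sqrt(noise_var_total * weights)
    noisy_values = feats.values + rng.normal(0.0, 1.0, size=feats.values.size) * sd

    noisy = CrossSpectralData(
        csd=features_to_csd(noisy_values, clean.freqs, clean.n_channels),
        freqs=clean.freqs,
    )
    return SyntheticDataset(
        params=params,
        direction=direction,
        data=noisy,
        log_precision=log_precision,
        seed=-1 if seed is None else int(seed),
    )


def colored_noise(
    psd: np.ndarray,
    freqs_native: np.ndarray,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Real time series whose one-sided PSD matches ``psd`` in expectation.

    ``psd`` is sampled on ``freqs_native = rfftfreq(n_samples, 1/fs)``
    (the DC entry is ignored and set to zero power).
    """
    amp = np.sqrt(np.maximum(psd, 0.0) * fs * n_samples / 2.0)
    z = rng.normal(size=freqs_native.size) + 1j * rng.normal(size=freqs_native.size)
    X = amp * z / np.sqrt(2.0)
    X[0] = 0.0
    if n_samples % 2 == 0:
        X[-1] = X[-1].real * np.sqrt(2.0)
    return np.fft.irfft(X, n=n_samples)


def _power_law(freqs: np.ndarray, amp: float, exponent: float) -> np.ndarray:
    out = np.zeros_like(freqs)
    pos = freqs > 0
    out[pos] = amp * (freqs[pos] ** (-exponent) + SPECTRAL_FLOOR)
    return out


def simulate_timeseries(
    params: CMCParameters,
    duration: float,
    fs: float = 2000.0,
    seed: int | None = None,
    *,
    direction: str = VERIDICAL,
    linearized: bool = True,
    input_scale: float = 1.0,
    epoch_length_s: float = 0.5,
    observation_noise: bool = True,
    blowup_norm: float = 1e6,
) -> EpochedTimeSeries:
    """Stochastic simulation of the two-source network, chopped into epochs.

    The linearized dynamics (default) are integrated with an exponential
    Euler-Maruyama scheme at ``dt = 1/fs`` (0.5 ms by default): the
    homogeneous intrinsic part advances by its exact matrix exponential,
    while the colored drive and the conduction-delayed extrinsic input are
    held constant over each step (first-order hold).  This removes the
    stiffness bias a plain Euler step incurs at the 2 ms synaptic time
    constants.  The full nonlinear dynamics (``linearized=False``) use a
    plain Euler-Maruyama step.  The extrinsic delay is handled with a
    state ring buffer in both cases.  Endogenous drives and observation
    noise are colored to the parameterized spectra; ``input_scale``
    multiplies the drive amplitude (useful for probing the linearization
    limit of the nonlinear model).
    """
    if not is_stable(params, direction):
        raise UnstableModelError("refusing to simulate an unstable parameterization")
    rng = np.random.default_rng(seed)
    structure = build_network(params, direction)
    dt = 1.0 / fs
    n_steps = int(round(duration * fs))
    n = structure.n_populations

    freqs_native = np.fft.rfftfreq(n_steps, dt)
    Gu = np.stack(
        [
            _power_law(
                freqs_native,
                params.value(f"u_amp_s{s}"),
                params.value(f"u_exp_s{s}"),
            )
            for s in range(N_SOURCES)
        ],
        axis=1,
    )
    drive = np.stack(
        [
            colored_noise(Gu[:, s], freqs_native, n_steps, fs, rng)
            for s in range(N_SOURCES)
        ],
        axis=1,
    ) * input_scale  # (n_steps, 2)

    k = structure.kappa
    k2 = k**2
    rho = structure.slope / 4.0
    d_steps = max(int(round(structure.delay_extrinsic_s * fs)), 0)
    ss_idx = np.array([N_POP * s + Population.SS for s in range(N_SOURCES)])

    V = np.empty((n_steps, n))
    if linearized:
        from scipy.linalg import expm

        # state x = [v, w]; A holds the intrinsic (undelayed) dynamics,
        # Ad the delayed extrinsic coupling into w_dot
        A = np.zeros((2 * n, 2 * n))
        A[:n, n:] = np.eye(n)
        A[n:, :n] = k[:, None] * (rho * structure.weights_intrinsic) - np.diag(k2)
        A[n:, n:] = -2.0 * np.diag(k)
        Ad = np.zeros((2 * n, 2 * n))
        Ad[n:, :n] = k[:, None] * (rho * structure.weights_extrinsic)
        E = expm(A * dt)
        M1 = np.linalg.solve(A, E - np.eye(2 * n))  # integrated input propagator

        Bu = np.zeros((n_steps, 2 * n))
        Bu[:, n + ss_idx] = k[ss_idx] * drive

        x = np.zeros(2 * n)
        hist = np.zeros((d_steps + 1, 2 * n))
        for t in range(n_steps):
            xd = hist[(t - d_steps) % (d_steps + 1)] if d_steps else x
            x = E @ x + M1 @ (Ad @ xd + Bu[t])
            if d_steps:
                hist[t % (d_steps + 1)] = x
            V[t] = x[:n]
            if t % 4096 == 0 and (
                np.abs(x).max() > blowup_norm or not np.isfinite(x).all()
            ):
                raise RuntimeError(
                    f"numerical blow-up at t={t * dt:.3f}s "
                    f"(|x|max={np.abs(x).max():.2e})"
                )
    else:
        Win_nl = structure.weights_intrinsic
        Wext_nl = structure.weights_extrinsic
        v = np.zeros(n)
        w = np.zeros(n)
        hist = np.zeros((d_steps + 1, n))
        for t in range(n_steps):
            vd = hist[(t - d_steps) % (d_steps + 1)] if d_steps else v
            u = Win_nl @ sigmoid_rate(v, structure.slope) + Wext_nl @ sigmoid_rate(
                vd, structure.slope
            )
            u[ss_idx] += drive[t]
            dv = w
            dw = k * u - 2.0 * k * w - k2 * v
            v = v + dt * dv
            w = w + dt * dw
            if d_steps:
                hist[t % (d_steps + 1)] = v
            V[t] = v
            if t % 4096 == 0 and (
                np.abs(v).max() > blowup_norm or not np.isfinite(v).all()
            ):
                raise RuntimeError(
                    f"numerical blow-up at t={t * dt:.3f}s "
                    f"(|v|max={np.abs(v).max():.2e})"
                )
    if np.abs(V).max() > blowup_norm or not np.isfinite(V).all():
        raise RuntimeError("numerical blow-up during simulation")

    M = observation_matrix(params)
    Y = V @ M.T  # (n_steps, C)

    if observation_noise:
        spec_amp = [
            _power_law(
                freqs_native,
                params.value(f"n_amp_ch{c}"),
                params.value(f"n_exp_ch{c}"),
            )
            for c in range(N_SOURCES)
        ]
        for c in range(N_SOURCES):
            Y[:, c] += colored_noise(spec_amp[c], freqs_native, n_steps, fs, rng)
        common = colored_noise(
            _power_law(freqs_native, params.value("c_amp"), params.value("c_exp")),
            freqs_native,
            n_steps,
            fs,
            rng,
        )
        Y += common[:, None]

    samples_per_epoch = int(round(epoch_length_s * fs))
    n_epochs = n_steps // samples_per_epoch
    Y = Y[: n_epochs * samples_per_epoch]
    data = Y.reshape(n_epochs, samples_per_epoch, N_SOURCES).transpose(0, 2, 1)
    return EpochedTimeSeries(data=data, fs=fs)
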