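"""Spectral forward model: linearization, transfer functions, predicted CSD.

The network is linearized at its fixed point (the origin, given the
centered sigmoid).  The linearized system has frequency response

    T(omega) = L (1j*omega*I - J(omega))^-1 B

where ``J(omega)`` is the Jacobian with frequency-domain phase factors
``exp(-1j*omega*delay)`` on the extrinsic couplings (exact for a linear
delay system), ``B`` maps per-source endogenous fluctuations into the
spiny stellate states and ``L`` selects population depolarizations.  The
predicted channel cross-spectral density is

    G_y(w) = M T(w) G_u(w) T(w)^H M^H + G_s(w) + G_c(w)

with observation mapping ``M`` (electrode gain x population contribution
weights), diagonal endogenous-fluctuation spectra ``G_u``, diagonal
channel-specific noise ``G_s`` and a rank-1 (all-channel-pairs) common
noise term ``G_c``.  Fluctuation and noise spectra are power laws
``amplitude * (f^-exponent + floor)`` with a small white floor for
numerical stability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .network import (
    ELECTRODE_GAIN_UNIT,
    N_POP,
    N_SOURCES,
    CMCParameters,
    ConnectivityStructure,
    Population,
    VERIDICAL,
    build_network,
    jacobian,
    state_derivatives,
)

__all__ = [
    "default_grid",
    "CrossSpectralData",
    "TransferFunctionSet",
    "UnstableModelError",
    "find_fixed_point",
    "is_stable",
    "transfer_functions",
    "fluctuation_spectra",
    "noise_spectra",
    "predict_csd",
    "source_population_csd",
    "population_csd",
    "denoised_csd",
]

#: White floor added (relative to the amplitude) to every power-law
#: spectral density for numerical stability.
SPECTRAL_FLOOR = 1e-6


class UnstableModelError(ValueError):
    """Raised when the linearization has an eigenvalue with Re >= 0."""


def default_grid(fmin: float = 1.0, fmax: float = 100.0, df: float = 1.0) -> np.ndarray:
    """Frequency grid in Hz (strictly increasing, positive)."""
    grid = np.arange(fmin, fmax + 0.5 * df, df, dtype=float)
    return validate_grid(grid)


def validate_grid(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValueError("frequency grid must be a nonempty 1-D array")
    if np.any(freqs <= 0) or not np.all(np.isfinite(freqs)):
        raise ValueError("frequencies must be positive and finite")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    return freqs


@dataclass
class CrossSpectralData:
    """Complex cross-spectral density matrices on a frequency grid.

    ``csd[k]`` is the (channels x channels) Hermitian matrix at
    ``freqs[k]``; diagonals are real and nonnegative (one-sided spectral
    density units, power / Hz).
    """

    csd: np.ndarray            # (F, C, C) complex
    freqs: np.ndarray          # (F,) Hz
    n_epochs: int = 0
    fs: float = 0.0
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.freqs = validate_grid(self.freqs)
        self.csd = np.asarray(self.csd, dtype=complex)
        if self.csd.ndim != 3 or self.csd.shape[0] != self.freqs.size:
            raise ValueError("csd must have shape (F, C, C) matching freqs")
        if self.csd.shape[1] != self.csd.shape[2]:
            raise ValueError("csd matrices must be square")
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{c}" for c in range(self.n_channels))

    @property
    def n_channels(self) -> int:
        return self.csd.shape[1]

    def is_hermitian(self, tol: float = 1e-10) -> bool:
        herm = np.abs(self.csd - np.conj(np.swapaxes(self.csd, 1, 2))).max()
        diag = np.diagonal(self.csd, axis1=1, axis2=2)
        return bool(herm <= tol and diag.imag.max(initial=0.0) <= tol
                    and diag.real.min(initial=0.0) >= -tol)

    def autospectrum(self, channel: int = 0) -> np.ndarray:
        return self.csd[:, channel, channel].real

    # ---- serialization ---------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        """Write datasets /csd_re, /csd_im, /freq and JSON metadata attrs."""
        with h5py.File(path, "w") as f:
            f.create_dataset("csd_re", data=self.csd.real)
            f.create_dataset("csd_im", data=self.csd.imag)
            f.create_dataset("freq", data=self.freqs)
            f.attrs["meta"] = json.dumps(
                {
                    "n_epochs": int(self.n_epochs),
                    "fs": float(self.fs),
                    "channel_labels": list(self.channel_labels),
                }
            )

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "CrossSpectralData":
        with h5py.File(path, "r") as f:
            csd = f["csd_re"][()] + 1j * f["csd_im"][()]
            freqs = f["freq"][()]
            meta = json.loads(f.attrs["meta"])
        return cls(
            csd=csd,
            freqs=freqs,
            n_epochs=meta["n_epochs"],
            fs=meta["fs"],
            channel_labels=tuple(meta["channel_labels"]),
        )

    def to_csv_bundle(self, directory: str | Path) -> None:
        """Plain-text bundle for small cases: one CSV per channel pair."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        C = self.n_channels
        header = "freq_hz,real,imag"
        for i in range(C):
            for j in range(i, C):
                rows = np.column_stack(
                    [self.freqs, self.csd[:, i, j].real, self.csd[:, i, j].imag]
                )
                np.savetxt(
                    directory / f"csd_{i}_{j}.csv",
                    rows,
                    delimiter=",",
                    header=header,
                    comments="",
                )
        (directory / "meta.json").write_text(
            json.dumps(
                {
                    "n_channels": C,
                    "n_epochs": int(self.n_epochs),
                    "fs": float(self.fs),
                    "channel_labels": list(self.channel_labels),
                }
            )
        )

    @classmethod
    def from_csv_bundle(cls, directory: str | Path) -> "CrossSpectralData":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        C = meta["n_channels"]
        first = np.loadtxt(directory / "csd_0_0.csv", delimiter=",", skiprows=1)
        freqs = first[:, 0]
        csd = np.zeros((freqs.size, C, C), dtype=complex)
        for i in range(C):
            for j in range(i, C):
                rows = np.loadtxt(directory / f"csd_{i}_{j}.csv", delimiter=",", skiprows=1)
                csd[:, i, j] = rows[:, 1] + 1j * rows[:, 2]
                if i != j:
                    csd[:, j, i] = np.conj(csd[:, i, j])
        return cls(
            csd=csd,
            freqs=freqs,
            n_epochs=meta["n_epochs"],
            fs=meta["fs"],
            channel_labels=tuple(meta["channel_labels"]),
        )


@dataclass(frozen=True)
class TransferFunctionSet:
    """Complex gains from each source's endogenous input to each population.

    ``tf[k, 4*s + p, m]`` is the gain at ``freqs[k]`` from the input of
    source ``m`` to the depolarization of population ``p`` of source ``s``.
    Cross-source entries are identically zero when extrinsic gains vanish.
    """

    tf: np.ndarray     # (F, 8, 2) complex
    freqs: np.ndarray  # (F,)
    direction: str

    def entry(self, target_source: int, population: Population, input_source: int) -> np.ndarray:
        return self.tf[:, N_POP * target_source + population, input_source]


def find_fixed_point(
    params: CMCParameters,
    direction: str = VERIDICAL,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> np.ndarray:
    """Fixed point of the noise-free dynamics.

    With the centered sigmoid the origin is a fixed point by construction;
    a damped-Newton refinement is still run so that non-centered variants
    would be handled, and the residual derivative norm is verified to be
    below ``tol``.
    """
    structure = build_network(params, direction)
    x = np.zeros(2 * structure.n_populations)
    for _ in range(max_iter):
        f = state_derivatives(x, structure)
        if np.linalg.norm(f) < tol:
            return x
        J = _numerical_jacobian(structure, x)
        x = x - np.linalg.solve(J, f)
    f = state_derivatives(x, structure)
    if np.linalg.norm(f) >= tol:
        raise UnstableModelError(
            "no fixed point found within iteration budget "
            f"(residual {np.linalg.norm(f):.2e})"
        )
    return x


def _numerical_jacobian(structure: ConnectivityStructure, x: np.ndarray, h: float = 1e-6):
    n = x.size
    J = np.zeros((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        J[:, i] = (
            state_derivatives(x + e, structure) - state_derivatives(x - e, structure)
        ) / (2 * h)
    return J


def is_stable(params: CMCParameters, direction: str = VERIDICAL) -> bool:
    """True if the delay-free Jacobian has all eigenvalues with Re < 0."""
    structure = build_network(params, direction)
    return bool(np.linalg.eigvals(jacobian(structure)).real.max() < 0)


def _batched_resolvent(structure: ConnectivityStructure, freqs: np.ndarray) -> np.ndarray:
    """(1j*w*I - J(w))^-1 B for all grid frequencies; shape (F, 16, 2)."""
    n = structure.n_populations
    rho = structure.slope / 4.0
    k = structure.kappa
    omega = 2.0 * np.pi * freqs
    F = freqs.size

    A = np.zeros((F, 2 * n, 2 * n), dtype=complex)
    A[:, :n, n:] = -np.eye(n)
    base = k[:, None] * (rho * structure.weights_intrinsic) - np.diag(k**2)
    ext = k[:, None] * (rho * structure.weights_extrinsic)
    phase = np.exp(-1j * omega * structure.delay_extrinsic_s)
    A[:, n:, :n] = -(base[None, :, :] + ext[None, :, :] * phase[:, None, None])
    A[:, n:, n:] = 2.0 * np.diag(k)[None, :, :]
    A += 1j * omega[:, None, None] * np.eye(2 * n)[None, :, :]

    B = np.zeros((2 * n, N_SOURCES))
    for s in range(N_SOURCES):
        B[n + N_POP * s + Population.SS, s] = k[N_POP * s + Population.SS]
    return np.linalg.solve(A, np.broadcast_to(B, (F, 2 * n, N_SOURCES)).copy())


def transfer_functions(
    params: CMCParameters,
    freqs: np.ndarray,
    direction: str = VERIDICAL,
) -> TransferFunctionSet:
    """Frequency-resolved gains from endogenous inputs to depolarizations.

    Raises :class:`UnstableModelError` if the linearization is unstable.
    """
    freqs = validate_grid(freqs)
    structure = build_network(params, direction)
    if np.linalg.eigvals(jacobian(structure)).real.max() >= 0:
        raise UnstableModelError("Jacobian has an eigenvalue with nonnegative real part")
    n = structure.n_populations
    resolvent = _batched_resolvent(structure, freqs)
    return TransferFunctionSet(tf=resolvent[:, :n, :], freqs=freqs, direction=direction)


def fluctuation_spectra(params: CMCParameters, freqs: np.ndarray) -> np.ndarray:
    """One-sided spectral densities of the endogenous inputs, (F, 2)."""
    freqs = validate_grid(freqs)
    out = np.empty((freqs.size, N_SOURCES))
    for s in range(N_SOURCES):
        amp = params.value(f"u_amp_s{s}")
        b = params.value(f"u_exp_s{s}")
        out[:, s] = amp * (freqs ** (-b) + SPECTRAL_FLOOR)
    return out


def noise_spectra(params: CMCParameters, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Channel-specific (F, C) and channel-unspecific (F,) noise densities."""
    freqs = validate_grid(freqs)
    spec = np.empty((freqs.size, N_SOURCES))
    for c in range(N_SOURCES):
        amp = params.value(f"n_amp_ch{c}")
        b = params.value(f"n_exp_ch{c}")
        spec[:, c] = amp * (freqs ** (-b) + SPECTRAL_FLOOR)
    common = params.value("c_amp") * (freqs ** (-params.value("c_exp")) + SPECTRAL_FLOOR)
    return spec, common


def _exact_hermitian(csd: np.ndarray) -> np.ndarray:
    """Copy the upper triangle onto the lower and realify the diagonal,
    making the Hermitian structure exact rather than round-off-close."""
    C = csd.shape[1]
    idx = np.arange(C)
    csd[:, idx, idx] = csd[:, idx, idx].real
    for i in range(C):
        for j in range(i + 1, C):
            csd[:, j, i] = np.conj(csd[:, i, j])
    return csd


def observation_matrix(params: CMCParameters, *, unit_gain: bool = False) -> np.ndarray:
    """Mapping (C, 8) from population depolarizations to channel signals.

    Channel ``c`` observes source ``c`` through the population contribution
    weights scaled by the electrode gain.  With ``unit_gain`` the electrode
    gain (and its unit scale) is set to one, leaving only the weights.
    """
    weights = params.obs_weights()
    gains = (
        np.ones(N_SOURCES)
        if unit_gain
        else ELECTRODE_GAIN_UNIT * params.electrode_gains()
    )
    M = np.zeros((N_SOURCES, N_POP * N_SOURCES))
    for c in range(N_SOURCES):
        M[c, N_POP * c : N_POP * (c + 1)] = gains[c] * weights
    return M


def predict_csd(
    params: CMCParameters,
    freqs: np.ndarray,
    direction: str = VERIDICAL,
    *,
    include_noise: bool = True,
    unit_gain: bool = False,
) -> CrossSpectralData:
    """Predicted complex CSD at the channels.

    ``G_y = M T G_u T^H M^H (+ G_s + G_c)``; Hermitian with nonnegative
    diagonal at every frequency by construction.
    """
    tfs = transfer_functions(params, freqs, direction)
    Gu = fluctuation_spectra(params, freqs)
    M = observation_matrix(params, unit_gain=unit_gain)
    MT = np.einsum("cn,fnm->fcm", M, tfs.tf)  # (F, C, 2)
    csd = np.einsum("fcm,fm,fdm->fcd", MT, Gu, np.conj(MT))
    if include_noise:
        spec, common = noise_spectra(params, freqs)
        idx = np.arange(N_SOURCES)
        csd[:, idx, idx] += spec
        csd += common[:, None, None]
    csd = _exact_hermitian(csd)
    return CrossSpectralData(csd=csd, freqs=tfs.freqs)


def source_population_csd(
    params: CMCParameters,
    freqs: np.ndarray,
    source: int,
    direction: str = VERIDICAL,
) -> CrossSpectralData:
    """Noise-free CSD among the four populations of one source (F, 4, 4)."""
    if source not in range(N_SOURCES):
        raise ValueError(f"source must be in {list(range(N_SOURCES))}")
    tfs = transfer_functions(params, freqs, direction)
    Gu = fluctuation_spectra(params, freqs)
    T = tfs.tf[:, N_POP * source : N_POP * (source + 1), :]
    csd = _exact_hermitian(np.einsum("fpm,fm,fqm->fpq", T, Gu, np.conj(T)))
    return CrossSpectralData(
        csd=csd,
        freqs=tfs.freqs,
        channel_labels=tuple(p.name for p in Population),
    )


def population_csd(
    params: CMCParameters,
    freqs: np.ndarray,
    population: Population,
    source: int,
    direction: str = VERIDICAL,
) -> CrossSpectralData:
    """Noise-free autospectrum of one population of one source.

    The observation vector is an indicator on the requested population
    (unit gain, zero noise), the selective-sampling counterpart of the
    channel observation model.
    """
    full = source_population_csd(params, freqs, source, direction)
    p = int(population)
    return CrossSpectralData(
        csd=full.csd[:, p : p + 1, p : p + 1],
        freqs=full.freqs,
        channel_labels=(Population(p).name,),
    )


def denoised_csd(fit, freqs: np.ndarray | None = None) -> CrossSpectralData:
    """Posterior-mean CSD with noise removed and electrode gains at unity.

    Reconstructs what would have been observed in the absence of
    channel-specific and channel-unspecific noise.
    """
    if not fit.converged:
        raise ValueError("denoised_csd requires a converged fit")
    params = fit.posterior_params()
    grid = fit.freqs if freqs is None else freqs
    return predict_csd(
        params, grid, fit.direction, include_noise=False, unit_gain=True
    )
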