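"""Cross-spectral density estimation from epoched multichannel recordings.

Mirrors the data-feature pathway used for local field potential analysis:
non-overlapping short epochs (0.5 s by default), per-epoch z-scoring, and
a multitaper (DPSS) cross-spectral estimator averaged over epochs and
tapers.  Bipolar re-referencing, line-noise subtraction and a variance
threshold for artifact rejection are provided as pure functions with
conservative defaults; they form the preprocessing contract for real
recordings and are not needed for synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy.signal import windows

from .spectral import CrossSpectralData, validate_grid

__all__ = [
    "EpochedTimeSeries",
    "preprocess_epochs",
    "estimate_csd",
    "bipolar_rereference",
    "subtract_line_noise",
    "reject_artifacts",
]

logger = logging.getLogger(__name__)

DEFAULT_EPOCH_LENGTH_S = 0.5


@dataclass
class EpochedTimeSeries:
    """Array of epochs x channels x samples at a fixed sampling rate."""

    data: np.ndarray  # (E, C, S)
    fs: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (epochs, channels, samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_length_s(self) -> float:
        return self.n_samples / self.fs

    # ---- HDF5 round trip -------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("fs", data=float(self.fs))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EpochedTimeSeries":
        with h5py.File(path, "r") as f:
            return cls(data=f["data"][()], fs=float(f["fs"][()]))


def preprocess_epochs(
    raw: EpochedTimeSeries, *, zero_variance_tol: float = 1e-12
) -> EpochedTimeSeries:
    """Per-epoch, per-channel z-scoring (mean 0, unit variance).

    Epochs containing a zero-variance channel carry no spectral
    information and are dropped with a log entry.  Idempotent up to
    floating-point error.
    """
    if raw.n_epochs < 2:
        raise ValueError("need at least 2 epochs")
    std = raw.data.std(axis=2, ddof=0)
    good = np.all(std > zero_variance_tol, axis=1)
    if not np.all(good):
        logger.warning(
            "dropping %d epoch(s) with zero-variance channels", int((~good).sum())
        )
    data = raw.data[good]
    mean = data.mean(axis=2, keepdims=True)
    std = data.std(axis=2, ddof=0, keepdims=True)
    return EpochedTimeSeries(data=(data - mean) / std, fs=raw.fs)


def estimate_csd(
    epochs: EpochedTimeSeries,
    freqs: np.ndarray,
    *,
    time_bandwidth: float = 2.0,
    n_tapers: int = 3,
) -> CrossSpectralData:
    """Multitaper cross-spectral density averaged over epochs and tapers.

    Returns one-sided spectral densities (power / Hz) interpolated onto
    the requested frequency grid.  The epoch length must resolve the grid
    spacing and the grid must lie below Nyquist.
    """
    freqs = validate_grid(freqs)
    S = epochs.n_samples
    fs = epochs.fs
    df_native = fs / S
    if np.min(np.diff(freqs)) < df_native - 1e-9:
        raise ValueError(
            f"epoch length {epochs.epoch_length_s:.3g}s cannot resolve grid spacing "
            f"{np.min(np.diff(freqs)):.3g} Hz (native resolution {df_native:.3g} Hz)"
        )
    if freqs[-1] > fs / 2:
        raise ValueError("frequency grid extends beyond Nyquist")

    tapers = windows.dpss(S, time_bandwidth, Kmax=n_tapers)  # (K, S), unit norm
    # tapered FFTs: (E, K, C, S//2+1)
    X = np.fft.rfft(epochs.data[:, None, :, :] * tapers[None, :, None, :], axis=-1)
    native = np.fft.rfftfreq(S, 1.0 / fs)
    # one-sided density: 2/fs, except DC and Nyquist
    scale = np.full(native.size, 2.0 / fs)
    scale[0] = 1.0 / fs
    if S % 2 == 0:
        scale[-1] = 1.0 / fs
    csd_native = np.einsum("ekcf,ekdf->fcd", X, np.conj(X)) / (
        epochs.n_epochs * n_tapers
    )
    csd_native *= scale[:, None, None]

    C = epochs.n_channels
    out = np.empty((freqs.size, C, C), dtype=complex)
    for i in range(C):
        for j in range(C):
            out[:, i, j] = np.interp(freqs, native, csd_native[:, i, j].real) + 1j * (
                np.interp(freqs, native, csd_native[:, i, j].imag)
            )
    # enforce exact Hermitian structure against interpolation round-off
    out = 0.5 * (out + np.conj(np.swapaxes(out, 1, 2)))
    return CrossSpectralData(
        csd=out, freqs=freqs, n_epochs=epochs.n_epochs, fs=fs
    )


# ---------------------------------------------------------------------------
# preprocessing contract for real recordings
# ---------------------------------------------------------------------------

def bipolar_rereference(
    epochs: EpochedTimeSeries, pairs: list[tuple[int, int]]
) -> EpochedTimeSeries:
    """Differences of neighboring electrodes; removes the common reference."""
    data = np.stack(
        [epochs.data[:, a, :] - epochs.data[:, b, :] for a, b in pairs], axis=1
    )
    return EpochedTimeSeries(data=data, fs=epochs.fs)


def subtract_line_noise(
    epochs: EpochedTimeSeries, line_freqs: tuple[float, ...] = (50.0, 100.0, 150.0)
) -> EpochedTimeSeries:
    """Remove least-squares sinusoid fits at the power-line harmonics."""
    t = np.arange(epochs.n_samples) / epochs.fs
    basis = []
    for f in line_freqs:
        basis += [np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)]
    A = np.stack(basis, axis=1)  # (S, 2L)
    pinv = np.linalg.pinv(A)
    flat = epochs.data.reshape(-1, epochs.n_samples)
    cleaned = flat - (A @ (pinv @ flat.T)).T
    return EpochedTimeSeries(data=cleaned.reshape(epochs.data.shape), fs=epochs.fs)


def reject_artifacts(
    epochs: EpochedTimeSeries, threshold_sd: float = 4.0
) -> EpochedTimeSeries:
    """Drop epochs whose variance is an outlier across the recording."""
    v = epochs.data.var(axis=(1, 2))
    z = (v - v.mean()) / (v.std() + 1e-30)
    keep = np.abs(z) < threshold_sd
    if not np.all(keep):
        logger.warning("rejecting %d artifact epoch(s)", int((~keep).sum()))
    return EpochedTimeSeries(data=epochs.data[keep], fs=epochs.fs)
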