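"""Two-source canonical microcircuit (CMC) network.

Each cortical source (column) contains four neural-mass populations:
spiny stellate cells (SS, granular layer), superficial pyramidal cells
(SPC), inhibitory interneurons (II) and deep pyramidal cells (DPC).
Populations interact through ten signed intrinsic connections and, across
sources, through a forward projection originating in SPC (terminating on
the granular SS population of the higher source) and backward projections
originating in DPC (terminating, with inhibitory effect, on SPC and II of
the lower source).

Every reciprocally connected population pair carries one excitatory and
one inhibitory direction, and all self-connections are inhibitory.  This
anti-symmetry balances excitation and inhibition and guarantees a
fixed-point attractor around which the dynamics can be linearized.

Dynamics follow the synaptic-convolution (Jansen–Rit style) form.  For a
population with synaptic time constant ``T`` (rate constant ``kappa =
1/T``) and total presynaptic drive ``u``::

    v_dot = w
    w_dot = kappa * u - 2 * kappa * w - kappa**2 * v

i.e. the postsynaptic kernel is the alpha function ``kappa * t *
exp(-kappa * t)`` peaking at ``t = T``.  Depolarization ``v`` is turned
into a firing rate by a centered logistic sigmoid, so the origin is a
fixed point of the noise-free system.

All biophysical parameters are stored as log-scaling deviations ``theta``
around the prior means, ``value = prior_mean * exp(theta)``, which keeps
every physical quantity positive; connection signs are part of the fixed
structure, never of the parameters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = [
    "Population",
    "INTRINSIC_CONNECTIONS",
    "TIME_CONSTANT_PRIOR_MS",
    "OBS_WEIGHT_PRIOR",
    "PriorConfig",
    "PriorDensity",
    "CMCParameters",
    "ConnectivityStructure",
    "build_network",
    "reversed_structure",
    "sigmoid_rate",
    "sigmoid_gain",
    "state_derivatives",
]


class Population(enum.IntEnum):
    """The four CMC populations, in canonical order."""

    SS = 0   # spiny stellate (granular input cells)
    SPC = 1  # superficial pyramidal cells
    II = 2   # inhibitory interneurons
    DPC = 3  # deep pyramidal cells


#: Intrinsic connections G1..G10 as (name, source pop, target pop, sign,
#: prior mean).  Signs: G1-G4, G7, G9, G10 inhibitory; G5, G6, G8 excitatory.
INTRINSIC_CONNECTIONS: tuple[tuple[str, Population, Population, int, float], ...] = (
    ("G1", Population.SS, Population.SS, -1, 4.0),
    ("G2", Population.SPC, Population.SS, -1, 4.0),
    ("G3", Population.II, Population.SS, -1, 4.0),
    ("G4", Population.II, Population.II, -1, 4.0),
    ("G5", Population.SS, Population.II, +1, 4.0),
    ("G6", Population.DPC, Population.II, +1, 2.0),
    ("G7", Population.SPC, Population.SPC, -1, 4.0),
    ("G8", Population.SS, Population.SPC, +1, 4.0),
    ("G9", Population.II, Population.DPC, -1, 2.0),
    ("G10", Population.DPC, Population.DPC, -1, 1.0),
)

#: Synaptic time-constant prior means in milliseconds (SS, SPC, II, DPC).
TIME_CONSTANT_PRIOR_MS: tuple[float, ...] = (2.0, 2.0, 16.0, 28.0)

#: Prior contribution of each population to the recorded LFP (SS, SPC, II, DPC).
OBS_WEIGHT_PRIOR: tuple[float, ...] = (0.2, 0.8, 0.0, 0.2)

# Fixed unit-conversion scales.  The tabulated coupling strengths are
# dimensionless ("arbitrary units"); these constants convert them to the
# drive units of the convolution dynamics.  They are part of the fixed
# model structure (like the connection signs) and are not estimated.
INTRINSIC_GAIN_UNIT = 800.0
FORWARD_GAIN_UNIT = 4000.0
BACKWARD_GAIN_UNIT_SPC = 4000.0
BACKWARD_GAIN_UNIT_II = 2000.0
#: Electrode gain unit: scales the dimensionless per-channel gain so that
#: the prior-mean channel autospectrum has O(1) power on the default grid.
ELECTRODE_GAIN_UNIT = 1.0e4

SIGMOID_SLOPE_PRIOR = 2.0 / 3.0
EXTRINSIC_DELAY_PRIOR_MS = 16.0

N_POP = 4
N_SOURCES = 2
N_STATES = 2 * N_POP * N_SOURCES  # 16 for the two-source network

VERIDICAL = "veridical"
REVERSED = "reversed"


@dataclass(frozen=True)
class PriorConfig:
    """Prior log-variances for each parameter class.

    The printed tables give prior means only; variances follow the
    conventions of this model family and are exposed here (and through the
    run configuration) so they can be changed in one place.
    """

    var_intrinsic: float = 1.0 / 8.0
    var_extrinsic: float = 1.0 / 8.0
    var_time_constant: float = 1.0 / 16.0
    var_slope: float = 1.0 / 16.0
    var_delay: float = 1.0 / 32.0
    var_electrode_gain: float = 1.0 / 8.0
    var_obs_weight: float = 1.0 / 16.0
    var_noise_amplitude: float = 1.0 / 8.0
    var_noise_exponent: float = 1.0 / 32.0


def _parameter_table(cfg: PriorConfig) -> list[tuple[str, float, float]]:
    """(name, prior mean of the physical value, prior log-variance)."""
    rows: list[tuple[str, float, float]] = []
    for s in range(N_SOURCES):
        for name, _src, _tgt, _sign, mean in INTRINSIC_CONNECTIONS:
            rows.append((f"{name}_s{s}", mean, cfg.var_intrinsic))
    for s in range(N_SOURCES):
        for p, mean in zip(Population, TIME_CONSTANT_PRIOR_MS):
            rows.append((f"T_{p.name}_s{s}", mean, cfg.var_time_constant))
    rows.append(("a_forward", 1.0, cfg.var_extrinsic))
    rows.append(("a_backward", 1.0, cfg.var_extrinsic))
    rows.append(("delay_ms", EXTRINSIC_DELAY_PRIOR_MS, cfg.var_delay))
    rows.append(("slope", SIGMOID_SLOPE_PRIOR, cfg.var_slope))
    for c in range(N_SOURCES):
        rows.append((f"gain_ch{c}", 1.0, cfg.var_electrode_gain))
    for p, mean in zip(Population, OBS_WEIGHT_PRIOR):
        # j_II has prior mean 0: it stays exactly 0 under log-scaling and
        # is therefore not a free parameter (variance 0).
        rows.append((f"j_{p.name}", mean, cfg.var_obs_weight if mean > 0 else 0.0))
    for s in range(N_SOURCES):
        rows.append((f"u_amp_s{s}", 1.0, cfg.var_noise_amplitude))
        rows.append((f"u_exp_s{s}", 1.0, cfg.var_noise_exponent))
    for c in range(N_SOURCES):
        rows.append((f"n_amp_ch{c}", 0.01, cfg.var_noise_amplitude))
        rows.append((f"n_exp_ch{c}", 1.0, cfg.var_noise_exponent))
    rows.append(("c_amp", 0.01, cfg.var_noise_amplitude))
    rows.append(("c_exp", 1.0, cfg.var_noise_exponent))
    return rows


@dataclass(frozen=True)
class PriorDensity:
    """Gaussian prior over the log-scaling deviations theta.

    ``theta = 0`` everywhere reproduces the printed prior means exactly.
    """

    names: tuple[str, ...]
    prior_means_physical: np.ndarray  # prior mean of value = mean * exp(theta)
    variances: np.ndarray             # log-space prior variances

    @classmethod
    def default(cls, cfg: PriorConfig | None = None) -> "PriorDensity":
        rows = _parameter_table(cfg or PriorConfig())
        names = tuple(r[0] for r in rows)
        means = np.array([r[1] for r in rows], dtype=float)
        variances = np.array([r[2] for r in rows], dtype=float)
        return cls(names, means, variances)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def zero_theta(self) -> np.ndarray:
        return np.zeros(self.n_params)


class CMCParameters:
    """All parameters of the two-source CMC network.

    A thin wrapper around the flat vector of log-scaling deviations; the
    physical value of parameter ``name`` is ``prior_mean * exp(theta)``.
    """

    def __init__(self, theta: np.ndarray, prior: PriorDensity):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (prior.n_params,):
            raise ValueError(
                f"theta has shape {theta.shape}, expected ({prior.n_params},)"
            )
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta must be finite")
        self.theta = theta
        self.prior = prior

    @classmethod
    def from_prior(cls, prior: PriorDensity | None = None) -> "CMCParameters":
        prior = prior or PriorDensity.default()
        return cls(prior.zero_theta(), prior)

    def value(self, name: str) -> float:
        i = self.prior.index(name)
        return float(self.prior.prior_means_physical[i] * np.exp(self.theta[i]))

    def with_theta(self, theta: np.ndarray) -> "CMCParameters":
        return CMCParameters(theta, self.prior)

    def with_updates(self, updates: Mapping[str, float]) -> "CMCParameters":
        """Return a copy with the named theta entries replaced."""
        theta = self.theta.copy()
        for name, v in updates.items():
            theta[self.prior.index(name)] = v
        return CMCParameters(theta, self.prior)

    # convenience accessors -------------------------------------------------
    def intrinsic_gains(self, source: int) -> np.ndarray:
        return np.array(
            [self.value(f"{name}_s{source}") for name, *_ in INTRINSIC_CONNECTIONS]
        )

    def time_constants_s(self, source: int) -> np.ndarray:
        """Synaptic time constants in seconds for one source."""
        return np.array(
            [self.value(f"T_{p.name}_s{source}") for p in Population]
        ) * 1e-3

    def obs_weights(self) -> np.ndarray:
        return np.array([self.value(f"j_{p.name}") for p in Population])

    def electrode_gains(self) -> np.ndarray:
        return np.array([self.value(f"gain_ch{c}") for c in range(N_SOURCES)])


@dataclass(frozen=True)
class ConnectivityStructure:
    """Signed, weighted directed graph over the 8 populations of 2 sources.

    Weights are in physical drive units (table value x unit scale, with the
    fixed sign).  State index of population ``p`` of source ``s`` is
    ``4 * s + p``.
    """

    weights_intrinsic: np.ndarray    # (8, 8) signed, [target, source]
    weights_extrinsic: np.ndarray    # (8, 8) signed, delayed couplings
    kappa: np.ndarray                # (8,) synaptic rate constants 1/s
    slope: float                     # sigmoid slope
    delay_extrinsic_s: float         # conduction delay on extrinsic terms
    direction: str                   # 'veridical' or 'reversed'

    @property
    def n_populations(self) -> int:
        return self.weights_intrinsic.shape[0]

    def signed_adjacency(self) -> np.ndarray:
        """Sign pattern of the full (intrinsic + extrinsic) graph."""
        return np.sign(self.weights_intrinsic + self.weights_extrinsic)


def build_network(
    params: CMCParameters,
    direction: str = VERIDICAL,
    *,
    forward_to_dpc: bool = False,
) -> ConnectivityStructure:
    """Assemble the signed, weighted two-source connectivity.

    Source 0 is the hierarchically lower area (V1-like), source 1 the
    higher area (V4-like).  Under ``veridical`` the forward (SPC-origin)
    projection runs lower -> higher and the backward (DPC-origin)
    projections higher -> lower; ``reversed`` swaps which source sends
    forward vs backward projections while leaving the intrinsic structure
    of each column untouched.

    Parameters
    ----------
    forward_to_dpc:
        If True, the forward projection additionally terminates on the
        deep pyramidal cells of the target source (half the granular
        unit weight), mimicking a less strictly granular termination.
    """
    if direction not in (VERIDICAL, REVERSED):
        raise ValueError(f"unknown direction {direction!r}")

    n = N_POP * N_SOURCES
    W = np.zeros((n, n))
    for s in range(N_SOURCES):
        off = N_POP * s
        for name, src, tgt, sign, _mean in INTRINSIC_CONNECTIONS:
            W[off + tgt, off + src] += (
                sign * INTRINSIC_GAIN_UNIT * params.value(f"{name}_s{s}")
            )

    if direction == VERIDICAL:
        lower, higher = 0, 1
    else:
        lower, higher = 1, 0
    E = _extrinsic_weights(params, lower, higher, forward_to_dpc)

    taus = np.concatenate([params.time_constants_s(s) for s in range(N_SOURCES)])
    if np.any(taus <= 0) or np.any(~np.isfinite(taus)):
        raise ValueError("nonpositive synaptic time constant")
    kappa = 1.0 / taus

    return ConnectivityStructure(
        weights_intrinsic=W,
        weights_extrinsic=E,
        kappa=kappa,
        slope=params.value("slope"),
        delay_extrinsic_s=params.value("delay_ms") * 1e-3,
        direction=direction,
    )


def _extrinsic_weights(
    params: CMCParameters, lower: int, higher: int, forward_to_dpc: bool
) -> np.ndarray:
    if lower == higher:
        raise ValueError("self-extrinsic (source to itself) coupling requested")
    n = N_POP * N_SOURCES
    E = np.zeros((n, n))
    a_f = FORWARD_GAIN_UNIT * params.value("a_forward")
    a_b = params.value("a_backward")
    lo, hi = N_POP * lower, N_POP * higher
    # forward: SPC(lower) -> SS(higher), excitatory
    E[hi + Population.SS, lo + Population.SPC] += a_f
    if forward_to_dpc:
        E[hi + Population.DPC, lo + Population.SPC] += 0.5 * a_f
    # backward: DPC(higher) -> SPC(lower) and -> II(lower), inhibitory
    E[lo + Population.SPC, hi + Population.DPC] -= BACKWARD_GAIN_UNIT_SPC * a_b
    E[lo + Population.II, hi + Population.DPC] -= BACKWARD_GAIN_UNIT_II * a_b
    return E


def reversed_structure(structure: ConnectivityStructure) -> ConnectivityStructure:
    """Swap forward/backward roles of the two sources (an involution)."""
    direction = REVERSED if structure.direction == VERIDICAL else VERIDICAL
    # Reversal only relabels which source is hierarchically lower; the
    # extrinsic weight pattern is the mirror image across the two blocks.
    perm = np.concatenate([np.arange(N_POP, 2 * N_POP), np.arange(N_POP)])
    E = structure.weights_extrinsic[np.ix_(perm, perm)]
    return replace(structure, weights_extrinsic=E, direction=direction)


def sigmoid_rate(v: np.ndarray | float, slope: float = SIGMOID_SLOPE_PRIOR):
    """Centered logistic firing-rate function.

    ``S(v) = 1/(1 + exp(-slope*v)) - 1/2``: monotone, bounded in
    (-1/2, 1/2), antisymmetric about 0, with ``S(0) = 0`` and
    ``S'(0) = slope / 4``.
    """
    return 1.0 / (1.0 + np.exp(-slope * np.asarray(v, dtype=float))) - 0.5


def sigmoid_gain(slope: float) -> float:
    """Linearized sigmoid gain at the fixed point, S'(0) = slope / 4."""
    return slope / 4.0


def state_derivatives(
    state: np.ndarray,
    structure: ConnectivityStructure,
    exogenous_input: np.ndarray | None = None,
    *,
    delayed_voltages: np.ndarray | None = None,
) -> np.ndarray:
    """Time derivative of the full nonlinear network state.

    ``state`` is ``[v(8), w(8)]`` with ``w = dv/dt``.  Exogenous drive (one
    value per source) enters the spiny stellate populations only.  If
    ``delayed_voltages`` is given (length 8), extrinsic couplings read
    presynaptic firing from it (conduction-delayed voltages); otherwise the
    instantaneous voltages are used.
    """
    state = np.asarray(state, dtype=float)
    n = structure.n_populations
    if state.shape != (2 * n,):
        raise ValueError(f"state must have shape ({2 * n},)")
    v, w = state[:n], state[n:]
    rates = sigmoid_rate(v, structure.slope)
    rates_delayed = (
        rates
        if delayed_voltages is None
        else sigmoid_rate(np.asarray(delayed_voltages, dtype=float), structure.slope)
    )
    u = structure.weights_intrinsic @ rates + structure.weights_extrinsic @ rates_delayed
    if exogenous_input is not None:
        drive = np.asarray(exogenous_input, dtype=float)
        if drive.shape != (N_SOURCES,):
            raise ValueError(f"exogenous input must have shape ({N_SOURCES},)")
        for s in range(N_SOURCES):
            u[N_POP * s + Population.SS] += drive[s]
    k = structure.kappa
    return np.concatenate([w, k * u - 2.0 * k * w - k**2 * v])


def jacobian(structure: ConnectivityStructure, omega: float | None = None) -> np.ndarray:
    """Jacobian of the dynamics at the origin.

    With ``omega`` given (rad/s), extrinsic couplings carry the
    frequency-domain conduction-delay phase ``exp(-1j*omega*delay)`` and
    the result is complex; with ``omega=None`` the delay-free (real)
    Jacobian is returned, which is the one used for stability checks.
    """
    n = structure.n_populations
    rho = sigmoid_gain(structure.slope)
    k = structure.kappa
    if omega is None:
        Wtot = rho * (structure.weights_intrinsic + structure.weights_extrinsic)
        J = np.zeros((2 * n, 2 * n))
    else:
        phase = np.exp(-1j * omega * structure.delay_extrinsic_s)
        Wtot = rho * (structure.weights_intrinsic + structure.weights_extrinsic * phase)
        J = np.zeros((2 * n, 2 * n), dtype=complex)
    J[:n, n:] = np.eye(n)
    J[n:, :n] = k[:, None] * Wtot - np.diag(k**2)
    J[n:, n:] = -2.0 * np.diag(k)
    return J
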