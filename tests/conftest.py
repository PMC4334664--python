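"""Shared fixtures.

Expensive computations (the 600 s oracle simulation, a reference model
fit, the selection-accuracy table over log precisions) are session-scoped
so unit tests and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import cmcsd


@pytest.fixture(scope="session")
def prior() -> cmcsd.PriorDensity:
    return cmcsd.PriorDensity.default()


@pytest.fixture(scope="session")
def prior_params(prior) -> cmcsd.CMCParameters:
    return cmcsd.CMCParameters.from_prior(prior)


@pytest.fixture(scope="session")
def coarse_grid() -> np.ndarray:
    """4-80 Hz at 4 Hz spacing: the grid used for desk-scale inversions."""
    return np.arange(4.0, 81.0, 4.0)


@pytest.fixture(scope="session")
def tiny_grid() -> np.ndarray:
    """5-80 Hz at 5 Hz spacing: the grid for repeated-fit simulations."""
    return np.arange(5.0, 81.0, 5.0)


@pytest.fixture(scope="session")
def oracle_grid() -> np.ndarray:
    return np.arange(5.0, 81.0, 2.0)


@pytest.fixture(scope="session")
def oracle_pair(prior_params, oracle_grid):
    """Analytic CSD and the Welch/multitaper CSD of a 600 s simulation.

    The simulation runs at dt = 0.5 ms; the estimator uses 2 s segments
    (spectral smoothing +/- 1 Hz) to resolve the sharp beta-band
    cross-spectral structure.
    """
    pred = cmcsd.predict_csd(prior_params, oracle_grid)
    ep = cmcsd.simulate_timeseries(
        prior_params, duration=600.0, fs=2000.0, seed=7, epoch_length_s=2.0
    )
    est = cmcsd.estimate_csd(ep, oracle_grid)
    return est, pred


@pytest.fixture(scope="session")
def noisy_dataset(prior, coarse_grid):
    """One synthetic dataset at the study's log precision of 7."""
    params = cmcsd.sample_prior(prior, seed=11)
    return cmcsd.generate_dataset(params, coarse_grid, 7.0, seed=42)


@pytest.fixture(scope="session")
def standard_fit(noisy_dataset, prior):
    """A converged veridical inversion of the λ=7 dataset."""
    return cmcsd.fit(noisy_dataset.data, prior, "veridical", max_iter=48)


@pytest.fixture(scope="session")
def recovery_table(prior, tiny_grid):
    """Fraction of 20 synthetic datasets whose hierarchy is recovered,
    per log precision in {1, 4, 7}."""
    out = {}
    for lam in (1.0, 4.0, 7.0):
        correct = 0
        for i in range(20):
            params = cmcsd.sample_prior(prior, seed=1000 + i)
            ds = cmcsd.generate_dataset(
                params, tiny_grid, lam, seed=2000 + 137 * i + int(lam)
            )
            rep = cmcsd.compare_models(ds.data, prior, max_iter=24)
            correct += rep.selected == "veridical"
        out[lam] = correct / 20
    return out
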