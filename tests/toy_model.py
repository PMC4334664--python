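"""A 2-parameter nonlinear toy problem for validating variational Laplace
against a dense-grid Bayesian computation."""

import numpy as np

from cmcsd.inversion import GaussianFeatureProblem, vl_fit


def toy_forward(theta):
    t1, t2 = theta
    return np.array(
        [t1 + 0.15 * t2**2, t2 + 0.15 * t1 * t2, 0.5 * t1 - 0.3 * t2]
    )


def run_toy_comparison():
    """Fit the toy model by VL and by dense-grid quadrature.

    Returns (vl_result, grid_mean, grid_cov); the grid posterior is
    conditional on the precision the VL scheme estimated.
    """
    theta_true = np.array([0.6, -0.4])
    y = toy_forward(theta_true)
    prior_var = np.array([0.5, 0.5])
    problem = GaussianFeatureProblem(
        forward=toy_forward,
        prior_mean=np.zeros(2),
        prior_var=prior_var,
        block_slices=[slice(0, 3)],
        hyper_mean=4.0,
        hyper_var=1.0 / 128.0,
    )
    res = vl_fit(problem, y, max_iter=64, tol=1e-6)

    prec = np.exp(res.lambdas[0])
    t1 = np.linspace(-2.0, 2.5, 301)
    t2 = np.linspace(-2.5, 2.0, 301)
    T1, T2 = np.meshgrid(t1, t2, indexing="ij")
    G0 = T1 + 0.15 * T2**2
    G1 = T2 + 0.15 * T1 * T2
    G2 = 0.5 * T1 - 0.3 * T2
    loglik = -0.5 * prec * (
        (y[0] - G0) ** 2 + (y[1] - G1) ** 2 + (y[2] - G2) ** 2
    )
    logprior = -0.5 * (T1**2 / prior_var[0] + T2**2 / prior_var[1])
    w = np.exp(loglik + logprior - (loglik + logprior).max())
    w /= w.sum()
    mean_grid = np.array([np.sum(w * T1), np.sum(w * T2)])
    d1, d2 = T1 - mean_grid[0], T2 - mean_grid[1]
    cov_grid = np.array(
        [
            [np.sum(w * d1 * d1), np.sum(w * d1 * d2)],
            [np.sum(w * d1 * d2), np.sum(w * d2 * d2)],
        ]
    )
    return res, mean_grid, cov_grid
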