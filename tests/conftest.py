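import itertools

import numpy as np
import pytest
from scipy.special import log_ndtr

import dweights as dw


def probit_grid_oracle(pc, registry, tol=1e-4, span=4.0, n_grid=9):
    """Brute-force probit MLE by iterative joint grid contraction.

    Evaluates the exact likelihood on a full Cartesian grid over all free
    scale values and repeatedly zooms onto the best cell.  Derivative-free,
    so it is an independent check on the Newton-based fit; the likelihood is
    concave, hence the contraction converges to the global maximum.
    """
    from dweights.pc_model import build_design

    design = build_design(pc, registry)
    k = design.n_params
    s = 2 * design.y - 1
    lo = np.full(k, -span)
    hi = np.full(k, span)

    def loglik(beta):
        ba = np.where(design.a_idx >= 0, beta[design.a_idx], 0.0)
        bb = np.where(design.b_idx >= 0, beta[design.b_idx], 0.0)
        return float(np.sum(design.counts * log_ndtr(s * (ba - bb))))

    best = None
    while np.max(hi - lo) > tol:
        grids = [np.linspace(lo[j], hi[j], n_grid) for j in range(k)]
        best_ll = -np.inf
        for combo in itertools.product(*grids):
            beta = np.asarray(combo)
            ll = loglik(beta)
            if ll > best_ll:
                best_ll, best = ll, beta
        step = (hi - lo) / (n_grid - 1)
        lo = best - step
        hi = best + step
    return dict(zip(design.columns, best)), best_ll


def interval_grid_oracle(lo_bounds, hi_bounds, log_scale=True, tol=1e-4):
    """Brute-force 2-parameter (mean, scale) censored-normal MLE for one state."""
    lo_b = np.log(np.asarray(lo_bounds)) if log_scale else np.asarray(lo_bounds)
    hi_b = np.log(np.asarray(hi_bounds)) if log_scale else np.asarray(hi_bounds)
    from scipy.stats import norm

    def loglik(mu, sigma):
        return float(np.sum(np.log(
            norm.cdf((hi_b - mu) / sigma) - norm.cdf((lo_b - mu) / sigma) + 1e-300
        )))

    mu_lo, mu_hi = lo_b.min() - 2, hi_b.max() + 2
    s_lo, s_hi = 1e-3, 5.0
    best = None
    while max(mu_hi - mu_lo, s_hi - s_lo) > tol:
        mus = np.linspace(mu_lo, mu_hi, 15)
        sigmas = np.linspace(s_lo, s_hi, 15)
        best_ll = -np.inf
        for m in mus:
            for sg in sigmas:
                ll = loglik(m, sg)
                if ll > best_ll:
                    best_ll, best = ll, (m, sg)
        mu_step = (mu_hi - mu_lo) / 14
        s_step = (s_hi - s_lo) / 14
        mu_lo, mu_hi = best[0] - mu_step, best[0] + mu_step
        s_lo, s_hi = max(best[1] - s_step, 1e-4), best[1] + s_step
    mu, sigma = best
    return (np.exp(mu) if log_scale else mu), sigma, best_ll


@pytest.fixture(scope="session")
def small_world():
    """A 5-substantive-state universe with known latent weights."""
    registry, truth = dw.make_state_registry(5, seed=101)
    return registry, truth


@pytest.fixture(scope="session")
def recovery_world():
    """The parameter-recovery conditions: 30 states, 500 respondents x 15 pairs."""
    registry, truth = dw.make_state_registry(30, seed=11)
    config = dw.SimConfig(n_respondents=500, k_pairs=15, sigma_pc=0.25, seed=11)
    pc = dw.simulate_pc_responses(registry, truth, config)
    return registry, truth, config, pc


@pytest.fixture(scope="session")
def reference_table():
    from dweights.evaluation_io import load_reference_table

    return load_reference_table()
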