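"""Shared adaptive random-walk Metropolis machinery.

All samplers in the package are random-walk Metropolis on unconstrained
transformed parameters, with step sizes adapted during burn-in toward an
acceptance rate in a target band (tuning stops at the end of burn-in, so
the retained draws come from a fixed kernel).
"""

from __future__ import annotations

import numpy as np

ACCEPT_LOW = 0.20
ACCEPT_HIGH = 0.50
ADAPT_EVERY = 100
ADAPT_FACTOR = 1.4


def adapt_steps(steps: np.ndarray, accepted: np.ndarray, window: int) -> None:
    """Scale step sizes in place toward the 20-50% acceptance band."""
    rate = accepted / max(window, 1)
    steps[rate < ACCEPT_LOW] /= ADAPT_FACTOR
    steps[rate > ACCEPT_HIGH] *= ADAPT_FACTOR


def batch_random_walk(
    logpost,
    theta0: np.ndarray,
    burn: int,
    keep: int,
    rng: np.random.Generator,
    step0: float = 0.5,
):
    """Vectorized scalar-parameter random walk over a batch of chains.

    ``logpost(theta)`` maps a vector of per-chain parameter values to a
    vector of log posterior densities. Returns (draws, acceptance_rate)
    with draws of shape (keep, n_chains).
    """
    theta = np.asarray(theta0, dtype=float).copy()
    n = theta.shape[0]
    steps = np.full(n, step0)
    lp = logpost(theta)
    draws = np.empty((keep, n))
    acc_window = np.zeros(n)
    acc_total = np.zeros(n)
    total = burn + keep
    for it in range(total):
        prop = theta + steps * rng.standard_normal(n)
        lp_prop = logpost(prop)
        accept = np.log(rng.random(n)) < lp_prop - lp
        theta[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        if it < burn:
            acc_window += accept
            if (it + 1) % ADAPT_EVERY == 0:
                adapt_steps(steps, acc_window, ADAPT_EVERY)
                acc_window[:] = 0
        else:
            acc_total += accept
            draws[it - burn] = theta
    return draws, acc_total / max(keep, 1)
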