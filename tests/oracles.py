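"""Independent Monte-Carlo and enumeration oracles used by the tests.

These re-simulate the model at the lineage / contact level from the event
probabilities alone; they share no code with the implementation paths they
check.
"""

from __future__ import annotations

import numpy as np


def lineage_emergence_mc(R0, ranked_R, mu, beta, g, n_lineages, rng,
                         threshold=2000, max_gen=4000):
    """Direct branching simulation of viral lineages against a frozen host.

    Each virion succeeds (adsorbs a susceptible host and bursts) with
    probability ``R0/beta``, producing exactly ``beta`` offspring; each
    offspring becomes a rank-``j`` single-match escape with probability
    ``mu*(1-mu)**(g-1)`` per rank.  Escape virions reproduce with success
    probability ``R_j/beta`` and do not mutate further.  A lineage counts as
    emerged once its population reaches ``threshold``.  Returns the emerged
    fraction and its binomial standard error.
    """
    pi0 = min(R0 / beta, 1.0)
    m = mu * (1.0 - mu) ** (g - 1)
    ell = len(ranked_R)
    pis = [min(R / beta, 1.0) for R in ranked_R]
    counts = np.zeros((n_lineages, 1 + ell), dtype=np.int64)
    counts[:, 0] = 1
    emerged = np.zeros(n_lineages, dtype=bool)
    alive_idx = np.arange(n_lineages)
    for _ in range(max_gen):
        if alive_idx.size == 0:
            break
        c = counts[alive_idx]
        new = np.zeros_like(c)
        off0 = rng.binomial(c[:, 0], pi0) * beta
        # multinomial thinning of wild offspring into escape ranks
        remaining = off0
        p_left = 1.0
        for j in range(ell):
            esc = rng.binomial(remaining, min(m / p_left, 1.0))
            new[:, 1 + j] += esc
            remaining = remaining - esc
            p_left -= m
        new[:, 0] = remaining
        for j in range(ell):
            new[:, 1 + j] += rng.binomial(c[:, 1 + j], pis[j]) * beta
        counts[alive_idx] = new
        tot = new.sum(axis=1)
        emerged[alive_idx[tot >= threshold]] = True
        alive_idx = alive_idx[(tot > 0) & (tot < threshold)]
    # unresolved lineages survived max_gen generations: count as emerged
    emerged[alive_idx] = True
    p = emerged.mean()
    # variance floored at 1/n: with zero observed events the plug-in
    # binomial variance degenerates, while the rule-of-three scale is ~1/n
    se = np.sqrt(max(p * (1 - p), 1.0 / n_lineages) / n_lineages)
    return p, se


def contact_escape_mc(S, q, mu, beta, n_trials, rng):
    """Contact-level simulation of single-match escape generation.

    A viral strain contacts ``S`` susceptible hosts; each contact triggers
    acquisition with probability ``q``, otherwise a burst of ``beta``
    offspring each escaping (mutating the focal protospacer) with
    probability ``mu``.  Returns (freq of >=1 escape, its SE, mean escapes,
    SE of the mean).
    """
    n_lysed = rng.binomial(S, 1.0 - q, size=n_trials)
    escapes = rng.binomial(n_lysed * beta, mu)
    p = float((escapes >= 1).mean())
    p_se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_trials))
    m = float(escapes.mean())
    m_se = float(escapes.std(ddof=1) / np.sqrt(n_trials))
    return p, p_se, m, m_se


def logistic_quasi_stationary_mean(r, K, n_max=None):
    """Mean of the quasi-stationary law of the logistic birth-death chain.

    Birth rate ``r*N``, death rate ``r*N^2/K``; detailed balance gives
    ``pi_{N+1}/pi_N = N*K/(N+1)^2`` on the positive states (absorption at 0
    is astronomically slow at the sizes used here).
    """
    if n_max is None:
        n_max = int(4 * K)
    log_pi = np.zeros(n_max + 1)
    log_pi[0] = -np.inf  # state 0 excluded
    for n in range(1, n_max):
        log_pi[n + 1] = log_pi[n] + np.log(n * K / (n + 1) ** 2)
    w = np.exp(log_pi[1:] - log_pi[1:].max())
    states = np.arange(1, n_max + 1)
    return float((states * w).sum() / w.sum())
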