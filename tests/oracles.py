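"""Independent brute-force oracles for the HMM and geometry tests.

Everything here is deliberately naive (path enumeration, textbook
formulas) and shares no code with the package implementation.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import norm


def _path_prob(path, obs, initial, P, means, sds):
    p = initial[path[0]] * norm.pdf(obs[0], means[path[0]], sds[path[0]])
    for t in range(1, len(obs)):
        p *= P[path[t - 1], path[t]] * norm.pdf(obs[t], means[path[t]], sds[path[t]])
    return p


def enum_loglik(obs, initial, P, means, sds) -> float:
    S, T = len(initial), len(obs)
    total = sum(_path_prob(path, obs, initial, P, means, sds)
                for path in product(range(S), repeat=T))
    return float(np.log(total))


def enum_posteriors(obs, initial, P, means, sds) -> np.ndarray:
    S, T = len(initial), len(obs)
    post = np.zeros((T, S))
    total = 0.0
    for path in product(range(S), repeat=T):
        p = _path_prob(path, obs, initial, P, means, sds)
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
    return post / total


def enum_viterbi(obs, initial, P, means, sds) -> np.ndarray:
    S, T = len(initial), len(obs)
    best, best_p = None, -1.0
    for path in product(range(S), repeat=T):
        p = _path_prob(path, obs, initial, P, means, sds)
        if p > best_p:
            best_p, best = p, path
    return np.array(best)


def law_of_cosines_km(lat1, lon1, lat2, lon2, radius_km=6371.0) -> float:
    """Spherical law of cosines: an independent great-circle formula."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    c = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(l2 - l1)
    return float(radius_km * np.arccos(np.clip(c, -1.0, 1.0)))


def random_hmm_instance(rng, n_states: int, n_obs: int, structural_zeros=False):
    """A random valid parameter set + observation vector for oracle tests."""
    P = rng.dirichlet(np.ones(n_states) * 2.0, size=n_states)
    zeros = ()
    if structural_zeros and n_states == 3:
        zeros = ((1, 2), (2, 1))
        for i, j in zeros:
            P[i, i] += P[i, j]
            P[i, j] = 0.0
    initial = rng.dirichlet(np.ones(n_states))
    means = rng.normal(0.0, 5.0, n_states)
    sds = rng.uniform(0.5, 4.0, n_states)
    obs = rng.normal(0.0, 5.0, n_obs)
    return obs, initial, P, means, sds, zeros
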