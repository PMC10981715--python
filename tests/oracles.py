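"""Independent brute-force oracles used by the tests.

These re-derive model quantities from first principles (path
enumeration, direct density formulas) without touching the package's
recursion code paths.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import norm


def bin_index(edges, value) -> int:
    """Interval index for value over open-ended increasing edges."""
    for i, e in enumerate(edges):
        if value <= e:
            return i
    return len(edges)


def mixture_pdf(x, weight, means, variances) -> float:
    return (1 - weight) * norm.pdf(x, means[0], np.sqrt(variances[0])) + weight * norm.pdf(
        x, means[1], np.sqrt(variances[1])
    )


def emission_prob(z, state, weights, means, variances) -> float:
    p = 1.0
    for f in range(3):
        p *= mixture_pdf(z[f], weights[state, f], means[state, f], variances[state, f])
    return p


def enumerate_paths(fragment, model, prior_k=None, prior_w=1.0):
    """All 2^L path probabilities of a fragment by direct products.

    Returns (paths, probabilities). When ``prior_k`` maps positions to
    priors, the posterior-emission parameterisation is used (as at
    decoding); otherwise plain emission densities (as in training).
    """
    obs = fragment.observations
    L = len(obs)
    start = model.startprob_
    trans = model.transmat_
    w8, mu, var = model.emission_weights_, model.emission_means_, model.emission_vars_
    off_edges, dist_edges = model.offset_edges, model.distance_edges

    B = np.empty((L, 2))
    for t in range(L):
        eu = emission_prob(obs[t].z, 0, w8, mu, var)
        em = emission_prob(obs[t].z, 1, w8, mu, var)
        if prior_k is None:
            B[t] = [eu, em]
        else:
            k = prior_w * prior_k.get(obs[t].ref_position, 0.5) + (1 - prior_w) * 0.5
            denom = em * k + eu * (1 - k)
            B[t] = [eu * (1 - k) / denom, em * k / denom]

    paths = list(product([0, 1], repeat=L))
    probs = []
    for path in paths:
        p = start[bin_index(off_edges, obs[0].offset), path[0]] * B[0, path[0]]
        for t in range(1, L):
            b = bin_index(dist_edges, obs[t].distance_to_prev)
            p *= trans[b, path[t - 1], path[t]] * B[t, path[t]]
        probs.append(p)
    return paths, np.array(probs)


def brute_force_loglik(fragment, model) -> float:
    _, probs = enumerate_paths(fragment, model)
    return float(np.log(probs.sum()))


def brute_force_viterbi(fragment, model, prior_k=None, prior_w=1.0):
    paths, probs = enumerate_paths(fragment, model, prior_k, prior_w)
    return np.array(paths[int(np.argmax(probs))]), probs


def exact_ranksum_p(case, control) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments."""
    from itertools import combinations

    pooled = np.concatenate([case, control])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n1 = len(case)
    observed = ranks[:n1].sum()
    null = [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), n1)]
    null = np.array(null)
    mean = null.mean()
    p = np.mean(np.abs(null - mean) >= abs(observed - mean) - 1e-12)
    return float(p)
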