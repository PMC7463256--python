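"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: likelihoods are
computed by explicit summation over internal-node states, distances by
textbook closed forms.
"""

from itertools import product

import numpy as np
from scipy.linalg import expm


def hky_rate_matrix(kappa, freqs):
    """Unnormalised-then-normalised HKY generator, built independently."""
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = (kappa if (i, j) in transitions else 1.0) * freqs[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    return Q / mu


def pmatrix_expm(kappa, freqs, distance):
    return expm(hky_rate_matrix(kappa, freqs) * distance)


def enumeration_log_likelihood(tree, patterns, weights, model):
    """Sum over all internal-state assignments; feasible for <= 5 taxa.

    ``patterns``: (n_tips, P) int codes in tree label order, 4 = missing.
    """
    K = model.n_categories
    cat_rates = model.category_rates
    n_tips = tree.n_tips
    internals = list(range(n_tips, tree.n_nodes))
    P = patterns.shape[1]

    site_like = np.zeros(P)
    for c in range(K):
        pmats = {}
        for node in range(tree.n_nodes):
            d = model.rate * cat_rates[c] * tree.branch_length(node)
            pmats[node] = pmatrix_expm(model.kappa, model.base_freqs, d)
        acc = np.zeros(P)
        for assign in product(range(4), repeat=len(internals)):
            state = dict(zip(internals, assign))
            pr = np.full(P, model.base_freqs[state[tree.root]])
            for node in range(tree.n_nodes):
                par = int(tree.parent[node])
                if par == -1:
                    continue
                if node < n_tips:
                    obs = patterns[node]
                    term = np.where(
                        obs == 4, 1.0, pmats[node][state[par], np.minimum(obs, 3)]
                    )
                    pr = pr * term
                else:
                    pr = pr * pmats[node][state[par], state[node]]
            acc += pr
        site_like += acc / K
    return weights @ np.log(site_like), site_like


def k80_distance(p, q):
    """Kimura 1980 closed form from transition/transversion proportions."""
    return -0.5 * np.log((1 - 2 * p - q) * np.sqrt(1 - 2 * q))


def hpd_bruteforce(samples, mass):
    s = np.sort(np.asarray(samples))
    n = len(s)
    m = int(np.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        width = s[i + m - 1] - s[i]
        if best is None or width < best[0]:
            best = (width, s[i], s[i + m - 1])
    return best[1], best[2]
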