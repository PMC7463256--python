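"""Compiled inner loops for the pruning engine.

Small fixed-size (4-state) loops dominate the MCMC step cost; these
kernels fuse the per-branch transition-matrix build, the partial-
likelihood path update and the root reduction, avoiding per-call numpy
overhead.  All arithmetic is plain double precision with a fixed
summation order, so results are bit-reproducible and match the numpy
reference path to rounding.

Falls back to ``HAVE_NUMBA = False`` when numba is unavailable; the
engine then uses its numpy implementation.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def pmat_update(nodes, branch_lengths, rate, cat_rates, w, left, right, pmats):
    """P(d) = left @ diag(exp(w d)) @ right for each node and category."""
    K = cat_rates.shape[0]
    ed = np.empty(4)
    for t in range(nodes.shape[0]):
        v = nodes[t]
        dt = branch_lengths[t]
        for k in range(K):
            d = rate * cat_rates[k] * dt
            for e in range(4):
                ed[e] = math.exp(d * w[e])
            for i in range(4):
                for j in range(4):
                    s = 0.0
                    for e in range(4):
                        s += left[i, e] * ed[e] * right[e, j]
                    if s < 0.0:
                        s = 0.0
                    elif s > 1.0:
                        s = 1.0
                    pmats[v, k, i, j] = s


@njit(cache=True)
def partials_update(path_nodes, children, pmats, partials):
    """Recompute partials for ``path_nodes`` (children-before-parent)."""
    K = partials.shape[1]
    P = partials.shape[3]
    for t in range(path_nodes.shape[0]):
        v = path_nodes[t]
        l = children[v, 0]
        r = children[v, 1]
        for k in range(K):
            for i in range(4):
                pl0 = pmats[l, k, i, 0]
                pl1 = pmats[l, k, i, 1]
                pl2 = pmats[l, k, i, 2]
                pl3 = pmats[l, k, i, 3]
                pr0 = pmats[r, k, i, 0]
                pr1 = pmats[r, k, i, 1]
                pr2 = pmats[r, k, i, 2]
                pr3 = pmats[r, k, i, 3]
                for p in range(P):
                    sl = (
                        pl0 * partials[l, k, 0, p]
                        + pl1 * partials[l, k, 1, p]
                        + pl2 * partials[l, k, 2, p]
                        + pl3 * partials[l, k, 3, p]
                    )
                    sr = (
                        pr0 * partials[r, k, 0, p]
                        + pr1 * partials[r, k, 1, p]
                        + pr2 * partials[r, k, 2, p]
                        + pr3 * partials[r, k, 3, p]
                    )
                    partials[v, k, i, p] = sl * sr


@njit(cache=True)
def root_loglik(root_partials, freqs, weights):
    """Sum_p w_p log( mean_k sum_i pi_i L_kip ); NaN signals underflow."""
    K = root_partials.shape[0]
    P = root_partials.shape[2]
    ll = 0.0
    for p in range(P):
        m = 0.0
        for k in range(K):
            v = 0.0
            for i in range(4):
                v += freqs[i] * root_partials[k, i, p]
            m += v
        m /= K
        if m <= 0.0:
            return np.nan
        ll += weights[p] * math.log(m)
    return ll
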