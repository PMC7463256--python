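"""Deterministic numerical core.

* HKY transition probabilities with 4-category discrete-gamma rate
  variation (spectral closed form of the reversible rate matrix),
* Felsenstein pruning log-likelihood on time-trees over compressed site
  patterns, with incremental per-branch updates for MCMC use,
* heterochronous constant-population-size coalescent log-density,
* F84 pairwise distances with pairwise deletion of missing data.

Time is measured in years; the clock ``rate`` is in substitutions per
site per year.  The HKY rate matrix is normalised to one expected
substitution per site per unit of ``rate * time``, so the clock rate is
directly interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from . import _kernels
from .tree import TimeTree, TreeError

__all__ = [
    "Alignment",
    "SubstModel",
    "DistanceMatrix",
    "hky_transition_matrix",
    "log_likelihood",
    "PruningEngine",
    "coalescent_log_density",
    "f84_distance",
    "distance_matrix",
    "empirical_base_freqs",
]

# nucleotide encoding: A C G T = 0..3, N and '-' = 4 (fully missing)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
for _b in "Nn-":
    _CODE[ord(_b)] = 4

MISSING = 4


def encode_sequence(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(arr < 0):
        bad = sorted({seq[i] for i in np.flatnonzero(arr < 0)[:5]})
        raise ValueError(f"sequence contains characters outside A,C,G,T,N,-: {bad}")
    return arr.astype(np.int8)


# ---------------------------------------------------------------------------
# alignment container


@dataclass
class Alignment:
    """Equal-length aligned sequences over {A,C,G,T,N,-}.

    Site patterns (unique columns with multiplicities) are computed
    lazily and cached; the pruning likelihood runs over patterns, which
    for low-divergence mitogenome alignments is a large saving.
    """

    ids: list[str]
    rows: list[str]
    _codes: np.ndarray = field(default=None, repr=False)
    _patterns: tuple = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lens)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_seq(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def codes(self) -> np.ndarray:
        """(n_seq, length) int8 matrix, 0..3 bases, 4 missing."""
        if self._codes is None:
            if self.length == 0:
                self._codes = np.zeros((self.n_seq, 0), dtype=np.int8)
            else:
                self._codes = np.vstack([encode_sequence(r) for r in self.rows])
        return self._codes

    def site_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """(patterns (n_seq, P), weights (P,)); weights sum to length."""
        if self._patterns is None:
            if self.length == 0:
                self._patterns = (
                    np.zeros((self.n_seq, 0), dtype=np.int8),
                    np.zeros(0, dtype=np.int64),
                )
            else:
                cols, counts = np.unique(self.codes, axis=1, return_counts=True)
                self._patterns = (cols, counts)
        return self._patterns

    def subset(self, ids) -> "Alignment":
        keep = set(ids)
        pairs = [(i, r) for i, r in zip(self.ids, self.rows) if i in keep]
        return Alignment([p[0] for p in pairs], [p[1] for p in pairs])


def empirical_base_freqs(alignment: Alignment) -> np.ndarray:
    """Base frequencies counted over the alignment, N/gaps excluded."""
    codes = alignment.codes
    counts = np.bincount(codes[codes < 4].ravel(), minlength=4).astype(float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# substitution model


def _gamma_category_rates(alpha: float, k: int) -> np.ndarray:
    """Equal-probability discrete-gamma rates (quantile medians), mean 1."""
    q = (2 * np.arange(k) + 1) / (2 * k)
    rates = _gamma_dist.ppf(q, a=alpha, scale=1.0 / alpha)
    return rates / rates.mean()


@dataclass
class SubstModel:
    """HKY+G substitution model with a strict molecular clock.

    Parameters
    ----------
    kappa : transition/transversion rate ratio (> 0)
    base_freqs : equilibrium frequencies of A, C, G, T (sum to 1)
    alpha : gamma shape of among-site rate variation (> 0)
    n_categories : discrete-gamma categories (default 4)
    rate : clock rate in substitutions/site/year
    """

    kappa: float
    base_freqs: np.ndarray
    alpha: float = 0.5
    n_categories: int = 4
    rate: float = 1e-8
    _eig: tuple = field(default=None, repr=False)
    _cat_rates: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.base_freqs.shape != (4,) or np.any(self.base_freqs <= 0):
            raise ValueError("base_freqs must be 4 positive values")
        if abs(self.base_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("base_freqs must sum to 1")
        if self.kappa <= 0 or self.alpha <= 0 or self.rate < 0:
            raise ValueError("kappa, alpha must be > 0 and rate >= 0")

    @property
    def category_rates(self) -> np.ndarray:
        if self._cat_rates is None:
            self._cat_rates = _gamma_category_rates(self.alpha, self.n_categories)
        return self._cat_rates

    def _eigensystem(self):
        """Spectral decomposition of the normalised HKY rate matrix.

        Q_ij = kappa*pi_j for transitions (A<->G, C<->T), pi_j for
        transversions, scaled so the expected substitution rate is 1.
        Reversibility lets us symmetrise with sqrt(pi) and use eigh.
        """
        if self._eig is None:
            pi = self.base_freqs
            k = self.kappa
            Q = np.empty((4, 4))
            for i in range(4):
                for j in range(4):
                    if i == j:
                        continue
                    ts = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
                    Q[i, j] = (k if ts else 1.0) * pi[j]
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            mu = -np.dot(pi, np.diag(Q))
            Q /= mu
            sq = np.sqrt(pi)
            S = (sq[:, None] * Q) / sq[None, :]
            w, V = np.linalg.eigh((S + S.T) / 2)
            left = V / sq[:, None]      # P(d) = left @ diag(e^{w d}) @ right
            right = V.T * sq[None, :]
            self._eig = (w, left, right)
        return self._eig

    def transition_matrices(self, distances: np.ndarray) -> np.ndarray:
        """Stacked P(d) for an array of expected-substitution distances."""
        d = np.atleast_1d(np.asarray(distances, dtype=float))
        if np.any(d < 0):
            raise ValueError("negative evolutionary distance")
        return self._pmats_fast(d)

    def _pmats_fast(self, d: np.ndarray) -> np.ndarray:
        # validation-free inner path for the MCMC engine
        w, left, right = self._eigensystem()
        E = np.exp(d[:, None] * w[None, :])             # (k, 4)
        P = (left[None, :, :] * E[:, None, :]) @ right  # (k, 4, 4)
        np.clip(P, 0.0, 1.0, out=P)
        return P


def hky_transition_matrix(
    model: SubstModel, elapsed_years: float, category_rate: float = 1.0
) -> np.ndarray:
    """4x4 transition-probability matrix for one branch.

    The branch's expected substitutions per site are
    ``model.rate * category_rate * elapsed_years``.
    """
    if elapsed_years < 0:
        raise ValueError("negative elapsed time")
    d = model.rate * category_rate * elapsed_years
    return model.transition_matrices(np.array([d]))[0]


# ---------------------------------------------------------------------------
# pruning likelihood


class PruningEngine:
    """Felsenstein pruning over site patterns with incremental updates.

    Partial likelihoods and per-branch transition matrices are cached
    per node and per gamma category; after a node-age or tip-age change
    only the path from the changed node to the root is recomputed, which
    keeps the per-step MCMC cost near O(tree depth) instead of O(n).
    Per-node rescaling guards against underflow on deep trees.
    """

    def __init__(self, tree: TimeTree, alignment: Alignment, model: SubstModel,
                 scaling: bool | None = None):
        missing = set(tree.labels) - set(alignment.ids)
        if missing:
            raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
        self.tree = tree
        self.model = model
        self.n_tips = tree.n_tips
        self.n_nodes = tree.n_nodes
        K = model.n_categories
        # per-node rescaling costs ~40% per update; shallow trees cannot
        # underflow double precision, so default it off below 80 tips and
        # re-enable automatically if a site likelihood ever hits zero
        self.scaling = scaling if scaling is not None else self.n_tips >= 80

        patterns, weights = alignment.site_patterns()
        row_of = {i: k for k, i in enumerate(alignment.ids)}
        order = [row_of[lab] for lab in tree.labels]
        self.patterns = patterns[order] if patterns.size else patterns[:0]
        self.weights = weights.astype(float)
        self.P = self.patterns.shape[1] if self.patterns.ndim == 2 else 0

        # tip partial-likelihood vectors: unit vector for a base, ones for N/-
        eye5 = np.vstack([np.eye(4), np.ones(4)])  # row 4 = missing
        self.partials = np.zeros((self.n_nodes, K, 4, self.P))
        for t in range(self.n_tips):
            tipL = eye5[self.patterns[t]].T if self.P else np.zeros((4, 0))
            self.partials[t] = tipL[None, :, :]
        self.cumscale = np.zeros((self.n_nodes, K, self.P))
        self.pmats = np.zeros((self.n_nodes, K, 4, 4))  # branch above node
        self.rate = model.rate
        self._cat_rates = model.category_rates
        w, left, right = model._eigensystem()
        self._eig_w = np.ascontiguousarray(w)
        self._eig_left = np.ascontiguousarray(left)
        self._eig_right = np.ascontiguousarray(right)
        self._fast = _kernels.HAVE_NUMBA and not self.scaling
        self._refresh_topology()
        self.full_recompute()

    def _refresh_topology(self) -> None:
        """Cache python-native topology lists (call after topology moves)."""
        tree = self.tree
        self._children = [
            (int(l), int(r)) if l >= 0 else None for l, r in tree.children
        ]
        self._children_np = np.ascontiguousarray(tree.children)
        self._parent = [int(p) for p in tree.parent]
        self._paths = [
            ([n] if n >= self.n_tips else []) + tree.path_to_root(n)
            for n in range(self.n_nodes)
        ]
        self._paths_np = [np.asarray(p, dtype=np.int64) for p in self._paths]
        self._postorder = [int(n) for n in tree.postorder()]
        self._postorder_np = np.asarray(self._postorder, dtype=np.int64)
        self._nonroot_np = np.asarray(
            [n for n in range(self.n_nodes) if self._parent[n] != -1], dtype=np.int64
        )
        self._root = tree.root

    def _enable_scaling(self) -> float:
        """Switch permanently to the rescaled numpy path (underflow seen)."""
        self.scaling = True
        self._fast = False
        self.cumscale[:] = 0.0
        for node in self._postorder:
            self.recompute_partial(node)
        return self.log_likelihood()

    # -- updates -------------------------------------------------------

    def update_pmat(self, node: int) -> None:
        if self._parent[node] == -1:
            return
        dt = self.tree.ages[self._parent[node]] - self.tree.ages[node]
        self.pmats[node] = self.model._pmats_fast(self.rate * dt * self._cat_rates)

    def recompute_partial(self, node: int) -> None:
        l, r = self._children[node]
        X = np.matmul(self.pmats[l], self.partials[l])
        X *= np.matmul(self.pmats[r], self.partials[r])
        if self.scaling:
            m = X.max(axis=1)  # (K, P)
            np.maximum(m, 1e-300, out=m)
            X /= m[:, None, :]
            self.cumscale[node] = np.log(m) + self.cumscale[l] + self.cumscale[r]
        self.partials[node] = X

    def _kernel_pmats(self, nodes: np.ndarray) -> None:
        ages = self.tree.ages
        bl = ages[self.tree.parent[nodes]] - ages[nodes]
        _kernels.pmat_update(
            nodes, bl, self.rate, self._cat_rates,
            self._eig_w, self._eig_left, self._eig_right, self.pmats,
        )

    def full_recompute(self) -> float:
        if self._fast and self.P:
            self._kernel_pmats(self._nonroot_np)
            _kernels.partials_update(
                self._postorder_np, self._children_np, self.pmats, self.partials
            )
            ll = _kernels.root_loglik(
                self.partials[self._root], self.model.base_freqs, self.weights
            )
            if not np.isnan(ll):
                return float(ll)
            return self._enable_scaling()
        for node in range(self.n_nodes):
            self.update_pmat(node)
        for node in self._postorder:
            self.recompute_partial(node)
        return self.log_likelihood()

    def update_path(self, start: int) -> None:
        """Recompute partials from ``start`` (inclusive if internal) to root."""
        for node in self._paths[start]:
            self.recompute_partial(node)

    def node_age_changed(self, node: int) -> float:
        """Refresh caches after ``tree.ages[node]`` was modified."""
        if self._fast and self.P:
            touched = [node]
            if node >= self.n_tips:
                touched.extend(self._children[node])
            touched = [n for n in touched if self._parent[n] != -1]
            self._kernel_pmats(np.asarray(touched, dtype=np.int64))
            _kernels.partials_update(
                self._paths_np[node], self._children_np, self.pmats, self.partials
            )
            ll = _kernels.root_loglik(
                self.partials[self._root], self.model.base_freqs, self.weights
            )
            if not np.isnan(ll):
                return float(ll)
            return self._enable_scaling()
        self.update_pmat(node)
        if node >= self.n_tips:
            l, r = self._children[node]
            self.update_pmat(l)
            self.update_pmat(r)
        self.update_path(node)
        return self.log_likelihood()

    def rate_changed(self, rate: float) -> float:
        self.rate = rate
        return self.full_recompute()

    # -- evaluation ----------------------------------------------------

    def log_likelihood(self) -> float:
        if self.P == 0:
            return 0.0
        root = self._root
        v = np.einsum(
            "kip,i->kp", self.partials[root], self.model.base_freqs, optimize=False
        )
        if not self.scaling:
            mean_v = v.mean(axis=0)
            if np.all(mean_v > 0.0):
                return float(self.weights @ np.log(mean_v))
            # underflow: switch to scaled mode permanently for this engine
            self.scaling = True
            self.cumscale[:] = 0.0
            for node in self._postorder:
                self.recompute_partial(node)
            v = np.einsum(
                "kip,i->kp", self.partials[root], self.model.base_freqs,
                optimize=False,
            )
        t = self.cumscale[root] + np.log(np.maximum(v, 1e-300))  # (K, P)
        m = t.max(axis=0)
        ll_pat = m + np.log(np.exp(t - m[None, :]).mean(axis=0))
        return float(self.weights @ ll_pat)

def log_likelihood(tree: TimeTree, alignment: Alignment, model: SubstModel) -> float:
    """HKY+G pruning log-likelihood of an alignment on a time-tree.

    N and '-' are fully missing (partial vector of ones); an all-missing
    alignment therefore has log-likelihood 0.
    """
    return PruningEngine(tree, alignment, model).log_likelihood()


# ---------------------------------------------------------------------------
# coalescent prior


def coalescent_log_density(tree: TimeTree, pop_size: float) -> float:
    """Log-density of a serially sampled constant-size coalescent genealogy.

    Going back in time, over an interval of duration dt with k active
    lineages the density accrues ``-k(k-1)/2 * dt / N``, and each
    coalescence contributes ``-log N``.  ``pop_size`` is on the tree's
    timescale (effective size times generation time, in years).
    """
    if pop_size <= 0:
        raise ValueError("pop_size must be positive")
    n = tree.n_tips
    kind = np.ones(tree.n_nodes)
    kind[n:] = -1.0         # coalescence; +1 = sampling
    # sort by age; at equal age process sampling events first so the
    # lineage count is correct when a coalescence abuts a sampling time
    order = np.lexsort((-kind, tree.ages))
    ages = tree.ages[order]
    k_after = np.cumsum(kind[order])    # lineages active after each event
    if np.any(k_after < 1):
        raise TreeError("coalescence with fewer than 2 active lineages")
    k = k_after[:-1]
    dt = np.diff(ages)
    logp = -np.dot(k * (k - 1.0), dt) / (2.0 * pop_size) - (n - 1) * np.log(pop_size)
    return float(logp)


# ---------------------------------------------------------------------------
# F84 distances


def f84_distance(seq_a, seq_b, freqs: np.ndarray | None = None) -> float:
    """F84 evolutionary distance in substitutions/site (NaN if undefined).

    Sites where either sequence is N or '-' are deleted pairwise.  Base
    frequencies default to the two sequences pooled over retained sites;
    pass ``freqs`` to use alignment-wide frequencies instead.  Returns
    NaN when the log arguments are non-positive (saturation) or no sites
    remain — undefined distances are flagged, never clamped.
    """
    a = seq_a if isinstance(seq_a, np.ndarray) else encode_sequence(seq_a)
    b = seq_b if isinstance(seq_b, np.ndarray) else encode_sequence(seq_b)
    if a.shape != b.shape:
        raise ValueError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    mask = (a < 4) & (b < 4)
    n = int(mask.sum())
    if n == 0:
        return float("nan")
    aa, bb = a[mask].astype(np.int64), b[mask].astype(np.int64)

    diff = aa != bb
    purine_a = (aa == 0) | (aa == 2)
    purine_b = (bb == 0) | (bb == 2)
    transitions = int(np.sum(diff & (purine_a == purine_b)))
    transversions = int(np.sum(diff & (purine_a != purine_b)))
    Pp = transitions / n
    Qp = transversions / n
    if Pp == 0 and Qp == 0:
        return 0.0

    if freqs is None:
        counts = np.bincount(aa, minlength=4) + np.bincount(bb, minlength=4)
        pi = counts / counts.sum()
    else:
        pi = np.asarray(freqs, dtype=float)
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    if piR <= 0 or piY <= 0:
        return float("nan")
    A = piC * piT / piY + piA * piG / piR
    B = piC * piT + piA * piG
    C = piR * piY
    if A <= 0 or C <= 0:
        return float("nan")
    arg1 = 1.0 - Pp / (2.0 * A) - (A - B) * Qp / (2.0 * A * C)
    arg2 = 1.0 - Qp / (2.0 * C)
    if arg1 <= 0 or arg2 <= 0:
        return float("nan")
    d = -2.0 * A * np.log(arg1) + 2.0 * (A - B - C) * np.log(arg2)
    return float(max(d, 0.0))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray   # (n, n), NaN where undefined
    defined: np.ndarray  # (n, n) bool

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.defined[np.ix_(idx, idx)]
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(alignment: Alignment, freq_mode: str = "global") -> DistanceMatrix:
    """All-pairs F84 distance matrix.

    ``freq_mode``: "global" estimates base frequencies once over the
    whole alignment (the convention of ape's ``dist.dna``); "pair" pools
    each pair's retained sites.
    """
    if freq_mode not in ("global", "pair"):
        raise ValueError("freq_mode must be 'global' or 'pair'")
    n = alignment.n_seq
    codes = alignment.codes
    freqs = empirical_base_freqs(alignment) if freq_mode == "global" else None
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = f84_distance(codes[i], codes[j], freqs=freqs)
            vals[i, j] = vals[j, i] = d
    defined = ~np.isnan(vals)
    if not defined.all():
        warnings.warn("some pairwise distances are undefined (saturation or no overlap)")
    return DistanceMatrix(list(alignment.ids), vals, defined)
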