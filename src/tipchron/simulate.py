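"""Synthetic-data generation for end-to-end verification.

Provides the statistical structure the inference machinery assumes:
serially sampled constant-size coalescent genealogies, HKY+G4 sequence
evolution along them, and ancient-DNA-style degraded read sets
(short fragments with terminal cytosine deamination) for the curation
stage.  Every public entry point takes a mandatory seed so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo import Alignment, SubstModel, encode_sequence
from .tree import TimeTree

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Fragment",
    "ReadSet",
    "simulate_coalescent_tree",
    "simulate_sequences",
    "simulate_dataset",
    "degrade_to_reads",
    "make_pileup",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for a synthetic serially sampled mitogenome set.

    Defaults mirror a Late/Middle Pleistocene proboscidean mitogenome
    study: ~16.5 kb sequences, tip ages spanning 0–800 ky before the
    youngest sample, a clock of order 1e-8 substitutions/site/year, and
    a coalescent population-size parameter on the same year timescale
    (effective size times generation time).
    """

    n_tips: int = 20
    tip_ages: np.ndarray | None = None      # years before youngest tip
    pop_size: float = 1e5                   # Ne * generation time, years
    rate: float = 3e-8                      # substitutions/site/year
    kappa: float = 20.0                     # mammalian-mtDNA-like ts/tv bias
    alpha: float = 0.5
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.array([0.32, 0.26, 0.13, 0.29])
    )
    seq_length: int = 16500
    missing_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if abs(self.base_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("base_freqs must sum to 1")
        if self.pop_size <= 0 or self.rate < 0 or self.kappa <= 0 or self.alpha <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.tip_ages is None:
            rng = np.random.default_rng(self.seed)
            ages = np.sort(rng.uniform(0.0, 8e5, self.n_tips))
            ages[0] = 0.0
            self.tip_ages = ages
        self.tip_ages = np.asarray(self.tip_ages, dtype=float)
        if len(self.tip_ages) != self.n_tips:
            raise ValueError("tip_ages length must equal n_tips")
        if np.any(self.tip_ages < 0) or not np.any(self.tip_ages == 0):
            raise ValueError("tip_ages must be >= 0 with at least one tip at 0")

    def model(self) -> SubstModel:
        return SubstModel(
            kappa=self.kappa, base_freqs=self.base_freqs, alpha=self.alpha,
            rate=self.rate,
        )


@dataclass
class GroundTruth:
    true_tree: TimeTree
    true_params: dict
    true_tip_ages: dict  # label -> years before youngest tip


@dataclass
class Fragment:
    start: int      # 0-based inclusive, reference coordinates
    end: int        # 0-based exclusive
    strand: str     # '+' or '-'
    sequence: str   # reference orientation, over {A,C,G,T,N}
    mapq: int = 60

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("fragment start must be < end")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("fragment sequence length != end - start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadSet:
    fragments: list[Fragment]

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)


# ---------------------------------------------------------------------------
# coalescent genealogies


def simulate_coalescent_tree(tip_ages, pop_size: float, seed: int) -> TimeTree:
    """Serially sampled constant-size coalescent genealogy.

    Going back in time, with k active lineages the waiting time to the
    next coalescence is Exp(k(k-1)/(2*pop_size)); the clock restarts
    whenever a new tip becomes active (memorylessness makes the restart
    exact).  Tip ages are years before the youngest tip.
    """
    tip_ages = np.asarray(tip_ages, dtype=float)
    if len(tip_ages) < 2:
        raise ValueError("need at least 2 tips")
    if pop_size <= 0:
        raise ValueError("pop_size must be positive")
    if np.any(~np.isfinite(tip_ages)) or np.any(tip_ages < 0):
        raise ValueError("tip ages must be finite and >= 0")
    rng = np.random.default_rng(seed)

    n = len(tip_ages)
    labels = [f"t{i}" for i in range(n)]
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    ages = np.zeros(2 * n - 1)
    ages[:n] = tip_ages

    pending = sorted(range(n), key=lambda i: tip_ages[i])  # tips not yet active
    active: list[int] = []
    t = 0.0
    next_internal = n
    while len(active) + len(pending) > 1 or len(active) > 1:
        if pending and not len(active) >= 2:
            # fewer than 2 active lineages: jump to the next sampling time
            tip = pending.pop(0)
            t = max(t, tip_ages[tip])
            active.append(tip)
            continue
        k = len(active)
        wait = rng.exponential(2.0 * pop_size / (k * (k - 1)))
        if pending and t + wait > tip_ages[pending[0]]:
            tip = pending.pop(0)
            t = tip_ages[tip]
            active.append(tip)
            continue
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node = next_internal
        next_internal += 1
        ages[node] = t
        children[node] = (a, b)
        parent[a] = node
        parent[b] = node
        active = [x for x in active if x not in (a, b)] + [node]
        if len(active) == 1 and not pending:
            break
    return TimeTree(labels, parent, children, ages)


# ---------------------------------------------------------------------------
# sequence evolution


def simulate_sequences(
    tree: TimeTree,
    rate: float,
    kappa: float,
    alpha: float,
    base_freqs,
    seq_length: int,
    seed: int,
    missing_frac: float = 0.0,
) -> Alignment:
    """Evolve sequences down a time-tree under HKY+G4.

    A root sequence is drawn from ``base_freqs``; each site is assigned
    one of 4 equal-probability mean-one discrete-gamma rate multipliers;
    states then evolve along each branch with the HKY transition matrix
    for that branch's duration.  ``missing_frac`` masks a contiguous run
    plus scattered sites to N per sequence, emulating incomplete ancient
    consensus sequences.
    """
    base_freqs = np.asarray(base_freqs, dtype=float)
    if abs(base_freqs.sum() - 1.0) > 1e-9 or np.any(base_freqs < 0):
        raise ValueError("base_freqs must be a simplex over A,C,G,T")
    rng = np.random.default_rng(seed)
    model = SubstModel(kappa=kappa, base_freqs=base_freqs, alpha=alpha, rate=rate)
    cat_rates = model.category_rates
    K = len(cat_rates)

    site_cat = rng.integers(0, K, size=seq_length)
    states = {tree.root: rng.choice(4, size=seq_length, p=base_freqs)}

    # preorder: parents before children
    visit = [tree.root]
    preorder = []
    while visit:
        v = visit.pop()
        preorder.append(v)
        if v >= tree.n_tips:
            visit.extend(int(c) for c in tree.children[v])
    for node in preorder:
        if node == tree.root:
            continue
        dt = tree.branch_length(node)
        pmats = model.transition_matrices(rate * cat_rates * dt)  # (K,4,4)
        parent_state = states[int(tree.parent[node])]
        child = np.empty(seq_length, dtype=np.int64)
        u = rng.random(seq_length)
        for c in range(K):
            sel = site_cat == c
            cdf = np.cumsum(pmats[c], axis=1)
            child[sel] = (u[sel, None] > cdf[parent_state[sel]]).sum(axis=1)
        states[node] = child

    rows = []
    for t in range(tree.n_tips):
        seq = _BASES[states[t]].copy()
        if missing_frac > 0:
            n_mask = int(round(missing_frac * seq_length))
            run = n_mask // 2
            start = 0
            if run > 0:
                start = int(rng.integers(0, max(1, seq_length - run)))
                seq[start : start + run] = "N"
            outside = np.concatenate(
                [np.arange(0, start), np.arange(start + run, seq_length)]
            )
            scatter = rng.choice(outside, size=n_mask - run, replace=False)
            seq[scatter] = "N"
        rows.append("".join(seq))
    return Alignment(list(tree.labels), rows)


def simulate_dataset(config: SimConfig) -> tuple[Alignment, GroundTruth]:
    """Genealogy + alignment + ground truth under one configuration."""
    tree = simulate_coalescent_tree(config.tip_ages, config.pop_size, config.seed)
    aln = simulate_sequences(
        tree,
        config.rate,
        config.kappa,
        config.alpha,
        config.base_freqs,
        config.seq_length,
        seed=config.seed + 1,
        missing_frac=config.missing_frac,
    )
    truth = GroundTruth(
        true_tree=tree,
        true_params={
            "rate": config.rate,
            "pop_size": config.pop_size,
            "kappa": config.kappa,
            "alpha": config.alpha,
        },
        true_tip_ages={lab: float(a) for lab, a in zip(tree.labels, tree.tip_ages())},
    )
    return aln, truth


# ---------------------------------------------------------------------------
# ancient-DNA degradation


def degrade_to_reads(
    sequence: str,
    frag_mean: float = 55.0,
    frag_sd: float = 15.0,
    deamination_rate: float = 0.0,
    coverage: float = 10.0,
    seed: int = 0,
    decay: float = 0.5,
    double_stranded: bool = True,
    min_length: int = 20,
    mapq: int = 60,
) -> ReadSet:
    """Fragment a genome into an aDNA-style read set.

    Fragments are tiled at random positions to the target mean depth,
    with Normal(frag_mean, frag_sd) lengths (truncated at
    ``min_length``).  Deamination applies C->T at the 5' end with
    per-offset probability ``deamination_rate * decay**offset``; in
    double-stranded mode the complementary G->A pattern is applied at
    the 3' end.  Fragment sequences are stored in reference orientation.
    """
    if not 0 <= deamination_rate < 1:
        raise ValueError("deamination_rate must be in [0, 1)")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    ref = np.array(list(sequence.upper()))
    L = len(ref)
    n_frags = int(np.ceil(coverage * L / frag_mean))

    frags: list[Fragment] = []
    lengths = np.maximum(
        np.round(rng.normal(frag_mean, frag_sd, n_frags)).astype(int), min_length
    )
    np.minimum(lengths, L, out=lengths)
    starts = rng.integers(0, np.maximum(L - lengths + 1, 1))
    strands = rng.choice(["+", "-"], size=n_frags)
    # damage window long enough that decay**w is negligible
    w = 30
    offsets = np.arange(w)
    p_damage = deamination_rate * decay ** offsets
    for s, length, strand in zip(starts, lengths, strands):
        seq = ref[s : s + length].copy()
        if deamination_rate > 0:
            wl = min(w, length)
            u5 = rng.random(wl)
            hit5 = (seq[:wl] == "C") & (u5 < p_damage[:wl])
            seq[:wl][hit5] = "T"
            if double_stranded:
                u3 = rng.random(wl)
                tail = seq[length - wl :]
                hit3 = (tail[::-1] == "G") & (u3 < p_damage[:wl])
                tail[::-1][hit3] = "A"
                seq[length - wl :] = tail
        frags.append(
            Fragment(int(s), int(s + length), str(strand), "".join(seq), mapq=mapq)
        )
    return ReadSet(frags)


def make_pileup(read_set: ReadSet, reference_length: int) -> np.ndarray:
    """Per-position A/C/G/T counts, shape (reference_length, 4).

    N bases in fragments contribute to no count; depth at a position is
    the row sum.
    """
    counts = np.zeros((reference_length, 4), dtype=np.int64)
    for frag in read_set:
        if frag.start < 0 or frag.end > reference_length:
            raise ValueError(
                f"fragment [{frag.start},{frag.end}) outside reference "
                f"of length {reference_length}"
            )
        codes = encode_sequence(frag.sequence)
        pos = np.arange(frag.start, frag.end)
        keep = codes < 4
        np.add.at(counts, (pos[keep], codes[keep].astype(np.int64)), 1)
    return counts
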