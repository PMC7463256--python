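"""Bayesian tip-date estimation by Metropolis-Hastings MCMC.

The model: HKY+G4 likelihood on a time-tree, a constant-population-size
coalescent tree prior, and a strict molecular clock.  Sampling times of
dated tips calibrate the clock; tips without dates get their ages
sampled as parameters under a bounded gamma prior (default
Gamma(shape=1, scale=200,000 yr) truncated to [50 ky, 800 ky] BP — the
practical windows of radiocarbon dating below and ancient-DNA survival
above).  Two procedures are provided:

* ``joint_dating`` — all undated tips estimated simultaneously,
* ``individual_dating`` — each undated tip first estimated alone
  against the dated tips, the resulting marginal re-encoded as that
  tip's prior (boundary-reflected KDE), then a combined run.

Internally ages are years before the youngest *fixed* tip; absolute
years-BP bounds are shifted onto this scale via
``TipDateSpec.reference_age`` (13,000 yr in the motivating dataset).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist
from scipy.stats import gaussian_kde

from .phylo import (
    Alignment,
    PruningEngine,
    SubstModel,
    coalescent_log_density,
    empirical_base_freqs,
)
from .tree import TimeTree

__all__ = [
    "TipDate",
    "TipDateSpec",
    "ClockPriors",
    "McmcConfig",
    "Trace",
    "PriorSpec",
    "log_posterior",
    "mcmc_run",
    "joint_dating",
    "individual_dating",
    "fit_prior",
    "hpd_interval",
    "summarize",
    "DatingResult",
]


# ---------------------------------------------------------------------------
# specifications


@dataclass
class TipDate:
    """Dating status of one tip.

    ``point_age`` (fixed tips) and the bounds are years BP; with
    ``TipDateSpec.bounds_absolute`` (default) they are converted to the
    internal scale by subtracting ``reference_age``.
    """

    status: str                      # 'fixed' | 'estimated'
    point_age: float | None = None   # years BP, fixed tips
    prior_shape: float = 1.0
    prior_scale: float = 200_000.0
    lower: float = 50_000.0          # years BP
    upper: float = 800_000.0
    prior_spec: "PriorSpec | None" = None  # overrides the gamma when set

    def __post_init__(self):
        if self.status not in ("fixed", "estimated"):
            raise ValueError(f"unknown tip status {self.status!r}")
        if self.status == "fixed" and self.point_age is None:
            raise ValueError("fixed tips need point_age")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be < upper bound")


@dataclass
class TipDateSpec:
    tips: dict[str, TipDate]
    reference_age: float = 0.0       # years BP of the youngest fixed tip
    bounds_absolute: bool = True     # bounds stated in BP (vs already relative)

    def fixed_labels(self) -> list[str]:
        return [l for l, t in self.tips.items() if t.status == "fixed"]

    def estimated_labels(self) -> list[str]:
        return [l for l, t in self.tips.items() if t.status == "estimated"]

    def rel_age(self, label: str) -> float:
        t = self.tips[label]
        if t.point_age is None:
            raise ValueError(f"tip {label} has no point age")
        return float(t.point_age) - self.reference_age

    def rel_bounds(self, label: str) -> tuple[float, float]:
        t = self.tips[label]
        if self.bounds_absolute:
            lo = max(t.lower - self.reference_age, 0.0)
            hi = t.upper - self.reference_age
        else:
            lo, hi = max(t.lower, 0.0), t.upper
        if not lo < hi:
            raise ValueError(f"empty bound interval for tip {label}")
        return lo, hi

    def to_bp(self, rel_age) -> np.ndarray:
        return np.asarray(rel_age) + self.reference_age

    def subset(self, labels) -> "TipDateSpec":
        return TipDateSpec(
            {l: self.tips[l] for l in labels},
            reference_age=self.reference_age,
            bounds_absolute=self.bounds_absolute,
        )


@dataclass
class ClockPriors:
    """Uniform priors on the strict-clock rate and coalescent size."""

    rate_lower: float = 4e-10        # substitutions/site/year
    rate_upper: float = 8e-8
    pop_lower: float = 1.0           # years (Ne * generation time)
    pop_upper: float = 1e6

    def __post_init__(self):
        if not (0 < self.rate_lower < self.rate_upper):
            raise ValueError("rate prior bounds must be positive and ordered")
        if not (0 < self.pop_lower < self.pop_upper):
            raise ValueError("pop-size prior bounds must be positive and ordered")

    def log_rate_prior(self, rate: float) -> float:
        if self.rate_lower <= rate <= self.rate_upper:
            return -np.log(self.rate_upper - self.rate_lower)
        return -np.inf

    def log_pop_prior(self, pop: float) -> float:
        if self.pop_lower <= pop <= self.pop_upper:
            return -np.log(self.pop_upper - self.pop_lower)
        return -np.inf


@dataclass
class McmcConfig:
    chain_length: int = 100_000
    sample_every: int = 100
    burnin_fraction: float = 0.1
    tip_move_weight: float = 5.0     # relative weight of tip-age proposals
    topology_moves: bool = False
    n_replicates: int = 2
    seed: int = 0
    tune: bool = True                # adapt proposal scales during burn-in only

    def __post_init__(self):
        if self.chain_length % self.sample_every:
            raise ValueError("chain_length must be divisible by sample_every")
        if self.tip_move_weight <= 0:
            raise ValueError("weights must be positive")


@dataclass
class Trace:
    """Post-burn-in MCMC samples plus move-acceptance diagnostics."""

    data: pd.DataFrame               # step, posterior, likelihood, prior, ...
    acceptance: dict
    seed: int

    def __post_init__(self):
        steps = self.data["step"].to_numpy()
        if len(steps) and np.any(np.diff(steps) <= 0):
            raise ValueError("trace steps must be strictly increasing")

    def __len__(self):
        return len(self.data)

    def __getitem__(self, col):
        return self.data[col].to_numpy()


# ---------------------------------------------------------------------------
# priors on tip ages


class _TruncatedGamma:
    """Gamma(shape, scale) renormalised to [lower, upper]."""

    def __init__(self, shape, scale, lower, upper):
        self.shape, self.scale = shape, scale
        self.lower, self.upper = lower, upper
        z = _gamma_dist.cdf(upper, a=shape, scale=scale) - _gamma_dist.cdf(
            lower, a=shape, scale=scale
        )
        if z <= 0:
            raise ValueError("gamma prior has no mass inside the bounds")
        # closed-form log-pdf constant (scipy's generic logpdf is ~100x slower)
        self._const = -math.lgamma(shape) - shape * math.log(scale) - math.log(z)

    def logpdf(self, x: float) -> float:
        if not self.lower <= x <= self.upper:
            return -np.inf
        if x <= 0:
            return -np.inf if self.shape > 1 else self._const - x / self.scale
        return self._const + (self.shape - 1.0) * math.log(x) - x / self.scale


@dataclass
class PriorSpec:
    """A univariate density on [lower, upper] encoded on a grid.

    Used to carry a stage-1 marginal posterior forward as a stage-2
    prior in the individually-dated procedure.
    """

    grid: np.ndarray
    density: np.ndarray
    lower: float
    upper: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        z = np.trapezoid(self.density, self.grid)
        if abs(z - 1.0) > 1e-3:
            raise ValueError(f"PriorSpec density integrates to {z:.6f}, not 1")

    def logpdf(self, x: float) -> float:
        if not self.lower <= x <= self.upper:
            return -np.inf
        d = float(np.interp(x, self.grid, self.density))
        return np.log(d) if d > 0 else -np.inf

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))


def fit_prior(samples, lower: float, upper: float, n_grid: int = 512) -> PriorSpec:
    """Boundary-reflected KDE of MCMC samples, normalised on [lower, upper]."""
    samples = np.asarray(samples, dtype=float)
    inside = samples[(samples >= lower) & (samples <= upper)]
    if len(inside) < 100:
        raise ValueError(
            f"need >= 100 samples within [{lower:g}, {upper:g}], got {len(inside)}"
        )
    grid = np.linspace(lower, upper, n_grid)
    if np.std(inside) == 0:
        # degenerate chain: near-point-mass at the sampled value
        sd = max((upper - lower) * 1e-3, 1e-12)
        dens = np.exp(-0.5 * ((grid - inside[0]) / sd) ** 2)
    else:
        augmented = np.concatenate([inside, 2 * lower - inside, 2 * upper - inside])
        # Silverman bandwidth from the *unaugmented* samples: the default
        # (augmented std) over-smooths and biases boundary-peaked densities
        iqr = np.subtract(*np.percentile(inside, [75, 25]))
        h = 0.9 * min(inside.std(), iqr / 1.34 if iqr > 0 else np.inf)
        h *= len(inside) ** -0.2
        dens = gaussian_kde(augmented, bw_method=h / augmented.std())(grid)
    dens = np.maximum(dens, 0.0)
    dens /= np.trapezoid(dens, grid)
    return PriorSpec(grid, dens, lower, upper)


# ---------------------------------------------------------------------------
# posterior


def _tip_log_prior(spec: TipDateSpec, label: str, rel_age: float) -> float:
    t = spec.tips[label]
    lo, hi = spec.rel_bounds(label)
    if t.prior_spec is not None:
        return t.prior_spec.logpdf(rel_age)
    return _TruncatedGamma(t.prior_shape, t.prior_scale, lo, hi).logpdf(rel_age)


def log_posterior(
    state: tuple[TimeTree, float, float],
    alignment: Alignment | None,
    tip_spec: TipDateSpec,
    clock_priors: ClockPriors,
    model: SubstModel,
    include_coalescent: bool = True,
) -> float:
    """Un-normalised log posterior of (tree, rate, pop_size).

    Estimated tip ages are read off the tree.  Returns -inf outside any
    prior bound; an empty/None alignment contributes log-likelihood 0.
    """
    tree, rate, pop_size = state
    lp = clock_priors.log_rate_prior(rate) + clock_priors.log_pop_prior(pop_size)
    if not np.isfinite(lp):
        return -np.inf
    idx = {l: i for i, l in enumerate(tree.labels)}
    for label in tip_spec.estimated_labels():
        lp += _tip_log_prior(tip_spec, label, float(tree.ages[idx[label]]))
        if not np.isfinite(lp):
            return -np.inf
    if include_coalescent:
        lp += coalescent_log_density(tree, pop_size)
    if alignment is not None and alignment.length > 0:
        model = replace(model, rate=rate, _eig=None, _cat_rates=None)
        engine = PruningEngine(tree, alignment, model)
        lp += engine.log_likelihood()
    return float(lp)


# ---------------------------------------------------------------------------
# the sampler


class _Chain:
    """One Metropolis-Hastings chain with incremental likelihood updates."""

    TARGET_ACC = 0.3

    def __init__(self, alignment, start_tree, tip_spec, clock_priors, model,
                 config, seed, prior_only=False):
        self.rng = np.random.default_rng(seed)
        self.spec = tip_spec
        self.priors = clock_priors
        self.config = config
        self.prior_only = prior_only

        self.tree = start_tree.copy() if start_tree is not None else None
        if self.tree is not None:
            self.idx = {l: i for i, l in enumerate(self.tree.labels)}
        self.est_labels = tip_spec.estimated_labels()
        self.est_bounds = {l: tip_spec.rel_bounds(l) for l in self.est_labels}
        self.tip_priors = {}
        for l in self.est_labels:
            t = tip_spec.tips[l]
            lo, hi = self.est_bounds[l]
            self.tip_priors[l] = (
                t.prior_spec
                if t.prior_spec is not None
                else _TruncatedGamma(t.prior_shape, t.prior_scale, lo, hi)
            )

        self.rate = float(model.rate)
        self.pop_size = 1e5 if clock_priors.pop_lower < 1e5 < clock_priors.pop_upper \
            else np.sqrt(clock_priors.pop_lower * clock_priors.pop_upper)
        if not clock_priors.rate_lower <= self.rate <= clock_priors.rate_upper:
            self.rate = np.sqrt(clock_priors.rate_lower * clock_priors.rate_upper)

        if prior_only:
            self.engine = None
            # prior-only mode keeps tip ages as free scalars, no genealogy
            self.tip_age = {
                l: 0.5 * (self.est_bounds[l][0] + self.est_bounds[l][1])
                for l in self.est_labels
            }
        else:
            if self.tree is None:
                raise ValueError("start_tree required unless prior_only")
            use_model = replace(model, rate=self.rate, _eig=None, _cat_rates=None)
            if alignment is not None and alignment.length > 0:
                self.engine = PruningEngine(self.tree, alignment, use_model)
                self.loglik = self.engine.log_likelihood()
            else:
                self.engine = None
                self.loglik = 0.0
            self.log_coal = coalescent_log_density(self.tree, self.pop_size)
        if prior_only:
            self.loglik, self.log_coal = 0.0, 0.0

        self.log_tip_prior = self._tip_prior_total()
        self.log_rate_p = clock_priors.log_rate_prior(self.rate)
        self.log_pop_p = clock_priors.log_pop_prior(self.pop_size)
        post = self.posterior()
        if not np.isfinite(post):
            raise ValueError(self._diagnose_start())

        # proposal scales (tuned during burn-in only)
        self.scales = {"rate": 0.3, "pop": 1.0, "root": 0.5}
        self.tip_scales = {
            l: 0.2 * (hi - lo) for l, (lo, hi) in self.est_bounds.items()
        }
        self.acc = {}
        self.tries = {}
        self._tune_acc = {}
        self._tune_tries = {}

        self._build_move_table()

    # -- bookkeeping ---------------------------------------------------

    def _tip_age_of(self, label):
        if self.prior_only:
            return self.tip_age[label]
        return float(self.tree.ages[self.idx[label]])

    def _tip_prior_total(self):
        return sum(
            self.tip_priors[l].logpdf(self._tip_age_of(l)) for l in self.est_labels
        )

    def posterior(self):
        return (
            self.loglik + self.log_coal + self.log_tip_prior
            + self.log_rate_p + self.log_pop_p
        )

    def _diagnose_start(self):
        terms = {
            "likelihood": self.loglik,
            "coalescent prior": self.log_coal,
            "tip-age priors": self.log_tip_prior,
            "rate prior": self.log_rate_p,
            "pop-size prior": self.log_pop_p,
        }
        bad = [k for k, v in terms.items() if not np.isfinite(v)]
        return f"start state has -inf posterior; offending terms: {bad}"

    def _build_move_table(self):
        moves = [("rate", 1.0), ("pop", 1.0)]
        if not self.prior_only:
            n_internal = self.tree.n_tips - 1
            moves.append(("node_age", float(n_internal)))
            if self.config.topology_moves and self.tree.n_tips >= 4:
                moves.append(("topology", float(self.tree.n_tips) / 2))
        if self.est_labels:
            moves.append(("tip_age", self.config.tip_move_weight * len(self.est_labels)))
        names, weights = zip(*moves)
        w = np.asarray(weights)
        self.move_names = list(names)
        self.move_cdf = np.cumsum(w / w.sum())
        self._move_funcs = [getattr(self, f"_move_{n}") for n in names]
        for name in names:
            self.acc[name] = 0
            self.tries[name] = 0
            self._tune_acc[name] = 0
            self._tune_tries[name] = 0

    def _record(self, move, accepted, tuning):
        self.tries[move] += 1
        self.acc[move] += accepted
        if tuning:
            self._tune_tries[move] += 1
            self._tune_acc[move] += accepted
            if self._tune_tries[move] >= 100:
                rate = self._tune_acc[move] / self._tune_tries[move]
                factor = np.exp(np.clip(rate - self.TARGET_ACC, -0.5, 0.5))
                if move in ("rate", "pop"):
                    self.scales[move] = float(
                        np.clip(self.scales[move] * factor, 1e-3, 5.0)
                    )
                elif move == "tip_age":
                    for l, (lo, hi) in self.est_bounds.items():
                        self.tip_scales[l] = float(
                            np.clip(self.tip_scales[l] * factor,
                                    1e-6 * (hi - lo), hi - lo)
                        )
                elif move == "node_age":
                    self.scales["root"] = float(
                        np.clip(self.scales["root"] * factor, 1e-3, 5.0)
                    )
                self._tune_acc[move] = 0
                self._tune_tries[move] = 0

    # -- individual moves ----------------------------------------------

    @staticmethod
    def _reflect(x, lo, hi):
        width = hi - lo
        y = (x - lo) % (2 * width)
        return lo + (y if y <= width else 2 * width - y)

    def _move_rate(self, tuning):
        s = self.scales["rate"]
        factor = np.exp(s * (self.rng.random() - 0.5))
        new = self.rate * factor
        log_hastings = np.log(factor)
        new_p = self.priors.log_rate_prior(new)
        if not np.isfinite(new_p):
            self._record("rate", False, tuning)
            return
        old_rate = self.rate
        new_ll = (
            self.engine.rate_changed(new) if self.engine is not None else self.loglik
        )
        delta = (new_ll - self.loglik) + (new_p - self.log_rate_p) + log_hastings
        if np.log(self.rng.random()) < delta:
            self.rate, self.loglik, self.log_rate_p = new, new_ll, new_p
            self._record("rate", True, tuning)
        else:
            if self.engine is not None:
                self.engine.rate_changed(old_rate)
            self._record("rate", False, tuning)

    def _move_pop(self, tuning):
        s = self.scales["pop"]
        factor = np.exp(s * (self.rng.random() - 0.5))
        new = self.pop_size * factor
        new_p = self.priors.log_pop_prior(new)
        if not np.isfinite(new_p):
            self._record("pop", False, tuning)
            return
        new_coal = (
            0.0 if self.prior_only else coalescent_log_density(self.tree, new)
        )
        delta = (new_coal - self.log_coal) + (new_p - self.log_pop_p) + np.log(factor)
        if np.log(self.rng.random()) < delta:
            self.pop_size, self.log_coal, self.log_pop_p = new, new_coal, new_p
            self._record("pop", True, tuning)
        else:
            self._record("pop", False, tuning)

    def _move_node_age(self, tuning):
        tree = self.tree
        node = int(self.rng.integers(tree.n_tips, tree.n_nodes))
        old_age = tree.ages[node]
        kids = tree.children[node]
        floor = max(tree.ages[int(kids[0])], tree.ages[int(kids[1])])
        parent = int(tree.parent[node])
        if parent == -1:
            # root: multiplicative move on the gap above the older child
            gap = old_age - floor
            factor = np.exp(self.scales["root"] * (self.rng.random() - 0.5))
            new_age = floor + gap * factor
            log_hastings = np.log(factor)
        else:
            ceil = tree.ages[parent]
            new_age = self.rng.uniform(floor, ceil)
            log_hastings = 0.0
        self._try_age_change(node, old_age, new_age, log_hastings, "node_age", tuning)

    def _move_tip_age(self, tuning):
        label = self.est_labels[int(self.rng.integers(len(self.est_labels)))]
        lo, hi = self.est_bounds[label]
        step = self.tip_scales[label] * (self.rng.random() - 0.5) * 2
        if self.prior_only:
            old = self.tip_age[label]
            new = self._reflect(old + step, lo, hi)
            d_prior = self.tip_priors[label].logpdf(new) - self.tip_priors[label].logpdf(old)
            if np.log(self.rng.random()) < d_prior:
                self.tip_age[label] = new
                self.log_tip_prior += d_prior
                self._record("tip_age", True, tuning)
            else:
                self._record("tip_age", False, tuning)
            return
        node = self.idx[label]
        old = float(self.tree.ages[node])
        new = self._reflect(old + step, lo, hi)
        parent = int(self.tree.parent[node])
        if new >= self.tree.ages[parent]:
            self._record("tip_age", False, tuning)  # would invert the branch
            return
        self._try_age_change(node, old, new, 0.0, "tip_age", tuning, tip_label=label)

    def _try_age_change(self, node, old_age, new_age, log_hastings, move, tuning,
                        tip_label=None):
        tree = self.tree
        d_tip_prior = 0.0
        if tip_label is not None:
            pr = self.tip_priors[tip_label]
            d_tip_prior = pr.logpdf(new_age) - pr.logpdf(old_age)
            if not np.isfinite(d_tip_prior):
                self._record(move, False, tuning)
                return
        tree.ages[node] = new_age
        new_coal = coalescent_log_density(tree, self.pop_size)
        new_ll = (
            self.engine.node_age_changed(node)
            if self.engine is not None
            else self.loglik
        )
        delta = (
            (new_ll - self.loglik) + (new_coal - self.log_coal)
            + d_tip_prior + log_hastings
        )
        if np.log(self.rng.random()) < delta:
            self.loglik, self.log_coal = new_ll, new_coal
            self.log_tip_prior += d_tip_prior
            self._record(move, True, tuning)
        else:
            tree.ages[node] = old_age
            if self.engine is not None:
                self.engine.node_age_changed(node)
            self._record(move, False, tuning)

    def _move_topology(self, tuning):
        """Narrow exchange: swap an internal node's child with its sibling."""
        tree = self.tree
        internal = [
            n for n in range(tree.n_tips, tree.n_nodes) if tree.parent[n] != -1
        ]
        if not internal:
            self._record("topology", False, tuning)
            return
        c = int(self.rng.choice(internal))
        p = int(tree.parent[c])
        sib = int(tree.children[p][0] if tree.children[p][1] == c else tree.children[p][1])
        g = int(tree.children[c][int(self.rng.integers(2))])
        if tree.ages[c] <= tree.ages[sib]:
            self._record("topology", False, tuning)
            return
        self._exchange(p, c, sib, g)
        new_coal = coalescent_log_density(tree, self.pop_size)
        new_ll = self.engine.full_recompute() if self.engine is not None else 0.0
        delta = (new_ll - self.loglik) + (new_coal - self.log_coal)
        if np.log(self.rng.random()) < delta:
            self.loglik, self.log_coal = new_ll, new_coal
            self._record("topology", True, tuning)
        else:
            self._exchange(p, c, g, sib)  # undo: swap back
            if self.engine is not None:
                self.engine.full_recompute()
            self._record("topology", False, tuning)

    def _exchange(self, p, c, child_of_p, child_of_c):
        """Swap ``child_of_p`` (attached to p) with ``child_of_c`` (attached to c)."""
        tree = self.tree
        kids = tree.children[p]
        kids[0 if kids[0] == child_of_p else 1] = child_of_c
        tree.parent[child_of_c] = p
        ckids = tree.children[c]
        ckids[0 if ckids[0] == child_of_c else 1] = child_of_p
        tree.parent[child_of_p] = c
        tree._postorder = None

    # -- main loop -----------------------------------------------------

    def run(self, track_nodes=None) -> Trace:
        cfg = self.config
        burnin = int(cfg.burnin_fraction * cfg.chain_length)
        track_nodes = track_nodes or {}
        records = []
        cols = (
            ["step", "posterior", "likelihood", "prior", "rate", "pop_size"]
            + [f"age_{l}" for l in self.est_labels]
            + [f"age_{name}" for name in track_nodes]
        )
        for step in range(1, cfg.chain_length + 1):
            tuning = cfg.tune and step <= burnin
            u = self.rng.random()
            self._move_funcs[int(np.searchsorted(self.move_cdf, u))](tuning)
            if step > burnin and step % cfg.sample_every == 0:
                row = [
                    step,
                    self.posterior(),
                    self.loglik,
                    self.posterior() - self.loglik,
                    self.rate,
                    self.pop_size,
                ]
                row += [self._tip_age_of(l) for l in self.est_labels]
                for name, labels in track_nodes.items():
                    row.append(float(self.tree.ages[self.tree.mrca(labels)]))
                records.append(row)
        data = pd.DataFrame(records, columns=cols)
        acceptance = {
            m: (self.acc[m] / self.tries[m] if self.tries[m] else np.nan)
            for m in self.move_names
        }
        return Trace(data=data, acceptance=acceptance, seed=cfg.seed)


def mcmc_run(
    alignment: Alignment | None,
    start_tree: TimeTree | None,
    tip_spec: TipDateSpec,
    clock_priors: ClockPriors | None = None,
    model: SubstModel | None = None,
    config: McmcConfig | None = None,
    prior_only: bool = False,
    track_nodes: dict | None = None,
) -> Trace:
    """Run one Metropolis-Hastings chain and return post-burn-in samples.

    Moves: multiplier proposals on rate and pop_size, uniform node-age
    slides bounded by each node's oldest child and its parent (a
    multiplier on the root gap), reflecting random walks on estimated
    tip ages (relative weight ``tip_move_weight`` per tip), and optional
    narrow-exchange topology moves.  Proposal scales adapt toward ~30%
    acceptance during burn-in only, then freeze, preserving detailed
    balance for the retained samples.

    ``prior_only=True`` samples the dating priors alone — no likelihood
    and no genealogy terms — so each estimated tip's marginal is exactly
    its (truncated) prior; used for prior-predictive validation.
    """
    clock_priors = clock_priors or ClockPriors()
    if model is None:
        freqs = (
            empirical_base_freqs(alignment)
            if alignment is not None and alignment.length
            else np.full(4, 0.25)
        )
        model = SubstModel(kappa=20.0, base_freqs=freqs, alpha=0.5, rate=2e-8)
    config = config or McmcConfig()
    chain = _Chain(
        alignment, start_tree, tip_spec, clock_priors, model, config,
        seed=config.seed, prior_only=prior_only,
    )
    return chain.run(track_nodes=track_nodes)


# ---------------------------------------------------------------------------
# posterior summaries


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ceil(mass*n) sorted samples."""
    samples = np.sort(np.asarray(samples, dtype=float))
    n = len(samples)
    if n == 0:
        raise ValueError("empty sample set")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(samples[0]), float(samples[-1])
    widths = samples[m - 1 :] - samples[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lower start
    return float(samples[i]), float(samples[i + m - 1])


def _ess(x: np.ndarray) -> float:
    if np.std(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x[None, :]))


def _histogram_mode(x: np.ndarray, bins: int = 50) -> float:
    counts, edges = np.histogram(x, bins=bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def summarize(
    trace: Trace | list[Trace],
    targets: list[str] | None = None,
    mass: float = 0.95,
    ess_warn: float = 200.0,
) -> pd.DataFrame:
    """Median, HPD interval, ESS and histogram mode per tracked parameter.

    Accepts one trace or a list of replicate traces (pooled for the
    summaries; ESS computed on the pooled draws).  Warns when any ESS
    falls below ``ess_warn``.
    """
    traces = trace if isinstance(trace, list) else [trace]
    if not traces or all(len(t) == 0 for t in traces):
        raise ValueError("empty trace")
    skip = {"step"}
    cols = targets or [c for c in traces[0].data.columns if c not in skip]
    rows = []
    for col in cols:
        x = np.concatenate([t[col] for t in traces])
        lo, hi = hpd_interval(x, mass)
        ess = _ess(x)
        if ess < ess_warn:
            warnings.warn(f"low ESS for {col}: {ess:.0f} < {ess_warn:.0f}")
        rows.append(
            {
                "parameter": col,
                "median": float(np.median(x)),
                f"hpd{int(mass*100)}_low": lo,
                f"hpd{int(mass*100)}_high": hi,
                "ess": ess,
                "mode": _histogram_mode(x),
                "n": len(x),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the two study procedures


@dataclass
class DatingResult:
    summary: pd.DataFrame            # per estimated tip / tracked node, years BP
    traces: list[Trace]
    stage1: dict | None = None       # individual procedure diagnostics


def _replicate_traces(alignment, start_tree, tip_spec, clock_priors, model,
                      config, prior_only=False, track_nodes=None) -> list[Trace]:
    traces = []
    for r in range(config.n_replicates):
        cfg = replace(config, seed=config.seed + 1000 * r)
        traces.append(
            mcmc_run(alignment, start_tree, tip_spec, clock_priors, model, cfg,
                     prior_only=prior_only, track_nodes=track_nodes)
        )
    return traces


def _bp_summary(summary: pd.DataFrame, tip_spec: TipDateSpec) -> pd.DataFrame:
    """Shift age columns from the internal scale to years BP."""
    out = summary.copy()
    agelike = out["parameter"].str.startswith("age_")
    for col in out.columns:
        if col in ("median", "mode") or col.startswith("hpd"):
            out.loc[agelike, col] = out.loc[agelike, col] + tip_spec.reference_age
    return out


def joint_dating(
    alignment: Alignment,
    start_tree: TimeTree,
    tip_spec: TipDateSpec,
    clock_priors: ClockPriors | None = None,
    model: SubstModel | None = None,
    config: McmcConfig | None = None,
    track_nodes: dict | None = None,
) -> DatingResult:
    """Joint procedure: all undated tips estimated in a single analysis."""
    if not tip_spec.estimated_labels() and not track_nodes:
        track_nodes = {"root": list(start_tree.labels)}
    config = config or McmcConfig()
    traces = _replicate_traces(
        alignment, start_tree, tip_spec, clock_priors, model, config,
        track_nodes=track_nodes,
    )
    summary = summarize(traces)
    return DatingResult(summary=_bp_summary(summary, tip_spec), traces=traces)


def individual_dating(
    alignment: Alignment,
    start_tree: TimeTree,
    tip_spec: TipDateSpec,
    clock_priors: ClockPriors | None = None,
    model: SubstModel | None = None,
    config: McmcConfig | None = None,
    track_nodes: dict | None = None,
) -> DatingResult:
    """Individually-dated procedure (three stages).

    1.  Each undated tip is dated alone against all fixed-date tips.
    2.  Each stage-1 marginal age posterior is re-encoded as that tip's
        prior via a boundary-reflected KDE.
    3.  A combined run over all tips uses the stage-2 priors in place of
        the original gamma priors.
    """
    config = config or McmcConfig()
    est = tip_spec.estimated_labels()
    if not est:
        raise ValueError("no estimated tips")
    fixed = tip_spec.fixed_labels()

    stage1: dict[str, Trace] = {}
    priors: dict[str, PriorSpec] = {}
    for k, label in enumerate(est):
        sub_labels = fixed + [label]
        sub_spec = tip_spec.subset(sub_labels)
        sub_aln = alignment.subset(sub_labels)
        sub_tree = start_tree.induced_subtree(sub_labels)
        cfg = replace(config, seed=config.seed + 7919 * (k + 1))
        tr = mcmc_run(sub_aln, sub_tree, sub_spec, clock_priors, model, cfg)
        stage1[label] = tr
        lo, hi = tip_spec.rel_bounds(label)
        priors[label] = fit_prior(tr[f"age_{label}"], lo, hi)

    stage3_spec = TipDateSpec(
        {
            l: (replace(t, prior_spec=priors[l]) if l in priors else t)
            for l, t in tip_spec.tips.items()
        },
        reference_age=tip_spec.reference_age,
        bounds_absolute=tip_spec.bounds_absolute,
    )
    traces = _replicate_traces(
        alignment, start_tree, stage3_spec, clock_priors, model, config,
        track_nodes=track_nodes,
    )
    summary = summarize(traces)
    return DatingResult(
        summary=_bp_summary(summary, tip_spec),
        traces=traces,
        stage1={l: summarize(t) for l, t in stage1.items()},
    )
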