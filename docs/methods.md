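# Methods

## Model

`tipchron` implements Bayesian molecular-clock dating for
heterochronous (serially sampled) sequence data. The generative model
has four parts.

**Substitution model.** HKY with transition/transversion rate ratio κ,
equilibrium frequencies π estimated empirically from the alignment
(N and gaps excluded), and among-site rate variation discretised into
4 equal-probability gamma categories. Category rates are the quantile
medians of Gamma(α, 1/α), normalised to mean 1 — the usual "+G4"
discretisation. The rate matrix is normalised to one expected
substitution per site per unit of rate × time, so the strict-clock
rate μ is directly in substitutions/site/year. Transition
probabilities use the spectral decomposition of the reversible
generator (symmetrised with √π), which is exact and cheap to
re-evaluate per branch; a test pins it against `scipy.linalg.expm` at
1e-10.

**Tree prior.** The constant-population-size coalescent for serial
samples. Time is measured in years before the youngest fixed-date tip;
the population-size parameter N therefore carries units of effective
size × generation time in years, matching the timescale on which its
uniform prior [1, 10⁶] is meaningful. The log-density accumulates
−k(k−1)Δt/2N over inter-event intervals with k active lineages and
−log N per coalescence.

**Tip-age priors.** Fixed tips have point ages (calibrated radiocarbon
medians treated as exact — calibration uncertainty is deliberately not
propagated, matching standard practice when medians are reported).
Estimated tips have Gamma(shape 1, scale 200,000 yr) priors truncated
and renormalised to [lower, upper] bounds, defaulting to 50–800 ky BP
with per-tip overrides (e.g. a 0 lower bound for specimens that could
be late-glacial). Bounds are stated in years BP and shifted onto the
internal scale by subtracting the reference age of the youngest fixed
tip; a `bounds_absolute` switch admits the alternative reading in
which bounds are offsets on the tree's own scale. Truncation
renormalises rather than shifts the gamma, so posterior mass may abut
the lower bound — the behaviour expected for specimens whose sequences
carry little age signal.

**Clock priors.** Uniform on [4 × 10⁻¹⁰, 8 × 10⁻⁸] subs/site/yr for μ
and [1, 10⁶] for N.

## Sampler

Single-chain Metropolis–Hastings over (node ages, estimated tip ages,
μ, N), with replicate chains (default 2) at different seeds pooled for
summaries. Moves and their relative weights:

- estimated tip ages: reflecting random walk inside the prior bounds,
  weight 5 per tip (undated-age mixing is the bottleneck, hence the
  elevated weight); a proposal older than the tip's parent is rejected;
- internal node ages: uniform draw between the node's oldest child and
  its parent (symmetric); the root age uses a multiplier on the gap
  above its older child (Hastings-corrected);
- μ and N: log-scale multiplier moves (Hastings-corrected);
- topology: optional narrow exchange (uncle–nephew swap), off by
  default. The default is a fixed user-supplied topology with node-age
  moves only, which keeps desk-scale problems tractable; analyses that
  need topological uncertainty enable the flag.

Proposal scales adapt toward ~30 % acceptance in batches of 100 during
burn-in (default 10 % of the chain) and freeze afterwards, preserving
detailed balance for the retained samples. Likelihoods are evaluated
by pruning over compressed site patterns with per-node caching: an age
move re-computes only the affected branch matrices and the partials on
the path to the root; a rejected move restores the caches by
re-running the same deterministic update at the old age, which is
bit-identical to the pre-move state. Per-node rescaling is enabled
automatically above 80 tips or on detected underflow; below that,
double precision cannot underflow and the rescaling cost is skipped.
The fixed-order inner loops are numba-compiled when numba is present,
with a pure-numpy fallback producing the same results.

A `prior_only` mode samples μ, N and the tip-age priors with no
likelihood and no genealogy terms. This is the mode used to validate
the sampler against the analytic truncated prior: with the coalescent
included, tip ages and node ages are coupled and the tip-age marginal
is no longer the bare prior, so prior-reproduction checks would
conflate sampler correctness with that coupling.

**Joint vs individually dated.** The joint procedure frees all undated
tips at once. The individually-dated procedure runs one analysis per
undated tip (that tip plus all fixed-date tips, on the induced
subtree), re-encodes each marginal age posterior as a prior, and runs
a combined analysis with those priors. The re-encoding is a
boundary-reflected Gaussian KDE on the bound interval, normalised on a
512-point grid; the bandwidth is Silverman's rule computed on the
un-augmented samples (the reflected copies triple the apparent spread
and would over-smooth boundary-peaked marginals). With a single
undated tip the two procedures agree up to the double use of that
tip's data, which narrows but does not materially shift the marginal —
verified as a test.

**Summaries.** Median, shortest-interval HPD (exhaustive window search
over sorted samples, ties broken toward the lower start),
autocorrelation-based ESS via ArviZ with a warning below 200, and a
50-bin histogram mode (modes are reported because bounded, skewed age
marginals can have medians well away from their density peak).

## Synthetic data

The generator emulates the statistical structure the inference
assumes: serial coalescent genealogies (validated against the analytic
E[TMRCA] = 2N(1−1/n) and the shifted-exponential serial case), HKY+Γ₄
evolution from a root draw (validated against the JC69 closed form,
stationarity, and a chi-square goodness-of-fit of 3-taxon site-pattern
frequencies against the pruning likelihood), missing-data masking, and
aDNA read degradation — Normal(55, 15) fragment lengths tiled to a
target depth, C→T damage at 5′ ends decaying geometrically
(probability r·0.5^offset) with the complementary G→A pattern at 3′
ends in double-stranded mode. Damage magnitudes are free parameters;
published studies report terminal damage qualitatively, so defaults
(rate 0–0.3, decay 0.5) were chosen to resemble typical non-UDG
Pleistocene libraries. Fragments are stored in reference orientation
and damage is applied at the reference-left (5′) and reference-right
(3′) ends, which is what aggregated damage profiles of mapped reads
show; per-strand asymmetry is not modelled.

What the generator does **not** emulate: sequencing error beyond
deamination, indels, alignment error, reference bias, contamination,
and rate variation across lineages. Passing recovery tests therefore
demonstrates correctness of the inference machinery under its own
model, not robustness to real-data violations of it.

Parameter defaults (κ = 20, π = [0.32, 0.26, 0.13, 0.29], α = 0.5,
μ = 3 × 10⁻⁸/site/yr, N·g = 10⁵ yr, 16.5 kb) are typical of mammalian
mitochondrial data on a years timescale.

## Curation rules

Filtering keeps fragments with length ≥ 24 and MAPQ ≥ 30 (inclusive
boundaries). Duplicates are fragments sharing both mapped ends and
strand; the highest-MAPQ copy is kept. Consensus is the strict
majority base per position, masked to N for depth < 3, tied
majorities, positions inside region masks (e.g. the proboscidean
VNTR), and coverage outliers: depth > mean + 3 SD with at least two
bases each supported by ≥ 2 reads. The mean/SD are computed over
covered positions only (uncovered flanks would deflate the mean; a
switch admits the all-positions variant). The ≥2-reads-each
quantification of "multiallelic" is this package's choice — a single
stray read should not trigger masking. A consensus is "complete" when
strictly more than 80 % of reference positions are called.
Mask-reason labels apply one reason per position with precedence
region > low-depth > coverage-outlier > tie. No deamination-aware
recalling is attempted; majority calls at ≥3× depth are the curation
contract.

## Diversity statistics

F84 distances from transition/transversion proportions with pairwise
deletion of missing sites. Base frequencies default to
alignment-wide estimates — the default of the conventional
implementation (`ape::dist.dna`), against which the implementation is
pinned to 1e-9 in a test — with a per-pair pooled option. Saturated
or empty pairs yield NaN and are excluded (with a warning and a
reduced pair count) rather than clamped. Clade diversity π is the
mean of all pairwise distances among members; its "SD" is the sample
standard deviation across pairwise distances (n−1 denominator;
a population-SD switch exists since either convention appears in the
literature). Two-member groups report their single value labelled
"distance" rather than "pi".

## Numerical and design notes

- Pattern compression makes the likelihood cost scale with sequence
  diversity, not length: a 15 kb low-divergence alignment typically
  compresses to a few hundred patterns.
- All simulation and inference entry points take explicit seeds; fixed
  seeds give bit-identical traces, alignments and read sets.
- The verification battery (tests and `scripts/acceptance.py`) uses a
  reduced problem scale — 20-tip, 15 kb datasets and 2 × 10⁵-step
  chains — chosen so the full battery completes in minutes while the
  coverage statistics remain well-resolved; production analyses of
  ~35-taxon mitogenome sets warrant chains two to three orders of
  magnitude longer, as replicate-chain agreement and ESS should
  dictate.
- Known limitations: no relaxed clocks, no skyline/skygrid priors, no
  marginal-likelihood (model-comparison) machinery, fixed topology by
  default, and point treatment of calibrated dates.
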