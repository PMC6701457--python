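# Methods

`traitsmm` models discrete phenotypic characters as continuous-time Markov
chains on a phylogeny, with two structural devices layered on top of the
plain k-state model: *amalgamation*, which merges several elementary
characters into one chain over the Cartesian product of their state spaces
with a structured (sparse, tied) intensity matrix, and an *observation
layer*, which maps possibly many hidden states onto each observable symbol.
Together these express hierarchical dependencies between anatomical traits
(a tail-color character that only evolves, and is only observable, while a
tail is present) and hidden drivers of trait evolution (regulatory states
behind an observable phenotype). This note records the model conventions,
the numerical choices, what the simulations emulate, and the known
limitations.

## Structured intensity matrices

An elementary character is a labeled intensity matrix: nonnegative
off-diagonal rates, rows summing to zero. Amalgamation operators build
product chains:

* **Independent** (`kron_sum_amalgamate`): the Kronecker sum
  `Q1 ⊕ Q2 = Q1 ⊗ I + I ⊗ Q2`, applied successively for more than two
  characters. Exactly one component may change per transition; all
  simultaneous-change cells are structural zeros. For `n` characters with
  `omega` states each, the fraction of structurally nonzero cells is
  `[1 + n(omega−1)]/omega^n` and the rates occupy `n(omega−1)` secondary
  diagonals; both formulas are verified against exhaustive counts in the
  tests.
* **Switch-on** (`switch_amalgamate`): `Q1 ⊗ I + D ⊗ Q2`, where `D` is the
  diagonal 0/1 indicator of the controller states in which the dependent
  character is allowed to evolve. The product state space is unchanged; the
  dependent's transitions are zeroed wherever the controller is "off". In
  chains of switches (tail → armor → armor color) a character is active only
  when its entire controller chain is switched on; this is the anatomically
  consistent reading of a multi-level hierarchy.
* **Synchronous** (`synchronous_amalgamate`): for redundantly coded,
  mutually exclusive characters (red-present and blue-present as two binary
  characters). Only simultaneous two-component changes are allowed; the
  admissible combinations are given as a bijective pairing of the two state
  sets, the rate of a joint move is taken from the first matrix, and product
  states outside the pairing are unreachable and pruned (logged). Pruning
  the redundant pair recovers the plain two-state color character exactly.
* **General** (`general_smm`): every off-diagonal cell its own parameter
  (optionally tied); the maximally correlated model.

`build_from_dependency_graph` assembles any acyclic graph of characters with
typed edges into one hidden chain and derives the observation layer: a
character's state is shown in the observable symbol only if the character is
active, and a controller's state is dropped when it is implied by a visible
dependent (a visible tail color implies the tail). For the tail-color
problem this gives the familiar three observable symbols {a, r, b} over four
hidden states {ar, ab, pr, pb}; for the tail-armor chain, four observable
over eight hidden.

## Lumpability

Merging states of a chain yields another Markov chain only when the
row-wise sum rule holds (strong lumpability): within every source block, the
summed rates into each target block are equal across rows. The aggregated
matrix is `N P M Pᵀ` with `P` the 0/1 membership matrix and `N` the diagonal
of reciprocal block sizes — uniform within-block weighting, the classical
convention, which reproduces the worked tail example (aggregating the
independent tail-color amalgam over color recovers the tail character's
alpha/beta rates exactly). The default tolerance for the rule is relative
1e−9, scaled by the largest off-diagonal rate.

`lumpability_error` returns the worst within-block spread of block row sums:
zero iff strongly lumpable, and a useful diagnostic for *nearly lumpable*
chains — amalgams of many characters with i.i.d. random rates aggregate with
an error that shrinks as the number of amalgamated characters grows (shown
as a Monte-Carlo trend in the tests). Weak lumpability (initial-vector
dependent) is deliberately unsupported: the pruning likelihood does not
preserve it; the API reserves the name and raises.

Strongly lumpable aggregation is exactly likelihood-preserving: for data
observed at the aggregated level, the hidden-level and aggregated-level
log-likelihoods agree to numerical precision (tested to 1e−8). Non-lumpable
aggregations — e.g. reducing the four tail-color hidden states to the three
observable symbols — are where the hidden (HMM) machinery is mandatory: the
observation layer is exactly equivalent to ambiguous/polymorphic coding of
tips.

## Likelihoods, Mk conversion, fitting

Felsenstein pruning over the hidden space, with per-node rescaling and
site-pattern compression; `"?"` scores every hidden state, polymorphic cells
score the union of their symbols' hidden sets, and an inapplicable `"-"`
resolves to the designated switched-off symbol's hidden set when the
observation map declares one (otherwise it is treated as missing, the
conventional reading). Transition probabilities use an eigendecomposition
fast path with a reconstruction check and conditioning threshold, falling
back to scaling-and-squaring (`scipy` `expm`) for defective or
ill-conditioned generators.

`to_mk` converts a structured template into a one-free-parameter Mk-type
model: the template is rescaled to one expected change per unit time at
equilibrium, the root vector is the stationary distribution (requiring a
single communicating class), and the likelihood is conditioned on variable
characters: each character's likelihood is divided by one minus the
probability that every tip shows the same observable symbol. "Constant"
is defined at the observable level — what a scorer can see — not the hidden
level.

`DiscreteTraitModel.fit` maximizes the log-likelihood over log10-rates in
[−9, 2] by multi-start L-BFGS-B (10 starts by default; replicate
experiments use fewer starts and a looser `ftol` since the 2–4 parameter
surfaces are smooth — spot checks against 20-start fits agree to <0.01 log
units). Parameter tying defaults to grouping cells with equal template
values; an explicit cell → parameter map overrides it. Standard errors come
from a central-difference Hessian on log-rates (delta method); fits that
reach a bound or a singular Hessian report no SEs rather than spurious
ones. Non-convergence across all starts is flagged on the results object,
never silent. The root vector for non-Mk fits defaults to uniform over
hidden states (equilibrium optional): the hidden-model fits here compare
models sharing an observation map, for which the uniform root is the
agnostic choice.

## Simulation and the packaged experiments

`sim_tree` draws pure-birth trees (unit birth rate) and rescales to a
requested mean root-to-tip height; `sim_character` simulates the chain
exactly (exponential waits, embedded jumps) along every branch, recording
hidden tip states and their observable symbols. One master seed spawns
per-replicate substreams, so a run is bitwise reproducible.

**Two-scientist experiment** (`two_scientist_replicates`). Two independent
binary genes ("color", "shape") with all rates equal evolve on each
replicate tree; scientist 1 scores color, shape and the joint four-state
character, scientist 2 scores one binary character (red AND triangular vs
anything else). Scientist 2's aggregation is not lumpable, so the plain
2-state Markov model is misspecified while a hidden model with four states
structured as two independent genes is correct; the comparison metric is
`AIC(MM) − AIC(HMM)`. The published protocol leaves the replicate sizes
unspecified; this package's defaults — 100-tip trees on the unit-birth-rate
time scale (height ln 100, total tree length ≈ 100), generating rate 0.05
per gene, and 50 characters per replicate — were chosen so that the
experiment is informative at all (a single character can never separate the
models by more than ~0.3 log-likelihood units here) and so that the rate
estimates recover the generating rate with mean squared errors at the 1e−3
scale; per-replicate characters are i.i.d. The binary MM carries 2 free
rates and the hidden model 4 (two per gene, all-rates-different), mirroring
standard hidden-rate-model practice. Constant codings are flagged and
skipped, not silently fitted.

**Benchmark fixtures** (`fixture`). Three packaged data sets exercise
hierarchical coding: `tcp_maddison` (14 taxa; two clades of tailed species,
two red and two blue each, nested inside tailless grades; every backbone
clade supported by a binary character; the left tailed clade's internal
resolution free, with the two mirrored pectinate resolutions named),
`tcp_modified` (three pairs of species with identical scores), and
`tail_armor` (four species spanning a two-level hierarchy). The right
tailed clade is resolved pectinate (reds basal) — the color-asymmetric
shape that the original parsimony paradox requires. Tail and armor
characters use the switch-on observation maps above; models come in the
independent (`ind`) and switch-on (`sw`) Mk variants.

## Bayesian machinery

Topology spaces are enumerated exactly: all rooted binary resolutions of
free clades (up to six taxa), uniform prior; branch lengths i.i.d.
exponential. Branch lengths are keyed by the clade (tip set) below each
edge, so a topology proposal carries every shared branch — all tip edges
and the fixed backbone — across unchanged and redraws only the newly
created internal edges from the prior (a reversible-jump move whose
Hastings terms cancel); this keeps mixing healthy even when the posterior
concentrates on few resolutions. Metropolis–Hastings mixes these topology
redraws with single-branch prior redraws and single-branch multipliers
(tuning 2.0). Marginal likelihoods
come from a power-posterior ladder (16 stones at Beta(0.3, 1) quantiles,
25% burn-in per stone, stones run from prior to posterior continuing state)
with both stepping-stone and path-sampling estimators; a two-taxon toy with
an exact quadrature oracle validates both to 0.1 log units. Chains report
an effective sample size (Geyer initial positive sequence) and flag poor
mixing rather than failing. Bayes factors are read on the Kass–Raftery
scale (<3.2 comparable, 3.2–10 moderate, >10 strong).

The branch-length prior deserves emphasis: with only a handful of taxa, the
data cannot overwhelm it, and both the topology posteriors of the
tail-color analyses and the ind-vs-sw Bayes factors move materially with
the prior mean (the package exposes `bl_prior_mean` everywhere). The
default is exponential with mean 1.0 expected changes per branch, chosen
so that the benchmark model comparisons behave sensibly: on the maximally
divergent four-taxon tail-armor data both models prefer long branches, and
short-mean priors (0.1–0.3) invert the model ordering by punishing the
independent model's longer optimal branches, while from mean ≈ 0.5 upward
the independent amalgam is correctly preferred and the maximum-likelihood
and Bayesian rankings agree. A sensitivity analysis over prior means is
still recommended for any substantive use, exactly as it is for small
morphological data sets generally.

## Ancestral reconstruction

`marginal_asr` computes per-node posteriors over hidden states by the
standard two-pass algorithm (validated against exhaustive enumeration over
all internal assignments on small trees), under any parameterization
including the fully general SMM. `aggregate_marginals` sums hidden
posteriors within each observable symbol — valid as a reporting device
always, and equal to reconstruction under the aggregated matrix exactly
when the model is lumpable. MAP states break ties toward the lowest
canonical state index and report the tie.

## Known limitations

* The tail-color and tail-armor Bayesian benchmarks are reconstructions:
  the original analyses' tree figure, priors and chain settings are not
  published in recoverable form. Under this package's reconstruction the
  two mirrored resolutions of the left tailed clade are *not* statistically
  equivalent — the tail-color state couples the two tailed clades through
  the tailless backbone (hidden color evolves along it in the independent
  model and is frozen along it in the switch model), so the resolved right
  clade pulls the left clade toward the color-matching resolution, and the
  effect survives every exponential branch-length prior examined (mean
  0.05–1.0). The package reports what it computes.
* Weak lumpability, rate heterogeneity across characters, reversible-jump
  exploration of hidden-space topologies, and unconstrained tree search are
  out of scope.
* NEXUS export requires single-character observable symbols (use CSV
  otherwise); the reader handles the `{..}`/`(..)` polymorphic dialects,
  `?` and `-`.
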