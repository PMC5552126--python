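# Methods

This note records the modelling conventions, priors, numerical choices and
known limitations of `cognatree`, in the spirit of a statistical software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

A dataset is a languages × features table of string states; `?` (and the
empty string) mean missing, and distinct strings are distinct states.
Matrix and long (CLDF-style) layouts are accepted; long-layout column names
are matched against a small synonym list (`Language_ID`/`Language`/`iso`/
`glottocode`, `Parameter_ID`/`Feature_ID`/`Feature`, `Value`/
`Cognate_Set`/`Cognate_class`). Cell values are whitespace-trimmed so that
stray spaces cannot split one state into two.

Preprocessing, in pipeline order per model block: feature include/exclude
lists → borrowing recoding (any cell parsing as a negative integer becomes
missing) → coverage filter (a feature with known values for strictly less
than the configured fraction of languages is dropped; the boundary case is
kept) → degeneracy filter (all-missing languages, all-missing and constant
features, iterated to a fixed point so the result is independent of
removal order) → binarization. Binarization expands a multi-state feature
with `k` attested classes into `k` presence/absence characters, ordered by
a numeric-aware sort of the class labels ("2" before "10") for
reproducible column order; a language missing in the source is missing in
every derived column. Already-binary blocks are recognised and left alone.
Polymorphic cells (one language in two classes) are not representable in
the input formats and are out of scope. Multiple datasets are aligned on
either the union of their languages (absent languages become all-missing)
or the intersection.

## Substitution models

All generators are held as normalised rate matrices with stationary
frequencies. Mk with non-uniform frequencies uses `q_ij ∝ π_j` — the
unique way to keep "all transitions equally likely" compatible with a
non-uniform stationary distribution — and reduces exactly to classic Mk
under uniform frequencies, where `P_ii(t) = 1/k + (k−1)/k · exp(−kt/(k−1))`.
Mk and BSVS are normalised to one expected substitution per unit branch
length. The covarion generator (hidden states 0slow, 1slow, 0fast, 1fast;
symmetric switch rate; hidden classes weighted equally; visible empirical
frequencies duplicated across classes) is normalised by the expected
*visible* substitution rate `(1+α)π₀π₁`: hidden fast/slow toggles are not
substitutions, and this choice makes the visible marginal at `α = 1`
coincide exactly with the binary model, so branch-length units are
consistent across model choices. BSVS requires all features of a block to
share one state space (its relative rates are block-level parameters);
per-feature state spaces are an Mk feature. Transition probabilities come
from a symmetrised eigendecomposition (all three families are reversible);
the public `transition_matrix` falls back to `scipy.linalg.expm` and both
paths are cross-checked in the tests.

Features of different state counts inside one Mk block are padded
block-diagonally to a common dimension with zero-frequency, unreachable
states, which lets the pruning recursion run once, vectorised over all
features, without affecting any likelihood value (verified against the
per-column reference implementation to machine precision).

## Priors

* Yule birthrate λ: Gamma(shape 2, rate 2), mean 1. Time units follow the
  calibrations (years) when present, otherwise substitutions per feature.
* Strict/mean clock rate (sampled only when calibrated): LogNormal(0, 2).
* Relaxed-clock spread: Exponential(1); branch multipliers iid with mean 1
  (lognormal `μ = −σ²/2`, exponential, or Gamma(shape = spread)).
* Random-local clock: Poisson(ln 2) prior on the number of rate changes,
  LogNormal(0, 0.7) multipliers composed along root-to-tip paths.
* Per-feature rates: iid Gamma(shape a, mean 1) conditioned on the rate
  vector's mean being exactly 1. The conditioning normaliser — the density
  of the rate sum, Gamma(F·a, a), at F — is included, which keeps the
  marginal of the shape calibrated; dropping it biases the shape upward.
  Shape hyperprior: Exponential(1).
* Covarion: switch rate Gamma(2, 2); slow/fast ratio Uniform(0, 1].
* BSVS: relative rates iid Exponential(1); Poisson(k−1) prior on the
  number of active transitions, restricted to connected graphs (the
  restriction's normaliser is constant in the state and drops out).

## Tree prior and calibrations

The Yule prior conditioned on `n` leaves is implemented in the interval
convention: while `m` lineages exist the waiting time to the next split is
Exponential(m·λ), `m = 2..n`, with uniformly random ranked labelled
topologies. The simulator (`simulate.sim_yule`) draws from exactly this
law, so density and generator are pinned to each other (checked by
numerical integration of the 3-leaf joint density against the
hypoexponential root marginal, and by prior-only MCMC whose λ marginal must
reproduce its hyperprior — which holds only when the tree density is
properly normalised over heights, as this one is). Under this convention
the 2-leaf root height is Exponential(2λ).

Calibrations (`A - B` in years) are uniform windows on clade MRCA ages by
default; a lognormal variant whose central 95% interval matches `[A, B]`
is available on the `CalibrationSpec`. The joint calibrated-Yule density is
the simple product of the Yule density and the calibration densities — a
multiplicative approximation, not the exactly conditioned law.

## MCMC

Plain Metropolis–Hastings. Proposals and weights: node-height slide (3),
node-height scaler (3), root scaler (1), narrow exchange (3), wide
exchange (1), subtree-prune-regraft (2), birthrate scaler (1), clock and
substitution-parameter scalers (1 each, branch-rate scalers 3), a
delta-exchange on feature rates that preserves their sum exactly (3), and
a Gamma-shape scaler (1). Scale moves draw the factor log-uniformly and
carry the `+log f` Hastings term; the SPR move re-uses the detached node's
parent as the attachment point and its Hastings ratio is the ratio of the
forward and reverse attachment-interval lengths (the candidate and target
counts coincide because both directions see the same pruned tree; verified
by a forced-replay antisymmetry test). Monophyly constraints are enforced
by rejection (zero prior), with the starting tree built by recursive
random resolution of the laminar constraint family and rescaled into the
root calibration window. Moving a child of the root is excluded from SPR
(reversibility); root exchanges are still reachable through the exchange
moves.

Likelihoods are recomputed in full after any proposal that can change them
(only the birthrate, Gamma-shape and relaxed-spread moves provably cannot);
every 1,000 steps the cached posterior is compared against a from-scratch
recomputation (tolerance 1e-8) and a mismatch aborts the run. Underflow is
handled by per-node scaling with log accumulators. Ascertainment
correction divides each feature's likelihood by one minus the total
probability of the constant patterns, computed with the same tree, clock
and rate context, and per feature (the most conservative reading); it is
enabled for a block exactly when constant characters are known to be
absent (the degeneracy filter removed some, or the block was binarized —
derived presence/absence columns of a non-constant slot are never
constant). Fixed-tree mode disables all topology and height moves and the
tree log.

The trace is TSV (sample, posterior, likelihood, prior, birthrate, clock
parameters, per-block Gamma shape and per-feature rates, substitution
parameters); trees are logged to NEXUS with a translate block. Every
output starts with a provenance header embedding the configuration text,
version, timestamp, seed and, on request, the full data files.

## Posterior summaries

Burn-in defaults to the first 10% of samples. Clade support is the
fraction of sampled trees containing the clade; the MCC tree is the
sampled tree maximising the product of its clades' supports (ties broken
by sample order), annotated with supports and per-clade median heights.
Medians of different clades need not be jointly time-consistent, so
parents are lifted minimally (1e-9 of the root height) above their
children afterwards. Rate tables report posterior means of the logged
mean-1 rates, ranked ascending (stable features first); rank correlations
between rankings use Spearman's rho (scipy's implementation; the test
suite pins it to the closed-form rank formula on all 5-item permutations).
Reports are MarkDown; maps are GeoJSON point collections in (longitude,
latitude) order.

## The synthetic-data generator

`simulate` produces exactly the structures the inference assumes: Yule
trees (interval convention above), characters drawn from the stationary
distribution at the root and propagated with exact finite-time transition
matrices (event-by-event simulation is used only to check the one-event
normalisation), uniform missing-data masks, and borrowing injection that
replaces a cell by the negation of a donor language's class — recoverable
by the borrowing recoder. Defaults: Yule birthrate 1 (root heights of a
few expected substitutions per feature, the regime where discrete
characters are informative rather than saturated), binary states for
typological-style data and small integer class labels for cognate-style
data. What it does *not* emulate: polymorphic cognate sets, dialect-chain
borrowing structure (borrowing donors are chosen uniformly), rate drift
along the tree, or non-contemporaneous (ancient) languages — all tips sit
at the present. Passing recovery tests therefore demonstrate correctness
of the inference under its own assumptions, not robustness to these
violations.

## Test problem sizes and statistical checks

The suite runs chains of 2,000–100,000 steps on 6–16 languages and 6–60
features — sizes chosen so the full suite completes in a few minutes while
each check retains power. Kolmogorov–Smirnov comparisons of MCMC marginals
thin the chain (one sample per ~1,600 steps) before testing, since KS
p-values assume independence. The Gamma-shape recovery test uses uniform
frequencies so the fitted model matches the generator: with per-column
empirical frequencies (estimated from the same handful of observations)
part of the between-feature rate signal is absorbed into the frequency
estimates and the shape is overestimated — a model-misspecification
effect users should expect on small datasets, not a sampler defect.

Per-feature rate *rankings* from single discrete characters are intrinsically
noisy at small language counts: an exhaustive profile-likelihood analysis
(the information ceiling for any estimator) shows Spearman correlations
with the generating ranks of only ~0.5–0.7 at 12 languages regardless of
state count, tree length, or rate spread, rising to ~0.8 at 60 languages.
The recovery test at 12 languages documents this ceiling; meaningful
stability rankings require tens to hundreds of languages.

## Known limitations

* No coalescent or birth–death tree priors; no dated (ancient) tips.
* The exact calibrated-Yule conditioning is not implemented (multiplicative
  approximation only).
* Covarion variant fixed to the symmetric-switch, equal-hidden-class form;
  results can be sensitive to the variant choice.
* Rates after binarization are per derived column, not tied per source
  meaning slot.
* Single chain, no parallel tempering or marginal-likelihood machinery.
* NEXUS/Newick input parsing is delegated to dendropy; full CLDF metadata
  (JSON-LD) is not read.
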