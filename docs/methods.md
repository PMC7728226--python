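# Methods

This note documents the models implemented in `rulewarp`, the synthetic
data that exercises them, and the numerical and design choices made where
the methods left room. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Task model

The CSST presents three options per trial, pairing the three colors with
the three shapes so that each feature is matched by exactly one option
(consequently a uniformly random chooser is rewarded on exactly 1/3 of
trials). The correct feature is drawn per block and the block ends after a
criterion number of correct choices — 10/15/20/30 in the original task,
default 15 here, since that was the value almost always used. When a block
ends, the next correct feature is drawn uniformly from the five features
*excluding* the current one: an uncued "change" is taken to mean a
different feature; this is configurable (`BlockSchedule.exclude_current`).
Trials and blocks are 1-based; screen positions are coded {1,2,3}
left-to-right (no analysis uses geometry); feature labels are fixed
canonical strings for file round-tripping.

## Rule-state HMM

Seven latent states: six rules and one residual. Emissions are fixed, not
learned: rule *i* emits only the option matching feature *i*; the residual
state emits each of the three options with probability 1/3 — the maximum
entropy choice, which also guarantees every choice sequence has positive
likelihood. Structural constraints: no direct rule→rule transitions,
transition parameters tied across rules, initial distribution a point mass
on the residual state. Two free parameters remain, `a_rr` and `a_oo`; the
residual exit mass is split uniformly over the six rules, (1 − a_oo)/6 —
the only split consistent with a two-parameter model, and model-defining
here.

Numerical choices:

- Forward–backward uses per-step scaling (no underflow at any session
  length; the log likelihood is the sum of log scale factors).
- Viterbi runs in log space with a −1e30 sentinel for structural zeros
  (never exponentiated); ties break toward the lowest state index
  (residual first, then features in canonical order), implemented via
  first-argmax.
- Baum–Welch M-step updates only (a_rr, a_oo), pooling expected
  self-transition counts across the six tied rule states; structural
  zeros and the emission model are untouched by construction.
- Convergence: |ΔLL| < 1e-6 or 500 iterations; restart initializations
  drawn uniform on (0.5, 0.999) for both parameters; the restart with the
  highest observed-data log likelihood wins. The original procedure used
  100 restarts; because the likelihood has only two parameters the surface
  is benign, and the test suite uses 3–20 restarts. If no restart
  converges, the best iterate is returned with `converged=False` and a
  warning.

Estimation accuracy (computed by the test suite, 20 seeds at T = 5,000
under the generating chain (0.95, 0.60)): pooled median absolute parameter
error ≈ 0.007. `a_oo` is intrinsically the harder parameter — residual
dwell times are short and residual emissions uninformative — and carries a
few-hundredths error floor even on data generated exactly from the model.

Model comparison against block-based labelings (all-correct, and correct
after a 5-trial burn-in) fits each neuron's counts as Poisson with a rate
depending only on the binary rule label. With a single binary regressor
the maximum-likelihood rates are the two group means, so the likelihood is
evaluated in closed form (a statsmodels GLM cross-check is in the tests).
Log likelihoods are summed within region; AIC = 2k − 2LL and
BIC = k ln(n) − 2LL with k = 2 × neurons and n = all counts in the
region; weights are normalized relative likelihoods exp(−Δ/2).

## Ideal-observer belief model

The one-trial-history simplification is implemented as specified: uniform
prior 1/6; rewarded likelihood 1/2 on the two chosen features; unrewarded
likelihood 1/4 on the four unchosen; posterior ∝ prior × likelihood.
Entropy is base-2 throughout with 0·log 0 := 0. When requested, exact
zeros in a posterior are replaced by |N(0, 1e-4)| draws before
renormalization (seeded); the expected-information-gain computation itself
uses exact updates, and its equality with a two-branch enumeration oracle
is asserted to 1e-9 on 1,000 random beliefs. The mixture prior for
residual trials weights the rewarded branch by the empirical probability
that the previous trial was rewarded (0.52 in the original data; the
parameter is exposed). Longer-horizon belief tracking is out of scope.

## Synthetic-data generator

The generator defines the study conditions; its defaults were chosen once.

**Behavior** (`AgentSpec`). A generative mirror of the HMM: the agent
moves between rule states and the residual state with
(a_rr_true, a_oo_true) = (0.95, 0.60), starts residual, and rule→rule
jumps are forbidden. Rule states emit the matching option (lapse
probability 0 by default). Residual choices realize a relation class
(0/1/2 feature dimensions changed from the previous choice) drawn from an
outcome-conditioned policy, then pick uniformly among qualifying options;
classes unavailable in the current option set are renormalized away, and a
policy with no mass on any available class raises a generation error
naming the trial. Defaults: after an omission (0.01, 0.04, 0.95) — novel
options dominate, matching the ~95% novel-choice rate the model-based
analyses predict to be optimal; after a reward (0.25, 0.65, 0.10) — most
often keep one feature and change the other, a feature-level win-stay.
On leaving the residual state the agent enters the block's correct rule
with probability 0.9, otherwise a uniformly random other rule.

Two optional departures from the pure Markov chain exist because real
subjects are not reward-blind:

- `a_rr_after_omission` (default None): rule-state stay probability after
  an unrewarded trial. The pure-Markov agent perseverates on stale rules
  after uncued block changes, so its rule states track the block's
  correct feature only ~30% of the time; setting this low (e.g. 0.1)
  yields "rule-follower-dominated" sessions whose decoded rules agree
  with the correct feature ≥ 90% of the time. Parameter-recovery tests
  keep the default so the generating chain is exactly the HMM's.
- `lapse`: probability a rule-state trial violates the rule (default 0).

**Spikes** (`TuningSpec`). Counts are Poisson over the fixed 3.35-s
decision epoch (overdispersion intentionally absent — Poisson is the
assumption of the downstream GLMs), with log rate = baseline
+ rule-identity term (6 levels) + chosen-color and chosen-shape terms
(3 + 3) + color×shape identity term (9), coefficients drawn i.i.d. normal
per neuron with configurable SDs, 60 neurons across OFC/VS/DS region tags
by default. State-dependent modulation:

- `state_gain` (default 0.9) multiplies the rate on rule-state trials —
  the firing-rate reduction during rule use.
- `gamma_rel` / `gamma_irr` multiply the chosen-feature coefficients of
  the rule-relevant / rule-irrelevant domain.
- `identity_gain` multiplies the identity (interaction) coefficients on
  rule trials. This knob exists because per-domain gains alone, averaged
  over pooled rule conditions, rescale shared- and unshared-feature pair
  distances proportionally and cannot create rule-specific categorical
  structure; suppressing interaction coding on rule trials is the
  generative counterpart of the identity→category tuning shift the
  analyses measure.

Three extra per-trial count columns simulate the 400-ms presentation
epochs: each epoch's log rate carries weak stimulus-feature terms for the
option on screen (SD 0.05 — stimulus tuning was found to be minimal) plus
the neuron's chosen-feature terms, both scaled by the relevance gains.

Two named profiles fix the conditions for the recovery tests:
`warping_tuning()` (additive SD 0.12, identity SD 0.4, γ_rel = 3.0,
γ_irr = 0.5, identity_gain = 0.25, state_gain = 0.9) makes residual
coding identity-dominated and rule-trial coding categorical with an
expanded relevant domain; `null_tuning()` removes *all* state dependence
including rule-identity coefficients, because rule coding by itself
already separates contexts and would contaminate a null.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: trial-to-trial and neuron-to-neuron noise
correlations (neurons are conditionally independent given the trial),
temporal autocorrelation of rates beyond state dependence, non-Poisson
variability, eye movements and within-trial dynamics, inter-session
heterogeneity, and any particular relationship between the warping gains
and biophysics. Recovery tests demonstrate that the pipeline detects the
effects it targets when they exist and stays silent under a matched null —
not that the brain works this way.

## Single-neuron statistics

- Rates are z-scored within neurons for all analyses except direct rate
  comparisons, which are centered only; zero-variance neurons under
  z-scoring are centered and logged.
- The permutation rate contrast shuffles state labels (1,000 permutations
  by default, two-sided, with the +1 small-sample correction); an exact
  enumeration path is used automatically when the label arrangements are
  few enough.
- Mutual information uses within-neuron quantile binning with two bins —
  ties broken by seeded jitter so sparse neurons split as evenly as
  possible — giving 2 types × 9 identities × 2 bins = 36 probability
  cells minimum. Rule trials are downsampled to the residual count so the
  two estimates share one limited-sampling bias, and the label-shuffle
  floor is reported alongside (not subtracted). Bits/spike divides MI by
  the mean spikes per trial within the same choice type — the most
  natural denominator where the original description left it unstated.
- The Gini index implements the printed formula
  1 − 2 Σ_k (x_k/‖x‖₁)((N − k + ½)/N) on ascending-sorted non-negative
  vectors: one-hot → 1 − 1/N, uniform → 0. (Accompanying prose in the
  source literature says a uniform population "would equal 0.5"; that
  describes the area under the Lorenz curve before the 1 − 2·area
  transform. The formula is authoritative here; group comparisons are
  unaffected by the convention.) All-zero pseudotrial vectors are
  undefined under the formula and are skipped with a logged count. The
  index is computed on resampled raw rates, not z-scored values, since it
  requires non-negative inputs.
- The identity–category index is F_id/F_cat: the one-way 9-level
  identity-model F against the overall F of the additive color + shape
  OLS model, per neuron and choice type; neurons missing an identity
  level are skipped and logged.
- The relevance-tuning GLM z-scores presentation-epoch responses within
  neuron, ranks each domain's three features best/intermediate/worst from
  all trials without regard to state (ties broken by canonical feature
  order), averages within (neuron, domain, relevance, rank) conditions,
  and fits fr = β₀ + β₁S + β₂R + β₃(S·R) pooled across neurons, plus
  paired best-minus-worst contrasts for relevant vs irrelevant domains.
  Residual trials enter the condition means and contrasts, not the GLM.
- Multiple comparisons: one-sided binomial tests against the 5% false
  positive rate for tuned-neuron proportions; Benjamini–Hochberg step-up
  at q = 0.05 elsewhere.

## Pseudopopulations and geometry

Pseudotrial matrices resample each neuron's (z-scored) trial rates with
replacement, independently across neurons, 20 pseudotrials per condition.
Exclusions: mean rate < 2 spikes/s over the full epoch and all trials;
≥ 5 missing conditions. 1–4 missing conditions are imputed with the
neuron's global mean (the within-neuron mean, not a within-type mean —
the less informative and simpler reading). A per-neuron recording mask
lets callers emulate neurons from different sessions; single-session
synthetic data otherwise has no per-neuron missingness. Split-half
construction partitions each condition's trials into two disjoint subsets
(≥ 1 each; a single-trial condition goes to one side, the other imputes),
so cross-half distances are cross-validated. The bootstrap rebuilds
matrices under fresh seeds (1,000 by default) and reports percentile CIs
and a doubled sign-crossing p floored at 1/n_boot.

RSA takes the arithmetic centroid per condition — the source text says
"geometric mean choice representation", but a literal geometric mean is
undefined for signed z-scored values, so "geometric" is read as "in
neural state space" — then Euclidean distances, z-scored over unique
off-diagonal entries (self-distances excluded everywhere). Planned
contrasts: within- vs between-context distances (2-sample t), total
spread per context (paired over matched identity pairs), shared- vs
unshared-feature distances within context (2-sample t), and within each
rule domain shared-relevant vs shared-irrelevant pairs. Structure ANOVAs
fit OLS on the unique pairs with the nested context factor and all
interactions; in the rule-domain scheme, same-identity pairs across
domains are omitted (they would make the design rank-deficient, which is
checked explicitly). Because the pairwise distances share conditions,
parametric F p-values for these ANOVAs are anticonservative; the test
suite calibrates them against a condition-label permutation null instead,
and the bootstrap-across-pseudopopulations route is the robust inferential
path.

Under generators that compress the irrelevant domain while rule-identity
coding is present, pairs sharing the rule-*relevant* feature (same
specific rule; they differ only along the compressed domain) are the
close ones — the direction implied by the compression mechanism, which is
what the recovery tests assert.

## Choice-predictive subspaces

Six one-vs-rest logistic classifiers (one per feature) are fit on the
per-rule pseudotrial matrix, so the choice axes marginalize over the
roughly balanced goal origins. Ridge penalty λ is chosen as the smallest
grid value attaining maximal mean cross-validated accuracy; the grid is
{0} ∪ 24 log-spaced values in [1e-4, 1e4] (a literal "25 log-spaced
values in [0, 1e4]" cannot include 0), folds are stratified (20 by
default), and λ is tied across the six classifiers with a per-classifier
option. Projections include the intercept so position is the log odds of
the choice; angle computations exclude intercepts. Rule classifiers use
the identical protocol on rule-based rows only (flag available), labeled
by rule identity. The projection ANOVA models chosen-feature projections
with a rule/residual main effect and relevance nested within rule-based;
pairwise contrasts are BH-corrected.

## Problem sizes

The test suite and examples run at desk scale, chosen as the smallest
sizes at which each effect or calibration is stable: sessions of 6–40
blocks (≈150–1,200 trials), 5,000-trial sessions for parameter recovery
(20 seeds), 60-neuron populations for geometry recovery, 500 neurons for
type-I-error calibration, 3–5-point λ grids with 4–5 folds in tests
(the full 25-point grid and 20 folds remain the library defaults), and
small restart/permutation/shuffle counts where the statistics allow.

## Known limitations

- Per-session fitting only; no hierarchical sharing across sessions.
- The emission model is fixed; a lapse-tolerant emission (rule states
  occasionally emitting non-matching choices) is generated by `lapse` but
  not modeled, so high-lapse agents will bias state inference.
- The belief model's one-trial history understates information available
  from longer histories; it is used for choice-type orderings, not fits.
- Pseudopopulations cannot recover noise correlations, and the RSA
  parametric p-values inherit the dependence problem noted above.
- The identity–category index is a ratio of F statistics; its absolute
  scale depends on trial counts and noise, so only within-neuron
  contrasts across choice types are interpretable.
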