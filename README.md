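# rulewarp

Analyses for rule-based decision-making experiments in the macaque
Cognitive Set-Shifting Task (CSST): infer which latent stimulus–response
rule (if any) produced each choice, characterize the residual
(hypothesis-testing) choices with a Bayesian ideal observer, and quantify
how rule adherence warps single-neuron and population representations of
choice. Everything runs end-to-end on synthetic behavior and synthetic
Poisson spike counts with known ground truth, so every stage is testable
without any recorded data.

It is a library for researchers analyzing trial-structured choice and
spike-count data from set-shifting tasks (and for anyone who wants a
worked, tested reference implementation of these methods).

## The task and the models

In the CSST, each trial presents three options pairing the colors
{cyan, magenta, yellow} with the shapes {circle, star, triangle}, each
color and shape used exactly once. A hidden *correct feature* — one of the
six — determines reward; it is fixed until the subject accumulates 15
correct choices, then changes without warning.

**Rule-state HMM** (`rulewarp.hmm`). Choices x_t are emissions of a hidden
state z_t with seven values: six rule states (state *i* emits only the
option matching feature *i*) and a maximum-entropy *residual* state
(p(x_t | residual) = 1/3). Direct rule→rule transitions are structurally
zero, transition parameters are tied across rules, and sessions start in
the residual state, leaving two free parameters —

- a_rr = p(rule_i → rule_i), and
- a_oo = p(residual → residual), with p(residual → rule_i) = (1 − a_oo)/6

— fit per session by Baum–Welch EM with random restarts and decoded with
the Viterbi algorithm. A Poisson GLM comparison
(fr = exp(β₀ + β₁·rule_t), AIC/BIC weights per region) checks the HMM
labels against block-based labelings.

**Ideal observer** (`rulewarp.belief`). A belief π(f = f*) over the six
features starts uniform (1/6); a rewarded choice puts likelihood 1/2 on
each chosen feature, an unrewarded one puts 1/4 on each unchosen feature.
For a candidate choice c, the expected information gain is
H_t − Σ_r p(r|c) H(posterior | r, c) in bits, with
p(r=1|c) = Σ_{f∈c} π(f). This model explains why residual choices favor
*novel* options (changing both feature dimensions) after reward omission.

**Neural analyses** (`rulewarp.metrics`, `pseudopop`, `rsa`, `subspace`).
Spike counts over a fixed 3.35-s decision epoch feed: permutation-tested
rate contrasts; one-way tuning ANOVAs with binomial tests on the tuned
fraction; the Gini index of population sparsity; plug-in mutual
information between median-split spike counts and the 9 choice identities
(rule trials downsampled to the residual count, label-shuffle floor);
an identity–category index F_id/F_cat per neuron; pseudotrial matrices
resampled per condition under three schemes (rule vs residual, color-rule
vs shape-rule, per-rule); Euclidean representational similarity matrices
with planned contrasts and structure ANOVAs; and one-vs-rest ridge
logistic classifiers whose coefficient vectors are choice-coding
dimensions, onto which pseudotrials are projected as log odds.

## Worked example

Fit the rule-state model to a simulated session
(`python examples/02_fit_rule_states.py`):

```
fitted a_rr = 0.947 (truth 0.95)
fitted a_oo = 0.482 (truth 0.6)
log likelihood = -359.3, converged = True
Viterbi state accuracy vs ground truth: 0.943
fraction of trials decoded as rule-based: 0.92
```

EM recovers the generating self-transition probabilities from the choice
sequence alone, and the decoded state path labels 94% of trials with the
true latent state. Project pseudotrials onto the fitted choice-coding
dimensions (`python examples/06_choice_subspace.py`):

```
6 choice classifiers, lambda = 1.0, CV accuracy = [0.98 0.99 0.99 0.96 0.99 0.98]
  mean chosen-feature projection, relevant  :  10.92
  mean chosen-feature projection, residual  :   9.54
  mean chosen-feature projection, irrelevant:   3.21
mean angle between rule and matching choice dimensions: 73.2 deg
```

Under a generator that expands rule-relevant coding and compresses
rule-irrelevant coding, chosen-feature projections order rule-relevant >
residual > rule-irrelevant — the population-level signature of
representational warping — while the rule and choice axes stay neither
identical nor orthogonal.

The other `examples/` scripts cover session simulation, the
information-gain account of residual choices, single-neuron metrics,
RSA geometry, and the full pipeline. The `rulewarp` CLI
(`rulewarp run --seed 7 --out run/`) executes every stage from one seeded
YAML config and writes TSV tables plus a JSON report; each stage can be
re-run from cached artifacts.

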