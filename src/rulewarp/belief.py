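"""Ideal-observer belief over the six features and expected information gain.

A Bayesian observer tracks the probability that each of the six features
(3 colors + 3 shapes) is the currently rewarded one. The one-trial-history
simplification starts from a uniform prior, updates on the last choice and
outcome, and asks which of the next options would most reduce the
observer's uncertainty (entropy, in bits) about the correct feature.

Likelihoods: a rewarded choice puts mass 1/2 on each of its two features;
an unrewarded choice zeroes its two features and spreads 1/(Nf-2) = 1/4
over the remaining four. Exact zeros are optionally replaced by small
half-normal noise (|N(0, 1e-4)|) before renormalization so that entropies
stay computable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import COLORS, FEATURES, SHAPES, choice_relation

N_F = len(FEATURES)
NOISE_SD = 1e-4


@dataclass
class Belief:
    """Probability vector over the six features, in canonical order."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_F,):
            raise ValueError(f"belief must have {N_F} entries")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("belief must be a probability distribution")

    def __getitem__(self, feature: str) -> float:
        return float(self.probs[FEATURES.index(feature)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.probs, index=list(FEATURES))


def init_prior() -> Belief:
    """Uniform prior: each feature correct with probability 1/6."""
    return Belief(np.full(N_F, 1.0 / N_F))


def likelihood(choice: tuple[str, str], reward: int) -> np.ndarray:
    """Per-feature likelihood vector for one observed (choice, outcome)."""
    if choice[0] not in COLORS or choice[1] not in SHAPES:
        raise ValueError(f"choice {choice!r} must name one color and one shape")
    chosen = np.array([f in choice for f in FEATURES])
    if reward:
        return np.where(chosen, 0.5, 0.0)
    return np.where(chosen, 0.0, 1.0 / (N_F - 2))


def update(
    belief: Belief,
    choice: tuple[str, str],
    reward: int,
    rng: np.random.Generator | None = None,
) -> Belief:
    """Posterior ~ prior x likelihood, renormalized.

    When ``rng`` is given, zeros in the unnormalized posterior are replaced
    by |N(0, 1e-4)| draws before renormalizing; with ``rng=None`` the update
    is exact (zeros kept).
    """
    post = belief.probs * likelihood(choice, reward)
    if post.sum() <= 0:
        raise RuntimeError("all-zero unnormalized posterior")
    if rng is not None:
        zero = post == 0.0
        post = post.copy()
        post[zero] = np.abs(rng.normal(0.0, NOISE_SD, size=int(zero.sum())))
    return Belief(post / post.sum())


def entropy(belief: Belief) -> float:
    """Shannon entropy in bits, with 0 log 0 := 0."""
    p = belief.probs[belief.probs > 0]
    return float(-(p * np.log2(p)).sum())


@dataclass
class InfoGainResult:
    """Expected-information-gain bookkeeping for one candidate choice."""

    choice: tuple[str, str]
    prior_entropy: float
    p_reward: float
    expected_posterior_entropy: float

    @property
    def infogain(self) -> float:
        return self.prior_entropy - self.expected_posterior_entropy


def expected_info_gain(belief: Belief, candidate: tuple[str, str]) -> InfoGainResult:
    """Expected entropy drop from making ``candidate`` the next choice.

    The reward probability is the belief mass on the candidate's two
    features; the expected posterior entropy averages the rewarded and
    unrewarded branch posteriors, weighted by that probability.
    """
    h_t = entropy(belief)
    p_rew = float(sum(belief[f] for f in candidate))
    h_hat = 0.0
    for r, w in ((1, p_rew), (0, 1.0 - p_rew)):
        if w <= 0:
            continue
        h_hat += w * entropy(update(belief, candidate, r))
    return InfoGainResult(choice=candidate, prior_entropy=h_t, p_reward=p_rew,
                          expected_posterior_entropy=h_hat)


def residual_prior_mixture(
    choice: tuple[str, str],
    p_prev_reward: float = 0.52,
    prior: Belief | None = None,
) -> Belief:
    """Belief before a residual choice, marginalizing the unknown previous
    outcome: the likelihood is a ``p_prev_reward``-weighted average of the
    rewarded and unrewarded branches for the previous ``choice``, combined
    with the prior and renormalized."""
    if not 0.0 <= p_prev_reward <= 1.0:
        raise ValueError("p_prev_reward must be in [0,1]")
    prior = prior or init_prior()
    lik = (p_prev_reward * likelihood(choice, 1)
           + (1.0 - p_prev_reward) * likelihood(choice, 0))
    post = prior.probs * lik
    return Belief(post / post.sum())


def choice_class_profile(
    trials: pd.DataFrame,
    state_labels: np.ndarray,
) -> pd.DataFrame:
    """Observed vs model-expected profile of residual choices by relation class.

    For each residual trial with a preceding trial, the realized choice and
    every offered option are classified by how many feature dimensions
    (0/1/2) they change relative to the previous choice. Returns, per
    (previous-outcome, class) cell: the empirical choice frequency, the
    chance availability rate of the class among offered options, and the
    model-expected information gain and reward probability (one-trial
    -history observer starting from a uniform prior).
    """
    state_labels = np.asarray(state_labels)
    if len(state_labels) != len(trials):
        raise ValueError("state labels not aligned to trials")
    residual = state_labels == "residual"

    recs = []
    tr = trials.reset_index(drop=True)
    for t in range(1, len(tr)):
        if not residual[t]:
            continue
        prev = (tr.loc[t - 1, "chosen_color"], tr.loc[t - 1, "chosen_shape"])
        prev_r = int(tr.loc[t - 1, "reward"])
        curr = (tr.loc[t, "chosen_color"], tr.loc[t, "chosen_shape"])
        chosen_class = choice_relation(prev, curr)
        avail = np.zeros(3)
        belief_t = update(init_prior(), prev, prev_r)
        gains = {0: [], 1: [], 2: []}
        rews = {0: [], 1: [], 2: []}
        for i in (1, 2, 3):
            opt = (tr.loc[t, f"opt{i}_color"], tr.loc[t, f"opt{i}_shape"])
            k = choice_relation(prev, opt)
            avail[k] += 1
            res = expected_info_gain(belief_t, opt)
            gains[k].append(res.infogain)
            rews[k].append(res.p_reward)
        for k in range(3):
            recs.append({
                "prev_reward": prev_r, "relation_class": k,
                "chosen": int(chosen_class == k),
                "available_frac": avail[k] / 3.0,
                "infogain": float(np.mean(gains[k])) if gains[k] else np.nan,
                "p_reward": float(np.mean(rews[k])) if rews[k] else np.nan,
            })
    if not recs:
        return pd.DataFrame(columns=["prev_reward", "relation_class", "frequency",
                                     "chance_frac", "infogain", "p_reward", "n"])
    df = pd.DataFrame(recs)
    out = (df.groupby(["prev_reward", "relation_class"])
             .agg(frequency=("chosen", "mean"),
                  chance_frac=("available_frac", "mean"),
                  infogain=("infogain", "mean"),
                  p_reward=("p_reward", "mean"),
                  n=("chosen", "size"))
             .reset_index())
    return out
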