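"""Constrained hidden Markov model for latent stimulus-response rule states.

Seven latent states: six rule states (one per task feature) and a
maximum-entropy residual state. A rule state can only emit the unique
option matching its feature (emission probability 1, else 0); the residual
state emits any of the N = 3 options with probability 1/3. Direct
transitions between different rule states are structurally zero (a new rule
can only be discovered by passing through the residual state), transition
parameters are tied across the six rule states, and the chain starts in the
residual state, so the model has exactly two free parameters: the rule-state
self-transition probability ``a_rr`` and the residual self-transition
probability ``a_oo``.

Fitting is by Baum-Welch EM over the two tied parameters with random
restarts; decoding by the Viterbi algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .spikes import SpikeCountTable
from .task import FEATURES

logger = logging.getLogger(__name__)

RESIDUAL = "residual"
#: Canonical state order: residual first, then features (3 colors, 3 shapes).
STATE_LABELS: tuple[str, ...] = (RESIDUAL,) + FEATURES
N_STATES = len(STATE_LABELS)

#: log-space sentinel for structurally impossible emissions/transitions
LOG_ZERO = -1e30


@dataclass(frozen=True)
class RuleHMM:
    """The 2-parameter constrained HMM."""

    a_rr: float
    a_oo: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_rr <= 1.0 and 0.0 <= self.a_oo <= 1.0):
            raise ValueError("a_rr and a_oo must be probabilities in [0,1]")

    @property
    def n_free_parameters(self) -> int:
        return 2

    @property
    def transition_matrix(self) -> np.ndarray:
        """7x7 row-stochastic matrix in canonical state order.

        residual->residual = a_oo; residual->rule_i = (1-a_oo)/6;
        rule_i->rule_i = a_rr; rule_i->residual = 1-a_rr;
        rule_i->rule_j (i != j) = 0.
        """
        t = np.zeros((N_STATES, N_STATES))
        t[0, 0] = self.a_oo
        t[0, 1:] = (1.0 - self.a_oo) / 6.0
        for i in range(1, N_STATES):
            t[i, i] = self.a_rr
            t[i, 0] = 1.0 - self.a_rr
        return t

    @property
    def initial_distribution(self) -> np.ndarray:
        """Point mass on the residual state (sessions start without a rule)."""
        pi = np.zeros(N_STATES)
        pi[0] = 1.0
        return pi


@dataclass
class StateInference:
    """Posteriors, decoding, and fit metadata for one session."""

    log_likelihood: float
    posteriors: np.ndarray              # (T, 7) rows sum to 1
    viterbi_path: np.ndarray | None = None  # (T,) str labels
    n_iter: int = 0
    converged: bool = True
    restart_index: int = 0

    @property
    def viterbi_is_rule(self) -> np.ndarray:
        if self.viterbi_path is None:
            raise ValueError("viterbi_path not computed")
        return self.viterbi_path != RESIDUAL


def build_hmm(a_rr: float, a_oo: float) -> RuleHMM:
    return RuleHMM(a_rr=a_rr, a_oo=a_oo)


def emission_logprob(chosen_color: str, chosen_shape: str, state: str) -> float:
    """Log emission probability of one choice from one state.

    Zero-probability emissions are returned as the ``LOG_ZERO`` sentinel.
    """
    if state == RESIDUAL:
        return float(np.log(1.0 / 3.0))
    if state not in FEATURES:
        raise ValueError(f"unknown state: {state!r}")
    return 0.0 if state in (chosen_color, chosen_shape) else LOG_ZERO


def emission_matrix(trials: pd.DataFrame) -> np.ndarray:
    """(T, 7) emission probabilities for every trial and state."""
    t_n = len(trials)
    e = np.zeros((t_n, N_STATES))
    e[:, 0] = 1.0 / 3.0
    colors = trials["chosen_color"].to_numpy()
    shapes = trials["chosen_shape"].to_numpy()
    for j, f in enumerate(FEATURES, start=1):
        e[:, j] = ((colors == f) | (shapes == f)).astype(float)
    return e


def forward_backward(trials: pd.DataFrame, hmm: RuleHMM) -> StateInference:
    """Scaled forward-backward pass: posteriors and log likelihood.

    Per-step scaling keeps the recursion stable for sessions of any length
    (the residual state gives every choice sequence positive probability, so
    the likelihood is always finite).
    """
    if len(trials) == 0:
        raise ValueError("empty session")
    e = emission_matrix(trials)
    t_mat = hmm.transition_matrix
    pi = hmm.initial_distribution
    t_n = len(trials)

    alpha = np.zeros((t_n, N_STATES))
    scale = np.zeros(t_n)
    a = pi * e[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, t_n):
        a = (alpha[t - 1] @ t_mat) * e[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]

    beta = np.zeros((t_n, N_STATES))
    beta[-1] = 1.0
    for t in range(t_n - 2, -1, -1):
        beta[t] = (t_mat @ (e[t + 1] * beta[t + 1])) / scale[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return StateInference(log_likelihood=float(np.log(scale).sum()), posteriors=gamma)


def viterbi(trials: pd.DataFrame, hmm: RuleHMM) -> np.ndarray:
    """Most probable joint state path; ties break toward the lowest state
    index (residual first, then features in canonical order)."""
    if len(trials) == 0:
        raise ValueError("empty session")
    log_e = np.where(emission_matrix(trials) > 0,
                     np.log(np.maximum(emission_matrix(trials), 1e-300)), LOG_ZERO)
    t_mat = hmm.transition_matrix
    log_t = np.where(t_mat > 0, np.log(np.maximum(t_mat, 1e-300)), LOG_ZERO)
    t_n = len(trials)

    delta = np.full((t_n, N_STATES), LOG_ZERO)
    psi = np.zeros((t_n, N_STATES), dtype=int)
    log_pi = np.where(hmm.initial_distribution > 0,
                      np.log(np.maximum(hmm.initial_distribution, 1e-300)), LOG_ZERO)
    delta[0] = log_pi + log_e[0]
    for t in range(1, t_n):
        cand = delta[t - 1][:, None] + log_t  # (from, to)
        psi[t] = np.argmax(cand, axis=0)      # first (lowest) index on ties
        delta[t] = cand[psi[t], np.arange(N_STATES)] + log_e[t]

    path = np.zeros(t_n, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(t_n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return np.array([STATE_LABELS[i] for i in path], dtype=object)


def _em_update(trials: pd.DataFrame, hmm: RuleHMM) -> tuple[RuleHMM, float]:
    """One Baum-Welch iteration: E-step (forward-backward + pairwise
    posteriors) and tied M-step over (a_rr, a_oo) only."""
    e = emission_matrix(trials)
    t_mat = hmm.transition_matrix
    pi = hmm.initial_distribution
    t_n = len(trials)

    alpha = np.zeros((t_n, N_STATES))
    scale = np.zeros(t_n)
    a = pi * e[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, t_n):
        a = (alpha[t - 1] @ t_mat) * e[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.zeros((t_n, N_STATES))
    beta[-1] = 1.0
    for t in range(t_n - 2, -1, -1):
        beta[t] = (t_mat @ (e[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    ll = float(np.log(scale).sum())

    # Expected transition counts, pooled across the tied states. With the
    # scaling used above, xi_t(i,j) = alpha_t(i) T_ij e_{t+1}(j)
    # beta_{t+1}(j) / scale_{t+1}.
    diag_rule_num = 0.0   # sum_t sum_{i in rules} xi_t(i,i)
    diag_res_num = 0.0    # sum_t xi_t(res,res)
    w = e[1:] * beta[1:] / scale[1:, None]      # (T-1, 7)
    diag_res_num = float(np.sum(alpha[:-1, 0] * t_mat[0, 0] * w[:, 0]))
    diag_rule_num = float(np.sum(alpha[:-1, 1:] * np.diag(t_mat)[1:][None, :] * w[:, 1:]))
    occ_res = float(gamma[:-1, 0].sum())
    occ_rule = float(gamma[:-1, 1:].sum())

    a_oo = diag_res_num / occ_res if occ_res > 0 else hmm.a_oo
    a_rr = diag_rule_num / occ_rule if occ_rule > 0 else hmm.a_rr
    a_oo = float(np.clip(a_oo, 0.0, 1.0))
    a_rr = float(np.clip(a_rr, 0.0, 1.0))
    return RuleHMM(a_rr=a_rr, a_oo=a_oo), ll


def fit_baum_welch(
    trials: pd.DataFrame,
    n_restarts: int = 100,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | np.random.Generator = 0,
    return_history: bool = False,
):
    """Fit (a_rr, a_oo) by EM with random restarts; best restart returned.

    Restart initializations are drawn uniform on (0.5, 0.999) for both
    parameters. Convergence: |change in log likelihood| < ``tol``. Returns
    ``(RuleHMM, StateInference)`` with the Viterbi path filled in; with
    ``return_history`` the per-iteration log-likelihood sequence of the best
    restart is also returned.
    """
    if len(trials) == 0:
        raise ValueError("empty session")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best: tuple[float, RuleHMM, int, bool, list[float]] | None = None
    any_converged = False
    for r in range(n_restarts):
        hmm = RuleHMM(a_rr=float(rng.uniform(0.5, 0.999)),
                      a_oo=float(rng.uniform(0.5, 0.999)))
        history: list[float] = []
        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            hmm, ll = _em_update(trials, hmm)
            history.append(ll)
            if abs(ll - prev_ll) < tol:
                converged = True
                break
            prev_ll = ll
        final_ll = forward_backward(trials, hmm).log_likelihood
        history.append(final_ll)
        any_converged = any_converged or converged
        if best is None or final_ll > best[0]:
            best = (final_ll, hmm, r, converged, history)

    assert best is not None
    _, hmm, r_idx, conv, history = best
    if not any_converged:
        logger.warning("no EM restart converged within %d iterations; "
                       "returning best iterate", max_iter)
    inf = forward_backward(trials, hmm)
    inf.viterbi_path = viterbi(trials, hmm)
    inf.n_iter = len(history) - 1
    inf.converged = conv
    inf.restart_index = r_idx
    if return_history:
        return hmm, inf, history
    return hmm, inf


# ---------------------------------------------------------------------------
# Alternative trial labelings and Poisson GLM model comparison


def alternative_labelings(trials: pd.DataFrame, burn_in: int = 5) -> dict[str, np.ndarray]:
    """Two block-based binary "rule" labelings used as baselines.

    ``correct``: rule iff the choice was rewarded. ``correct_after_burnin``:
    rule iff rewarded and more than ``burn_in`` trials into the block.
    """
    correct = trials["reward"].to_numpy().astype(bool)
    after = correct & (trials["block_trial"].to_numpy() > burn_in)
    return {"correct": correct, "correct_after_burnin": after}


def _poisson_binary_ll(counts: np.ndarray, labels: np.ndarray) -> float:
    """Exact maximized Poisson log likelihood of ``counts`` under a rate
    that depends only on a binary label (fr = exp(b0 + b1*label)): the MLE
    rate in each group is the group mean."""
    ll = 0.0
    for g in (False, True):
        y = counts[labels == g]
        if len(y) == 0:
            continue
        lam = max(y.mean(), 1e-12)
        ll += float(np.sum(y * np.log(lam) - lam - gammaln(y + 1)))
    return ll


def compare_labelings(
    spikes: SpikeCountTable,
    labelings: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-region AIC/BIC model comparison of trial labelings.

    For each neuron and labeling, firing is modeled as Poisson with a rate
    depending only on the binary rule label (2 parameters per neuron). Log
    likelihoods are summed within region; AIC = 2k - 2LL, BIC = k ln(n) -
    2LL; Akaike/Schwarz weights are normalized relative likelihoods
    exp(-delta/2) across the candidate labelings. Neurons with zero spikes
    on every trial are excluded (logged).
    """
    for name, lab in labelings.items():
        if len(lab) != spikes.n_trials:
            raise ValueError(f"labeling {name!r} not aligned to spike table")
    active = spikes.counts.sum(axis=0) > 0
    if not active.all():
        logger.info("compare_labelings: excluding %d silent neurons",
                    int((~active).sum()))
    rows = []
    for region in np.unique(spikes.regions):
        sel = (spikes.regions == region) & active
        counts = spikes.counts[:, sel]
        n_obs = counts.size
        k = 2 * counts.shape[1]
        for name, lab in labelings.items():
            lab = np.asarray(lab).astype(bool)
            ll = sum(_poisson_binary_ll(counts[:, j], lab)
                     for j in range(counts.shape[1]))
            rows.append({"region": region, "labeling": name, "n_neurons": counts.shape[1],
                         "log_likelihood": ll, "k": k,
                         "aic": 2 * k - 2 * ll, "bic": k * np.log(n_obs) - 2 * ll})
    out = pd.DataFrame(rows)
    for crit in ("aic", "bic"):
        w = []
        for region, grp in out.groupby("region"):
            delta = grp[crit] - grp[crit].min()
            rel = np.exp(-delta / 2.0)
            w.append(pd.Series(rel / rel.sum(), index=grp.index))
        out[f"{crit}_weight"] = pd.concat(w)
    return out
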