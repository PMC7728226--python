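"""Synthetic CSST behavior and Poisson spike counts with known ground truth.

The behavioral agent mirrors the latent-state model generatively: it moves
between six rule states (follow one feature) and a residual state under a
two-parameter Markov chain (rule->rule transitions forbidden), emits
rule-matching choices in rule states, and hypothesis-testing choices in the
residual state, expressed as a distribution over choice-relation classes
(0/1/2 feature dimensions changed from the last choice) conditioned on the
last outcome.

Spike counts are Poisson with a log-linear rate: baseline + rule-identity,
chosen-color, chosen-shape and color-x-shape identity terms, an overall
multiplicative rate factor on rule-state trials, and relevance gains that
scale the chosen-feature coefficients of the rule-relevant / rule-irrelevant
domain. These gains are a construct for recovery testing -- they let the
generator emulate the expansion/compression effects the analyses are
designed to detect -- not a claim about the brain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import task
from .spikes import SpikeCountTable
from .task import (
    COLORS, SHAPES, FEATURES, BlockSchedule, FeatureSpace, DEFAULT_FEATURES,
    TRIALS_COLUMNS, choice_relation, generate_option_set, option_set_to_row,
)

RESIDUAL = "residual"


class GenerationError(RuntimeError):
    pass


def _check_probs(vec, name: str) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError(f"{name} entries must be in [0,1]")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1")
    return v


@dataclass(frozen=True)
class AgentSpec:
    """Generative behavioral agent.

    ``residual_policy_after_omission`` / ``..._after_reward`` give the
    probability of choosing an option in relation class 0 / 1 / 2 with
    respect to the previous choice, conditioned on the previous outcome.
    Defaults: after an omission the agent almost always takes the novel
    option (class 2); after a reward it most often keeps one feature and
    shifts the other (class 1), a hypothesis-testing win-stay at the level
    of features.
    """

    a_rr_true: float = 0.95
    a_oo_true: float = 0.60
    #: rule-state stay probability after an unrewarded trial; None keeps the
    #: pure-Markov a_rr_true (reward-blind persistence). Small values mimic
    #: subjects that abandon a rule as soon as it stops paying, which keeps
    #: rule states aligned with the block's correct feature.
    a_rr_after_omission: float | None = None
    residual_policy_after_omission: tuple[float, float, float] = (0.01, 0.04, 0.95)
    residual_policy_after_reward: tuple[float, float, float] = (0.25, 0.65, 0.10)
    p_enter_correct: float = 0.90
    lapse: float = 0.0

    def __post_init__(self) -> None:
        for p, name in ((self.a_rr_true, "a_rr_true"), (self.a_oo_true, "a_oo_true"),
                        (self.p_enter_correct, "p_enter_correct"), (self.lapse, "lapse"),
                        *([(self.a_rr_after_omission, "a_rr_after_omission")]
                          if self.a_rr_after_omission is not None else [])):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        _check_probs(self.residual_policy_after_omission, "residual_policy_after_omission")
        _check_probs(self.residual_policy_after_reward, "residual_policy_after_reward")

    def residual_policy(self, last_reward: int) -> np.ndarray:
        if last_reward:
            return np.asarray(self.residual_policy_after_reward, dtype=float)
        return np.asarray(self.residual_policy_after_omission, dtype=float)


@dataclass
class GroundTruth:
    """Per-trial true latent state plus the generating specs."""

    states: np.ndarray  # str array: "residual" or a feature label
    agent: AgentSpec
    schedule: BlockSchedule

    @property
    def is_rule(self) -> np.ndarray:
        return self.states != RESIDUAL


def simulate_behavior(
    agent: AgentSpec,
    schedule: BlockSchedule | None = None,
    n_blocks: int = 20,
    seed: int | np.random.Generator = 0,
    session_id: str = "synthetic",
    max_trials: int = 200_000,
    n_trials: int | None = None,
    features: FeatureSpace = DEFAULT_FEATURES,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one session of ``n_blocks`` completed blocks.

    If ``n_trials`` is given the session instead stops after exactly that
    many trials, regardless of block completion.

    The session starts in the residual state. Rule states emit the unique
    option matching the state's feature (up to ``lapse``); residual choices
    realize a relation class drawn from the outcome-conditioned policy,
    restricted to the classes available in the current option set, then pick
    uniformly among qualifying options.
    """
    schedule = schedule or BlockSchedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows: list[dict] = []
    states: list[str] = []
    state = RESIDUAL
    correct_feature = schedule.draw_feature(rng, current=None, features=features)
    block_index, correct_count, blocks_done = 1, 0, 0
    block_trial = 0
    prev_choice: tuple[str, str] | None = None
    prev_reward = 0
    t = 0

    while (t < n_trials) if n_trials is not None else (blocks_done < n_blocks):
        t += 1
        block_trial += 1
        if t > max_trials:
            raise GenerationError(
                f"exceeded {max_trials} trials before completing {n_blocks} blocks")
        opts = generate_option_set(rng)

        if state == RESIDUAL:
            if prev_choice is None:
                choice_idx = int(rng.integers(3)) + 1
            else:
                rel = np.array([
                    choice_relation(prev_choice, (o.color, o.shape)) for o in opts.options
                ])
                policy = agent.residual_policy(prev_reward)
                avail = np.array([np.any(rel == k) for k in range(3)])
                mass = policy * avail
                if mass.sum() <= 0:
                    raise GenerationError(
                        f"trial {t}: residual policy has no mass on available "
                        f"relation classes {sorted(set(rel.tolist()))}")
                k = int(rng.choice(3, p=mass / mass.sum()))
                cand = np.flatnonzero(rel == k)
                choice_idx = int(cand[rng.integers(len(cand))]) + 1
        else:
            choice_idx = opts.matching_index(state, features)
            if agent.lapse > 0 and rng.random() < agent.lapse:
                others = [i for i in (1, 2, 3) if i != choice_idx]
                choice_idx = others[int(rng.integers(2))]

        chosen = opts.options[choice_idx - 1]
        reward = int(chosen.matches(correct_feature))

        row = {
            "session_id": session_id,
            "trial_index": t,
            "block_index": block_index,
            "block_trial": block_trial,
            "correct_feature": correct_feature,
            **option_set_to_row(opts),
            "choice_index": choice_idx,
            "chosen_color": chosen.color,
            "chosen_shape": chosen.shape,
            "reward": reward,
        }
        rows.append(row)
        states.append(state)

        correct_count, changed, correct_feature = task.advance_block(
            correct_count, reward, schedule, rng, correct_feature, features)
        if changed:
            blocks_done += 1
            block_index += 1
            block_trial = 0

        # latent-state transition into the next trial
        if state == RESIDUAL:
            if rng.random() >= agent.a_oo_true:
                if rng.random() < agent.p_enter_correct:
                    state = correct_feature
                else:
                    pool = [f for f in features.features if f != correct_feature]
                    state = pool[int(rng.integers(len(pool)))]
        else:
            stay = agent.a_rr_true
            if reward == 0 and agent.a_rr_after_omission is not None:
                stay = agent.a_rr_after_omission
            if rng.random() >= stay:
                state = RESIDUAL

        prev_choice = (chosen.color, chosen.shape)
        prev_reward = reward

    trials = pd.DataFrame(rows, columns=list(TRIALS_COLUMNS))
    truth = GroundTruth(states=np.array(states, dtype=object), agent=agent,
                        schedule=schedule)
    return trials, truth


# ---------------------------------------------------------------------------
# Poisson spike counts


@dataclass(frozen=True)
class TuningSpec:
    """Hyperparameters of the Poisson rate model.

    Coefficient standard deviations set how strongly neurons are tuned to
    rule identity, chosen color/shape, and the 9-level color-x-shape
    identity. ``state_gain`` multiplies the rate on rule-state trials
    (default < 1: rule adherence reduces firing). ``gamma_rel`` /
    ``gamma_irr`` scale the chosen-feature coefficients of the domain that
    is relevant / irrelevant to the current rule; ``identity_gain`` scales
    the color-x-shape identity (interaction) coefficients on rule-state
    trials (values < 1 emulate the identity-to-category tuning shift).
    """

    n_neurons: dict = field(default_factory=lambda: {"OFC": 20, "VS": 20, "DS": 20})
    baseline_log_rate: float = float(np.log(5.0))
    baseline_sd: float = 0.4
    rule_coef_sd: float = 0.3
    color_coef_sd: float = 0.3
    shape_coef_sd: float = 0.3
    identity_coef_sd: float = 0.15
    stim_coef_sd: float = 0.05
    state_gain: float = 0.9
    gamma_rel: float = 1.0
    gamma_irr: float = 1.0
    identity_gain: float = 1.0
    epoch_duration: float = 3.35
    presentation_epoch_duration: float = 0.4

    def __post_init__(self) -> None:
        if self.state_gain <= 0:
            raise ValueError("state_gain must be positive (rates must stay positive)")
        if self.gamma_rel < 0 or self.gamma_irr < 0 or self.identity_gain < 0:
            raise ValueError("relevance gains must be non-negative")
        if self.epoch_duration <= 0 or self.presentation_epoch_duration <= 0:
            raise ValueError("epoch durations must be positive")


@dataclass
class NeuronTruth:
    """Drawn per-neuron coefficients (ground truth for recovery tests)."""

    regions: np.ndarray
    baseline: np.ndarray          # (N,)
    b_rule: np.ndarray            # (N, 6) by canonical feature order
    b_color: np.ndarray           # (N, 3)
    b_shape: np.ndarray           # (N, 3)
    b_identity: np.ndarray        # (N, 9), row-major color x shape
    b_stim_color: np.ndarray      # (N, 3)
    b_stim_shape: np.ndarray      # (N, 3)
    spec: TuningSpec


def draw_tuning(spec: TuningSpec, rng: np.random.Generator) -> NeuronTruth:
    regions = np.concatenate([
        np.full(n, region, dtype=object) for region, n in spec.n_neurons.items()
    ])
    n = len(regions)
    return NeuronTruth(
        regions=regions,
        baseline=spec.baseline_log_rate + spec.baseline_sd * rng.standard_normal(n),
        b_rule=spec.rule_coef_sd * rng.standard_normal((n, 6)),
        b_color=spec.color_coef_sd * rng.standard_normal((n, 3)),
        b_shape=spec.shape_coef_sd * rng.standard_normal((n, 3)),
        b_identity=spec.identity_coef_sd * rng.standard_normal((n, 9)),
        b_stim_color=spec.stim_coef_sd * rng.standard_normal((n, 3)),
        b_stim_shape=spec.stim_coef_sd * rng.standard_normal((n, 3)),
        spec=spec,
    )


def _domain_gains(states: np.ndarray, spec: TuningSpec,
                  features: FeatureSpace = DEFAULT_FEATURES) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial multipliers for (color-domain, shape-domain) coefficients."""
    g_color = np.ones(len(states))
    g_shape = np.ones(len(states))
    for t, s in enumerate(states):
        if s == RESIDUAL:
            continue
        if features.domain(s) == "color":
            g_color[t], g_shape[t] = spec.gamma_rel, spec.gamma_irr
        else:
            g_color[t], g_shape[t] = spec.gamma_irr, spec.gamma_rel
    return g_color, g_shape


def _identity_index(color: str, shape: str) -> int:
    return COLORS.index(color) * 3 + SHAPES.index(shape)


def expected_log_rates(trials: pd.DataFrame, states: np.ndarray,
                       truth: NeuronTruth) -> np.ndarray:
    """(T, N) log firing rate (spikes/s) over the analysis epoch."""
    spec = truth.spec
    t_n = len(trials)
    ci = np.array([COLORS.index(c) for c in trials["chosen_color"]])
    si = np.array([SHAPES.index(s) for s in trials["chosen_shape"]])
    ii = ci * 3 + si
    is_rule = states != RESIDUAL
    rule_idx = np.array([FEATURES.index(s) if s != RESIDUAL else 0 for s in states])
    g_color, g_shape = _domain_gains(states, spec)

    log_r = np.tile(truth.baseline, (t_n, 1))
    log_r += np.where(is_rule[:, None], truth.b_rule[:, rule_idx].T, 0.0)
    log_r += g_color[:, None] * truth.b_color[:, ci].T
    log_r += g_shape[:, None] * truth.b_shape[:, si].T
    id_gain = np.where(is_rule, spec.identity_gain, 1.0)
    log_r += id_gain[:, None] * truth.b_identity[:, ii].T
    log_r += np.where(is_rule[:, None], np.log(spec.state_gain), 0.0)
    return log_r


def _epoch_log_rates(trials: pd.DataFrame, states: np.ndarray,
                     truth: NeuronTruth) -> np.ndarray:
    """(T, N, 3) log rates for the three presentation epochs.

    Each epoch's rate carries weak stimulus-feature terms for the option on
    the screen plus the neuron's chosen-feature terms (the developing
    choice), both scaled by the relevance gains of their domain.
    """
    spec = truth.spec
    g_color, g_shape = _domain_gains(states, spec)
    ci = np.array([COLORS.index(c) for c in trials["chosen_color"]])
    si = np.array([SHAPES.index(s) for s in trials["chosen_shape"]])
    base = (truth.baseline[None, :, None]
            + (g_color[:, None] * truth.b_color[:, ci].T)[:, :, None]
            + (g_shape[:, None] * truth.b_shape[:, si].T)[:, :, None])
    is_rule = (states != RESIDUAL)[:, None, None]
    base = base + np.where(is_rule, np.log(spec.state_gain), 0.0)
    out = np.broadcast_to(base, (len(trials), len(truth.baseline), 3)).astype(float)
    for e in range(3):
        sc = np.array([COLORS.index(task.option_set_from_row(row).by_order(e + 1).color)
                       for _, row in trials.iterrows()])
        ss = np.array([SHAPES.index(task.option_set_from_row(row).by_order(e + 1).shape)
                       for _, row in trials.iterrows()])
        out[:, :, e] += g_color[:, None] * truth.b_stim_color[:, sc].T
        out[:, :, e] += g_shape[:, None] * truth.b_stim_shape[:, ss].T
    return out


def simulate_neurons(
    trials: pd.DataFrame,
    truth: GroundTruth | np.ndarray,
    tuning: TuningSpec | NeuronTruth | None = None,
    seed: int | np.random.Generator = 0,
    noiseless: bool = False,
    with_presentation_epochs: bool = True,
) -> tuple[SpikeCountTable, NeuronTruth]:
    """Generate Poisson spike counts aligned to a session.

    ``truth`` may be a :class:`GroundTruth` or a bare state-label array.
    ``tuning`` may be a :class:`TuningSpec` (coefficients are drawn from the
    seed) or an explicit :class:`NeuronTruth`. ``noiseless=True`` returns
    expected counts (rate x duration) instead of Poisson draws.
    """
    states = truth.states if isinstance(truth, GroundTruth) else np.asarray(truth)
    if len(states) != len(trials):
        raise ValueError("states and trials are not aligned")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(tuning, NeuronTruth):
        ntruth = tuning
    else:
        ntruth = draw_tuning(tuning or TuningSpec(), rng)
    spec = ntruth.spec

    lam = np.exp(expected_log_rates(trials, states, ntruth)) * spec.epoch_duration
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        raise ValueError("configuration yields nonpositive or non-finite rates")
    counts = lam if noiseless else rng.poisson(lam).astype(float)

    epoch_counts = None
    if with_presentation_epochs:
        lam_e = (np.exp(_epoch_log_rates(trials, states, ntruth))
                 * spec.presentation_epoch_duration)
        epoch_counts = lam_e if noiseless else rng.poisson(lam_e).astype(float)

    table = SpikeCountTable(
        counts=counts,
        neuron_ids=np.array([f"{r}_{i:03d}" for i, r in enumerate(ntruth.regions)],
                            dtype=object),
        regions=ntruth.regions,
        trial_index=trials["trial_index"].to_numpy(),
        session_id=str(trials["session_id"].iloc[0]),
        epoch_duration=spec.epoch_duration,
        epoch_counts=epoch_counts,
        presentation_epoch_duration=spec.presentation_epoch_duration,
    )
    return table, ntruth


def warping_tuning(**overrides) -> TuningSpec:
    """The representational-warping study condition.

    Choice coding is identity-dominated at baseline (weak additive color/
    shape terms), so residual representations carry little categorical
    structure; on rule trials the relevant domain expands (gamma_rel = 3),
    the irrelevant domain compresses (gamma_irr = 0.5), identity coding is
    suppressed (identity_gain = 0.25) and overall rate drops (state_gain =
    0.9). This is the generator under which the population-geometry
    analyses should recover the rule-based categorical shift, the
    per-domain irrelevant collapse, and the relevant > residual >
    irrelevant projection ordering.
    """
    kw = dict(color_coef_sd=0.12, shape_coef_sd=0.12, identity_coef_sd=0.4,
              gamma_rel=3.0, gamma_irr=0.5, identity_gain=0.25, state_gain=0.9)
    kw.update(overrides)
    return TuningSpec(**kw)


def null_tuning(**overrides) -> TuningSpec:
    """State-independent coding: no rate change, no relevance gains, no
    rule-identity coefficients. Every state-contrast analysis should be
    null under this generator."""
    kw = dict(gamma_rel=1.0, gamma_irr=1.0, identity_gain=1.0, state_gain=1.0,
              rule_coef_sd=0.0, identity_coef_sd=0.3)
    kw.update(overrides)
    return TuningSpec(**kw)


# ---------------------------------------------------------------------------
# Canonical fixtures


def make_fixture_suite(seed: int = 0) -> dict:
    """Small canonical datasets with ground-truth manifests.

    Returns a dict with:
      ``session``           6-block behavioral session (default agent) + truth
      ``spikes``            60-neuron, 3-region spike table on that session
      ``residual_session``  degenerate all-residual session + truth
      ``minipop``           high-rate, strongly tuned mini-population whose
                            first half is identity (interaction) tuned and
                            second half additively (color+shape) tuned
    """
    root = np.random.default_rng(seed)
    s1, s2, s3, s4 = root.spawn(4)

    trials, truth = simulate_behavior(AgentSpec(), n_blocks=6, seed=s1,
                                      session_id="fixture_a")
    spikes, ntruth = simulate_neurons(trials, truth, TuningSpec(), seed=s2)

    res_trials, res_truth = simulate_behavior(
        AgentSpec(a_oo_true=1.0), n_blocks=4, seed=s3, session_id="fixture_c")

    mini_trials, mini_truth = simulate_behavior(AgentSpec(), n_blocks=10, seed=s4,
                                                session_id="fixture_d")
    spec = TuningSpec(n_neurons={"OFC": 12}, baseline_sd=0.0, rule_coef_sd=0.0,
                      stim_coef_sd=0.0, state_gain=1.0,
                      baseline_log_rate=float(np.log(50.0)))
    n = 12
    regions = np.full(n, "OFC", dtype=object)
    coef_rng = np.random.default_rng(seed + 1)
    b_identity = np.zeros((n, 9))
    b_color = np.zeros((n, 3))
    b_shape = np.zeros((n, 3))
    # additive tuning is kept small: log-linear coefficients are additive on
    # the rate scale only to first order, so large ones would induce a
    # multiplicative (identity-like) interaction
    b_identity[: n // 2] = 0.8 * coef_rng.standard_normal((n // 2, 9))
    b_color[n // 2:] = 0.2 * coef_rng.standard_normal((n // 2, 3))
    b_shape[n // 2:] = 0.2 * coef_rng.standard_normal((n // 2, 3))
    mini_ntruth = NeuronTruth(
        regions=regions,
        baseline=np.full(n, spec.baseline_log_rate),
        b_rule=np.zeros((n, 6)),
        b_color=b_color, b_shape=b_shape, b_identity=b_identity,
        b_stim_color=np.zeros((n, 3)), b_stim_shape=np.zeros((n, 3)),
        spec=spec,
    )
    mini_spikes, _ = simulate_neurons(mini_trials, mini_truth, mini_ntruth,
                                      seed=s4, with_presentation_epochs=False)

    return {
        "session": (trials, truth),
        "spikes": (spikes, ntruth),
        "residual_session": (res_trials, res_truth),
        "minipop": (mini_trials, mini_truth, mini_spikes, mini_ntruth),
    }
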