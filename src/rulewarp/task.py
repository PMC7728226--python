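"""Cognitive Set-Shifting Task (CSST) structure.

The CSST is a macaque analog of the Wisconsin Card Sorting Task. On every
trial three options are presented, each a unique pairing of one of three
colors (cyan, magenta, yellow) with one of three shapes (circle, star,
triangle), at randomized screen positions and presentation orders. A hidden
"correct feature" -- one color or one shape, six possibilities -- determines
reward: the choice is rewarded iff it matches the correct feature. The
correct feature is fixed until a criterion number of correct choices is
reached (a "block"), then changes uncued.

Because each trial's options pair every color with every shape exactly once,
any feature is matched by exactly one option, so a uniformly random chooser
is rewarded on exactly 1/3 of trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

COLORS: tuple[str, ...] = ("cyan", "magenta", "yellow")
SHAPES: tuple[str, ...] = ("circle", "star", "triangle")
FEATURES: tuple[str, ...] = COLORS + SHAPES

#: Canonical column order of the trials table (TSV external interface).
TRIALS_COLUMNS: tuple[str, ...] = (
    "session_id",
    "trial_index",
    "block_index",
    "block_trial",
    "correct_feature",
    "opt1_color", "opt1_shape", "opt1_position", "opt1_order",
    "opt2_color", "opt2_shape", "opt2_position", "opt2_order",
    "opt3_color", "opt3_shape", "opt3_position", "opt3_order",
    "choice_index",
    "chosen_color",
    "chosen_shape",
    "reward",
)


class InvalidFeatureError(ValueError):
    """A label is not one of the six task features."""


@dataclass(frozen=True)
class FeatureSpace:
    """The 3 colors x 3 shapes feature space of the task.

    The six features (the disjoint union of colors and shapes) double as the
    six possible correct features / rule states.
    """

    colors: tuple[str, ...] = COLORS
    shapes: tuple[str, ...] = SHAPES
    n_options: int = 3

    def __post_init__(self) -> None:
        if len(self.colors) != 3 or len(set(self.colors)) != 3:
            raise ValueError("exactly 3 distinct colors required")
        if len(self.shapes) != 3 or len(set(self.shapes)) != 3:
            raise ValueError("exactly 3 distinct shapes required")
        if set(self.colors) & set(self.shapes):
            raise ValueError("colors and shapes must be disjoint")
        if self.n_options != 3:
            raise ValueError("the task presents exactly 3 options")

    @property
    def features(self) -> tuple[str, ...]:
        return self.colors + self.shapes

    @property
    def n_features(self) -> int:
        return len(self.features)

    def domain(self, feature: str) -> str:
        """Return ``"color"`` or ``"shape"`` for a feature label."""
        if feature in self.colors:
            return "color"
        if feature in self.shapes:
            return "shape"
        raise InvalidFeatureError(f"unknown feature: {feature!r}")


DEFAULT_FEATURES = FeatureSpace()


@dataclass(frozen=True)
class Option:
    color: str
    shape: str
    position: int
    order: int

    def matches(self, feature: str) -> bool:
        return feature == self.color or feature == self.shape


@dataclass(frozen=True)
class OptionSet:
    """Three options pairing each color with each shape exactly once."""

    options: tuple[Option, Option, Option]

    def __post_init__(self) -> None:
        colors = [o.color for o in self.options]
        shapes = [o.shape for o in self.options]
        if len(set(colors)) != 3 or len(set(shapes)) != 3:
            raise ValueError("option colors and shapes must each be distinct")
        if sorted(o.position for o in self.options) != [1, 2, 3]:
            raise ValueError("positions must be a permutation of {1,2,3}")
        if sorted(o.order for o in self.options) != [1, 2, 3]:
            raise ValueError("orders must be a permutation of {1,2,3}")

    def matching_index(self, feature: str, features: FeatureSpace = DEFAULT_FEATURES) -> int:
        """1-based index of the unique option matching ``feature``."""
        features.domain(feature)  # validates the label
        for i, opt in enumerate(self.options, start=1):
            if opt.matches(feature):
                return i
        raise AssertionError("unreachable: every feature matches exactly one option")

    def by_order(self, order: int) -> Option:
        """The option presented at presentation slot ``order`` (1-based)."""
        for opt in self.options:
            if opt.order == order:
                return opt
        raise ValueError(f"no option with order {order}")


@dataclass(frozen=True)
class BlockSchedule:
    """Block termination rule: a block ends after ``criterion`` correct choices.

    The next correct feature is drawn uniformly from the five features other
    than the current one when ``exclude_current`` (the default; a block
    "change" is taken to imply a different feature).
    """

    criterion: int = 15
    exclude_current: bool = True

    def __post_init__(self) -> None:
        if self.criterion <= 0:
            raise ValueError("criterion must be positive")

    def draw_feature(
        self,
        rng: np.random.Generator,
        current: str | None = None,
        features: FeatureSpace = DEFAULT_FEATURES,
    ) -> str:
        pool = list(features.features)
        if current is not None and self.exclude_current:
            pool = [f for f in pool if f != current]
        return pool[rng.integers(len(pool))]


def generate_option_set(rng: np.random.Generator) -> OptionSet:
    """Draw a random option set: color<->shape pairing, position, and order
    are each uniform and independent."""
    shapes = list(SHAPES)
    positions = [1, 2, 3]
    orders = [1, 2, 3]
    shapes = [shapes[i] for i in rng.permutation(3)]
    positions = [positions[i] for i in rng.permutation(3)]
    orders = [orders[i] for i in rng.permutation(3)]
    return OptionSet(tuple(
        Option(color=c, shape=s, position=p, order=o)
        for c, s, p, o in zip(COLORS, shapes, positions, orders)
    ))


def is_correct(trial: Mapping, features: FeatureSpace = DEFAULT_FEATURES) -> int:
    """1 iff the chosen option's color or shape equals the correct feature.

    ``trial`` is any mapping (dict, pandas row) with ``chosen_color``,
    ``chosen_shape`` and ``correct_feature`` keys.
    """
    f = trial["correct_feature"]
    if f not in features.features:
        raise InvalidFeatureError(f"correct_feature {f!r} not in feature space")
    return int(f == trial["chosen_color"] or f == trial["chosen_shape"])


def choice_relation(prev: tuple[str, str], curr: tuple[str, str]) -> int:
    """Number of feature dimensions (color, shape) on which two choices
    differ: 0 (same option), 1, or 2 (a "novel" option)."""
    return int(prev[0] != curr[0]) + int(prev[1] != curr[1])


def advance_block(
    correct_count: int,
    reward: int,
    schedule: BlockSchedule,
    rng: np.random.Generator,
    current_feature: str,
    features: FeatureSpace = DEFAULT_FEATURES,
) -> tuple[int, bool, str]:
    """Advance the within-block correct-choice counter after one trial.

    Returns ``(new_count, block_changed, feature)``. A rewarded trial
    increments the counter; reaching the criterion resets it to zero and
    draws the next correct feature.
    """
    if correct_count >= schedule.criterion:
        raise ValueError("correct_count must be below the criterion")
    count = correct_count + int(reward)
    if count >= schedule.criterion:
        return 0, True, schedule.draw_feature(rng, current=current_feature, features=features)
    return count, False, current_feature


def simulate_random_policy(
    n_trials: int,
    seed: int | np.random.Generator = 0,
    schedule: BlockSchedule | None = None,
    features: FeatureSpace = DEFAULT_FEATURES,
) -> float:
    """Reward rate of a uniformly random chooser over ``n_trials`` CSST
    trials (full option generation, block schedule and reward rule).

    Because every feature is matched by exactly one of the three options,
    the analytic value is 1/3.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schedule = schedule or BlockSchedule()
    correct_feature = schedule.draw_feature(rng, current=None, features=features)
    count = 0
    rewarded = 0
    for _ in range(n_trials):
        opts = generate_option_set(rng)
        chosen = opts.options[int(rng.integers(3))]
        reward = int(chosen.matches(correct_feature))
        rewarded += reward
        count, _, correct_feature = advance_block(
            count, reward, schedule, rng, correct_feature, features)
    return rewarded / n_trials


# ---------------------------------------------------------------------------
# Trials-table helpers

def option_set_to_row(opts: OptionSet) -> dict:
    row: dict = {}
    for i, opt in enumerate(opts.options, start=1):
        row[f"opt{i}_color"] = opt.color
        row[f"opt{i}_shape"] = opt.shape
        row[f"opt{i}_position"] = opt.position
        row[f"opt{i}_order"] = opt.order
    return row


def option_set_from_row(row: Mapping) -> OptionSet:
    return OptionSet(tuple(
        Option(
            color=row[f"opt{i}_color"],
            shape=row[f"opt{i}_shape"],
            position=int(row[f"opt{i}_position"]),
            order=int(row[f"opt{i}_order"]),
        )
        for i in (1, 2, 3)
    ))


def validate_session(trials: pd.DataFrame, features: FeatureSpace = DEFAULT_FEATURES) -> None:
    """Assert the trial/option invariants on a trials table; raises on failure."""
    missing = set(TRIALS_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trials table missing columns: {sorted(missing)}")
    if len(trials) == 0:
        raise ValueError("empty trials table")
    for _, row in trials.iterrows():
        opts = option_set_from_row(row)  # OptionSet invariants
        chosen = opts.options[int(row["choice_index"]) - 1]
        if chosen.color != row["chosen_color"] or chosen.shape != row["chosen_shape"]:
            raise ValueError(f"trial {row['trial_index']}: chosen features mismatch")
        if int(row["reward"]) != is_correct(row, features):
            raise ValueError(f"trial {row['trial_index']}: reward inconsistent")
    idx = trials["trial_index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(trials) + 1)):
        raise ValueError("trial_index must be 1..T")


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.loc[:, list(TRIALS_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
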