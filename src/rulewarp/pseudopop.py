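"""Pseudotrial matrices from separately recorded neurons.

Neurons recorded in different sessions are combined into pseudopopulations:
within each task condition (chosen color x shape x state context), each
neuron's trial firing rates are resampled with replacement, independently
across neurons, to form pseudotrial population vectors. Three condition
schemes are supported, differing only in how the state context is defined:

``rule_vs_residual``   choice identity x {rule-based, residual}; rule-based
                       trials pooled without regard to the specific rule.
``color_vs_shape_rule`` choice identity x rule domain (rule trials only).
``per_rule``           choice identity x specific state (each of the six
                       rules, which admit only their three matching
                       identities, plus residual with all nine).

Sampling, imputation and exclusion rules: 20 pseudotrials per condition;
neurons missing 1-4 conditions have their mean rate imputed for those
conditions; neurons missing 5+ conditions, or with mean rate below
2 spikes/s, are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .spikes import SpikeCountTable
from .task import COLORS, SHAPES, DEFAULT_FEATURES

RESIDUAL = "residual"
SCHEMES = ("rule_vs_residual", "color_vs_shape_rule", "per_rule")


class FixtureTooSmallError(RuntimeError):
    pass


def enumerate_conditions(scheme: str) -> list[tuple[str, str, str]]:
    """All (color, shape, context) conditions of a scheme, in canonical order."""
    if scheme == "rule_vs_residual":
        return [(c, s, ctx) for ctx in ("rule", RESIDUAL) for c in COLORS for s in SHAPES]
    if scheme == "color_vs_shape_rule":
        return [(c, s, ctx) for ctx in ("color_rule", "shape_rule")
                for c in COLORS for s in SHAPES]
    if scheme == "per_rule":
        conds = []
        for f in COLORS:
            conds += [(f, s, f"rule:{f}") for s in SHAPES]
        for f in SHAPES:
            conds += [(c, f, f"rule:{f}") for c in COLORS]
        conds += [(c, s, RESIDUAL) for c in COLORS for s in SHAPES]
        return conds
    raise ValueError(f"unknown scheme {scheme!r}")


def trial_contexts(states: np.ndarray, scheme: str) -> np.ndarray:
    """Per-trial context label for a scheme; None where the trial is unused."""
    states = np.asarray(states)
    out = np.empty(len(states), dtype=object)
    for t, s in enumerate(states):
        if s == RESIDUAL:
            out[t] = RESIDUAL if scheme != "color_vs_shape_rule" else None
        elif scheme == "rule_vs_residual":
            out[t] = "rule"
        elif scheme == "color_vs_shape_rule":
            out[t] = f"{DEFAULT_FEATURES.domain(s)}_rule"
        else:
            out[t] = f"rule:{s}"
    return out


@dataclass
class PseudotrialMatrix:
    """Stacked pseudotrial vectors with condition labels and a roster log.

    ``values`` are z-scored within neuron; ``rates`` hold the same resampled
    pseudotrials in raw spikes/s (needed by non-negative statistics such as
    the Gini index).
    """

    values: np.ndarray                 # (rows, neurons), z-scored
    rates: np.ndarray                  # (rows, neurons), spikes/s
    rows: pd.DataFrame                 # color, shape, context per row
    neuron_ids: np.ndarray
    regions: np.ndarray
    roster: pd.DataFrame               # per input neuron: excluded, reason, counts
    scheme: str

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def region_view(self, region: str) -> "PseudotrialMatrix":
        m = self.regions == region
        return PseudotrialMatrix(self.values[:, m], self.rates[:, m], self.rows,
                                 self.neuron_ids[m], self.regions[m],
                                 self.roster, self.scheme)


def _condition_trials(trials: pd.DataFrame, contexts: np.ndarray,
                      conditions: list) -> dict:
    colors = trials["chosen_color"].to_numpy()
    shapes = trials["chosen_shape"].to_numpy()
    return {
        cond: np.flatnonzero((colors == cond[0]) & (shapes == cond[1])
                             & (contexts == cond[2]))
        for cond in conditions
    }


def _roster(spikes: SpikeCountTable, cond_idx: dict,
            valid_trials: np.ndarray | None, min_rate: float,
            impute_max_missing: int) -> pd.DataFrame:
    mean_rate = spikes.rates.mean(axis=0)
    recs = []
    for j in range(spikes.n_neurons):
        missing = []
        for cond, idx in cond_idx.items():
            use = idx if valid_trials is None else idx[valid_trials[idx, j]]
            if len(use) == 0:
                missing.append(cond)
        reason = ""
        excluded = False
        if mean_rate[j] < min_rate:
            excluded, reason = True, "rate<2"
        elif len(missing) > impute_max_missing:
            excluded, reason = True, f"missing>={impute_max_missing + 1}"
        recs.append({"neuron_id": spikes.neuron_ids[j], "region": spikes.regions[j],
                     "mean_rate": mean_rate[j], "n_missing": len(missing),
                     "n_imputed": 0 if excluded else len(missing),
                     "excluded": excluded, "reason": reason})
    return pd.DataFrame(recs)


def build_pseudotrials(
    spikes: SpikeCountTable,
    trials: pd.DataFrame,
    states: np.ndarray,
    scheme: str,
    n_per_condition: int = 20,
    seed: int | np.random.Generator = 0,
    min_rate: float = 2.0,
    impute_max_missing: int = 4,
    valid_trials: np.ndarray | None = None,
) -> PseudotrialMatrix:
    """Build one pseudotrial matrix under a condition scheme.

    ``valid_trials`` is an optional (trials x neurons) boolean mask marking
    which trials each neuron was recorded on (all, by default); it is how
    per-neuron missing conditions arise when neurons come from different
    sessions.
    """
    contexts = trial_contexts(states, scheme)
    conditions = enumerate_conditions(scheme)
    cond_idx = _condition_trials(trials, contexts, conditions)

    globally_missing = [c for c, idx in cond_idx.items() if len(idx) == 0]
    if len(globally_missing) > impute_max_missing:
        raise FixtureTooSmallError(
            f"conditions missing from the session entirely: {globally_missing[:5]}...")

    roster = _roster(spikes, cond_idx, valid_trials, min_rate, impute_max_missing)
    keep = ~roster["excluded"].to_numpy()
    if keep.sum() == 0:
        raise FixtureTooSmallError("all neurons excluded")
    sub = spikes.select_neurons(keep)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = sub.rates
    from .metrics import zscore_within_neuron
    z = zscore_within_neuron(rates, mode="zscore")
    mean_rate = rates.mean(axis=0)

    n_k = sub.n_neurons
    vrows, rrows, meta = [], [], []
    vmask = None if valid_trials is None else valid_trials[:, keep]
    for cond in conditions:
        idx = cond_idx[cond]
        vblock = np.empty((n_per_condition, n_k))
        rblock = np.empty((n_per_condition, n_k))
        if vmask is None:
            if len(idx) == 0:
                vblock[:] = 0.0
                rblock[:] = mean_rate[None, :]
            else:
                draw = idx[rng.integers(0, len(idx), size=(n_per_condition, n_k))]
                vblock = z[draw, np.arange(n_k)[None, :]]
                rblock = rates[draw, np.arange(n_k)[None, :]]
        else:
            n_missing_here = 0
            for j in range(n_k):
                use = idx[vmask[idx, j]]
                if len(use) == 0:
                    n_missing_here += 1
                    vblock[:, j] = 0.0        # neuron mean in z units
                    rblock[:, j] = mean_rate[j]
                else:
                    d = use[rng.integers(0, len(use), size=n_per_condition)]
                    vblock[:, j] = z[d, j]
                    rblock[:, j] = rates[d, j]
            if n_missing_here > n_k / 2:
                raise FixtureTooSmallError(
                    f"condition {cond} missing for more than half of neurons")
        vrows.append(vblock)
        rrows.append(rblock)
        meta += [{"color": cond[0], "shape": cond[1], "context": cond[2]}] * n_per_condition

    return PseudotrialMatrix(
        values=np.vstack(vrows), rates=np.vstack(rrows),
        rows=pd.DataFrame(meta), neuron_ids=sub.neuron_ids, regions=sub.regions,
        roster=roster, scheme=scheme,
    )


def split_half_pseudotrials(
    spikes: SpikeCountTable,
    trials: pd.DataFrame,
    states: np.ndarray,
    scheme: str,
    n_per_condition: int = 20,
    seed: int | np.random.Generator = 0,
    **kwargs,
) -> tuple[PseudotrialMatrix, PseudotrialMatrix]:
    """Two pseudotrial matrices from disjoint random halves of the trials.

    Each condition's trials are partitioned so that both subsets contain at
    least one trial (single-trial conditions put their trial in one subset;
    the other side falls back to imputation). Distances computed between
    the two matrices are cross-validated: no trial contributes to both.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    contexts = trial_contexts(states, scheme)
    conditions = enumerate_conditions(scheme)
    cond_idx = _condition_trials(trials, contexts, conditions)

    n_t = len(trials)
    in_a = np.zeros(n_t, dtype=bool)
    in_b = np.zeros(n_t, dtype=bool)
    for cond, idx in cond_idx.items():
        if len(idx) == 0:
            continue
        perm = rng.permutation(idx)
        half = max(1, len(perm) // 2)
        if len(perm) == 1:
            in_a[perm] = True
        else:
            in_a[perm[:half]] = True
            in_b[perm[half:]] = True

    n_n = spikes.n_neurons
    base = kwargs.pop("valid_trials", None)
    mask_a = np.repeat(in_a[:, None], n_n, axis=1)
    mask_b = np.repeat(in_b[:, None], n_n, axis=1)
    if base is not None:
        mask_a &= base
        mask_b &= base
    seed_a, seed_b = rng.spawn(2)
    a = build_pseudotrials(spikes, trials, states, scheme, n_per_condition,
                           seed=seed_a, valid_trials=mask_a, **kwargs)
    b = build_pseudotrials(spikes, trials, states, scheme, n_per_condition,
                           seed=seed_b, valid_trials=mask_b, **kwargs)
    return a, b


def write_pseudotrials(matrix: PseudotrialMatrix, prefix) -> None:
    """Serialize a pseudotrial matrix as TSV (values, rates, roster) plus a
    JSON sidecar with the scheme and neuron regions."""
    import json
    from pathlib import Path
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for name, arr in (("values", matrix.values), ("rates", matrix.rates)):
        df = pd.concat([matrix.rows.reset_index(drop=True),
                        pd.DataFrame(arr, columns=list(matrix.neuron_ids))], axis=1)
        df.to_csv(f"{prefix}_{name}.tsv", sep="\t", index=False)
    matrix.roster.to_csv(f"{prefix}_roster.tsv", sep="\t", index=False)
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump({"scheme": matrix.scheme,
                   "neuron_ids": list(map(str, matrix.neuron_ids)),
                   "regions": list(map(str, matrix.regions))}, fh, indent=1)


def read_pseudotrials(prefix) -> PseudotrialMatrix:
    import json
    with open(f"{prefix}_meta.json") as fh:
        meta = json.load(fh)
    ids = meta["neuron_ids"]
    vals = pd.read_csv(f"{prefix}_values.tsv", sep="\t")
    rates = pd.read_csv(f"{prefix}_rates.tsv", sep="\t")
    roster = pd.read_csv(f"{prefix}_roster.tsv", sep="\t").fillna({"reason": ""})
    return PseudotrialMatrix(
        values=vals[ids].to_numpy(), rates=rates[ids].to_numpy(),
        rows=vals[["color", "shape", "context"]],
        neuron_ids=np.array(ids, dtype=object),
        regions=np.array(meta["regions"], dtype=object),
        roster=roster, scheme=meta["scheme"],
    )


@dataclass
class BootstrapResult:
    distribution: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    p: float


def bootstrap_pseudopopulations(
    builder: Callable[[np.random.Generator], object],
    statistic: Callable[[object], float],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> BootstrapResult:
    """Re-seeded pseudopopulation bootstrap of a scalar statistic.

    ``builder(rng)`` rebuilds a pseudotrial matrix (or pair) from a fresh
    random stream; ``statistic`` maps it to a scalar (for paired contrasts,
    the within-rebuild difference). Returns the bootstrap distribution, its
    mean, the 95% percentile CI, and a two-sided sign-crossing p-value
    (doubled, floored at 1/n_boot).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = np.empty(n_boot)
    for b, sub in enumerate(rng.spawn(n_boot)):
        try:
            dist[b] = statistic(builder(sub))
        except Exception as err:
            raise RuntimeError(f"statistic failed on bootstrap rebuild {b}") from err
    lo, hi = np.percentile(dist, [2.5, 97.5])
    frac_le = np.mean(dist <= 0)
    frac_ge = np.mean(dist >= 0)
    if np.ptp(dist) == 0:
        p = 1.0
    else:
        p = max(2.0 * min(frac_le, frac_ge), 1.0 / n_boot)
        p = min(p, 1.0)
    return BootstrapResult(distribution=dist, mean=float(dist.mean()),
                           ci_low=float(lo), ci_high=float(hi), p=float(p))
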