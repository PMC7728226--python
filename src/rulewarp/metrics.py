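"""Single-neuron and per-population scalar statistics.

Rate contrasts by permutation test, one-way tuning ANOVAs with binomial
tests on the proportion of tuned cells, the Gini index of population
sparsity, plug-in mutual information between binned spike counts and choice
identity (with trial-count matching and a label-shuffle floor), the
identity-category tuning index, the relevance-tuning GLM over the three
presentation epochs, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spikes import SpikeCountTable
from .task import COLORS, SHAPES, DEFAULT_FEATURES

logger = logging.getLogger(__name__)

RESIDUAL = "residual"


# ---------------------------------------------------------------------------
# normalization


def zscore_within_neuron(counts: np.ndarray, mode: str = "zscore") -> np.ndarray:
    """Center (and optionally scale) each neuron's counts across trials.

    ``mode="zscore"`` gives per-neuron mean 0 and unit sample SD;
    ``mode="center_only"`` subtracts the mean only (used for direct
    firing-rate comparisons, where scale matters). Zero-variance neurons
    under ``zscore`` are centered only, with a log notice.
    """
    if mode not in ("zscore", "center_only"):
        raise ValueError("mode must be 'zscore' or 'center_only'")
    x = np.asarray(counts, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 trials per neuron")
    out = x - x.mean(axis=0, keepdims=True)
    if mode == "zscore":
        sd = x.std(axis=0, ddof=1, keepdims=True)
        flat = sd[0] == 0
        if flat.any():
            logger.info("zscore_within_neuron: %d zero-variance neurons centered only",
                        int(flat.sum()))
        sd = np.where(sd == 0, 1.0, sd)
        out = out / sd
    return out


# ---------------------------------------------------------------------------
# permutation rate contrast


def rate_contrast_permutation(
    counts: np.ndarray,
    is_rule: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    exact: bool | None = None,
) -> tuple[float, float]:
    """Two-sided permutation test on the rule-minus-residual mean difference.

    Returns ``(mean_difference, p)``. ``exact=True`` (or automatically when
    the number of distinct label assignments is small) enumerates every
    assignment of the group sizes instead of sampling.
    """
    counts = np.asarray(counts, dtype=float)
    is_rule = np.asarray(is_rule).astype(bool)
    n1, n0 = int(is_rule.sum()), int((~is_rule).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each label class needs at least 2 trials")
    obs = counts[is_rule].mean() - counts[~is_rule].mean()

    n = len(counts)
    if exact is None:
        exact = comb(n, n1) <= 20000
    if exact:
        from itertools import combinations
        total = counts.sum()
        diffs = []
        for idx in combinations(range(n), n1):
            s1 = counts[list(idx)].sum()
            diffs.append(s1 / n1 - (total - s1) / n0)
        diffs = np.asarray(diffs)
        p = float(np.mean(np.abs(diffs) >= abs(obs) - 1e-12))
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        diffs = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            s1 = counts[perm[:n1]].sum()
            diffs[b] = s1 / n1 - (counts.sum() - s1) / n0
        p = float((1 + np.sum(np.abs(diffs) >= abs(obs) - 1e-12)) / (n_perm + 1))
    return float(obs), p


# ---------------------------------------------------------------------------
# tuning ANOVAs


def _anova_p(y: np.ndarray, groups: np.ndarray, min_per_level: int = 2) -> float:
    """One-way ANOVA p-value; NaN when a level is too thin."""
    levels = np.unique(groups)
    samples = [y[groups == g] for g in levels]
    if len(samples) < 2 or any(len(s) < min_per_level for s in samples):
        return np.nan
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(y) == 0:
        return np.nan
    return float(stats.f_oneway(*samples).pvalue)


def tuning_anova_suite(
    spikes: SpikeCountTable,
    trials: pd.DataFrame,
    states: np.ndarray,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-neuron one-way ANOVAs for three tuning factors.

    Factors: rule use (rule-based vs residual, 2 levels), rule identity
    (6 levels, residual trials excluded), and choice identity (9 color x
    shape levels). Returns ``(per_neuron, summary)``: per-neuron p-values,
    and per region x factor the proportion of neurons with p < alpha with a
    one-sided binomial test against a false-positive rate of alpha.
    """
    states = np.asarray(states)
    is_rule = states != RESIDUAL
    identity = (trials["chosen_color"] + "/" + trials["chosen_shape"]).to_numpy()
    rows = []
    for j in range(spikes.n_neurons):
        y = spikes.counts[:, j].astype(float)
        rows.append({
            "neuron_id": spikes.neuron_ids[j],
            "region": spikes.regions[j],
            "p_rule_use": _anova_p(y, is_rule.astype(int)),
            "p_rule_identity": _anova_p(y[is_rule], states[is_rule]),
            "p_choice_identity": _anova_p(y, identity),
        })
    per_neuron = pd.DataFrame(rows)

    srows = []
    for region, grp in per_neuron.groupby("region"):
        for factor in ("p_rule_use", "p_rule_identity", "p_choice_identity"):
            p = grp[factor].dropna()
            k = int((p < alpha).sum())
            m = len(p)
            binom_p = stats.binomtest(k, m, alpha, alternative="greater").pvalue if m else np.nan
            srows.append({"region": region, "factor": factor.removeprefix("p_"),
                          "n_significant": k, "n_tested": m,
                          "proportion": k / m if m else np.nan,
                          "binomial_p": binom_p})
    return per_neuron, pd.DataFrame(srows)


# ---------------------------------------------------------------------------
# Gini sparsity


def gini_index(x: np.ndarray) -> float:
    """Gini index of a non-negative vector (population sparsity).

    After ascending sort and L1 normalization:
    ``1 - 2 * sum_k (x_k/||x||_1) * (N - k + 1/2)/N``. A one-hot vector of
    length N gives 1 - 1/N; a uniform vector gives 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("x must be a non-empty 1-d vector")
    if np.any(x < 0):
        raise ValueError("entries must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero vector: Gini undefined")
    xs = np.sort(x)
    n = len(xs)
    k = np.arange(1, n + 1)
    return float(1.0 - 2.0 * np.sum(xs / total * (n - k + 0.5) / n))


def gini_by_pseudotrial(values: np.ndarray) -> np.ndarray:
    """Row-wise Gini over a (pseudotrials x neurons) non-negative matrix;
    all-zero rows are skipped (returned as NaN) with a log notice."""
    out = np.full(values.shape[0], np.nan)
    skipped = 0
    for i, row in enumerate(values):
        if row.sum() == 0:
            skipped += 1
            continue
        out[i] = gini_index(row)
    if skipped:
        logger.info("gini_by_pseudotrial: skipped %d all-zero pseudotrials", skipped)
    return out


# ---------------------------------------------------------------------------
# mutual information


@dataclass
class MIResult:
    """Per choice type: plug-in MI (bits/trial), shuffle floor, bits/spike."""

    mi: dict
    mi_shuffle: dict
    bits_per_spike: dict
    n_trials_used: dict
    excluded: bool = False


def _quantile_bins(y: np.ndarray, n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Rank-based quantile bins; ties broken by seeded jitter so sparse
    neurons split as evenly as possible."""
    jitter = rng.uniform(0, 1e-9, size=len(y))
    ranks = stats.rankdata(y + jitter, method="ordinal") - 1
    return (ranks * n_bins // len(y)).astype(int)


def _plugin_mi(bins: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete variables."""
    joint = pd.crosstab(pd.Series(bins), pd.Series(labels)).to_numpy().astype(float)
    joint /= joint.sum()
    pr = joint.sum(axis=1, keepdims=True)
    pc = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / (pr * pc))
    return float(np.nansum(term))


def mutual_information(
    counts: np.ndarray,
    choice_labels: np.ndarray,
    is_rule: np.ndarray,
    n_bins: int = 2,
    seed: int | np.random.Generator = 0,
    n_shuffle: int = 100,
) -> MIResult:
    """Choice information in one neuron, separately per choice type.

    Firing is discretized into ``n_bins`` within-neuron quantile bins.
    Rule-based trials are randomly downsampled to the residual trial count
    so both estimates share the same limited-sampling bias. The shuffle
    floor is the mean MI after shuffling labels. Bits/spike divides MI by
    the mean spike count per trial within the choice type.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=float)
    choice_labels = np.asarray(choice_labels)
    is_rule = np.asarray(is_rule).astype(bool)
    n_res = int((~is_rule).sum())
    n_rule = int(is_rule.sum())
    if min(n_res, n_rule) < 2 * n_bins:
        raise ValueError("need at least 2*n_bins trials per choice type")

    keep_rule = np.flatnonzero(is_rule)
    keep_rule = rng.choice(keep_rule, size=n_res, replace=False) if n_rule > n_res else keep_rule
    groups = {"rule": np.sort(keep_rule), "residual": np.flatnonzero(~is_rule)}

    mi, mi_sh, bps, n_used = {}, {}, {}, {}
    excluded = False
    for name, idx in groups.items():
        y, lab = counts[idx], choice_labels[idx]
        bins = _quantile_bins(y, n_bins, rng)
        if len(np.unique(bins)) < n_bins:
            excluded = True
            logger.info("mutual_information: neuron unsplittable into %d bins "
                        "for %s trials", n_bins, name)
            mi[name] = mi_sh[name] = bps[name] = np.nan
            n_used[name] = len(idx)
            continue
        mi[name] = _plugin_mi(bins, lab)
        sh = np.empty(n_shuffle)
        for b in range(n_shuffle):
            sh[b] = _plugin_mi(bins, lab[rng.permutation(len(lab))])
        mi_sh[name] = float(sh.mean())
        mean_count = y.mean()
        bps[name] = mi[name] / mean_count if mean_count > 0 else np.nan
        n_used[name] = len(idx)
    return MIResult(mi=mi, mi_shuffle=mi_sh, bits_per_spike=bps,
                    n_trials_used=n_used, excluded=excluded)


def mutual_information_table(
    spikes: SpikeCountTable,
    trials: pd.DataFrame,
    states: np.ndarray,
    n_bins: int = 2,
    seed: int = 0,
    n_shuffle: int = 100,
) -> pd.DataFrame:
    """Per-neuron MI summary over the 9-level choice identity."""
    identity = (trials["chosen_color"] + "/" + trials["chosen_shape"]).to_numpy()
    is_rule = np.asarray(states) != RESIDUAL
    root = np.random.default_rng(seed)
    rows = []
    for j in range(spikes.n_neurons):
        res = mutual_information(spikes.counts[:, j], identity, is_rule,
                                 n_bins=n_bins, seed=root.spawn(1)[0],
                                 n_shuffle=n_shuffle)
        rows.append({
            "neuron_id": spikes.neuron_ids[j], "region": spikes.regions[j],
            "mi_rule": res.mi.get("rule"), "mi_residual": res.mi.get("residual"),
            "mi_shuffle_rule": res.mi_shuffle.get("rule"),
            "mi_shuffle_residual": res.mi_shuffle.get("residual"),
            "bps_rule": res.bits_per_spike.get("rule"),
            "bps_residual": res.bits_per_spike.get("residual"),
            "excluded": res.excluded,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# identity vs category tuning


@dataclass
class IdentityCategoryResult:
    f_identity: float
    f_category: float

    @property
    def index(self) -> float:
        return self.f_identity / self.f_category


def _oneway_f(y: np.ndarray, groups: np.ndarray) -> float:
    levels = np.unique(groups)
    samples = [y[groups == g] for g in levels]
    return float(stats.f_oneway(*samples).statistic)


def _additive_f(y: np.ndarray, colors: np.ndarray, shapes: np.ndarray) -> float:
    """Overall F statistic of the additive color + shape OLS model."""
    n = len(y)
    x_cols = []
    for lev in COLORS[1:]:
        x_cols.append((colors == lev).astype(float))
    for lev in SHAPES[1:]:
        x_cols.append((shapes == lev).astype(float))
    x = np.column_stack([np.ones(n)] + x_cols)
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    df_model = rank - 1
    df_resid = n - rank
    if df_resid <= 0 or rss <= 0:
        return np.inf
    return ((tss - rss) / df_model) / (rss / df_resid)


def identity_category_index(
    counts: np.ndarray,
    colors: np.ndarray,
    shapes: np.ndarray,
) -> IdentityCategoryResult:
    """Ratio of identity-model to category-model F statistics for one neuron.

    The identity model codes each of the 9 color x shape combinations
    independently (one-way, 9 levels); the category model treats color and
    shape as additive. Index > 1: identity coding beyond additive category
    coding; <= 1: categories suffice.
    """
    identity = np.char.add(np.char.add(colors.astype(str), "/"), shapes.astype(str))
    if len(np.unique(identity)) < 9:
        raise ValueError("all 9 choice identities must be present")
    return IdentityCategoryResult(
        f_identity=_oneway_f(np.asarray(counts, float), identity),
        f_category=_additive_f(np.asarray(counts, float), np.asarray(colors),
                               np.asarray(shapes)),
    )


def identity_category_table(
    spikes: SpikeCountTable,
    trials: pd.DataFrame,
    states: np.ndarray,
) -> pd.DataFrame:
    """Per-neuron identity-category index for rule-based and residual trials;
    neurons missing an identity level in either choice type are skipped."""
    is_rule = np.asarray(states) != RESIDUAL
    colors = trials["chosen_color"].to_numpy()
    shapes = trials["chosen_shape"].to_numpy()
    rows = []
    skipped = 0
    for j in range(spikes.n_neurons):
        rec = {"neuron_id": spikes.neuron_ids[j], "region": spikes.regions[j]}
        try:
            for name, mask in (("rule", is_rule), ("residual", ~is_rule)):
                r = identity_category_index(spikes.counts[mask, j],
                                            colors[mask], shapes[mask])
                rec[f"index_{name}"] = r.index
                rec[f"f_id_{name}"] = r.f_identity
                rec[f"f_cat_{name}"] = r.f_category
        except ValueError:
            skipped += 1
            continue
        rows.append(rec)
    if skipped:
        logger.info("identity_category_table: skipped %d neurons with missing "
                    "identity levels", skipped)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# relevance-tuning GLM over presentation epochs


@dataclass
class TuningGLMResult:
    """OLS fit of fr = b0 + b1*S + b2*R + b3*(S*R) over neuron-condition rows.

    S ranks the feature from worst (1) to best (3) within neuron and domain
    (from all trials, without regard to state); R flags whether the domain
    was relevant to the rule on those trials. ``contrasts`` holds the paired
    best-minus-worst tuning-depth comparisons.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    condition_means: pd.DataFrame
    contrasts: pd.DataFrame


def relevance_tuning_glm(
    spikes: SpikeCountTable,
    trials: pd.DataFrame,
    states: np.ndarray,
    target: str = "choice",
) -> TuningGLMResult:
    """How rule relevance sharpens single-neuron feature tuning.

    Uses the three 400-ms presentation-epoch responses. ``target="choice"``
    sorts epoch responses by the features of the upcoming choice;
    ``target="stimulus"`` by the features of the option on the screen during
    each epoch. Responses are z-scored within neuron, averaged per
    (neuron, domain, relevance, rank) condition, and fit with the pooled
    linear model above across rule-based trials. Residual trials enter the
    condition means and contrasts but not the GLM.
    """
    if spikes.epoch_counts is None:
        raise ValueError("spike table has no presentation-epoch counts")
    if target not in ("choice", "stimulus"):
        raise ValueError("target must be 'choice' or 'stimulus'")
    from .task import option_set_from_row

    states = np.asarray(states)
    t_n, n_n, _ = spikes.epoch_counts.shape
    flat = spikes.epoch_counts.transpose(0, 2, 1).reshape(t_n * 3, n_n).astype(float)
    # z-score within neuron across all epoch responses
    z = zscore_within_neuron(flat, mode="zscore").reshape(t_n, 3, n_n)

    if target == "choice":
        ep_color = np.repeat(trials["chosen_color"].to_numpy()[:, None], 3, axis=1)
        ep_shape = np.repeat(trials["chosen_shape"].to_numpy()[:, None], 3, axis=1)
    else:
        ep_color = np.empty((t_n, 3), dtype=object)
        ep_shape = np.empty((t_n, 3), dtype=object)
        for t, (_, row) in enumerate(trials.iterrows()):
            opts = option_set_from_row(row)
            for e in range(3):
                opt = opts.by_order(e + 1)
                ep_color[t, e] = opt.color
                ep_shape[t, e] = opt.shape

    rule_domain = np.array([
        None if s == RESIDUAL else DEFAULT_FEATURES.domain(s) for s in states
    ], dtype=object)

    # per-neuron best/intermediate/worst ranking per domain from ALL responses
    ranks = {}  # (j, domain, level) -> S in {1,2,3}
    for j in range(n_n):
        for domain, levels, ep_lab in (("color", COLORS, ep_color),
                                       ("shape", SHAPES, ep_shape)):
            means = np.array([z[:, :, j][ep_lab == lev].mean() for lev in levels])
            order = np.argsort(means, kind="stable")  # worst..best; ties canonical
            for s_rank, li in enumerate(order, start=1):
                ranks[(j, domain, levels[li])] = s_rank

    cond_rows = []
    for j in range(n_n):
        for domain, levels, ep_lab in (("color", COLORS, ep_color),
                                       ("shape", SHAPES, ep_shape)):
            for context in ("relevant", "irrelevant", "residual"):
                if context == "residual":
                    tmask = rule_domain == None  # noqa: E711
                elif context == "relevant":
                    tmask = rule_domain == domain
                else:
                    tmask = (rule_domain != None) & (rule_domain != domain)  # noqa: E711
                for lev in levels:
                    sel = tmask[:, None] & (ep_lab == lev)
                    if not sel.any():
                        continue
                    cond_rows.append({
                        "neuron": j, "domain": domain, "context": context,
                        "level": lev, "S": ranks[(j, domain, lev)],
                        "R": 1 if context == "relevant" else 0,
                        "fr": float(z[:, :, j][sel].mean()),
                    })
    cond = pd.DataFrame(cond_rows)

    import statsmodels.api as sm
    glm_rows = cond[cond["context"] != "residual"]
    x = sm.add_constant(np.column_stack([
        glm_rows["S"], glm_rows["R"], glm_rows["S"] * glm_rows["R"],
    ]))
    fit = sm.OLS(glm_rows["fr"].to_numpy(), x).fit()
    names = ["b0", "b1_S", "b2_R", "b3_SxR"]
    params = pd.Series(fit.params, index=names)
    bse = pd.Series(fit.bse, index=names)
    pvals = pd.Series(fit.pvalues, index=names)

    # paired best-minus-worst tuning depth, relevant vs irrelevant domain
    depth = (cond.pivot_table(index=["neuron", "domain", "context"], columns="S",
                              values="fr")
             .assign(depth=lambda d: d[3] - d[1])["depth"].reset_index())
    crows = []
    for ctx_name, dom_rel in (("color_rule", "color"), ("shape_rule", "shape"),
                              ("residual", None)):
        if dom_rel is None:
            a = depth[(depth["context"] == "residual") & (depth["domain"] == "color")]
            b = depth[(depth["context"] == "residual") & (depth["domain"] == "shape")]
            label = "color_vs_shape"
        else:
            a = depth[(depth["context"] == "relevant") & (depth["domain"] == dom_rel)]
            b = depth[(depth["context"] == "irrelevant") & (depth["domain"] != dom_rel)]
            label = "relevant_vs_irrelevant"
        merged = a.merge(b, on="neuron", suffixes=("_a", "_b")).dropna()
        if len(merged) >= 2:
            t, p = stats.ttest_rel(merged["depth_a"], merged["depth_b"])
        else:
            t, p = np.nan, np.nan
        crows.append({"state_class": ctx_name, "contrast": label,
                      "mean_depth_a": merged["depth_a"].mean(),
                      "mean_depth_b": merged["depth_b"].mean(),
                      "mean_difference": (merged["depth_a"] - merged["depth_b"]).mean(),
                      "t": t, "p": p, "n": len(merged)})
    return TuningGLMResult(params=params, bse=bse, pvalues=pvals,
                           condition_means=cond, contrasts=pd.DataFrame(crows))


# ---------------------------------------------------------------------------
# multiple comparisons


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control at level ``q``.

    Returns ``(reject, p_adjusted)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0,1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
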