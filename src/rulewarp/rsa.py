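"""Representational similarity analysis over pseudopopulation centroids.

Condition centroids (mean pseudotrial vectors) are compared by Euclidean
distance; the resulting condition x condition matrix is z-scored over its
unique off-diagonal entries (the self-distance is excluded everywhere).
Planned contrasts and structure ANOVAs then quantify how the geometry of
choice representations differs between rule-based and residual decisions
(shared-feature compression) or between color-rule and shape-rule decisions
(rule-irrelevant collapse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist, squareform

from .pseudopop import PseudotrialMatrix

RESIDUAL = "residual"


@dataclass
class RSAMatrix:
    """Pairwise condition distances, raw and z-scored.

    ``z`` has NaN on the diagonal; z-scoring used the unique off-diagonal
    entries only. ``degenerate`` flags an all-equal raw matrix (zero
    variance), in which case ``z`` is all zeros off-diagonal.
    """

    labels: pd.DataFrame          # color, shape, context per condition
    raw: np.ndarray
    z: np.ndarray
    scheme: str
    degenerate: bool = False
    cross_validated: bool = False

    @property
    def n_conditions(self) -> int:
        return self.raw.shape[0]

    def pair_table(self) -> pd.DataFrame:
        """Long table of unique (i<j) pairs with structural descriptors."""
        lab = self.labels
        recs = []
        for i in range(self.n_conditions):
            for j in range(i + 1, self.n_conditions):
                a, b = lab.iloc[i], lab.iloc[j]
                recs.append({
                    "i": i, "j": j,
                    "context_i": a["context"], "context_j": b["context"],
                    "same_context": a["context"] == b["context"],
                    "share_color": a["color"] == b["color"],
                    "share_shape": a["shape"] == b["shape"],
                    "same_identity": (a["color"] == b["color"]
                                      and a["shape"] == b["shape"]),
                    "raw": self.raw[i, j], "z": self.z[i, j],
                })
        df = pd.DataFrame(recs)
        df["share_any"] = df["share_color"] | df["share_shape"]
        return df


def condition_centroids(matrix: PseudotrialMatrix) -> tuple[np.ndarray, pd.DataFrame]:
    """Mean pseudotrial vector per condition (arithmetic centroid in neural
    state space). Returns ``(centroids, labels)``."""
    key = matrix.rows[["color", "shape", "context"]]
    groups = key.drop_duplicates().reset_index(drop=True)
    if len(groups) < 1 or matrix.n_rows == 0:
        raise ValueError("empty pseudotrial matrix")
    cents = np.empty((len(groups), matrix.values.shape[1]))
    for g, (_, row) in enumerate(groups.iterrows()):
        m = ((key["color"] == row["color"]) & (key["shape"] == row["shape"])
             & (key["context"] == row["context"])).to_numpy()
        if not m.any():
            raise ValueError(f"empty condition {tuple(row)}")
        cents[g] = matrix.values[m].mean(axis=0)
    return cents, groups


def _zscore_offdiag(d: np.ndarray) -> tuple[np.ndarray, bool]:
    iu = np.triu_indices_from(d, k=1)
    vals = d[iu]
    sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
    degenerate = sd == 0
    z = np.zeros_like(d) if degenerate else (d - vals.mean()) / sd
    np.fill_diagonal(z, np.nan)
    return z, bool(degenerate)


def distance_matrix(centroids: np.ndarray, labels: pd.DataFrame,
                    scheme: str = "") -> RSAMatrix:
    """Euclidean distances between condition centroids, z-scored over the
    unique off-diagonal entries."""
    if centroids.shape[0] < 3:
        raise ValueError("need at least 3 conditions")
    d = squareform(pdist(centroids, metric="euclidean"))
    z, degenerate = _zscore_offdiag(d)
    return RSAMatrix(labels=labels.reset_index(drop=True), raw=d, z=z,
                     scheme=scheme, degenerate=degenerate)


def cross_distance_matrix(centroids_a: np.ndarray, centroids_b: np.ndarray,
                          labels: pd.DataFrame, scheme: str = "") -> RSAMatrix:
    """Cross-validated distances between split-half centroids (A rows vs B
    columns, symmetrized). The diagonal (a condition against itself in the
    held-out half) stays available in ``raw`` but is excluded from
    z-scoring and statistics as usual."""
    d = cdist(centroids_a, centroids_b, metric="euclidean")
    d = 0.5 * (d + d.T)
    z, degenerate = _zscore_offdiag(d)
    return RSAMatrix(labels=labels.reset_index(drop=True), raw=d, z=z,
                     scheme=scheme, degenerate=degenerate, cross_validated=True)


def _t2(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if len(a) < 2 or len(b) < 2:
        raise ValueError("contrast needs at least 2 elements per side")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def rsa_contrasts(rsam: RSAMatrix, scheme: str | None = None) -> pd.DataFrame:
    """The planned contrasts over z-scored distances for a scheme.

    rule_vs_residual: (1) within vs between choice type; (2) total spread
    within rule-based vs within residual (paired over identity pairs);
    (3) shared-feature vs no-shared-feature, separately within each type.
    color_vs_shape_rule: (1) within vs between rule domain; (2) within each
    domain, pairs sharing the rule-relevant feature vs the rule-irrelevant
    feature.
    """
    scheme = scheme or rsam.scheme
    pairs = rsam.pair_table()
    rows = []

    within = pairs[pairs["same_context"]]["z"].to_numpy()
    between = pairs[~pairs["same_context"]]["z"].to_numpy()
    t, p = _t2(within, between)
    rows.append({"contrast": "within_vs_between", "context": "all",
                 "mean_a": within.mean(), "mean_b": between.mean(),
                 "difference": within.mean() - between.mean(),
                 "t": t, "p": p, "test": "2-sample"})

    if scheme == "rule_vs_residual":
        ctxs = ("rule", RESIDUAL)
    elif scheme == "color_vs_shape_rule":
        ctxs = ("color_rule", "shape_rule")
    else:
        raise ValueError(f"no contrast set defined for scheme {scheme!r}")

    # total representational spread, paired over matched identity pairs
    wa = pairs[pairs["same_context"] & (pairs["context_i"] == ctxs[0])]
    wb = pairs[pairs["same_context"] & (pairs["context_i"] == ctxs[1])]
    if len(wa) == len(wb) and len(wa) >= 2:
        t, p = stats.ttest_rel(wa.sort_values(["i", "j"])["z"].to_numpy(),
                               wb.sort_values(["i", "j"])["z"].to_numpy())
        rows.append({"contrast": "space_size", "context": f"{ctxs[0]}_vs_{ctxs[1]}",
                     "mean_a": wa["z"].mean(), "mean_b": wb["z"].mean(),
                     "difference": wa["z"].mean() - wb["z"].mean(),
                     "t": float(t), "p": float(p), "test": "paired"})

    if scheme == "rule_vs_residual":
        for ctx in ctxs:
            grp = pairs[pairs["same_context"] & (pairs["context_i"] == ctx)
                        & ~pairs["same_identity"]]
            a = grp[grp["share_any"]]["z"].to_numpy()
            b = grp[~grp["share_any"]]["z"].to_numpy()
            t, p = _t2(a, b)
            rows.append({"contrast": "shared_vs_unshared_feature", "context": ctx,
                         "mean_a": a.mean(), "mean_b": b.mean(),
                         "difference": a.mean() - b.mean(),
                         "t": t, "p": p, "test": "2-sample"})
    else:
        for ctx in ctxs:
            grp = pairs[pairs["same_context"] & (pairs["context_i"] == ctx)
                        & ~pairs["same_identity"]]
            rel_dom = "color" if ctx == "color_rule" else "shape"
            a = grp[grp[f"share_{rel_dom}"]]["z"].to_numpy()       # share relevant
            irr_dom = "shape" if rel_dom == "color" else "color"
            b = grp[grp[f"share_{irr_dom}"]]["z"].to_numpy()       # share irrelevant
            t, p = _t2(a, b)
            rows.append({"contrast": "shared_relevant_vs_shared_irrelevant",
                         "context": ctx,
                         "mean_a": a.mean(), "mean_b": b.mean(),
                         "difference": a.mean() - b.mean(),
                         "t": t, "p": p, "test": "2-sample"})
    return pd.DataFrame(rows)


def rsa_anova(rsam: RSAMatrix, scheme: str | None = None) -> pd.DataFrame:
    """Categorical ANOVA over the unique off-diagonal z distances.

    rule_vs_residual predictors: within/between choice type, within-rule vs
    within-residual (nested in "within"), shared feature vs not, with all
    interactions. color_vs_shape_rule: within/between rule domain, nested
    within-color-rule vs within-shape-rule, and shared-color / shared-shape
    / no-shared-feature; identity pairs that match both features across
    domains are omitted (they would make the design rank-deficient).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    scheme = scheme or rsam.scheme
    pairs = rsam.pair_table()
    if scheme == "rule_vs_residual":
        df = pairs.copy()
        df["within"] = df["same_context"].astype(int)
        df["nested_a"] = (df["same_context"] & (df["context_i"] == "rule")).astype(int)
        df["match"] = df["share_any"].astype(int)
        formula = "z ~ within + nested_a + match + within:match + nested_a:match"
    elif scheme == "color_vs_shape_rule":
        df = pairs[~(pairs["same_identity"] & ~pairs["same_context"])].copy()
        df["within"] = df["same_context"].astype(int)
        df["nested_a"] = (df["same_context"]
                          & (df["context_i"] == "color_rule")).astype(int)
        df["match3"] = np.select(
            [df["share_color"].to_numpy(), df["share_shape"].to_numpy()],
            ["color", "shape"], default="none")
        formula = "z ~ within + nested_a + C(match3) + within:C(match3) + nested_a:C(match3)"
    else:
        raise ValueError(f"no ANOVA defined for scheme {scheme!r}")

    fit = ols(formula, data=df).fit()
    rank = np.linalg.matrix_rank(fit.model.exog)
    if rank < fit.model.exog.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient RSA design matrix "
            f"(rank {rank} < {fit.model.exog.shape[1]} columns); "
            f"column names: {fit.model.exog_names}")
    table = anova_lm(fit, typ=2).reset_index().rename(columns={"index": "term"})
    return table
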