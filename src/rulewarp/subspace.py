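"""Choice-predictive coding dimensions via one-vs-rest ridge logistic
classifiers, and projections of pseudotrials onto them.

Six classifiers -- one per feature (3 colors + 3 shapes) -- are fit on the
per-rule pseudotrial matrix to predict whether the choice includes that
feature. Each coefficient vector is a coding dimension in neuron space:
projection (plus intercept) is the log odds of the choice including that
feature. Comparing projections onto the chosen features' dimensions across
residual, rule-relevant and rule-irrelevant contexts tests whether rule
adherence expands relevant and compresses irrelevant choice coding.

The ridge penalty is chosen as the smallest value on a grid of {0} plus 24
log-spaced values in [1e-4, 1e4] that attains the maximal mean
cross-validated accuracy (stratified folds, tied across the six
classifiers by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .pseudopop import PseudotrialMatrix
from .task import COLORS, SHAPES, FEATURES, DEFAULT_FEATURES

RESIDUAL = "residual"


def default_lambda_grid() -> np.ndarray:
    """{0} plus 24 log-spaced penalties spanning [1e-4, 1e4]."""
    return np.concatenate([[0.0], np.logspace(-4, 4, 24)])


@dataclass
class CodingDimensions:
    """A bank of 6 one-vs-rest classifiers over a neuron roster."""

    features: tuple[str, ...]
    coefs: np.ndarray                  # (6, n_neurons)
    intercepts: np.ndarray             # (6,)
    lambda_: float | np.ndarray        # tied scalar or per-classifier
    cv_accuracy: np.ndarray            # (6,) at the chosen penalty
    neuron_ids: np.ndarray
    kind: str = "choice"

    @property
    def n_classifiers(self) -> int:
        return len(self.features)

    def coef(self, feature: str) -> np.ndarray:
        return self.coefs[self.features.index(feature)]


def _fit_single(x: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    c = np.inf if lam == 0.0 else 1.0 / lam
    return LogisticRegression(C=c, max_iter=2000).fit(x, y)


def _cv_accuracy(x: np.ndarray, ys: list[np.ndarray], lam: float,
                 cv_folds: int, seed: int) -> np.ndarray:
    """Mean CV accuracy per classifier at one penalty, shared folds."""
    acc = np.zeros(len(ys))
    for k, y in enumerate(ys):
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scores = []
        for tr, te in skf.split(x, y):
            if len(np.unique(y[tr])) < 2:
                raise ValueError("a class is absent from a CV fold")
            clf = _fit_single(x[tr], y[tr], lam)
            scores.append(clf.score(x[te], y[te]))
        acc[k] = np.mean(scores)
    return acc


def _fit_bank(
    matrix: PseudotrialMatrix,
    ys: list[np.ndarray],
    features: tuple[str, ...],
    kind: str,
    cv_folds: int,
    lambdas: np.ndarray | None,
    seed: int,
    tie_lambda: bool,
    row_mask: np.ndarray | None = None,
) -> CodingDimensions:
    x = matrix.values if row_mask is None else matrix.values[row_mask]
    lambdas = default_lambda_grid() if lambdas is None else np.asarray(lambdas, float)
    order = np.argsort(lambdas)
    lambdas = lambdas[order]

    acc = np.vstack([_cv_accuracy(x, ys, lam, cv_folds, seed) for lam in lambdas])
    if tie_lambda:
        mean_acc = acc.mean(axis=1)
        best = int(np.flatnonzero(mean_acc >= mean_acc.max() - 1e-12)[0])
        chosen = np.full(len(ys), lambdas[best])
        chosen_acc = acc[best]
        lam_out: float | np.ndarray = float(lambdas[best])
    else:
        idx = [int(np.flatnonzero(acc[:, k] >= acc[:, k].max() - 1e-12)[0])
               for k in range(len(ys))]
        chosen = np.array([lambdas[i] for i in idx])
        chosen_acc = np.array([acc[i, k] for k, i in enumerate(idx)])
        lam_out = chosen

    coefs = np.zeros((len(ys), x.shape[1]))
    icepts = np.zeros(len(ys))
    for k, y in enumerate(ys):
        clf = _fit_single(x, y, chosen[k])
        coefs[k] = clf.coef_[0] * (1 if clf.classes_[1] else -1)
        icepts[k] = float(clf.intercept_[0]) * (1 if clf.classes_[1] else -1)
    return CodingDimensions(features=features, coefs=coefs, intercepts=icepts,
                            lambda_=lam_out, cv_accuracy=chosen_acc,
                            neuron_ids=matrix.neuron_ids, kind=kind)


def fit_choice_classifiers(
    matrix: PseudotrialMatrix,
    cv_folds: int = 20,
    lambdas: np.ndarray | None = None,
    seed: int = 0,
    tie_lambda: bool = True,
) -> CodingDimensions:
    """Fit the 6 one-vs-rest choice classifiers on all pseudotrial rows.

    Rows should span the three goal origins (color rules, shape rules,
    residual) so the choice axes marginalize over goals.
    """
    ys = ([np.asarray(matrix.rows["color"] == f) for f in COLORS]
          + [np.asarray(matrix.rows["shape"] == f) for f in SHAPES])
    for f, y in zip(FEATURES, ys):
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError(f"feature {f!r} has a single class in the rows")
    return _fit_bank(matrix, ys, FEATURES, "choice", cv_folds, lambdas, seed,
                     tie_lambda)


def fit_rule_classifiers(
    matrix: PseudotrialMatrix,
    cv_folds: int = 20,
    lambdas: np.ndarray | None = None,
    seed: int = 0,
    tie_lambda: bool = True,
    rule_rows_only: bool = True,
) -> CodingDimensions:
    """Same protocol, but labels are the identity of the current rule
    (fit on rule-based rows only by default)."""
    ctx = matrix.rows["context"].to_numpy()
    mask = np.char.startswith(ctx.astype(str), "rule:") if rule_rows_only \
        else np.ones(len(ctx), bool)
    rules = np.array([c.removeprefix("rule:") if c.startswith("rule:") else ""
                      for c in ctx[mask]])
    ys = [rules == f for f in FEATURES]
    for f, y in zip(FEATURES, ys):
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError(f"rule {f!r} has a single class in the rows")
    sub = PseudotrialMatrix(matrix.values[mask], matrix.rates[mask],
                            matrix.rows[mask].reset_index(drop=True),
                            matrix.neuron_ids, matrix.regions, matrix.roster,
                            matrix.scheme)
    return _fit_bank(sub, ys, FEATURES, "rule", cv_folds, lambdas, seed,
                     tie_lambda)


def project(matrix: PseudotrialMatrix, dims: CodingDimensions) -> pd.DataFrame:
    """Project every pseudotrial onto every coding dimension.

    Returns a long table with one row per (pseudotrial, dimension):
    ``projection`` is the log odds (x . beta + intercept); ``chosen`` flags
    whether the dimension's feature is part of the row's choice;
    ``relevance`` tags chosen-feature projections as rule-relevant,
    rule-irrelevant, or residual, from the row's state context and the
    dimension's feature domain.
    """
    if list(matrix.neuron_ids) != list(dims.neuron_ids):
        extra = set(matrix.neuron_ids) ^ set(dims.neuron_ids)
        raise ValueError(f"neuron roster mismatch: {sorted(extra)[:10]}")
    proj = matrix.values @ dims.coefs.T + dims.intercepts[None, :]
    recs = []
    ctx = matrix.rows["context"].to_numpy()
    colors = matrix.rows["color"].to_numpy()
    shapes = matrix.rows["shape"].to_numpy()
    for k, f in enumerate(dims.features):
        dom = DEFAULT_FEATURES.domain(f)
        chosen = (colors == f) if dom == "color" else (shapes == f)
        for i in range(matrix.n_rows):
            if ctx[i] == RESIDUAL:
                rel = "residual"
            elif ctx[i].startswith("rule:"):
                rule_dom = DEFAULT_FEATURES.domain(ctx[i].removeprefix("rule:"))
                rel = "relevant" if rule_dom == dom else "irrelevant"
            else:
                rel = "unknown"
            recs.append({"row": i, "context": ctx[i], "chosen_color": colors[i],
                         "chosen_shape": shapes[i], "dimension": f,
                         "domain": dom, "chosen": bool(chosen[i]),
                         "relevance": rel, "projection": float(proj[i, k])})
    return pd.DataFrame(recs)


def dimension_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two coefficient vectors in degrees (intercepts are not
    part of the vectors)."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero vector has no direction")
    c = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def projection_anova(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA and pairwise contrasts over chosen-feature projections.

    Main effect: residual vs rule-based; nested within rule-based: whether
    the dimension's feature domain was rule-relevant. Pairwise 2-sample t
    contrasts (relevant vs irrelevant, relevant vs residual, irrelevant vs
    residual) are Benjamini-Hochberg corrected.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm
    from .metrics import bh_fdr

    df = table[table["chosen"]].copy()
    for lev in ("relevant", "irrelevant", "residual"):
        if (df["relevance"] == lev).sum() == 0:
            raise ValueError(f"no chosen-feature projections with relevance {lev!r}")
    df["is_rule"] = (df["relevance"] != "residual").astype(int)
    df["nested_rel"] = (df["relevance"] == "relevant").astype(int)
    fit = ols("projection ~ is_rule + nested_rel", data=df).fit()
    anova = anova_lm(fit, typ=2).reset_index().rename(columns={"index": "term"})

    groups = {lev: df[df["relevance"] == lev]["projection"].to_numpy()
              for lev in ("relevant", "irrelevant", "residual")}
    crows = []
    for a, b in (("relevant", "irrelevant"), ("relevant", "residual"),
                 ("irrelevant", "residual")):
        t, p = stats.ttest_ind(groups[a], groups[b])
        crows.append({"contrast": f"{a}_vs_{b}", "mean_a": groups[a].mean(),
                      "mean_b": groups[b].mean(),
                      "difference": groups[a].mean() - groups[b].mean(),
                      "t": float(t), "p": float(p)})
    contrasts = pd.DataFrame(crows)
    reject, p_adj = bh_fdr(contrasts["p"].to_numpy())
    contrasts["p_bh"] = p_adj
    contrasts["significant_bh"] = reject
    return anova, contrasts
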