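"""Choice-predictive coding dimensions: classifier bank, projections, angles."""

import numpy as np
import pandas as pd
import pytest

from rulewarp import pseudopop, subspace, synth
from rulewarp.pseudopop import PseudotrialMatrix, build_pseudotrials
from rulewarp.subspace import (
    default_lambda_grid, dimension_angle, fit_choice_classifiers,
    fit_rule_classifiers, project, projection_anova,
)
from rulewarp.task import COLORS, FEATURES, SHAPES

SMALL_GRID = np.array([0.0, 1.0, 100.0])


def separable_matrix(n_per=12, noise=0.05, seed=0, contexts=("residual",)):
    """A pseudotrial matrix whose first six neurons are one-hot indicators
    of the six features: linearly separable by construction."""
    rng = np.random.default_rng(seed)
    rows, vals = [], []
    for ctx in contexts:
        for c in COLORS:
            for s in SHAPES:
                if ctx.startswith("rule:"):
                    f = ctx.removeprefix("rule:")
                    if f not in (c, s):
                        continue
                for _ in range(n_per):
                    v = np.zeros(8)
                    v[FEATURES.index(c)] = 1.0
                    v[FEATURES.index(s)] = 1.0
                    v += rng.normal(0, noise, size=8)
                    vals.append(v)
                    rows.append((c, s, ctx))
    vals = np.asarray(vals)
    return PseudotrialMatrix(
        values=vals, rates=np.abs(vals),
        rows=pd.DataFrame(rows, columns=["color", "shape", "context"]),
        neuron_ids=np.array([f"n{i}" for i in range(8)], dtype=object),
        regions=np.array(["OFC"] * 8, dtype=object),
        roster=pd.DataFrame(), scheme="per_rule",
    )


def test_lambda_grid_is_zero_plus_24_log_spaced():
    grid = default_lambda_grid()
    assert len(grid) == 25
    assert grid[0] == 0.0
    assert grid[1] == pytest.approx(1e-4)
    assert grid[-1] == pytest.approx(1e4)
    assert np.allclose(np.diff(np.log10(grid[1:])), np.diff(np.log10(grid[1:]))[0])


def test_separable_population_classified_accurately():
    m = separable_matrix()
    dims = fit_choice_classifiers(m, cv_folds=5, lambdas=SMALL_GRID, seed=0)
    assert dims.n_classifiers == 6
    assert (dims.cv_accuracy >= 0.95).all()
    assert dims.features == FEATURES


def test_shuffled_labels_score_at_one_vs_rest_chance():
    m = separable_matrix(noise=0.05)
    rng = np.random.default_rng(1)
    shuffled = m.rows.copy()
    shuffled[["color", "shape"]] = (
        shuffled[["color", "shape"]].sample(frac=1, random_state=2)
        .reset_index(drop=True))
    m_sh = PseudotrialMatrix(m.values, m.rates, shuffled, m.neuron_ids,
                             m.regions, m.roster, m.scheme)
    dims = fit_choice_classifiers(m_sh, cv_folds=5, lambdas=SMALL_GRID, seed=0)
    # one-vs-rest base rates are 1/3 vs 2/3: chance accuracy ~2/3
    assert abs(dims.cv_accuracy.mean() - 2 / 3) < 0.08


def test_large_penalty_shrinks_coefficients_monotonically():
    m = separable_matrix()
    norms = []
    for lam in (0.0, 10.0, 1000.0):
        dims = fit_choice_classifiers(m, cv_folds=4, lambdas=np.array([lam]),
                                      seed=0)
        norms.append(np.linalg.norm(dims.coefs))
    assert norms[0] > norms[1] > norms[2]


def test_smallest_lambda_attaining_max_accuracy_is_chosen():
    m = separable_matrix(noise=0.01)
    dims = fit_choice_classifiers(m, cv_folds=4,
                                  lambdas=np.array([0.0, 1e-3, 1e-2]), seed=0)
    # perfectly separable at every penalty: ties resolve to the smallest
    assert dims.lambda_ == 0.0


def test_rule_classifiers_share_protocol_with_choice_classifiers():
    """Rule classifiers run the same one-vs-rest CV protocol on rule-based
    rows. On a choice-coding fixture the rule is only partially decodable
    (the rule feature is always chosen in its own domain, but the same
    choice also occurs under other rules): accuracy sits above the 2/3
    one-vs-rest base rate yet below the choice classifiers'."""
    m = separable_matrix(contexts=[f"rule:{f}" for f in FEATURES])
    dims_rule = fit_rule_classifiers(m, cv_folds=4, lambdas=SMALL_GRID, seed=3)
    assert dims_rule.kind == "rule"
    assert dims_rule.n_classifiers == 6
    assert dims_rule.cv_accuracy.mean() > 0.70
    dims_choice = fit_choice_classifiers(m, cv_folds=4, lambdas=SMALL_GRID, seed=3)
    assert dims_choice.cv_accuracy.mean() > dims_rule.cv_accuracy.mean()


def test_rule_only_coding_dissociates_rule_from_choice_axes():
    """A population that encodes rule identity but not choice features:
    rule classifiers accurate, choice classifiers near chance."""
    rng = np.random.default_rng(4)
    rows, vals = [], []
    for f in FEATURES:
        ids = ([(f, s) for s in SHAPES] if f in COLORS
               else [(c, f) for c in COLORS])
        for c, s in ids:
            for _ in range(12):
                v = np.zeros(8)
                v[FEATURES.index(f)] = 2.0       # rule coding only
                v += rng.normal(0, 0.05, 8)
                vals.append(v)
                rows.append((c, s, f"rule:{f}"))
    m = PseudotrialMatrix(
        values=np.asarray(vals), rates=np.abs(np.asarray(vals)),
        rows=pd.DataFrame(rows, columns=["color", "shape", "context"]),
        neuron_ids=np.array([f"n{i}" for i in range(8)], dtype=object),
        regions=np.array(["OFC"] * 8, dtype=object),
        roster=pd.DataFrame(), scheme="per_rule")
    dims_rule = fit_rule_classifiers(m, cv_folds=4, lambdas=SMALL_GRID, seed=5)
    dims_choice = fit_choice_classifiers(m, cv_folds=4, lambdas=SMALL_GRID, seed=5)
    assert dims_rule.cv_accuracy.mean() > 0.95
    # choice labels are only partially confounded with the rule: accuracy
    # stays well below the rule classifiers'
    assert dims_choice.cv_accuracy.mean() < dims_rule.cv_accuracy.mean() - 0.05


def test_projection_table_structure_and_separable_ordering():
    m = separable_matrix(contexts=("residual", "rule:cyan", "rule:star"))
    dims = fit_choice_classifiers(m, cv_folds=4, lambdas=SMALL_GRID, seed=0)
    table = project(m, dims)
    assert len(table) == m.n_rows * 6
    chosen = table[table["chosen"]]
    unchosen = table[~table["chosen"]]
    assert chosen["projection"].mean() > unchosen["projection"].mean() + 1.0
    # positive log odds on the own-class side of each hyperplane
    for f in FEATURES:
        own = chosen[chosen["dimension"] == f]["projection"]
        assert own.mean() > 0


def test_projection_of_zero_vector_is_intercept():
    m = separable_matrix()
    dims = fit_choice_classifiers(m, cv_folds=4, lambdas=SMALL_GRID, seed=0)
    z = np.zeros((1, 8))
    proj = z @ dims.coefs.T + dims.intercepts[None, :]
    np.testing.assert_allclose(proj[0], dims.intercepts)


def test_projection_relevance_tags():
    """A cyan choice under the cyan rule: its color-dimension projection is
    rule-relevant, its shape-dimension projection rule-irrelevant."""
    m = separable_matrix(contexts=("rule:cyan", "residual"))
    dims = fit_choice_classifiers(m, cv_folds=4, lambdas=SMALL_GRID, seed=0)
    table = project(m, dims)
    sub = table[(table["context"] == "rule:cyan") & table["chosen"]]
    assert (sub.loc[sub["domain"] == "color", "relevance"] == "relevant").all()
    assert (sub.loc[sub["domain"] == "shape", "relevance"] == "irrelevant").all()
    res = table[(table["context"] == "residual") & table["chosen"]]
    assert (res["relevance"] == "residual").all()


def test_roster_mismatch_rejected():
    m = separable_matrix()
    dims = fit_choice_classifiers(m, cv_folds=4, lambdas=SMALL_GRID, seed=0)
    m_bad = PseudotrialMatrix(m.values[:, :7], m.rates[:, :7], m.rows,
                              m.neuron_ids[:7], m.regions[:7], m.roster,
                              m.scheme)
    with pytest.raises(ValueError, match="roster"):
        project(m_bad, dims)


def test_dimension_angle_geometry():
    v = np.array([1.0, 2.0, 3.0])
    assert dimension_angle(v, v) == pytest.approx(0.0)
    assert dimension_angle(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(90.0)
    assert dimension_angle(v, -v) == pytest.approx(180.0)
    with pytest.raises(ValueError):
        dimension_angle(v, np.zeros(3))
    # independent random vectors in high dimension concentrate near 90 deg
    rng = np.random.default_rng(6)
    angles = [dimension_angle(rng.standard_normal(400), rng.standard_normal(400))
              for _ in range(50)]
    assert abs(np.mean(angles) - 90.0) < 3.0
    assert np.std(angles) < 5.0


def test_classifiers_invariant_to_row_order():
    m = separable_matrix()
    rng = np.random.default_rng(7)
    perm = rng.permutation(m.n_rows)
    m_perm = PseudotrialMatrix(m.values[perm], m.rates[perm],
                               m.rows.iloc[perm].reset_index(drop=True),
                               m.neuron_ids, m.regions, m.roster, m.scheme)
    d1 = fit_choice_classifiers(m, cv_folds=4, lambdas=np.array([1.0]), seed=0)
    d2 = fit_choice_classifiers(m_perm, cv_folds=4, lambdas=np.array([1.0]), seed=0)
    np.testing.assert_allclose(d1.coefs, d2.coefs, atol=1e-6)


def test_projection_anova_recovers_warping_order(warped_bundle):
    """Warping generator: chosen-feature projections order rule-relevant >
    residual > rule-irrelevant, all pairwise significant after BH."""
    trials, truth, spikes, _ = warped_bundle
    m = build_pseudotrials(spikes, trials, truth.states, "per_rule", seed=9)
    dims = fit_choice_classifiers(m, cv_folds=5, lambdas=SMALL_GRID, seed=1)
    table = project(m, dims)
    anova, contrasts = projection_anova(table)
    means = {lev: table[table["chosen"] & (table["relevance"] == lev)]
             ["projection"].mean() for lev in ("relevant", "irrelevant", "residual")}
    assert means["relevant"] > means["residual"] > means["irrelevant"]
    assert contrasts["significant_bh"].all()
    an = anova.set_index("term")
    assert an.loc["is_rule", "PR(>F)"] < 0.05 or an.loc["nested_rel", "PR(>F)"] < 0.05


def test_projection_anova_null_under_no_warping(null_bundle):
    trials, truth, spikes, _ = null_bundle
    m = build_pseudotrials(spikes, trials, truth.states, "per_rule", seed=9)
    dims = fit_choice_classifiers(m, cv_folds=5, lambdas=SMALL_GRID, seed=1)
    _, contrasts = projection_anova(project(m, dims))
    rel_irr = contrasts.set_index("contrast").loc["relevant_vs_irrelevant"]
    assert rel_irr["p_bh"] > 0.01


def test_held_out_projection_ordering_survives_outer_cv(warped_bundle):
    """Chosen > unchosen projection ordering on rows never seen in
    training (guards against overfitting artifacts)."""
    trials, truth, spikes, _ = warped_bundle
    m = build_pseudotrials(spikes, trials, truth.states, "per_rule", seed=10)
    rng = np.random.default_rng(11)
    fold = rng.integers(5, size=m.n_rows)
    diffs = []
    for k in range(5):
        tr, te = fold != k, fold == k
        m_tr = PseudotrialMatrix(m.values[tr], m.rates[tr],
                                 m.rows[tr].reset_index(drop=True),
                                 m.neuron_ids, m.regions, m.roster, m.scheme)
        m_te = PseudotrialMatrix(m.values[te], m.rates[te],
                                 m.rows[te].reset_index(drop=True),
                                 m.neuron_ids, m.regions, m.roster, m.scheme)
        dims = fit_choice_classifiers(m_tr, cv_folds=4, lambdas=np.array([1.0]),
                                      seed=k)
        table = project(m_te, dims)
        diffs.append(table[table["chosen"]]["projection"].mean()
                     - table[~table["chosen"]]["projection"].mean())
    assert (np.asarray(diffs) > 0).all()
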