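"""Single-neuron statistics: calibration, closed-form identities, oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rulewarp import metrics, synth
from rulewarp.metrics import (
    bh_fdr, gini_index, identity_category_index, mutual_information,
    rate_contrast_permutation, zscore_within_neuron,
)
from rulewarp.spikes import SpikeCountTable
from rulewarp.task import COLORS, SHAPES


# ---------------------------------------------------------------------------
# normalization


def test_zscore_modes():
    rng = np.random.default_rng(0)
    x = rng.poisson(5.0, size=(100, 4)).astype(float)
    z = zscore_within_neuron(x, "zscore")
    assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-9)
    c = zscore_within_neuron(x, "center_only")
    assert np.allclose(c.mean(axis=0), 0, atol=1e-9)
    # ordering preserved: scaling changes only the scale
    assert (np.argsort(z[:, 0]) == np.argsort(c[:, 0])).all()
    const = np.ones((10, 1))
    assert np.allclose(zscore_within_neuron(const, "center_only"), 0)
    assert np.allclose(zscore_within_neuron(const, "zscore"), 0)  # flagged, centered


# ---------------------------------------------------------------------------
# permutation test


def test_permutation_matches_exact_enumeration():
    rng = np.random.default_rng(1)
    y = rng.normal(size=8)
    labels = np.array([True] * 4 + [False] * 4)
    obs, p = rate_contrast_permutation(y, labels, exact=True)
    # independent oracle: enumerate all C(8,4) assignments by hand
    diffs = [y[list(idx)].mean() - np.delete(y, list(idx)).mean()
             for idx in combinations(range(8), 4)]
    p_oracle = np.mean(np.abs(diffs) >= abs(obs) - 1e-12)
    assert p == pytest.approx(p_oracle)
    assert obs == pytest.approx(y[:4].mean() - y[4:].mean())


def test_permutation_null_p_is_uniform():
    """Under independent labels, permutation p-values are uniform (KS test
    over repeated synthetic draws, alpha = 0.01)."""
    rng = np.random.default_rng(2)
    ps = []
    labels = np.array([True] * 30 + [False] * 30)
    for i in range(200):
        y = rng.normal(size=60)
        _, p = rate_contrast_permutation(y, labels, n_perm=199, seed=rng,
                                         exact=False)
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_permutation_detects_injected_shift():
    rng = np.random.default_rng(3)
    y = np.concatenate([rng.normal(1.0, 1.0, 200), rng.normal(0.0, 1.0, 200)])
    labels = np.array([True] * 200 + [False] * 200)
    diff, p = rate_contrast_permutation(y, labels, n_perm=1000, seed=4, exact=False)
    assert p < 0.01 and diff > 0.5


def test_permutation_requires_two_per_class():
    with pytest.raises(ValueError):
        rate_contrast_permutation(np.arange(5.0), np.array([True] + [False] * 4))


# ---------------------------------------------------------------------------
# tuning ANOVAs


def _spike_table(counts, regions=None):
    n = counts.shape[1]
    return SpikeCountTable(
        counts=counts,
        neuron_ids=np.array([f"n{i}" for i in range(n)], dtype=object),
        regions=np.array(regions if regions is not None else ["OFC"] * n,
                         dtype=object),
        trial_index=np.arange(1, counts.shape[0] + 1),
    )


def test_anova_f_matches_hand_computed_toy():
    """One-way F for a 3-group toy equals the hand-computed between/within
    variance ratio."""
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
    g = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    means = [2.0, 5.0, 8.0]
    grand = 5.0
    ss_between = 3 * sum((m - grand) ** 2 for m in means)     # 54
    ss_within = sum((y[i] - means[i // 3]) ** 2 for i in range(9))  # 6
    f_hand = (ss_between / 2) / (ss_within / 6)               # 27
    f_scipy = stats.f_oneway(y[:3], y[3:6], y[6:]).statistic
    assert f_scipy == pytest.approx(f_hand)
    assert f_hand == pytest.approx(27.0)


def test_tuning_anova_suite_detects_rule_identity_tuning(small_session):
    trials, truth = small_session
    spikes, _ = synth.simulate_neurons(
        trials, truth, synth.TuningSpec(rule_coef_sd=0.8, n_neurons={"OFC": 40}),
        seed=1, with_presentation_epochs=False)
    _, summary = metrics.tuning_anova_suite(spikes, trials, truth.states)
    rid = summary[summary["factor"] == "rule_identity"].iloc[0]
    assert rid["proportion"] > 0.5
    assert rid["binomial_p"] < 1e-6


def test_tuning_anova_false_positive_rate_calibrated():
    """Pure-noise neurons are significant at about the nominal 5% rate."""
    trials, truth = synth.simulate_behavior(synth.AgentSpec(), n_blocks=20, seed=30)
    spec = synth.TuningSpec(rule_coef_sd=0, color_coef_sd=0, shape_coef_sd=0,
                            identity_coef_sd=0, state_gain=1.0,
                            n_neurons={"OFC": 200})
    spikes, _ = synth.simulate_neurons(trials, truth, spec, seed=2,
                                       with_presentation_epochs=False)
    _, summary = metrics.tuning_anova_suite(spikes, trials, truth.states)
    for _, row in summary.iterrows():
        sd = np.sqrt(0.05 * 0.95 / row["n_tested"])
        assert abs(row["proportion"] - 0.05) < 3 * sd + 1e-9
        assert row["binomial_p"] > 0.001


# ---------------------------------------------------------------------------
# Gini


def test_gini_closed_form_values():
    assert gini_index(np.array([0, 0, 0, 1.0])) == pytest.approx(0.75)  # 1 - 1/N
    for n in (3, 10, 57):
        assert gini_index(np.full(n, 3.7)) == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=40)
       .filter(lambda v: sum(v) > 0),
       st.floats(min_value=1e-3, max_value=1e3),
       st.randoms())
def test_gini_scale_and_permutation_invariance(vec, c, pyrandom):
    x = np.asarray(vec)
    g = gini_index(x)
    assert -1e-9 <= g < 1  # uniform input sits at 0 up to float error
    assert gini_index(c * x) == pytest.approx(g, abs=1e-9)
    perm = list(range(len(x)))
    pyrandom.shuffle(perm)
    assert gini_index(x[perm]) == pytest.approx(g, abs=1e-9)


def test_gini_zero_neuron_increases_sparsity():
    x = np.array([1.0, 2.0, 3.0])
    assert gini_index(np.append(x, 0.0)) > gini_index(x)


def test_gini_rejects_degenerate_input():
    with pytest.raises(ValueError):
        gini_index(np.zeros(4))
    with pytest.raises(ValueError):
        gini_index(np.array([1.0, -1.0]))


# ---------------------------------------------------------------------------
# mutual information


def test_mi_noiseless_binary_channel_is_one_bit():
    rng = np.random.default_rng(5)
    n = 120
    labels = np.array((["a"] * (n // 2) + ["b"] * (n // 2)) * 2)
    counts = np.where(labels == "a", 1.0, 10.0)  # disjoint count ranges
    is_rule = np.array([True] * n + [False] * n)
    res = mutual_information(counts, labels, is_rule, seed=rng, n_shuffle=10)
    assert res.mi["rule"] == pytest.approx(1.0)
    assert res.mi["residual"] == pytest.approx(1.0)
    assert res.bits_per_spike["rule"] == pytest.approx(1.0 / 5.5)


def test_mi_matches_hand_plugin_on_printed_table():
    """A 2x2 joint count table 30/10/10/30 gives the hand-computed plug-in
    MI to 1e-12."""
    bins = np.array([0] * 40 + [1] * 40)
    labels = np.array(["x"] * 30 + ["y"] * 10 + ["x"] * 10 + ["y"] * 30)
    mi = metrics._plugin_mi(bins, labels)
    p = np.array([[30, 10], [10, 30]]) / 80
    hand = sum(p[i, j] * np.log2(p[i, j] / (p[i].sum() * p[:, j].sum()))
               for i in range(2) for j in range(2))
    assert mi == pytest.approx(hand, abs=1e-12)
    assert hand == pytest.approx(0.1887218755408671)


def test_mi_independent_counts_sit_at_shuffle_floor():
    """Counts independent of choice: MI minus the shuffle floor has no
    systematic sign across 50 synthetic neurons."""
    rng = np.random.default_rng(6)
    identities = np.array([f"{c}/{s}" for c in COLORS for s in SHAPES])
    diffs = []
    for _ in range(50):
        n = 180
        labels = identities[rng.integers(9, size=n)]
        counts = rng.poisson(8.0, size=n).astype(float)
        is_rule = rng.random(n) < 0.5
        if min(is_rule.sum(), (~is_rule).sum()) < 5:
            continue
        res = mutual_information(counts, labels, is_rule, seed=rng, n_shuffle=30)
        diffs.append(res.mi["rule"] - res.mi_shuffle["rule"])
    t, p = stats.ttest_1samp(diffs, 0.0)
    assert p > 0.01


def test_mi_downsamples_rule_trials():
    rng = np.random.default_rng(7)
    n_rule, n_res = 150, 40
    labels = np.array(["a", "b"] * ((n_rule + n_res) // 2))
    counts = rng.poisson(5.0, size=n_rule + n_res).astype(float)
    is_rule = np.array([True] * n_rule + [False] * n_res)
    res = mutual_information(counts, labels, is_rule, seed=rng, n_shuffle=5)
    assert res.n_trials_used["rule"] == n_res


# ---------------------------------------------------------------------------
# identity-category index


def test_identity_index_orders_interaction_above_additive():
    """Across matched noise seeds, interaction-tuned responses score a
    higher index than additive responses."""
    rng = np.random.default_rng(8)
    colors = np.array([c for c in COLORS for _ in range(30)] * 3)
    shapes = np.array([s for _ in range(90) for s in SHAPES])
    wins = 0
    for _ in range(10):
        noise = rng.normal(0, 1.0, size=len(colors))
        b_id = {(c, s): rng.normal(0, 2) for c in COLORS for s in SHAPES}
        y_inter = np.array([b_id[(c, s)] for c, s in zip(colors, shapes)]) + noise
        b_c = {c: rng.normal(0, 2) for c in COLORS}
        b_s = {s: rng.normal(0, 2) for s in SHAPES}
        y_add = (np.array([b_c[c] for c in colors])
                 + np.array([b_s[s] for s in shapes]) + noise)
        i_inter = identity_category_index(y_inter, colors, shapes).index
        i_add = identity_category_index(y_add, colors, shapes).index
        wins += i_inter > i_add
    assert wins >= 9


def test_identity_index_identical_inputs_identical_output():
    rng = np.random.default_rng(9)
    colors = np.array([COLORS[i] for i in rng.integers(3, size=180)])
    shapes = np.array([SHAPES[i] for i in rng.integers(3, size=180)])
    y = rng.normal(size=180)
    a = identity_category_index(y, colors, shapes)
    b = identity_category_index(y.copy(), colors.copy(), shapes.copy())
    assert a.index == b.index


def test_identity_index_f_values_match_statsmodels():
    """Both F statistics equal a reference statsmodels OLS/ANOVA fit."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    rng = np.random.default_rng(10)
    colors = np.array([COLORS[i] for i in rng.integers(3, size=90)])
    shapes = np.array([SHAPES[i] for i in rng.integers(3, size=90)])
    y = rng.normal(size=90) + (colors == "cyan") * 1.5
    res = identity_category_index(y, colors, shapes)
    df = pd.DataFrame({"y": y, "color": colors, "shape": shapes,
                       "ident": [f"{c}/{s}" for c, s in zip(colors, shapes)]})
    f_id_ref = ols("y ~ C(ident)", df).fit().fvalue
    f_cat_ref = ols("y ~ C(color) + C(shape)", df).fit().fvalue
    assert res.f_identity == pytest.approx(f_id_ref, abs=1e-9)
    assert res.f_category == pytest.approx(f_cat_ref, abs=1e-9)


# ---------------------------------------------------------------------------
# relevance-tuning GLM


@pytest.fixture(scope="module")
def glm_session():
    return synth.simulate_behavior(synth.AgentSpec(), n_blocks=25, seed=12)


def test_relevance_glm_detects_sharpening(glm_session):
    trials, truth = glm_session
    spikes, _ = synth.simulate_neurons(
        trials, truth, synth.TuningSpec(gamma_rel=1.8, gamma_irr=0.5,
                                        color_coef_sd=0.4, shape_coef_sd=0.4),
        seed=13)
    res = metrics.relevance_tuning_glm(spikes, trials, truth.states, target="choice")
    assert res.params["b3_SxR"] > 0
    assert res.pvalues["b3_SxR"] < 0.01
    assert res.params["b1_S"] > 0
    rel = res.contrasts[res.contrasts["contrast"] == "relevant_vs_irrelevant"]
    assert (rel["mean_difference"] > 0).all()


def test_relevance_glm_null_when_no_modulation(glm_session):
    trials, truth = glm_session
    spikes, _ = synth.simulate_neurons(
        trials, truth, synth.TuningSpec(gamma_rel=1.0, gamma_irr=1.0,
                                        state_gain=1.0, rule_coef_sd=0.0),
        seed=14)
    res = metrics.relevance_tuning_glm(spikes, trials, truth.states, target="choice")
    t_b3 = res.params["b3_SxR"] / res.bse["b3_SxR"]
    assert abs(t_b3) < 3
    assert res.params["b1_S"] > 0  # forced by the best/worst ranking


def test_relevance_glm_stimulus_target_runs(glm_session):
    trials, truth = glm_session
    spikes, _ = synth.simulate_neurons(
        trials, truth, synth.TuningSpec(stim_coef_sd=0.3, gamma_rel=1.5,
                                        gamma_irr=0.6), seed=15)
    res = metrics.relevance_tuning_glm(spikes, trials, truth.states,
                                       target="stimulus")
    assert set(res.params.index) == {"b0", "b1_S", "b2_R", "b3_SxR"}
    assert res.params["b1_S"] > 0


# ---------------------------------------------------------------------------
# BH-FDR


def test_bh_fdr_extremes_and_hand_worked_example():
    reject, _ = bh_fdr([0.001] * 10)
    assert reject.all()
    reject, _ = bh_fdr([0.9] * 10)
    assert not reject.any()
    # hand-worked 5-value step-up at q=0.05:
    # sorted p = .004 .01 .02 .04 .3; thresholds k/m*q = .01 .02 .03 .04 .05
    # largest k with p_(k) <= k/m*q is k=4 -> reject the four smallest
    p = [0.02, 0.3, 0.004, 0.04, 0.01]
    reject, p_adj = bh_fdr(p)
    assert list(reject) == [True, False, True, True, True]
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])
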