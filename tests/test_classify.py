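"""ROC analysis, published cut-off rules and the logistic model."""

import numpy as np
import pytest

from lobmorph import (
    CaseSummary,
    apply_rules,
    fit_logistic,
    published_rules,
    roc_curve,
)
from conftest import brute_force_auc


def test_roc_perfect_separation():
    res = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert res.auc == 1.0
    assert res.chosen_sens == 1.0 and res.chosen_spec == 1.0
    assert 3 <= res.chosen_threshold < 10


def test_roc_null_symmetry(rng):
    """Random labels on distinct scores: mean AUC over seeds ~ 0.5."""
    aucs = []
    for _ in range(200):
        scores = rng.permutation(40).astype(float)
        labels = np.r_[np.ones(20), np.zeros(20)]
        aucs.append(roc_curve(scores, labels).auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)


def test_roc_auc_matches_u_statistic_oracle(rng):
    for _ in range(25):
        n = 30
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        res = roc_curve(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


def test_roc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.normal(size=200)
    labels = (rng.uniform(size=200) < 1 / (1 + np.exp(-scores))).astype(int)
    assert roc_curve(scores, labels).auc == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12
    )


def test_roc_monotone_transform_invariance(rng):
    scores = rng.normal(size=80)
    labels = rng.integers(0, 2, 80)
    labels[:3] = 1
    labels[-3:] = 0
    a = roc_curve(scores, labels)
    b = roc_curve(np.exp(scores), labels)  # strictly increasing transform
    assert a.auc == pytest.approx(b.auc, abs=1e-12)
    assert b.chosen_threshold == pytest.approx(np.exp(a.chosen_threshold))
    c = roc_curve(-scores, labels)
    assert c.auc == pytest.approx(1 - a.auc, abs=1e-12)


def test_roc_one_class_errors():
    with pytest.raises(ValueError):
        roc_curve([1.0, 2.0], [1, 1])


def test_published_rule_set_constants():
    rules = published_rules()
    assert len(rules) == 8
    by_key = {(r.parameter, r.statistic): r.threshold for r in rules}
    assert by_key[("area", "median")] == 48.2
    assert by_key[("perimeter", "median")] == 25.2
    assert by_key[("min_feret", "median")] == 6.8
    assert by_key[("max_feret", "median")] == 9.1
    assert by_key[("area", "iqr")] == 19.4
    assert by_key[("perimeter", "iqr")] == 5.3
    assert by_key[("min_feret", "iqr")] == 1.5
    assert by_key[("max_feret", "iqr")] == 2.2
    assert all(r.direction == "greater" for r in rules)


def _area_summary(key, median, q1, q3):
    return CaseSummary.from_quartiles(key, {"area": (median, q1, q3)})


def test_rules_on_published_pilc_cases():
    """Printed per-case values: case 5 fires both area rules, case 2 only
    the variability (IQR) rule."""
    area_rules = [r for r in published_rules() if r.parameter == "area"]
    case5 = _area_summary("case_05", 82.5, 60.5, 60.5 + 45.4)
    res5 = apply_rules(case5, area_rules, combination="all_of")
    assert res5.flags[("area", "median")] and res5.flags[("area", "iqr")]
    assert res5.call
    case2 = _area_summary("case_02", 47.0, 29.0, 29.0 + 37.1)
    res2 = apply_rules(case2, area_rules, combination="any_of")
    assert not res2.flags[("area", "median")]
    assert res2.flags[("area", "iqr")]
    assert res2.call


def test_rule_boundary_is_strict():
    # thresholds exactly representable in binary so the boundary is exact
    from lobmorph import CutoffRule

    rules = [
        CutoffRule("area", "median", 48.25),
        CutoffRule("area", "iqr", 19.0),
    ]
    exactly_at = _area_summary("edge", 48.25, 48.25 - 9.5, 48.25 + 9.5)
    res = apply_rules(exactly_at, rules, combination="any_of")
    assert not any(res.flags.values())
    assert not res.call
    just_above = _area_summary("above", 48.2500001, 48.25 - 9.5, 48.25 + 9.5000001)
    res = apply_rules(just_above, rules, combination="any_of")
    assert all(res.flags.values())


def test_rule_flags_monotone():
    rules = [r for r in published_rules() if r.parameter == "area"]
    lo = _area_summary("lo", 50.0, 40.0, 61.0)
    hi = _area_summary("hi", 70.0, 45.0, 95.0)  # every statistic increased
    flo = apply_rules(lo, rules, "all_of").flags
    fhi = apply_rules(hi, rules, "all_of").flags
    for k in flo:
        assert fhi[k] >= flo[k]


def test_combination_policies():
    rules = published_rules()
    s = CaseSummary.from_quartiles(
        "c",
        {
            "area": (60.0, 45.0, 70.0),       # median fires, iqr (25) fires
            "perimeter": (24.0, 22.0, 26.0),  # neither fires
            "min_feret": (7.0, 6.5, 7.6),     # median fires, iqr (1.1) no
            "max_feret": (9.5, 8.5, 11.0),    # median fires, iqr (2.5) fires
        },
    )
    assert apply_rules(s, rules, "single_parameter").call  # both max_feret rules
    assert not apply_rules(s, rules, "all_of").call
    assert apply_rules(s, rules, "any_of").call
    assert apply_rules(s, rules, "vote_k", vote_k=5).call
    assert not apply_rules(s, rules, "vote_k", vote_k=6).call


def test_rules_missing_parameter_errors():
    s = _area_summary("c", 60.0, 45.0, 70.0)
    with pytest.raises(KeyError):
        apply_rules(s, published_rules(), "all_of")


def test_logistic_two_by_two_closed_form():
    """Single binary feature: the fitted odds ratio is the cross-product
    ratio ad/bc of the 2x2 table (a=10, b=5, c=4, d=20 -> OR 10)."""
    x = np.r_[np.ones(10), np.zeros(5), np.ones(4), np.zeros(20)].reshape(-1, 1)
    y = np.r_[np.ones(15), np.zeros(24)]
    model = fit_logistic(x, y, ["exposed"])
    eff = model.effect("exposed")
    assert eff.odds_ratio == pytest.approx(10.0, abs=1e-6)
    assert model.converged and not model.separation
    assert eff.ci_low <= eff.odds_ratio <= eff.ci_high


def test_logistic_null_false_positive_rate():
    """Labels independent of the feature: Wald p > 0.05 in >= 90% of
    replicates (nominal size of the test)."""
    root = np.random.default_rng(123)
    n_nonsig = 0
    for _ in range(100):
        r = np.random.default_rng(root.integers(2**31))
        x = r.standard_normal((500, 1))
        y = r.integers(0, 2, 500)
        model = fit_logistic(x, y, ["f"])
        if model.effect("f").p_value > 0.05:
            n_nonsig += 1
    assert n_nonsig >= 90


def test_logistic_recovers_generating_coefficients():
    r = np.random.default_rng(2024)
    n = 400
    X = r.standard_normal((n, 2))
    true_beta = np.array([0.8, -1.2])
    p = 1 / (1 + np.exp(-(0.3 + X @ true_beta)))
    y = (r.uniform(size=n) < p).astype(float)
    model = fit_logistic(X, y, ["a", "b"])
    for name, beta in zip(("a", "b"), true_beta):
        eff = model.effect(name)
        assert abs(eff.coefficient - beta) < 2 * eff.std_error


def test_logistic_separation_flagged():
    x = np.r_[np.zeros(10), np.ones(10)].reshape(-1, 1)
    y = np.r_[np.zeros(10), np.ones(10)]
    with pytest.warns(UserWarning, match="separation"):
        model = fit_logistic(x, y, ["f"])
    assert model.separation


def test_logistic_input_validation():
    with pytest.raises(ValueError, match="constant"):
        fit_logistic(np.ones((10, 1)), np.r_[np.ones(5), np.zeros(5)])
    with pytest.raises(ValueError, match="both classes"):
        fit_logistic(np.arange(10.0).reshape(-1, 1), np.ones(10))
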