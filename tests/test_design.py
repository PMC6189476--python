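"""Model construction: effect structures, parameter counts, response
probabilities, monotonicity."""

import itertools

import numpy as np
import pytest

from hdcm.design import (ModelSpec, ParameterSet, build_model,
                         check_monotonicity, class_probabilities,
                         count_free_parameters, degrees_of_freedom,
                         response_probability)
from hdcm.hierarchy import (AttributeHierarchy, enumerate_permissible_patterns,
                            hierarchy_preset, restrict_pattern)


# -- degrees of freedom against the published study designs ---------------

@pytest.mark.parametrize("family, hierarchy, k, df", [
    ("hdcm", "linear", 65, 145),
    ("hdcm", "divergent", 77, 133),
    ("hdcm", "convergent", 68, 142),
    ("hdcm", "unstructured", 89, 121),
    ("lcdm", None, 121, 89),
    ("dina", None, 71, 139),
])
def test_parameter_counts_simulation_qmatrix(q20, family, hierarchy, k, df):
    h = hierarchy_preset(hierarchy) if hierarchy else None
    spec = build_model(family, q20, h)
    assert count_free_parameters(spec) == k
    assert degrees_of_freedom(spec) == df


@pytest.mark.parametrize("family, hierarchy, df", [
    ("hdcm", "ecpe-linear", 338),
    ("lcdm", None, 325),
    ("dina", None, 343),
    ("crum", None, 334),
])
def test_parameter_counts_ecpe_qmatrix(q_ecpe, family, hierarchy, df):
    h = hierarchy_preset(hierarchy) if hierarchy else None
    spec = build_model(family, q_ecpe, h)
    assert degrees_of_freedom(spec) == df


# -- effect-term structure -------------------------------------------------

def test_hdcm_linear_item_terms():
    """Item measuring {1,2,4} under the 5-attribute chain: main effect of
    1, interaction of 2 nested in 1, and the three-way term."""
    q = np.array([[1, 1, 0, 1, 0]])
    spec = build_model("hdcm", q, hierarchy_preset("linear"))
    terms = [t.attrs for t in spec.items[0].terms]
    assert terms == [(1,), (1, 2), (1, 2, 4)]
    assert spec.items[0].n_params == 4


def test_hdcm_divergent_item_terms():
    q = np.array([[1, 1, 0, 1, 0]])
    spec = build_model("hdcm", q, hierarchy_preset("divergent"))
    terms = [t.attrs for t in spec.items[0].terms]
    assert terms == [(1,), (1, 2), (1, 4), (1, 2, 4)]


def test_lcdm_item_is_saturated():
    q = np.array([[1, 1, 1]])
    spec = build_model("lcdm", q)
    assert spec.items[0].n_params == 8  # 2**3


def test_crum_and_dina_item_sizes():
    q = np.array([[1, 1, 1], [0, 1, 0]])
    crum = build_model("crum", q)
    assert [it.n_params for it in crum.items] == [4, 2]
    dina = build_model("dina", q)
    assert [it.n_params for it in dina.items] == [2, 2]
    assert dina.items[0].terms[0].attrs == (1, 2, 3)


def test_hdcm_equals_lcdm_without_hierarchy():
    q = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 0]])
    hd = build_model("hdcm", q, AttributeHierarchy(3, []))
    lc = build_model("lcdm", q)
    assert [it.n_params for it in hd.items] == [it.n_params for it in lc.items]
    assert all(t1.attrs == t2.attrs
               for i1, i2 in zip(hd.items, lc.items)
               for t1, t2 in zip(i1.terms, i2.terms))


@pytest.mark.parametrize("name", ["linear", "convergent", "divergent",
                                  "unstructured"])
def test_item_params_equal_distinct_reduced_patterns(name):
    """Parameter-count law: HDCM item parameters = number of distinct
    reduced permissible patterns on the item's required attributes,
    checked for every possible nonzero 5-attribute item."""
    h = hierarchy_preset(name)
    pats = enumerate_permissible_patterns(h)
    rows = [r for r in itertools.product((0, 1), repeat=5) if any(r)]
    spec = build_model("hdcm", np.array(rows), h)
    for row, item in zip(rows, spec.items):
        distinct = {tuple(restrict_pattern(p, np.array(row))) for p in pats}
        assert item.n_params == len(distinct)


def test_design_rows_separate_reduced_patterns(q20, linear5):
    """Two classes share a design row iff they project identically onto
    the item's required attributes."""
    spec = build_model("hdcm", q20, linear5)
    for j, item in enumerate(spec.items):
        for a in range(spec.n_classes):
            for b in range(a + 1, spec.n_classes):
                same_row = np.array_equal(item.design[a], item.design[b])
                same_reduced = np.array_equal(
                    restrict_pattern(spec.patterns[a], q20[j]),
                    restrict_pattern(spec.patterns[b], q20[j]))
                assert same_row == same_reduced


# -- response probabilities ------------------------------------------------

def test_logistic_closed_form():
    """Single-attribute item with main effect 2, intercept -1: masters at
    logistic(1) = 0.7311, non-masters at logistic(-1) = 0.2689."""
    q = np.array([[1]])
    spec = build_model("lcdm", q)
    params = ParameterSet(spec, [np.array([-1.0, 2.0])])
    p_non = response_probability(spec, params, 0, 0)
    p_mas = response_probability(spec, params, 1, 0)
    assert p_non == pytest.approx(0.2689, abs=1e-4)
    assert p_mas == pytest.approx(0.7311, abs=1e-4)


def test_partial_mastery_uses_only_relevant_effects():
    """q=(0,1,1) and mastery (1,1,0): only the main effect of attribute 2
    enters the predictor."""
    q = np.array([[0, 1, 1]])
    spec = build_model("lcdm", q)
    b = np.array([0.3, 1.1, 0.7, 0.9])  # intercept, main2, main3, int23
    params = ParameterSet(spec, [b])
    cls = [tuple(p) for p in spec.patterns]
    p = response_probability(spec, params, cls.index((1, 1, 0)), 0)
    assert p == pytest.approx(1 / (1 + np.exp(-(0.3 + 1.1))), abs=1e-12)


def test_dina_guessing_slip_mapping():
    """DINA in intercept/effect form: g = logistic(b0),
    1 - s = logistic(b0 + b1); checked with g=0.74, s=0.17."""
    from scipy.special import logit
    q = np.array([[0, 1, 0]])
    spec = build_model("dina", q)
    g, s = 0.74, 0.17
    params = ParameterSet(spec, [np.array([logit(g), logit(1 - s) - logit(g)])])
    probs = {tuple(p): response_probability(spec, params, i, 0)
             for i, p in enumerate(spec.patterns)}
    for pat, pr in probs.items():
        expected = 1 - s if pat[1] == 1 else g
        assert pr == pytest.approx(expected, abs=1e-12)


def test_saturating_predictor_no_overflow():
    q = np.array([[1]])
    spec = build_model("lcdm", q)
    params = ParameterSet(spec, [np.array([-200.0, 400.0])])
    p = class_probabilities(spec, params)
    assert np.isfinite(p).all()
    assert (p > 0).all() and (p < 1).all()


# -- monotonicity ----------------------------------------------------------

def test_monotone_for_positive_effects(q20, linear5):
    from hdcm.datagen import build_true_parameters
    spec = build_model("hdcm", q20, linear5)
    ok, violations = check_monotonicity(spec, build_true_parameters(spec))
    assert ok and violations == []


def test_negative_main_effect_is_flagged():
    q = np.array([[1]])
    spec = build_model("lcdm", q)
    params = ParameterSet(spec, [np.array([0.5, -1.0])])
    ok, violations = check_monotonicity(spec, params)
    assert not ok and len(violations) == 1


def test_dina_monotone_iff_g_below_one_minus_s():
    from scipy.special import logit
    q = np.array([[1, 1]])
    spec = build_model("dina", q)
    good = ParameterSet(spec, [np.array([logit(0.2), logit(0.8) - logit(0.2)])])
    assert check_monotonicity(spec, good)[0]
    bad = ParameterSet(spec, [np.array([logit(0.7), logit(0.4) - logit(0.7)])])
    assert not check_monotonicity(spec, bad)[0]


# -- serialization and guards ---------------------------------------------

def test_spec_json_roundtrip(q20, linear5):
    spec = build_model("hdcm", q20, linear5)
    spec2 = ModelSpec.from_json(spec.to_json())
    assert spec2.family == spec.family
    assert np.array_equal(spec2.q, spec.q)
    assert spec2.n_free_parameters() == spec.n_free_parameters()


def test_unknown_family_rejected(q20):
    with pytest.raises(ValueError, match="family"):
        build_model("rum", q20)


def test_saturated_model_rejected_for_margin_test():
    # 2 items -> d = 3; any model with k >= 3 has no testable margins
    q = np.array([[1], [1]])
    spec = build_model("lcdm", q)
    with pytest.raises(ValueError, match="margin"):
        degrees_of_freedom(spec)
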