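"""M2 statistic: margins, covariance, Jacobian, RMSEA2 — all checked
against literal dense constructions on small tests."""

import warnings

import numpy as np
import pytest

from hdcm.datagen import GenConfig, generate_dataset
from hdcm.design import ParameterSet, build_model, class_probabilities
from hdcm.estimator import DiagnosticClassificationModel
from hdcm.gof import (m2_statistic, margin_index, marginal_operator,
                      model_margins, observed_margins, rmsea2,
                      rmsea2_interval, _delta2, _xi2)
from hdcm.hierarchy import AttributeHierarchy


def _fit(family, q, X, **kw):
    kw.setdefault("n_starts", 1)
    kw.setdefault("tol", 1e-9)
    kw.setdefault("max_iter", 20000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return DiagnosticClassificationModel(family, q, **kw).fit(X)


# -- margins ---------------------------------------------------------------

def test_observed_margins_hand_counts():
    X = np.array([[1, 0], [0, 1]])
    assert observed_margins(X).tolist() == [0.5, 0.5, 0.0]
    assert (observed_margins(np.ones((4, 3))) == 1).all()


def test_margin_operator_matches_streamed_for_three_items():
    """The literal d x 2**J selector applied to the empirical pattern
    distribution reproduces the streamed computation (J = 3)."""
    rng = np.random.default_rng(0)
    X = (rng.random((200, 3)) < 0.4).astype(int)
    L2 = marginal_operator(3)
    assert L2.shape == (6, 8)
    p_full = np.zeros(8)
    for x in X:
        p_full[x[0] + 2 * x[1] + 4 * x[2]] += 1
    p_full /= len(X)
    assert np.allclose(L2 @ p_full, observed_margins(X), atol=1e-12)


def test_model_margins_two_class_mixture():
    """Two equi-probable classes with item probabilities (0.9, 0.9) and
    (0.1, 0.1): univariate margins 0.5, bivariate 0.41."""
    q = np.array([[1], [1]])
    spec = build_model("lcdm", q)
    b = np.log(9.0)  # logistic(-b) = 0.1, logistic(+b) = 0.9
    params = ParameterSet(spec, [np.array([-b, 2 * b]) for _ in range(2)],
                          class_probs=[0.5, 0.5])
    pi2 = model_margins(spec, params)
    assert pi2[:2] == pytest.approx([0.5, 0.5])
    assert pi2[2] == pytest.approx(0.41)


def test_model_margins_enumeration_oracle(q20, linear5):
    """Streamed mixture margins equal the materialized L2 x full-table
    product for the 5-attribute HDCM (J reduced to 10 items)."""
    q = q20[:10]
    spec = build_model("hdcm", q, linear5)
    from hdcm.datagen import build_true_parameters
    params = build_true_parameters(spec)
    nu = np.linspace(1, 2, spec.n_classes)
    params = ParameterSet(spec, params.item_params, nu / nu.sum())
    P = class_probabilities(spec, params)
    J = 10
    L2 = marginal_operator(J)
    pi_full = np.zeros(2 ** J)
    for col in range(2 ** J):
        bits = np.array([(col >> j) & 1 for j in range(J)])
        pi_full[col] = float(params.class_probs
                             @ np.prod(np.where(bits == 1, P, 1 - P), axis=1))
    assert np.allclose(L2 @ pi_full, model_margins(spec, params), atol=1e-10)


# -- the full statistic against the dense construction ---------------------

@pytest.fixture(scope="module")
def dense_case(tiny_q):
    """A fitted DINA model on J=6 (full-rank margins Jacobian) plus its
    dense ingredients."""
    spec = build_model("lcdm", tiny_q)
    X, _ = generate_dataset(spec, GenConfig(500, mean=0.2, correlation=0.4),
                            np.random.default_rng(5))
    est = _fit("dina", tiny_q, X)
    return est, X


def test_m2_equals_dense_construction(dense_case):
    from helpers import dense_m2
    est, X = dense_case
    res = m2_statistic(est, X)
    assert res.m2 == pytest.approx(dense_m2(est, X), abs=1e-8)
    assert res.d == 21 and res.k == 15 and res.df == 6


def test_xi2_matches_dense(dense_case):
    from helpers import full_pattern_table
    est, X = dense_case
    spec, params = est.spec_, est.params_
    P = class_probabilities(spec, params)
    nu = params.class_probs
    L2 = marginal_operator(spec.n_items)
    pi_full = full_pattern_table(spec, params)
    Xi2_dense = L2 @ (np.diag(pi_full) - np.outer(pi_full, pi_full)) @ L2.T
    assert np.allclose(Xi2_dense, _xi2(P, nu), atol=1e-12)


def test_delta2_analytic_vs_finite_difference(q20, linear5):
    """Analytic margin Jacobian matches central differences of the
    streamed margins to 1e-6 on the 20-item HDCM."""
    spec = build_model("hdcm", q20, linear5)
    rng = np.random.default_rng(3)
    betas = [rng.normal(0, 0.8, it.n_params) for it in spec.items]
    nu = rng.dirichlet(np.full(spec.n_classes, 3.0))
    params = ParameterSet(spec, betas, nu)
    analytic = _delta2(spec, params)

    eps = 1e-6
    fd = np.zeros_like(analytic)
    col = 0
    for j, it in enumerate(spec.items):
        for t in range(it.n_params):
            bp = [b.copy() for b in betas]
            bm = [b.copy() for b in betas]
            bp[j][t] += eps
            bm[j][t] -= eps
            fd[:, col] = (model_margins(spec, ParameterSet(spec, bp, nu))
                          - model_margins(spec, ParameterSet(spec, bm, nu))
                          ) / (2 * eps)
            col += 1
    eta = np.log(nu / nu[0])
    for b in range(1, spec.n_classes):
        ep, em = eta.copy(), eta.copy()
        ep[b] += eps
        em[b] -= eps
        nup = np.exp(ep) / np.exp(ep).sum()
        num = np.exp(em) / np.exp(em).sum()
        fd[:, col] = (model_margins(spec, ParameterSet(spec, betas, nup))
                      - model_margins(spec, ParameterSet(spec, betas, num))
                      ) / (2 * eps)
        col += 1
    assert np.abs(analytic - fd).max() < 1e-6


def test_softmax_chart_invariance(dense_case):
    """M2 is invariant to the reference class of the structural chart."""
    est, X = dense_case
    a = m2_statistic(est, X, reference_class=0)
    b = m2_statistic(est, X, reference_class=2)
    assert a.m2 == pytest.approx(b.m2, abs=1e-8)


def test_m2_invariant_to_item_and_row_order(dense_case):
    est, X = dense_case
    base = m2_statistic(est, X).m2
    perm_rows = np.random.default_rng(0).permutation(X.shape[0])
    assert m2_statistic(est, X[perm_rows]).m2 == pytest.approx(base, abs=1e-10)
    item_perm = [3, 1, 5, 0, 4, 2]
    q_perm = np.asarray(est.spec_.q)[item_perm]
    est2 = _fit("dina", q_perm, X[:, item_perm])
    assert m2_statistic(est2, X[:, item_perm]).m2 == pytest.approx(
        base, rel=1e-4)


def test_perfect_margin_fit_gives_zero():
    """When model margins equal the observed margins exactly, M2 and
    RMSEA2 are zero: the uniform model against the full factorial of
    J = 4 items."""
    import itertools
    q = np.array([[1]] * 4)
    spec = build_model("lcdm", q)
    X = np.array(list(itertools.product((0, 1), repeat=4)))
    params = ParameterSet(spec, [np.zeros(2)] * 4, class_probs=[0.5, 0.5])
    res = m2_statistic(spec, X, params)
    assert res.m2 == pytest.approx(0.0, abs=1e-12)
    assert res.rmsea2 == 0.0


def test_degenerate_margin_error(tiny_q):
    spec = build_model("lcdm", tiny_q)
    X, _ = generate_dataset(spec, GenConfig(200, mean=0.0, correlation=0.4),
                            np.random.default_rng(12))
    est = _fit("lcdm", tiny_q, X)
    # force a degenerate fitted item: probability ~1 in every class
    for c in (0, 1):
        est.params_.item_params[0][c] = 40.0
    with pytest.raises(ValueError, match="singular|degenerate"):
        m2_statistic(est, X)


# -- RMSEA2 ----------------------------------------------------------------

@pytest.mark.parametrize("m2, df, n, expected", [
    (514.280, 338, 2922, 0.013),
    (470.809, 325, 2922, 0.012),
    (515.607, 343, 2922, 0.013),
])
def test_rmsea2_published_triples(m2, df, n, expected):
    assert round(rmsea2(m2, df, n), 3) == expected


def test_rmsea2_clamps_at_zero():
    assert rmsea2(100.0, 120, 500) == 0.0


def test_rmsea2_interval_brackets_point():
    m2, df, n = 514.280, 338, 2922
    lo, hi = rmsea2_interval(m2, df, n)
    point = rmsea2(m2, df, n)
    assert lo <= point <= hi
    # inverting the bounds recovers the tail probabilities
    from scipy import stats
    assert stats.ncx2.cdf(m2, df, lo ** 2 * n * df) == pytest.approx(0.95,
                                                                     abs=1e-6)
    assert stats.ncx2.cdf(m2, df, hi ** 2 * n * df) == pytest.approx(0.05,
                                                                     abs=1e-6)


def test_rmsea2_interval_zero_lower_bound_for_good_fit():
    lo, hi = rmsea2_interval(100.0, 120, 500)
    assert lo == 0.0 and hi >= 0.0


def test_m2_result_fields(dense_case):
    est, X = dense_case
    res = m2_statistic(est, X)
    assert res.df == res.d - res.k
    assert 0 <= res.p_value <= 1
    assert res.residuals.shape == (res.d,)
    assert res.n == X.shape[0]
    d = res.to_dict()
    assert set(d) >= {"M2", "df", "p_value", "RMSEA2", "RMSEA2_90ci", "N"}
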