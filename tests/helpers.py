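"""Shared brute-force oracles for small-J checks.

These deliberately take the literal route — materialized selector matrix,
full 2**J response-pattern table, explicit weight-matrix algebra, finite
differences — independent of the streamed implementation they check.
"""

import numpy as np

from hdcm.design import ParameterSet, class_probabilities
from hdcm.gof import marginal_operator


def full_pattern_table(spec, params):
    """Model probabilities of all 2**J response patterns (item 1 is the
    least significant bit of the column index)."""
    P = class_probabilities(spec, params)
    nu = params.class_probs
    J = spec.n_items
    out = np.zeros(2 ** J)
    for col in range(2 ** J):
        bits = np.array([(col >> j) & 1 for j in range(J)])
        out[col] = float(nu @ np.prod(np.where(bits == 1, P, 1 - P), axis=1))
    return out


def empirical_pattern_table(X):
    X = np.asarray(X)
    J = X.shape[1]
    p = np.zeros(2 ** J)
    for x in X:
        p[int(sum(int(b) << j for j, b in enumerate(x)))] += 1
    return p / X.shape[0]


def dense_delta2(spec, params, eps=1e-6):
    """Margin Jacobian by central finite differences of the full table."""
    L2 = marginal_operator(spec.n_items)
    nu = params.class_probs
    cols = []
    for j, it in enumerate(spec.items):
        for t in range(it.n_params):
            bp = [b.copy() for b in params.item_params]
            bm = [b.copy() for b in params.item_params]
            bp[j][t] += eps
            bm[j][t] -= eps
            fp = full_pattern_table(spec, ParameterSet(spec, bp, nu))
            fm = full_pattern_table(spec, ParameterSet(spec, bm, nu))
            cols.append((fp - fm) / (2 * eps))
    eta = np.log(nu / nu[0])
    for b in range(1, spec.n_classes):
        ep, em = eta.copy(), eta.copy()
        ep[b] += eps
        em[b] -= eps
        nup = np.exp(ep) / np.exp(ep).sum()
        num = np.exp(em) / np.exp(em).sum()
        fp = full_pattern_table(spec, ParameterSet(spec, params.item_params,
                                                   nup))
        fm = full_pattern_table(spec, ParameterSet(spec, params.item_params,
                                                   num))
        cols.append((fp - fm) / (2 * eps))
    return L2 @ np.array(cols).T


def dense_m2(est, X):
    """Literal statistic: explicit selector, full table, explicit
    inverse-based weight matrix.  Valid when the margins Jacobian has
    full column rank."""
    spec, params = est.spec_, est.params_
    N = X.shape[0]
    L2 = marginal_operator(spec.n_items)
    pi_full = full_pattern_table(spec, params)
    p_full = empirical_pattern_table(X)
    Xi2 = L2 @ (np.diag(pi_full) - np.outer(pi_full, pi_full)) @ L2.T
    Delta2 = dense_delta2(spec, params)
    r2 = L2 @ (p_full - pi_full)
    Xi2i = np.linalg.inv(Xi2)
    A = Delta2.T @ Xi2i @ Delta2
    W2 = Xi2i - Xi2i @ Delta2 @ np.linalg.inv(A) @ Delta2.T @ Xi2i
    return float(N * r2 @ W2 @ r2)
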