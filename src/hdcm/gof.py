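"""Limited-information goodness of fit: the M2 statistic and RMSEA2.

Full-information chi-square tests over the 2**J response-pattern table
are useless for realistic test lengths because the table is almost empty.
M2 instead compares observed and model-implied first- and second-order
margins (item proportions correct and pairwise joint proportions), a
vector of length d = J + J(J-1)/2.  With residuals r2 = p2 - pi2_hat and
the weight matrix

    W2 = Xi2^-1 - Xi2^-1 D2 (D2' Xi2^-1 D2)^-1 D2' Xi2^-1,

where Xi2 is the multinomial covariance of the margins and D2 the
Jacobian of the model margins in the free parameters, the statistic
M2 = N r2' W2 r2 is asymptotically chi-square with d - k degrees of
freedom at the MLE.  RMSEA2 = sqrt(max(M2 - df, 0) / (N df)) turns it
into an effect-size-like misfit index; its 90% CI comes from inverting
the noncentral chi-square distribution.

Everything is assembled from class-mixture moments of at most four items
at a time — the 2**J table is never materialized (a dense construction is
available for small J as a cross-check oracle, see ``marginal_operator``).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import cholesky, solve_triangular

from .design import ModelSpec, ParameterSet, class_probabilities

__all__ = [
    "M2Result",
    "margin_index",
    "marginal_operator",
    "observed_margins",
    "model_margins",
    "m2_statistic",
    "rmsea2",
    "rmsea2_interval",
    "null_calibration",
]


def margin_index(J: int):
    """Ordered margin item-sets: all singletons, then pairs (i<j)."""
    return ([(j,) for j in range(J)]
            + [tuple(p) for p in itertools.combinations(range(J), 2)])


def marginal_operator(J: int) -> np.ndarray:
    """Materialized d x 2**J selector matrix L2 (small J only).

    Column order enumerates response patterns with item 1 as the least
    significant bit; row r selects the patterns scoring 1 on every item
    of the r-th margin set.
    """
    if J > 20:
        raise ValueError("refusing to materialize L2 for J > 20")
    margins = margin_index(J)
    d = len(margins)
    L2 = np.zeros((d, 2 ** J), dtype=int)
    for col in range(2 ** J):
        bits = [(col >> j) & 1 for j in range(J)]
        for r, s in enumerate(margins):
            L2[r, col] = int(all(bits[j] for j in s))
    return L2


def observed_margins(X) -> np.ndarray:
    """Observed first- and second-order proportions p2 of a 0/1 matrix."""
    X = np.asarray(X, dtype=float)
    J = X.shape[1]
    uni = X.mean(axis=0)
    pairs = margin_index(J)[J:]
    i_idx = np.array([p[0] for p in pairs], dtype=int)
    j_idx = np.array([p[1] for p in pairs], dtype=int)
    biv = (X[:, i_idx] * X[:, j_idx]).mean(axis=0)
    return np.concatenate([uni, biv])


def model_margins(spec: ModelSpec, params: ParameterSet) -> np.ndarray:
    """Model-implied margins pi2_hat via the class mixture.

    Local independence within class gives pi_j = sum_c nu_c p_jc and
    pi_jj' = sum_c nu_c p_jc p_j'c without touching the 2**J table.
    """
    P = class_probabilities(spec, params)      # (C, J)
    nu = params.class_probs
    J = spec.n_items
    uni = nu @ P
    pairs = margin_index(J)[J:]
    i_idx = np.array([p[0] for p in pairs], dtype=int)
    j_idx = np.array([p[1] for p in pairs], dtype=int)
    biv = nu @ (P[:, i_idx] * P[:, j_idx])
    return np.concatenate([uni, biv])


def _margin_profiles(P: np.ndarray):
    """(d, C) per-class products over each margin's item set."""
    C, J = P.shape
    pairs = margin_index(J)[J:]
    i_idx = np.array([p[0] for p in pairs], dtype=int)
    j_idx = np.array([p[1] for p in pairs], dtype=int)
    return np.vstack([P.T, (P[:, i_idx] * P[:, j_idx]).T])


def _xi2(P: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the margins, Xi2 = L2 Xi L2'.

    Entry (a, b) equals pi_{a u b} - pi_a pi_b, where the union involves
    at most four items.  The disjoint case is a rank-C product; entries
    whose margin sets overlap are corrected with exact joint moments of
    up to three items.
    """
    C, J = P.shape
    A = _margin_profiles(P)                    # (d, C)
    pi = A @ nu                                # (d,)
    # disjoint-union approximation, then overlap corrections
    xi = (A * nu) @ A.T - np.outer(pi, pi)

    def pos(s):
        s = tuple(sorted(s))
        if len(s) == 1:
            return s[0]
        i, j = s
        # pairs are ordered lexicographically after the J singletons
        return J + (i * (2 * J - i - 1)) // 2 + (j - i - 1)

    # joint moments of all item triples (unions of overlapping pairs)
    pi3 = {}
    for (i, j, l) in itertools.combinations(range(J), 3):
        pi3[(i, j, l)] = float(nu @ (P[:, i] * P[:, j] * P[:, l]))

    # univariate diagonal: E[x_j^2] = pi_j
    for j in range(J):
        xi[j, j] = pi[j] - pi[j] ** 2
    # univariate x bivariate sharing the item, and bivariate diagonal
    for (i, j) in itertools.combinations(range(J), 2):
        b = pos((i, j))
        xi[i, b] = xi[b, i] = pi[b] - pi[i] * pi[b]
        xi[j, b] = xi[b, j] = pi[b] - pi[j] * pi[b]
        xi[b, b] = pi[b] - pi[b] ** 2
    # bivariate pairs sharing exactly one item
    for (i, j, l) in itertools.combinations(range(J), 3):
        m = pi3[(i, j, l)]
        for s1, s2 in (((i, j), (i, l)), ((i, j), (j, l)), ((i, l), (j, l))):
            a, b = pos(s1), pos(s2)
            xi[a, b] = xi[b, a] = m - pi[a] * pi[b]
    return xi


def _delta2(spec: ModelSpec, params: ParameterSet,
            reference_class: int = 0) -> np.ndarray:
    """Analytic Jacobian D2 of the model margins in the free parameters.

    Columns: item coefficients in item order (intercept first), then the
    C - 1 softmax structural parameters (log-odds against the reference
    class).  Margins are smooth class mixtures, so every entry is exact:
    d pi_S / d lambda_jt = sum_c nu_c p_jc (1 - p_jc) D_j[c, t]
    prod_{j' in S \\ j} p_j'c, and the structural columns follow the
    softmax chain rule d nu_c / d eta_b = nu_c (1[c=b] - nu_b).
    """
    P = class_probabilities(spec, params)
    nu = params.class_probs
    C, J = P.shape
    d = J + J * (J - 1) // 2
    g = P * (1.0 - P)                          # (C, J)
    A = _margin_profiles(P)                    # (d, C)
    pi = A @ nu

    n_item = sum(it.n_params for it in spec.items)
    delta = np.zeros((d, n_item + C - 1))

    pairs = margin_index(J)[J:]
    pair_rows: dict[int, list] = {j: [] for j in range(J)}
    for r, (i, j) in enumerate(pairs):
        pair_rows[i].append((J + r, j))
        pair_rows[j].append((J + r, i))

    col = 0
    for j, it in enumerate(spec.items):
        D = it.design.astype(float)            # (C, p_j)
        w_uni = nu * g[:, j]
        delta[j, col:col + it.n_params] = w_uni @ D
        for row, partner in pair_rows[j]:
            delta[row, col:col + it.n_params] = (w_uni * P[:, partner]) @ D
        col += it.n_params

    # structural block: d pi_S / d eta_b = nu_b (A[S, b] - pi_S)
    b_cols = [c for c in range(C) if c != reference_class]
    delta[:, n_item:] = nu[b_cols] * (A[:, b_cols] - pi[:, None])
    return delta


@dataclass
class M2Result:
    """M2 fit test with RMSEA2 effect size.

    ``rank_deficient`` flags a Jacobian whose numerical column rank fell
    short of k (near-boundary class proportions); the projection then
    spans only the identified directions.
    """

    m2: float
    d: int
    k: int
    df: int
    p_value: float
    rmsea2: float
    rmsea2_ci: tuple
    residuals: np.ndarray
    n: int
    rank_deficient: bool = False

    def __repr__(self):
        lo, hi = self.rmsea2_ci
        return (f"M2Result(M2={self.m2:.3f}, df={self.df}, "
                f"p={self.p_value:.4g}, RMSEA2={self.rmsea2:.4f} "
                f"[{lo:.4f}, {hi:.4f}], N={self.n})")

    def to_dict(self):
        return {
            "M2": self.m2, "d": self.d, "k": self.k, "df": self.df,
            "p_value": self.p_value, "RMSEA2": self.rmsea2,
            "RMSEA2_90ci": list(self.rmsea2_ci), "N": self.n,
        }


def rmsea2(m2: float, df: int, n: int) -> float:
    """RMSEA2 = sqrt(max(M2 - df, 0) / (N df))."""
    if df <= 0 or n <= 0:
        raise ValueError("df and N must be positive")
    return float(np.sqrt(max(m2 - df, 0.0) / (n * df)))


def rmsea2_interval(m2: float, df: int, n: int, level: float = 0.90):
    """Noncentrality-inversion confidence interval for RMSEA2.

    The lower (upper) bound is the noncentrality lambda at which the
    observed M2 sits at the upper (lower) tail quantile of the noncentral
    chi-square(df, lambda); the bound is sqrt(lambda / (N df)).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0

    def _solve(prob):
        # find lambda with ncx2.cdf(m2, df, lambda) = prob
        if stats.chi2.cdf(m2, df) <= prob:
            return 0.0
        lo, hi = 0.0, max(4.0 * (m2 - df + 1), 10.0)
        while stats.ncx2.cdf(m2, df, hi) > prob:
            hi *= 2.0
            if hi > 1e8:
                break
        from scipy.optimize import brentq
        return brentq(lambda nc: stats.ncx2.cdf(m2, df, nc) - prob,
                      lo, hi, xtol=1e-10)

    lam_lower = _solve(1.0 - tail)
    lam_upper = _solve(tail)
    return (float(np.sqrt(lam_lower / (n * df))),
            float(np.sqrt(lam_upper / (n * df))))


def m2_statistic(model_or_spec, X, params: ParameterSet | None = None,
                 reference_class: int = 0, level: float = 0.90) -> M2Result:
    """Compute M2, its p-value, and RMSEA2 with CI for a fitted model.

    Accepts either a fitted ``DiagnosticClassificationModel`` or an
    explicit ``(ModelSpec, params)`` pair evaluated at the MLE.
    ``reference_class`` picks the softmax chart for the structural
    Jacobian; the statistic is invariant to this choice because W2
    projects out the model's tangent space.
    """
    if params is None:
        est = model_or_spec
        spec, params = est.spec_, est.params_
    else:
        spec = model_or_spec
    X = np.asarray(X)
    N, J = X.shape
    if J != spec.n_items:
        raise ValueError("X and model disagree on the number of items")

    d = J + J * (J - 1) // 2
    k = spec.n_free_parameters()
    df = d - k
    if df < 1:
        raise ValueError("non-positive degrees of freedom; the model is "
                         "saturated in the bivariate margins")

    p2 = observed_margins(X)
    pi2 = model_margins(spec, params)
    r2 = p2 - pi2

    P = class_probabilities(spec, params)
    nu = params.class_probs
    xi2 = _xi2(P, nu)
    degenerate = np.flatnonzero((pi2 < 1e-10) | (pi2 > 1 - 1e-10))
    try:
        L = cholesky(xi2, lower=True)
    except np.linalg.LinAlgError:
        names = [str(tuple(i + 1 for i in s))
                 for s in np.array(margin_index(J), dtype=object)[degenerate]]
        raise ValueError(
            "margin covariance is singular; degenerate margins: "
            + (", ".join(names) if names else "(none flagged)"))

    delta = _delta2(spec, params, reference_class=reference_class)
    e = solve_triangular(L, r2, lower=True)
    B = solve_triangular(L, delta, lower=True)
    # The projection depends only on the column span of B, so equilibrate
    # the columns before rank detection: structural directions of
    # near-empty classes are scaled by nu_b but remain genuine tangent
    # directions (the limit of interior estimates), whereas an exact
    # linear dependence (the linear-hierarchy HDCM loses one direction to
    # margins of order >= 3) stays at machine zero either way.
    norms = np.linalg.norm(B, axis=0)
    nonzero = norms > 0
    Bn = B[:, nonzero] / norms[nonzero]
    U, s, _ = np.linalg.svd(Bn, full_matrices=False)
    keep = s > s[0] * 1e-8
    rank_deficient = int(keep.sum()) < k
    if rank_deficient:
        # conventional df = d - k is kept regardless
        warnings.warn(
            f"margins Jacobian has column rank {int(keep.sum())} < k={k}; "
            "some parameter combinations are not identified from first- "
            "and second-order margins", stacklevel=2)
    s_kept = s[keep]
    if s_kept.size and s_kept[0] / s_kept[-1] > 1e12:
        warnings.warn("ill-conditioned margin Jacobian "
                      f"(condition {s_kept[0] / s_kept[-1]:.2e})",
                      stacklevel=2)
    proj = U[:, keep].T @ e
    m2 = float(N * max(e @ e - proj @ proj, 0.0))

    p_value = float(stats.chi2.sf(m2, df))
    point = rmsea2(m2, df, N)
    ci = rmsea2_interval(m2, df, N, level=level)
    return M2Result(m2=m2, d=d, k=k, df=df, p_value=p_value,
                    rmsea2=point, rmsea2_ci=ci, residuals=r2, n=N,
                    rank_deficient=rank_deficient)


def null_calibration(family, q_matrix, hierarchy, n_examinees, reps,
                     seed, alphas=(0.01, 0.05, 0.10, 0.20, 0.25),
                     gen_config=None, fit_opts=None):
    """Empirical distribution of M2 under a correctly specified model.

    Generates ``reps`` datasets from the model family itself (redrawing
    the latent-normal mean and correlation per replication unless fixed
    in ``gen_config``), refits the same specification, and tabulates the
    mean and SD of M2 plus rejection proportions at ``alphas``.  Failed
    fits are excluded and counted.  Returns a dict.
    """
    from .experiments import run_cell  # local import to avoid a cycle

    cell = run_cell(gen_family=family, gen_hierarchy=hierarchy,
                    q_matrix=q_matrix, fit_family=family,
                    fit_hierarchy=hierarchy, n_examinees=n_examinees,
                    reps=reps, seed=seed, gen_config=gen_config,
                    fit_opts=fit_opts)
    m2s = np.array([r["m2"] for r in cell["replications"]])
    ps = np.array([r["p_value"] for r in cell["replications"]])
    return {
        "df": cell["replications"][0]["df"] if cell["replications"] else None,
        "reps": len(m2s),
        "failed": cell["failed"],
        "mean": float(m2s.mean()) if m2s.size else np.nan,
        "sd": float(m2s.std(ddof=1)) if m2s.size > 1 else np.nan,
        "rejection": {a: float((ps < a).mean()) for a in alphas},
        "m2_values": m2s,
        "p_values": ps,
    }
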