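"""Marginal maximum-likelihood estimation of diagnostic classification
models by EM over the permissible latent classes.

The observed-data likelihood of a response matrix X under any of the four
families is a finite mixture over the C permissible mastery patterns,

    L = prod_i sum_c nu_c prod_j p_jc^{x_ij} (1 - p_jc)^{1 - x_ij},

with p_jc the logistic item response probability of class c.  The E-step
computes posterior class memberships; the M-step solves one weighted
logistic regression per item on its class-level design matrix (Newton
steps with step-halving, coefficients box-bounded) and updates the class
proportions as posterior means, so the observed log-likelihood is
monotone non-decreasing across iterations.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .design import (ModelSpec, ParameterSet, PREDICTOR_BOUND, build_model,
                     class_probabilities, count_free_parameters)
from .hierarchy import AttributeHierarchy, hierarchy_preset

__all__ = [
    "DiagnosticClassificationModel",
    "fit",
    "log_likelihood",
    "information_criteria",
    "EFFECT_BOUND",
]

#: Box bound on item coefficients; practical identifiability ends well
#: before this (real-data boundary estimates sit around |lambda| ~ 21).
EFFECT_BOUND = 30.0

_PROB_FLOOR = 1e-12


def _resolve_hierarchy(hierarchy, K):
    if hierarchy is None:
        return None
    if isinstance(hierarchy, AttributeHierarchy):
        return hierarchy
    if isinstance(hierarchy, str):
        return hierarchy_preset(hierarchy, None if hierarchy != "none" else K)
    return AttributeHierarchy(K, hierarchy)


def _validate_X(X, J):
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D examinees x items array")
    if J is not None and X.shape[1] != J:
        raise ValueError(f"X has {X.shape[1]} items but the model expects {J}")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("responses must be binary 0/1 with no missingness")
    return X.astype(float)


def _class_loglik(X, P):
    """(N, C) matrix of log P(x_i | class c) under local independence."""
    P = np.clip(P, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    logit = np.log(P) - np.log1p(-P)        # (C, J)
    base = np.log1p(-P).sum(axis=1)         # (C,)
    return X @ logit.T + base


def log_likelihood(spec: ModelSpec, params: ParameterSet, X) -> float:
    """Observed-data log-likelihood of X under (spec, params)."""
    X = _validate_X(X, spec.n_items)
    P = class_probabilities(spec, params)
    lc = _class_loglik(X, P) + np.log(params.class_probs)
    return float(logsumexp(lc, axis=1).sum())


def information_criteria(loglik: float, k: int, n: int):
    """(AIC, BIC) = (-2LL + 2k, -2LL + k log n)."""
    return (-2.0 * loglik + 2.0 * k, -2.0 * loglik + k * np.log(n))


def _mstep_item(design, successes, totals, beta, lower=None):
    """Newton ascent of one item's weighted binomial log-likelihood.

    ``design`` is the C x p class design matrix, ``successes``/``totals``
    the posterior-weighted success and trial counts per class.  Steps are
    halved until the objective does not decrease, and coefficients are
    clipped to the box [``lower``, EFFECT_BOUND] (``lower`` defaults to
    -EFFECT_BOUND everywhere; a zero lower bound on effect coordinates
    enforces monotonicity).
    """
    if lower is None:
        lower = np.full(beta.shape, -EFFECT_BOUND)

    def objective(b):
        eta = np.clip(design @ b, -EFFECT_BOUND - 5, EFFECT_BOUND + 5)
        return successes @ eta - totals @ np.logaddexp(0.0, eta)

    obj = objective(beta)
    for _ in range(25):
        eta = np.clip(design @ beta, -EFFECT_BOUND - 5, EFFECT_BOUND + 5)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = design.T @ (successes - totals * p)
        w = totals * p * (1.0 - p)
        H = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            step = grad
        improved = False
        for _ in range(20):
            cand = np.clip(beta + step, lower, EFFECT_BOUND)
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                improved = cand_obj > obj + 1e-10
                beta, obj = cand, cand_obj
                break
            step *= 0.5
        if not improved and np.max(np.abs(grad)) < 1e-9:
            break
        if not improved:
            break
    return beta


def _class_probs_direct(designs, betas):
    """(C, J) success probabilities straight from designs and coefficients."""
    cols = [1.0 / (1.0 + np.exp(-np.clip(D @ b, -PREDICTOR_BOUND,
                                         PREDICTOR_BOUND)))
            for D, b in zip(designs, betas)]
    return np.column_stack(cols)


def _em(spec, X, beta0, nu0, tol, max_iter, monotone=False):
    """Run EM from one start; returns (betas, nu, loglik, n_iter, converged,
    posterior).

    Rows of X are compressed to unique response patterns with counts, so
    the E-step scales with the number of distinct patterns rather than N.
    Plain EM steps are interleaved with squared-extrapolation (SQUAREM)
    jumps, each accepted only if it does not lower the observed
    log-likelihood, so ascent is preserved while slow geometric
    convergence — typical for many-class mixtures — is short-circuited.
    """
    designs = [it.design.astype(float) for it in spec.items]
    lowers = [None] * spec.n_items
    if monotone:
        lowers = [np.concatenate([[-EFFECT_BOUND], np.zeros(len(it.terms))])
                  for it in spec.items]
    Xu, inverse, counts = np.unique(X, axis=0, return_inverse=True,
                                    return_counts=True)
    w = counts.astype(float)
    sizes = np.cumsum([0] + [len(b) for b in beta0])

    def pack(betas, nu):
        return np.concatenate(betas + [np.log(np.maximum(nu, _PROB_FLOOR))])

    def unpack(theta):
        betas = [theta[a:b] for a, b in zip(sizes[:-1], sizes[1:])]
        if monotone:
            betas = [np.clip(b, lo, EFFECT_BOUND)
                     for b, lo in zip(betas, lowers)]
        else:
            betas = [np.clip(b, -EFFECT_BOUND, EFFECT_BOUND) for b in betas]
        lognu = theta[sizes[-1]:]
        nu = np.exp(lognu - lognu.max())
        nu = np.maximum(nu / nu.sum(), _PROB_FLOOR)
        return betas, nu / nu.sum()

    def loglik_and_post(betas, nu):
        P = _class_probs_direct(designs, betas)
        lc = _class_loglik(Xu, P) + np.log(np.maximum(nu, _PROB_FLOOR))
        ll_u = logsumexp(lc, axis=1)
        return float(w @ ll_u), np.exp(lc - ll_u[:, None])

    def em_update(betas, nu):
        """One EM step; returns updated parameters and the input LL."""
        ll, post = loglik_and_post(betas, nu)
        wpost = post * w[:, None]
        totals = wpost.sum(axis=0)
        successes = wpost.T @ Xu
        new_betas = [
            _mstep_item(designs[j], successes[:, j], totals, betas[j].copy(),
                        lowers[j] if monotone else None)
            for j in range(spec.n_items)]
        new_nu = np.maximum(totals / totals.sum(), _PROB_FLOOR)
        return new_betas, new_nu / new_nu.sum(), ll

    betas, nu = [b.copy() for b in beta0], nu0.copy()
    n_steps = 0
    converged = False
    ll_current = -np.inf
    while n_steps < max_iter:
        b1, nu1, ll0 = em_update(betas, nu)
        b2, nu2, ll1 = em_update(b1, nu1)
        n_steps += 2
        ll_current = ll1
        if np.isfinite(ll0) and abs(ll1 - ll0) < tol * abs(ll0):
            betas, nu = b2, nu2
            converged = True
            break
        p0, p1, p2 = pack(betas, nu), pack(b1, nu1), pack(b2, nu2)
        r, v = p1 - p0, p2 - 2 * p1 + p0
        vnorm = np.linalg.norm(v)
        if vnorm < 1e-12:
            betas, nu = b2, nu2
            continue
        alpha = -max(1.0, np.linalg.norm(r) / vnorm)
        bx, nux = unpack(p0 - 2 * alpha * r + alpha ** 2 * v)
        llx, _ = loglik_and_post(bx, nux)
        if np.isfinite(llx) and llx >= ll1:
            betas, nu = bx, nux
        else:
            betas, nu = b2, nu2
    ll_final, post = loglik_and_post(betas, nu)
    return betas, nu, ll_final, n_steps, converged, post[inverse]


class DiagnosticClassificationModel(BaseEstimator):
    """Latent-class diagnostic model (HDCM / LCDM / DINA / C-RUM).

    Parameters
    ----------
    family : {"hdcm", "lcdm", "dina", "crum"}, default "hdcm"
        Item parameterization.
    q_matrix : array-like of shape (n_items, n_attributes)
        0/1 incidence of attributes measured by each item.
    hierarchy : None, str, AttributeHierarchy, or edge list
        Prerequisite structure; a preset name ("linear", "convergent",
        "divergent", "unstructured", "ecpe-linear") or explicit 1-based
        edge pairs.  ``None`` means no hierarchy (full 2**K space).
    n_starts : int, default 3
        EM restarts; the first uses neutral starting values (intercepts
        -1, effects +1, uniform class proportions), the rest jitter them.
        The best final log-likelihood wins.
    tol : float, default 1e-7
        Relative log-likelihood change for convergence.
    max_iter : int, default 2000
        EM iteration cap per start.
    monotone : bool, default False
        Constrain all effect coefficients to be non-negative during
        estimation, enforcing monotone response functions (the model's
        defining constraint; off by default so boundary behaviour is
        visible rather than hidden).
    random_state : int or Generator, optional
        Controls the multistart jitter only.

    Attributes
    ----------
    spec_ : ModelSpec
        Built effect structure and latent space.
    params_ : ParameterSet
        Maximum-likelihood item coefficients and class proportions.
    log_likelihood_ : float
    n_parameters_ : int
        Free parameter count k (item parameters plus C - 1).
    aic_, bic_ : float
    converged_ : bool
    n_iter_ : int
        EM iterations used by the winning start.
    posterior_ : ndarray of shape (n_examinees, n_classes)
        Posterior class memberships of the training data.
    """

    def __init__(self, family="hdcm", q_matrix=None, hierarchy=None,
                 n_starts=3, tol=1e-7, max_iter=2000, monotone=False,
                 random_state=None):
        self.family = family
        self.q_matrix = q_matrix
        self.hierarchy = hierarchy
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.monotone = monotone
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def _build_spec(self) -> ModelSpec:
        if self.q_matrix is None:
            raise ValueError("q_matrix must be provided")
        q = np.asarray(self.q_matrix)
        h = _resolve_hierarchy(self.hierarchy, q.shape[1])
        return build_model(self.family, q, h)

    def fit(self, X, y=None):
        spec = self._build_spec()
        X = _validate_X(X, spec.n_items)
        n = X.shape[0]
        k = count_free_parameters(spec)
        if n < 10 * k:
            warnings.warn(
                f"only {n} examinees for k={k} free parameters; "
                "estimates may be unstable", stacklevel=2)
        rng = np.random.default_rng(
            self.random_state if not isinstance(
                self.random_state, np.random.Generator) else None)
        if isinstance(self.random_state, np.random.Generator):
            rng = self.random_state

        C = spec.n_classes
        best = None
        for s in range(max(1, int(self.n_starts))):
            beta0 = []
            for it in spec.items:
                b = np.concatenate([[-1.0], np.ones(len(it.terms))])
                if s > 0:
                    b = b + rng.normal(0.0, 0.5, size=b.shape)
                beta0.append(b)
            nu0 = (np.full(C, 1.0 / C) if s == 0
                   else rng.dirichlet(np.full(C, 2.0)))
            result = _em(spec, X, beta0, nu0, self.tol, self.max_iter,
                         monotone=self.monotone)
            if best is None or result[2] > best[2]:
                best = result
        betas, nu, ll, n_iter, converged, post = best
        if not converged:
            warnings.warn("EM did not converge within max_iter",
                          stacklevel=2)
        self.spec_ = spec
        self.params_ = ParameterSet(spec, betas, nu)
        self.log_likelihood_ = ll
        self.n_parameters_ = k
        self.aic_, self.bic_ = information_criteria(ll, k, n)
        self.converged_ = bool(converged)
        self.n_iter_ = n_iter
        self.posterior_ = post
        self.n_examinees_ = n
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class-membership probabilities, shape (n, C)."""
        X = _validate_X(X, self.spec_.n_items)
        P = class_probabilities(self.spec_, self.params_)
        lc = _class_loglik(X, P) + np.log(self.params_.class_probs)
        return np.exp(lc - logsumexp(lc, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        """Posterior-mode mastery pattern per examinee, shape (n, K)."""
        post = self.predict_proba(X)
        return self.spec_.patterns[post.argmax(axis=1)]

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per examinee."""
        X = _validate_X(X, self.spec_.n_items)
        return log_likelihood(self.spec_, self.params_, X) / X.shape[0]


def fit(family, q_matrix, X, hierarchy=None, **opts
        ) -> DiagnosticClassificationModel:
    """Functional wrapper: build and fit a model in one call."""
    return DiagnosticClassificationModel(
        family=family, q_matrix=q_matrix, hierarchy=hierarchy, **opts
    ).fit(X)
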