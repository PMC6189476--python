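"""Synthetic attribute profiles and item responses.

The generating design mirrors the standard simulation setup for
hierarchical diagnostic models: attribute profiles come from thresholding
a multivariate normal at 0 (exchangeable correlation), are projected onto
the hierarchy's permissible set, and responses are Bernoulli draws from
the class-conditional logistic model with main effects fixed at 2,
interaction effects at 1, and each intercept at -0.5 times the sum of the
item's effects (so full masters and full non-masters sit symmetrically at
p and 1 - p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import (ModelSpec, ParameterSet, class_probabilities)
from .hierarchy import AttributeHierarchy

__all__ = [
    "GenConfig",
    "draw_attribute_profiles",
    "build_true_parameters",
    "simulate_responses",
    "pattern_indices",
    "MAIN_EFFECT_VALUE",
    "INTERACTION_EFFECT_VALUE",
]

MAIN_EFFECT_VALUE = 2.0
INTERACTION_EFFECT_VALUE = 1.0


@dataclass
class GenConfig:
    """Generating conditions for one simulated dataset.

    ``mean`` / ``correlation`` may be fixed numbers (arrays / scalar) or
    ``None``, in which case they are drawn per dataset: means uniform on
    (-0.5, 0.5) per attribute, a single exchangeable correlation uniform
    on (0.5, 0.8).
    """

    n_examinees: int
    mean: object = None
    correlation: object = None
    mean_range: tuple = (-0.5, 0.5)
    correlation_range: tuple = (0.5, 0.8)

    def draw_mvn_params(self, K: int, rng: np.random.Generator):
        mu = (rng.uniform(*self.mean_range, size=K)
              if self.mean is None else np.broadcast_to(
                  np.asarray(self.mean, dtype=float), (K,)).copy())
        rho = (rng.uniform(*self.correlation_range)
               if self.correlation is None else float(self.correlation))
        return mu, rho


def _exchangeable_corr(K: int, rho: float) -> np.ndarray:
    if not -1.0 / max(K - 1, 1) < rho < 1.0:
        raise ValueError(
            f"exchangeable correlation {rho} is not positive definite "
            f"for K={K}")
    sigma = np.full((K, K), rho)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def draw_attribute_profiles(hierarchy: AttributeHierarchy, n: int,
                            mean, correlation: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw n permissible mastery patterns.

    A latent normal vector Z ~ N(mean, R) with exchangeable correlation R
    is thresholded at 0 (attribute mastered iff Z_k > 0).  Draws whose
    raw pattern violates the hierarchy are rejected and redrawn, so the
    profiles follow the threshold distribution truncated to the
    permissible set.
    """
    K = hierarchy.n_attributes
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (K,))
    sigma = _exchangeable_corr(K, correlation)
    prereq = hierarchy.prerequisites()
    req_idx = [(k - 1, np.array([a - 1 for a in prereq[k]], dtype=int))
               for k in range(1, K + 1) if prereq[k]]

    def permissible_mask(raw):
        ok = np.ones(raw.shape[0], dtype=bool)
        for k0, pre in req_idx:
            ok &= (raw[:, k0] == 0) | raw[:, pre].all(axis=1)
        return ok

    out = np.empty((n, K), dtype=int)
    filled = 0
    for _ in range(1000):
        need = n - filled
        if need == 0:
            break
        # oversample to amortize the rejection rate
        m = max(int(need * 1.6) + 16, need)
        z = rng.multivariate_normal(mean, sigma, size=m, method="cholesky")
        raw = (z > 0).astype(int)
        good = raw[permissible_mask(raw)][:need]
        out[filled:filled + good.shape[0]] = good
        filled += good.shape[0]
    if filled < n:
        raise RuntimeError("rejection sampling failed to produce enough "
                           "permissible profiles; check the hierarchy")
    return out


def build_true_parameters(spec: ModelSpec, class_probs=None) -> ParameterSet:
    """Generating item parameters under the fixed-value rule.

    Main effects (single-attribute terms) are 2, interaction terms 1, and
    the intercept is -0.5 times the sum of the item's effect values.
    Defined for the logistic families with per-term effects (HDCM/LCDM;
    C-RUM also works since it only has main effects).
    """
    if spec.family == "dina":
        raise ValueError("the fixed-value generating rule applies to "
                         "effect-parameterized families, not DINA")
    item_params = []
    for it in spec.items:
        effects = np.where([t.is_main for t in it.terms],
                           MAIN_EFFECT_VALUE, INTERACTION_EFFECT_VALUE)
        intercept = -0.5 * effects.sum()
        item_params.append(np.concatenate([[intercept], effects]))
    return ParameterSet(spec, item_params, class_probs)


def pattern_indices(spec: ModelSpec, profiles: np.ndarray) -> np.ndarray:
    """Map each profile row to its class index in ``spec.patterns``."""
    key = {tuple(p): i for i, p in enumerate(spec.patterns)}
    try:
        return np.array([key[tuple(row)] for row in np.asarray(profiles)])
    except KeyError as exc:
        raise ValueError(f"profile {exc.args[0]} is not permissible "
                         "under the model's hierarchy") from None


def simulate_responses(spec: ModelSpec, params: ParameterSet,
                       profiles: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Bernoulli item responses for the given mastery profiles.

    Returns the (n, J) 0/1 response matrix; responses are locally
    independent given the profile.
    """
    idx = pattern_indices(spec, profiles)
    P = class_probabilities(spec, params)[idx]  # (n, J)
    return (rng.random(P.shape) < P).astype(int)


def generate_dataset(spec: ModelSpec, cfg: GenConfig,
                     rng: np.random.Generator):
    """One simulated dataset: draws MVN parameters, profiles, responses.

    Returns ``(X, profiles)``.
    """
    mu, rho = cfg.draw_mvn_params(spec.n_attributes, rng)
    profiles = draw_attribute_profiles(spec.hierarchy, cfg.n_examinees,
                                       mu, rho, rng)
    params = build_true_parameters(spec)
    X = simulate_responses(spec, params, profiles, rng)
    return X, profiles
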