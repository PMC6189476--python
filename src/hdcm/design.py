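"""Item effect structures and response functions for four DCM families.

All four models are logistic latent-class models: given a latent mastery
pattern ``alpha``, the probability of a correct response to item j is

    P(X_j = 1 | alpha) = logistic(lambda_j0 + sum_t lambda_jt * d_t(alpha))

where the indicator ``d_t(alpha)`` is 1 when the class masters every
attribute of effect term t.  The families differ only in which effect
terms an item carries:

* LCDM  — all main effects and all interactions among the item's required
  attributes (2**m - 1 terms for an m-attribute item);
* HDCM  — the LCDM constrained by an attribute hierarchy: one parameter
  per *distinct* reduced mastery pattern on the item's required
  attributes.  Terms are generated constructively as the supports of the
  non-null distinct reduced patterns, so nested prerequisites collapse
  redundant interactions (a linear chain leaves a single main effect plus
  nested interactions);
* DINA  — intercept (guessing logit) plus a single conjunction term over
  all required attributes: g = logistic(b0), 1 - s = logistic(b0 + b1);
* C-RUM — intercept plus one main effect per required attribute, no
  interactions.

The structural side is a saturated categorical distribution over the
permissible patterns (C - 1 free parameters, softmax with a reference
class), so the total free-parameter count is
``k = sum_j (1 + n_terms_j) + (C - 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .hierarchy import AttributeHierarchy, enumerate_permissible_patterns
from .qmatrix import validate_qmatrix

__all__ = [
    "EffectTerm",
    "ItemDesign",
    "ModelSpec",
    "ParameterSet",
    "build_model",
    "count_free_parameters",
    "degrees_of_freedom",
    "response_probability",
    "class_probabilities",
    "check_monotonicity",
    "FAMILIES",
]

FAMILIES = ("hdcm", "lcdm", "dina", "crum")

#: Bound on the linear predictor before exponentiation.  Boundary items
#: (estimates of magnitude ~20 occur in real grammar-test fits) would
#: otherwise overflow the logistic.
PREDICTOR_BOUND = 35.0


def _logistic(eta):
    eta = np.clip(eta, -PREDICTOR_BOUND, PREDICTOR_BOUND)
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class EffectTerm:
    """One item effect: active for classes mastering all of ``attrs``.

    ``attrs`` holds 1-based attribute indices; a singleton is a main
    effect, anything larger an interaction (possibly hierarchy-nested).
    """

    attrs: tuple

    def __post_init__(self):
        object.__setattr__(self, "attrs", tuple(sorted(self.attrs)))
        if len(self.attrs) == 0:
            raise ValueError("effect term needs at least one attribute")

    @property
    def order(self) -> int:
        return len(self.attrs)

    @property
    def is_main(self) -> bool:
        return len(self.attrs) == 1

    def label(self) -> str:
        return "l1(%s)" % self.attrs if self.is_main else (
            "l%d(%s)" % (len(self.attrs), ",".join(map(str, self.attrs))))


@dataclass(frozen=True)
class ItemDesign:
    """Effect structure of one item.

    ``design`` is the C x (1 + T) 0/1 matrix mapping each latent class to
    the intercept (first column, always 1) and the term indicators.
    """

    item: int
    terms: tuple
    design: np.ndarray

    @property
    def n_params(self) -> int:
        return 1 + len(self.terms)


class ModelSpec:
    """Fully built model: item designs plus the structural class space.

    Attributes
    ----------
    family : str
        One of ``FAMILIES``.
    q : (J, K) ndarray
        Validated Q-matrix.
    hierarchy : AttributeHierarchy
        Structural hierarchy (empty edge set for no hierarchy).
    patterns : (C, K) ndarray
        Permissible mastery patterns, lexicographic order.
    items : list of ItemDesign
    """

    def __init__(self, family, q, hierarchy, patterns, items):
        self.family = family
        self.q = q
        self.hierarchy = hierarchy
        self.patterns = patterns
        self.items = items

    @property
    def n_items(self) -> int:
        return self.q.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.q.shape[1]

    @property
    def n_classes(self) -> int:
        return self.patterns.shape[0]

    @property
    def item_param_counts(self) -> list:
        return [it.n_params for it in self.items]

    def n_free_parameters(self) -> int:
        return sum(self.item_param_counts) + (self.n_classes - 1)

    def to_json(self) -> str:
        return json.dumps({
            "family": self.family,
            "q": self.q.tolist(),
            "hierarchy": {
                "n_attributes": self.hierarchy.n_attributes,
                "edges": sorted(map(list, self.hierarchy.edges)),
            },
            "terms": [[list(t.attrs) for t in it.terms] for it in self.items],
        })

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        obj = json.loads(text)
        h = AttributeHierarchy(obj["hierarchy"]["n_attributes"],
                               [tuple(e) for e in obj["hierarchy"]["edges"]])
        spec = build_model(obj["family"], np.array(obj["q"]), h)
        # terms are reconstructed; sanity-check against the stored ones
        stored = [[tuple(t) for t in it] for it in obj["terms"]]
        built = [[t.attrs for t in it.terms] for it in spec.items]
        if stored != built:
            raise ValueError("stored effect terms do not match rebuild")
        return spec


def _distinct_reduced_patterns(patterns: np.ndarray, q_row: np.ndarray):
    """Unique projections of the permissible patterns onto an item's
    required attributes, as a list of attribute-index frozensets."""
    req = np.flatnonzero(q_row == 1)
    seen = {}
    for p in patterns:
        support = frozenset((req[p[req] == 1] + 1).tolist())
        seen.setdefault(support, None)
    return sorted(seen, key=lambda s: (len(s), sorted(s)))


def build_model(family: str, q, hierarchy: AttributeHierarchy | None = None,
                ) -> ModelSpec:
    """Construct the item designs and structural space for one family.

    ``hierarchy=None`` means no hierarchy (all 2**K patterns).  For HDCM
    the hierarchy shapes both the item effect structure and the latent
    space; for DINA and C-RUM it restricts only the latent space; LCDM
    ignores it entirely (its structural space is the full 2**K set).
    """
    family = family.lower().replace("-", "")
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    q = validate_qmatrix(q)
    J, K = q.shape
    if hierarchy is None or family == "lcdm":
        hierarchy = AttributeHierarchy(K, [])
    if hierarchy.n_attributes != K:
        raise ValueError("hierarchy attribute count does not match Q-matrix")
    patterns = enumerate_permissible_patterns(hierarchy)
    mastered = [frozenset((np.flatnonzero(p) + 1).tolist()) for p in patterns]

    items = []
    for j in range(J):
        req = frozenset((np.flatnonzero(q[j] == 1) + 1).tolist())
        if family in ("hdcm", "lcdm"):
            distinct = _distinct_reduced_patterns(patterns, q[j])
            terms = tuple(EffectTerm(s) for s in distinct if s)
            if not terms:
                raise ValueError(
                    f"item {j + 1} admits a single reduced pattern under "
                    "the hierarchy and is unidentified"
                )
        elif family == "dina":
            terms = (EffectTerm(req),)
        else:  # crum
            terms = tuple(EffectTerm((k,)) for k in sorted(req))
        design = np.ones((patterns.shape[0], 1 + len(terms)), dtype=int)
        for t_idx, term in enumerate(terms):
            active = [set(term.attrs) <= m for m in mastered]
            design[:, 1 + t_idx] = np.asarray(active, dtype=int)
        items.append(ItemDesign(item=j + 1, terms=terms, design=design))
    return ModelSpec(family, q, hierarchy, patterns, items)


def count_free_parameters(spec: ModelSpec) -> int:
    """Total free parameters k: item intercepts and effects plus C - 1
    structural class proportions."""
    return spec.n_free_parameters()


def degrees_of_freedom(spec: ModelSpec) -> int:
    """Degrees of freedom of the bivariate-margin fit statistic:
    df = d - k with d = J + J(J-1)/2 first- and second-order margins."""
    J = spec.n_items
    d = J + J * (J - 1) // 2
    df = d - spec.n_free_parameters()
    if df <= 0:
        raise ValueError(
            f"model has k={spec.n_free_parameters()} free parameters but "
            f"only d={d} margins; the margin-based fit test is undefined"
        )
    return df


# ---------------------------------------------------------------------------
# parameters and response probabilities
# ---------------------------------------------------------------------------

class ParameterSet:
    """Item coefficients plus structural class proportions for a ModelSpec.

    ``item_params[j]`` is the vector (intercept, effect values...) matching
    ``spec.items[j]``; ``class_probs`` is the length-C probability vector
    over permissible patterns.
    """

    def __init__(self, spec: ModelSpec, item_params, class_probs=None):
        self.spec = spec
        self.item_params = [np.asarray(b, dtype=float) for b in item_params]
        for j, b in enumerate(self.item_params):
            if b.shape != (spec.items[j].n_params,):
                raise ValueError(f"item {j + 1}: expected "
                                 f"{spec.items[j].n_params} coefficients")
        if class_probs is None:
            class_probs = np.full(spec.n_classes, 1.0 / spec.n_classes)
        class_probs = np.asarray(class_probs, dtype=float)
        if class_probs.shape != (spec.n_classes,) or (class_probs <= 0).any():
            raise ValueError("class_probs must be positive over all classes")
        self.class_probs = class_probs / class_probs.sum()

    def flat(self) -> np.ndarray:
        """Item parameters concatenated in item order (no structural part)."""
        return np.concatenate(self.item_params)

    def to_json(self) -> str:
        return json.dumps({
            "family": self.spec.family,
            "items": [
                {"item": it.item,
                 "intercept": b[0],
                 "effects": {t.label(): v
                             for t, v in zip(it.terms, b[1:].tolist())}}
                for it, b in zip(self.spec.items, self.item_params)
            ],
            "class_probs": self.class_probs.tolist(),
            "patterns": self.spec.patterns.tolist(),
        }, indent=1)


def class_probabilities(spec: ModelSpec, params: ParameterSet) -> np.ndarray:
    """The (C, J) table of class-conditional success probabilities."""
    C, J = spec.n_classes, spec.n_items
    P = np.empty((C, J))
    for j, (it, b) in enumerate(zip(spec.items, params.item_params)):
        P[:, j] = _logistic(it.design @ b)
    return P


def response_probability(spec: ModelSpec, params: ParameterSet,
                         class_index: int, item: int) -> float:
    """P(correct | latent class) for one class/item pair (0-based indices)."""
    it = spec.items[item]
    eta = it.design[class_index] @ params.item_params[item]
    return float(_logistic(eta))


def check_monotonicity(spec: ModelSpec, params: ParameterSet):
    """Verify success probabilities are non-decreasing in mastery.

    Checks every item over all pairs of permissible patterns ordered
    componentwise.  Returns ``(ok, violations)`` with violations listed as
    ``(item, class_low, class_high)`` index triples.
    """
    P = class_probabilities(spec, params)
    pat = spec.patterns
    C = pat.shape[0]
    violations = []
    for a in range(C):
        for b in range(C):
            if a == b or not (pat[a] <= pat[b]).all():
                continue
            bad = np.flatnonzero(P[a] > P[b] + 1e-12)
            violations.extend((int(j), a, b) for j in bad)
    return (len(violations) == 0, violations)
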