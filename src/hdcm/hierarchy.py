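"""Attribute hierarchies and permissible mastery-pattern enumeration.

A diagnostic assessment measures K binary skills ("attributes").  A
hierarchy is a directed acyclic graph of prerequisite relations: an edge
``a -> b`` states that attribute ``a`` must be mastered before ``b`` can
be.  A mastery pattern (a length-K 0/1 vector) is *permissible* when every
mastered attribute has all of its direct and indirect prerequisites
mastered as well.  A linear chain over K attributes reduces the latent
space from 2**K patterns to K + 1; an empty edge set leaves all 2**K.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttributeHierarchy",
    "enumerate_permissible_patterns",
    "restrict_pattern",
    "hierarchy_preset",
    "PRESET_EDGES",
]

#: Named five-attribute prerequisite structures commonly used in simulation
#: work, plus the three-attribute chain (lexical -> cohesive ->
#: morphosyntactic) of the ECPE grammar test.  Edges are 1-indexed
#: (prerequisite, dependent) pairs.
PRESET_EDGES: dict[str, tuple[int, list[tuple[int, int]]]] = {
    "linear": (5, [(1, 2), (2, 3), (3, 4), (4, 5)]),
    "convergent": (5, [(1, 2), (2, 3), (2, 4), (3, 5), (4, 5)]),
    "divergent": (5, [(1, 2), (2, 3), (1, 4), (4, 5)]),
    "unstructured": (5, [(1, 2), (1, 3), (1, 4), (1, 5)]),
    # ECPE columns: V1 = morphosyntactic, V2 = cohesive, V3 = lexical.
    "ecpe-linear": (3, [(3, 2), (2, 1)]),
    "none": (0, []),
}


class CycleError(ValueError):
    """Raised when a prerequisite graph contains a directed cycle."""


@dataclass(frozen=True)
class AttributeHierarchy:
    """Prerequisite DAG over ``n_attributes`` binary attributes.

    Parameters
    ----------
    n_attributes : int
        Number of attributes K (positive).
    edges : sequence of (int, int)
        Ordered pairs ``(a, b)`` with 1-based attribute indices meaning
        "a is a prerequisite of b".  An empty set means no hierarchy.
    """

    n_attributes: int
    edges: frozenset

    def __init__(self, n_attributes, edges=()):
        if n_attributes < 1:
            raise ValueError("n_attributes must be a positive integer")
        edges = frozenset((int(a), int(b)) for a, b in edges)
        for a, b in edges:
            if not (1 <= a <= n_attributes and 1 <= b <= n_attributes):
                raise ValueError(
                    f"edge ({a}, {b}) outside attribute range 1..{n_attributes}"
                )
            if a == b:
                raise CycleError(f"self-loop on attribute {a}")
        object.__setattr__(self, "n_attributes", int(n_attributes))
        object.__setattr__(self, "edges", edges)
        self._check_acyclic()

    # -- graph machinery -------------------------------------------------
    def _children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {k: [] for k in range(1, self.n_attributes + 1)}
        for a, b in self.edges:
            ch[a].append(b)
        return ch

    def _check_acyclic(self) -> None:
        ch = self._children()
        color = {k: 0 for k in ch}  # 0 new, 1 on stack, 2 done
        stack_path: list[int] = []

        def visit(u: int) -> None:
            color[u] = 1
            stack_path.append(u)
            for v in ch[u]:
                if color[v] == 1:
                    cyc = stack_path[stack_path.index(v):] + [v]
                    raise CycleError(
                        "prerequisite graph has a cycle: "
                        + " -> ".join(map(str, cyc))
                    )
                if color[v] == 0:
                    visit(v)
            stack_path.pop()
            color[u] = 2

        for k in ch:
            if color[k] == 0:
                visit(k)

    def prerequisites(self) -> dict[int, frozenset]:
        """Transitive prerequisite sets, per attribute (1-based keys).

        Indirect prerequisites are included: with 1->2 and 2->3, attribute
        3 requires both 1 and 2.
        """
        parents: dict[int, set] = {k: set() for k in range(1, self.n_attributes + 1)}
        for a, b in self.edges:
            parents[b].add(a)
        # Floyd–Warshall-style closure; K is small in practice.
        changed = True
        while changed:
            changed = False
            for b in parents:
                before = len(parents[b])
                for a in list(parents[b]):
                    parents[b] |= parents[a]
                if len(parents[b]) != before:
                    changed = True
        return {k: frozenset(v) for k, v in parents.items()}

    def is_permissible(self, bits) -> bool:
        """True when every mastered attribute has all prerequisites mastered."""
        bits = np.asarray(bits, dtype=int)
        if bits.shape != (self.n_attributes,):
            raise ValueError("pattern length does not match n_attributes")
        prereq = self.prerequisites()
        for k in range(1, self.n_attributes + 1):
            if bits[k - 1] and any(not bits[a - 1] for a in prereq[k]):
                return False
        return True

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {"n_attributes": self.n_attributes,
             "edges": sorted(map(list, self.edges))}
        )

    @classmethod
    def from_json(cls, text: str) -> "AttributeHierarchy":
        obj = json.loads(text)
        if isinstance(obj, list):  # bare edge list; infer K
            edges = [tuple(e) for e in obj]
            K = max((max(e) for e in edges), default=1)
            return cls(K, edges)
        return cls(obj["n_attributes"], [tuple(e) for e in obj["edges"]])


def hierarchy_preset(name: str, n_attributes: int | None = None) -> AttributeHierarchy:
    """Return one of the named prerequisite structures.

    ``"none"`` gives the empty hierarchy; pass ``n_attributes`` to size it
    (defaults to 5 for the five-attribute presets).
    """
    if name not in PRESET_EDGES:
        raise KeyError(f"unknown hierarchy preset {name!r}; "
                       f"choose from {sorted(PRESET_EDGES)}")
    K, edges = PRESET_EDGES[name]
    if name == "none":
        if n_attributes is None:
            raise ValueError("preset 'none' requires n_attributes")
        return AttributeHierarchy(n_attributes, [])
    if n_attributes is not None and n_attributes != K:
        raise ValueError(f"preset {name!r} is defined for K={K}")
    return AttributeHierarchy(K, edges)


def enumerate_permissible_patterns(hierarchy: AttributeHierarchy) -> np.ndarray:
    """All mastery patterns consistent with the hierarchy.

    Returns a ``(C, K)`` 0/1 array in lexicographic order with attribute 1
    most significant.  For a linear chain this has K + 1 rows; for an
    empty edge set, 2**K.
    """
    K = hierarchy.n_attributes
    prereq = hierarchy.prerequisites()
    out = []
    for bits in itertools.product((0, 1), repeat=K):
        ok = all(
            not bits[k - 1] or all(bits[a - 1] for a in prereq[k])
            for k in range(1, K + 1)
        )
        if ok:
            out.append(bits)
    return np.array(out, dtype=int)


def restrict_pattern(pattern, q_row) -> np.ndarray:
    """Project a mastery pattern onto the attributes an item requires.

    ``q_row`` is the item's 0/1 Q-matrix row; the result is the sub-vector
    of ``pattern`` at the required positions.
    """
    pattern = np.asarray(pattern, dtype=int)
    q_row = np.asarray(q_row, dtype=int)
    if pattern.shape != q_row.shape:
        raise ValueError("pattern and Q-matrix row have different lengths")
    return pattern[q_row == 1]
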