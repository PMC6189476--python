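"""Q-matrix handling: I/O, validation, fixtures, and misspecification.

The Q-matrix is the J x K 0/1 incidence matrix saying which of the K
attributes each of the J items measures.  Two Q-matrices ship with the
package: a 20-item, 5-attribute simulation matrix and the 28-item,
3-attribute matrix of the ECPE English grammar test.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "validate_qmatrix",
    "load_qmatrix",
    "save_qmatrix",
    "sim_qmatrix",
    "ecpe_qmatrix",
    "misspecify_qmatrix",
]


def validate_qmatrix(q) -> np.ndarray:
    """Coerce to a 0/1 integer array and check every item row is nonempty."""
    q = np.asarray(q)
    if q.ndim != 2 or q.shape[0] < 1 or q.shape[1] < 1:
        raise ValueError("Q-matrix must be a 2-D items x attributes array")
    if not np.isin(q, (0, 1)).all():
        raise ValueError("Q-matrix entries must be 0 or 1")
    q = q.astype(int)
    empty = np.flatnonzero(q.sum(axis=1) == 0)
    if empty.size:
        raise ValueError(f"Q-matrix rows with no attributes: items {empty + 1}")
    return q


def load_qmatrix(path, sep: str | None = None) -> np.ndarray:
    """Read a headered CSV/TSV Q-matrix (one row per item, 0/1 cells).

    An ``item`` index column, if present, is dropped.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = [c for c in df.columns if c.lower() not in ("item", "items", "j")]
    return validate_qmatrix(df[cols].to_numpy())


def save_qmatrix(q, path) -> None:
    q = validate_qmatrix(q)
    df = pd.DataFrame(q, columns=[f"V{k + 1}" for k in range(q.shape[1])])
    df.insert(0, "item", np.arange(1, q.shape[0] + 1))
    df.to_csv(path, index=False)


def _load_fixture(name: str) -> np.ndarray:
    with resources.files("hdcm.data").joinpath(name).open("r") as fh:
        return load_qmatrix(fh)


def sim_qmatrix() -> np.ndarray:
    """The 20-item, 5-attribute simulation Q-matrix (each attribute measured
    by an equal number of items; items measure one, two or three attributes)."""
    return _load_fixture("qmatrix_sim_20x5.csv")


def ecpe_qmatrix() -> np.ndarray:
    """The ECPE 28-item, 3-attribute Q-matrix (V1 morphosyntactic,
    V2 cohesive, V3 lexical)."""
    return _load_fixture("qmatrix_ecpe_28x3.csv")


def misspecify_qmatrix(q, fraction: float, rng_seed) -> np.ndarray:
    """Randomly corrupt a Q-matrix under the random balance design.

    A budget of ``round(fraction * J * K)`` cells is altered.  Items are
    drawn uniformly without replacement; the alteration depends on how
    many attributes the item originally measures (K_j):

    * K_j = 1: one 0 flips to 1 (over-specification; 1 cell),
    * K_j = 2: one 1 flips to 0 (under-specification; 1 cell),
    * K_j = 3: one of each (2 cells).

    Every output row keeps at least one attribute, and the output differs
    from the input in exactly the budgeted number of cells.  Deterministic
    given ``rng_seed``.
    """
    q = validate_qmatrix(q)
    J, K = q.shape
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    budget = int(round(fraction * J * K))
    if budget == 0:
        return q.copy()

    rng = np.random.default_rng(rng_seed)
    kj = q.sum(axis=1)
    if (kj > 3).any():
        raise ValueError("random balance design is defined for items "
                         "measuring at most 3 attributes")
    cost = np.where(kj == 3, 2, 1)
    if budget > cost.sum():
        raise ValueError(
            f"cannot alter {budget} cells: the random balance design "
            f"admits at most {cost.sum()} for this Q-matrix"
        )
    # A random item order can strand a 1-cell remainder when only 2-cell
    # (three-attribute) items are left unvisited; redraw the order then.
    for _ in range(100):
        out = q.copy()
        order = rng.permutation(J)
        remaining = budget
        for j in order:
            if remaining <= 0:
                break
            if cost[j] > remaining:
                continue
            row = out[j]
            if kj[j] == 1:
                zero = rng.choice(np.flatnonzero(row == 0))
                row[zero] = 1
            elif kj[j] == 2:
                one = rng.choice(np.flatnonzero(row == 1))
                row[one] = 0
            else:  # kj == 3: over- and under-specify one cell each
                zero = rng.choice(np.flatnonzero(row == 0))
                one = rng.choice(np.flatnonzero(row == 1))
                row[zero] = 1
                row[one] = 0
            remaining -= cost[j]
        if remaining == 0:
            return out
    raise ValueError(
        f"cannot alter exactly {budget} cells with this Q-matrix's "
        "mix of item attribute counts"
    )
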