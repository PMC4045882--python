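"""Maximum-weight bipartite matching.

One service used three times in the pipeline: to pair compounds when
scoring substrate/product sets, to pair reaction paths (the matching
sigma), and to pair reactions from the match-frequency matrix (the
matching rho).  The assignment problem itself is solved with
``scipy.optimize.linear_sum_assignment``; this module adds label
handling, a deterministic lexicographic tie-break and pruning of
zero-weight pairs.

Because all weights are non-negative, a maximum-weight matching always
exists among the complete assignments of the smaller side, which is
exactly what the rectangular linear sum assignment computes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["WeightTable", "max_weight_matching"]


@dataclass(frozen=True)
class WeightTable:
    """A rectangular table of non-negative weights over two label sets."""

    left: tuple[Hashable, ...]
    right: tuple[Hashable, ...]
    weights: np.ndarray  # shape (len(left), len(right))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.left), len(self.right)):
            raise ValueError(
                f"weight shape {w.shape} does not match labels "
                f"({len(self.left)}, {len(self.right)})"
            )
        if len(set(self.left)) != len(self.left):
            raise ValueError("duplicate left labels")
        if len(set(self.right)) != len(self.right):
            raise ValueError("duplicate right labels")
        if w.size and not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if w.size and (w < 0).any():
            raise ValueError("negative weight in table")

    @classmethod
    def from_pairs(
        cls,
        pairs: dict[tuple[Hashable, Hashable], float],
        left: Sequence[Hashable],
        right: Sequence[Hashable],
        default: float = 0.0,
    ) -> "WeightTable":
        w = np.full((len(left), len(right)), default, dtype=float)
        li = {l: i for i, l in enumerate(left)}
        ri = {r: j for j, r in enumerate(right)}
        for (l, r), v in pairs.items():
            w[li[l], ri[r]] = v
        return cls(tuple(left), tuple(right), w)

    def transpose(self) -> "WeightTable":
        return WeightTable(self.right, self.left, self.weights.T)


def _sorted_order(labels: Sequence[Hashable]) -> list[int]:
    try:
        return sorted(range(len(labels)), key=lambda i: labels[i])
    except TypeError:  # mixed unorderable labels: fall back to string order
        return sorted(range(len(labels)), key=lambda i: str(labels[i]))


def max_weight_matching(table: WeightTable) -> list[tuple[Hashable, Hashable]]:
    """Return a maximum-weight matching as sorted (left, right) pairs.

    Pairs whose weight is exactly zero are pruned from the result: a
    zero-similarity pairing carries no signal and would pollute the
    downstream reaction matching.  When several matchings attain the
    optimum, the one that is lexicographically smallest in sorted
    (left label, right label) order is preferred; ties are resolved by
    adding a geometrically decaying epsilon bonus (relative size 1e-9)
    to the weights, so weight differences below that are treated as
    ties.
    """
    w = table.weights
    if w.size == 0:
        return []
    lorder = _sorted_order(table.left)
    rorder = _sorted_order(table.right)
    ws = w[np.ix_(lorder, rorder)]
    n, m = ws.shape
    # geometric bonus: prefer the lexicographically smallest optimal pair set
    rank = np.arange(n * m, dtype=float).reshape(n, m)
    with np.errstate(under="ignore"):
        bonus = np.power(2.0, -np.minimum(rank, 1070.0))
    eps = 1e-9 * max(float(ws.max()), 1.0)
    rows, cols = linear_sum_assignment(ws + eps * bonus, maximize=True)
    pairs = [
        (table.left[lorder[i]], table.right[rorder[j]])
        for i, j in zip(rows, cols)
        if ws[i, j] > 0.0
    ]
    try:
        return sorted(pairs)
    except TypeError:
        return sorted(pairs, key=lambda p: (str(p[0]), str(p[1])))
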