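"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
enumeration) rather than calling the library's own algorithms.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_matching_weight(weights: np.ndarray) -> float:
    """Maximum matching weight by exhaustive enumeration of all
    assignments of the smaller side (weights are non-negative, so some
    complete assignment of the smaller side is optimal)."""
    w = np.asarray(weights, dtype=float)
    n, m = w.shape
    if n == 0 or m == 0:
        return 0.0
    if n > m:
        return brute_force_matching_weight(w.T)
    best = 0.0
    for cols in itertools.permutations(range(m), n):
        best = max(best, sum(w[i, c] for i, c in enumerate(cols)))
    return best


def brute_force_set_similarity(X, Y, provider) -> float:
    """Compound-set similarity by enumerating every possible matching."""
    xs, ys = sorted(set(X)), sorted(set(Y))
    if not xs and not ys:
        return 1.0
    if not xs or not ys:
        return 0.0
    w = np.array([[provider.score(x, y) for y in ys] for x in xs])
    return brute_force_matching_weight(w) / max(len(xs), len(ys))


def exhaustive_maximal_paths(H) -> set[tuple[str, ...]]:
    """All maximal simple reaction paths, from the definition.

    Breadth-first expansion of every path prefix starting at reactions
    that consume a source compound; a path is maximal when no unused
    connected reaction extends it.
    """
    reactions = list(H.reactions.values())
    inputs_of = {r.id: r.inputs for r in reactions}
    outputs_of = {r.id: r.outputs for r in reactions}
    seen_in = set().union(*(r.inputs for r in reactions)) if reactions else set()
    seen_out = set().union(*(r.outputs for r in reactions)) if reactions else set()
    source_compounds = seen_in - seen_out
    starts = [r.id for r in reactions if r.inputs & source_compounds]

    def extensions(path):
        return [
            r.id
            for r in reactions
            if r.id not in path and outputs_of[path[-1]] & inputs_of[r.id]
        ]

    maximal: set[tuple[str, ...]] = set()
    frontier = [(s,) for s in starts]
    while frontier:
        path = frontier.pop()
        exts = extensions(path)
        if not exts:
            maximal.add(path)
        else:
            frontier.extend(path + (e,) for e in exts)
    return maximal
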