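"""Enzyme, compound-set and reaction similarity.

The reaction similarity combines three terms with fixed weights:

    SimReact(Ri, Rj) = SimEnz(Ei, Ej) * w_e
                     + SimComp(Ii, Ij) * w_i
                     + SimComp(Oi, Oj) * w_o

with defaults w_e = 0.4 and w_i = w_o = 0.3, balancing enzymatic
function against substrate/product chemistry.

* SimEnz is the hierarchical EC similarity: the length of the longest
  common prefix of the two 4-level EC numbers, divided by 4 (so the
  arginase/creatinase pair 3.5.3.1 vs 3.5.3.3 scores 0.75).  Reactions
  carrying several EC annotations take the best pair.
* SimComp pairs up the two compound sets by maximum-weight bipartite
  matching over externally supplied compound-compound scores (e.g.
  precomputed SIMCOMP chemical-structure similarities) and divides the
  matched weight by max{|X|, |Y|}.

Chemical compound similarity itself is *not* computed here; it enters
through a :class:`CompoundSimilarityProvider` (a symmetric score cache,
by default identity: 1 for identical ids, 0 otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .matching import WeightTable, max_weight_matching
from .pathway_model import ECNumber, Reaction

__all__ = [
    "ScoreWeights",
    "DEFAULT_WEIGHTS",
    "CompoundSimilarityProvider",
    "ec_similarity",
    "enzyme_similarity",
    "compound_set_similarity",
    "reaction_similarity",
]


@dataclass(frozen=True)
class ScoreWeights:
    """Weights (w_e, w_i, w_o) of the three reaction-similarity terms.

    Used exactly as given, without renormalization; the defaults sum
    to 1 so SimReact stays in [0, 1].
    """

    w_e: float = 0.4
    w_i: float = 0.3
    w_o: float = 0.3

    def __post_init__(self) -> None:
        if min(self.w_e, self.w_i, self.w_o) < 0:
            raise ValueError("similarity weights must be non-negative")


DEFAULT_WEIGHTS = ScoreWeights()


class CompoundSimilarityProvider:
    """Symmetric compound-compound similarity scores in [0, 1].

    Identical ids score ``self_similarity`` (default 1) even when absent
    from the cache; pairs not present in the cache fall back to
    ``default_missing`` (default 0, the conservative choice).
    """

    def __init__(
        self,
        scores: Mapping[tuple[str, str], float] | None = None,
        default_missing: float = 0.0,
        self_similarity: float = 1.0,
    ) -> None:
        self.default_missing = float(default_missing)
        self.self_similarity = float(self_similarity)
        self._scores: dict[frozenset, float] = {}
        if scores:
            for (a, b), v in scores.items():
                self._set(a, b, float(v))

    def _set(self, a: str, b: str, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"similarity score({a},{b})={value} outside [0,1]")
        key = frozenset((a, b))
        old = self._scores.get(key)
        if old is not None and old != value:
            raise ValueError(f"conflicting scores for pair ({a},{b}): {old} vs {value}")
        self._scores[key] = value

    def score(self, a: str, b: str) -> float:
        if a == b:
            return self.self_similarity
        return self._scores.get(frozenset((a, b)), self.default_missing)

    @classmethod
    def identity(cls) -> "CompoundSimilarityProvider":
        return cls()

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str]) -> "CompoundSimilarityProvider":
        """Load a score cache from TSV with columns
        compound_id_1, compound_id_2, score (symmetric)."""
        df = pd.read_csv(source, sep="\t", dtype={0: str, 1: str})
        required = {"compound_id_1", "compound_id_2", "score"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"similarity cache needs columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        provider = cls()
        for row in df.itertuples(index=False):
            provider._set(str(row.compound_id_1), str(row.compound_id_2),
                          float(row.score))
        return provider

    def to_tsv(self, target: str | Path | IO[str]) -> None:
        rows = sorted((tuple(sorted(k)) if len(k) == 2 else (min(k), min(k)), v)
                      for k, v in self._scores.items())
        df = pd.DataFrame(
            [(a, b, v) for (a, b), v in rows],
            columns=["compound_id_1", "compound_id_2", "score"],
        )
        df.to_csv(target, sep="\t", index=False)

    @classmethod
    def random_symmetric(
        cls,
        compound_ids: Iterable[str],
        seed: int,
        low: float = 0.0,
        high: float = 1.0,
    ) -> "CompoundSimilarityProvider":
        """A seeded random symmetric score table over the given ids, for
        exercising the set-matching machinery in tests."""
        ids = sorted(set(compound_ids))
        rng = np.random.default_rng(seed)
        provider = cls()
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                provider._set(a, b, float(rng.uniform(low, high)))
        return provider


def ec_similarity(e: ECNumber | str, e2: ECNumber | str) -> float:
    """Hierarchical EC similarity: common-prefix length / 4.

    Wildcard components (``-`` or ``*``) never match, not even each
    other; a differing first level gives 0.
    """
    a = ECNumber.parse(e)
    b = ECNumber.parse(e2)
    prefix = 0
    for x, y in zip(a.levels, b.levels):
        if x == y and x.isdigit():
            prefix += 1
        else:
            break
    return prefix / 4.0


def enzyme_similarity(
    enzymes_a: Iterable[ECNumber | str], enzymes_b: Iterable[ECNumber | str]
) -> float:
    """Best EC similarity over all enzyme pairs; 0 if either side has
    no EC annotation."""
    ea = list(enzymes_a)
    eb = list(enzymes_b)
    if not ea or not eb:
        return 0.0
    return max(ec_similarity(x, y) for x in ea for y in eb)


def compound_set_similarity(
    X: Iterable[str],
    Y: Iterable[str],
    provider: CompoundSimilarityProvider,
) -> float:
    """Similarity of two compound sets via maximum-weight matching.

    The complete bipartite graph X x Y is weighted with provider scores,
    a maximum-weight matching is computed, and the matched weight is
    divided by max{|X|, |Y|}.  Two empty sets are vacuously identical
    (1); an empty set against a non-empty one scores 0.
    """
    xs = sorted(set(X))
    ys = sorted(set(Y))
    if not xs and not ys:
        return 1.0
    if not xs or not ys:
        return 0.0
    weights = np.array([[provider.score(x, y) for y in ys] for x in xs])
    pairs = max_weight_matching(WeightTable(tuple(xs), tuple(ys), weights))
    total = sum(provider.score(x, y) for x, y in pairs)
    return total / max(len(xs), len(ys))


def reaction_similarity(
    r1: Reaction,
    r2: Reaction,
    provider: CompoundSimilarityProvider,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
) -> float:
    """SimReact: weighted sum of enzyme, input-set and output-set
    similarity."""
    return (
        enzyme_similarity(r1.enzymes, r2.enzymes) * weights.w_e
        + compound_set_similarity(r1.inputs, r2.inputs, provider) * weights.w_i
        + compound_set_similarity(r1.outputs, r2.outputs, provider) * weights.w_o
    )
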