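"""Multi-pathway comparative analyses.

Given per-organism collections of pathways, this module averages the
pairwise pathway similarity scores over the common pathways of each
organism pair,

    AverageScore(O1, O2) = (1/k) * sum_i Score(H1_i, H2_i),

converts averages into distances d(O1, O2) = 2(1 - AverageScore), and
hands the resulting distance matrix to standard agglomerative
clustering (single / average / complete / Ward linkage) to reconstruct
organism dendrograms.  It also intersects conserved subpathways across
the members of a cluster to extract the cluster's common reaction
motif.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

import networkx as nx

from .alignment import AlignConfig, DEFAULT_CONFIG, align_pathways, score_to_distance
from .pathway_model import PathwayHypergraph
from .paths import reaction_adjacency
from .similarity import CompoundSimilarityProvider

__all__ = [
    "OrganismProfile",
    "DistanceMatrix",
    "NoCommonPathwayError",
    "average_score",
    "plan_alignment_tasks",
    "organism_distance_matrix",
    "cluster_common_motif",
    "hierarchical_linkage",
    "linkage_to_newick",
]

LINKAGE_METHODS = ("single", "average", "complete", "ward")


class NoCommonPathwayError(ValueError):
    """Raised when an organism pair shares no pathway and is therefore
    incomparable."""


@dataclass
class OrganismProfile:
    """One organism's pathway collection, keyed by pathway id."""

    organism_id: str
    pathways: dict[str, PathwayHypergraph] = field(default_factory=dict)

    def common_pathway_ids(self, other: "OrganismProfile") -> list[str]:
        return sorted(set(self.pathways) & set(other.pathways))


@dataclass
class DistanceMatrix:
    """A labeled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def to_tsv(self, target: str | FsPath | IO[str]) -> None:
        self.to_dataframe().to_csv(target, sep="\t", float_format="%.12g",
                                   index_label="")

    def to_phylip(self, target: str | FsPath | IO[str]) -> None:
        """PHYLIP-style square matrix for external tree tools."""
        lines = [f"{len(self.labels)}"]
        for label, row in zip(self.labels, self.values):
            lines.append(
                f"{label:<10}" + "  ".join(f"{x:.6f}" for x in row)
            )
        text = "\n".join(lines) + "\n"
        if hasattr(target, "write"):
            target.write(text)  # type: ignore[union-attr]
        else:
            FsPath(target).write_text(text)

    @classmethod
    def from_tsv(cls, source: str | FsPath | IO[str]) -> "DistanceMatrix":
        df = pd.read_csv(source, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def average_score(scores: Sequence[float]) -> float:
    """Arithmetic mean of per-pathway similarity scores; an empty list
    means the organism pair is incomparable."""
    if len(scores) == 0:
        raise NoCommonPathwayError("no common pathways: pair is incomparable")
    return float(sum(scores)) / len(scores)


def plan_alignment_tasks(
    organism_ids: Sequence[str],
    pathway_ids: Sequence[str],
) -> list[tuple[str, str, str]]:
    """The all-vs-all schedule of the matrix driver: one task per
    unordered organism pair (self-comparisons included) and common
    pathway.  For 8 organisms and 40 shared pathways this is
    36 * 40 = 1440 tasks."""
    return [
        (o1, o2, pid)
        for o1, o2 in itertools.combinations_with_replacement(sorted(organism_ids), 2)
        for pid in pathway_ids
    ]


def organism_distance_matrix(
    profiles: Sequence[OrganismProfile],
    provider: CompoundSimilarityProvider | None = None,
    config: AlignConfig = DEFAULT_CONFIG,
    on_missing: str = "raise",
) -> DistanceMatrix:
    """Pairwise organism distances from averaged pathway alignments.

    Every unordered organism pair is compared on its common pathways;
    the mean score is converted with the configured distance variant.
    A pair with no common pathway raises :class:`NoCommonPathwayError`
    naming the pair, or is recorded as NaN under ``on_missing="nan"``.
    The diagonal is zero by definition of the distance.
    """
    if on_missing not in ("raise", "nan"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    ids = [p.organism_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate organism ids")
    n = len(profiles)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = profiles[i], profiles[j]
        common = a.common_pathway_ids(b)
        if not common:
            if on_missing == "raise":
                raise NoCommonPathwayError(
                    f"organisms {a.organism_id} and {b.organism_id} share no pathway"
                )
            values[i, j] = values[j, i] = math.nan
            continue
        scores = [
            align_pathways(a.pathways[pid], b.pathways[pid], provider, config).score
            for pid in common
        ]
        d = score_to_distance(average_score(scores), config.distance_variant)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(ids), values)


def cluster_common_motif(
    pathways: Sequence[PathwayHypergraph],
    provider: CompoundSimilarityProvider | None = None,
    config: AlignConfig = DEFAULT_CONFIG,
    all_pairs: bool = False,
) -> set[str]:
    """The common conserved-reaction motif of one cluster of pathways.

    For a singleton cluster the motif is the reaction set of the
    largest connected component of the pathway's reaction-connectivity
    graph.  Otherwise consecutive pairs in the given order are aligned
    and the H1-side conserved reaction sets are intersected (reaction
    ids are assumed comparable across pathways, as KEGG ids are);
    ``all_pairs=True`` intersects over every unordered pair instead.
    """
    if not pathways:
        raise ValueError("cluster must contain at least one pathway")
    if len(pathways) == 1:
        G = reaction_adjacency(pathways[0])
        if G.number_of_nodes() == 0:
            return set()
        components = sorted(
            (sorted(c) for c in nx.weakly_connected_components(G)),
            key=lambda c: (-len(c), c),
        )
        return set(components[0])
    if all_pairs:
        pair_iter = itertools.combinations(range(len(pathways)), 2)
    else:
        pair_iter = ((i, i + 1) for i in range(len(pathways) - 1))
    motif: set[str] | None = None
    for i, j in pair_iter:
        result = align_pathways(pathways[i], pathways[j], provider, config)
        conserved_h1 = {r for r, _ in result.conserved}
        motif = conserved_h1 if motif is None else motif & conserved_h1
    assert motif is not None
    return motif


def hierarchical_linkage(dm: DistanceMatrix, method: str = "ward") -> np.ndarray:
    """Agglomerative clustering of a distance matrix (condensed form)."""
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}")
    if dm.has_missing():
        raise ValueError("distance matrix has missing entries")
    n = len(dm.labels)
    condensed = dm.values[np.triu_indices(n, k=1)]
    return linkage(condensed, method=method)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch
    lengths measured as merge-height differences."""
    root = to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"
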