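"""Reaction-path enumeration.

A *reaction path* linearizes the hypergraph topology: a sequence of
distinct reactions R1..Rk where R1 consumes at least one source
compound (an input-only node), each step's products overlap the next
step's substrates, and the sequence cannot be extended at its tail by
any unused connected reaction (maximality).  The set of all such paths
is the unit of comparison for the alignment stage.

Enumeration is a depth-first search from the source reactions.  The
number of maximal simple paths can blow up exponentially, so the search
carries configurable caps on path count and depth; hitting a cap is
reported via a truncation flag, never silently.

A documented consequence of starting only at source reactions: a
reaction unreachable from every source compound (e.g. one lying on an
isolated cycle) appears in no path and can therefore never be matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import IO, Iterable

import networkx as nx

from .pathway_model import PathwayHypergraph, classify_compounds

__all__ = [
    "ReactionPath",
    "PathSet",
    "source_reactions",
    "enumerate_reaction_paths",
    "reaction_adjacency",
    "write_paths_tsv",
]

DEFAULT_MAX_PATHS = 10_000
DEFAULT_MAX_DEPTH = 100


@dataclass(frozen=True, order=True)
class ReactionPath:
    """An ordered sequence of reaction ids forming one reaction path."""

    reactions: tuple[str, ...]
    pathway_id: str = ""

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValueError("a reaction path has at least one reaction")
        if len(set(self.reactions)) != len(self.reactions):
            raise ValueError(f"repeated reaction in path {self.reactions}")

    def __len__(self) -> int:
        return len(self.reactions)


@dataclass
class PathSet:
    """Enumeration result: the paths plus a truncation flag that is set
    when a cap stopped the search before exhausting all maximal paths."""

    paths: list[ReactionPath] = field(default_factory=list)
    truncated: bool = False


def reaction_adjacency(H: PathwayHypergraph) -> nx.DiGraph:
    """Directed reaction-connectivity graph: edge Ri -> Rj whenever some
    output compound of Ri is an input compound of Rj."""
    G = nx.DiGraph()
    G.add_nodes_from(H.reactions)
    items = sorted(H.reactions.values(), key=lambda r: r.id)
    for a in items:
        for b in items:
            if a.id != b.id and a.outputs & b.inputs:
                G.add_edge(a.id, b.id)
    return G


def source_reactions(H: PathwayHypergraph) -> frozenset[str]:
    """Reactions consuming at least one source compound.

    One source input suffices; a reaction may also consume internal
    compounds and still qualify.
    """
    sources, _, _ = classify_compounds(H)
    return frozenset(
        r.id for r in H.reactions.values() if r.inputs & sources
    )


def enumerate_reaction_paths(
    H: PathwayHypergraph,
    max_paths: int = DEFAULT_MAX_PATHS,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> PathSet:
    """Enumerate all maximal simple reaction paths from the sources.

    When neither cap is hit, the result is exactly the set of maximal
    paths; prefixes are discarded during DFS backtracking.  Paths cut
    short by ``max_depth`` are kept (marked via the set-level truncation
    flag); once ``max_paths`` paths are collected the search stops and
    the flag is raised.
    """
    if max_paths <= 0 or max_depth <= 0:
        raise ValueError("path and depth caps must be positive")
    G = reaction_adjacency(H)
    adjacency = {rid: sorted(G.successors(rid)) for rid in G.nodes}
    result = PathSet()

    def dfs(path: list[str], used: set[str]) -> None:
        if len(result.paths) >= max_paths:
            result.truncated = True
            return
        extensions = [s for s in adjacency[path[-1]] if s not in used]
        if extensions and len(path) >= max_depth:
            result.truncated = True
            extensions = []
        if not extensions:
            result.paths.append(ReactionPath(tuple(path), H.id))
            return
        for nxt in extensions:
            used.add(nxt)
            path.append(nxt)
            dfs(path, used)
            path.pop()
            used.remove(nxt)

    for start in sorted(source_reactions(H)):
        if len(result.paths) >= max_paths:
            result.truncated = True
            break
        dfs([start], {start})
    return result


def write_paths_tsv(paths: Iterable[ReactionPath], target: str | FsPath | IO[str]) -> None:
    """Debug export: one path per line, reactions tab-separated."""
    lines = "".join("\t".join(p.reactions) + "\n" for p in paths)
    if hasattr(target, "write"):
        target.write(lines)  # type: ignore[union-attr]
    else:
        FsPath(target).write_text(lines)
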