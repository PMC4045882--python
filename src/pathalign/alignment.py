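"""Pairwise pathway alignment.

Given two pathway hypergraphs H1 and H2, the alignment proceeds in five
steps:

1. enumerate the reaction-path sets RH1 and RH2 (:mod:`pathalign.paths`);
2. align every path pair with Smith-Waterman local alignment, using the
   reaction similarity SimReact as the substitution score; the optimal
   local score is normalized by the longer path length to give
   scorePath(p, p') in [0, 1];
3. compute the path matching sigma by maximum-weight bipartite matching
   on the scorePath table;
4. build the match-frequency matrix M (how often each H1 reaction is
   column-aligned to each H2 reaction across the sigma pairs) and derive
   the one-to-one reaction matching rho by maximum-weight matching on M;
5. score the whole alignment,

       Score(H1, H2) = sum over (R, R') in rho of maxscorePath(R, R')
                       ------------------------------------------------
                                      max{|E1|, |E2|}

   where maxscorePath(R, R') is the best scorePath among the sigma pairs
   whose alignment puts R and R' in the same column, and extract the
   largest conserved subpathway: the biggest connected component of the
   relational graph G whose nodes are the rho-matched H1 reactions and
   whose edges require reaction connectivity to be preserved on *both*
   sides of rho.

The similarity score is turned into a distance via d = 2(1 - Score)
(with an optional sqrt(2(1 - Score)) variant).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import IO, Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .matching import WeightTable, max_weight_matching
from .pathway_model import PathwayHypergraph
from .paths import (
    DEFAULT_MAX_DEPTH,
    DEFAULT_MAX_PATHS,
    ReactionPath,
    enumerate_reaction_paths,
)
from .similarity import (
    DEFAULT_WEIGHTS,
    CompoundSimilarityProvider,
    ScoreWeights,
    reaction_similarity,
)

__all__ = [
    "AlignConfig",
    "PathAlignment",
    "AlignmentResult",
    "align_reaction_paths",
    "match_paths",
    "build_match_frequency",
    "match_reactions",
    "final_score",
    "build_relational_graph",
    "largest_conserved_subpathway",
    "align_pathways",
    "score_to_distance",
    "identity_reaction_sim",
    "write_path_alignment_report",
    "write_reaction_matching_tsv",
    "write_final_alignment_tsv",
    "score_report",
    "write_score_report",
]

_TOL = 1e-9

SimFn = Callable[[str, str], float]


@dataclass(frozen=True)
class AlignConfig:
    """Tunable knobs of the alignment pipeline.

    gap_penalty is the linear Smith-Waterman gap cost (default 0, the
    setting under which the normalized path scores reproduce the known
    perfect-path and one-overlap anchors); distance_variant selects the
    linear 2(1-s) or the Euclidean-style sqrt(2(1-s)) conversion.
    """

    weights: ScoreWeights = DEFAULT_WEIGHTS
    gap_penalty: float = 0.0
    max_paths: int = DEFAULT_MAX_PATHS
    max_depth: int = DEFAULT_MAX_DEPTH
    distance_variant: str = "linear"

    def __post_init__(self) -> None:
        if self.gap_penalty < 0:
            raise ValueError("gap penalty must be non-negative")
        if self.distance_variant not in ("linear", "sqrt"):
            raise ValueError(f"unknown distance variant {self.distance_variant!r}")


DEFAULT_CONFIG = AlignConfig()


def identity_reaction_sim(r1: str, r2: str) -> float:
    """Substitution oracle scoring 1 for identical reaction ids, else 0."""
    return 1.0 if r1 == r2 else 0.0


@dataclass(frozen=True)
class PathAlignment:
    """A local alignment of two reaction paths.

    ``columns`` covers both full paths: unaligned flanks appear against
    gaps (``None``), the locally aligned core in the middle; no column
    is gap-gap.  ``score_path`` is the optimal local score divided by
    max{|p|, |p'|}.
    """

    left: ReactionPath
    right: ReactionPath
    columns: tuple[tuple[str | None, str | None], ...]
    raw_score: float
    score_path: float

    @property
    def matched_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b in self.columns if a is not None and b is not None]


def align_reaction_paths(
    p: ReactionPath,
    q: ReactionPath,
    sim: SimFn,
    gap_penalty: float = 0.0,
) -> PathAlignment:
    """Smith-Waterman local alignment of two reaction paths.

    Substitution score sim(R, R') in [0, 1], linear gap penalty.  The
    traceback prefers substitution over a gap in p over a gap in q, so
    the reported columns are deterministic.
    """
    a, b = p.reactions, q.reactions
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            h = prev[j - 1] + sim(a[i - 1], b[j - 1])
            h = max(0.0, h, prev[j] - gap_penalty, row[j - 1] - gap_penalty)
            row[j] = h
            if h > best + _TOL:
                best, bi, bj = h, i, j

    core: list[tuple[str | None, str | None]] = []
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > _TOL:
        h = H[i][j]
        if abs(h - (H[i - 1][j - 1] + sim(a[i - 1], b[j - 1]))) <= _TOL:
            core.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif abs(h - (H[i - 1][j] - gap_penalty)) <= _TOL:
            core.append((a[i - 1], None))
            i -= 1
        else:
            core.append((None, b[j - 1]))
            j -= 1
    core.reverse()
    start_i, start_j = i, j

    columns: list[tuple[str | None, str | None]] = []
    columns += [(x, None) for x in a[:start_i]]
    columns += [(None, y) for y in b[:start_j]]
    columns += core
    columns += [(x, None) for x in a[bi:]]
    columns += [(None, y) for y in b[bj:]]
    return PathAlignment(
        left=p,
        right=q,
        columns=tuple(columns),
        raw_score=best,
        score_path=best / max(n, m),
    )


def match_paths(
    paths1: Sequence[ReactionPath],
    paths2: Sequence[ReactionPath],
    score_table: Mapping[tuple[int, int], float],
) -> list[tuple[int, int]]:
    """The path matching sigma: maximum-weight matching over the
    complete scorePath table (keyed by path indices)."""
    table = WeightTable.from_pairs(
        dict(score_table), tuple(range(len(paths1))), tuple(range(len(paths2)))
    )
    return [(int(i), int(j)) for i, j in max_weight_matching(table)]


def build_match_frequency(
    sigma: Iterable[tuple[int, int]],
    alignments: Mapping[tuple[int, int], PathAlignment],
    reactions1: Sequence[str],
    reactions2: Sequence[str],
) -> pd.DataFrame:
    """The match-frequency matrix M: m[i, j] counts, over the sigma
    pairs, how many alignments put reaction Ri of H1 and Rj of H2 in the
    same column.  Gap columns contribute nothing."""
    M = pd.DataFrame(
        0, index=sorted(reactions1), columns=sorted(reactions2), dtype=int
    )
    for key in sigma:
        for r1, r2 in alignments[key].matched_pairs:
            M.loc[r1, r2] += 1
    return M


def match_reactions(M: pd.DataFrame) -> list[tuple[str, str]]:
    """The reaction matching rho: maximum-weight matching on M, pairing
    each H1 reaction with at most one H2 reaction."""
    table = WeightTable(
        tuple(M.index), tuple(M.columns), M.to_numpy(dtype=float)
    )
    return max_weight_matching(table)


def final_score(
    rho: Sequence[tuple[str, str]],
    sigma: Iterable[tuple[int, int]],
    alignments: Mapping[tuple[int, int], PathAlignment],
    n_reactions1: int,
    n_reactions2: int,
) -> tuple[float, dict[tuple[str, str], float]]:
    """The pathway similarity score and the per-pair maxscorePath map.

    For each rho pair (R, R'), maxscorePath is the best scorePath among
    sigma-matched path pairs whose alignment places R and R' in the same
    column; pairs with no qualifying sigma pair contribute 0.
    """
    msp: dict[tuple[str, str], float] = {pair: 0.0 for pair in rho}
    for key in sigma:
        alignment = alignments[key]
        for pair in alignment.matched_pairs:
            if pair in msp and alignment.score_path > msp[pair]:
                msp[pair] = alignment.score_path
    denom = max(n_reactions1, n_reactions2)
    score = sum(msp.values()) / denom if denom else 0.0
    return score, msp


def build_relational_graph(
    H1: PathwayHypergraph,
    H2: PathwayHypergraph,
    rho: Sequence[tuple[str, str]],
) -> nx.DiGraph:
    """The relational graph G over the rho-matched H1 reactions.

    Edge (Ri, Rj) requires connectivity on both sides: some output of
    Ri feeds Rj in H1 *and* some output of rho(Ri) feeds rho(Rj) in H2.
    """
    rho_map = dict(rho)
    G = nx.DiGraph()
    G.add_nodes_from(sorted(rho_map))
    for ri in rho_map:
        for rj in rho_map:
            if ri == rj:
                continue
            a1, b1 = H1.reactions[ri], H1.reactions[rj]
            a2, b2 = H2.reactions[rho_map[ri]], H2.reactions[rho_map[rj]]
            if (a1.outputs & b1.inputs) and (a2.outputs & b2.inputs):
                G.add_edge(ri, rj)
    return G


def largest_conserved_subpathway(
    G: nx.DiGraph, rho: Sequence[tuple[str, str]] | Mapping[str, str]
) -> list[tuple[str, str]]:
    """The conserved subpathway: the largest (weakly) connected
    component of G, with rho images.  Size ties go to the component
    whose sorted reaction-id list is lexicographically smallest."""
    rho_map = dict(rho)
    if G.number_of_nodes() == 0:
        return []
    components = sorted(
        (sorted(c) for c in nx.weakly_connected_components(G)),
        key=lambda c: (-len(c), c),
    )
    return [(r, rho_map[r]) for r in components[0]]


@dataclass
class AlignmentResult:
    """Everything the five-step alignment produces."""

    pathway_id_1: str
    pathway_id_2: str
    paths1: list[ReactionPath]
    paths2: list[ReactionPath]
    sigma: list[tuple[int, int]]
    alignments: dict[tuple[int, int], PathAlignment]
    match_frequency: pd.DataFrame
    rho: list[tuple[str, str]]
    max_score_path: dict[tuple[str, str], float]
    score: float
    relational_graph: nx.DiGraph
    conserved: list[tuple[str, str]]
    n_reactions_1: int
    n_reactions_2: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def sigma_paths(self) -> list[tuple[ReactionPath, ReactionPath]]:
        return [(self.paths1[i], self.paths2[j]) for i, j in self.sigma]


def _empty_result(H1: PathwayHypergraph, H2: PathwayHypergraph,
                  diagnostics: dict) -> AlignmentResult:
    return AlignmentResult(
        pathway_id_1=H1.id,
        pathway_id_2=H2.id,
        paths1=[],
        paths2=[],
        sigma=[],
        alignments={},
        match_frequency=pd.DataFrame(
            0, index=sorted(H1.reactions), columns=sorted(H2.reactions), dtype=int
        ),
        rho=[],
        max_score_path={},
        score=0.0,
        relational_graph=nx.DiGraph(),
        conserved=[],
        n_reactions_1=H1.n_reactions,
        n_reactions_2=H2.n_reactions,
        diagnostics=diagnostics,
    )


def _flip_result(result: AlignmentResult) -> AlignmentResult:
    """Swap the two sides of an alignment result."""
    alignments = {
        (j, i): PathAlignment(
            left=al.right,
            right=al.left,
            columns=tuple((b, a) for a, b in al.columns),
            raw_score=al.raw_score,
            score_path=al.score_path,
        )
        for (i, j), al in result.alignments.items()
    }
    rho = sorted((b, a) for a, b in result.rho)
    # the relational graph lives on the (new) H1 side; the caller
    # rebuilds it from the flipped rho
    G = nx.DiGraph()
    return AlignmentResult(
        pathway_id_1=result.pathway_id_2,
        pathway_id_2=result.pathway_id_1,
        paths1=result.paths2,
        paths2=result.paths1,
        sigma=sorted((j, i) for i, j in result.sigma),
        alignments=alignments,
        match_frequency=result.match_frequency.T,
        rho=rho,
        max_score_path={(b, a): v for (a, b), v in result.max_score_path.items()},
        score=result.score,
        relational_graph=G,
        conserved=sorted((b, a) for a, b in result.conserved),
        n_reactions_1=result.n_reactions_2,
        n_reactions_2=result.n_reactions_1,
        diagnostics={
            "truncated_1": result.diagnostics.get("truncated_2", False),
            "truncated_2": result.diagnostics.get("truncated_1", False),
            "no_reaction_paths": result.diagnostics.get("no_reaction_paths",
                                                        False),
        },
    )


def align_pathways(
    H1: PathwayHypergraph,
    H2: PathwayHypergraph,
    provider: CompoundSimilarityProvider | None = None,
    config: AlignConfig = DEFAULT_CONFIG,
) -> AlignmentResult:
    """Run the full five-step alignment of two pathway hypergraphs.

    Deterministic for fixed inputs and configuration.  The pair is
    evaluated in a canonical orientation (smaller pathway key first)
    and mapped back, so the score is exactly symmetric even when
    co-optimal tracebacks or matchings exist; without this, ties could
    resolve differently in the two orientations.  A pathway with no
    reaction paths (e.g. no source compounds) yields Score 0, an empty
    alignment and the ``no_reaction_paths`` diagnostic flag.
    """
    key1 = (H1.id, H1.n_reactions, tuple(sorted(H1.reactions)))
    key2 = (H2.id, H2.n_reactions, tuple(sorted(H2.reactions)))
    if key2 < key1:
        flipped = _align_oriented(H2, H1, provider, config)
        result = _flip_result(flipped)
        rho_positive = [p for p in result.rho if result.max_score_path[p] > 0.0]
        result.relational_graph = build_relational_graph(H1, H2, rho_positive)
        result.conserved = largest_conserved_subpathway(
            result.relational_graph, rho_positive
        )
        return result
    return _align_oriented(H1, H2, provider, config)


def _align_oriented(
    H1: PathwayHypergraph,
    H2: PathwayHypergraph,
    provider: CompoundSimilarityProvider | None = None,
    config: AlignConfig = DEFAULT_CONFIG,
) -> AlignmentResult:
    if provider is None:
        provider = CompoundSimilarityProvider.identity()

    ps1 = enumerate_reaction_paths(H1, config.max_paths, config.max_depth)
    ps2 = enumerate_reaction_paths(H2, config.max_paths, config.max_depth)
    diagnostics = {
        "truncated_1": ps1.truncated,
        "truncated_2": ps2.truncated,
        "no_reaction_paths": not ps1.paths or not ps2.paths,
    }
    paths1 = sorted(ps1.paths)
    paths2 = sorted(ps2.paths)
    if diagnostics["no_reaction_paths"]:
        result = _empty_result(H1, H2, diagnostics)
        result.paths1, result.paths2 = paths1, paths2
        return result

    cache: dict[tuple[str, str], float] = {}

    def sim(r1: str, r2: str) -> float:
        key = (r1, r2)
        value = cache.get(key)
        if value is None:
            value = reaction_similarity(
                H1.reactions[r1], H2.reactions[r2], provider, config.weights
            )
            cache[key] = value
        return value

    alignments: dict[tuple[int, int], PathAlignment] = {}
    score_table: dict[tuple[int, int], float] = {}
    for i, p in enumerate(paths1):
        for j, q in enumerate(paths2):
            alignment = align_reaction_paths(p, q, sim, config.gap_penalty)
            alignments[(i, j)] = alignment
            score_table[(i, j)] = alignment.score_path

    sigma = match_paths(paths1, paths2, score_table)
    M = build_match_frequency(
        sigma, alignments, sorted(H1.reactions), sorted(H2.reactions)
    )
    rho = match_reactions(M)
    score, msp = final_score(rho, sigma, alignments, H1.n_reactions, H2.n_reactions)
    rho_positive = [pair for pair in rho if msp[pair] > 0.0]
    G = build_relational_graph(H1, H2, rho_positive)
    conserved = largest_conserved_subpathway(G, rho_positive)
    return AlignmentResult(
        pathway_id_1=H1.id,
        pathway_id_2=H2.id,
        paths1=paths1,
        paths2=paths2,
        sigma=sigma,
        alignments=alignments,
        match_frequency=M,
        rho=rho,
        max_score_path=msp,
        score=score,
        relational_graph=G,
        conserved=conserved,
        n_reactions_1=H1.n_reactions,
        n_reactions_2=H2.n_reactions,
        diagnostics=diagnostics,
    )


def score_to_distance(score: float, variant: str = "linear") -> float:
    """Convert a similarity score into a distance: 2(1 - s), or its
    square root under the ``sqrt`` variant."""
    if not 0.0 <= score <= 1.0 + _TOL:
        raise ValueError(f"score {score} outside [0, 1]")
    d = 2.0 * (1.0 - min(score, 1.0))
    if variant == "linear":
        return d
    if variant == "sqrt":
        return math.sqrt(d)
    raise ValueError(f"unknown distance variant {variant!r}")


# --------------------------------------------------------------------------
# Report writers
# --------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _dialect(rid: str, rev_dialect: str) -> str:
    if rev_dialect == "#rev" and rid.endswith("rev") and not rid.endswith("#rev"):
        return rid[:-3] + "#rev"
    return rid


def write_path_alignment_report(
    result: AlignmentResult,
    target: str | FsPath | IO[str],
    rev_dialect: str = "rev",
) -> None:
    """Per matched path pair: a score line, then one tab-separated
    column per row with '-' for gaps."""
    lines = [f"Path alignment {result.pathway_id_1}-{result.pathway_id_2}"]
    for key in result.sigma:
        alignment = result.alignments[key]
        lines.append(f"Score: {_fmt(alignment.score_path)}")
        for a, b in alignment.columns:
            lines.append(
                f"{_dialect(a, rev_dialect) if a else '-'}\t"
                f"{_dialect(b, rev_dialect) if b else '-'}"
            )
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)  # type: ignore[union-attr]
    else:
        FsPath(target).write_text(text)


def write_reaction_matching_tsv(
    result: AlignmentResult,
    target: str | FsPath | IO[str],
    rev_dialect: str = "rev",
) -> None:
    """The reaction matching rho, one pair per line."""
    header = f"{result.pathway_id_1}\t{result.pathway_id_2}\n"
    body = "".join(
        f"{_dialect(a, rev_dialect)}\t{_dialect(b, rev_dialect)}\n"
        for a, b in result.rho
    )
    text = header + body
    if hasattr(target, "write"):
        target.write(text)  # type: ignore[union-attr]
    else:
        FsPath(target).write_text(text)


def write_final_alignment_tsv(
    result: AlignmentResult,
    H1: PathwayHypergraph,
    target: str | FsPath | IO[str],
    rev_dialect: str = "rev",
) -> None:
    """The final alignment (largest conserved subpathway): reaction,
    matched reaction, catalyzing enzyme(s)."""
    lines = ["reaction\tmatched_reaction\tenzyme"]
    for r1, r2 in result.conserved:
        ecs = ",".join(f"ec:{e}" for e in H1.reactions[r1].enzymes)
        lines.append(f"{_dialect(r1, rev_dialect)}\t{_dialect(r2, rev_dialect)}\t{ecs}")
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)  # type: ignore[union-attr]
    else:
        FsPath(target).write_text(text)


def score_report(result: AlignmentResult, distance_variant: str = "linear") -> dict:
    """Summary statistics of one alignment as a JSON-ready mapping."""
    return {
        "pathway_1": result.pathway_id_1,
        "pathway_2": result.pathway_id_2,
        "score": result.score,
        "distance": score_to_distance(result.score, distance_variant),
        "n_paths_1": len(result.paths1),
        "n_paths_2": len(result.paths2),
        "n_matched_reactions": len(result.rho),
        "conserved_size": len(result.conserved),
        "diagnostics": dict(result.diagnostics),
    }


def write_score_report(
    result: AlignmentResult,
    target: str | FsPath | IO[str],
    distance_variant: str = "linear",
) -> None:
    text = json.dumps(score_report(result, distance_variant), indent=2,
                      sort_keys=True) + "\n"
    if hasattr(target, "write"):
        target.write(text)  # type: ignore[union-attr]
    else:
        FsPath(target).write_text(text)
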