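from __future__ import annotations

import math

import pandas as pd
import pytest

from pathalign import (
    AlignConfig,
    CompoundSimilarityProvider,
    align_pathways,
    align_reaction_paths,
    build_hypergraph,
    generate_pathway,
    identity_reaction_sim,
    perturb_pathway,
    score_to_distance,
)
from pathalign.alignment import (
    PathAlignment,
    build_match_frequency,
    build_relational_graph,
    final_score,
    largest_conserved_subpathway,
    match_paths,
    match_reactions,
)
from pathalign.paths import ReactionPath
from pathalign.synth import SynthSpec

from conftest import chain_records


class TestSmithWaterman:
    def test_zero_similarity_gives_empty_core(self):
        p = ReactionPath(("R1", "R2"))
        q = ReactionPath(("S1",))
        a = align_reaction_paths(p, q, lambda x, y: 0.0)
        assert a.score_path == 0.0
        assert a.matched_pairs == []
        assert all((x is None) != (y is None) for x, y in a.columns)

    def test_columns_preserve_path_order(self):
        p = ReactionPath(("R1", "R2", "R3"))
        q = ReactionPath(("R2", "R3", "R4"))
        a = align_reaction_paths(p, q, identity_reaction_sim)
        left = [x for x, _ in a.columns if x is not None]
        right = [y for _, y in a.columns if y is not None]
        assert left == list(p.reactions) and right == list(q.reactions)
        assert a.matched_pairs == [("R2", "R2"), ("R3", "R3")]
        assert a.score_path == pytest.approx(2 / 3)

    def test_internal_gap_with_zero_penalty(self):
        p = ReactionPath(("R1", "Rx", "R2"))
        q = ReactionPath(("R1", "R2"))
        a = align_reaction_paths(p, q, identity_reaction_sim, gap_penalty=0.0)
        assert a.raw_score == pytest.approx(2.0)
        assert a.score_path == pytest.approx(2 / 3)

    def test_gap_penalty_discourages_gapped_alignment(self):
        p = ReactionPath(("R1", "Rx", "R2"))
        q = ReactionPath(("R1", "R2"))
        a = align_reaction_paths(p, q, identity_reaction_sim, gap_penalty=2.0)
        # bridging the gap costs more than restarting: keep one match
        assert a.raw_score == pytest.approx(1.0)


def _alignment(pairs, score):
    cols = tuple(pairs)
    left = ReactionPath(tuple(a for a, _ in pairs if a))
    right = ReactionPath(tuple(b for _, b in pairs if b))
    return PathAlignment(left, right, cols, score * max(len(left), len(right)),
                         score)


class TestPathAndReactionMatching:
    def test_single_self_path_matches_itself(self):
        p = [ReactionPath(("R1", "R2"))]
        sigma = match_paths(p, p, {(0, 0): 1.0})
        assert sigma == [(0, 0)]

    def test_best_scoring_path_pair_wins(self):
        p1 = [ReactionPath(("A1",)), ReactionPath(("A2",))]
        p2 = [ReactionPath(("B1",))]
        sigma = match_paths(p1, p2, {(0, 0): 0.9, (1, 0): 0.3})
        assert sigma == [(0, 0)]

    def test_all_zero_scores_give_empty_sigma(self):
        p1 = [ReactionPath(("A1",))]
        p2 = [ReactionPath(("B1",))]
        assert match_paths(p1, p2, {(0, 0): 0.0}) == []

    def test_frequency_single_pair(self):
        alignments = {(0, 0): _alignment([("Ra", "Rx")], 1.0)}
        M = build_match_frequency([(0, 0)], alignments, ["Ra", "Rb"],
                                  ["Rx", "Ry"])
        assert M.loc["Ra", "Rx"] == 1
        assert M.to_numpy().sum() == 1

    def test_frequency_counts_column_alignments_across_sigma(self):
        # Ri appears in 3 matched paths, aligned to Rj in 2 of them
        alignments = {
            (0, 0): _alignment([("Ri", "Rj")], 0.5),
            (1, 1): _alignment([("Ri", "Rj")], 0.5),
            (2, 2): _alignment([("Ri", "Rz")], 0.5),
        }
        M = build_match_frequency(
            [(0, 0), (1, 1), (2, 2)], alignments, ["Ri"], ["Rj", "Rz"]
        )
        assert M.loc["Ri", "Rj"] == 2
        assert M.loc["Ri", "Rz"] == 1

    def test_empty_sigma_gives_zero_matrix(self):
        M = build_match_frequency([], {}, ["Ra"], ["Rx"])
        assert (M.to_numpy() == 0).all()

    def test_reaction_matching_takes_max_weight_not_greedy(self):
        M = pd.DataFrame([[2, 1], [2, 0]], index=["R1", "R2"],
                         columns=["C1", "C2"])
        assert match_reactions(M) == [("R1", "C2"), ("R2", "C1")]

    def test_zero_matrix_gives_empty_rho(self):
        M = pd.DataFrame(0, index=["R1"], columns=["C1"])
        assert match_reactions(M) == []


class TestFinalScore:
    def test_empty_rho_scores_zero(self):
        score, msp = final_score([], [], {}, 3, 3)
        assert score == 0.0 and msp == {}

    def test_direct_arithmetic(self):
        alignments = {
            (0, 0): _alignment([("R1", "C1")], 0.5),
            (1, 1): _alignment([("R2", "C2")], 0.5),
        }
        score, msp = final_score(
            [("R1", "C1"), ("R2", "C2")], [(0, 0), (1, 1)], alignments, 2, 4
        )
        assert score == pytest.approx(0.25)
        assert msp == {("R1", "C1"): 0.5, ("R2", "C2"): 0.5}

    def test_pair_never_column_aligned_contributes_zero(self):
        alignments = {(0, 0): _alignment([("R1", "C2")], 0.8)}
        score, msp = final_score([("R1", "C1")], [(0, 0)], alignments, 1, 2)
        assert score == 0.0 and msp[("R1", "C1")] == 0.0


class TestRelationalGraph:
    def test_identity_matching_preserves_connectivity(self, chain3):
        rho = [(r, r) for r in chain3.reactions]
        G = build_relational_graph(chain3, chain3, rho)
        assert set(G.edges) == {("R1", "R2"), ("R2", "R3")}

    def test_broken_connectivity_in_h2_drops_edge(self, chain3):
        H2 = build_hypergraph(
            [
                {"id": "S1", "inputs": ["P"], "outputs": ["Q"]},
                {"id": "S2", "inputs": ["V"], "outputs": ["W"]},
                {"id": "S3", "inputs": ["W"], "outputs": ["Z"]},
            ],
            pathway_id="h2",
        )
        G = build_relational_graph(chain3, H2, [("R1", "S1"), ("R2", "S2"),
                                                ("R3", "S3")])
        # R1-R2 connected in H1 but S1,S2 disconnected in H2
        assert set(G.edges) == {("R2", "R3")}

    def test_empty_rho_gives_empty_graph(self, chain3):
        G = build_relational_graph(chain3, chain3, [])
        assert G.number_of_nodes() == 0
        assert largest_conserved_subpathway(G, {}) == []

    def test_largest_component_selected(self, chain3):
        H2 = build_hypergraph(
            [
                {"id": "S1", "inputs": ["P"], "outputs": ["Q"]},
                {"id": "S2", "inputs": ["Q"], "outputs": ["V"]},
                {"id": "S3", "inputs": ["X"], "outputs": ["Y"]},
            ],
            pathway_id="h2",
        )
        rho = [("R1", "S1"), ("R2", "S2"), ("R3", "S3")]
        G = build_relational_graph(chain3, H2, rho)
        conserved = largest_conserved_subpathway(G, rho)
        assert conserved == [("R1", "S1"), ("R2", "S2")]


class TestAlignPathways:
    def test_self_alignment_of_connected_chain_is_perfect(self, chain3):
        result = align_pathways(chain3, chain3)
        assert result.score == pytest.approx(1.0)
        assert result.conserved == [("R1", "R1"), ("R2", "R2"), ("R3", "R3")]

    def test_extra_branch_reaction_costs_one_quarter(self, chain3):
        records = chain_records(3) + [
            {"id": "R4", "inputs": ["B"], "outputs": ["Z"], "ec": ["6.9.9.9"]}
        ]
        H2 = build_hypergraph(records, pathway_id="chain3+branch")
        result = align_pathways(chain3, H2)
        assert result.score == pytest.approx(0.75)
        assert [r for r, _ in result.conserved] == ["R1", "R2", "R3"]

    def test_disjoint_pathways_score_zero(self, chain3):
        H2 = build_hypergraph(
            [{"id": "S1", "inputs": ["P"], "outputs": ["Q"], "ec": ["6.1.1.1"]}],
            pathway_id="other",
        )
        result = align_pathways(chain3, H2)
        assert result.score == 0.0
        assert result.conserved == []

    def test_pathway_without_sources_flags_diagnostic(self, chain3):
        cycle = build_hypergraph(
            [
                {"id": "R1", "inputs": ["A"], "outputs": ["B"]},
                {"id": "R2", "inputs": ["B"], "outputs": ["A"]},
            ],
            pathway_id="cycle",
        )
        result = align_pathways(chain3, cycle)
        assert result.score == 0.0
        assert result.diagnostics["no_reaction_paths"]

    def test_unreachable_reaction_lowers_self_score(self, chain3):
        records = chain_records(3) + [
            {"id": "X1", "inputs": ["M"], "outputs": ["N"], "ec": ["1.1.1.2"]},
            {"id": "X2", "inputs": ["N"], "outputs": ["M"], "ec": ["1.1.1.3"]},
        ]
        H = build_hypergraph(records, pathway_id="chain+cycle")
        result = align_pathways(H, H)
        assert result.score == pytest.approx(3 / 5)

    def test_deleting_a_reaction_never_increases_score(self):
        H = generate_pathway(SynthSpec(n_reactions=8, n_compounds=14, seed=12))
        base = align_pathways(H, H).score
        for rid in sorted(H.reactions):
            reduced, _ = perturb_pathway(
                H, [("delete_reaction", {"reaction": rid})]
            )
            assert align_pathways(H, reduced).score <= base + 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_score_symmetric_and_bounded(self, seed):
        Ha = generate_pathway(
            SynthSpec(n_reactions=6, n_compounds=11, fraction_reversible=0.3,
                      ec_scheme="shared_family", seed=seed)
        )
        Hb = generate_pathway(
            SynthSpec(n_reactions=7, n_compounds=12, fraction_reversible=0.3,
                      ec_scheme="shared_family", seed=seed + 1000)
        )
        provider = CompoundSimilarityProvider.random_symmetric(
            sorted(set(Ha.compounds) | set(Hb.compounds)), seed
        )
        s_ab = align_pathways(Ha, Hb, provider).score
        s_ba = align_pathways(Hb, Ha, provider).score
        assert 0.0 <= s_ab <= 1.0
        assert s_ab == pytest.approx(s_ba, abs=1e-9)

    def test_conserved_subpathway_connected_on_both_sides(self):
        import networkx as nx
        from pathalign import reaction_adjacency

        Ha = generate_pathway(SynthSpec(n_reactions=8, n_compounds=14, seed=3))
        Hb, _ = perturb_pathway(Ha, ["delete_reaction", "mutate_ec_level"],
                                seed=9)
        result = align_pathways(Ha, Hb)
        if len(result.conserved) > 1:
            left = [r for r, _ in result.conserved]
            right = [r for _, r in result.conserved]
            ga = reaction_adjacency(Ha).to_undirected().subgraph(left)
            gb = reaction_adjacency(Hb).to_undirected().subgraph(right)
            assert nx.is_connected(ga)
            assert nx.is_connected(gb)


class TestScoreToDistance:
    @pytest.mark.parametrize(("s", "d"), [(1.0, 0.0), (0.5, 1.0), (0.0, 2.0)])
    def test_linear_form(self, s, d):
        assert score_to_distance(s) == pytest.approx(d)

    def test_sqrt_variant(self):
        assert score_to_distance(0.5, "sqrt") == pytest.approx(1.0)
        assert score_to_distance(0.0, "sqrt") == pytest.approx(math.sqrt(2))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_to_distance(1.2)
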