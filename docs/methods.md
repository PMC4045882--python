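# Methods

This note documents the model implemented by `pathalign`, the
parameters that matter, the numerical and design choices made where the
construction was genuinely open, what the synthetic-data generator does
and does not emulate, and known limitations.

## Pathway model

A metabolic pathway is represented as a directed hypergraph
*H* = (*V*, *E*): compounds are nodes, and each reaction is a directed
hyperedge *R* = (*I*, *E*, *O*) from its substrate set to its product
set, carrying the EC numbers of its catalyzing enzymes as attributes
(enzymes are not nodes).

* **Ubiquitous compounds.** Currency metabolites connect nearly every
  reaction pair and would drown the topology in spurious edges, so they
  are removed from all substrate/product sets at build time. The
  default exclusion list (overridable per run) contains water,
  ATP/ADP/AMP, NAD(P)(H), orthophosphate, diphosphate, CO₂, O₂, H⁺ and
  CoA, addressed by KEGG C-number. A reaction emptied on *one* side by
  filtering is kept — it becomes a path endpoint; a reaction emptied on
  both sides is dropped, since a hyperedge needs at least one endpoint.
* **Reversibility.** A reversible reaction becomes two hyperedges: the
  forward copy keeps the identifier, the backward copy swaps *I* and
  *O* and appends the suffix `rev`. Identifiers are otherwise opaque
  strings; no KEGG-format validation is performed, so synthetic
  fixtures may use arbitrary names.
* **Sources and sinks.** A compound appearing in some reaction's inputs
  and no reaction's outputs is a *source*; the converse is a *sink*;
  everything else referenced by a reaction is *internal*. These model
  exchange with the rest of metabolism. Note that reversible expansion
  makes both compounds of an A ⇌ B pair internal.

Input formats: KGML (KEGG XML) and a plain JSON dialect. JSON written
by the package is marked `"expanded": true` and re-read verbatim
(reversible reactions are *not* re-expanded), which gives an exact
build → write → read round trip; serialization is canonical (sorted
keys/lists), so write → read → write is byte-identical.

## Reaction similarity

    SimReact(Rᵢ, Rⱼ) = SimEnz·wₑ + SimComp(Iᵢ, Iⱼ)·wᵢ + SimComp(Oᵢ, Oⱼ)·wₒ

* **Weights** default to wₑ = 0.4, wᵢ = wₒ = 0.3 (unitless; they sum to
  1, keeping SimReact in [0, 1]). User-supplied weights are used
  exactly as given, without renormalization.
* **SimEnz** is the hierarchical EC similarity: the length of the
  longest common prefix of the two 4-level EC numbers, divided by 4.
  It takes only the values {0, 0.25, 0.5, 0.75, 1}. Wildcard levels
  (`-`/`*`) never match, not even each other. When a reaction carries
  several EC annotations (KGML allows this), the best pair is taken:
  the single-enzyme formula extends to lists without leaving [0, 1],
  and any shared catalytic function should count. A reaction with no
  EC annotation scores 0 against everything.
* **SimComp** builds the complete bipartite graph between the two
  compound sets, weighted by an external compound-similarity provider,
  finds a maximum-weight matching and divides the matched weight by
  max{|X|, |Y|}. Chemical structure similarity itself is out of scope:
  the provider is a symmetric score cache (TSV of
  `compound_id_1  compound_id_2  score`), e.g. precomputed SIMCOMP
  values. Identical ids score 1 even when absent from the cache; a
  missing pair scores 0 (the conservative default). Degenerate cases:
  two empty sets are vacuously identical (1); empty vs non-empty is 0.

## Alignment pipeline

1. **Reaction paths.** A reaction path is a maximal simple sequence of
   reactions starting at a reaction that consumes at least one source
   compound (one suffices, even if the reaction also consumes internal
   compounds), with consecutive reactions linked by a shared compound
   (outputs ∩ inputs ≠ ∅). Maximality means not extendable at the tail
   by any unused connected reaction; prefixes are discarded during DFS
   backtracking. The number of such paths can grow exponentially, so
   the search carries caps (defaults: 10 000 paths, depth 100) and sets
   an explicit truncation flag when a cap is hit — never a silent drop.
   A consequence of anchoring paths at sources: reactions unreachable
   from every source (e.g. on an isolated cycle) lie on no path and can
   never be matched, so even a self-comparison scores below 1 when such
   reactions exist.
2. **Path alignment.** Each path pair is aligned with Smith–Waterman
   local alignment, substitution score SimReact, and a linear gap
   penalty (default 0; configurable). The normalized score is
   *scorePath(p, p′)* = (optimal local score) / max{|p|, |p′|}, which
   lies in [0, 1]: a perfect 3-reaction self-alignment gives 1.0, and a
   single match between paths of lengths 2 and 1 gives 0.5. This
   normalization is a design choice; it is the one consistent with both
   of those anchor values (normalizing by the shorter or the aligned
   length is not). The traceback prefers substitution over a gap in the
   first path over a gap in the second, making reports deterministic.
3. **Path matching σ** is the maximum-weight bipartite matching on the
   all-against-all scorePath table.
4. **Reaction matching ρ.** The match-frequency matrix M counts, over
   the σ pairs, how often reaction Rᵢ of H₁ sits in the same alignment
   column as Rⱼ of H₂ (gap columns contribute nothing); ρ is the
   maximum-weight matching on M.
5. **Score and conserved subpathway.** For each ρ pair,
   maxscorePath(R, R′) is the best scorePath among σ pairs whose
   alignment column-aligns R with R′ (0, and exclusion from the
   conserved output, if no σ pair qualifies); the pathway score is the
   sum over ρ divided by max{|E₁|, |E₂|}. The relational graph G has
   the ρ-matched H₁ reactions as nodes and an edge (Rᵢ, Rⱼ) exactly
   when Rᵢ feeds Rⱼ in H₁ *and* ρ(Rᵢ) feeds ρ(Rⱼ) in H₂; the largest
   connected component of G (ties broken toward the lexicographically
   smallest reaction-id list) is the conserved subpathway, reported
   with its ρ images. By construction its H₁ side is connected in H₁
   and its image is connected in H₂.

**Matching tie-break.** All three matchings use the rectangular linear
sum assignment (every weight is non-negative, so a complete assignment
of the smaller side attains the optimum). Zero-weight pairs are pruned
from results: a zero-similarity "match" carries no information and
would pollute ρ. Among co-optimal matchings the lexicographically
smallest pair set (in sorted label order) is preferred, implemented by
a geometrically decaying epsilon bonus (relative size 1e-9); weight
differences below that are treated as ties, and for tables beyond
~1000 cells the bonus underflows and the result is merely
deterministic rather than strictly lexicographic.

**Symmetry.** The score's ingredients are symmetric, but co-optimal
Smith–Waterman tracebacks and co-optimal matchings can resolve
differently depending on which pathway is "left", shifting M and hence
ρ and the score by small amounts. `align_pathways` therefore evaluates
each pair in a canonical orientation (lexicographic pathway key) and
maps σ, ρ, M and the conserved set back, so Score(H₁, H₂) =
Score(H₂, H₁) holds exactly, ties included.

**Distance.** d = 2(1 − Score) by default. A Euclidean-style variant
√(2(1 − Score)) is available behind the `distance_variant="sqrt"`
switch for users who want the conversion to behave like a metric
embedding; the linear form is the default.

## Organism-level analyses

For organisms O₁, O₂ with k common pathways,
AverageScore = (1/k) Σ Score(H₁ᵢ, H₂ᵢ) and d(O₁, O₂) =
2(1 − AverageScore). A pair with no common pathway is incomparable and
raises an error naming the pair (the CLI matrix driver instead records
it as missing and continues, skipping dendrogram export). The matrix
driver schedules one task per unordered organism pair — self
comparisons included — per common pathway (8 organisms × 40 pathways →
36 × 40 = 1440 tasks); the distance diagonal is 0 by definition.
Hierarchical clustering (single, average, complete, Ward) is delegated
to scipy on the condensed matrix, with Newick export of the resulting
dendrograms.

**Cluster motifs.** The common motif of a cluster of pathways is the
intersection, over consecutive pairwise alignments in the given order,
of the H₁-side conserved reaction sets (reaction ids are assumed
comparable across pathways, as KEGG ids are). The member order is the
caller's choice — conventionally lexicographic organism id — and an
all-pairs intersection variant is available behind a flag, since
either reading of "pairwise alignments in a predetermined order" is
defensible. A singleton cluster's motif is the reaction set of the
largest connected component of its own reaction-connectivity graph.
Adding a member never enlarges a motif.

## Synthetic data generator

`generate_pathway(SynthSpec(...))` grows a pathway forward from a small
pool of seed substrates (~15% of the compound budget, at least one):
each reaction consumes one or two already-available compounds — the
main substrate drawn from a recent-compound window whose size is the
branching factor + 1, so branching 1 yields chains and larger values
bushier networks — and produces one or two fresh compounds. Defaults:
8 reactions, 14 compounds, branching 2, 25% reversible, uniformly
random 4-level EC numbers (a `shared_family` scheme with few top
families is available to exercise graded EC similarities). The first
reaction is kept irreversible and claims a dedicated seed substrate
that no later reaction may consume, guaranteeing at least one source
compound; without this, backward copies of reversible reactions can
regenerate every seed and leave the pathway sourceless. Generation is
deterministic per seed, and the seed is recorded in the pathway id.

`perturb_pathway` applies evolution-like edits — reaction deletion
(demoting an orphaned reversible twin to irreversible), EC-digit
mutation and substrate swaps (both kept mirrored across reversible
twins), and reaction gain — returning the edited pathway plus an
evolution log. Under repeated deletions the similarity to the original
decreases monotonically, and seeded radiations of a common ancestor
yield distance matrices whose single-linkage clustering recovers the
planted topology; the test suite checks both.

These are deliberately toy networks. They reproduce the structural
features the aligner consumes — sources and sinks, branching,
reversibility, EC hierarchy, compound overlap — but not the degree
distributions, currency-metabolite load, stoichiometry or
thermodynamics of real metabolism. Passing tests therefore validate
the algorithmic machinery, not biological conclusions about any real
organism pair.

## Numerical choices and problem sizes

* Floating-point ties in the Smith–Waterman recurrence and traceback
  are resolved with an absolute tolerance of 1e-9; matching ties as
  described above.
* Degenerate inputs: an empty record list builds an empty hypergraph; a
  pathway with no reaction paths aligns with score 0 and a
  `no_reaction_paths` diagnostic; empty σ gives an all-zero M, empty ρ
  and an empty conserved set.
* The test suite and the acceptance script run on small synthetic
  problems (pathways of 1–16 reactions, path sets well under the caps,
  up to 100 seeded random pairs per property), which keeps the whole
  suite in the low seconds while still crossing every code path —
  chosen because the properties under test (exactness against
  brute-force oracles, symmetry, monotonicity, topology recovery) are
  size-independent.

## Known limitations

* Chemical compound similarity is consumed, never computed; without a
  score cache the provider falls back to identity, which understates
  the similarity of chemically close but distinct compounds.
* Path enumeration is worst-case exponential; the caps make runtime
  predictable at the cost of completeness on pathological topologies
  (always flagged).
* One-to-one reaction matching only; one-to-many matchings (for
  reactions duplicated or fused across species) are out of scope.
* Hyperedges are traversed compound-wise (any shared compound links two
  reactions); the stricter semantics in which a reaction requires all
  its inputs simultaneously is not modeled.
* Stoichiometry, compartments and gene associations are not
  represented.
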