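"""Synthetic pathway generation and perturbation.

Every stage of the pipeline is testable without any database download:
:func:`generate_pathway` builds seeded random pathway hypergraphs and
:func:`perturb_pathway` applies evolution-like edits (reaction loss,
EC drift, substrate swaps, reaction gain), emulating the cross-species
divergence that real pathway comparisons measure — e.g. the gain of a
single enzyme completing a cycle in one clade but not another.

The generator grows a pathway forward from a small pool of seed
substrates: each reaction consumes one or two already-available
compounds (a window controlled by the branching factor decides how
bushy the network gets) and produces fresh compounds, so the result is
acyclic before reversible expansion and always keeps at least one
source compound (the first reaction is forced irreversible).  These are
toy networks: they reproduce the *structural* features the alignment
consumes (sources, branches, reversibility, EC hierarchy), not the
degree distributions or thermodynamics of real metabolism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .pathway_model import (
    ECNumber,
    PathwayHypergraph,
    PathwayError,
    RawReactionRecord,
    Reaction,
    build_hypergraph,
)

__all__ = ["SynthSpec", "generate_pathway", "perturb_pathway", "PERTURBATION_OPS"]

PERTURBATION_OPS = (
    "delete_reaction",
    "mutate_ec_level",
    "swap_compound",
    "add_reaction",
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic pathway draw.

    ``branching`` is the size of the recent-compound window a new
    reaction picks its main substrate from: 1 yields a chain, larger
    values yield bushier networks.  ``fraction_reversible`` applies to
    every reaction but the first (kept irreversible so a source
    compound always survives reversible expansion).
    """

    n_reactions: int = 8
    n_compounds: int = 14
    branching: int = 2
    fraction_reversible: float = 0.25
    ec_scheme: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reactions <= 0 or self.n_compounds <= 0:
            raise ValueError("counts must be positive")
        if self.branching <= 0:
            raise ValueError("branching factor must be positive")
        if not 0.0 <= self.fraction_reversible <= 1.0:
            raise ValueError("fraction_reversible must lie in [0, 1]")
        if self.ec_scheme not in ("random", "shared_family"):
            raise ValueError(f"unknown EC scheme {self.ec_scheme!r}")


def _sample_ec(rng: np.random.Generator, scheme: str) -> str:
    if scheme == "shared_family":
        # few top families: EC prefixes collide often, giving graded
        # enzyme similarities
        d1 = rng.integers(1, 3)
        d2 = rng.integers(1, 3)
        d3 = rng.integers(1, 4)
        d4 = rng.integers(1, 6)
    else:
        d1 = rng.integers(1, 7)
        d2 = rng.integers(1, 21)
        d3 = rng.integers(1, 21)
        d4 = rng.integers(1, 100)
    return f"{d1}.{d2}.{d3}.{d4}"


def generate_pathway(spec: SynthSpec) -> PathwayHypergraph:
    """Draw one valid pathway hypergraph; deterministic per seed.

    Raises if the spec is infeasible: every reaction must produce at
    least one fresh compound beyond the seed substrates.
    """
    n_sources = max(1, round(0.15 * spec.n_compounds))
    if spec.n_compounds < n_sources + spec.n_reactions:
        raise ValueError(
            f"infeasible spec: {spec.n_reactions} reactions need at least "
            f"{n_sources + spec.n_reactions} compounds, got {spec.n_compounds}"
        )
    rng = np.random.default_rng(spec.seed)
    compounds = [f"c{i + 1:03d}" for i in range(spec.n_compounds)]
    available = compounds[:n_sources]
    fresh = list(compounds[n_sources:])
    records: list[RawReactionRecord] = []
    for k in range(spec.n_reactions):
        if k == 0:
            # the first reaction claims the first seed substrate for
            # itself (and stays irreversible): no later reaction can
            # ever produce that compound, so it remains a source node
            inputs = [available.pop(0)]
            window = []
        else:
            window = available[-min(len(available), spec.branching + 1):]
            inputs = [window[rng.integers(0, len(window))]]
        if len(available) > 1 and rng.random() < 0.3:
            extra = available[rng.integers(0, len(available))]
            if extra not in inputs:
                inputs.append(extra)
        remaining_needed = spec.n_reactions - k - 1
        can_take_two = len(fresh) - 2 >= remaining_needed
        n_out = 2 if (can_take_two and rng.random() < 0.25) else 1
        outputs, fresh = fresh[:n_out], fresh[n_out:]
        available = available + outputs
        reversible = bool(k > 0 and rng.random() < spec.fraction_reversible)
        records.append(
            RawReactionRecord(
                id=f"R{k + 1:04d}",
                inputs=tuple(inputs),
                outputs=tuple(outputs),
                enzymes=(_sample_ec(rng, spec.ec_scheme),),
                reversible=reversible,
            )
        )
    H = build_hypergraph(
        records, ubiquitous_list=(), pathway_id=f"synth-{spec.seed}"
    )
    return H


def _as_op(op) -> tuple[str, dict]:
    if isinstance(op, str):
        return op, {}
    name, params = op
    return name, dict(params)


def _rebuild(
    pathway_id: str, reactions: dict[str, Reaction]
) -> PathwayHypergraph:
    from .pathway_model import Compound

    compounds: dict[str, Compound] = {}
    for rxn in reactions.values():
        for cid in rxn.inputs | rxn.outputs:
            compounds.setdefault(cid, Compound(cid))
    H = PathwayHypergraph(
        id=pathway_id,
        compounds=compounds,
        reactions=dict(sorted(reactions.items())),
    )
    H.validate()
    return H


def perturb_pathway(
    H: PathwayHypergraph,
    ops: Sequence,
    seed: int = 0,
) -> tuple[PathwayHypergraph, list[dict]]:
    """Apply evolution-like edits to a built hypergraph.

    ``ops`` is a sequence of operation names, or (name, params) pairs;
    unspecified targets are drawn from a single seeded random stream.
    Supported: ``delete_reaction`` (params: reaction), ``mutate_ec_level``
    (params: reaction, level 1-4), ``swap_compound`` (params: reaction),
    ``add_reaction``.  Returns the perturbed pathway and an evolution
    log of the operations actually applied.  Deleting a reaction that
    does not exist is an error.
    """
    rng = np.random.default_rng(seed)
    reactions = dict(H.reactions)
    log: list[dict] = []
    fresh_counter = 0
    added_counter = 0

    def random_reaction() -> str:
        ids = sorted(reactions)
        return ids[rng.integers(0, len(ids))]

    for op in ops:
        name, params = _as_op(op)
        if name == "delete_reaction":
            rid = params.get("reaction") or random_reaction()
            if rid not in reactions:
                raise PathwayError(f"cannot delete unknown reaction {rid}")
            # deleting either copy of a reversible pair orphans the
            # twin's backward flag; demote the survivor to irreversible
            del reactions[rid]
            twin = rid[:-3] if rid.endswith("rev") else rid + "rev"
            if twin in reactions:
                reactions[twin] = replace(
                    reactions[twin], reversible=False, is_backward=False
                )
            log.append({"op": name, "reaction": rid})
        elif name == "mutate_ec_level":
            rid = params.get("reaction") or random_reaction()
            if rid not in reactions or not reactions[rid].enzymes:
                log.append({"op": name, "reaction": rid, "skipped": True})
                continue
            level = int(params.get("level", 4))
            if not 1 <= level <= 4:
                raise ValueError(f"EC level must be 1-4, got {level}")
            ec = reactions[rid].enzymes[0]
            levels = list(ec.levels)
            old = levels[level - 1]
            new = old
            while new == old:
                new = str(int(rng.integers(1, 100)))
            levels[level - 1] = new
            new_ec = ECNumber(tuple(levels))  # type: ignore[arg-type]
            reactions[rid] = replace(
                reactions[rid],
                enzymes=(new_ec,) + reactions[rid].enzymes[1:],
            )
            _sync_twin_enzymes(reactions, rid)
            log.append({"op": name, "reaction": rid, "from": str(ec),
                        "to": str(new_ec)})
        elif name == "swap_compound":
            rid = params.get("reaction") or random_reaction()
            if rid not in reactions:
                raise PathwayError(f"cannot perturb unknown reaction {rid}")
            rxn = reactions[rid]
            side = "inputs" if rng.random() < 0.5 and rxn.inputs else "outputs"
            pool = sorted(getattr(rxn, side) or (rxn.inputs | rxn.outputs))
            victim = pool[rng.integers(0, len(pool))]
            fresh_counter += 1
            newcomer = f"x{seed}_{fresh_counter:03d}"
            new_inputs = frozenset(
                newcomer if c == victim else c for c in rxn.inputs
            )
            new_outputs = frozenset(
                newcomer if c == victim else c for c in rxn.outputs
            )
            reactions[rid] = replace(rxn, inputs=new_inputs, outputs=new_outputs)
            twin = rid[:-3] if rid.endswith("rev") else rid + "rev"
            if twin in reactions:  # keep the reversible pair mirrored
                reactions[twin] = replace(
                    reactions[twin], inputs=new_outputs, outputs=new_inputs
                )
            log.append({"op": name, "reaction": rid, "from": victim,
                        "to": newcomer})
        elif name == "add_reaction":
            referenced = sorted(
                {c for r in reactions.values() for c in r.inputs | r.outputs}
            )
            added_counter += 1
            fresh_counter += 1
            rid = f"A{seed}_{added_counter:03d}"
            substrate = (
                referenced[rng.integers(0, len(referenced))]
                if referenced else f"x{seed}_{fresh_counter:03d}"
            )
            product = f"x{seed}_{fresh_counter:03d}p"
            reactions[rid] = Reaction(
                id=rid,
                inputs=frozenset({substrate}),
                outputs=frozenset({product}),
                enzymes=(ECNumber.parse(_sample_ec(rng, "random")),),
            )
            log.append({"op": name, "reaction": rid, "substrate": substrate,
                        "product": product})
        else:
            raise ValueError(f"unknown perturbation op {name!r}")

    if not reactions:
        raise PathwayError("perturbation removed every reaction")
    return _rebuild(f"{H.id}-perturbed-{seed}", reactions), log


def _sync_twin_enzymes(reactions: dict[str, Reaction], rid: str) -> None:
    """A reversible pair shares its enzyme annotation; keep twins in sync."""
    twin = rid[:-3] if rid.endswith("rev") else rid + "rev"
    if twin in reactions:
        reactions[twin] = replace(reactions[twin],
                                  enzymes=reactions[rid].enzymes)
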