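"""Directed-hypergraph model of a metabolic pathway.

A pathway is modeled as a directed hypergraph H = (V, E): compounds are
nodes and every reaction is a directed hyperedge R = (I, E, O) consuming
the substrate set I and producing the product set O, annotated with the
EC numbers of its catalyzing enzymes.  Three modeling choices shape the
graph:

* ubiquitous ("currency") compounds such as water and ATP are stripped
  from substrate/product sets, because they would connect nearly every
  pair of reactions and drown the pathway topology in noise;
* a reversible reaction is expanded into two directed hyperedges, the
  forward copy keeping the original identifier and the backward copy
  carrying a ``rev`` suffix with swapped substrates and products;
* compounds that only ever appear as inputs (sources) or only as outputs
  (sinks) mark the exchange points with the rest of metabolism.

Pathways are read from KGML (the KEGG XML dialect) or from a plain JSON
format, and written back to both.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

from lxml import etree

logger = logging.getLogger(__name__)

#: Default ubiquitous-compound exclusion list (KEGG C-numbers): water,
#: ATP/ADP/AMP, NAD(P)(H), orthophosphate, diphosphate, CO2, O2, H+, CoA.
#: Overridable at build time; synthetic fixtures use arbitrary compound
#: names that never collide with these.
DEFAULT_UBIQUITOUS: frozenset[str] = frozenset(
    {
        "C00001",  # H2O
        "C00002",  # ATP
        "C00008",  # ADP
        "C00020",  # AMP
        "C00003",  # NAD+
        "C00004",  # NADH
        "C00005",  # NADPH
        "C00006",  # NADP+
        "C00009",  # orthophosphate
        "C00013",  # diphosphate
        "C00011",  # CO2
        "C00007",  # O2
        "C00080",  # H+
        "C00010",  # CoA
    }
)

REV_SUFFIX = "rev"

_EC_COMPONENT = re.compile(r"^(\d+|-|\*)$")


class PathwayError(ValueError):
    """Raised for invalid pathway structures or records."""


@dataclass(frozen=True)
class Compound:
    """A pathway node: a compound identifier plus an optional label."""

    id: str
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PathwayError("compound id must be non-empty")


@dataclass(frozen=True, order=True)
class ECNumber:
    """A 4-level Enzyme Commission number d1.d2.d3.d4.

    Components are kept as strings; a dash or ``*`` is an unspecified
    (wildcard) level.  The first level must be a number.
    """

    levels: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.levels) != 4:
            raise PathwayError(f"EC number needs exactly 4 levels, got {self.levels!r}")
        for part in self.levels:
            if not _EC_COMPONENT.match(part):
                raise PathwayError(f"malformed EC component {part!r} in {self.levels!r}")
        if not self.levels[0].isdigit():
            raise PathwayError(f"first EC level must be numeric in {self.levels!r}")

    @classmethod
    def parse(cls, text: "str | ECNumber") -> "ECNumber":
        if isinstance(text, ECNumber):
            return text
        parts = str(text).strip().split(".")
        if len(parts) != 4:
            raise PathwayError(f"malformed EC number {text!r}")
        return cls(tuple(parts))  # type: ignore[arg-type]

    def __str__(self) -> str:
        return ".".join(self.levels)


@dataclass(frozen=True)
class RawReactionRecord:
    """One reaction as it appears in the source data, before expansion."""

    id: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    enzymes: tuple[str, ...] = ()
    reversible: bool = False

    @classmethod
    def from_dict(cls, obj: Mapping) -> "RawReactionRecord":
        return cls(
            id=str(obj["id"]),
            inputs=tuple(obj.get("inputs", ())),
            outputs=tuple(obj.get("outputs", ())),
            enzymes=tuple(obj.get("ec", obj.get("enzymes", ()))),
            reversible=bool(obj.get("reversible", False)),
        )


@dataclass(frozen=True)
class Reaction:
    """A directed hyperedge R = (I, E, O).

    ``is_backward`` marks the swapped copy of a reversible reaction; its
    id is the forward id plus the ``rev`` suffix.
    """

    id: str
    inputs: frozenset[str]
    outputs: frozenset[str]
    enzymes: tuple[ECNumber, ...] = ()
    reversible: bool = False
    is_backward: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise PathwayError("reaction id must be non-empty")


@dataclass
class PathwayHypergraph:
    """A pathway as a directed hypergraph: compounds plus reactions.

    ``ubiquitous_filter`` records the exclusion list applied at build
    time so a serialized pathway documents its own provenance.
    """

    id: str
    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    ubiquitous_filter: frozenset[str] = frozenset()

    def validate(self) -> None:
        for rxn in self.reactions.values():
            if rxn.id not in self.reactions or self.reactions[rxn.id] is not rxn:
                raise PathwayError(f"reaction index inconsistent for {rxn.id}")
            if not (rxn.inputs | rxn.outputs):
                raise PathwayError(f"reaction {rxn.id} has no compounds")
            for cid in rxn.inputs | rxn.outputs:
                if cid not in self.compounds:
                    raise PathwayError(
                        f"reaction {rxn.id} references unknown compound {cid}"
                    )
            if rxn.is_backward:
                fwd_id = rxn.id[: -len(REV_SUFFIX)]
                fwd = self.reactions.get(fwd_id)
                if fwd is None:
                    raise PathwayError(f"backward reaction {rxn.id} lacks forward twin")
                if fwd.inputs != rxn.outputs or fwd.outputs != rxn.inputs:
                    raise PathwayError(
                        f"backward reaction {rxn.id} is not the swap of {fwd_id}"
                    )

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def referenced_compounds(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.inputs | rxn.outputs
        return frozenset(out)


def expand_reversible(record: RawReactionRecord) -> list[Reaction]:
    """Expand one raw record into one (irreversible) or two (reversible)
    directed reactions; the backward copy swaps I and O and appends the
    ``rev`` suffix to the id."""
    enzymes = tuple(ECNumber.parse(e) for e in record.enzymes)
    forward = Reaction(
        id=record.id,
        inputs=frozenset(record.inputs),
        outputs=frozenset(record.outputs),
        enzymes=enzymes,
        reversible=record.reversible,
    )
    if not record.reversible:
        return [forward]
    backward = Reaction(
        id=record.id + REV_SUFFIX,
        inputs=frozenset(record.outputs),
        outputs=frozenset(record.inputs),
        enzymes=enzymes,
        reversible=True,
        is_backward=True,
    )
    return [forward, backward]


def build_hypergraph(
    records: Iterable[RawReactionRecord | Mapping],
    ubiquitous_list: Iterable[str] = DEFAULT_UBIQUITOUS,
    pathway_id: str = "pathway",
) -> PathwayHypergraph:
    """Build a validated hypergraph from raw reaction records.

    Ubiquitous compounds are removed from every substrate/product set,
    reversible records are expanded into forward/backward copies, and
    reactions left with no compounds on either side are dropped.  A
    reaction with no compounds *in the input* is rejected outright, as
    is a duplicated reaction id.
    """
    ubiq = frozenset(ubiquitous_list)
    reactions: dict[str, Reaction] = {}
    for rec in records:
        if not isinstance(rec, RawReactionRecord):
            rec = RawReactionRecord.from_dict(rec)
        if not rec.id:
            raise PathwayError("reaction record without id")
        if not rec.inputs and not rec.outputs:
            raise PathwayError(f"reaction {rec.id} has no compounds at all")
        for rxn in expand_reversible(rec):
            filtered = Reaction(
                id=rxn.id,
                inputs=frozenset(rxn.inputs - ubiq),
                outputs=frozenset(rxn.outputs - ubiq),
                enzymes=rxn.enzymes,
                reversible=rxn.reversible,
                is_backward=rxn.is_backward,
            )
            if not (filtered.inputs | filtered.outputs):
                logger.debug("dropping reaction %s: only ubiquitous compounds", rxn.id)
                continue
            if filtered.id in reactions:
                raise PathwayError(f"duplicate reaction id: {filtered.id}")
            reactions[filtered.id] = filtered
    compounds = {
        cid: Compound(cid)
        for rxn in reactions.values()
        for cid in rxn.inputs | rxn.outputs
    }
    H = PathwayHypergraph(
        id=pathway_id,
        compounds=compounds,
        reactions=reactions,
        ubiquitous_filter=ubiq,
    )
    H.validate()
    return H


def classify_compounds(
    H: PathwayHypergraph,
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Partition the referenced compounds into (sources, sinks, internal).

    A source appears in some reaction's inputs and in no reaction's
    outputs; a sink is the converse; everything else referenced by a
    reaction is internal.
    """
    as_input: set[str] = set()
    as_output: set[str] = set()
    for rxn in H.reactions.values():
        as_input |= rxn.inputs
        as_output |= rxn.outputs
    sources = frozenset(as_input - as_output)
    sinks = frozenset(as_output - as_input)
    internal = frozenset((as_input | as_output) - sources - sinks)
    return sources, sinks, internal


# --------------------------------------------------------------------------
# Plain JSON pathway format
# --------------------------------------------------------------------------

def _pathway_to_obj(H: PathwayHypergraph) -> dict:
    return {
        "id": H.id,
        "expanded": True,
        "ubiquitous_filter": sorted(H.ubiquitous_filter),
        "compounds": [
            {"id": c.id, **({"name": c.name} if c.name else {})}
            for c in sorted(H.compounds.values(), key=lambda c: c.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "inputs": sorted(r.inputs),
                "outputs": sorted(r.outputs),
                "ec": [str(e) for e in r.enzymes],
                "reversible": r.reversible,
                "is_backward": r.is_backward,
            }
            for r in sorted(H.reactions.values(), key=lambda r: r.id)
        ],
    }


def write_pathway_json(H: PathwayHypergraph, target: str | Path | IO[str]) -> None:
    """Serialize a built hypergraph to the plain JSON pathway format.

    The serialization is canonical (sorted keys and lists) so that
    write -> read -> write is byte-identical.
    """
    text = json.dumps(_pathway_to_obj(H), indent=2, sort_keys=True) + "\n"
    if hasattr(target, "write"):
        target.write(text)  # type: ignore[union-attr]
    else:
        Path(target).write_text(text)


def read_pathway_json(
    source: str | Path | IO[str],
    ubiquitous_list: Iterable[str] | None = None,
) -> PathwayHypergraph:
    """Read a pathway from plain JSON.

    Two dialects are accepted: a *raw* pathway (reactions with a
    ``reversible`` flag, to be filtered and expanded here) and the
    *expanded* dialect written by :func:`write_pathway_json`, marked
    with ``"expanded": true``, which is loaded verbatim.
    """
    if hasattr(source, "read"):
        obj = json.load(source)  # type: ignore[arg-type]
    else:
        obj = json.loads(Path(source).read_text())
    pid = str(obj.get("id", "pathway"))
    if obj.get("expanded"):
        reactions = {}
        for r in obj["reactions"]:
            rxn = Reaction(
                id=str(r["id"]),
                inputs=frozenset(r.get("inputs", ())),
                outputs=frozenset(r.get("outputs", ())),
                enzymes=tuple(ECNumber.parse(e) for e in r.get("ec", ())),
                reversible=bool(r.get("reversible", False)),
                is_backward=bool(r.get("is_backward", False)),
            )
            if rxn.id in reactions:
                raise PathwayError(f"duplicate reaction id: {rxn.id}")
            reactions[rxn.id] = rxn
        names = {c["id"]: c.get("name") for c in obj.get("compounds", ())}
        compounds = {
            cid: Compound(cid, names.get(cid))
            for r in reactions.values()
            for cid in r.inputs | r.outputs
        }
        H = PathwayHypergraph(
            id=pid,
            compounds=compounds,
            reactions=reactions,
            ubiquitous_filter=frozenset(obj.get("ubiquitous_filter", ())),
        )
        H.validate()
        return H
    if ubiquitous_list is None:
        ubiquitous_list = obj.get("ubiquitous_filter", DEFAULT_UBIQUITOUS)
    records = [RawReactionRecord.from_dict(r) for r in obj["reactions"]]
    return build_hypergraph(records, ubiquitous_list, pathway_id=pid)


# --------------------------------------------------------------------------
# KGML (KEGG XML)
# --------------------------------------------------------------------------

_COMPOUND_PREFIXES = ("cpd:", "gl:", "dr:")


def _strip_compound_prefix(name: str) -> str:
    for prefix in _COMPOUND_PREFIXES:
        if name.startswith(prefix):
            return name[len(prefix):]
    return name


def parse_kgml(source: str | Path | IO) -> list[RawReactionRecord]:
    """Parse a KGML document into raw reaction records.

    Substrate/product compound ids are taken from the ``name`` attribute
    of the substrate/product elements (falling back to the referenced
    compound entry); EC numbers come from enzyme entries whose
    ``reaction`` attribute names the reaction.  Reactions with neither
    substrates nor products are skipped with a warning.  Malformed XML
    raises :class:`lxml.etree.XMLSyntaxError`.
    """
    tree = etree.parse(str(source) if isinstance(source, Path) else source)
    root = tree.getroot()

    entry_compound: dict[str, str] = {}
    reaction_ecs: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        etype = entry.get("type")
        name = entry.get("name", "")
        if etype == "compound":
            first = name.split()[0] if name.split() else ""
            if first:
                entry_compound[entry.get("id", "")] = _strip_compound_prefix(first)
        elif etype in ("enzyme", "ortholog", "gene"):
            reaction_attr = entry.get("reaction")
            if not reaction_attr:
                continue
            ecs = [tok[3:] for tok in name.split() if tok.startswith("ec:")]
            for rname in reaction_attr.split():
                reaction_ecs.setdefault(rname, []).extend(ecs)

    def compound_of(element: etree._Element) -> str | None:
        name = element.get("name")
        if name:
            return _strip_compound_prefix(name.split()[0])
        return entry_compound.get(element.get("id", ""))

    records: list[RawReactionRecord] = []
    for rxn in root.findall("reaction"):
        substrates = [c for c in map(compound_of, rxn.findall("substrate")) if c]
        products = [c for c in map(compound_of, rxn.findall("product")) if c]
        if not substrates and not products:
            logger.warning(
                "skipping KGML reaction %s: no substrates or products",
                rxn.get("name", rxn.get("id", "?")),
            )
            continue
        reversible = rxn.get("type") == "reversible"
        for rname in rxn.get("name", "").split() or [f"reaction{rxn.get('id', '')}"]:
            rid = rname.split(":", 1)[-1]
            records.append(
                RawReactionRecord(
                    id=rid,
                    inputs=tuple(dict.fromkeys(substrates)),
                    outputs=tuple(dict.fromkeys(products)),
                    enzymes=tuple(dict.fromkeys(reaction_ecs.get(rname, ()))),
                    reversible=reversible,
                )
            )
    return records


def read_kgml(
    source: str | Path | IO,
    ubiquitous_list: Iterable[str] = DEFAULT_UBIQUITOUS,
    pathway_id: str | None = None,
) -> PathwayHypergraph:
    """Parse KGML and build the hypergraph in one step."""
    if pathway_id is None:
        try:
            tree = etree.parse(str(source) if isinstance(source, Path) else source)
            pathway_id = tree.getroot().get("name", "pathway").split(":")[-1]
            if hasattr(source, "seek"):
                source.seek(0)  # type: ignore[union-attr]
        except etree.XMLSyntaxError:
            raise
    records = parse_kgml(source)
    return build_hypergraph(records, ubiquitous_list, pathway_id=pathway_id)


def write_kgml(H: PathwayHypergraph, target: str | Path | IO[bytes]) -> None:
    """Write a minimal KGML document for a built hypergraph.

    Backward copies of reversible reactions are folded back into a
    single ``type="reversible"`` KGML reaction.
    """
    root = etree.Element("pathway", name=f"path:{H.id}")
    next_id = 1
    compound_entry: dict[str, str] = {}
    for cid in sorted(H.compounds):
        eid = str(next_id)
        next_id += 1
        compound_entry[cid] = eid
        etree.SubElement(root, "entry", id=eid, name=f"cpd:{cid}", type="compound")
    forward = [r for r in sorted(H.reactions.values(), key=lambda r: r.id)
               if not r.is_backward]
    for rxn in forward:
        if rxn.enzymes:
            etree.SubElement(
                root,
                "entry",
                id=str(next_id),
                name=" ".join(f"ec:{e}" for e in rxn.enzymes),
                type="enzyme",
                reaction=f"rn:{rxn.id}",
            )
            next_id += 1
    for rxn in forward:
        el = etree.SubElement(
            root,
            "reaction",
            id=str(next_id),
            name=f"rn:{rxn.id}",
            type="reversible" if rxn.reversible else "irreversible",
        )
        next_id += 1
        for cid in sorted(rxn.inputs):
            etree.SubElement(el, "substrate", id=compound_entry[cid], name=f"cpd:{cid}")
        for cid in sorted(rxn.outputs):
            etree.SubElement(el, "product", id=compound_entry[cid], name=f"cpd:{cid}")
    data = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
    if hasattr(target, "write"):
        target.write(data)  # type: ignore[union-attr]
    else:
        Path(target).write_bytes(data)
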