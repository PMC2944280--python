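"""KGML (KEGG pathway markup) reader.

KGML is explicit where GPML is pictorial: ``entry`` elements carry gene
ids directly (an entry may list several genes — a family box), and
``relation`` elements connect entries. The reader maps relation subtypes
onto the three-relation formalization: activation/expression become
*activate*, inhibition/repression become *inhibit*, everything else
(state changes with no sign, missing subtypes) is *neutral*. Enzyme-
enzyme relations (ECrel) are metabolic adjacency — proteins catalyzing
consecutive steps — and are always neutral. When a metabolic file has no
relation elements at all, adjacency is recovered from ``reaction``
elements: two enzymes whose reactions share a compound (product of one,
substrate of the other) form a neutral pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from xml.etree import ElementTree as ET

from .core import GeneNode, Pathway, Relation, finalize_pathway

log = logging.getLogger(__name__)

__all__ = ["KgmlEntry", "EntryType", "parse_kgml", "DEFAULT_ORGANISM"]

DEFAULT_ORGANISM = "hsa"

#: subtype name -> relation sign; names not listed fall back to neutral.
_SUBTYPE_RELATIONS = {
    "activation": Relation.ACTIVATE,
    "expression": Relation.ACTIVATE,
    "inhibition": Relation.INHIBIT,
    "repression": Relation.INHIBIT,
}


class EntryType(str, Enum):
    GENE = "gene"
    GROUP = "group"
    COMPOUND = "compound"
    MAP = "map"
    OTHER = "other"


@dataclass
class KgmlEntry:
    entry_id: str
    entry_type: EntryType
    gene_ids: list[int] = field(default_factory=list)
    component_ids: list[str] = field(default_factory=list)
    reaction: str | None = None


def _entry_gene_ids(name: str, organism: str, warnings: list[str]) -> list[int]:
    """Strip 'hsa:7157'-style tokens to numeric ids, skipping other taxa."""
    ids: list[int] = []
    for token in name.split():
        prefix, _, num = token.partition(":")
        if not num:
            continue
        if prefix != organism:
            warnings.append(f"entry gene {token!r} not in organism {organism!r}; skipped")
            log.warning("entry gene %r not in organism %r; skipped", token, organism)
            continue
        if num.isdigit():
            ids.append(int(num))
    return ids


def _relation_sign(rel_type: str, subtypes: list[str]) -> Relation:
    if rel_type == "ECrel":
        return Relation.NEUTRAL
    for s in subtypes:
        sign = _SUBTYPE_RELATIONS.get(s.strip().lower())
        if sign is not None:
            return sign
    return Relation.NEUTRAL


def parse_kgml(document: str | Path, organism: str = DEFAULT_ORGANISM,
               database: str = "KEGG", pathway_id: str | None = None) -> Pathway:
    """Parse one KGML document into a finalized :class:`Pathway`.

    Group entries expand to the union of their components' genes; a
    relation between entries expands to the cross product of the two
    entries' gene lists. Relations touching non-gene entries (compounds,
    map links) are skipped with a warning.
    """
    text = str(document)
    if "<" not in text:
        text = Path(document).read_text(encoding="utf-8")
    root = ET.fromstring(text)
    if root.tag != "pathway":
        raise ValueError(f"not a KGML document (root element {root.tag!r})")
    title = root.attrib.get("title") or root.attrib.get("name", "")
    if not title:
        raise ValueError("KGML document has no pathway title")

    warnings: list[str] = []
    entries: dict[str, KgmlEntry] = {}
    for el in root.findall("entry"):
        etype_raw = el.attrib.get("type", "other")
        try:
            etype = EntryType(etype_raw)
        except ValueError:
            etype = EntryType.OTHER
        entry = KgmlEntry(
            entry_id=el.attrib["id"],
            entry_type=etype,
            component_ids=[c.attrib["id"] for c in el.findall("component")],
            reaction=el.attrib.get("reaction"),
        )
        if etype == EntryType.GENE:
            entry.gene_ids = _entry_gene_ids(el.attrib.get("name", ""),
                                             organism, warnings)
        entries[entry.entry_id] = entry

    def genes_of(entry_id: str, seen: frozenset[str] = frozenset()) -> list[int]:
        e = entries.get(entry_id)
        if e is None or entry_id in seen:
            return []
        if e.entry_type == EntryType.GROUP:
            out: list[int] = []
            for cid in e.component_ids:
                for gid in genes_of(cid, seen | {entry_id}):
                    if gid not in out:
                        out.append(gid)
            return out
        return list(e.gene_ids)

    def endpoint(entry_id: str) -> GroupOrNone:
        gids = genes_of(entry_id)
        if not gids:
            return None
        return tuple(GeneNode(f"entry:{entry_id}", gid) for gid in gids)

    relations = []
    rel_elements = root.findall("relation")
    for rel in rel_elements:
        e1, e2 = rel.attrib.get("entry1"), rel.attrib.get("entry2")
        rel_type = rel.attrib.get("type", "")
        subtypes = [s.attrib.get("name", "") for s in rel.findall("subtype")]
        g1, g2 = endpoint(e1), endpoint(e2)
        if g1 is None or g2 is None:
            warnings.append(f"relation {e1}->{e2} touches a non-gene entry; skipped")
            log.warning("relation %s->%s touches a non-gene entry; skipped", e1, e2)
            continue
        relations.append((_as_group(g1), _as_group(g2),
                          _relation_sign(rel_type, subtypes)))

    # Metabolic fallback: without explicit relations, derive enzyme
    # adjacency from shared reaction compounds (product of one step is
    # substrate of the next).
    if not rel_elements:
        relations.extend(_reaction_adjacency(root, entries, genes_of))

    nodes = [GeneNode(f"entry:{e.entry_id}", gid)
             for e in entries.values() if e.entry_type == EntryType.GENE
             for gid in e.gene_ids]
    return finalize_pathway(title, database, nodes=nodes, relations=relations,
                            pathway_id=pathway_id)


GroupOrNone = tuple | None


def _as_group(nodes: tuple[GeneNode, ...]):
    from .core import GroupNode
    if len(nodes) == 1:
        return nodes[0]
    return GroupNode(nodes[0].label, nodes)


def _reaction_adjacency(root: ET.Element, entries: dict[str, KgmlEntry],
                        genes_of) -> list[tuple]:
    """Neutral enzyme-enzyme pairs from consecutive reactions."""
    substrates: dict[str, set[str]] = {}
    products: dict[str, set[str]] = {}
    for rx in root.findall("reaction"):
        name = rx.attrib.get("name", rx.attrib.get("id", ""))
        substrates[name] = {s.attrib.get("name", "") for s in rx.findall("substrate")}
        products[name] = {p.attrib.get("name", "") for p in rx.findall("product")}
        if rx.attrib.get("type") == "reversible":
            substrates[name] |= products[name]
            products[name] |= substrates[name]

    by_reaction: dict[str, list[str]] = {}
    for e in entries.values():
        if e.reaction and e.entry_type == EntryType.GENE:
            for rname in e.reaction.split():
                by_reaction.setdefault(rname, []).append(e.entry_id)

    relations = []
    names = sorted(substrates)
    for i, r1 in enumerate(names):
        for r2 in names:
            if r1 == r2:
                continue
            if products.get(r1, set()) & substrates.get(r2, set()):
                for eid1 in by_reaction.get(r1, []):
                    for eid2 in by_reaction.get(r2, []):
                        g1, g2 = genes_of(eid1), genes_of(eid2)
                        if not g1 or not g2 or eid1 == eid2:
                            continue
                        relations.append((
                            _as_group(tuple(GeneNode(f"entry:{eid1}", g) for g in g1)),
                            _as_group(tuple(GeneNode(f"entry:{eid2}", g) for g in g2)),
                            Relation.NEUTRAL,
                        ))
    return relations
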