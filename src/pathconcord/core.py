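"""Common pathway formalization shared by every parser and metric.

A pathway, whatever its source (a WikiPathways diagram, a KEGG KGML file,
a hand-curated table), is reduced to two features: the set of genes it
contains and the set of directed gene-gene relationships among them, each
relationship being one of *activate*, *inhibit* or *neutral* (the neutral
case covers metabolic adjacency, where two enzymes catalyze consecutive
steps without either activating or inhibiting the other).

Gene identity is the numeric NCBI Gene ID. Source labels (symbols, protein
names) are resolved through an offline symbol-to-id mapping table; diagram
symbols standing for protein families ("group nodes") are expanded so that
a relation between a 3-gene family and a 2-gene family becomes the full
cross product of 6 gene-level relations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Relation",
    "GeneNode",
    "GroupNode",
    "GenePair",
    "Pathway",
    "PathwayDatabase",
    "GeneMapping",
    "normalize_gene",
    "expand_group_relation",
    "pair_key",
    "finalize_pathway",
    "read_pathways_tsv",
]


class Relation(str, Enum):
    """The three admissible gene-gene relationship types."""

    ACTIVATE = "activate"
    INHIBIT = "inhibit"
    NEUTRAL = "neutral"

    @classmethod
    def from_string(cls, text: str) -> "Relation":
        t = text.strip().lower()
        for member in cls:
            if member.value == t:
                return member
        raise ValueError(f"unknown relation {text!r}; expected one of "
                         f"{[m.value for m in cls]}")


@dataclass(frozen=True)
class GeneNode:
    """A pathway node resolved (or to be resolved) to a numeric gene id.

    ``x``/``y`` hold layout coordinates in pixels for spatial sources such
    as GPML and are absent for non-spatial sources.
    """

    label: str
    gene_id: int | None = None
    x: float | None = None
    y: float | None = None

    @property
    def resolved(self) -> bool:
        return self.gene_id is not None and self.gene_id > 0


@dataclass(frozen=True)
class GroupNode:
    """A symbol standing for a protein family/class: one label, many genes."""

    label: str
    members: tuple[GeneNode, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.label!r} has no members")

    @property
    def gene_ids(self) -> tuple[int, ...]:
        return tuple(m.gene_id for m in self.members if m.resolved)


@dataclass(frozen=True)
class GenePair:
    """A directed interacting gene pair with provenance.

    ``relation`` distinguishes activation from inhibition; metabolic
    adjacency is recorded as neutral. Overlap counting across databases
    uses :func:`pair_key`, which deliberately ignores both direction and
    relation type.
    """

    source_gene_id: int
    target_gene_id: int
    relation: Relation
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.source_gene_id <= 0 or self.target_gene_id <= 0:
            raise ValueError("gene ids in a pair must be positive integers")
        if not isinstance(self.relation, Relation):
            object.__setattr__(self, "relation", Relation.from_string(str(self.relation)))


PairKey = tuple[int, int]


def pair_key(p: GenePair) -> PairKey:
    """Canonical overlap key: the unordered gene-id pair.

    The relation type is not part of the key — two databases asserting
    opposite relations on the same gene pair still share that pair (the
    conflict is surfaced at merge time, not hidden at counting time).
    """
    a, b = p.source_gene_id, p.target_gene_id
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Pathway:
    """A finalized pathway: name, source database, genes and expanded pairs.

    Invariants enforced at construction: every gene id referenced by a
    pair is a member of ``genes``; pairs are duplicate-free under the
    directed (source, target, relation) triple.
    """

    pathway_id: str
    name: str
    database: str
    genes: frozenset[int]
    pairs: tuple[GenePair, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, Relation]] = set()
        for p in self.pairs:
            if p.source_gene_id not in self.genes or p.target_gene_id not in self.genes:
                raise ValueError(
                    f"pathway {self.name!r}: pair {p.source_gene_id}->{p.target_gene_id} "
                    "references a gene not in the gene set")
            triple = (p.source_gene_id, p.target_gene_id, p.relation)
            if triple in seen:
                raise ValueError(f"pathway {self.name!r}: duplicate pair {triple}")
            seen.add(triple)

    @property
    def pair_keys(self) -> frozenset[PairKey]:
        return frozenset(pair_key(p) for p in self.pairs)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class PathwayDatabase:
    """A named collection of pathways with unique ids and names."""

    name: str
    pathways: list[Pathway] = field(default_factory=list)

    def add(self, pathway: Pathway) -> None:
        if any(p.pathway_id == pathway.pathway_id for p in self.pathways):
            raise ValueError(f"duplicate pathway id {pathway.pathway_id!r} "
                             f"in database {self.name!r}")
        if any(p.name == pathway.name for p in self.pathways):
            raise ValueError(f"duplicate pathway name {pathway.name!r} "
                             f"in database {self.name!r}")
        self.pathways.append(pathway)

    def get(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)


class GeneMapping:
    """Offline symbol -> NCBI Gene ID mapping table.

    Lookups are case-insensitive and whitespace-trimmed. A symbol may map
    to several ids (e.g. MDM1 -> 252867 and 56890); all are returned, in
    table order. The reverse direction (:meth:`symbol_of`) returns the
    first symbol in table order mapped to an id.
    """

    def __init__(self, rows: Iterable[tuple[str, int]] = ()) -> None:
        self.rows: list[tuple[str, int]] = []
        self._by_symbol: dict[str, list[int]] = {}
        self._by_id: dict[int, str] = {}
        for symbol, gid in rows:
            self.add(symbol, int(gid))

    @staticmethod
    def _norm(symbol: str) -> str:
        return symbol.strip().upper()

    def add(self, symbol: str, gene_id: int) -> None:
        if gene_id <= 0:
            raise ValueError(f"gene id must be positive, got {gene_id}")
        key = self._norm(symbol)
        self.rows.append((symbol.strip(), gene_id))
        ids = self._by_symbol.setdefault(key, [])
        if gene_id not in ids:
            ids.append(gene_id)
        self._by_id.setdefault(gene_id, symbol.strip())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneMapping":
        """Read a two-column ``symbol<TAB>gene_id`` table ('#' comments)."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["symbol", "gene_id"], dtype={"symbol": str})
        return cls((str(s), int(g)) for s, g in zip(df["symbol"], df["gene_id"]))

    def lookup(self, label: str) -> list[int]:
        return list(self._by_symbol.get(self._norm(label), []))

    def symbol_of(self, gene_id: int) -> str:
        return self._by_id.get(gene_id, str(gene_id))

    def __len__(self) -> int:
        return len(self.rows)


def normalize_gene(label: str, mapping: GeneMapping) -> list[int]:
    """Resolve a source text label to its numeric gene ids.

    Returns every id the (case-folded, trimmed) label maps to; an empty
    list if unmapped, in which case the caller decides whether to skip
    the node (real diagrams contain metabolites and free-text labels).
    """
    if not label or not label.strip():
        raise ValueError("empty gene label")
    ids = mapping.lookup(label)
    if not ids:
        log.warning("unmapped gene label %r (skipped)", label)
    return ids


Endpoint = Union[GeneNode, GroupNode]


def _endpoint_nodes(e: Endpoint) -> tuple[GeneNode, ...]:
    if isinstance(e, GroupNode):
        return e.members
    return (e,)


def expand_group_relation(a: Endpoint, b: Endpoint, relation: Relation,
                          provenance: str = "") -> list[GenePair]:
    """Expand a relation between two family symbols into gene-level pairs.

    A relation between a group of |A| genes and a group of |B| genes
    stands for the full cross product: |A| * |B| gene pairs, all carrying
    the given relation. Plain gene nodes behave as singleton groups.
    """
    na = _endpoint_nodes(a)
    nb = _endpoint_nodes(b)
    if not na or not nb:
        raise ValueError("cannot expand a relation touching an empty group")
    unresolved = [n.label for n in (*na, *nb) if not n.resolved]
    if unresolved:
        raise ValueError(f"cannot expand relation with unresolved nodes: {unresolved}")
    return [
        GenePair(src.gene_id, tgt.gene_id, relation, provenance)
        for src in na for tgt in nb
    ]


def finalize_pathway(
    name: str,
    database: str,
    nodes: Iterable[GeneNode] = (),
    groups: Iterable[GroupNode] = (),
    relations: Iterable[tuple[Endpoint, Endpoint, Relation]] = (),
    pathway_id: str | None = None,
) -> Pathway:
    """Assemble a :class:`Pathway` from raw parser output.

    Gene set = every resolved gene id among the nodes, the group members
    and the relation endpoints; pair set = all relations expanded through
    :func:`expand_group_relation` and deduplicated on the directed
    (source, target, relation) triple. Unresolved standalone nodes are
    skipped with a warning; unresolved relation endpoints are an error
    (the relation would silently lose genes otherwise).
    """
    genes: set[int] = set()
    for n in nodes:
        if n.resolved:
            genes.add(n.gene_id)
        else:
            log.warning("pathway %r: dropping unresolved node %r", name, n.label)
    for g in groups:
        genes.update(g.gene_ids)

    pairs: list[GenePair] = []
    seen: set[tuple[int, int, Relation]] = set()
    for a, b, rel in relations:
        for p in expand_group_relation(a, b, rel, provenance=database):
            triple = (p.source_gene_id, p.target_gene_id, p.relation)
            if triple in seen:
                continue
            seen.add(triple)
            pairs.append(p)
            genes.add(p.source_gene_id)
            genes.add(p.target_gene_id)

    return Pathway(
        pathway_id=pathway_id if pathway_id is not None else name,
        name=name,
        database=database,
        genes=frozenset(genes),
        pairs=tuple(pairs),
    )


def _parse_label(label: str, mapping: GeneMapping) -> Endpoint | None:
    """Turn a tabular label into a GeneNode or GroupNode.

    Group syntax: ``FAMILY=SYM1|SYM2|...``. A plain symbol mapping to
    several gene ids is treated as an implicit group of all its ids.
    """
    label = label.strip()
    if "=" in label:
        fam, _, members = label.partition("=")
        nodes: list[GeneNode] = []
        for sym in members.split("|"):
            for gid in normalize_gene(sym, mapping):
                nodes.append(GeneNode(sym.strip(), gid))
        if not nodes:
            return None
        return GroupNode(fam.strip(), tuple(nodes))
    ids = normalize_gene(label, mapping)
    if not ids:
        return None
    if len(ids) == 1:
        return GeneNode(label, ids[0])
    return GroupNode(label, tuple(GeneNode(label, gid) for gid in ids))


def read_pathways_tsv(path: str | Path, mapping: GeneMapping,
                      database: str) -> PathwayDatabase:
    """Import the generic tabular pathway format.

    Columns: ``pathway_name, source_label, target_label, relation`` with
    relation in {activate, inhibit, neutral}. A row with an empty target
    declares genes only. This format stands in for manually curated
    sources that have no machine-readable export.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=0,
                     keep_default_na=False, dtype=str)
    expected = ["pathway_name", "source_label", "target_label", "relation"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")

    db = PathwayDatabase(database)
    for pname, chunk in df.groupby("pathway_name", sort=False):
        nodes: list[GeneNode] = []
        groups: list[GroupNode] = []
        relations: list[tuple[Endpoint, Endpoint, Relation]] = []
        for _, row in chunk.iterrows():
            src = _parse_label(row["source_label"], mapping)
            if src is None:
                continue
            if not row["target_label"].strip():
                (groups if isinstance(src, GroupNode) else nodes).append(src)
                continue
            tgt = _parse_label(row["target_label"], mapping)
            if tgt is None:
                continue
            relations.append((src, tgt, Relation.from_string(row["relation"])))
        db.add(finalize_pathway(str(pname), database, nodes, groups, relations))
    return db
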