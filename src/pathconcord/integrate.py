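"""Integrated pathway store: merging, provenance, and the query surface.

Matched pathways from different databases are union-merged: every gene
and every pair of every member survives, each annotated with the set of
contributing databases. When two sources assert contradictory relations
on the same gene pair (one says activate, the other inhibit) *both* are
kept and a :class:`RelationConflict` is recorded — the store surfaces
disagreement instead of silently picking a winner.

:class:`PathwayStore` loads databases into memory, assigns global
numeric pathway ids, and answers the JSON-shaped queries (gene lookup,
pathway search, interaction listing, pathway diff). All list outputs are
ordered ascending by numeric id, then lexicographically, so serialized
results are byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core import (
    GeneMapping,
    GenePair,
    PairKey,
    Pathway,
    PathwayDatabase,
    Relation,
    pair_key,
)
from .metrics import _UnionFind

__all__ = [
    "IntegratedPair",
    "RelationConflict",
    "IntegratedPathway",
    "merge_class",
    "PathwayStore",
]


@dataclass(frozen=True)
class IntegratedPair:
    """A canonical gene pair in the merged store, with full provenance."""

    key: PairKey
    relations: frozenset[Relation]
    databases: frozenset[str]


@dataclass(frozen=True)
class RelationConflict:
    """Contradictory relations asserted on one gene pair.

    Recorded only when at least two distinct non-neutral relations are
    asserted (activate vs inhibit); a neutral assertion alongside a
    signed one is under-specification, not contradiction.
    """

    key: PairKey
    relations_by_db: tuple[tuple[str, tuple[str, ...]], ...]


@dataclass
class IntegratedPathway:
    class_id: int
    name: str
    members: list[Pathway]
    genes: frozenset[int]
    pairs: list[IntegratedPair]
    conflicts: list[RelationConflict] = field(default_factory=list)

    @property
    def databases(self) -> list[str]:
        return sorted({m.database for m in self.members})


def merge_class(members: Sequence[Pathway], class_id: int = 0) -> IntegratedPathway:
    """Union-merge the pathways of one match class.

    The merged gene set is the union of the members' gene sets; merged
    pairs are keyed canonically, carrying every asserted relation and
    every contributing database.
    """
    if not members:
        raise ValueError("cannot merge an empty pathway class")
    genes: set[int] = set()
    rels: dict[PairKey, dict[str, set[Relation]]] = {}
    for m in members:
        genes |= m.genes
        for p in m.pairs:
            k = pair_key(p)
            rels.setdefault(k, {}).setdefault(m.database, set()).add(p.relation)

    pairs: list[IntegratedPair] = []
    conflicts: list[RelationConflict] = []
    for k in sorted(rels):
        by_db = rels[k]
        all_rel = frozenset(r for rs in by_db.values() for r in rs)
        pairs.append(IntegratedPair(k, all_rel, frozenset(by_db)))
        signed = {r for r in all_rel if r != Relation.NEUTRAL}
        if len(signed) >= 2:
            conflicts.append(RelationConflict(
                k, tuple((db, tuple(sorted(r.value for r in rs)))
                         for db, rs in sorted(by_db.items()))))
    return IntegratedPathway(class_id, members[0].name, list(members),
                             frozenset(genes), pairs, conflicts)


def _relation_label(rel: Relation) -> str:
    return rel.value.capitalize()


class PathwayStore:
    """In-memory pathway store with global numeric ids and JSON queries.

    The store replaces a hosted web cache with an explicit, local,
    reproducible object: databases are imported once, ids are assigned
    sequentially in import order, and every query is a pure function of
    the loaded state.
    """

    def __init__(self, mapping: GeneMapping | None = None) -> None:
        self.mapping = mapping or GeneMapping()
        self.databases: dict[str, PathwayDatabase] = {}
        self._pathways: dict[int, Pathway] = {}
        self._next_id = 1

    # -- loading ---------------------------------------------------------
    def add_database(self, db: PathwayDatabase) -> None:
        if db.name in self.databases:
            raise ValueError(f"database {db.name!r} already loaded")
        self.databases[db.name] = db
        for p in db:
            self._pathways[self._next_id] = p
            self._next_id += 1

    def numeric_id(self, pathway: Pathway) -> int:
        for pid, p in self._pathways.items():
            if p is pathway or (p.database == pathway.database
                                and p.pathway_id == pathway.pathway_id):
                return pid
        raise KeyError(pathway.pathway_id)

    def pathway(self, numeric_id: int) -> Pathway:
        try:
            return self._pathways[int(numeric_id)]
        except KeyError:
            raise KeyError(f"no pathway with id {numeric_id}") from None

    def symbol_of(self, gene_id: int) -> str:
        return self.mapping.symbol_of(gene_id)

    # -- queries (JSON shapes) -------------------------------------------
    def get_databases(self) -> list[str]:
        return list(self.databases)

    def get_gene(self, symbol: str) -> list[list[str]]:
        """``[[symbol, gene_id], ...]`` for every id the symbol maps to."""
        ids = self.mapping.lookup(symbol)
        sym = symbol.strip()
        canonical = next((s for s, g in self.mapping.rows
                          if s.upper() == sym.upper()), sym)
        return [[canonical, str(gid)] for gid in ids]

    def get_db_pathways(self, database_name: str) -> dict[str, dict[str, str]]:
        """``{"<id>": {"DatabaseName": ..., "PathwayName": ...}, ...}``."""
        db = self.databases.get(database_name)
        if db is None:
            return {}
        return {
            str(pid): {"DatabaseName": database_name, "PathwayName": p.name}
            for pid, p in sorted(self._pathways.items())
            if p.database == database_name
        }

    def get_pathway(self, name_fragment: str) -> list[list[str]]:
        """Case-insensitive substring search: ``[[name, database, id], ...]``."""
        frag = name_fragment.casefold()
        return [[p.name, p.database, str(pid)]
                for pid, p in sorted(self._pathways.items())
                if frag in p.name.casefold()]

    def get_pathway_genes(self, pathway_id: int) -> dict[str, str]:
        p = self.pathway(pathway_id)
        return {str(gid): self.symbol_of(gid) for gid in sorted(p.genes)}

    def get_gene_pathways(self, gene_id: int) -> dict[str, str]:
        return {str(pid): p.name for pid, p in sorted(self._pathways.items())
                if int(gene_id) in p.genes}

    def get_pathway_interactions(self, pathway_id: int) -> list[list[str]]:
        """``[[src_id, src_symbol, tgt_id, tgt_symbol, "Activate"], ...]``."""
        p = self.pathway(pathway_id)
        rows = [[str(pr.source_gene_id), self.symbol_of(pr.source_gene_id),
                 str(pr.target_gene_id), self.symbol_of(pr.target_gene_id),
                 _relation_label(pr.relation)] for pr in p.pairs]
        rows.sort(key=lambda r: (int(r[0]), int(r[2]), r[4]))
        return rows

    def _pair_label(self, key: PairKey) -> str:
        return f"{self.symbol_of(key[0])}_{self.symbol_of(key[1])}"

    def get_pathway_diff(self, id1: int, id2: int) -> list[list[str]]:
        """Four arrays: genes only in 1, genes only in 2, pairs only in 1,
        pairs only in 2 (pairs serialized ``SYM1_SYM2`` on canonical keys)."""
        p1, p2 = self.pathway(id1), self.pathway(id2)
        genes_1 = [self.symbol_of(g) for g in sorted(p1.genes - p2.genes)]
        genes_2 = [self.symbol_of(g) for g in sorted(p2.genes - p1.genes)]
        pairs_1 = [self._pair_label(k) for k in sorted(p1.pair_keys - p2.pair_keys)]
        pairs_2 = [self._pair_label(k) for k in sorted(p2.pair_keys - p1.pair_keys)]
        return [genes_1, genes_2, pairs_1, pairs_2]

    # -- merging ---------------------------------------------------------
    def merge(self, match_reports: Iterable) -> list[IntegratedPathway]:
        """Union-merge every match class implied by the confirmed matches."""
        uf = _UnionFind()
        for pid in self._pathways:
            uf.find(pid)
        for report in match_reports:
            for m in report.matches:
                uf.union(self.numeric_id(m.pathway_a), self.numeric_id(m.pathway_b))
        classes: dict[int, list[int]] = {}
        for pid in sorted(self._pathways):
            classes.setdefault(uf.find(pid), []).append(pid)
        return [merge_class([self._pathways[pid] for pid in members], class_id=root)
                for root, members in sorted(classes.items())]

    # -- persistence -----------------------------------------------------
    def to_json(self) -> dict:
        return {
            "mapping": [[s, g] for s, g in self.mapping.rows],
            "databases": [
                {
                    "name": db.name,
                    "pathways": [
                        {
                            "pathway_id": p.pathway_id,
                            "name": p.name,
                            "genes": sorted(p.genes),
                            "pairs": [[pr.source_gene_id, pr.target_gene_id,
                                       pr.relation.value] for pr in p.pairs],
                        }
                        for p in db
                    ],
                }
                for db in self.databases.values()
            ],
        }

    @classmethod
    def from_json(cls, payload: dict) -> "PathwayStore":
        store = cls(GeneMapping((s, int(g)) for s, g in payload.get("mapping", [])))
        for dbj in payload.get("databases", []):
            db = PathwayDatabase(dbj["name"])
            for pj in dbj["pathways"]:
                db.add(Pathway(
                    pathway_id=pj["pathway_id"], name=pj["name"],
                    database=dbj["name"], genes=frozenset(pj["genes"]),
                    pairs=tuple(GenePair(s, t, Relation(r), provenance=dbj["name"])
                                for s, t, r in pj["pairs"])))
            store.add_database(db)
        return store

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PathwayStore":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))

    def export_tsv(self, path: str | Path) -> None:
        """Flat dump: one row per pair, ``database pathway src tgt relation``."""
        lines = ["database\tpathway\tsource_gene_id\ttarget_gene_id\trelation"]
        for pid, p in sorted(self._pathways.items()):
            for pr in p.pairs:
                lines.append(f"{p.database}\t{p.name}\t{pr.source_gene_id}"
                             f"\t{pr.target_gene_id}\t{pr.relation.value}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
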