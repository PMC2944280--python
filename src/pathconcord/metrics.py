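"""Consistency and comprehensiveness statistics.

For a matched pathway pair the *agreement count* is the size of the
gene (or canonical gene-pair) intersection, and the *agreement
percentage* divides that count by the smaller of the two set sizes,
rounded half-up to an integer percent. The per-metric minimum is the
natural denominator: it asks "of the genes the more conservative
curator committed to, how many does the other database confirm?".

Database-level comprehensiveness uses two scores. The *pathway
comprehensive score* groups pathways into cross-database equivalence
classes (union-find over confirmed matches) and scores each database by
the fraction of classes it hosts. The *gene pair coverage score* is the
fraction of the union of all canonical gene-pair keys a database hosts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .core import Pathway, PathwayDatabase

log = logging.getLogger(__name__)

__all__ = [
    "round_half_up_pct",
    "agreement_pct",
    "gene_agreement",
    "pair_agreement",
    "AgreementRow",
    "consistency_table",
    "ComprehensivenessReport",
    "pathway_comprehensive_score",
    "gene_pair_coverage_score",
    "venn_summary",
]


def round_half_up_pct(count: int, denominator: int) -> int:
    """``100 * count / denominator`` rounded half-up to an integer.

    Banker's rounding (Python's built-in ``round``) would send 7.5% to
    8% but 12.5% to 12%; half-up is the convention that reproduces
    hand-computed report tables.
    """
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    return int((Decimal(100) * Decimal(count) / Decimal(denominator))
               .quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def agreement_pct(overlap: int, count_a: int, count_b: int) -> int:
    """Agreement percentage from printed-style counts.

    Validates the basic set identity ``overlap <= min(count_a, count_b)``
    — an overlap exceeding the smaller set is impossible and indicates
    corrupt source data.
    """
    if count_a <= 0 or count_b <= 0:
        raise ValueError("agreement percentage undefined for an empty set")
    m = min(count_a, count_b)
    if overlap < 0 or overlap > m:
        raise ValueError(
            f"overlap {overlap} exceeds the smaller set size {m}: inconsistent counts")
    return round_half_up_pct(overlap, m)


def gene_agreement(p1: Pathway, p2: Pathway) -> tuple[int, int]:
    """(count, percentage) of genes shared by the two pathways."""
    if p1.n_genes == 0 or p2.n_genes == 0:
        raise ValueError("gene agreement undefined for a pathway with no genes")
    count = len(p1.genes & p2.genes)
    return count, agreement_pct(count, p1.n_genes, p2.n_genes)


def pair_agreement(p1: Pathway, p2: Pathway) -> tuple[int, int]:
    """(count, percentage) of canonical gene-pair keys shared."""
    if p1.n_pairs == 0 or p2.n_pairs == 0:
        raise ValueError("pair agreement undefined for a pathway with no pairs")
    count = len(p1.pair_keys & p2.pair_keys)
    return count, agreement_pct(count, len(p1.pair_keys), len(p2.pair_keys))


@dataclass
class AgreementRow:
    """One row of a cross-database consistency table."""

    name_a: str
    name_b: str
    gene_count_a: int
    gene_count_b: int
    pair_count_a: int
    pair_count_b: int
    gene_overlap_count: int
    gene_overlap_pct: int
    pair_overlap_count: int | None
    pair_overlap_pct: int | None

    @property
    def gene_counts_cell(self) -> str:
        return f"{self.gene_count_a} vs {self.gene_count_b}"

    @property
    def pair_counts_cell(self) -> str:
        return f"{self.pair_count_a} vs {self.pair_count_b}"

    @property
    def gene_overlap_cell(self) -> str:
        return f"{self.gene_overlap_count}({self.gene_overlap_pct}%)"

    @property
    def pair_overlap_cell(self) -> str:
        if self.pair_overlap_count is None:
            return "-"
        return f"{self.pair_overlap_count}({self.pair_overlap_pct}%)"

    def to_json(self) -> dict:
        return {
            "name_a": self.name_a, "name_b": self.name_b,
            "gene_count": self.gene_counts_cell,
            "pair_count": self.pair_counts_cell,
            "gene_overlap": self.gene_overlap_cell,
            "pair_overlap": self.pair_overlap_cell,
        }


def consistency_table(matches) -> list[AgreementRow]:
    """One agreement row per confirmed match, in match order.

    Pathways without pairs leave the pair cells empty rather than
    failing the whole table.
    """
    rows: list[AgreementRow] = []
    for m in matches.matches if hasattr(matches, "matches") else matches:
        a, b = m.pathway_a, m.pathway_b
        g_count, g_pct = gene_agreement(a, b)
        if a.n_pairs and b.n_pairs:
            p_count, p_pct = pair_agreement(a, b)
        else:
            p_count = p_pct = None
        rows.append(AgreementRow(
            a.name, b.name, a.n_genes, b.n_genes,
            len(a.pair_keys), len(b.pair_keys),
            g_count, g_pct, p_count, p_pct))
    return rows


@dataclass
class ComprehensivenessReport:
    pathway_scores: dict[str, float] = field(default_factory=dict)
    coverage_scores: dict[str, float] = field(default_factory=dict)
    total_unique_pathways: int = 0
    total_unique_pairs: int = 0
    classes: list[list[tuple[str, str]]] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "pathway_comprehensive_score": self.pathway_scores,
            "gene_pair_coverage_score": self.coverage_scores,
            "total_unique_pathways": self.total_unique_pathways,
            "total_unique_pairs": self.total_unique_pairs,
        }


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def pathway_comprehensive_score(dbs: Sequence[PathwayDatabase],
                                match_reports: Iterable = ()) -> ComprehensivenessReport:
    """Fraction of unique pathway classes each database hosts.

    Classes are the union-find closure of confirmed cross-database
    matches; unmatched pathways are singleton classes. A class that ends
    up holding two pathways from the same database (chained matches) is
    kept but logged — it usually marks near-duplicate entries.
    """
    uf = _UnionFind()
    for db in dbs:
        for p in db:
            uf.find((db.name, p.pathway_id))
    for report in match_reports:
        for m in report.matches:
            uf.union((m.pathway_a.database, m.pathway_a.pathway_id),
                     (m.pathway_b.database, m.pathway_b.pathway_id))

    classes: dict = {}
    for db in dbs:
        for p in db:
            classes.setdefault(uf.find((db.name, p.pathway_id)), []).append(
                (db.name, p.pathway_id))
    for members in classes.values():
        names = [d for d, _ in members]
        if len(names) != len(set(names)):
            log.warning("pathway class %s holds several pathways from one database",
                        members)

    report = ComprehensivenessReport()
    report.classes = sorted(classes.values())
    total = len(classes)
    report.total_unique_pathways = total
    for db in dbs:
        hosted = sum(1 for members in classes.values()
                     if any(d == db.name for d, _ in members))
        report.pathway_scores[db.name] = hosted / total if total else 0.0
    return report


def gene_pair_coverage_score(dbs: Sequence[PathwayDatabase]) -> dict[str, float]:
    """Fraction of the union of all canonical pair keys each database hosts."""
    universe: set = set()
    per_db: dict[str, set] = {}
    for db in dbs:
        keys: set = set()
        for p in db:
            keys |= p.pair_keys
        per_db[db.name] = keys
        universe |= keys
    if not universe:
        raise ValueError("gene pair coverage undefined: no pairs in any database")
    return {name: len(keys) / len(universe) for name, keys in per_db.items()}


def venn_summary(dbs: Sequence[PathwayDatabase],
                 match_reports: Iterable = ()) -> dict[str, int]:
    """Counts of pathway classes per database combination (Venn cells)."""
    report = pathway_comprehensive_score(dbs, match_reports)
    cells: dict[str, int] = {}
    for members in report.classes:
        combo = "&".join(sorted({d for d, _ in members}))
        cells[combo] = cells.get(combo, 0) + 1
    return dict(sorted(cells.items()))
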