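"""Cross-database pathway matching.

The same biological pathway carries different names in different
databases ("Wnt signaling pathway" vs "Wnt Signaling Pathway" vs "Wnt
signaling - Homo sapiens (human)"). Three matchers are provided:

* **LCS matching** — rank candidate names by the length of their longest
  common substring after normalization. Near-identical names are
  confirmed automatically; borderline proposals are emitted as *pending*
  and decided by an explicit confirm-list, the auditable stand-in for a
  curator's manual scan.
* **gene-pair overlap matching** — greedy best-first pairing on the
  number of shared interacting gene pairs, with a minimum-overlap
  threshold (default 20 pairs) below which matches are rejected.
* **gene overlap matching** — the same, scored by shared genes. Cheap,
  but prone to spurious matches: large pathways share housekeeping genes
  without sharing any wiring.

Three comparison procedures quantify how the matchers agree, mirroring
the evaluation a database curator would run before trusting one of them.
"""

from __future__ import annotations

import math
import re
import statistics
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .core import Pathway, PathwayDatabase
from .metrics import round_half_up_pct

__all__ = [
    "MatchMethod",
    "PathwayMatch",
    "MatchReport",
    "normalize_name",
    "longest_common_substring",
    "rank_by_lcs",
    "match_by_lcs",
    "match_by_pair_overlap",
    "match_by_gene_overlap",
    "compare_lcs_vs_gene_overlap",
    "compare_lcs_vs_pair_overlap",
    "topk_overlap_curve",
    "load_confirm_list",
    "gene_overlap",
    "pair_overlap",
    "DEFAULT_MIN_PAIR_OVERLAP",
    "DEFAULT_AUTO_CONFIRM_FRACTION",
]

DEFAULT_MIN_PAIR_OVERLAP = 20
DEFAULT_AUTO_CONFIRM_FRACTION = 0.8

_ORGANISM_SUFFIX = re.compile(r"\s*-\s*homo sapiens\s*\(human\)\s*$")


class MatchMethod(str, Enum):
    LCS = "lcs"
    GENE = "gene"
    GENE_PAIR = "gene_pair"


def normalize_name(name: str) -> str:
    """Case-fold, collapse whitespace, strip the organism boilerplate
    suffix. Words like "pathway"/"signaling" are kept: they contribute
    to the common substring exactly as curators wrote them."""
    s = re.sub(r"\s+", " ", name.casefold().strip())
    return _ORGANISM_SUFFIX.sub("", s)


def longest_common_substring(a: str, b: str) -> tuple[int, str]:
    """Longest contiguous substring common to the two normalized names.

    Classic O(len(a)*len(b)) dynamic program; on ties the substring
    occurring first in ``a`` is returned, making the choice deterministic.
    """
    a, b = normalize_name(a), normalize_name(b)
    if not a or not b:
        return 0, ""
    best_len, best_end = 0, 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len, best_end = cur[j], i
        prev = cur
    return best_len, a[best_end - best_len:best_end]


def gene_overlap(p: Pathway, q: Pathway) -> int:
    return len(p.genes & q.genes)


def pair_overlap(p: Pathway, q: Pathway) -> int:
    return len(p.pair_keys & q.pair_keys)


def _pair_overlap_pct(p: Pathway, q: Pathway) -> int | None:
    m = min(len(p.pair_keys), len(q.pair_keys))
    if m == 0:
        return None
    return round_half_up_pct(pair_overlap(p, q), m)


def _gene_overlap_pct(p: Pathway, q: Pathway) -> int | None:
    m = min(p.n_genes, q.n_genes)
    if m == 0:
        return None
    return round_half_up_pct(gene_overlap(p, q), m)


@dataclass
class PathwayMatch:
    """One proposed or confirmed cross-database pathway pairing."""

    pathway_a: Pathway
    pathway_b: Pathway
    method: MatchMethod
    lcs_len: int = 0
    gene_overlap: int = 0
    pair_overlap: int = 0
    confirmed: bool = False

    def __post_init__(self) -> None:
        assert self.gene_overlap <= min(self.pathway_a.n_genes, self.pathway_b.n_genes)
        assert self.pair_overlap <= min(self.pathway_a.n_pairs, self.pathway_b.n_pairs)

    @property
    def key(self) -> tuple[str, str]:
        return (self.pathway_a.pathway_id, self.pathway_b.pathway_id)


@dataclass
class UnmatchedRecord:
    """A pathway the LCS matcher left unmatched (the PU list), with its
    best gene-overlap partner (PUM) and the pair-overlap percentage of
    that pairing."""

    pathway: Pathway
    best_partner: Pathway | None
    gene_overlap: int = 0
    gene_overlap_pct: int | None = None
    pair_overlap_pct: int | None = None


@dataclass
class MatchReport:
    """Outcome of one matcher run over a database pair."""

    method: MatchMethod
    db_a: str
    db_b: str
    matches: list[PathwayMatch] = field(default_factory=list)
    pending: list[PathwayMatch] = field(default_factory=list)
    unmatched_a: list[UnmatchedRecord] = field(default_factory=list)

    def match_keys(self) -> set[tuple[str, str]]:
        return {m.key for m in self.matches}

    def to_json(self) -> dict:
        def row(m: PathwayMatch) -> dict:
            return {
                "pathway_a": m.pathway_a.pathway_id, "name_a": m.pathway_a.name,
                "pathway_b": m.pathway_b.pathway_id, "name_b": m.pathway_b.name,
                "lcs_len": m.lcs_len, "gene_overlap": m.gene_overlap,
                "pair_overlap": m.pair_overlap, "confirmed": m.confirmed,
            }
        return {
            "method": self.method.value, "db_a": self.db_a, "db_b": self.db_b,
            "matches": [row(m) for m in self.matches],
            "pending": [row(m) for m in self.pending],
            "unmatched_a": [
                {"pathway": u.pathway.pathway_id, "name": u.pathway.name,
                 "best_partner": None if u.best_partner is None else u.best_partner.pathway_id,
                 "gene_overlap": u.gene_overlap,
                 "gene_overlap_pct": u.gene_overlap_pct,
                 "pair_overlap_pct": u.pair_overlap_pct}
                for u in self.unmatched_a
            ],
        }


def rank_by_lcs(x: Pathway, candidates: Sequence[Pathway]) -> list[tuple[Pathway, int]]:
    """Candidates sorted by descending LCS length against ``x``'s name;
    ties broken by normalized-name lexicographic order."""
    if not candidates:
        raise ValueError("no candidates to rank")
    scored = [(c, longest_common_substring(x.name, c.name)[0]) for c in candidates]
    scored.sort(key=lambda t: (-t[1], normalize_name(t[0].name)))
    return scored


def load_confirm_list(path: str | Path) -> dict[tuple[str, str], str]:
    """Read the curator confirm-list: ``id_a<TAB>id_b<TAB>accept|reject``."""
    decisions: dict[tuple[str, str], str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b, verdict = line.split("\t")
        if verdict not in ("accept", "reject"):
            raise ValueError(f"confirm-list verdict must be accept|reject, got {verdict!r}")
        decisions[(a, b)] = verdict
    return decisions


def _fill_unmatched(report: MatchReport, leftovers: Iterable[Pathway],
                    db2: PathwayDatabase) -> None:
    for p in leftovers:
        best, best_ov = None, -1
        for q in sorted(db2, key=lambda q: normalize_name(q.name)):
            ov = gene_overlap(p, q)
            if ov > best_ov:
                best, best_ov = q, ov
        rec = UnmatchedRecord(p, best)
        if best is not None:
            rec.gene_overlap = best_ov
            rec.gene_overlap_pct = _gene_overlap_pct(p, best)
            rec.pair_overlap_pct = _pair_overlap_pct(p, best)
        report.unmatched_a.append(rec)


def match_by_lcs(db1: PathwayDatabase, db2: PathwayDatabase,
                 decisions: dict[tuple[str, str], str] | None = None,
                 auto_confirm_fraction: float = DEFAULT_AUTO_CONFIRM_FRACTION,
                 ) -> MatchReport:
    """Name-based matching with an explicit manual-confirmation channel.

    All db1 x db2 name pairs are ranked by LCS length and walked
    greedily into a one-to-one matching. A pair is eligible when the
    common substring covers at least ``auto_confirm_fraction`` of the
    shorter normalized name, or when the ``decisions`` confirm-list
    accepts it (``reject`` entries veto auto-confirmation). Walking the
    full ranked list rather than each pathway's single best candidate
    keeps generic name fragments (" signaling pathway") from shadowing
    an exact match further down the list. Unmatched db1 pathways form
    the PU list, each annotated with its best gene-overlap partner
    (PUM) and that pairing's pair-overlap percentage.
    """
    decisions = decisions or {}
    report = MatchReport(MatchMethod.LCS, db1.name, db2.name)
    if len(db2) == 0:
        _fill_unmatched(report, db1, db2)
        return report

    def confirmable(p: Pathway, c: Pathway, lcs_len: int) -> bool:
        verdict = decisions.get((p.pathway_id, c.pathway_id))
        if verdict == "reject":
            return False
        if verdict == "accept":
            return True
        shorter = min(len(normalize_name(p.name)), len(normalize_name(c.name)))
        return shorter > 0 and lcs_len >= auto_confirm_fraction * shorter

    # every cross pair, descending LCS (a ranked list per pathway, walked
    # greedily across the whole database pair)
    scored = [
        (p, c, longest_common_substring(p.name, c.name)[0])
        for p in db1 for c in db2
    ]
    scored.sort(key=lambda t: (-t[2], normalize_name(t[0].name),
                               normalize_name(t[1].name)))

    taken_a: set[str] = set()
    taken_b: set[str] = set()
    for p, c, lcs_len in scored:
        if p.pathway_id in taken_a or c.pathway_id in taken_b:
            continue
        if not confirmable(p, c, lcs_len):
            continue
        taken_a.add(p.pathway_id)
        taken_b.add(c.pathway_id)
        report.matches.append(PathwayMatch(
            p, c, MatchMethod.LCS, lcs_len=lcs_len,
            gene_overlap=gene_overlap(p, c), pair_overlap=pair_overlap(p, c),
            confirmed=True))

    leftovers: list[Pathway] = []
    for p in db1:
        if p.pathway_id in taken_a:
            continue
        leftovers.append(p)
        remaining = [c for c in db2 if c.pathway_id not in taken_b]
        if remaining:
            (cand, lcs_len), *_ = rank_by_lcs(p, remaining)
            report.pending.append(PathwayMatch(
                p, cand, MatchMethod.LCS, lcs_len=lcs_len,
                gene_overlap=gene_overlap(p, cand),
                pair_overlap=pair_overlap(p, cand), confirmed=False))
    _fill_unmatched(report, leftovers, db2)
    return report


def _match_by_overlap(db1: PathwayDatabase, db2: PathwayDatabase,
                      method: MatchMethod, score_fn, min_score: int) -> MatchReport:
    """Greedy best-first one-to-one assignment on descending score."""
    report = MatchReport(method, db1.name, db2.name)
    scored = []
    for p in db1:
        for q in db2:
            s = score_fn(p, q)
            if s >= min_score:
                scored.append((s, normalize_name(p.name), normalize_name(q.name), p, q))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken_a: set[str] = set()
    taken_b: set[str] = set()
    for s, _, _, p, q in scored:
        if p.pathway_id in taken_a or q.pathway_id in taken_b:
            continue
        taken_a.add(p.pathway_id)
        taken_b.add(q.pathway_id)
        report.matches.append(PathwayMatch(
            p, q, method, lcs_len=longest_common_substring(p.name, q.name)[0],
            gene_overlap=gene_overlap(p, q), pair_overlap=pair_overlap(p, q),
            confirmed=True))
    _fill_unmatched(report, (p for p in db1 if p.pathway_id not in taken_a), db2)
    return report


def match_by_pair_overlap(db1: PathwayDatabase, db2: PathwayDatabase,
                          min_pairs: int = DEFAULT_MIN_PAIR_OVERLAP) -> MatchReport:
    """Match on shared interacting gene pairs; pairings sharing fewer
    than ``min_pairs`` pairs (default 20) are rejected — below that the
    matcher floods with false positives."""
    return _match_by_overlap(db1, db2, MatchMethod.GENE_PAIR, pair_overlap, min_pairs)


def match_by_gene_overlap(db1: PathwayDatabase, db2: PathwayDatabase,
                          min_genes: int = 1) -> MatchReport:
    """Match on shared genes (the weakest signal; kept for comparison)."""
    return _match_by_overlap(db1, db2, MatchMethod.GENE, gene_overlap, min_genes)


def compare_lcs_vs_gene_overlap(db1: PathwayDatabase, db2: PathwayDatabase,
                                top_n: int = 3,
                                decisions: dict[tuple[str, str], str] | None = None,
                                ) -> dict:
    """For each LCS-confirmed match, is the partner within the top-n of
    the gene-overlap ranking? Disagreements are adjudicated by comparing
    pair-overlap percentages of the two candidate partners."""
    lcs_report = match_by_lcs(db1, db2, decisions=decisions)
    rows = []
    for m in lcs_report.matches:
        ranked = sorted(db2, key=lambda q: (-gene_overlap(m.pathway_a, q),
                                            normalize_name(q.name)))
        top = ranked[:top_n]
        in_top = m.pathway_b.pathway_id in {q.pathway_id for q in top}
        row = {
            "pathway_a": m.pathway_a.pathway_id,
            "lcs_partner": m.pathway_b.pathway_id,
            "in_top": in_top,
        }
        if not in_top:
            row["lcs_partner_pair_pct"] = _pair_overlap_pct(m.pathway_a, m.pathway_b)
            row["top_candidates_pair_pct"] = [
                {"pathway_b": q.pathway_id,
                 "pair_pct": _pair_overlap_pct(m.pathway_a, q)}
                for q in top
            ]
        rows.append(row)
    n = len(rows)
    return {
        "top_n": top_n,
        "rows": rows,
        "fraction_in_top": (sum(r["in_top"] for r in rows) / n) if n else None,
    }


def _summary(values: list[float]) -> dict:
    if not values:
        return {"n": 0, "mean": None, "median": None}
    return {"n": len(values), "mean": statistics.fmean(values),
            "median": statistics.median(values)}


def compare_lcs_vs_pair_overlap(db1: PathwayDatabase, db2: PathwayDatabase,
                                decisions: dict[tuple[str, str], str] | None = None,
                                ) -> dict:
    """(gene-overlap %, pair-overlap %) scatter for LCS-matched pathways
    versus the PU/PUM pathways the LCS matcher could not place, plus
    summary statistics of the two pair-overlap distributions."""
    lcs_report = match_by_lcs(db1, db2, decisions=decisions)
    matched_points, unmatched_points = [], []
    for m in lcs_report.matches:
        matched_points.append({
            "pathway_a": m.pathway_a.pathway_id,
            "partner": m.pathway_b.pathway_id,
            "gene_pct": _gene_overlap_pct(m.pathway_a, m.pathway_b),
            "pair_pct": _pair_overlap_pct(m.pathway_a, m.pathway_b),
        })
    for u in lcs_report.unmatched_a:
        if u.best_partner is None:
            continue
        unmatched_points.append({
            "pathway_a": u.pathway.pathway_id,
            "partner": u.best_partner.pathway_id,
            "gene_pct": u.gene_overlap_pct,
            "pair_pct": u.pair_overlap_pct,
        })
    return {
        "matched": matched_points,
        "unmatched": unmatched_points,
        "matched_pair_pct": _summary([p["pair_pct"] for p in matched_points
                                      if p["pair_pct"] is not None]),
        "unmatched_pair_pct": _summary([p["pair_pct"] for p in unmatched_points
                                        if p["pair_pct"] is not None]),
    }


def topk_overlap_curve(db1: PathwayDatabase, db2: PathwayDatabase,
                       k_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5,
                                                  0.6, 0.7, 0.8, 0.9, 1.0),
                       decisions: dict[tuple[str, str], str] | None = None,
                       min_pairs: int = 0) -> dict:
    """Agreement-with-LCS curves for the two overlap matchers.

    For each fraction k, take the top k of each overlap matcher's
    matches (ranked by overlap size) and report the fraction that agree
    with the LCS reference matching.
    """
    reference = match_by_lcs(db1, db2, decisions=decisions).match_keys()
    out = {"k": list(k_grid), "gene": [], "gene_pair": []}
    for label, report in (
        ("gene", match_by_gene_overlap(db1, db2)),
        ("gene_pair", match_by_pair_overlap(db1, db2, min_pairs=min_pairs)),
    ):
        ranked = sorted(report.matches,
                        key=lambda m: (-(m.pair_overlap if label == "gene_pair"
                                         else m.gene_overlap),
                                       normalize_name(m.pathway_a.name)))
        for k in k_grid:
            top = ranked[:math.ceil(k * len(ranked))]
            frac = (sum(m.key in reference for m in top) / len(top)) if top else None
            out[label].append(frac)
    return out
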