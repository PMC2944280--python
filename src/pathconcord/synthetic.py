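"""Synthetic inputs with known ground truth.

Real pathway databases are moving targets; every quantitative claim in
this package is therefore exercised on generated data whose true
structure is known by construction:

* :func:`generate_databases` plants cross-database pathway pairs with
  *exact* requested gene- and pair-overlap counts and realistic name
  variants ("X", "X Signaling", "X - Homo sapiens (human)",
  "X signaling pathway"), so matcher recall and agreement percentages
  have an arithmetic oracle. The default specification mirrors the
  magnitudes observed between large public curated sources: pathways of
  tens to hundreds of genes, gene agreement roughly 30-90% of the
  smaller pathway, pair agreement far lower.
* :func:`generate_gpml` renders a pathway as a GPML diagram whose
  layout provably respects (or, on request, deliberately straddles) the
  100-pixel clustering threshold, for parser round-trip oracles.
* :func:`generate_kgml` renders a pathway as a KGML document, with
  multi-gene entries exercising the group-expansion rule.

Every generator is driven by a single integer seed and returns a
manifest; regenerating with the same seed reproduces the manifest
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import count
from typing import Iterable, Sequence
from random import Random
from xml.sax.saxutils import quoteattr

from .core import GenePair, Pathway, PathwayDatabase, Relation

__all__ = [
    "LayoutParams",
    "PlantedPathwayPair",
    "DatabaseSpec",
    "FixtureManifest",
    "default_database_spec",
    "generate_databases",
    "generate_gpml",
    "generate_kgml",
    "random_pathway",
    "NAME_VARIANTS",
]

NAME_VARIANTS = ("{base}", "{base} Signaling", "{base} - Homo sapiens (human)",
                 "{base} signaling pathway")

_RELATIONS = (Relation.ACTIVATE, Relation.INHIBIT, Relation.NEUTRAL)


def _pct(numer: int, denom: int) -> int:
    # independent of the metrics module on purpose: the manifest is an oracle
    return int((Decimal(100) * numer / denom).quantize(Decimal("1"),
                                                       rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# planted databases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPathwayPair:
    """One cross-database pathway pair with exact requested overlaps."""

    name_a: str
    name_b: str
    n_genes_a: int
    n_genes_b: int
    gene_overlap: int
    n_pairs_a: int
    n_pairs_b: int
    pair_overlap: int

    def validate(self) -> None:
        if self.gene_overlap > min(self.n_genes_a, self.n_genes_b):
            raise ValueError(f"{self.name_a!r}: gene overlap exceeds smaller gene set")
        if self.pair_overlap > min(self.n_pairs_a, self.n_pairs_b):
            raise ValueError(f"{self.name_a!r}: pair overlap exceeds smaller pair set")
        g = self.gene_overlap
        if self.pair_overlap > g * (g - 1) // 2:
            raise ValueError(f"{self.name_a!r}: pair overlap infeasible for "
                             f"{g} shared genes")
        for n_genes, n_pairs in ((self.n_genes_a, self.n_pairs_a),
                                 (self.n_genes_b, self.n_pairs_b)):
            own = n_genes * (n_genes - 1) // 2 - g * (g - 1) // 2
            if n_pairs - self.pair_overlap > own:
                raise ValueError(f"{self.name_a!r}: not enough non-shared gene "
                                 "pairs available")


@dataclass(frozen=True)
class UnmatchedPathway:
    name: str
    database: int  # index into db_names
    n_genes: int = 20
    n_pairs: int = 15


@dataclass(frozen=True)
class DatabaseSpec:
    db_names: tuple[str, str] = ("KEGG", "Wiki")
    planted: tuple[PlantedPathwayPair, ...] = ()
    unmatched: tuple[UnmatchedPathway, ...] = ()


def default_database_spec() -> DatabaseSpec:
    """Two toy databases emulating the magnitudes seen between large
    public curated sources (pathways of 46-203 genes, gene agreement
    30-90% of the smaller pathway, pair agreement far lower), with the
    name-variant patterns those sources actually use."""
    planted = (
        PlantedPathwayPair("Apoptosis - Homo sapiens (human)", "Apoptosis",
                           89, 82, 38, 151, 133, 21),
        PlantedPathwayPair("Cell cycle - Homo sapiens (human)", "Cell cycle",
                           119, 91, 76, 78, 147, 35),
        PlantedPathwayPair("Focal Adhesion - Homo sapiens (human)", "Focal Adhesion",
                           203, 188, 154, 706, 288, 110),
        PlantedPathwayPair("Notch signaling pathway - Homo sapiens (human)",
                           "Notch Signaling", 46, 46, 39, 90, 98, 32),
        PlantedPathwayPair("Wnt signaling pathway - Homo sapiens (human)",
                           "Wnt Signaling Pathway", 152, 61, 49, 778, 184, 34),
        PlantedPathwayPair("T cell receptor signaling pathway - Homo sapiens (human)",
                           "T cell receptor Signaling", 94, 135, 37, 175, 261, 6),
        PlantedPathwayPair("TGF-beta signaling pathway - Homo sapiens (human)",
                           "TGF-beta Signaling", 87, 52, 23, 155, 80, 6),
    )
    unmatched = (
        UnmatchedPathway("Urea cycle - Homo sapiens (human)", 0, 28, 69),
        UnmatchedPathway("Tryptophan metabolism - Homo sapiens (human)", 0, 51, 233),
        UnmatchedPathway("Olfactory transduction", 1, 40, 30),
    )
    return DatabaseSpec(planted=planted, unmatched=unmatched)


@dataclass
class FixtureManifest:
    """Ground truth for one generated fixture set."""

    seed: int
    params: dict
    databases: dict = field(default_factory=dict)
    expected_matches: list = field(default_factory=list)
    expected_agreements: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)


def _sample_keys(rng: Random, pool_a: Sequence[int], pool_b: Sequence[int],
                 n: int, forbidden: set[tuple[int, int]],
                 require_a: bool = False) -> list[tuple[int, int]]:
    """n distinct unordered id pairs drawn from pool_a x pool_b.

    With ``require_a`` the first endpoint must come from ``pool_a`` only
    (used to keep non-shared pairs out of the partner database).
    """
    keys: set[tuple[int, int]] = set()
    attempts = 0
    limit = 200 * n + 1000
    while len(keys) < n:
        attempts += 1
        if attempts > limit:
            raise ValueError("could not sample the requested number of gene pairs")
        a = rng.choice(pool_a)
        b = rng.choice(pool_b)
        if a == b:
            continue
        k = (a, b) if a < b else (b, a)
        if k in forbidden or k in keys:
            continue
        keys.add(k)
    return sorted(keys)


def _pairs_from_keys(rng: Random, keys: Iterable[tuple[int, int]],
                     database: str) -> list[GenePair]:
    pairs = []
    for a, b in keys:
        src, tgt = (a, b) if rng.random() < 0.5 else (b, a)
        pairs.append(GenePair(src, tgt, rng.choice(_RELATIONS), database))
    return pairs


def generate_databases(seed: int, spec: DatabaseSpec | None = None,
                       ) -> tuple[list[PathwayDatabase], FixtureManifest]:
    """Build two databases with planted matches and exact overlaps.

    Gene-id blocks are disjoint between pathway pairs, so overlaps are
    exactly the planted ones. The manifest records every expected match
    and the arithmetically derived agreement counts/percentages.
    """
    spec = spec or default_database_spec()
    rng = Random(seed)
    ids = count(1001)
    dbs = [PathwayDatabase(name) for name in spec.db_names]
    manifest = FixtureManifest(seed=seed, params=asdict(spec))

    for i, plant in enumerate(spec.planted):
        plant.validate()
        shared = [next(ids) for _ in range(plant.gene_overlap)]
        only_a = [next(ids) for _ in range(plant.n_genes_a - plant.gene_overlap)]
        only_b = [next(ids) for _ in range(plant.n_genes_b - plant.gene_overlap)]
        genes_a = shared + only_a
        genes_b = shared + only_b

        shared_keys = _sample_keys(rng, shared, shared, plant.pair_overlap, set())
        forb = set(shared_keys)
        extra_a = _sample_keys(rng, only_a, genes_a,
                               plant.n_pairs_a - plant.pair_overlap, forb)
        extra_b = _sample_keys(rng, only_b, genes_b,
                               plant.n_pairs_b - plant.pair_overlap, forb)

        shared_pairs = _pairs_from_keys(rng, shared_keys, "")
        pa = Pathway(f"{spec.db_names[0]}_{i}", plant.name_a, spec.db_names[0],
                     frozenset(genes_a),
                     tuple(GenePair(p.source_gene_id, p.target_gene_id, p.relation,
                                    spec.db_names[0]) for p in shared_pairs)
                     + tuple(_pairs_from_keys(rng, extra_a, spec.db_names[0])))
        pb = Pathway(f"{spec.db_names[1]}_{i}", plant.name_b, spec.db_names[1],
                     frozenset(genes_b),
                     tuple(GenePair(p.source_gene_id, p.target_gene_id, p.relation,
                                    spec.db_names[1]) for p in shared_pairs)
                     + tuple(_pairs_from_keys(rng, extra_b, spec.db_names[1])))
        dbs[0].add(pa)
        dbs[1].add(pb)

        manifest.expected_matches.append([pa.pathway_id, pb.pathway_id])
        manifest.expected_agreements.append({
            "name_a": plant.name_a, "name_b": plant.name_b,
            "gene_overlap": plant.gene_overlap,
            "gene_overlap_pct": _pct(plant.gene_overlap,
                                     min(plant.n_genes_a, plant.n_genes_b)),
            "pair_overlap": plant.pair_overlap,
            "pair_overlap_pct": _pct(plant.pair_overlap,
                                     min(plant.n_pairs_a, plant.n_pairs_b)),
        })

    for j, um in enumerate(spec.unmatched):
        genes = [next(ids) for _ in range(um.n_genes)]
        keys = _sample_keys(rng, genes, genes, um.n_pairs, set())
        p = Pathway(f"{spec.db_names[um.database]}_u{j}", um.name,
                    spec.db_names[um.database], frozenset(genes),
                    tuple(_pairs_from_keys(rng, keys, spec.db_names[um.database])))
        dbs[um.database].add(p)

    for db in dbs:
        manifest.databases[db.name] = [
            {"pathway_id": p.pathway_id, "name": p.name,
             "n_genes": p.n_genes, "n_pairs": p.n_pairs,
             "genes": sorted(p.genes),
             "pair_keys": [list(k) for k in sorted(p.pair_keys)]}
            for p in db
        ]
    return dbs, manifest


# ---------------------------------------------------------------------------
# GPML / KGML documents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutParams:
    """Geometry of a generated diagram, in pixels.

    Valid layouts keep nodes of one cluster within ``intra_spacing`` of
    their neighbour (below the clustering threshold) and distinct
    clusters at least ``inter_spacing`` apart (well above it).
    """

    threshold: float = 100.0
    intra_spacing: float = 50.0
    inter_spacing: float = 400.0
    jitter: float = 40.0
    node_width: float = 80.0
    node_height: float = 20.0

    def validate(self) -> None:
        if not (0 < self.intra_spacing < self.threshold < self.inter_spacing):
            raise ValueError("layout must satisfy intra < threshold < inter spacing")


def _derive_cluster_relations(pathway: Pathway, clusters: Sequence[Sequence[int]],
                              ) -> list[tuple[int, int, Relation]]:
    """Lift gene-level pairs to cluster-level relations, checking that
    each lifted relation is a *complete* cross product (otherwise no
    diagram of these clusters parses back to the input pathway)."""
    where = {g: i for i, cl in enumerate(clusters) for g in cl}
    if set(where) != set(pathway.genes):
        raise ValueError("clusters must partition the pathway's gene set")
    triples = {(p.source_gene_id, p.target_gene_id, p.relation) for p in pathway.pairs}
    if len(triples) != len(pathway.pairs):
        raise ValueError("duplicate directed pairs cannot be drawn")
    lifted: dict[tuple[int, int, Relation], set[tuple[int, int]]] = {}
    for s, t, rel in triples:
        lifted.setdefault((where[s], where[t], rel), set()).add((s, t))
    for (ci, cj, rel), present in lifted.items():
        full = {(a, b) for a in clusters[ci] for b in clusters[cj] if a != b or ci != cj}
        if present != full:
            raise ValueError(
                f"pairs between clusters {ci} and {cj} are not a full cross "
                "product; choose finer clusters")
    return sorted(lifted, key=lambda t: (t[0], t[1], t[2].value))


def _cluster_layout(rng: Random, clusters: Sequence[Sequence[int]],
                    layout: LayoutParams) -> list[list[tuple[float, float]]]:
    """Place cluster centers in convex position on a jittered circle.

    Convexity guarantees that the straight line between any two cluster
    boxes clears every other cluster, so relation lines are always
    drawable; the radius is sized so adjacent clusters stay beyond the
    clustering threshold node-to-node. Nodes stack vertically inside
    their cluster at ``intra_spacing``.
    """
    import math
    n = len(clusters)
    r_max = max(math.hypot(layout.node_width / 2,
                           ((len(cl) - 1) * layout.intra_spacing
                            + layout.node_height) / 2) for cl in clusters)
    if n == 1:
        centers = [(500.0 + rng.uniform(-layout.jitter, layout.jitter),
                    500.0 + rng.uniform(-layout.jitter, layout.jitter))]
    else:
        theta = 2 * math.pi / n
        margin = 30.0
        need_sep = max(layout.inter_spacing,
                       layout.threshold + 2 * r_max + 2 * layout.jitter + margin)
        radius = need_sep / (2 * math.sin(theta / 2))
        if n >= 3:
            # chord-to-third-point clearance on a circle is >= R(1 - cos theta)
            radius = max(radius, (2 * r_max + 2 * layout.jitter + margin)
                         / (1 - math.cos(theta)))
        centers = []
        for i in range(n):
            rr = radius + rng.uniform(-layout.jitter, layout.jitter)
            centers.append((2 * radius + rr * math.cos(i * theta),
                            2 * radius + rr * math.sin(i * theta)))
    positions = []
    for (cx, cy), cl in zip(centers, clusters):
        top = cy - (len(cl) - 1) * layout.intra_spacing / 2
        positions.append([(cx, top + k * layout.intra_spacing)
                          for k in range(len(cl))])
    return positions


def _bbox(points: list[tuple[float, float]], layout: LayoutParams):
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return (min(xs) - layout.node_width / 2, min(ys) - layout.node_height / 2,
            max(xs) + layout.node_width / 2, max(ys) + layout.node_height / 2)


def _seg_box_hit(p0, u, box, tmax) -> float | None:
    t0, t1 = 0.0, tmax
    for o, d, lo, hi in ((p0[0], u[0], box[0], box[2]),
                         (p0[1], u[1], box[1], box[3])):
        if abs(d) < 1e-12:
            if not (lo <= o <= hi):
                return None
            continue
        ta, tb = (lo - o) / d, (hi - o) / d
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return None
    return t0


def _line_endpoints(src_box, tgt_box, boxes, delta: float = 12.0):
    """A drawn segment between two cluster boxes: starts just outside
    the source box, ends just outside the target box, and crosses no
    third box. Returns None when the geometry fails (caller re-jitters)."""
    import math
    c_src = ((src_box[0] + src_box[2]) / 2, (src_box[1] + src_box[3]) / 2)
    c_tgt = ((tgt_box[0] + tgt_box[2]) / 2, (tgt_box[1] + tgt_box[3]) / 2)
    dx, dy = c_tgt[0] - c_src[0], c_tgt[1] - c_src[1]
    dist = math.hypot(dx, dy)
    if dist < 1e-9:
        return None
    u = (dx / dist, dy / dist)
    exit_src = _seg_box_hit(c_tgt, (-u[0], -u[1]), src_box, dist)
    entry_tgt = _seg_box_hit(c_src, u, tgt_box, dist)
    if exit_src is None or entry_tgt is None:
        return None
    start = (c_tgt[0] - (exit_src - delta) * u[0], c_tgt[1] - (exit_src - delta) * u[1])
    end = (c_src[0] + (entry_tgt - delta) * u[0], c_src[1] + (entry_tgt - delta) * u[1])
    seg_len = math.dist(start, end)
    if seg_len < 1e-6:
        return None
    for i, box in enumerate(boxes):
        if box is src_box or box is tgt_box:
            continue
        inside = (box[0] <= start[0] <= box[2] and box[1] <= start[1] <= box[3]) or \
                 (box[0] <= end[0] <= box[2] and box[1] <= end[1] <= box[3])
        crossed = _seg_box_hit(start, u, box, seg_len + 2 * delta + 1) is not None
        behind = _seg_box_hit(end, (-u[0], -u[1]), box,
                              seg_len + 2 * delta + 1) is not None
        if inside or crossed or behind:
            return None
    return start, end


_ARROWHEADS = {Relation.ACTIVATE: "Arrow", Relation.INHIBIT: "TBar",
               Relation.NEUTRAL: "Line"}


def generate_gpml(pathway: Pathway, layout: LayoutParams | None = None,
                  seed: int = 0, clusters: Sequence[Sequence[int]] | None = None,
                  labels: dict[int, str] | None = None,
                  max_attempts: int = 60) -> tuple[str, dict]:
    """Render a pathway as a GPML diagram that parses back to itself.

    ``clusters`` partitions the gene set into drawn stacks (default:
    one node per gene); relations between clusters must be complete
    cross products of the pathway's pairs. The layout is validated
    geometrically (cluster separation, unobstructed relation lines) and
    re-jittered until valid; an impossible layout raises.
    """
    layout = layout or LayoutParams()
    layout.validate()
    if clusters is None:
        clusters = [[g] for g in sorted(pathway.genes)]
    clusters = [sorted(cl) for cl in clusters]
    relations = _derive_cluster_relations(pathway, clusters)
    labels = labels or {}
    rng = Random(seed)

    for _ in range(max_attempts):
        positions = _cluster_layout(rng, clusters, layout)
        boxes = [_bbox(p, layout) for p in positions]
        # distinct clusters must stay beyond the threshold, node to node
        import math
        ok = all(
            math.dist(p, q) > layout.threshold
            for i in range(len(clusters)) for j in range(i + 1, len(clusters))
            for p in positions[i] for q in positions[j]
        )
        if not ok:
            continue
        lines = []
        for ci, cj, rel in relations:
            got = _line_endpoints(boxes[ci], boxes[cj], boxes)
            if got is None:
                break
            lines.append((got[0], got[1], rel))
        else:
            return (_render_gpml(pathway.name, clusters, positions, lines,
                                 layout, labels),
                    _document_manifest(pathway, clusters, len(lines)))
    raise ValueError("could not find a valid diagram layout for this pathway")


def _document_manifest(pathway: Pathway, clusters, n_lines: int) -> dict:
    return {
        "name": pathway.name,
        "genes": sorted(pathway.genes),
        "pairs": sorted([p.source_gene_id, p.target_gene_id, p.relation.value]
                        for p in pathway.pairs),
        "pair_keys": [list(k) for k in sorted(pathway.pair_keys)],
        "clusters": [list(cl) for cl in clusters],
        "n_lines": n_lines,
    }


def _render_gpml(name: str, clusters, positions, lines, layout: LayoutParams,
                 labels: dict[int, str]) -> str:
    out = [f'<?xml version="1.0" encoding="UTF-8"?>',
           f'<Pathway xmlns="http://pathvisio.org/GPML/2013a" Name={quoteattr(name)} '
           'Organism="Homo sapiens">']
    for cl, pos in zip(clusters, positions):
        for gid, (x, y) in zip(cl, pos):
            label = labels.get(gid, f"G{gid}")
            out.append(
                f'  <DataNode TextLabel={quoteattr(label)} Type="GeneProduct">\n'
                f'    <Graphics CenterX="{x:.1f}" CenterY="{y:.1f}" '
                f'Width="{layout.node_width:.1f}" Height="{layout.node_height:.1f}" />\n'
                f'    <Xref Database="Entrez Gene" ID="{gid}" />\n'
                '  </DataNode>')
    for start, end, rel in lines:
        out.append(
            '  <Interaction>\n    <Graphics>\n'
            f'      <Point X="{start[0]:.1f}" Y="{start[1]:.1f}" />\n'
            f'      <Point X="{end[0]:.1f}" Y="{end[1]:.1f}" '
            f'ArrowHead="{_ARROWHEADS[rel]}" />\n'
            '    </Graphics>\n  </Interaction>')
    out.append('</Pathway>')
    return "\n".join(out)


_KGML_SUBTYPES = {Relation.ACTIVATE: ("PPrel", "activation"),
                  Relation.INHIBIT: ("PPrel", "inhibition"),
                  Relation.NEUTRAL: ("ECrel", None)}


def generate_kgml(pathway: Pathway, seed: int = 0,
                  entries: Sequence[Sequence[int]] | None = None,
                  organism: str = "hsa") -> tuple[str, dict]:
    """Render a pathway as a KGML document that parses back to itself.

    ``entries`` partitions the gene set into KGML entry elements
    (multi-gene entries exercise cross-product expansion); relations
    between entries must be complete cross products, as in
    :func:`generate_gpml`. Activation/inhibition become PPrel subtypes;
    neutral pairs become enzyme-enzyme (ECrel) relations.
    """
    if entries is None:
        entries = [[g] for g in sorted(pathway.genes)]
    entries = [sorted(e) for e in entries]
    relations = _derive_cluster_relations(pathway, entries)

    out = ['<?xml version="1.0" encoding="UTF-8"?>',
           f'<pathway name="path:{organism}99999" org="{organism}" number="99999" '
           f'title={quoteattr(pathway.name)}>']
    for i, e in enumerate(entries, start=1):
        names = " ".join(f"{organism}:{g}" for g in e)
        out.append(f'  <entry id="{i}" name="{names}" type="gene" />')
    for ci, cj, rel in relations:
        rel_type, subtype = _KGML_SUBTYPES[rel]
        if subtype is None:
            out.append(f'  <relation entry1="{ci + 1}" entry2="{cj + 1}" '
                       f'type="{rel_type}" />')
        else:
            out.append(f'  <relation entry1="{ci + 1}" entry2="{cj + 1}" '
                       f'type="{rel_type}">\n'
                       f'    <subtype name="{subtype}" value="" />\n'
                       '  </relation>')
    out.append('</pathway>')
    return "\n".join(out), _document_manifest(pathway, entries, len(relations))


def random_pathway(rng: Random, name: str, database: str,
                   n_genes: int = 8, n_pairs: int = 6,
                   id_start: int = 1) -> Pathway:
    """Small random pathway on a fresh id block (for property tests)."""
    genes = list(range(id_start, id_start + n_genes))
    n_pairs = min(n_pairs, n_genes * (n_genes - 1) // 2)
    keys = _sample_keys(rng, genes, genes, n_pairs, set())
    return Pathway(name, name, database, frozenset(genes),
                   tuple(_pairs_from_keys(rng, keys, database)))
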