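"""GPML (WikiPathways) reader: from drawn diagram to pathway graph.

GPML encodes a *picture* of a pathway: gene boxes with pixel coordinates,
and arrows/T-bars drawn between regions of the canvas. Which genes an
arrow connects is not stated explicitly, so the parser reconstructs it
geometrically:

1. extract every gene/protein DataNode with its center coordinates;
2. cluster nodes spatially (single-linkage, centers closer than a
   100-pixel threshold join the same cluster) — a drawn stack like
   "CDK2 / CycE" acts as one endpoint;
3. treat each Line/Interaction as a straight segment, extend it as a ray
   on both sides, and take the nearest cluster bounding box hit on each
   side as the relation's source and target;
4. the arrow-head style sets the relation: Arrow = activate,
   T-Bar = inhibit, plain/solid = neutral.

Cluster-to-cluster relations are then expanded to gene-level cross
products and assembled into a :class:`~pathconcord.core.Pathway`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from xml.etree import ElementTree as ET

import networkx as nx

from .core import (
    GeneMapping,
    GeneNode,
    GroupNode,
    Pathway,
    Relation,
    finalize_pathway,
    normalize_gene,
)

log = logging.getLogger(__name__)

__all__ = [
    "SpatialNode",
    "NodeCluster",
    "RelationshipLine",
    "LineKind",
    "GpmlParseResult",
    "parse_gpml",
    "cluster_nodes",
    "resolve_line",
    "gpml_to_pathway",
    "DEFAULT_CLUSTER_THRESHOLD",
]

DEFAULT_CLUSTER_THRESHOLD = 100.0  # pixels, center-to-center

#: DataNode Type attributes accepted as network members. Metabolites,
#: labels and nested-pathway nodes are not genes and are excluded.
_GENE_NODE_TYPES = {None, "", "GeneProduct", "Protein", "Complex", "Rna", "RNA"}

_ENTREZ_XREF_DATABASES = {"entrez gene", "entrezgene", "ncbi gene", "ncbi"}


class LineKind(str, Enum):
    ARROW = "arrow"
    TBAR = "tbar"
    SOLID = "solid"


#: arrow-head attribute vocabulary -> line kind; anything unrecognized is
#: treated as solid (neutral) with a warning.
_ARROWHEAD_KINDS = {
    "arrow": LineKind.ARROW,
    "tbar": LineKind.TBAR,
    "t-bar": LineKind.TBAR,
    "line": LineKind.SOLID,
    "solid": LineKind.SOLID,
    "": LineKind.SOLID,
}

_KIND_TO_RELATION = {
    LineKind.ARROW: Relation.ACTIVATE,
    LineKind.TBAR: Relation.INHIBIT,
    LineKind.SOLID: Relation.NEUTRAL,
}


@dataclass(frozen=True)
class SpatialNode:
    """A gene box on the canvas: label, optional resolved id, geometry."""

    label: str
    gene_id: int | None
    x: float
    y: float
    width: float
    height: float
    group_ref: str | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"node {self.label!r}: non-positive extent")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (self.x - self.width / 2, self.y - self.height / 2,
                self.x + self.width / 2, self.y + self.height / 2)


@dataclass(frozen=True)
class NodeCluster:
    """A maximal set of spatially adjacent nodes, acting as one endpoint."""

    nodes: tuple[SpatialNode, ...]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("empty cluster")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        xs0, ys0, xs1, ys1 = zip(*(n.bbox for n in self.nodes))
        return (min(xs0), min(ys0), max(xs1), max(ys1))

    @property
    def centroid(self) -> tuple[float, float]:
        return (sum(n.x for n in self.nodes) / len(self.nodes),
                sum(n.y for n in self.nodes) / len(self.nodes))


@dataclass(frozen=True)
class RelationshipLine:
    """A drawn relation: straight segment plus arrow-head style."""

    start: tuple[float, float]
    end: tuple[float, float]
    kind: LineKind

    def __post_init__(self) -> None:
        if self.start == self.end:
            raise ValueError("degenerate relationship line (start == end)")


@dataclass
class GpmlParseResult:
    name: str
    nodes: list[SpatialNode]
    lines: list[RelationshipLine]
    warnings: list[str] = field(default_factory=list)


def _local(tag: str) -> str:
    """Element tag without its XML namespace."""
    return tag.rsplit("}", 1)[-1]


def _parse_graphics(el: ET.Element) -> tuple[float, float, float, float] | None:
    """Center x, y and extents from a Graphics element.

    Accepts both the CenterX/CenterY spelling (2008a/2010a) and plain
    X/Y (some 2013a writers).
    """
    for g in el:
        if _local(g.tag) != "Graphics":
            continue
        a = g.attrib
        x = a.get("CenterX", a.get("X"))
        y = a.get("CenterY", a.get("Y"))
        if x is None or y is None:
            return None
        w = float(a.get("Width", 80.0))
        h = float(a.get("Height", 20.0))
        return float(x), float(y), w, h
    return None


def _line_geometry(el: ET.Element) -> tuple[list[tuple[float, float]], str]:
    """Point coordinates and arrow-head style of a Line/Interaction.

    Multi-point (curved/elbowed) lines are approximated by their
    first-to-last segment. The arrow-head is read from the end point;
    if only the start point carries one, the direction is flipped.
    """
    points: list[tuple[float, float, str]] = []
    for g in el:
        if _local(g.tag) != "Graphics":
            continue
        for p in g:
            if _local(p.tag) == "Point":
                points.append((float(p.attrib.get("X", "nan")),
                               float(p.attrib.get("Y", "nan")),
                               p.attrib.get("ArrowHead", "")))
    if len(points) < 2:
        return [], ""
    first, last = points[0], points[-1]
    if not last[2] and first[2]:
        first, last = last, first
    return [(first[0], first[1]), (last[0], last[1])], last[2]


def parse_gpml(document: str | Path) -> GpmlParseResult:
    """Extract spatial nodes and relationship lines from a GPML document.

    ``document`` is a path or an XML string. Nodes without coordinates
    and degenerate lines are dropped with a recorded warning.
    """
    text = str(document)
    if "<" not in text:
        text = Path(document).read_text(encoding="utf-8")
    root = ET.fromstring(text)
    if _local(root.tag) != "Pathway":
        raise ValueError(f"not a GPML document (root element {_local(root.tag)!r})")
    name = root.attrib.get("Name", "")

    result = GpmlParseResult(name=name, nodes=[], lines=[])
    for el in root:
        tag = _local(el.tag)
        if tag == "DataNode":
            if el.attrib.get("Type") not in _GENE_NODE_TYPES:
                continue
            label = el.attrib.get("TextLabel", "").strip()
            geom = _parse_graphics(el)
            if geom is None:
                result.warnings.append(f"DataNode {label!r} has no coordinates; dropped")
                log.warning("DataNode %r has no coordinates; dropped", label)
                continue
            gene_id = None
            for xr in el:
                if _local(xr.tag) == "Xref":
                    db = xr.attrib.get("Database", "").strip().lower()
                    xid = xr.attrib.get("ID", "").strip()
                    if db in _ENTREZ_XREF_DATABASES and xid.isdigit():
                        gene_id = int(xid)
            x, y, w, h = geom
            result.nodes.append(SpatialNode(label, gene_id, x, y, w, h,
                                            group_ref=el.attrib.get("GroupRef")))
        elif tag in ("Line", "Interaction"):
            pts, head = _line_geometry(el)
            if len(pts) < 2 or pts[0] == pts[1]:
                result.warnings.append("degenerate relationship line dropped")
                continue
            key = head.strip().lower()
            if key not in _ARROWHEAD_KINDS:
                result.warnings.append(f"unknown arrow-head style {head!r}; treated as neutral")
                log.warning("unknown arrow-head style %r; treated as neutral", head)
            kind = _ARROWHEAD_KINDS.get(key, LineKind.SOLID)
            result.lines.append(RelationshipLine(pts[0], pts[1], kind))
    return result


def cluster_nodes(nodes: list[SpatialNode],
                  threshold: float = DEFAULT_CLUSTER_THRESHOLD) -> list[NodeCluster]:
    """Single-linkage spatial clustering of gene boxes.

    Two nodes join the same cluster when their center-to-center Euclidean
    distance is strictly below ``threshold`` (default 100 px), transitively:
    the clusters are the connected components of the proximity graph, so
    they always partition the node set. Output order follows the first
    member's input position.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if math.dist((nodes[i].x, nodes[i].y), (nodes[j].x, nodes[j].y)) < threshold:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return [NodeCluster(tuple(nodes[i] for i in comp)) for comp in comps]


def _ray_box_entry(origin: tuple[float, float], u: tuple[float, float],
                   box: tuple[float, float, float, float],
                   tmax: float) -> float | None:
    """Entry parameter t >= 0 where the ray origin + t*u first meets an
    axis-aligned box, or None if it misses within [0, tmax] (slab method)."""
    t0, t1 = 0.0, tmax
    for o, d, lo, hi in ((origin[0], u[0], box[0], box[2]),
                         (origin[1], u[1], box[1], box[3])):
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


def _point_in_box(p: tuple[float, float], box: tuple[float, float, float, float]) -> bool:
    return box[0] <= p[0] <= box[2] and box[1] <= p[1] <= box[3]


def _pick_cluster(origin: tuple[float, float], u: tuple[float, float],
                  clusters: list[NodeCluster], cap: float) -> int | None:
    """Nearest cluster whose box contains the endpoint or is hit by the
    ray from it; ties broken by centroid distance, then cluster index."""
    best: tuple[float, float, int] | None = None
    for idx, c in enumerate(clusters):
        box = c.bbox
        if _point_in_box(origin, box):
            t = 0.0
        else:
            hit = _ray_box_entry(origin, u, box, cap)
            if hit is None:
                continue
            t = hit
        cd = math.dist(origin, c.centroid)
        cand = (t, cd, idx)
        if best is None or cand < best:
            best = cand
    return best[2] if best else None


def resolve_line(line: RelationshipLine, clusters: list[NodeCluster],
                 cap: float | None = None) -> tuple[NodeCluster, NodeCluster] | None:
    """Assign source and target clusters to a drawn relation.

    The segment is extended as a ray beyond each endpoint (capped, by
    default, at the diagram diagonal): the nearest cluster box on the
    end-point side becomes the target, the nearest on the start side the
    source. An endpoint already inside a cluster box needs no extension.
    Returns None (caller logs/skips) when either side finds no cluster.
    """
    if not clusters:
        return None
    if cap is None:
        boxes = [c.bbox for c in clusters]
        xs0, ys0, xs1, ys1 = zip(*boxes)
        span = (min(xs0 + line.start[:1] + line.end[:1]),
                min(ys0 + line.start[1:] + line.end[1:]),
                max(xs1 + line.start[:1] + line.end[:1]),
                max(ys1 + line.start[1:] + line.end[1:]))
        cap = math.hypot(span[2] - span[0], span[3] - span[1]) or 1.0
    dx = line.end[0] - line.start[0]
    dy = line.end[1] - line.start[1]
    norm = math.hypot(dx, dy)
    u = (dx / norm, dy / norm)
    tgt = _pick_cluster(line.end, u, clusters, cap)
    src = _pick_cluster(line.start, (-u[0], -u[1]), clusters, cap)
    if src is None or tgt is None:
        return None
    return clusters[src], clusters[tgt]


def _cluster_group(cluster: NodeCluster, mapping: GeneMapping | None,
                   warnings: list[str]) -> GroupNode | None:
    """Resolve a cluster's member nodes to gene ids; None if nothing maps."""
    members: list[GeneNode] = []
    for n in cluster.nodes:
        if n.gene_id is not None:
            members.append(GeneNode(n.label, n.gene_id, n.x, n.y))
        elif mapping is not None:
            ids = normalize_gene(n.label, mapping) if n.label else []
            if not ids:
                warnings.append(f"node {n.label!r} unresolved; skipped")
                continue
            members.extend(GeneNode(n.label, gid, n.x, n.y) for gid in ids)
        else:
            warnings.append(f"node {n.label!r} unresolved; skipped")
    if not members:
        return None
    return GroupNode(" / ".join(n.label for n in cluster.nodes), tuple(members))


def gpml_to_pathway(document: str | Path, mapping: GeneMapping | None = None,
                    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
                    database: str = "Wiki",
                    pathway_id: str | None = None) -> Pathway:
    """Full GPML pipeline: parse, resolve ids, cluster, wire, finalize.

    Explicit GPML Group memberships (GroupRef) are honored as clusters
    as drawn; only the remaining nodes are clustered spatially. A
    document yielding zero resolved genes is an error.
    """
    parsed = parse_gpml(document)

    grouped: dict[str, list[SpatialNode]] = {}
    loose: list[SpatialNode] = []
    for n in parsed.nodes:
        if n.group_ref:
            grouped.setdefault(n.group_ref, []).append(n)
        else:
            loose.append(n)
    clusters = [NodeCluster(tuple(v)) for _, v in sorted(grouped.items())]
    clusters += cluster_nodes(loose, threshold)

    resolved_groups: list[GroupNode | None] = [
        _cluster_group(c, mapping, parsed.warnings) for c in clusters
    ]

    relations = []
    for line in parsed.lines:
        hit = resolve_line(line, clusters)
        if hit is None:
            parsed.warnings.append("unresolved relationship line skipped")
            log.warning("pathway %r: unresolved relationship line skipped", parsed.name)
            continue
        src_c, tgt_c = hit
        src = resolved_groups[clusters.index(src_c)]
        tgt = resolved_groups[clusters.index(tgt_c)]
        if src is None or tgt is None:
            parsed.warnings.append("relationship endpoint cluster has no resolved genes")
            continue
        relations.append((src, tgt, _KIND_TO_RELATION[line.kind]))

    groups = [g for g in resolved_groups if g is not None]
    if not groups:
        raise ValueError(f"GPML document {parsed.name!r} yielded no resolved genes")
    return finalize_pathway(parsed.name or "unnamed", database,
                            groups=groups, relations=relations,
                            pathway_id=pathway_id)
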