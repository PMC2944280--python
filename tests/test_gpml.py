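"""Diagram parsing: node extraction, spatial clustering, line resolution."""

from random import Random

import pytest

from oracles import brute_force_partition
from pathconcord.core import GenePair, Pathway, Relation
from pathconcord.gpml import (
    LineKind,
    NodeCluster,
    RelationshipLine,
    SpatialNode,
    cluster_nodes,
    gpml_to_pathway,
    parse_gpml,
    resolve_line,
)
from pathconcord.synthetic import generate_gpml, random_pathway


def _node(label, x, y, gid=None, w=80.0, h=20.0):
    return SpatialNode(label, gid, x, y, w, h)


FIVE_NODE_DOC = """<?xml version="1.0"?>
<Pathway xmlns="http://pathvisio.org/GPML/2013a" Name="Toy">
  <DataNode TextLabel="ATM" Type="GeneProduct">
    <Graphics CenterX="100" CenterY="100" Width="80" Height="20"/>
    <Xref Database="Entrez Gene" ID="472"/>
  </DataNode>
  <DataNode TextLabel="CHK1" Type="GeneProduct">
    <Graphics CenterX="600" CenterY="100" Width="80" Height="20"/>
    <Xref Database="Entrez Gene" ID="1111"/>
  </DataNode>
  <DataNode TextLabel="MDM2" Type="GeneProduct">
    <Graphics CenterX="100" CenterY="600" Width="80" Height="20"/>
    <Xref Database="Entrez Gene" ID="4193"/>
  </DataNode>
  <DataNode TextLabel="TP53" Type="GeneProduct">
    <Graphics CenterX="600" CenterY="600" Width="80" Height="20"/>
    <Xref Database="Entrez Gene" ID="7157"/>
  </DataNode>
  <DataNode TextLabel="CHK2" Type="GeneProduct">
    <Graphics CenterX="1100" CenterY="1100" Width="80" Height="20"/>
    <Xref Database="Entrez Gene" ID="11200"/>
  </DataNode>
  <DataNode TextLabel="glucose" Type="Metabolite">
    <Graphics CenterX="900" CenterY="900" Width="80" Height="20"/>
  </DataNode>
  <Interaction>
    <Graphics>
      <Point X="160" Y="100"/>
      <Point X="540" Y="100" ArrowHead="Arrow"/>
    </Graphics>
  </Interaction>
  <Interaction>
    <Graphics>
      <Point X="160" Y="600"/>
      <Point X="540" Y="600" ArrowHead="TBar"/>
    </Graphics>
  </Interaction>
</Pathway>
"""


class TestParseGpml:
    def test_counts_preserved_and_metabolites_excluded(self):
        parsed = parse_gpml(FIVE_NODE_DOC)
        assert parsed.name == "Toy"
        assert len(parsed.nodes) == 5
        assert len(parsed.lines) == 2
        assert [n.label for n in parsed.nodes] == ["ATM", "CHK1", "MDM2", "TP53", "CHK2"]

    def test_tbar_line_kind(self):
        parsed = parse_gpml(FIVE_NODE_DOC)
        assert parsed.lines[1].kind == LineKind.TBAR
        assert parsed.lines[0].kind == LineKind.ARROW

    def test_unknown_arrowhead_treated_as_neutral_with_warning(self):
        doc = FIVE_NODE_DOC.replace('ArrowHead="Arrow"', 'ArrowHead="Wiggle"')
        parsed = parse_gpml(doc)
        assert parsed.lines[0].kind == LineKind.SOLID
        assert any("Wiggle" in w for w in parsed.warnings)

    def test_generated_document_round_trips_labels(self, rng):
        p = random_pathway(rng, "Gen", "Wiki", n_genes=5, n_pairs=3, id_start=10)
        xml, manifest = generate_gpml(p, seed=4)
        parsed = parse_gpml(xml)
        assert sorted(n.gene_id for n in parsed.nodes) == manifest["genes"]
        assert len(parsed.lines) == manifest["n_lines"]

    def test_malformed_xml_raises(self):
        with pytest.raises(Exception):
            parse_gpml("<Pathway><unclosed></Pathway")


class TestClusterNodes:
    def test_close_nodes_form_one_cluster(self):
        nodes = [_node("a", 0, 0), _node("b", 50, 0)]
        assert len(cluster_nodes(nodes)) == 1

    def test_distant_nodes_stay_separate(self):
        nodes = [_node("a", 0, 0), _node("b", 500, 0)]
        assert len(cluster_nodes(nodes)) == 2

    def test_chain_is_transitively_merged(self):
        nodes = [_node("a", 0, 0), _node("b", 90, 0), _node("c", 180, 0)]
        assert len(cluster_nodes(nodes)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_transitive_closure(self, seed):
        rng = Random(seed)
        n = rng.randint(1, 12)
        nodes = [_node(f"n{i}", rng.uniform(0, 600), rng.uniform(0, 600))
                 for i in range(n)]
        got = {frozenset(nodes.index(m) for m in c.nodes)
               for c in cluster_nodes(nodes)}
        want = brute_force_partition([(nd.x, nd.y) for nd in nodes], 100.0)
        assert got == want

    def test_partition_covers_every_node_exactly_once(self, rng):
        nodes = [_node(f"n{i}", rng.uniform(0, 400), rng.uniform(0, 400))
                 for i in range(15)]
        clusters = cluster_nodes(nodes, threshold=120)
        members = [m for c in clusters for m in c.nodes]
        assert len(members) == len(nodes)
        assert {id(m) for m in members} == {id(n) for n in nodes}

    def test_translation_invariance(self, rng):
        nodes = [_node(f"n{i}", rng.uniform(0, 500), rng.uniform(0, 500))
                 for i in range(10)]
        shifted = [SpatialNode(n.label, n.gene_id, n.x + 1234.5, n.y - 987.2,
                               n.width, n.height) for n in nodes]
        part = lambda ns: {frozenset(m.label for m in c.nodes)
                           for c in cluster_nodes(ns)}
        assert part(nodes) == part(shifted)

    def test_reordering_invariance(self, rng):
        nodes = [_node(f"n{i}", rng.uniform(0, 500), rng.uniform(0, 500))
                 for i in range(10)]
        reordered = list(nodes)
        rng.shuffle(reordered)
        part = lambda ns: {frozenset(m.label for m in c.nodes)
                           for c in cluster_nodes(ns)}
        assert part(nodes) == part(reordered)


class TestResolveLine:
    def test_tbar_between_kinase_stack_and_orc_family(self):
        # a CDK2/CycE stack inhibiting a family of ORC genes, drawn as a
        # short T-bar between the two stacks
        cdk = NodeCluster((_node("CDK2", 100, 100, 1017), _node("CCNE1", 100, 140, 898)))
        orc = NodeCluster((_node("ORC1", 600, 100, 4998), _node("ORC2", 600, 140, 4999),
                           _node("ORC3", 600, 180, 23595)))
        line = RelationshipLine((200, 120), (450, 120), LineKind.TBAR)
        src, tgt = resolve_line(line, [cdk, orc])
        assert src is cdk and tgt is orc

    def test_endpoints_inside_boxes_need_no_extension(self):
        a = NodeCluster((_node("a", 100, 100),))
        b = NodeCluster((_node("b", 500, 100),))
        line = RelationshipLine((100, 100), (500, 100), LineKind.ARROW)
        src, tgt = resolve_line(line, [a, b])
        assert src is a and tgt is b

    def test_line_pointing_nowhere_is_unresolved(self):
        a = NodeCluster((_node("a", 100, 100),))
        b = NodeCluster((_node("b", 200, 100),))
        line = RelationshipLine((100, 900), (200, 900), LineKind.ARROW)
        assert resolve_line(line, [a, b]) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_generated_wiring_recovered(self, seed):
        rng = Random(100 + seed)
        p = random_pathway(rng, f"W{seed}", "Wiki", n_genes=9, n_pairs=7, id_start=30)
        xml, manifest = generate_gpml(p, seed=seed)
        parsed = gpml_to_pathway(xml)
        got = sorted([q.source_gene_id, q.target_gene_id, q.relation.value]
                     for q in parsed.pairs)
        assert got == manifest["pairs"]


class TestGpmlToPathway:
    def test_activation_and_inhibition_semantics(self, mapping):
        pw = gpml_to_pathway(FIVE_NODE_DOC, mapping)
        rels = {(p.source_gene_id, p.target_gene_id, p.relation) for p in pw.pairs}
        assert (472, 1111, Relation.ACTIVATE) in rels   # ATM -> CHK1
        assert (4193, 7157, Relation.INHIBIT) in rels   # MDM2 -| TP53
        assert pw.genes == {472, 1111, 4193, 7157, 11200}

    def test_document_without_lines_yields_genes_only(self):
        doc = FIVE_NODE_DOC.split("<Interaction>")[0] + "</Pathway>"
        pw = gpml_to_pathway(doc)
        assert pw.n_genes == 5
        assert pw.pairs == ()

    def test_no_resolvable_genes_is_an_error(self):
        doc = """<Pathway xmlns="g" Name="Empty"></Pathway>"""
        with pytest.raises(ValueError):
            gpml_to_pathway(doc)

    def test_explicit_groups_honored_as_clusters(self):
        # two far-apart nodes joined by an explicit GroupRef become one
        # endpoint even though spatial clustering would separate them
        doc = """<Pathway xmlns="g" Name="G">
          <DataNode TextLabel="A" Type="GeneProduct" GroupRef="g1">
            <Graphics CenterX="100" CenterY="100"/><Xref Database="Entrez Gene" ID="1"/>
          </DataNode>
          <DataNode TextLabel="B" Type="GeneProduct" GroupRef="g1">
            <Graphics CenterX="100" CenterY="400"/><Xref Database="Entrez Gene" ID="2"/>
          </DataNode>
          <DataNode TextLabel="C" Type="GeneProduct">
            <Graphics CenterX="800" CenterY="250"/><Xref Database="Entrez Gene" ID="3"/>
          </DataNode>
          <Interaction><Graphics>
            <Point X="200" Y="250"/><Point X="700" Y="250" ArrowHead="Arrow"/>
          </Graphics></Interaction>
        </Pathway>"""
        pw = gpml_to_pathway(doc)
        assert {(p.source_gene_id, p.target_gene_id) for p in pw.pairs} == {(1, 3), (2, 3)}

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_on_generated_layouts(self, seed):
        rng = Random(seed)
        p = random_pathway(rng, f"R{seed}", "Wiki", n_genes=7, n_pairs=5, id_start=50)
        xml, _ = generate_gpml(p, seed=seed)
        q = gpml_to_pathway(xml)
        assert q.genes == p.genes
        assert q.pair_keys == p.pair_keys
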