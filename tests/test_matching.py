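"""Name- and overlap-based pathway matching and the matcher comparisons."""

from random import Random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_lcs
from conftest import make_pathway
from pathconcord.core import GenePair, Pathway, PathwayDatabase, Relation
from pathconcord.matching import (
    compare_lcs_vs_gene_overlap,
    compare_lcs_vs_pair_overlap,
    longest_common_substring,
    match_by_gene_overlap,
    match_by_lcs,
    match_by_pair_overlap,
    normalize_name,
    rank_by_lcs,
    topk_overlap_curve,
)
from pathconcord.synthetic import (
    DatabaseSpec,
    PlantedPathwayPair,
    generate_databases,
)

simple_names = st.text(alphabet="ab", min_size=0, max_size=8)


class TestLongestCommonSubstring:
    def test_case_folded_match_spans_thirteen_characters(self):
        length, sub = longest_common_substring("Wnt signaling", "Wnt Signaling Pathway")
        assert length == 13
        assert sub == "wnt signaling"

    def test_identity_is_full_length(self):
        s = "apoptosis signaling"
        assert longest_common_substring(s, s)[0] == len(s)

    def test_organism_suffix_is_boilerplate(self):
        length, _ = longest_common_substring("Apoptosis - Homo sapiens (human)",
                                             "Apoptosis")
        assert length == len("apoptosis")

    @settings(max_examples=200, derandomize=True)
    @given(a=simple_names, b=simple_names)
    def test_equals_all_substrings_oracle(self, a, b):
        assert longest_common_substring(a, b)[0] == brute_force_lcs(a, b)

    @settings(max_examples=100, derandomize=True)
    @given(a=simple_names, b=simple_names)
    def test_symmetric_and_bounded(self, a, b):
        la = longest_common_substring(a, b)[0]
        assert la == longest_common_substring(b, a)[0]
        assert la <= min(len(a), len(b))


def _named(pid, name, db="X", genes=(1, 2), pairs=()):
    return Pathway(pid, name, db, frozenset(genes),
                   tuple(GenePair(s, t, Relation(r)) for s, t, r in pairs))


class TestRankByLcs:
    def test_closest_name_ranks_first(self):
        x = _named("x", "Apoptosis")
        ranked = rank_by_lcs(x, [_named("a", "Cell cycle"),
                                 _named("b", "Apoptosis Signaling")])
        assert ranked[0][0].name == "Apoptosis Signaling"

    def test_single_candidate(self):
        x = _named("x", "Anything")
        ranked = rank_by_lcs(x, [_named("a", "Else")])
        assert ranked[0][0].name == "Else"

    def test_order_agrees_with_pairwise_lcs(self, rng):
        x = _named("x", "wnt signaling pathway")
        cands = [_named(str(i), "".join(rng.choice("wnt sigpath") for _ in range(10)))
                 for i in range(12)]
        ranked = rank_by_lcs(x, cands)
        scores = [longest_common_substring(x.name, c.name)[0] for c, _ in ranked]
        assert scores == sorted(scores, reverse=True)


def _dbs_for(*pathway_pairs):
    a, b = PathwayDatabase("A"), PathwayDatabase("B")
    for pa, pb in pathway_pairs:
        if pa is not None:
            a.add(pa)
        if pb is not None:
            b.add(pb)
    return a, b


class TestMatchByLcs:
    def test_near_identical_names_auto_confirm(self):
        a, b = _dbs_for((_named("1", "T cell receptor signaling", "A"),
                         _named("2", "T cell receptor Signaling", "B")))
        report = match_by_lcs(a, b)
        assert [(m.key, m.confirmed) for m in report.matches] == [(("1", "2"), True)]

    def test_disjoint_names_stay_pending(self):
        a, b = _dbs_for((_named("1", "Urea cycle", "A"),
                         _named("2", "Olfactory transduction", "B")))
        report = match_by_lcs(a, b)
        assert report.matches == []
        assert len(report.pending) == 1
        assert [u.pathway.pathway_id for u in report.unmatched_a] == ["1"]

    def test_confirm_list_accepts_and_rejects(self):
        a, b = _dbs_for((_named("1", "Urea cycle", "A"),
                         _named("2", "Olfactory transduction", "B")))
        accepted = match_by_lcs(a, b, decisions={("1", "2"): "accept"})
        assert [m.key for m in accepted.matches] == [("1", "2")]
        same = _dbs_for((_named("1", "Apoptosis", "A"), _named("2", "Apoptosis", "B")))
        rejected = match_by_lcs(*same, decisions={("1", "2"): "reject"})
        assert rejected.matches == []

    def test_planted_name_variants_fully_recovered(self, planted):
        (db1, db2), manifest = planted
        report = match_by_lcs(db1, db2)
        got = sorted(m.key for m in report.matches)
        assert got == sorted(map(tuple, manifest.expected_matches))

    def test_matching_is_injective_both_ways(self, planted):
        (db1, db2), _ = planted
        report = match_by_lcs(db1, db2)
        lefts = [m.pathway_a.pathway_id for m in report.matches]
        rights = [m.pathway_b.pathway_id for m in report.matches]
        assert len(lefts) == len(set(lefts))
        assert len(rights) == len(set(rights))


def _overlap_spec(n_shared_pairs):
    plant = PlantedPathwayPair("Alpha complex assembly", "Beta oxidation chain",
                               30, 30, 25, 40, 40, n_shared_pairs)
    return DatabaseSpec(db_names=("A", "B"), planted=(plant,))


class TestOverlapMatchers:
    def test_pair_overlap_above_threshold_matches(self):
        dbs, _ = generate_databases(3, _overlap_spec(25))
        report = match_by_pair_overlap(*dbs)
        assert [m.pair_overlap for m in report.matches] == [25]

    def test_nineteen_shared_pairs_rejected_at_default_threshold(self):
        dbs, _ = generate_databases(3, _overlap_spec(19))
        assert match_by_pair_overlap(*dbs).matches == []
        assert len(match_by_pair_overlap(*dbs, min_pairs=19).matches) == 1

    def test_identical_pathway_matches_itself_by_genes(self):
        p = make_pathway("1", "Same", "A", [(1, 2, "activate"), (2, 3, "inhibit")])
        q = make_pathway("2", "Same", "B", [(1, 2, "activate"), (2, 3, "inhibit")])
        report = match_by_gene_overlap(*_dbs_for((p, q)))
        assert [m.key for m in report.matches] == [("1", "2")]

    def test_gene_matcher_pairs_spurious_overlap_pair_matcher_does_not(self):
        # same gene complement, fully disjoint wiring: a false positive
        # for gene matching, invisible to pair matching
        genes = range(1, 21)
        pa = Pathway("1", "Urea cycle", "A", frozenset(genes),
                     tuple(GenePair(i, i + 1, Relation.ACTIVATE) for i in range(1, 10)))
        pb = Pathway("2", "Olfactory transduction", "B", frozenset(genes),
                     tuple(GenePair(i, i + 1, Relation.ACTIVATE) for i in range(11, 20)))
        a, b = _dbs_for((pa, pb))
        assert len(match_by_gene_overlap(a, b).matches) == 1
        assert match_by_pair_overlap(a, b, min_pairs=1).matches == []

    def test_greedy_assignment_equals_brute_force_on_small_instance(self, rng):
        a, b = PathwayDatabase("A"), PathwayDatabase("B")
        for i in range(4):
            a.add(make_pathway(f"a{i}", f"Left {i}", "A",
                               [(10 * i + j, 10 * i + j + 1, "neutral")
                                for j in range(1, 5)]))
            b.add(make_pathway(f"b{i}", f"Right {i}", "B",
                               [(10 * i + j, 10 * i + j + 1, "neutral")
                                for j in range(1, 3 + i)]))
        report = match_by_pair_overlap(a, b, min_pairs=1)
        # brute force: repeatedly take the highest-overlap remaining pair
        remaining_a = {p.pathway_id: p for p in a}
        remaining_b = {p.pathway_id: p for p in b}
        expected = []
        while True:
            best = None
            for pa in remaining_a.values():
                for pb in remaining_b.values():
                    ov = len(pa.pair_keys & pb.pair_keys)
                    if ov >= 1:
                        key = (-ov, normalize_name(pa.name), normalize_name(pb.name))
                        if best is None or key < best[0]:
                            best = (key, pa, pb, ov)
            if best is None:
                break
            _, pa, pb, ov = best
            expected.append((pa.pathway_id, pb.pathway_id))
            del remaining_a[pa.pathway_id]
            del remaining_b[pb.pathway_id]
        assert [m.key for m in report.matches] == expected


class TestMatcherComparisons:
    def test_planted_lcs_partners_in_gene_overlap_top_three(self, planted):
        (db1, db2), _ = planted
        report = compare_lcs_vs_gene_overlap(db1, db2)
        assert report["fraction_in_top"] == 1.0

    def test_empty_database_gives_empty_report(self):
        a, b = PathwayDatabase("A"), PathwayDatabase("B")
        report = compare_lcs_vs_gene_overlap(a, b)
        assert report["rows"] == []
        assert report["fraction_in_top"] is None

    def test_matched_pathways_dominate_unmatched_in_pair_overlap(self, planted):
        (db1, db2), _ = planted
        report = compare_lcs_vs_pair_overlap(db1, db2)
        assert report["matched_pair_pct"]["n"] > 0
        assert report["unmatched_pair_pct"]["n"] > 0
        assert report["matched_pair_pct"]["mean"] > report["unmatched_pair_pct"]["mean"]

    def test_single_pathway_per_database_gives_one_point(self):
        a, b = _dbs_for((make_pathway("1", "Apoptosis", "A", [(1, 2, "activate")]),
                         make_pathway("2", "Apoptosis", "B", [(1, 2, "activate")])))
        report = compare_lcs_vs_pair_overlap(a, b)
        assert len(report["matched"]) == 1
        assert report["unmatched"] == []

    def test_topk_curve_is_all_ones_for_identical_databases(self):
        a, b = PathwayDatabase("A"), PathwayDatabase("B")
        for i in range(5):
            spec = [(10 * i + j, 10 * i + j + 1, "activate") for j in range(1, 6)]
            a.add(make_pathway(f"a{i}", f"Pathway number {i}", "A", spec))
            b.add(make_pathway(f"b{i}", f"Pathway number {i}", "B", spec))
        curve = topk_overlap_curve(a, b, min_pairs=0)
        assert all(v == 1.0 for v in curve["gene"])
        assert all(v == 1.0 for v in curve["gene_pair"])

    def test_pair_curve_dominates_gene_curve_on_spurious_gene_overlap(self):
        a, b = PathwayDatabase("A"), PathwayDatabase("B")
        shared = tuple(range(100, 140))  # housekeeping genes in everything
        for i in range(4):
            wiring = [(10 * i + j, 10 * i + j + 1, "activate") for j in range(1, 6)]
            a.add(make_pathway(f"a{i}", f"Distinct name {i}", "A", wiring,
                               extra_genes=shared))
            b.add(make_pathway(f"b{i}", f"Distinct name {i}", "B", wiring,
                               extra_genes=shared[: 40 - i]))
        curve = topk_overlap_curve(a, b, min_pairs=0)
        assert all(gp >= g for gp, g in zip(curve["gene_pair"], curve["gene"])
                   if gp is not None and g is not None)
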