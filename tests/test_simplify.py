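"""Pruning, complement decomposition, maximal path search and unfolding."""

import random

import pytest

from graphbwt.build import build
from graphbwt.fixtures import FixtureSpec, gen_fixture
from graphbwt.graph import BidirectedGraph, encode_node, node_id, reverse_node, reverse_path
from graphbwt.simplify import (
    PruneParams,
    UnfoldMapping,
    complement_components,
    embed_path,
    find_maximal_paths,
    induced_graph,
    prune,
    simplify,
    translate,
    unfold,
    unfolded_component_paths,
)

from conftest import random_spec


def chain_graph(n, label="ACGT"):
    g = BidirectedGraph()
    for i in range(1, n + 1):
        g.add_node(i, label)
    for i in range(1, n):
        g.add_edge(encode_node(i), encode_node(i + 1))
    return g


def random_pruned(rng, graph, params=PruneParams()):
    """Default heuristic pruning plus random extra edge/node removal."""
    pruned = prune(graph, params)
    seen = set()
    for u, v in sorted(pruned.edges()):
        key = min((u, v), (reverse_node(v), reverse_node(u)))
        if key in seen:
            continue
        seen.add(key)
        if rng.random() < 0.3:
            pruned.remove_edge(u, v)
    for gid in sorted(pruned.labels):
        if rng.random() < 0.15:
            pruned.remove_node(gid)
    return pruned


class TestPrune:
    def test_linear_chain_unchanged(self):
        g = chain_graph(10)
        for params in [PruneParams(min_component_bp=1), PruneParams(k=8, max_choices=0, min_component_bp=1)]:
            assert prune(g, params).edges() == g.edges()

    def test_small_component_deleted(self):
        g = BidirectedGraph()
        g.add_node(1, "ACGTACGTAC")  # 10 bp < 33 bp
        assert not prune(g, PruneParams()).has_node(1)
        g2 = BidirectedGraph()
        g2.add_node(1, "A" * 40)
        assert prune(g2, PruneParams()).has_node(1)

    def test_dense_bubble_cluster_pruned(self):
        # five adjacent biallelic sites with 1 bp alleles: any 24 bp window
        # through the middle makes far more than 3 edge choices
        g = BidirectedGraph()
        nid = 1

        def add(label):
            nonlocal nid
            g.add_node(nid, label)
            nid += 1
            return nid - 1

        head, tail = add("T" * 30), add("T" * 30)
        prev = encode_node(head)
        middles = []
        for _ in range(5):
            a, b, m = add("A"), add("C"), add("G")
            g.add_edge(prev, encode_node(a))
            g.add_edge(prev, encode_node(b))
            g.add_edge(encode_node(a), encode_node(m))
            g.add_edge(encode_node(b), encode_node(m))
            prev = encode_node(m)
            middles.append((a, b, m))
        g.add_edge(prev, encode_node(tail))
        pruned = prune(g, PruneParams(min_component_bp=1))
        # the middle bubbles lose their branching edges
        a, b, m = middles[2]
        assert not pruned.has_edge(encode_node(a), encode_node(m))
        assert not pruned.has_edge(encode_node(b), encode_node(m))
        # but the unbranched head edge of the chain keeps its window intact
        assert pruned.has_node(head)

    def test_forced_edges_never_removed(self):
        g = chain_graph(3, label="A")  # 1 bp labels: windows span everything
        pruned = prune(g, PruneParams(k=24, max_choices=0, min_component_bp=1))
        assert pruned.edges() == g.edges()

    def test_restore_reference(self):
        g = chain_graph(3, label="A")
        g.reference_paths["ref"] = (2, 4, 6)
        params = PruneParams(min_component_bp=100, restore_reference=True)
        restored = prune(g, params)
        assert restored.has_node(1) and restored.has_edge(2, 4)
        assert not prune(g, PruneParams(min_component_bp=100)).has_node(1)


class TestComplement:
    def test_no_pruning_no_components(self, f1):
        g, paths = f1
        idx = build(paths)
        assert complement_components(induced_graph(g, idx), g) == []

    def test_single_bubble_component(self, f1):
        g, paths = f1
        idx = build(paths)
        pruned = g.copy()
        for gid in (2, 3, 4):
            pruned.remove_node(gid)
        comps = complement_components(induced_graph(g, idx), pruned)
        assert len(comps) == 1
        assert comps[0].nodes == {1, 2, 3, 4, 5}
        assert comps[0].border == {1, 5}
        assert comps[0].internal == {2, 3, 4}

    def test_two_disjoint_bubbles(self):
        g = chain_graph(7)
        for gid, (a, b) in [(8, (1, 3)), (9, (4, 6))]:
            g.add_node(gid, "T")
            g.add_edge(encode_node(a), encode_node(gid))
            g.add_edge(encode_node(gid), encode_node(b))
        paths = [
            (2, 16, 6, 8, 18, 12, 14),
            (2, 4, 6, 8, 10, 12, 14),
        ]
        idx = build(paths)
        pruned = g.copy()
        pruned.remove_node(8)
        pruned.remove_node(9)
        comps = complement_components(induced_graph(g, idx), pruned)
        assert len(comps) == 2
        assert comps[0].nodes == {1, 3, 8}
        assert comps[1].nodes == {4, 6, 9}


class TestMaximalPaths:
    def test_f1_bubble(self, f1):
        g, paths = f1
        idx = build(paths)
        pruned = g.copy()
        for gid in (2, 3, 4):
            pruned.remove_node(gid)
        comp = complement_components(induced_graph(g, idx), pruned)[0]
        found = find_maximal_paths(comp, idx)
        # exactly the two haplotype routes, no mixing of bubble alleles
        assert set(found) == {(2, 4, 8, 10), (2, 6, 8, 10)}

    def test_untouched_component_empty(self, f1):
        g, paths = f1
        idx = build([(2, 4, 8, 10)])
        pruned = g.copy()
        pruned.remove_node(3)  # only the unused allele is pruned
        comps = complement_components(induced_graph(g, idx), pruned)
        assert comps == []  # induced graph never used node 3

    def test_haplotype_crossing_twice_gives_two_paths(self):
        g = chain_graph(5)
        path = (2, 4, 6, 8, 10)
        idx = build([path])
        pruned = g.copy()
        pruned.remove_edge(2, 4)
        pruned.remove_edge(6, 8)
        comps = complement_components(induced_graph(g, idx), pruned)
        found = [p for c in comps for p in find_maximal_paths(c, idx)]
        assert sorted(found) == [(2, 4), (6, 8)]


class TestUnfold:
    def test_single_path_duplication(self):
        # one maximal path of length 4 through a pruned bubble: the two
        # border nodes are reused and the two internal nodes duplicated
        g = chain_graph(4)
        idx = build([(2, 4, 6, 8)])
        pruned = g.copy()
        pruned.remove_node(2)
        pruned.remove_node(3)
        comp = complement_components(induced_graph(g, idx), pruned)[0]
        paths = find_maximal_paths(comp, idx)
        assert paths == [(2, 4, 6, 8)]
        mapping = UnfoldMapping(originals=set(g.labels))
        _, report = unfold(pruned, comp, paths, g, mapping, next_id=5)
        assert len(report.duplicate_ids) == 2
        assert len(report.added_edges) == 3
        witness = embed_path(pruned, mapping, (2, 4, 6, 8))
        assert witness is not None
        assert translate(mapping, witness) == (2, 4, 6, 8)

    def test_shared_prefix_shares_duplicate(self, f1):
        g, paths = f1
        idx = build(paths)
        pruned = g.copy()
        for gid in (2, 3, 4):
            pruned.remove_node(gid)
        simp, mapping, details = simplify(g, idx, pruned=pruned, return_details=True)
        # paths (1,2,4,5) and (1,3,4,5) share the length-1 prefix root (border)
        # and the whole suffix (4,5): one duplicate each for nodes 2 and 3,
        # one shared duplicate for node 4
        dup_targets = sorted(mapping.duplicates.values())
        assert dup_targets == [4, 6, 8]

    def test_translate_respects_orientation(self, f1):
        g, paths = f1
        idx = build(paths)
        pruned = g.copy()
        pruned.remove_node(2)
        simp, mapping = simplify(g, idx, pruned=pruned)
        for p in idx.forward_paths():
            w = embed_path(simp, mapping, p)
            assert translate(mapping, reverse_path(w)) == reverse_path(
                translate(mapping, w)
            )

    def test_translate_unknown_node(self):
        mapping = UnfoldMapping(originals={1, 2})
        assert translate(mapping, (2, 4)) == (2, 4)
        with pytest.raises(ValueError):
            translate(mapping, (2, 4, 99))


class TestSimplify:
    def test_no_pruned_edges_identity(self, f1):
        g, paths = f1
        idx = build(paths)
        simp, mapping = simplify(g, idx, pruned=g)
        assert simp == g
        assert mapping.duplicates == {}

    def test_bubble_restored_via_duplicates(self, f1):
        g, paths = f1
        idx = build(paths)
        pruned = g.copy()
        pruned.remove_node(2)  # haplotype-supported allele removed
        simp, mapping = simplify(g, idx, pruned=pruned)
        assert mapping.duplicates  # restored through duplicates
        for p in idx.forward_paths():
            assert embed_path(simp, mapping, p) is not None

    @pytest.mark.parametrize("seed", range(8))
    def test_completeness_and_tightness_random(self, seed):
        rng = random.Random(4000 + seed)
        g, paths = gen_fixture(random_spec(rng, 4000 + seed, path_count=12))
        idx = build(paths)
        pruned = random_pruned(rng, g)
        simp, mapping, details = simplify(g, idx, pruned=pruned, return_details=True)
        for p in idx.forward_paths():
            w = embed_path(simp, mapping, p)
            assert w is not None
            assert translate(mapping, w) == tuple(p)
            assert simp.is_path(w)
            assert simp.spell(w) == g.spell(p)
        for d in details:
            assert unfolded_component_paths(simp, mapping, d) == set(d.maximal_paths)

    def test_kmer_preservation(self, seed=99):
        rng = random.Random(seed)
        g, paths = gen_fixture(random_spec(rng, seed, path_count=10))
        idx = build(paths)
        pruned = random_pruned(rng, g)
        simp, mapping = simplify(g, idx, pruned=pruned)
        k = 8
        for p in idx.forward_paths():
            hap = g.spell(p)
            witness = embed_path(simp, mapping, p)
            spelled = simp.spell(witness)
            for i in range(len(hap) - k + 1):
                assert hap[i : i + k] in spelled
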