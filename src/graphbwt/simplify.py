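"""Haplotype-aware graph simplification: pruning and path unfolding.

Pruning removes edges that force too many edge choices within a k-base
window (an *edge choice* is the traversal of an edge whose source has
out-degree >= 2 or whose target has in-degree >= 2), then drops weakly
connected components with too little sequence.  An edge is kept if at least
one k-base window crossing it stays within the choice budget, and edges with
no alternatives (sole outgoing and sole incoming) are never deleted.

Pruning breaks paths taken by known haplotypes.  Unfolding restores them:
the complement of the pruned graph with respect to the graph induced by the
indexed haplotype paths decomposes into connected components; within each
component the haplotype-supported *maximal paths* (border-to-border,
dead-end, or entirely internal) are enumerated with GBWT search states, each
path is split into a prefix and a suffix of equal length, and a trie of the
prefixes plus a trie of the reverse suffixes is turned back into graph
structure.  Shared trie edges share duplicated nodes, which keeps the number
of duplicates — and the spurious recombinations they could create — small,
while a translation table maps every duplicate back to its original oriented
node.  After unfolding, every indexed haplotype path is embeddable in the
simplified graph.

The unfolding step works with any pruning algorithm that removes nodes or
edges; it only looks at the complement edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

from .gbwt import GBWTIndex, SearchState, UnsupportedOperationError
from .graph import (
    ENDMARKER,
    BidirectedGraph,
    encode_node,
    node_id,
    reverse_node,
    reverse_path,
)


@dataclass(frozen=True)
class PruneParams:
    k: int = 24  # window length in bases
    max_choices: int = 3  # allowed edge choices per window
    min_component_bp: int = 33  # smaller components are deleted
    restore_reference: bool = False

    def __post_init__(self) -> None:
        if self.k < 1 or self.max_choices < 0:
            raise ValueError("k must be >= 1 and max_choices >= 0")


# -- pruning -------------------------------------------------------------------


def _min_window_choices(graph: BidirectedGraph, u: int, v: int, k: int) -> int:
    """Minimum number of edge choices over all k-base windows crossing (u, v).

    A window is a walk spelling k bases with at least one base on each side
    of the u|v boundary; walks that run off the graph are allowed to be
    shorter.  Memoised over (oriented node, remaining bases).
    """

    def is_choice(a: int, b: int) -> bool:
        return graph.out_degree(a) >= 2 or graph.in_degree(b) >= 2

    def length(x: int) -> int:
        return len(graph.labels[node_id(x)])

    fwd_memo: dict[tuple[int, int], int] = {}
    bwd_memo: dict[tuple[int, int], int] = {}

    def g_fwd(x: int, need: int) -> int:
        # cheapest continuation consuming `need` bases starting at x's first base
        if need <= length(x):
            return 0
        key = (x, need)
        if key in fwd_memo:
            return fwd_memo[key]
        fwd_memo[key] = best = min(
            (
                (1 if is_choice(x, w) else 0) + g_fwd(w, need - length(x))
                for w in graph.successors(x)
            ),
            default=0,  # the walk runs off the graph: shorter window
        )
        return best

    def g_bwd(x: int, need: int) -> int:
        if need <= length(x):
            return 0
        key = (x, need)
        if key in bwd_memo:
            return bwd_memo[key]
        bwd_memo[key] = best = min(
            (
                (1 if is_choice(t, x) else 0) + g_bwd(t, need - length(x))
                for t in graph.predecessors(x)
            ),
            default=0,
        )
        return best

    base = 1 if is_choice(u, v) else 0
    return base + min(g_bwd(u, x) + g_fwd(v, k - x) for x in range(1, k))


def prune(graph: BidirectedGraph, params: PruneParams) -> BidirectedGraph:
    """Heuristically simplify a graph for k-mer indexing."""
    pruned = graph.copy()
    doomed = []
    seen = set()
    for u, v in graph.edges():
        mirror = (reverse_node(v), reverse_node(u))
        if min((u, v), mirror) in seen:
            continue
        seen.add(min((u, v), mirror))
        forced = graph.out_degree(u) == 1 and graph.in_degree(v) == 1
        if forced:
            continue
        if _min_window_choices(graph, u, v, params.k) > params.max_choices:
            doomed.append((u, v))
    for u, v in doomed:
        pruned.remove_edge(u, v)

    # delete weakly connected components with too little sequence
    parent = {gid: gid for gid in pruned.labels}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in pruned.edges():
        a, b = find(node_id(u)), find(node_id(v))
        if a != b:
            parent[a] = b
    sizes: dict[int, int] = {}
    for gid in pruned.labels:
        root = find(gid)
        sizes[root] = sizes.get(root, 0) + len(pruned.labels[gid])
    for gid in list(pruned.labels):
        if sizes[find(gid)] < params.min_component_bp:
            pruned.remove_node(gid)

    if params.restore_reference:
        for name in sorted(graph.reference_paths):
            path = graph.reference_paths[name]
            for v in path:
                if not pruned.has_node(node_id(v)):
                    pruned.add_node(node_id(v), graph.labels[node_id(v)])
            for a, b in zip(path, path[1:]):
                pruned.add_edge(a, b)
    return pruned


# -- complement decomposition --------------------------------------------------


@dataclass
class ComplementComponent:
    """One connected component of the edges removed by pruning."""

    nodes: set[int]  # graph ids
    edges: set[tuple[int, int]]  # oriented, closed under symmetry
    border: set[int]  # graph ids shared with the pruned graph

    @property
    def internal(self) -> set[int]:
        return self.nodes - self.border

    def successors(self, v: int) -> list[int]:
        return sorted(w for u, w in self.edges if u == v)


def induced_graph(graph: BidirectedGraph, gbwt: GBWTIndex) -> BidirectedGraph:
    """The subgraph of nodes and edges actually used by the indexed paths."""
    g = BidirectedGraph()
    for path in gbwt.forward_paths():
        for v in path:
            g.labels.setdefault(node_id(v), graph.labels[node_id(v)])
        for a, b in zip(path, path[1:]):
            g.add_edge(a, b)
    g.reference_paths = dict(graph.reference_paths)
    return g


def complement_components(
    induced: BidirectedGraph, pruned: BidirectedGraph
) -> list[ComplementComponent]:
    """Connected components of the complement edge set, with their borders,
    ordered by smallest graph id."""
    comp_edges = induced.edges() - pruned.edges()
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in comp_edges:
        a, b = find(node_id(u)), find(node_id(v))
        if a != b:
            parent[a] = b
    groups: dict[int, ComplementComponent] = {}
    for u, v in comp_edges:
        root = find(node_id(u))
        comp = groups.setdefault(root, ComplementComponent(set(), set(), set()))
        comp.nodes.update((node_id(u), node_id(v)))
        comp.edges.add((u, v))
    comps = sorted(groups.values(), key=lambda c: min(c.nodes))
    for comp in comps:
        comp.border = {gid for gid in comp.nodes if pruned.has_node(gid)}
    return comps


# -- maximal path search -------------------------------------------------------


def _canonical(path: tuple[int, ...]) -> tuple[int, ...]:
    return min(path, reverse_path(path))


def _path_start_count(gbwt: GBWTIndex, v: int) -> int:
    """Number of indexed sequences starting with node v."""
    rec = gbwt.records[ENDMARKER]
    return rec.rank(rec.body_length, v)


def find_maximal_paths(
    comp: ComplementComponent,
    gbwt: GBWTIndex,
    reference_paths: dict[str, tuple[int, ...]] | None = None,
) -> list[tuple[int, ...]]:
    """Haplotype-supported maximal paths through a pruned component.

    Starts a search state at every orientation of every component node: a
    full-record state on border nodes, a path-start state on internal nodes.
    A state stops when it reaches the border again (output if it also started
    there), and is output as a dead end when no extension is supported by the
    haplotypes.  Dead-end paths ending on a reference path are extended along
    it until the border or the component runs out.  Output is canonicalised
    (the smaller of P and its reverse path) and de-duplicated.
    """
    if not gbwt.both_orientations:
        raise UnsupportedOperationError(
            "maximal path search explores both orientations; "
            "build the GBWT with both orientations"
        )
    succ: dict[int, list[int]] = {}
    for u, v in comp.edges:
        succ.setdefault(u, []).append(v)
    for lst in succ.values():
        lst.sort()

    stack: list[tuple[tuple[int, ...], SearchState]] = []
    for gid in sorted(comp.nodes):
        for v in (encode_node(gid), encode_node(gid, True)):
            if gid in comp.border:
                state = gbwt.full_state(v)
                if not state.empty:
                    stack.append(((v,), state))
            else:
                starts = _path_start_count(gbwt, v)
                if starts > 0:
                    stack.append(((v,), SearchState(v, 0, starts - 1)))

    out: set[tuple[int, ...]] = set()
    while stack:
        path, state = stack.pop()
        last = path[-1]
        if len(path) >= 2 and node_id(last) in comp.border:
            if node_id(path[0]) in comp.border:
                out.add(_canonical(path))
            continue
        extended = False
        for w in succ.get(last, ()):
            nxt = gbwt.extend(state, w)
            if not nxt.empty:
                stack.append((path + (w,), nxt))
                extended = True
        if not extended and len(path) >= 2:
            dead_end = path
            if reference_paths:
                dead_end = _extend_with_reference(dead_end, comp, reference_paths)
            out.add(_canonical(dead_end))
    return sorted(out)


def _extend_with_reference(
    path: tuple[int, ...],
    comp: ComplementComponent,
    reference_paths: dict[str, tuple[int, ...]],
) -> tuple[int, ...]:
    """Extend a dead-end path along a reference path until the border is
    reached or the component is exhausted (smallest reference name wins)."""
    last = path[-1]
    for name in sorted(reference_paths):
        for oriented in (reference_paths[name], reverse_path(reference_paths[name])):
            if last not in oriented:
                continue
            ext = list(path)
            for w in oriented[oriented.index(last) + 1 :]:
                if node_id(w) not in comp.nodes:
                    return tuple(ext)
                ext.append(w)
                if node_id(w) in comp.border:
                    return tuple(ext)
            return tuple(ext)
    return path


# -- unfolding -----------------------------------------------------------------


@dataclass
class UnfoldMapping:
    """Translation from duplicated node ids back to original oriented nodes."""

    duplicates: dict[int, int] = field(default_factory=dict)
    originals: set[int] = field(default_factory=set)

    def translate_node(self, v: int) -> int:
        gid = node_id(v)
        orig = self.duplicates.get(gid)
        if orig is not None:
            return reverse_node(orig) if v & 1 else orig
        if not self.originals or gid in self.originals:
            return v
        raise ValueError(f"node {gid} is neither a duplicate nor an original node")


def translate(mapping: UnfoldMapping, path: Sequence[int]) -> tuple[int, ...]:
    """Node-wise substitution of duplicates by their originals."""
    return tuple(mapping.translate_node(v) for v in path)


class _Trie:
    __slots__ = ("children",)

    def __init__(self) -> None:
        self.children: dict[int, "_Trie"] = {}

    def insert(self, seq: Sequence[int]) -> None:
        node = self
        for v in seq:
            node = node.children.setdefault(v, _Trie())


@dataclass
class UnfoldedComponent:
    """What unfolding one component added to the pruned graph."""

    component: ComplementComponent
    maximal_paths: list[tuple[int, ...]]
    duplicate_ids: set[int]
    added_edges: set[tuple[int, int]]  # oriented, as added (one per pair)


def unfold(
    pruned: BidirectedGraph,
    comp: ComplementComponent,
    maximal_paths: Sequence[tuple[int, ...]],
    original: BidirectedGraph,
    mapping: UnfoldMapping,
    next_id: int,
) -> tuple[int, UnfoldedComponent]:
    """Insert the maximal paths of one component into the pruned graph.

    Each path is split into a prefix of ceil(|P|/2) nodes and the remaining
    suffix; a trie of prefixes and a trie of reversed suffixes are built, and
    every trie edge becomes a graph node — border nodes are reused, internal
    nodes are duplicated with fresh ids recorded in ``mapping``.  One cross
    edge per path connects its prefix end to its suffix start.  Returns the
    next free id.
    """
    report = UnfoldedComponent(comp, sorted(set(maximal_paths)), set(), set())
    prefix_trie, suffix_trie = _Trie(), _Trie()
    splits: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    for path in sorted(set(maximal_paths)):
        if len(path) < 2:
            raise ValueError("maximal paths have at least two nodes")
        h = ceil(len(path) / 2)
        pre, suf = path[:h], path[h:]
        prefix_trie.insert(pre)
        suffix_trie.insert(tuple(reversed(suf)))
        splits.append((pre, suf))

    def materialise(trie: _Trie, forward: bool) -> dict[tuple[int, ...], int]:
        """Assign one graph node per trie edge (preorder, sorted labels);
        returns trie-path -> oriented node in the unfolded graph."""
        nonlocal next_id
        assigned: dict[tuple[int, ...], int] = {}

        def visit(node: _Trie, prefix: tuple[int, ...], parent: int | None) -> None:
            nonlocal next_id
            for label in sorted(node.children):
                key = prefix + (label,)
                if parent is None and node_id(label) in comp.border:
                    used = label  # border nodes already exist in the pruned graph
                else:
                    dup = next_id
                    next_id += 1
                    pruned.add_node(dup, original.label(label))
                    mapping.duplicates[dup] = label
                    report.duplicate_ids.add(dup)
                    used = encode_node(dup)
                assigned[key] = used
                if parent is not None:
                    edge = (parent, used) if forward else (used, parent)
                    pruned.add_edge(*edge)
                    report.added_edges.add(edge)
                visit(node.children[label], key, used)

        visit(trie, (), None)
        return assigned

    pre_nodes = materialise(prefix_trie, forward=True)
    suf_nodes = materialise(suffix_trie, forward=False)
    for pre, suf in splits:
        u = pre_nodes[pre]
        w = suf_nodes[tuple(reversed(suf))]
        pruned.add_edge(u, w)
        report.added_edges.add((u, w))
    return next_id, report


def simplify(
    graph: BidirectedGraph,
    gbwt: GBWTIndex,
    params: PruneParams = PruneParams(),
    pruned: BidirectedGraph | None = None,
    return_details: bool = False,
):
    """Prune, decompose, search and unfold: the simplified graph supports
    every indexed haplotype path via :func:`translate`.

    A pre-pruned graph may be supplied (``pruned``), in which case the
    heuristic pruning step is skipped — unfolding works with any pruning
    algorithm that removes nodes or edges.
    """
    if pruned is None:
        pruned = prune(graph, params)
    else:
        pruned = pruned.copy()
    induced = induced_graph(graph, gbwt)
    comps = complement_components(induced, pruned)
    mapping = UnfoldMapping(originals=set(graph.labels))
    next_id = max(graph.labels, default=0) + 1
    details: list[UnfoldedComponent] = []
    for comp in comps:
        paths = find_maximal_paths(comp, gbwt, graph.reference_paths)
        next_id, report = unfold(pruned, comp, paths, graph, mapping, next_id)
        details.append(report)
    # single-node haplotype paths cannot form a maximal path; restore directly
    for path in gbwt.forward_paths():
        if len(path) == 1 and not pruned.has_node(node_id(path[0])):
            pruned.add_node(node_id(path[0]), graph.labels[node_id(path[0])])
    if return_details:
        return pruned, mapping, details
    return pruned, mapping


def unfolded_component_paths(
    simplified: BidirectedGraph,
    mapping: UnfoldMapping,
    detail: UnfoldedComponent,
) -> set[tuple[int, ...]]:
    """Translated, canonicalised maximal paths realised by one unfolded
    component, enumerated from the concrete graph structure.

    Walks start at border nodes and at duplicates with no predecessor inside
    the component, follow only edges the unfolding added, and stop at border
    nodes or dead ends.  For a correct unfolding this equals the component's
    haplotype-supported maximal path set.
    """
    comp = detail.component
    allowed: set[tuple[int, int]] = set()
    for u, v in detail.added_edges:
        allowed.add((u, v))
        allowed.add((reverse_node(v), reverse_node(u)))
    entries: list[int] = []
    for gid in sorted(comp.border):
        entries.extend((encode_node(gid), encode_node(gid, True)))
    for dup in sorted(detail.duplicate_ids):
        for v in (encode_node(dup), encode_node(dup, True)):
            if not any((u, v) in allowed for u in simplified.predecessors(v)):
                entries.append(v)
    out: set[tuple[int, ...]] = set()
    stack: list[tuple[int, ...]] = [(v,) for v in entries]
    while stack:
        path = stack.pop()
        last = path[-1]
        if (
            len(path) >= 2
            and node_id(last) not in detail.duplicate_ids
            and node_id(last) in comp.border
        ):
            out.add(_canonical(translate(mapping, path)))
            continue
        extended = False
        for w in sorted(simplified.successors(last)):
            if (last, w) in allowed:
                stack.append(path + (w,))
                extended = True
        if not extended and len(path) >= 2:
            out.add(_canonical(translate(mapping, path)))
    return out


def embed_path(
    graph: BidirectedGraph, mapping: UnfoldMapping, path: Sequence[int]
) -> tuple[int, ...] | None:
    """A concrete path of ``graph`` whose translation equals ``path``, or
    None if the path is not embeddable."""
    rev_dup: dict[int, list[int]] = {}
    for dup, orig in sorted(mapping.duplicates.items()):
        rev_dup.setdefault(orig, []).append(encode_node(dup))
        rev_dup.setdefault(reverse_node(orig), []).append(encode_node(dup, True))

    def candidates(v: int) -> list[int]:
        cands = [v] if graph.has_node(node_id(v)) else []
        return cands + rev_dup.get(v, [])

    frontier: dict[int, int | None] = {c: None for c in candidates(path[0])}
    parents: list[dict[int, int | None]] = [dict(frontier)]
    for v in path[1:]:
        nxt: dict[int, int | None] = {}
        for c in candidates(v):
            for p in frontier:
                if graph.has_edge(p, c):
                    nxt[c] = p
                    break
        if not nxt:
            return None
        frontier = nxt
        parents.append(dict(frontier))
    if not frontier:
        return None
    cur = min(frontier)
    witness = [cur]
    for step in range(len(path) - 1, 0, -1):
        cur = parents[step][cur]  # type: ignore[assignment]
        witness.append(cur)
    return tuple(reversed(witness))
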