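"""Bidirected variation graphs simulated as directed graphs over oriented nodes.

A bidirected graph node ``n`` has two orientations.  We simulate the graph
with a directed graph over *oriented nodes*: the forward orientation of graph
node ``n`` is encoded as the integer ``2n`` and the reverse orientation as
``2n + 1``.  The value ``0`` is reserved for the end-marker ``$`` used by the
index; it has no orientation and no label.  This encoding keeps oriented node
values a dense subset of an integer range and makes ``$`` the smallest symbol
in every lexicographic comparison.

Edges are ordered pairs of oriented nodes.  The bidirected structure is
enforced through edge symmetry: ``(u, v)`` is an edge if and only if
``(reverse(v), reverse(u))`` is one.  Traversing a node in reverse orientation
spells the reverse complement of its label.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence, TextIO

ENDMARKER = 0

Path = tuple  # sequence of oriented nodes, each > 0

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


class MalformedInputError(ValueError):
    """Raised for structurally invalid GFA or path input."""


class UnsupportedDialectError(MalformedInputError):
    """Raised for GFA features outside the supported dialect (e.g. overlaps)."""


def encode_node(graph_id: int, reverse: bool = False) -> int:
    """Encode a graph id and an orientation as an oriented node."""
    if graph_id <= 0:
        raise ValueError(f"graph ids must be positive, got {graph_id}")
    return 2 * graph_id + (1 if reverse else 0)


def decode_node(v: int) -> tuple[int, bool]:
    """Decode an oriented node into (graph id, is_reverse)."""
    if v <= 1:
        raise ValueError(f"not a valid oriented node: {v}")
    return v // 2, bool(v & 1)


def node_id(v: int) -> int:
    """Graph id component of an oriented node."""
    if v <= 1:
        raise ValueError(f"not a valid oriented node: {v}")
    return v // 2


def is_reverse(v: int) -> bool:
    return bool(v & 1)


def reverse_node(v: int) -> int:
    """Flip the orientation of an oriented node.  The end-marker has no reverse."""
    if v <= 1:
        raise ValueError("the end-marker has no reverse orientation")
    return v ^ 1


def reverse_path(path: Sequence[int]) -> tuple[int, ...]:
    """The reverse path: reverse nodes in the reverse order."""
    if len(path) == 0:
        raise ValueError("cannot reverse an empty path")
    return tuple(reverse_node(v) for v in reversed(path))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class BidirectedGraph:
    """A node-labeled bidirected graph with symmetric oriented edges.

    ``labels`` maps graph ids to non-empty DNA strings.  Edges are kept closed
    under the symmetry ``(u, v) <=> (reverse(v), reverse(u))``; both members of
    each symmetric pair are stored explicitly.  ``reference_paths`` are named
    paths used as coordinate backbones (optional).
    """

    def __init__(self) -> None:
        self.labels: dict[int, str] = {}
        self._succ: dict[int, set[int]] = {}
        self.reference_paths: dict[str, tuple[int, ...]] = {}

    # -- nodes ---------------------------------------------------------------

    def add_node(self, graph_id: int, label: str) -> None:
        if graph_id <= 0:
            raise ValueError(f"graph ids must be positive, got {graph_id}")
        if not label:
            raise ValueError(f"node {graph_id} must have a non-empty label")
        self.labels[graph_id] = label

    def has_node(self, graph_id: int) -> bool:
        return graph_id in self.labels

    def remove_node(self, graph_id: int) -> None:
        """Remove a node and every edge incident to either orientation."""
        self.labels.pop(graph_id, None)
        for v in (2 * graph_id, 2 * graph_id + 1):
            for w in list(self._succ.get(v, ())):
                self.remove_edge(v, w)
            for u in list(self.predecessors(v)):
                self.remove_edge(u, v)
            self._succ.pop(v, None)

    def node_ids(self) -> list[int]:
        return sorted(self.labels)

    def label(self, v: int) -> str:
        """Label spelled when traversing oriented node ``v``."""
        gid, rev = decode_node(v)
        seq = self.labels[gid]
        return reverse_complement(seq) if rev else seq

    # -- edges ---------------------------------------------------------------

    def add_edge(self, u: int, v: int) -> None:
        """Add oriented edge (u, v) and its symmetric mirror."""
        for x in (u, v):
            if x <= 1:
                raise ValueError(f"not a valid oriented node: {x}")
            if node_id(x) not in self.labels:
                raise MalformedInputError(f"edge endpoint {node_id(x)} has no label")
        self._succ.setdefault(u, set()).add(v)
        self._succ.setdefault(reverse_node(v), set()).add(reverse_node(u))

    def remove_edge(self, u: int, v: int) -> None:
        self._succ.get(u, set()).discard(v)
        self._succ.get(reverse_node(v), set()).discard(reverse_node(u))

    def has_edge(self, u: int, v: int) -> bool:
        return v in self._succ.get(u, ())

    def edges(self) -> set[tuple[int, int]]:
        return {(u, v) for u, succ in self._succ.items() for v in succ}

    def successors(self, v: int) -> set[int]:
        return set(self._succ.get(v, ()))

    def predecessors(self, v: int) -> set[int]:
        return {reverse_node(w) for w in self._succ.get(reverse_node(v), ())}

    def out_degree(self, v: int) -> int:
        return len(self._succ.get(v, ()))

    def in_degree(self, v: int) -> int:
        return len(self._succ.get(reverse_node(v), ()))

    # -- paths ---------------------------------------------------------------

    def is_path(self, path: Sequence[int]) -> bool:
        """True iff every consecutive pair of ``path`` is an edge (empty: True)."""
        return all(self.has_edge(u, v) for u, v in zip(path, path[1:]))

    def spell(self, path: Sequence[int]) -> str:
        """Concatenated oriented labels along a path."""
        return "".join(self.label(v) for v in path)

    def copy(self) -> "BidirectedGraph":
        g = BidirectedGraph()
        g.labels = dict(self.labels)
        g._succ = {v: set(s) for v, s in self._succ.items()}
        g.reference_paths = dict(self.reference_paths)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BidirectedGraph):
            return NotImplemented
        return self.labels == other.labels and self.edges() == other.edges()

    def __repr__(self) -> str:
        return (
            f"BidirectedGraph(nodes={len(self.labels)}, "
            f"edges={len(self.edges()) // 2}, refs={len(self.reference_paths)})"
        )


# -- GFA1 I/O ------------------------------------------------------------------


def _orient_char(v: int) -> str:
    return "-" if is_reverse(v) else "+"


def _parse_oriented(seg: str, orient: str, labels: Mapping[int, str], line: str) -> int:
    try:
        gid = int(seg)
    except ValueError:
        raise MalformedInputError(f"non-integer segment id {seg!r} in: {line!r}")
    if gid not in labels:
        raise MalformedInputError(f"unknown segment {seg!r} referenced in: {line!r}")
    if orient not in "+-":
        raise MalformedInputError(f"bad orientation {orient!r} in: {line!r}")
    return encode_node(gid, orient == "-")


def read_gfa(source) -> tuple[BidirectedGraph, dict[str, tuple[int, ...]]]:
    """Read a GFA1 file (S/L lines, optional P lines, 0M overlaps only).

    Returns the graph and the named paths from P lines.  Path names of the
    form ``sample#phase#contig#fragment`` carry haplotype metadata.
    """
    close = False
    if isinstance(source, (str, bytes)):
        stream: TextIO = open(source)
        close = True
    else:
        stream = source
    graph = BidirectedGraph()
    paths: dict[str, tuple[int, ...]] = {}
    deferred: list[list[str]] = []  # L and P lines, resolved after all S lines
    try:
        for raw in stream:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise MalformedInputError(f"truncated S line: {line!r}")
                try:
                    gid = int(fields[1])
                except ValueError:
                    raise MalformedInputError(f"non-integer segment id in: {line!r}")
                if gid in graph.labels:
                    raise MalformedInputError(f"duplicate segment id {gid}")
                graph.add_node(gid, fields[2])
            elif tag in ("L", "P"):
                deferred.append(fields)
            # H and other lines are ignored
        for fields in deferred:
            line = "\t".join(fields)
            if fields[0] == "L":
                if len(fields) < 6:
                    raise MalformedInputError(f"truncated L line: {line!r}")
                if fields[5] != "0M":
                    raise UnsupportedDialectError(
                        f"only 0M overlaps are supported, got {fields[5]!r}"
                    )
                u = _parse_oriented(fields[1], fields[2], graph.labels, line)
                v = _parse_oriented(fields[3], fields[4], graph.labels, line)
                graph.add_edge(u, v)
            else:  # P line
                if len(fields) < 3:
                    raise MalformedInputError(f"truncated P line: {line!r}")
                name = fields[1]
                steps = []
                for step in fields[2].split(","):
                    if len(step) < 2:
                        raise MalformedInputError(f"bad path step {step!r} in: {line!r}")
                    steps.append(
                        _parse_oriented(step[:-1], step[-1], graph.labels, line)
                    )
                paths[name] = tuple(steps)
    finally:
        if close:
            stream.close()
    return graph, paths


def write_gfa(
    graph: BidirectedGraph,
    paths: Mapping[str, Sequence[int]] | None,
    dest,
) -> None:
    """Write GFA1 deterministically: S lines in ascending id order, then L, then P.

    One L line is emitted per symmetric edge pair (the lexicographically
    smaller representative).
    """
    close = False
    if isinstance(dest, (str, bytes)):
        stream: TextIO = open(dest, "w")
        close = True
    else:
        stream = dest
    try:
        stream.write("H\tVN:Z:1.0\n")
        for gid in sorted(graph.labels):
            stream.write(f"S\t{gid}\t{graph.labels[gid]}\n")
        canonical = set()
        for u, v in graph.edges():
            mirror = (reverse_node(v), reverse_node(u))
            canonical.add(min((u, v), mirror))
        for u, v in sorted(canonical):
            stream.write(
                f"L\t{node_id(u)}\t{_orient_char(u)}\t"
                f"{node_id(v)}\t{_orient_char(v)}\t0M\n"
            )
        for name in sorted(paths or {}):
            steps = ",".join(f"{node_id(v)}{_orient_char(v)}" for v in paths[name])
            stream.write(f"P\t{name}\t{steps}\t*\n")
    finally:
        if close:
            stream.close()


def gfa_to_string(graph: BidirectedGraph, paths=None) -> str:
    buf = io.StringIO()
    write_gfa(graph, paths, buf)
    return buf.getvalue()


# -- plain path files ----------------------------------------------------------


def signed_to_oriented(signed_id: int) -> int:
    """Signed graph id (negative = reverse orientation) to oriented node."""
    if signed_id == 0:
        raise ValueError("0 is not a valid signed graph id")
    return encode_node(abs(signed_id), signed_id < 0)


def oriented_to_signed(v: int) -> int:
    gid, rev = decode_node(v)
    return -gid if rev else gid


def read_path_file(source) -> list[tuple[int, ...]]:
    """Read paths, one per line, as space-separated signed graph ids."""
    close = False
    if isinstance(source, (str, bytes)):
        stream: TextIO = open(source)
        close = True
    else:
        stream = source
    paths = []
    try:
        for raw in stream:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            paths.append(tuple(signed_to_oriented(int(tok)) for tok in line.split()))
    finally:
        if close:
            stream.close()
    return paths


def write_path_file(paths: Iterable[Sequence[int]], dest) -> None:
    close = False
    if isinstance(dest, (str, bytes)):
        stream: TextIO = open(dest, "w")
        close = True
    else:
        stream = dest
    try:
        for path in paths:
            stream.write(" ".join(str(oriented_to_signed(v)) for v in path) + "\n")
    finally:
        if close:
            stream.close()
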