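"""Brute-force reverse-prefix-sorting oracle for the GBWT.

Ground truth for records, document array and queries, computed by explicit
enumeration and sorting.  Every occurrence of a node on a path (plus one
end-marker occurrence per path) gets a sort key: the node followed by the
reversed prefix before it and the path's own end-marker.  End-markers are
distinct, ordered by path identifier, and smaller than every node; with m
paths, the end-marker of path j is encoded as the integer ``j - m`` so that
plain tuple comparison realises the ordering.

This module must stay independent of the construction and query code it
checks: records here come from a global sort, never from LF-mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .gbwt import Record
from .graph import ENDMARKER


@dataclass(frozen=True)
class Occurrence:
    path_id: int
    offset: int  # on-path offset; -1 for the end-marker occurrence
    node: int  # record this occurrence belongs to (0 = end-marker record)
    key: tuple  # full sort key, unique across the collection
    successor: int  # next node on the path, or 0 at the path end


@dataclass
class OracleBWT:
    """Sorted occurrence list with per-node record views and document array."""

    num_paths: int
    occurrences: list[Occurrence]
    records: dict[int, Record]
    document_array: dict[int, list[int]]  # node -> path ids, by record offset


def naive_gbwt(paths: Sequence[Sequence[int]]) -> OracleBWT:
    m = len(paths)
    occs: list[Occurrence] = []
    for j, path in enumerate(paths):
        if len(path) == 0:
            raise ValueError(f"path {j} is empty")
        marker = j - m  # distinct end-marker, smaller than every node
        occs.append(Occurrence(j, -1, ENDMARKER, (marker,), path[0]))
        for i, v in enumerate(path):
            key = (v,) + tuple(reversed(path[:i])) + (marker,)
            succ = path[i + 1] if i + 1 < len(path) else ENDMARKER
            occs.append(Occurrence(j, i, v, key, succ))
    occs.sort(key=lambda o: o.key)
    # group into per-node record views (the global key order groups by node)
    by_node: dict[int, list[Occurrence]] = {}
    for occ in occs:
        by_node.setdefault(occ.node, []).append(occ)
    records: dict[int, Record] = {}
    da: dict[int, list[int]] = {}
    running: dict[int, int] = {}
    for node in sorted(by_node):
        symbols = [occ.successor for occ in by_node[node]]
        records[node] = Record.from_symbols(symbols, running)
        da[node] = [occ.path_id for occ in by_node[node]]
        for w in symbols:
            running[w] = running.get(w, 0) + 1
    return OracleBWT(m, occs, records, da)


def naive_find(paths: Sequence[Sequence[int]], pattern: Sequence[int]) -> int:
    """Number of occurrences of ``pattern`` as a contiguous subpath."""
    if len(pattern) == 0:
        raise ValueError("empty pattern")
    pat = tuple(pattern)
    count = 0
    for path in paths:
        for i in range(len(path) - len(pat) + 1):
            if tuple(path[i : i + len(pat)]) == pat:
                count += 1
    return count


def naive_locate(paths: Sequence[Sequence[int]], pattern: Sequence[int]) -> list[int]:
    """Multiset (sorted list) of path ids containing ``pattern``, one per
    occurrence."""
    if len(pattern) == 0:
        raise ValueError("empty pattern")
    pat = tuple(pattern)
    ids: list[int] = []
    for j, path in enumerate(paths):
        for i in range(len(path) - len(pat) + 1):
            if tuple(path[i : i + len(pat)]) == pat:
                ids.append(j)
    return sorted(ids)


def substitute_alleles(
    reference: str,
    records: Sequence[tuple[int, str, Sequence[str]]],
    choices: Sequence[int],
    policy: str = "phase-break",
) -> tuple[str, int]:
    """String-level haplotype oracle: apply chosen alleles to the reference.

    Works directly on the sequence, independently of any graph.  Returns the
    haplotype sequence and the number of unresolvable overlaps (alternate
    alleles starting inside a previously applied alternate allele).  Under
    ``phase-break`` such an allele is applied from the overlap point onward —
    matching the concatenation of the path fragments a phase break produces —
    and under ``force-ref`` it is dropped.
    """
    trimmed = []
    for (pos0, ref_allele, alts), choice in zip(records, choices):
        alleles = [ref_allele, *alts]
        p = 0
        while all(len(a) > p and a[p] == ref_allele[p] for a in alleles):
            p += 1
        s = 0
        while s < min(len(a) for a in alleles) - p and all(
            a[len(a) - 1 - s] == ref_allele[len(ref_allele) - 1 - s] for a in alleles
        ):
            s += 1
        chosen = alleles[choice]
        trimmed.append(
            (pos0 + p, pos0 + len(ref_allele) - s, chosen[p : len(chosen) - s], choice)
        )
    trimmed.sort(key=lambda t: (t[0], t[1]))
    out: list[str] = []
    pos = 0  # reference coordinate consumed by applied alternate alleles
    breaks = 0
    for start, end, core, choice in trimmed:
        if choice == 0:
            continue
        if start >= pos:
            out.append(reference[pos:start])
            out.append(core)
            pos = end
        else:
            breaks += 1
            if policy == "phase-break":
                out.append(core)
                pos = max(pos, end)
            # force-ref: the overlapping alternate allele is dropped
    out.append(reference[pos:])
    return "".join(out), breaks


def subpath_stats(
    paths: Sequence[Sequence[int]], max_len: int
) -> dict[tuple, list[int]]:
    """Occurrence id-multisets for every subpath of length <= max_len, in one
    pass (equivalent to naive_locate per pattern)."""
    stats: dict[tuple, list[int]] = {}
    for j, path in enumerate(paths):
        n = len(path)
        for i in range(n):
            for L in range(1, min(max_len, n - i) + 1):
                stats.setdefault(tuple(path[i : i + L]), []).append(j)
    for ids in stats.values():
        ids.sort()
    return stats
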