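"""Merging GBWT indexes and removing paths.

``merge`` combines two indexes over the same graph; the contract is
structural equality with a single build over the concatenated path lists, so
the second index's paths are re-threaded into the first (the identifiers of
B are offset by the number of paths in A).  ``merge_fast`` handles the
disjoint-node case (different chromosomes): every non-end-marker record can
be reused as is, because no record of one index ever counts occurrences of
the other's nodes; only the end-marker record, the identifier samples and the
metadata need concatenating.
"""

from __future__ import annotations

from typing import Iterable

from .build import DynamicGBWT, build
from .gbwt import GBWTIndex, IncompatibleIndexError, Record
from .graph import ENDMARKER


def _check_compatible(a: GBWTIndex, b: GBWTIndex) -> None:
    if a.both_orientations != b.both_orientations:
        raise IncompatibleIndexError("orientation flags differ between indexes")
    if a.sample_interval != b.sample_interval:
        raise IncompatibleIndexError("sample intervals differ between indexes")


def merge(a: GBWTIndex, b: GBWTIndex) -> GBWTIndex:
    """Merge two GBWTs over the same graph; B's identifiers follow A's."""
    _check_compatible(a, b)
    dyn = DynamicGBWT.from_index(a)
    paths = b.forward_paths()
    if paths:
        dyn.insert_batch(paths, b.metadata if b.metadata else None)
    elif b.metadata:
        dyn.metadata.extend(b.metadata)
    return dyn.freeze()


def merge_fast(a: GBWTIndex, b: GBWTIndex) -> GBWTIndex:
    """Merge two GBWTs with disjoint node sets by reusing their records."""
    _check_compatible(a, b)
    shared = set(a.nodes()) & set(b.nodes())
    if shared:
        raise ValueError(
            f"node sets are not disjoint: node {min(shared)} is in both indexes"
        )
    records: dict[int, Record] = {}
    for v in a.nodes():
        records[v] = a.records[v]
    for v in b.nodes():
        records[v] = b.records[v]
    end_symbols = a.records[ENDMARKER].symbols() + b.records[ENDMARKER].symbols()
    records[ENDMARKER] = Record.from_symbols(end_symbols, {})
    # node-valued successors only ever occur in their own index's records, so
    # their cumulative ranks carry over; the end-marker occurs in both, and
    # its cumulative ranks must be recounted over the union ordering.
    zeros_before = 0
    for v in sorted(records):
        if v == ENDMARKER:
            continue
        rec = records[v]
        if rec.header and rec.header[0][0] == ENDMARKER:
            if rec.header[0][1] != zeros_before:
                rec = Record(
                    [(ENDMARKER, zeros_before)] + rec.header[1:], list(rec.body)
                )
                records[v] = rec
            zeros_before += rec.range_count(0, rec.body_length - 1, ENDMARKER)
    offset = a.num_sequences
    samples = dict(a.id_samples)
    for pos, sid in b.id_samples.items():
        samples[pos] = sid + offset
    return GBWTIndex(
        records,
        a.sample_interval,
        samples,
        list(a.metadata) + list(b.metadata),
        a.both_orientations,
    )


def remove_paths(index: GBWTIndex, ids: Iterable[int]) -> GBWTIndex:
    """Remove the given path identifiers (forward numbering; the reverse
    companion of each path is removed with it).

    Remaining paths keep their relative order and are renumbered
    consecutively; the result is structurally identical to a build over the
    remaining paths.
    """
    ids = set(ids)
    n = index.num_paths
    unknown = [j for j in ids if not 0 <= j < n]
    if unknown:
        raise ValueError(f"unknown path identifier {min(unknown)} (have {n} paths)")
    keep = [j for j in range(n) if j not in ids]
    paths = [index.extract(2 * j if index.both_orientations else j) for j in keep]
    metadata = [index.metadata[j] for j in keep] if index.metadata else None
    return build(
        paths,
        both_orientations=index.both_orientations,
        sample_interval=index.sample_interval,
        metadata=metadata,
    )
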