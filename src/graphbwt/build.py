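"""GBWT construction: batched BCR-style insertion into a dynamic index.

Texts are inserted front-to-back, one symbol per round over the whole batch,
into a dynamic representation with uncompressed record bodies.  Each round
first computes every text's target position with the positional LF-mapping
against the round-start state, then applies the insertions in sorted
(record, offset, text) order, shifting offsets for insertions that land in
the same record.  Processing texts in identifier order resolves ties exactly
like the distinct end-markers ``$_j < $_{j+1}`` do in the sorted view, so the
post-state is structurally identical to a from-scratch build regardless of
how the path list is split into batches.

Records are rebuilt (re-encoded) wholesale when the index is frozen; during
construction the bodies are plain successor lists, which is cheap because the
local alphabet is small and body lengths are bounded by the number of
haplotypes through the node.
"""

from __future__ import annotations

from bisect import insort
from collections import Counter
from typing import Iterable, Sequence

from .gbwt import GBWTIndex, PathMetadata, Record
from .graph import ENDMARKER, reverse_path

DEFAULT_BUFFER_CAPACITY = 100_000_000  # total nodes buffered before a flush
DEFAULT_SAMPLE_INTERVAL = 1024


def _check_batch(batch: Sequence[Sequence[int]]) -> None:
    for i, path in enumerate(batch):
        if len(path) == 0:
            raise ValueError(f"empty path at batch index {i}")
        for v in path:
            if v <= 1:
                raise ValueError(f"invalid node {v} in path at batch index {i}")


class DynamicGBWT:
    """Mutable GBWT used during construction; freeze() yields a GBWTIndex."""

    def __init__(
        self,
        sample_interval: int = DEFAULT_SAMPLE_INTERVAL,
        both_orientations: bool = True,
    ) -> None:
        self.bodies: dict[int, list[int]] = {ENDMARKER: []}
        self.counts: dict[int, Counter] = {ENDMARKER: Counter()}
        self._nodes: list[int] = [ENDMARKER]  # sorted record keys
        self.sample_interval = sample_interval
        self.both_orientations = both_orientations
        self.metadata: list[PathMetadata] = []

    @classmethod
    def from_index(cls, index: GBWTIndex) -> "DynamicGBWT":
        dyn = cls(index.sample_interval, index.both_orientations)
        for node, rec in index.records.items():
            symbols = rec.symbols()
            dyn.bodies[node] = symbols
            dyn.counts[node] = Counter(symbols)
            if node != ENDMARKER:
                insort(dyn._nodes, node)
        dyn.metadata = list(index.metadata)
        return dyn

    @property
    def num_sequences(self) -> int:
        return len(self.bodies[ENDMARKER])

    # -- insertion -----------------------------------------------------------

    def _lf_offset(self, pos: tuple[int, int], w: int) -> int:
        """Offset of the w-successor occurrence following position ``pos``."""
        u, i = pos
        total = 0
        for v in self._nodes:
            if v >= u:
                break
            total += self.counts[v][w]
        body = self.bodies[u]
        total += body[:i].count(w)
        return total

    def _ensure_record(self, v: int) -> list[int]:
        body = self.bodies.get(v)
        if body is None:
            body = self.bodies[v] = []
            self.counts[v] = Counter()
            insort(self._nodes, v)
        return body

    def insert_sequences(self, seqs: Sequence[Sequence[int]]) -> None:
        """BCR batch insertion of raw sequences, in order, as new texts."""
        _check_batch(seqs)
        base = self.num_sequences
        positions: dict[int, tuple[int, int]] = {}
        for t, seq in enumerate(seqs):
            # the $_j occurrences append to the end-marker record in id order
            self.bodies[ENDMARKER].append(seq[0])
            self.counts[ENDMARKER][seq[0]] += 1
            positions[t] = (ENDMARKER, base + t)
        active = list(range(len(seqs)))
        k = 0
        while active:
            staged = []
            for t in active:
                seq = seqs[t]
                v = seq[k]
                off = self._lf_offset(positions[t], v)
                succ = seq[k + 1] if k + 1 < len(seq) else ENDMARKER
                staged.append((v, off, t, succ))
            # the computed offsets are final: every same-round insertion that
            # sorts earlier is already accounted for by its predecessor entry,
            # so applying in ascending order needs no further shifting
            staged.sort()
            for v, off, t, succ in staged:
                body = self._ensure_record(v)
                body.insert(off, succ)
                self.counts[v][succ] += 1
                positions[t] = (v, off)
            k += 1
            active = [t for t in active if k < len(seqs[t])]

    def insert_batch(
        self,
        batch: Sequence[Sequence[int]],
        metadata: Sequence[PathMetadata] | None = None,
    ) -> None:
        """Insert a batch of paths (plus reverse paths when the index stores
        both orientations: path j becomes sequences 2j and 2j+1)."""
        _check_batch(batch)
        if metadata is not None and len(metadata) != len(batch):
            raise ValueError("metadata length must match the batch")
        if self.both_orientations:
            seqs: list[Sequence[int]] = []
            for path in batch:
                seqs.append(tuple(path))
                seqs.append(reverse_path(path))
        else:
            seqs = [tuple(path) for path in batch]
        self.insert_sequences(seqs)
        if metadata is not None:
            self.metadata.extend(metadata)

    # -- freezing ------------------------------------------------------------

    def freeze(self) -> GBWTIndex:
        records: dict[int, Record] = {}
        running: Counter = Counter()
        for v in self._nodes:
            records[v] = Record.from_symbols(self.bodies[v], running)
            running.update(self.counts[v])
        index = GBWTIndex(
            records,
            self.sample_interval,
            id_samples={},
            metadata=list(self.metadata),
            both_orientations=self.both_orientations,
        )
        index.id_samples.update(_sample_positions(index))
        return index


def _sample_positions(index: GBWTIndex) -> dict[tuple[int, int], int]:
    """Walk every sequence, sampling on-path offsets divisible by the
    interval plus the final position."""
    d = index.sample_interval
    samples: dict[tuple[int, int], int] = {}
    for j in range(index.num_sequences):
        pos = (ENDMARKER, j)
        i = -1
        while True:
            w = index.records[pos[0]].symbol_at(pos[1])
            if i >= 0 and (i % d == 0 or w == ENDMARKER):
                samples[pos] = j
            if w == ENDMARKER:
                break
            nxt = index.lf(pos, w)
            assert nxt is not None
            pos = nxt
            i += 1
    return samples


class ConstructionBuffer:
    """Buffers pending paths up to a capacity in total nodes; flush order is
    insertion order."""

    def __init__(self, capacity: int = DEFAULT_BUFFER_CAPACITY) -> None:
        if capacity <= 0:
            raise ValueError("buffer capacity must be positive")
        self.capacity = capacity
        self.paths: list[tuple[int, ...]] = []
        self.metadata: list[PathMetadata] = []
        self.total_nodes = 0

    @property
    def full(self) -> bool:
        return self.total_nodes >= self.capacity

    def add(self, path: Sequence[int], meta: PathMetadata | None = None) -> None:
        self.paths.append(tuple(path))
        if meta is not None:
            self.metadata.append(meta)
        self.total_nodes += len(path)

    def clear(self) -> None:
        self.paths = []
        self.metadata = []
        self.total_nodes = 0


class GBWTBuilder:
    """Incremental construction: buffered paths are inserted batch by batch."""

    def __init__(
        self,
        both_orientations: bool = True,
        sample_interval: int = DEFAULT_SAMPLE_INTERVAL,
        buffer_capacity: int = DEFAULT_BUFFER_CAPACITY,
    ) -> None:
        self.dynamic = DynamicGBWT(sample_interval, both_orientations)
        self.buffer = ConstructionBuffer(buffer_capacity)
        self._with_metadata = False

    def add(self, path: Sequence[int], meta: PathMetadata | None = None) -> None:
        if meta is not None:
            self._with_metadata = True
        self.buffer.add(path, meta)
        if self.buffer.full:
            self.flush()

    def flush(self) -> None:
        if not self.buffer.paths:
            return
        self.dynamic.insert_batch(
            self.buffer.paths,
            self.buffer.metadata if self._with_metadata else None,
        )
        self.buffer.clear()

    def finish(self) -> GBWTIndex:
        self.flush()
        return self.dynamic.freeze()


def build(
    paths: Iterable[Sequence[int]],
    both_orientations: bool = True,
    sample_interval: int = DEFAULT_SAMPLE_INTERVAL,
    metadata: Sequence[PathMetadata] | None = None,
    buffer_capacity: int = DEFAULT_BUFFER_CAPACITY,
) -> GBWTIndex:
    """Build a GBWT over a path collection.

    With ``both_orientations`` (the default), path j is indexed as sequence
    2j and its reverse path as sequence 2j+1, turning the index into an
    FMD-index that supports bidirectional search.
    """
    paths = [tuple(p) for p in paths]
    if metadata is not None and len(metadata) != len(paths):
        raise ValueError("metadata length must match the path list")
    builder = GBWTBuilder(both_orientations, sample_interval, buffer_capacity)
    for i, path in enumerate(paths):
        builder.add(path, metadata[i] if metadata is not None else None)
    return builder.finish()


def insert_batch(
    index: GBWTIndex,
    batch: Sequence[Sequence[int]],
    metadata: Sequence[PathMetadata] | None = None,
) -> GBWTIndex:
    """Insert a batch of new paths into an existing index (non-destructive).

    The result is structurally identical to a from-scratch build over the
    previously indexed paths followed by the batch.
    """
    dyn = DynamicGBWT.from_index(index)
    dyn.insert_batch(batch, metadata)
    return dyn.freeze()
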