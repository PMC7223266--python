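"""The GBWT: a run-length encoded FM-index of paths, partitioned into per-node records.

The index stores a collection of paths (strings over the oriented-node
alphabet, see :mod:`graphbwt.graph`).  Conceptually we build an FM-index of
the *reverse* strings: the occurrence of node ``v`` at offset ``i`` of path
``j`` is sorted by the key ``(v, P_j[i-1], ..., P_j[0], $_j)``, with the
per-path end-markers ``$_j`` distinct and smaller than every node, ordered by
path identifier.  Sorting reverse prefixes makes the LF-mapping traverse
edges forwards along the paths.

Instead of one global BWT string, the BWT is partitioned into substrings
``BWT_v``, one per node, each encoded over the node's local successor
alphabet.  A *record* holds the local alphabet with cumulative ranks (header)
and the run-length encoded successor sequence (body).  Positions are
node/offset pairs, and

    LF((v, i), w) = (w, BWT.rank(v, w) + BWT_v.rank(i, w))

where ``BWT.rank(v, w)`` — the header's cumulative rank — counts occurrences
of ``w`` in the bodies of all records before ``v``.

When both orientations are indexed (every path together with its reverse
path), the index doubles as an FMD-index and supports bidirectional search.
"""

from __future__ import annotations

import hashlib
import struct
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable, Sequence

from .graph import ENDMARKER, reverse_node

FORMAT_MAGIC = b"GBWTPY1"
FORMAT_VERSION = 1
ORIENTATION_ENCODING = 1  # forward node n -> 2n, reverse -> 2n+1, 0 = $


class MalformedIndexError(ValueError):
    """Raised when deserializing a damaged or foreign index file."""


class IncompatibleIndexError(ValueError):
    """Raised when combining indexes with mismatched flags or encodings."""


class UnsupportedOperationError(RuntimeError):
    """Raised for queries requiring a capability the index was built without."""


# -- records -------------------------------------------------------------------


@dataclass(frozen=True)
class Run:
    code: int  # index into the record's local alphabet (header)
    length: int


@dataclass
class Record:
    """Per-node BWT fragment.

    ``header`` lists ``(successor, cumulative_rank)`` pairs with successors
    strictly increasing; the successors are the local alphabet.  ``body`` is
    the run-length encoded successor sequence in sorted-occurrence order.
    """

    header: list[tuple[int, int]] = field(default_factory=list)
    body: list[Run] = field(default_factory=list)

    @classmethod
    def from_symbols(
        cls, symbols: Sequence[int], cumulative: dict[int, int]
    ) -> "Record":
        """Build a record from an uncompressed successor sequence."""
        alphabet = sorted(set(symbols))
        header = [(w, cumulative.get(w, 0)) for w in alphabet]
        code_of = {w: k for k, (w, _) in enumerate(header)}
        body: list[Run] = []
        for w in symbols:
            code = code_of[w]
            if body and body[-1].code == code:
                body[-1] = Run(code, body[-1].length + 1)
            else:
                body.append(Run(code, 1))
        return cls(header, body)

    @property
    def body_length(self) -> int:
        return sum(run.length for run in self.body)

    def successors(self) -> list[int]:
        return [w for w, _ in self.header]

    def header_index(self, w: int) -> int | None:
        i = bisect_left(self.header, (w, -1))
        if i < len(self.header) and self.header[i][0] == w:
            return i
        return None

    def cumulative_rank(self, w: int) -> int | None:
        i = self.header_index(w)
        return None if i is None else self.header[i][1]

    def symbols(self) -> list[int]:
        """Uncompressed successor sequence."""
        out: list[int] = []
        for run in self.body:
            out.extend([self.header[run.code][0]] * run.length)
        return out

    def symbol_at(self, i: int) -> int:
        pos = 0
        for run in self.body:
            pos += run.length
            if i < pos:
                return self.header[run.code][0]
        raise IndexError(f"offset {i} out of range (body length {pos})")

    def rank(self, i: int, w: int) -> int:
        """Occurrences of successor ``w`` among the first ``i`` body symbols."""
        code = self.header_index(w)
        if code is None:
            return 0
        count = 0
        pos = 0
        for run in self.body:
            if pos >= i:
                break
            take = min(run.length, i - pos)
            if run.code == code:
                count += take
            pos += run.length
        return count

    def range_count(self, sp: int, ep: int, w: int) -> int:
        """Occurrences of ``w`` among body offsets ``sp..ep`` inclusive."""
        if ep < sp:
            return 0
        return self.rank(ep + 1, w) - self.rank(sp, w)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Record):
            return NotImplemented
        return self.header == other.header and self.body == other.body


# -- search states -------------------------------------------------------------


@dataclass(frozen=True)
class SearchState:
    """A node plus an inclusive offset range [sp, ep] within its record."""

    node: int
    sp: int
    ep: int

    @property
    def empty(self) -> bool:
        return self.ep < self.sp

    @property
    def size(self) -> int:
        return max(0, self.ep - self.sp + 1)


EMPTY_STATE = SearchState(ENDMARKER, 0, -1)


@dataclass(frozen=True)
class BiState:
    """Paired forward/backward states of a bidirectional (FMD) search."""

    forward: SearchState
    backward: SearchState
    pattern_length: int

    @property
    def empty(self) -> bool:
        return self.forward.empty

    @property
    def size(self) -> int:
        return self.forward.size


EMPTY_BISTATE = BiState(EMPTY_STATE, EMPTY_STATE, 0)


@dataclass(frozen=True)
class PathMetadata:
    sample: str = ""
    phase: int = 0
    contig: str = ""
    fragment: int = 0


# -- the index -----------------------------------------------------------------


class GBWTIndex:
    """Immutable (frozen) GBWT over a path collection.

    ``records`` maps oriented nodes (plus the end-marker 0) to records.  The
    end-marker record's body lists the first node of every indexed sequence in
    identifier order.  ``id_samples`` stores sequence identifiers at every
    on-path offset divisible by ``sample_interval`` and at every final
    position, bounding the number of LF steps a locate query needs.
    """

    def __init__(
        self,
        records: dict[int, Record],
        sample_interval: int = 1024,
        id_samples: dict[tuple[int, int], int] | None = None,
        metadata: list[PathMetadata] | None = None,
        both_orientations: bool = True,
    ) -> None:
        if sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if ENDMARKER not in records:
            records = dict(records)
            records[ENDMARKER] = Record()
        self.records = records
        self.sample_interval = sample_interval
        self.id_samples = id_samples if id_samples is not None else {}
        self.metadata = metadata if metadata is not None else []
        self.both_orientations = both_orientations

    # -- basic accessors ----------------------------------------------------

    @property
    def num_sequences(self) -> int:
        return self.records[ENDMARKER].body_length

    @property
    def num_paths(self) -> int:
        """Number of original (forward) paths."""
        return self.num_sequences // 2 if self.both_orientations else self.num_sequences

    def nodes(self) -> list[int]:
        return sorted(v for v in self.records if v != ENDMARKER)

    def full_state(self, v: int) -> SearchState:
        rec = self.records.get(v)
        if rec is None or rec.body_length == 0:
            return EMPTY_STATE
        return SearchState(v, 0, rec.body_length - 1)

    def metadata_for(self, seq_id: int) -> tuple[PathMetadata, bool]:
        """Metadata of a sequence and whether it is a reverse companion."""
        if self.both_orientations:
            return self.metadata[seq_id // 2], bool(seq_id & 1)
        return self.metadata[seq_id], False

    # -- LF and search -------------------------------------------------------

    def lf(self, pos: tuple[int, int], w: int) -> tuple[int, int] | None:
        """Positional LF-mapping; ``None`` signals an impossible step."""
        if w == ENDMARKER:
            raise ValueError("cannot take LF into the end-marker")
        rec = self.records.get(pos[0])
        if rec is None:
            return None
        cum = rec.cumulative_rank(w)
        if cum is None:
            return None
        return (w, cum + rec.rank(pos[1], w))

    def extend(self, state: SearchState, w: int) -> SearchState:
        """Extend the pattern of ``state`` with one more node ``w``."""
        if state.empty:
            return EMPTY_STATE
        rec = self.records[state.node]
        cum = rec.cumulative_rank(w)
        if cum is None:
            return EMPTY_STATE
        sp = cum + rec.rank(state.sp, w)
        ep = cum + rec.rank(state.ep + 1, w) - 1
        if ep < sp:
            return EMPTY_STATE
        return SearchState(w, sp, ep)

    def find(self, pattern: Sequence[int]) -> SearchState:
        """Search state of a pattern; its size is the occurrence count."""
        if len(pattern) == 0:
            raise ValueError("cannot search for an empty pattern")
        state = self.full_state(pattern[0])
        for w in pattern[1:]:
            if state.empty:
                return EMPTY_STATE
            state = self.extend(state, w)
        return state

    def count(self, pattern: Sequence[int]) -> int:
        return self.find(pattern).size

    # -- locate --------------------------------------------------------------

    def _locate_one(self, pos: tuple[int, int]) -> int:
        steps = 0
        limit = self.sample_interval + sum(
            r.body_length for r in self.records.values()
        )
        while pos not in self.id_samples:
            rec = self.records[pos[0]]
            w = rec.symbol_at(pos[1])
            if w == ENDMARKER:
                raise MalformedIndexError(f"final position {pos} is not sampled")
            nxt = self.lf(pos, w)
            assert nxt is not None
            pos = nxt
            steps += 1
            if steps > limit:
                raise MalformedIndexError("locate walk did not reach a sample")
        return self.id_samples[pos]

    def locate_direct(self, state: SearchState) -> list[int]:
        """Sequence identifiers of the occurrences in ``state`` (a multiset).

        Each position is walked separately along the LF-mapping until a
        sampled position is reached.  The result is sorted; duplicates mean a
        sequence contains the pattern several times.
        """
        if state.empty:
            return []
        return sorted(
            self._locate_one((state.node, i)) for i in range(state.sp, state.ep + 1)
        )

    def locate_fast(self, state: SearchState) -> list[int]:
        """Same contract as :meth:`locate_direct`, processing the whole range
        per LF round and advancing every offset of a run in one scan."""
        if state.empty:
            return []
        found: list[int] = []
        pending: dict[int, list[int]] = {state.node: list(range(state.sp, state.ep + 1))}
        while pending:
            nxt: dict[int, list[int]] = {}
            for node, offsets in pending.items():
                rec = self.records[node]
                offsets.sort()
                remaining = []
                for i in offsets:
                    sid = self.id_samples.get((node, i))
                    if sid is not None:
                        found.append(sid)
                    else:
                        remaining.append(i)
                if not remaining:
                    continue
                # one scan over the runs advances every remaining offset
                seen: dict[int, int] = {}  # code -> occurrences before current run
                run_start = 0
                it = iter(remaining)
                i = next(it)
                for run in rec.body:
                    run_end = run_start + run.length
                    while i is not None and i < run_end:
                        w = rec.header[run.code][0]
                        if w == ENDMARKER:
                            raise MalformedIndexError(
                                f"final position {(node, i)} is not sampled"
                            )
                        off = (
                            rec.header[run.code][1]
                            + seen.get(run.code, 0)
                            + (i - run_start)
                        )
                        nxt.setdefault(w, []).append(off)
                        i = next(it, None)
                    seen[run.code] = seen.get(run.code, 0) + run.length
                    run_start = run_end
                    if i is None:
                        break
            pending = nxt
        return sorted(found)

    def locate(self, state: SearchState) -> list[int]:
        return self.locate_fast(state)

    # -- extract -------------------------------------------------------------

    def extract(self, seq_id: int) -> tuple[int, ...]:
        """The exact node sequence inserted as sequence ``seq_id``."""
        if not 0 <= seq_id < self.num_sequences:
            raise ValueError(
                f"sequence id {seq_id} out of range (have {self.num_sequences})"
            )
        out: list[int] = []
        pos = (ENDMARKER, seq_id)
        while True:
            w = self.records[pos[0]].symbol_at(pos[1])
            if w == ENDMARKER:
                return tuple(out)
            out.append(w)
            nxt = self.lf(pos, w)
            assert nxt is not None
            pos = nxt

    def sequences(self) -> list[tuple[int, ...]]:
        return [self.extract(j) for j in range(self.num_sequences)]

    def forward_paths(self) -> list[tuple[int, ...]]:
        """The originally inserted (forward-orientation) paths."""
        if self.both_orientations:
            return [self.extract(2 * j) for j in range(self.num_paths)]
        return self.sequences()

    def document_array(self) -> dict[int, list[int]]:
        """Per-record sequence identifiers, aligned with body offsets.

        Computed by walking every sequence along the LF-mapping (independent
        of any locate sampling)."""
        da = {v: [-1] * rec.body_length for v, rec in self.records.items()}
        for j in range(self.num_sequences):
            pos = (ENDMARKER, j)
            while True:
                da[pos[0]][pos[1]] = j
                w = self.records[pos[0]].symbol_at(pos[1])
                if w == ENDMARKER:
                    break
                pos = self.lf(pos, w)  # type: ignore[assignment]
        return da

    # -- bidirectional search -------------------------------------------------

    def _require_fmd(self) -> None:
        if not self.both_orientations:
            raise UnsupportedOperationError(
                "bidirectional search needs an index built with both orientations"
            )

    def bd_start(self, v: int) -> BiState:
        """Bidirectional state for the single-node pattern [v]."""
        self._require_fmd()
        fwd = self.full_state(v)
        if fwd.empty:
            return EMPTY_BISTATE
        return BiState(fwd, self.full_state(reverse_node(v)), 1)

    def bd_find(self, pattern: Sequence[int]) -> BiState:
        if len(pattern) == 0:
            raise ValueError("cannot search for an empty pattern")
        bs = self.bd_start(pattern[0])
        for w in pattern[1:]:
            bs = self.bd_extend(bs, w, "forward")
        return bs

    def _smaller_block_count(self, state: SearchState, threshold: int) -> int:
        """Occurrences in ``state`` whose companion-side continuation sorts
        before the reverse of the chosen extension.

        The companion occurrences continue with ``$`` (when the pattern ends a
        sequence) or with the reverse of the successor; blocks are ordered by
        that value, with ``$`` first.
        """
        rec = self.records[state.node]
        count = rec.range_count(state.sp, state.ep, ENDMARKER)
        for c, _ in rec.header:
            if c != ENDMARKER and reverse_node(c) < threshold:
                count += rec.range_count(state.sp, state.ep, c)
        return count

    def bd_extend(self, bs: BiState, w: int, direction: str = "forward") -> BiState:
        """Extend a bidirectional state: append ``w`` (forward) or prepend it
        (backward).  Forward and backward ranges always have equal size."""
        self._require_fmd()
        if bs.empty:
            return EMPTY_BISTATE
        if direction == "forward":
            shift = self._smaller_block_count(bs.forward, reverse_node(w))
            fwd = self.extend(bs.forward, w)
            if fwd.empty:
                return EMPTY_BISTATE
            bwd = SearchState(
                bs.backward.node,
                bs.backward.sp + shift,
                bs.backward.sp + shift + fwd.size - 1,
            )
            return BiState(fwd, bwd, bs.pattern_length + 1)
        elif direction == "backward":
            shift = self._smaller_block_count(bs.backward, w)
            bwd = self.extend(bs.backward, reverse_node(w))
            if bwd.empty:
                return EMPTY_BISTATE
            fwd = SearchState(
                bs.forward.node,
                bs.forward.sp + shift,
                bs.forward.sp + shift + bwd.size - 1,
            )
            return BiState(fwd, bwd, bs.pattern_length + 1)
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")

    # -- equality ------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GBWTIndex):
            return NotImplemented
        return (
            self.records == other.records
            and self.sample_interval == other.sample_interval
            and self.id_samples == other.id_samples
            and self.metadata == other.metadata
            and self.both_orientations == other.both_orientations
        )

    def __repr__(self) -> str:
        runs = sum(len(r.body) for r in self.records.values())
        return (
            f"GBWTIndex(sequences={self.num_sequences}, "
            f"nodes={len(self.records) - 1}, runs={runs}, "
            f"both_orientations={self.both_orientations})"
        )


# -- serialization -------------------------------------------------------------
#
# Portable container: magic "GBWTPY1", little-endian integers, then
#   u32 version | u8 orientation-encoding | u8 both-orientations | u64 d
#   u64 #records { u64 node | u64 #header (u64 succ, u64 rank)* |
#                  u64 #runs (u64 code, u64 len)* }
#   u64 #samples { u64 node, u64 offset, u64 id }*
#   u64 #metadata { str sample | u32 phase | str contig | u32 fragment }*
# followed by the SHA-256 digest of everything before it.  Strings are u32
# length-prefixed UTF-8.  Output is byte-deterministic for a given index.


def _pack_str(s: str) -> bytes:
    b = s.encode()
    return struct.pack("<I", len(b)) + b


class _Reader:
    def __init__(self, data: bytes) -> None:
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise MalformedIndexError("truncated index file")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def u64(self) -> int:
        return struct.unpack("<Q", self.take(8))[0]

    def u32(self) -> int:
        return struct.unpack("<I", self.take(4))[0]

    def u8(self) -> int:
        return self.take(1)[0]

    def string(self) -> str:
        return self.take(self.u32()).decode()


def serialize(index: GBWTIndex, dest) -> None:
    """Write a GBWT index; output bytes are a deterministic function of it."""
    chunks: list[bytes] = [FORMAT_MAGIC]
    chunks.append(
        struct.pack(
            "<IBBQ",
            FORMAT_VERSION,
            ORIENTATION_ENCODING,
            1 if index.both_orientations else 0,
            index.sample_interval,
        )
    )
    chunks.append(struct.pack("<Q", len(index.records)))
    for node in sorted(index.records):
        rec = index.records[node]
        chunks.append(struct.pack("<QQ", node, len(rec.header)))
        for w, rank in rec.header:
            chunks.append(struct.pack("<QQ", w, rank))
        chunks.append(struct.pack("<Q", len(rec.body)))
        for run in rec.body:
            chunks.append(struct.pack("<QQ", run.code, run.length))
    chunks.append(struct.pack("<Q", len(index.id_samples)))
    for (node, offset), sid in sorted(index.id_samples.items()):
        chunks.append(struct.pack("<QQQ", node, offset, sid))
    chunks.append(struct.pack("<Q", len(index.metadata)))
    for meta in index.metadata:
        chunks.append(_pack_str(meta.sample))
        chunks.append(struct.pack("<I", meta.phase))
        chunks.append(_pack_str(meta.contig))
        chunks.append(struct.pack("<I", meta.fragment))
    payload = b"".join(chunks)
    blob = payload + hashlib.sha256(payload).digest()
    if isinstance(dest, (str, bytes)):
        with open(dest, "wb") as fh:
            fh.write(blob)
    else:
        dest.write(blob)


def deserialize(source) -> GBWTIndex:
    if isinstance(source, (str, bytes)):
        with open(source, "rb") as fh:
            data = fh.read()
    else:
        data = source.read()
    if len(data) < len(FORMAT_MAGIC) + 32:
        raise MalformedIndexError("truncated index file")
    payload, digest = data[:-32], data[-32:]
    if hashlib.sha256(payload).digest() != digest:
        raise MalformedIndexError("checksum mismatch")
    r = _Reader(payload)
    if r.take(len(FORMAT_MAGIC)) != FORMAT_MAGIC:
        raise MalformedIndexError("bad magic bytes")
    version = r.u32()
    if version != FORMAT_VERSION:
        raise MalformedIndexError(f"unsupported format version {version}")
    encoding = r.u8()
    if encoding != ORIENTATION_ENCODING:
        raise MalformedIndexError(f"unknown orientation encoding {encoding}")
    both = bool(r.u8())
    interval = r.u64()
    records: dict[int, Record] = {}
    for _ in range(r.u64()):
        node = r.u64()
        header = [(r.u64(), r.u64()) for _ in range(r.u64())]
        body = [Run(r.u64(), r.u64()) for _ in range(r.u64())]
        records[node] = Record(header, body)
    samples = {}
    for _ in range(r.u64()):
        node, offset, sid = r.u64(), r.u64(), r.u64()
        samples[(node, offset)] = sid
    metadata = []
    for _ in range(r.u64()):
        sample = r.string()
        phase = r.u32()
        contig = r.string()
        fragment = r.u32()
        metadata.append(PathMetadata(sample, phase, contig, fragment))
    if r.pos != len(payload):
        raise MalformedIndexError("trailing bytes in index file")
    return GBWTIndex(records, interval, samples, metadata, both)
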