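# Methods

## The index

`graphbwt` stores a collection of haplotype paths over a bidirected variation
graph as a graph BWT (GBWT): an FM-index of the paths viewed as strings over
the oriented-node alphabet. A bidirected graph is simulated as a directed
graph in which graph node *n* appears as a forward node (encoded `2n`) and a
reverse node (`2n+1`), with the edge symmetry `(u,v) ∈ E ⇔ (v̄,ū) ∈ E`; `0`
is reserved for the end-marker `$`. The encoding keeps node values dense,
gives a total order with `$` smallest, and makes orientation flipping a
single XOR.

Instead of sorting suffixes, the index sorts **reverse prefixes**: the
occurrence of node `v` at offset `i` of path `j` has sort key
`(v, P_j[i−1], …, P_j[0], $_j)`, with per-path end-markers distinct, ordered
by path identifier and smaller than every node. Two consequences matter:

* the LF-mapping walks *forwards* along paths, so iterating it from the
  end-marker record extracts a path front to back;
* the end-marker record is ordered by path identifier, so `extract(j)` can
  start at position `(0, j)` without any lookup table.

The BWT is partitioned into one **record** per node. A record's header lists
the local successor alphabet with cumulative ranks (`BWT.rank(v, w)` = the
number of `w`-successors in all records before `v`); the body run-length
encodes the successor sequence. Positions are `(node, offset)` pairs and

    LF((v, i), w) = (w, BWT.rank(v, w) + BWT_v.rank(i, w)).

`find` extends a pattern node by node with the usual backward-search
recurrence (which, on reverse prefixes, is forward extension); `locate`
returns path identifiers (one per occurrence — a multiset, deliberately not
de-duplicated, matching document-array semantics; callers that want the set
can dedupe). Identifier samples are stored at every on-path offset divisible
by the sample interval *d* plus every final position, so a locate walk needs
at most *d* LF steps. *d* defaults to 1024. `locate_fast` advances an entire
offset range through a record in one scan of its runs instead of walking each
position separately.

By default every path is indexed together with its reverse path (sequence
`2j` and `2j+1`), making the index an FMD-index. Bidirectional extension
keeps a forward state and a state for the reverse pattern in the same index;
when the pattern is extended by `w`, the companion range is shifted by the
number of occurrences whose companion-side continuation sorts before
`reverse(w)` — the `$`-terminated block first, then blocks ordered by the
reversed successor value — counted on the record being extended.

Cycles, revisits and sparse node ids are all supported; the assumptions the
original design makes about near-linear, dense graphs affect performance
only, and the test fixtures deliberately violate them.

## Construction, merging, removal

Construction inserts texts in batches, one symbol per round across the whole
batch (BCR style), into a dynamic index with uncompressed record bodies.
Each round computes every text's target position with positional LF against
the round-start state and applies the insertions in ascending
(record, offset, text) order. The computed offsets are final: an insertion
that sorts earlier in the same round is represented, at LF time, by its
predecessor entry inserted in the previous round, and processing texts in
identifier order realises the `$_j < $_{j+1}` tie-break. The post-state is
therefore structurally identical to a from-scratch build for *any* batch
split, which is the property the tests pin down. Freezing re-encodes bodies
as runs, fills in cumulative ranks, and collects identifier samples by
walking each sequence once.

`merge(A, B)` re-threads B's paths into A (the contract is structural
equality with `build(paths(A)+paths(B))`, so re-insertion and BWT-merge are
interchangeable; re-insertion is simpler and exact). `merge_fast` handles
disjoint node sets (different chromosomes) by reusing records verbatim; only
the end-marker record, the cumulative ranks of the end-marker successor
(which count occurrences across both indexes), the identifier samples and the
metadata need touching. `remove_paths` rebuilds over the retained paths;
remaining identifiers are renumbered consecutively in order.

Serialization is a little-endian container (`GBWTPY1` magic) holding the
flags, records, samples and metadata, with a SHA-256 digest; output bytes are
a deterministic function of the index. Bit-compressed layouts are out of
scope.

## Haplotype paths from phased VCFs

`construct_graph` splits the reference at variant-allele boundaries (after
trimming prefixes/suffixes shared by all alleles of a record) and at a
maximum node length of 32 bp; alternate alleles become chains of new nodes
and pure deletions become bypass edges. Threading appends reference nodes up
to each site and then the chosen allele's path. Overlapping sites are
resolved in a fixed order: a reference allele keeps only its not-yet-covered
nodes; an alternate allele may trim trailing reference nodes back to its
start; otherwise the overlap is unresolvable and the policy decides —
`phase-break` starts a new path fragment at the site, `force-ref` drops the
alternate allele. Unphased heterozygotes are a phase break (or reference,
under `force-ref`); missing genotypes are reference. The parser expects
diploid samples with haploid regions allowed. Parsed VCFs can be staged to
plain-text files (reference layout + allele paths, plus independently
readable per-batch run-length-encoded phasing files, 200 samples per batch by
default) so that index construction never re-parses the VCF.

## Pruning and unfolding

Pruning removes edges that cannot be crossed by any k-base window making at
most `max_choices` edge choices (default 3 choices in a 24-mer), where an
edge choice is traversing an edge whose source has out-degree ≥ 2 or target
in-degree ≥ 2. The window minimum is computed exactly by memoised search
over label lengths in both directions; edges that are the sole outgoing and
sole incoming edge of their endpoints are never removed. Weakly connected
components with less than 33 bp of sequence are then deleted, and reference
paths can be restored.

Unfolding restores haplotype support: the complement of the pruned graph with
respect to the graph induced by the indexed paths decomposes into connected
components; each component's border is its intersection with the pruned
graph. Haplotype-supported maximal paths (border-to-border, dead ends of
length ≥ 2, and paths lying entirely inside the component) are enumerated
with GBWT search states — border nodes seed full-record states, internal
nodes seed path-start states, and extension follows component edges in both
orientations. Dead ends on a reference path are extended along it (smallest
path name, at the dead-end tail) until the border or the component runs out.
Paths are canonicalised as the smaller of the path and its reverse. Each
path is split into a prefix of ⌈|P|/2⌉ nodes and the remaining suffix; a trie
of prefixes and a trie of reversed suffixes become graph structure, with
border root edges reusing original nodes, every other trie edge a fresh
duplicate recorded in the translation map, and one cross edge per path from
prefix end to suffix start. Shared trie edges share duplicates, which is
what keeps spurious recombinations out: the border-to-border paths realised
by an unfolded component are exactly the maximal path set, a property the
tests check by exhaustive enumeration. A single-node haplotype path whose
node was pruned away is restored directly, since the trie construction needs
at least two nodes. Duplicate labels carry the oriented spelling of their
original, so every haplotype's base sequence — hence every k-mer — survives
simplification; the tests verify 8-mers explicitly.

## Synthetic data

The fixture generator builds a backbone chain with biallelic bubbles
(occasionally traversed in reverse, to exercise orientations), optional
cycles, and mostly dense but occasionally gapped node ids. Haplotypes derive
from a few founder walks by per-step recombination; with recombination rate
zero every haplotype is an exact founder copy (asserted by a test), and with
a positive rate a small fraction of degenerate single-node paths is mixed in.
The VCF fixture writes a 1 kb reference with 20 variants — SNVs, insertions,
deletions and one engineered overlapping-deletion pair — for 10 phased
diploid samples. What the generators do **not** emulate: realistic
coalescent genealogies, mutation/error models, structural variation,
megabase-scale inputs, or VCF oddities beyond symbolic-allele records; green
tests show structural and algorithmic correctness at desk scale, not
performance or robustness to malformed real-world files.

## Oracles and numerical choices

Ground truth comes from two independent routes: a brute-force oracle that
enumerates every occurrence, sorts by explicit reverse-prefix keys
(end-marker of path *j* encoded as `j − m` so plain tuple comparison is the
intended order) and partitions into records; and, for the VCF pipeline, a
string-level substitution oracle that applies alleles directly to the
reference sequence. Neither shares code with the construction or query
paths. All comparisons are exact — the structures are discrete, so there are
no tolerances anywhere. Problem sizes used by the tests and the acceptance
script (≤ 40 graph ids, ≤ 30 paths, path length ≤ 60; 100–200 random
fixtures per property; a 1 kb cohort) were chosen to exercise every code
path, including cyclic and duplicate-path cases, while a full run stays in
the tens of seconds.

## Known limitations

Pure-Python record bodies are rebuilt wholesale on every update; construction
is single-threaded and suitable for desk-scale collections, not population
cohorts. The dynamic index keeps uncompressed bodies in memory. GFA support
is the 0M-overlap GFA1 dialect with P lines (no W lines, no GFA2). Arbitrary
ploidy beyond diploid-with-haploid-regions is not parsed from VCFs, and
structural/symbolic variants are skipped.
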