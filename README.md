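# graphbwt

A pure-Python graph BWT (GBWT): a run-length encoded FM-index of haplotype
paths over bidirected variation graphs, with haplotype-aware graph
simplification.

Variation graphs represent genetic variation as bubbles in a reference
backbone, but the graph alone cannot tell biological haplotypes from
arbitrary recombinations of them — almost every path through a dense cluster
of variants is one nobody carries. `graphbwt` stores the observed haplotypes
as paths and indexes them so that one can ask, for any walk through the
graph, whether and how often real haplotypes take it. It is aimed at people
building or analysing pangenome graphs from phased cohorts at tool-building
and method-development scale.

## The structure

Paths `P_0, …, P_{m−1}` over the node alphabet (node *n* forward is encoded
`2n`, reverse `2n+1`, `$ = 0`) are indexed as an FM-index of their reverse
strings: the occurrence of node *v* at offset *i* of path *j* is sorted by
the key `(v, P_j[i−1], …, P_j[0], $_j)` with distinct end-markers
`$_0 < $_1 < …`, all smaller than every node. The BWT is partitioned per
node into
**records** — a header of `(successor, BWT.rank(v, w))` pairs and a
run-length encoded successor sequence — and positions are `(node, offset)`
pairs with

    LF((v, i), w) = (w, BWT.rank(v, w) + BWT_v.rank(i, w)).

On top of this the package provides:

* `find` / `locate` / `extract` and FMD-style bidirectional search
  (every path is indexed with its reverse path by default);
* batched BCR construction, index merging (including fast merging of
  disjoint-chromosome indexes), path removal and a deterministic,
  checksummed serialization format;
* variation-graph construction from FASTA + phased VCF, haplotype threading
  with overlap resolution and phase breaks, and plain-text staging files so
  the VCF is parsed once;
* haplotype-aware simplification: prune edges that force more than 3 edge
  choices in a 24-mer, drop components under 33 bp, then *unfold* the
  haplotype-supported maximal paths through each pruned region back into the
  graph via prefix/suffix tries, duplicating nodes with a translation table
  — so the simplified graph still spells every haplotype k-mer;
* a seeded fixture generator and a brute-force sorting oracle that defines
  ground truth for every structure and query.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from graphbwt import build, fixture_f1

graph, paths = fixture_f1()   # 5-node bubble; paths 1-2-4-5, 1-3-4-5, 1-2-4-5
index = build(paths)

print("sequences:", index.num_sequences)
state = index.find([4, 8])            # oriented encoding of graph path 2 -> 4
print("occurrences of 2->4:", state.size)
print("carried by sequences:", index.locate(state))
print("path 1:", index.extract(2))    # sequence 2j is forward path j
rec = index.records[8]                # record of forward node 4
print("record of node 4: header", rec.header, "runs", rec.body)
```

prints

```
sequences: 6
occurrences of 2->4: 2
carried by sequences: [0, 4]
path 1: (2, 6, 8, 10)
record of node 4: header [(10, 0)] runs [Run(code=0, length=3)]
```

Six sequences are indexed (three paths and their reverses). The edge from
node 2 to node 4 is used twice, by sequences 0 and 4 — the forward
orientations of paths 0 and 2; path 1 takes the other allele, and its
oriented node sequence `(2, 6, 8, 10)` decodes to `1 3 4 5`. Node 4's record
shows all three visits leaving for node 5 in a single run — the run-length
encoding that keeps the index small however many identical haplotypes are
inserted.

The same operations are available from the shell:

```sh
graphbwt simulate --seed 3 --out-gfa g.gfa --out-paths p.txt
graphbwt build --paths p.txt --gfa g.gfa --out idx.gbwt
graphbwt query --index idx.gbwt find 1 2
graphbwt index-vcf --ref ref.fa --vcf phased.vcf --out hap.gbwt
graphbwt simplify --gfa g.gfa --index idx.gbwt --out-gfa s.gfa --mapping map.tsv
```

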