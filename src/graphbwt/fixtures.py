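"""Synthetic variation graphs and haplotype path collections for testing.

The generator emulates the shape of small variation graphs: a reference-like
backbone chain with biallelic bubbles (occasionally traversed in reverse, to
exercise orientation handling), optional cycles, and haplotype paths derived
from a few founder walks by random recombination.  With a recombination rate
of zero every generated haplotype is an exact founder copy; with a positive
rate a small fraction of degenerate single-node paths is mixed in.  Node ids
are mostly dense but may contain gaps, so nothing downstream may rely on
contiguous identifiers.

Everything is driven by a single seed: the same spec always yields the same
fixture.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .graph import BidirectedGraph, encode_node

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    max_nodes: int = 20  # bound on the number of graph ids
    bubble_density: float = 0.4  # probability of a bubble between backbone nodes
    path_count: int = 8
    max_path_length: int = 30
    recomb_rate: float = 0.1  # per-step founder switching probability
    cycles: bool = False
    n_founders: int | None = None  # None: drawn from the seed


def fixture_f1() -> tuple[BidirectedGraph, list[tuple[int, ...]]]:
    """The fixed exemplar: a single bubble graph with three haplotype paths.

    Graph ids 1..5 labeled G, A, T, GGG, C; edges 1->2, 1->3, 2->4, 3->4,
    4->5 (forward orientations); paths 1 2 4 5, 1 3 4 5 and 1 2 4 5 again.
    """
    g = BidirectedGraph()
    for gid, label in enumerate(["G", "A", "T", "GGG", "C"], start=1):
        g.add_node(gid, label)
    for a, b in [(1, 2), (1, 3), (2, 4), (3, 4), (4, 5)]:
        g.add_edge(encode_node(a), encode_node(b))
    e = encode_node
    paths = [
        (e(1), e(2), e(4), e(5)),
        (e(1), e(3), e(4), e(5)),
        (e(1), e(2), e(4), e(5)),
    ]
    return g, paths


def gen_fixture_with_founders(
    spec: FixtureSpec,
) -> tuple[BidirectedGraph, list[tuple[int, ...]], list[tuple[int, ...]]]:
    """Generate a fixture, also returning the founder paths."""
    rng = random.Random(spec.seed)
    g = BidirectedGraph()

    next_id = 0

    def fresh_id() -> int:
        nonlocal next_id
        next_id += 1
        if rng.random() < 0.1:  # occasional id gap
            next_id += rng.randint(1, 3)
        return next_id

    def random_label() -> str:
        return "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 6)))

    backbone: list[int] = []
    budget = max(2, spec.max_nodes)
    nodes_made = 0
    while nodes_made < budget:
        gid = fresh_id()
        g.add_node(gid, random_label())
        nodes_made += 1
        v = encode_node(gid)
        if backbone:
            g.add_edge(backbone[-1], v)
            # a bubble parallel to the edge we just added
            if nodes_made < budget and rng.random() < spec.bubble_density:
                alt = fresh_id()
                g.add_node(alt, random_label())
                nodes_made += 1
                inverted = rng.random() < 0.25
                a = encode_node(alt, inverted)
                g.add_edge(backbone[-1], a)
                g.add_edge(a, v)
        backbone.append(v)
    if spec.cycles and len(backbone) >= 3:
        j = rng.randrange(2, len(backbone))
        i = rng.randrange(0, j - 1)
        g.add_edge(backbone[j], backbone[i])

    def random_walk() -> tuple[int, ...]:
        cur = backbone[0]
        walk = [cur]
        while len(walk) < spec.max_path_length:
            succs = sorted(g.successors(cur))
            if not succs:
                break
            cur = rng.choice(succs)
            walk.append(cur)
        return tuple(walk)

    n_founders = (
        spec.n_founders if spec.n_founders is not None else rng.randint(1, 4)
    )
    founders = [random_walk() for _ in range(n_founders)]

    # founder node -> list of (founder, position), for recombination targets
    shared: dict[int, list[tuple[int, int]]] = {}
    for f, founder in enumerate(founders):
        for i, v in enumerate(founder):
            shared.setdefault(v, []).append((f, i))

    paths: list[tuple[int, ...]] = []
    for _ in range(spec.path_count):
        if spec.recomb_rate > 0 and rng.random() < 0.1:
            founder = rng.choice(founders)
            paths.append((rng.choice(founder),))  # degenerate single-node path
            continue
        f = rng.randrange(n_founders)
        i = 0
        hap: list[int] = []
        while i < len(founders[f]) and len(hap) < spec.max_path_length:
            v = founders[f][i]
            hap.append(v)
            if rng.random() < spec.recomb_rate:
                f2, i2 = rng.choice(shared[v])
                f, i = f2, i2
            i += 1
        paths.append(tuple(hap))

    for path in founders + paths:
        assert g.is_path(path), "generator produced an invalid path"
    return g, paths, founders


def gen_fixture(
    spec: FixtureSpec,
) -> tuple[BidirectedGraph, list[tuple[int, ...]]]:
    """Seeded random fixture: a labeled graph with symmetric edges and a list
    of valid haplotype paths."""
    graph, paths, _ = gen_fixture_with_founders(spec)
    return graph, paths


def vcf_fixture(
    seed: int,
    directory,
    ref_len: int = 1000,
    n_variants: int = 20,
    n_samples: int = 10,
    contig: str = "chr1",
) -> dict:
    """Write a synthetic reference FASTA and a phased diploid VCF.

    The variants mix SNVs, insertions and deletions at well separated
    positions, plus one engineered pair of overlapping deletions near the
    end; the first sample's first haplotype always carries both overlapping
    deletions.  Returns the file paths, the raw variant records as
    ``(pos0, ref_allele, alt_alleles)`` and the phased genotypes per sample.
    """
    import os

    rng = random.Random(seed)
    ref = "".join(rng.choice(_BASES) for _ in range(ref_len))
    n_regular = n_variants - 2
    step = max(14, (ref_len - 80) // max(1, n_regular))
    records: list[tuple[int, str, tuple[str, ...]]] = []
    for i in range(n_regular):
        p = 10 + i * step + rng.randint(0, max(0, step - 14))
        kind = ("snv", "ins", "del")[i % 3]
        if kind == "snv":
            alt = rng.choice([b for b in _BASES if b != ref[p]])
            records.append((p, ref[p], (alt,)))
        elif kind == "ins":
            ins = "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 6)))
            records.append((p, ref[p], (ref[p] + ins,)))
        else:
            d = rng.randint(1, 6)
            records.append((p, ref[p : p + 1 + d], (ref[p],)))
    # engineered overlapping deletion pair
    q = 10 + n_regular * step
    records.append((q, ref[q : q + 7], (ref[q],)))  # deletes [q+1, q+7)
    records.append((q + 3, ref[q + 3 : q + 10], (ref[q + 3],)))  # deletes [q+4, q+10)
    overlap_pair = (len(records) - 2, len(records) - 1)

    samples = [f"S{i + 1}" for i in range(n_samples)]
    genotypes: dict[str, list[tuple[int, int]]] = {
        s: [(rng.randint(0, 1), rng.randint(0, 1)) for _ in records] for s in samples
    }
    # the first haplotype of the first sample carries both overlapping deletions
    for r in overlap_pair:
        a, b = genotypes[samples[0]][r]
        genotypes[samples[0]][r] = (1, b)

    os.makedirs(str(directory), exist_ok=True)
    ref_path = os.path.join(str(directory), "ref.fa")
    with open(ref_path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(ref), 60):
            fh.write(ref[i : i + 60] + "\n")
    vcf_path = os.path.join(str(directory), "haplotypes.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={ref_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r, (pos0, ra, alts) in enumerate(records):
            gts = "\t".join(f"{a}|{b}" for a, b in (genotypes[s][r] for s in samples))
            fh.write(
                f"{contig}\t{pos0 + 1}\t.\t{ra}\t{','.join(alts)}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return {
        "contig": contig,
        "reference": ref,
        "ref_path": ref_path,
        "vcf_path": vcf_path,
        "records": records,
        "samples": samples,
        "genotypes": genotypes,
        "overlap_pair": overlap_pair,
    }


def random_absent_patterns(
    rng: random.Random,
    graph: BidirectedGraph,
    paths: list[tuple[int, ...]],
    count: int,
    max_len: int = 5,
) -> list[tuple[int, ...]]:
    """Random patterns over the graph's oriented nodes that occur in no path."""
    present: set[tuple[int, ...]] = set()
    for path in paths:
        for i in range(len(path)):
            for L in range(1, min(max_len, len(path) - i) + 1):
                present.add(tuple(path[i : i + L]))
    alphabet = [encode_node(gid, r) for gid in graph.node_ids() for r in (False, True)]
    out: list[tuple[int, ...]] = []
    attempts = 0
    while len(out) < count and attempts < count * 100:
        attempts += 1
        L = rng.randint(1, max_len)
        pat = tuple(rng.choice(alphabet) for _ in range(L))
        if pat not in present:
            out.append(pat)
    return out
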