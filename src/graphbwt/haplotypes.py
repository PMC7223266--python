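"""Variation-graph construction from FASTA + VCF and haplotype path threading.

The reference is split into nodes at variant-allele boundaries and at a
maximum node length (default 32 bp); each alternate allele becomes a chain of
new nodes, and pure deletions become edges that bypass the deleted reference
nodes.  Phased genotypes are then threaded through the allele paths: for each
haplotype we append reference nodes up to the next variant site and then the
path of the chosen allele.

Overlapping sites are resolved deterministically, in this order:
1. a reference allele whose interval was partially consumed keeps only its
   not-yet-covered reference nodes;
2. if the already generated path ends in reference nodes extending past the
   new site's start, those are removed and the alternate allele is applied;
3. otherwise the overlap is unresolvable and the policy decides: under
   ``phase-break`` the haplotype path is split into a new fragment starting
   at the site, under ``force-ref`` the alternate allele is replaced by the
   reference.  Unphased heterozygous genotypes are treated as phase breaks
   under ``phase-break`` and as reference under ``force-ref``.  Missing
   genotypes are treated as reference.

The parser expects a diploid genome where some regions may be haploid.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .build import DEFAULT_SAMPLE_INTERVAL, GBWTBuilder
from .gbwt import GBWTIndex, PathMetadata
from .graph import BidirectedGraph, MalformedInputError, encode_node, oriented_to_signed, signed_to_oriented

DEFAULT_MAX_NODE_LEN = 32
DEFAULT_BATCH_SIZE = 200  # samples per phasing batch

Genotype = tuple[tuple[int | None, ...], bool]  # (allele indices, phased)


@dataclass
class VariantSite:
    """One variant locus: a reference interval and one node path per allele
    (index 0 = reference allele)."""

    contig: str
    start: int  # 0-based, after trimming shared allele prefixes/suffixes
    end: int  # half-open
    allele_paths: list[tuple[int, ...]]


@dataclass
class ReferenceLayout:
    """The reference node chain of one contig: (graph id, start, end) per node."""

    contig: str
    nodes: list[tuple[int, int, int]]

    def path(self) -> tuple[int, ...]:
        return tuple(encode_node(gid) for gid, _, _ in self.nodes)

    @property
    def length(self) -> int:
        return self.nodes[-1][2] if self.nodes else 0


@dataclass
class PhasingRow:
    """Phased allele choices of one sample on one contig, aligned with the
    contig's site list."""

    sample: str
    genotypes: list[Genotype]
    ploidy: int = 2


@dataclass
class SamplePhasing:
    sample: str
    rows: dict[str, PhasingRow] = field(default_factory=dict)  # contig -> row


# -- input parsing -------------------------------------------------------------


def _load_reference(reference) -> dict[str, str]:
    if isinstance(reference, Mapping):
        return {name: str(seq).upper() for name, seq in reference.items()}
    import pyfaidx

    fasta = pyfaidx.Fasta(str(reference))
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def _is_symbolic(allele: str | None) -> bool:
    if allele is None:
        return True
    return any(ch in allele for ch in "<>[]*") or allele == "."


@dataclass
class _VcfData:
    samples: list[str]
    # contig -> list of (pos0, ref, alts, genotypes per sample)
    records: dict[str, list[tuple[int, str, tuple[str, ...], list[Genotype]]]]
    skipped: int


def _read_vcf(path) -> _VcfData:
    import pysam

    skipped = 0
    records: dict[str, list] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = tuple(rec.alts or ())
            if not alts or _is_symbolic(rec.ref) or any(_is_symbolic(a) for a in alts):
                skipped += 1
                continue
            genotypes: list[Genotype] = []
            for name in samples:
                call = rec.samples[name]
                alleles = tuple(call.get("GT", (None,)) or (None,))
                genotypes.append((alleles, bool(call.phased)))
            records.setdefault(rec.contig, []).append(
                (rec.start, rec.ref.upper(), tuple(a.upper() for a in alts), genotypes)
            )
    if skipped:
        import warnings

        warnings.warn(
            f"skipped {skipped} variant record(s) with symbolic or breakend alleles",
            stacklevel=2,
        )
    return _VcfData(samples, records, skipped)


def _trim_alleles(pos0: int, ref: str, alts: tuple[str, ...]) -> tuple[int, int, list[str]]:
    """Strip prefix/suffix shared by all alleles; return core interval + alt cores."""
    alleles = [ref, *alts]
    p = 0
    while all(len(a) > p and a[p] == ref[p] for a in alleles):
        p += 1
    s = 0
    while s < min(len(a) for a in alleles) - p and all(
        a[len(a) - 1 - s] == ref[len(ref) - 1 - s] for a in alleles
    ):
        s += 1
    return pos0 + p, pos0 + len(ref) - s, [a[p : len(a) - s] for a in alts]


# -- graph construction --------------------------------------------------------


class _GraphAssembler:
    def __init__(self, max_node_len: int) -> None:
        if max_node_len < 1:
            raise ValueError("max_node_len must be at least 1")
        self.max_node_len = max_node_len
        self.graph = BidirectedGraph()
        self.next_id = 1

    def new_node(self, label: str) -> int:
        gid = self.next_id
        self.next_id += 1
        self.graph.add_node(gid, label)
        return gid

    def chain(self, seq: str) -> list[int]:
        """A chain of new nodes spelling ``seq`` in chunks <= max_node_len."""
        ids = []
        for i in range(0, len(seq), self.max_node_len):
            ids.append(self.new_node(seq[i : i + self.max_node_len]))
        for a, b in zip(ids, ids[1:]):
            self.graph.add_edge(encode_node(a), encode_node(b))
        return ids

    def build_contig(
        self,
        contig: str,
        seq: str,
        records: list[tuple[int, str, tuple[str, ...], list[Genotype]]],
    ) -> tuple[ReferenceLayout, list[VariantSite], list[list[Genotype]]]:
        trimmed = []
        for pos0, ref, alts, genotypes in records:
            if seq[pos0 : pos0 + len(ref)] != ref:
                raise MalformedInputError(
                    f"{contig}:{pos0 + 1}: REF {ref!r} does not match the reference"
                )
            cs, ce, alt_cores = _trim_alleles(pos0, ref, alts)
            trimmed.append((cs, ce, alt_cores, genotypes))
        trimmed.sort(key=lambda t: (t[0], t[1]))

        boundaries = sorted({0, len(seq)} | {t[0] for t in trimmed} | {t[1] for t in trimmed})
        ref_nodes: list[tuple[int, int, int]] = []
        for a, b in zip(boundaries, boundaries[1:]):
            pos = a
            while pos < b:
                end = min(pos + self.max_node_len, b)
                ref_nodes.append((self.new_node(seq[pos:end]), pos, end))
                pos = end
        for (ga, _, _), (gb, _, _) in zip(ref_nodes, ref_nodes[1:]):
            self.graph.add_edge(encode_node(ga), encode_node(gb))
        layout = ReferenceLayout(contig, ref_nodes)
        ends_at = {e: gid for gid, _, e in ref_nodes}
        starts_at = {s: gid for gid, s, _ in ref_nodes}

        sites: list[VariantSite] = []
        genotype_columns: list[list[Genotype]] = []
        for cs, ce, alt_cores, genotypes in trimmed:
            ref_path = tuple(
                encode_node(gid) for gid, s, e in ref_nodes if cs <= s and e <= ce
            )
            prev = ends_at.get(cs) if cs > 0 else None
            nxt = starts_at.get(ce) if ce < len(seq) else None
            allele_paths = [ref_path]
            for alt in alt_cores:
                if not alt:  # pure deletion: an edge bypassing the ref nodes
                    if prev is not None and nxt is not None:
                        self.graph.add_edge(encode_node(prev), encode_node(nxt))
                    allele_paths.append(())
                    continue
                ids = self.chain(alt)
                if prev is not None:
                    self.graph.add_edge(encode_node(prev), encode_node(ids[0]))
                if nxt is not None:
                    self.graph.add_edge(encode_node(ids[-1]), encode_node(nxt))
                allele_paths.append(tuple(encode_node(g) for g in ids))
            sites.append(VariantSite(contig, cs, ce, allele_paths))
            genotype_columns.append(genotypes)
        return layout, sites, genotype_columns


def construct_graph(
    reference,
    variants,
    max_node_len: int = DEFAULT_MAX_NODE_LEN,
) -> tuple[BidirectedGraph, dict[str, list[VariantSite]], dict[str, ReferenceLayout]]:
    """Build a variation graph from a reference and a VCF.

    Returns the graph (with one reference path per contig), the variant sites
    per contig (sorted by position) and the reference layouts.  Symbolic and
    breakend alleles are skipped and counted on the returned graph as
    ``skipped_variants``.
    """
    graph, sites, layouts, _ = _construct(reference, variants, max_node_len)
    return graph, sites, layouts


def _construct(reference, variants, max_node_len):
    ref = _load_reference(reference)
    data = _read_vcf(variants) if variants is not None else _VcfData([], {}, 0)
    unknown = set(data.records) - set(ref)
    if unknown:
        raise MalformedInputError(
            f"VCF contig(s) {sorted(unknown)} missing from the reference"
        )
    assembler = _GraphAssembler(max_node_len)
    sites: dict[str, list[VariantSite]] = {}
    layouts: dict[str, ReferenceLayout] = {}
    phasing: dict[str, list[PhasingRow]] = {}
    for contig, seq in ref.items():
        if not seq:
            raise MalformedInputError(f"contig {contig!r} is empty")
        layout, contig_sites, columns = assembler.build_contig(
            contig, seq, data.records.get(contig, [])
        )
        layouts[contig] = layout
        sites[contig] = contig_sites
        assembler.graph.reference_paths[contig] = layout.path()
        rows = []
        for si, sample in enumerate(data.samples):
            genotypes = [col[si] for col in columns]
            ploidy = max((len(g[0]) for g in genotypes), default=2)
            rows.append(PhasingRow(sample, genotypes, max(1, min(2, ploidy))))
        phasing[contig] = rows
    assembler.graph.skipped_variants = data.skipped  # type: ignore[attr-defined]
    return assembler.graph, sites, layouts, (data.samples, phasing)


def parse_vcf_phasing(
    reference, variants, max_node_len: int = DEFAULT_MAX_NODE_LEN
) -> tuple[list[str], dict[str, list[PhasingRow]]]:
    """Per-contig phasing rows, aligned with the sites of construct_graph."""
    _, _, _, (samples, phasing) = _construct(reference, variants, max_node_len)
    return samples, phasing


# -- haplotype threading -------------------------------------------------------


def generate_haplotype_paths(
    sites: Sequence[VariantSite],
    row: PhasingRow,
    layout: ReferenceLayout,
    policy: str = "phase-break",
) -> list[tuple[tuple[int, ...], PathMetadata]]:
    """Thread one sample's phased alleles into haplotype path fragments.

    Under ``phase-break`` a haplotype yields one fragment plus one per
    unresolvable overlap or unphased heterozygote; under ``force-ref`` always
    a single fragment per haplotype.
    """
    if policy not in ("phase-break", "force-ref"):
        raise ValueError(f"unknown overlap policy {policy!r}")
    if len(row.genotypes) != len(sites):
        raise ValueError(
            f"phasing row covers {len(row.genotypes)} sites, expected {len(sites)}"
        )
    out: list[tuple[tuple[int, ...], PathMetadata]] = []
    ref_nodes = layout.nodes
    for h in range(row.ploidy):
        fragments: list[list[int]] = []
        cur: list[int] = []
        ref_i = 0  # next reference node to emit
        ref_pos = 0  # reference coordinate covered so far
        alt_end = 0  # coordinate up to which the tail content is non-reference

        def emit_ref_until(coord: int) -> None:
            nonlocal ref_i, ref_pos
            while ref_i < len(ref_nodes) and ref_nodes[ref_i][2] <= coord:
                cur.append(encode_node(ref_nodes[ref_i][0]))
                ref_pos = ref_nodes[ref_i][2]
                ref_i += 1

        def close_fragment() -> None:
            nonlocal cur
            if cur:
                fragments.append(cur)
            cur = []

        for site, (alleles, phased) in zip(sites, row.genotypes):
            a = alleles[h] if h < len(alleles) else alleles[0]
            if a is None:
                a = 0
            if a >= len(site.allele_paths):
                raise ValueError(
                    f"allele {a} out of range at {site.contig}:{site.start + 1}"
                )
            het = len(set(x for x in alleles if x is not None)) > 1
            if not phased and het and len(alleles) > 1:
                if policy == "force-ref":
                    a = 0
                else:  # phase break at the unphased site
                    emit_ref_until(site.start)
                    close_fragment()
            if site.start < ref_pos:  # overlap with already generated content
                if a == 0:
                    # keep only the not-yet-covered reference nodes of the allele
                    emit_ref_until(site.end)
                    continue
                if alt_end <= site.start:
                    # the intruding tail is pure reference: remove it
                    while cur and ref_i > 0 and ref_nodes[ref_i - 1][1] >= site.start:
                        cur.pop()
                        ref_i -= 1
                    ref_pos = ref_nodes[ref_i - 1][2] if ref_i > 0 else 0
                else:  # unresolvable
                    if policy == "force-ref":
                        continue  # reference resumes after the previous allele
                    close_fragment()
                    # the new fragment starts at this site
                    while ref_i < len(ref_nodes) and ref_nodes[ref_i][1] < site.end:
                        ref_i += 1
                    ref_pos = site.end
                    cur.extend(site.allele_paths[a])
                    alt_end = site.end
                    continue
            emit_ref_until(site.start)
            cur.extend(site.allele_paths[a])
            while ref_i < len(ref_nodes) and ref_nodes[ref_i][1] < site.end:
                ref_i += 1
            ref_pos = site.end
            if a != 0:
                alt_end = site.end
        emit_ref_until(layout.length)
        close_fragment()
        for f, frag in enumerate(fragments):
            meta = PathMetadata(row.sample, h + 1, layout.contig, f)
            out.append((tuple(frag), meta))
    return out


# -- staging bundles -----------------------------------------------------------


@dataclass
class StagingBundle:
    """Parsed VCF information in a directly usable format: the main part
    (reference layouts + allele paths per site) and per-batch phasing parts."""

    layouts: dict[str, ReferenceLayout]
    sites: dict[str, list[VariantSite]]
    batch_size: int
    batches: list[list[SamplePhasing]]

    def all_samples(self) -> list[SamplePhasing]:
        return [sp for batch in self.batches for sp in batch]


def make_staging(
    layouts: dict[str, ReferenceLayout],
    sites: dict[str, list[VariantSite]],
    phasing: dict[str, list[PhasingRow]],
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> StagingBundle:
    samples: dict[str, SamplePhasing] = {}
    for contig, rows in phasing.items():
        for row in rows:
            samples.setdefault(row.sample, SamplePhasing(row.sample)).rows[
                contig
            ] = row
    ordered = list(samples.values())
    batches = [
        ordered[i : i + batch_size] for i in range(0, len(ordered), batch_size)
    ]
    return StagingBundle(layouts, sites, batch_size, batches)


def _genotype_token(gt: Genotype) -> str:
    alleles, phased = gt
    sep = "|" if phased else "/"
    return sep.join("." if a is None else str(a) for a in alleles)


def _parse_genotype(token: str) -> Genotype:
    phased = "|" in token
    parts = token.replace("|", "/").split("/")
    return (tuple(None if p == "." else int(p) for p in parts), phased)


def _rle_tokens(genotypes: list[Genotype]) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(genotypes):
        j = i
        while j < len(genotypes) and genotypes[j] == genotypes[i]:
            j += 1
        tok = _genotype_token(genotypes[i])
        out.append(tok if j - i == 1 else f"{tok}*{j - i}")
        i = j
    return out


def _parse_rle(tokens: list[str]) -> list[Genotype]:
    out: list[Genotype] = []
    for tok in tokens:
        if "*" in tok:
            tok, count = tok.split("*")
            out.extend([_parse_genotype(tok)] * int(count))
        else:
            out.append(_parse_genotype(tok))
    return out


def _path_token(path: tuple[int, ...]) -> str:
    return ",".join(str(oriented_to_signed(v)) for v in path) if path else "."


def _parse_path(token: str) -> tuple[int, ...]:
    if token == ".":
        return ()
    return tuple(signed_to_oriented(int(t)) for t in token.split(","))


def write_staging(bundle: StagingBundle, directory) -> None:
    """Write a staging bundle as plain-text files plus a JSON manifest; each
    phasing batch file is independently readable."""
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "format": "graphbwt-staging-1",
        "batch_size": bundle.batch_size,
        "n_batches": len(bundle.batches),
        "contigs": sorted(bundle.layouts),
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(directory, "main.txt"), "w") as fh:
        for contig in sorted(bundle.layouts):
            layout = bundle.layouts[contig]
            fh.write(f"contig\t{contig}\n")
            for gid, s, e in layout.nodes:
                fh.write(f"N\t{gid}\t{s}\t{e}\n")
            for site in bundle.sites[contig]:
                paths = "\t".join(_path_token(p) for p in site.allele_paths)
                fh.write(f"S\t{site.start}\t{site.end}\t{paths}\n")
    for k, batch in enumerate(bundle.batches):
        with open(os.path.join(directory, f"phasing_{k}.txt"), "w") as fh:
            for sp in batch:
                fh.write(f"sample\t{sp.sample}\n")
                for contig in sorted(sp.rows):
                    row = sp.rows[contig]
                    tokens = " ".join(_rle_tokens(row.genotypes))
                    fh.write(f"c\t{contig}\t{row.ploidy}\t{tokens}\n")


def read_staging(directory, batches: Sequence[int] | None = None) -> StagingBundle:
    """Read a staging bundle; ``batches`` selects a subset of phasing parts."""
    directory = str(directory)
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "graphbwt-staging-1":
        raise MalformedInputError("not a staging directory (bad manifest)")
    n_batches = manifest["n_batches"]
    wanted = list(range(n_batches)) if batches is None else sorted(set(batches))
    bad = [k for k in wanted if not 0 <= k < n_batches]
    if bad:
        raise MalformedInputError(f"staging has {n_batches} batches; no batch {bad}")
    missing = [
        k
        for k in wanted
        if not os.path.exists(os.path.join(directory, f"phasing_{k}.txt"))
    ]
    if missing:
        raise MalformedInputError(f"missing staging batch files: {missing}")

    layouts: dict[str, ReferenceLayout] = {}
    sites: dict[str, list[VariantSite]] = {}
    contig = None
    with open(os.path.join(directory, "main.txt")) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "contig":
                contig = fields[1]
                layouts[contig] = ReferenceLayout(contig, [])
                sites[contig] = []
            elif fields[0] == "N":
                layouts[contig].nodes.append(
                    (int(fields[1]), int(fields[2]), int(fields[3]))
                )
            elif fields[0] == "S":
                sites[contig].append(
                    VariantSite(
                        contig,
                        int(fields[1]),
                        int(fields[2]),
                        [_parse_path(tok) for tok in fields[3:]],
                    )
                )
    loaded: list[list[SamplePhasing]] = []
    for k in wanted:
        batch: list[SamplePhasing] = []
        with open(os.path.join(directory, f"phasing_{k}.txt")) as fh:
            current: SamplePhasing | None = None
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if fields[0] == "sample":
                    current = SamplePhasing(fields[1])
                    batch.append(current)
                elif fields[0] == "c":
                    assert current is not None
                    tokens = fields[3].split() if len(fields) > 3 and fields[3] else []
                    current.rows[fields[1]] = PhasingRow(
                        current.sample, _parse_rle(tokens), int(fields[2])
                    )
        loaded.append(batch)
    return StagingBundle(layouts, sites, manifest["batch_size"], loaded)


# -- end-to-end construction ---------------------------------------------------


def paths_from_staging(
    bundle: StagingBundle, policy: str = "phase-break"
) -> list[tuple[tuple[int, ...], PathMetadata]]:
    out = []
    for batch in bundle.batches:
        for sp in batch:
            for contig in sorted(sp.rows):
                out.extend(
                    generate_haplotype_paths(
                        bundle.sites[contig],
                        sp.rows[contig],
                        bundle.layouts[contig],
                        policy,
                    )
                )
    return out


def index_from_staging(
    bundle: StagingBundle,
    policy: str = "phase-break",
    both_orientations: bool = True,
    sample_interval: int = DEFAULT_SAMPLE_INTERVAL,
) -> GBWTIndex:
    builder = GBWTBuilder(both_orientations, sample_interval)
    for path, meta in paths_from_staging(bundle, policy):
        if path:
            builder.add(path, meta)
    return builder.finish()


def index_vcf(
    reference,
    variants,
    max_node_len: int = DEFAULT_MAX_NODE_LEN,
    policy: str = "phase-break",
    batch_size: int = DEFAULT_BATCH_SIZE,
    both_orientations: bool = True,
    sample_interval: int = DEFAULT_SAMPLE_INTERVAL,
) -> tuple[BidirectedGraph, GBWTIndex]:
    """Build the variation graph and the GBWT of all phased haplotypes."""
    graph, sites, layouts, (_, phasing) = _construct(reference, variants, max_node_len)
    bundle = make_staging(layouts, sites, phasing, batch_size)
    return graph, index_from_staging(bundle, policy, both_orientations, sample_interval)
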