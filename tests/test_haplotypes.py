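"""Graph construction from FASTA + VCF and haplotype path threading."""

import pytest

from graphbwt.haplotypes import (
    PhasingRow,
    _construct,
    construct_graph,
    generate_haplotype_paths,
    index_from_staging,
    index_vcf,
    make_staging,
    paths_from_staging,
    read_staging,
    write_staging,
)
from graphbwt.graph import MalformedInputError
from graphbwt.fixtures import vcf_fixture
from graphbwt.oracle import substitute_alleles


def write_inputs(tmp_path, ref, vcf_body, samples=("S1",)):
    ref_file = tmp_path / "ref.fa"
    ref_file.write_text(">chr1\n" + ref + "\n")
    vcf_file = tmp_path / "v.vcf"
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        header += "\tFORMAT\t" + "\t".join(samples)
    vcf_file.write_text(
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID=chr1,length={len(ref)}>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        + header
        + "\n"
        + vcf_body
    )
    return str(ref_file), str(vcf_file)


class TestConstructGraph:
    def test_single_snv(self, tmp_path):
        ref, vcf = write_inputs(
            tmp_path, "ACGTACGT", "chr1\t4\t.\tT\tG\t.\tPASS\t.\tGT\t0|1\n"
        )
        graph, sites, layouts = construct_graph(ref, vcf)
        site = sites["chr1"][0]
        assert (site.start, site.end) == (3, 4)
        assert len(site.allele_paths) == 2
        assert graph.spell(site.allele_paths[0]) == "T"
        assert graph.spell(site.allele_paths[1]) == "G"
        assert graph.spell(layouts["chr1"].path()) == "ACGTACGT"

    def test_no_variants_single_chain(self, tmp_path):
        ref, vcf = write_inputs(tmp_path, "A" * 100, "")
        graph, sites, layouts = construct_graph(ref, vcf, max_node_len=32)
        assert sites["chr1"] == []
        assert graph.spell(layouts["chr1"].path()) == "A" * 100
        assert all(len(lbl) <= 32 for lbl in graph.labels.values())

    def test_deletion_becomes_edge(self, tmp_path):
        # REF ACG at pos 2 deletes bases 3-4 (anchor A kept)
        ref, vcf = write_inputs(
            tmp_path, "TACGTT", "chr1\t2\t.\tACG\tA\t.\tPASS\t.\tGT\t1|1\n"
        )
        graph, sites, layouts = construct_graph(ref, vcf)
        site = sites["chr1"][0]
        assert site.allele_paths[1] == ()  # deletion: no nodes, just an edge
        assert len(site.allele_paths[1]) < len(site.allele_paths[0])
        row = PhasingRow("S1", [((1, 1), True)])
        frags = generate_haplotype_paths(sites["chr1"], row, layouts["chr1"])
        assert graph.spell(frags[0][0]) == "TATT"
        assert graph.is_path(frags[0][0])

    def test_contig_mismatch(self, tmp_path):
        ref, vcf = write_inputs(
            tmp_path, "ACGT", "chr1\t2\t.\tC\tT\t.\tPASS\t.\tGT\t0|1\n"
        )
        bad_ref = tmp_path / "other.fa"
        bad_ref.write_text(">chrX\nACGT\n")
        with pytest.raises(MalformedInputError):
            construct_graph(str(bad_ref), vcf)

    def test_symbolic_alleles_skipped_and_counted(self, tmp_path):
        ref, vcf = write_inputs(
            tmp_path,
            "ACGTACGT",
            "chr1\t2\t.\tC\t<DEL>\t.\tPASS\t.\tGT\t0|1\n"
            "chr1\t4\t.\tT\tG\t.\tPASS\t.\tGT\t0|1\n",
        )
        graph, sites, _ = construct_graph(ref, vcf)
        assert len(sites["chr1"]) == 1
        assert graph.skipped_variants == 1


class TestThreading:
    def test_all_reference_genotypes(self, tmp_path):
        ref, vcf = write_inputs(
            tmp_path, "ACGTACGT", "chr1\t4\t.\tT\tG\t.\tPASS\t.\tGT\t0|0\n"
        )
        graph, sites, layouts, (_, phasing) = _construct(ref, vcf, 32)
        frags = generate_haplotype_paths(
            sites["chr1"], phasing["chr1"][0], layouts["chr1"]
        )
        assert len(frags) == 2
        for path, meta in frags:
            assert path == layouts["chr1"].path()

    def test_diploid_fidelity(self, tmp_path):
        ref_seq = "ACGTACGTAAACCCGGGTTT"
        body = (
            "chr1\t4\t.\tT\tG\t.\tPASS\t.\tGT\t0|1\n"
            "chr1\t10\t.\tA\tATTT\t.\tPASS\t.\tGT\t1|0\n"
            "chr1\t14\t.\tCGG\tC\t.\tPASS\t.\tGT\t1|1\n"
        )
        ref, vcf = write_inputs(tmp_path, ref_seq, body)
        graph, sites, layouts, (_, phasing) = _construct(ref, vcf, 5)
        records = [
            (3, "T", ("G",)),
            (9, "A", ("ATTT",)),
            (13, "CGG", ("C",)),
        ]
        gts = [(0, 1), (1, 0), (1, 1)]
        frags = generate_haplotype_paths(
            sites["chr1"], phasing["chr1"][0], layouts["chr1"]
        )
        for h in (1, 2):
            expect, breaks = substitute_alleles(
                ref_seq, records, [g[h - 1] for g in gts]
            )
            concat = "".join(graph.spell(p) for p, m in frags if m.phase == h)
            assert breaks == 0
            assert concat == expect

    def test_overlapping_deletions_policies(self, tmp_path):
        ref_seq = "TTTTTAAAAACCCCCGGGGGTTTTTAAAAA"
        # deletions [6,10) and [8,13) (0-based core intervals): unresolvable
        body = (
            "chr1\t6\t.\tAAAAA\tA\t.\tPASS\t.\tGT\t1|0\n"
            "chr1\t8\t.\tAAACCCCC\tA\t.\tPASS\t.\tGT\t1|0\n"
        )
        ref, vcf = write_inputs(tmp_path, ref_seq, body)
        graph, sites, layouts, (_, phasing) = _construct(ref, vcf, 32)
        row = phasing["chr1"][0]
        broken = generate_haplotype_paths(sites["chr1"], row, layouts["chr1"], "phase-break")
        forced = generate_haplotype_paths(sites["chr1"], row, layouts["chr1"], "force-ref")
        count = lambda frags, h: sum(1 for _, m in frags if m.phase == h)
        assert count(broken, 1) == 2  # haplotype 1 carries both deletions
        assert count(broken, 2) == 1
        assert count(forced, 1) == 1
        assert count(forced, 2) == 1
        for policy, frags in (("phase-break", broken), ("force-ref", forced)):
            for h in (1, 2):
                expect, _ = substitute_alleles(
                    ref_seq,
                    [(5, "AAAAA", ("A",)), (7, "AAACCCCC", ("A",))],
                    [1 if h == 1 else 0] * 2,
                    policy,
                )
                concat = "".join(graph.spell(p) for p, m in frags if m.phase == h)
                assert concat == expect, (policy, h)

    def test_unphased_het_breaks_phase(self, tmp_path):
        ref, vcf = write_inputs(
            tmp_path, "ACGTACGT", "chr1\t4\t.\tT\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        _, sites, layouts, (_, phasing) = _construct(ref, vcf, 32)
        row = phasing["chr1"][0]
        broken = generate_haplotype_paths(sites["chr1"], row, layouts["chr1"])
        assert sum(1 for _, m in broken if m.phase == 1) == 2
        forced = generate_haplotype_paths(sites["chr1"], row, layouts["chr1"], "force-ref")
        assert sum(1 for _, m in forced if m.phase == 1) == 1

    def test_allele_out_of_range_names_site(self, tmp_path):
        ref, vcf = write_inputs(
            tmp_path, "ACGTACGT", "chr1\t4\t.\tT\tG\t.\tPASS\t.\tGT\t0|1\n"
        )
        _, sites, layouts, _ = _construct(ref, vcf, 32)
        row = PhasingRow("S1", [((0, 5), True)])
        with pytest.raises(ValueError, match="chr1:4"):
            generate_haplotype_paths(sites["chr1"], row, layouts["chr1"])


class TestStaging:
    @pytest.fixture
    def bundle(self, tmp_path):
        fx = vcf_fixture(21, tmp_path, ref_len=300, n_variants=8, n_samples=5)
        _, sites, layouts, (_, phasing) = _construct(fx["ref_path"], fx["vcf_path"], 32)
        return make_staging(layouts, sites, phasing, batch_size=2), fx

    def test_round_trip_identity(self, bundle, tmp_path):
        staged, fx = bundle
        d = tmp_path / "staging"
        write_staging(staged, d)
        loaded = read_staging(d)
        assert paths_from_staging(loaded) == paths_from_staging(staged)
        assert index_from_staging(loaded) == index_from_staging(staged)

    def test_staged_index_equals_vcf_index(self, bundle, tmp_path):
        staged, fx = bundle
        d = tmp_path / "staging"
        write_staging(staged, d)
        _, direct = index_vcf(fx["ref_path"], fx["vcf_path"], batch_size=2)
        assert index_from_staging(read_staging(d)) == direct

    def test_batch_subset(self, bundle, tmp_path):
        staged, fx = bundle
        d = tmp_path / "staging"
        write_staging(staged, d)
        sub = read_staging(d, batches=[1])
        assert [sp.sample for sp in sub.batches[0]] == [
            sp.sample for sp in staged.batches[1]
        ]

    def test_missing_batch_listed(self, bundle, tmp_path):
        staged, fx = bundle
        d = tmp_path / "staging"
        write_staging(staged, d)
        (d / "phasing_1.txt").unlink()
        with pytest.raises(MalformedInputError, match=r"\[1\]"):
            read_staging(d)

    def test_empty_sample_set_main_part_only(self, tmp_path):
        ref, vcf = write_inputs(tmp_path, "ACGT", "", samples=())
        _, sites, layouts, (_, phasing) = _construct(ref, vcf, 32)
        staged = make_staging(layouts, sites, phasing)
        d = tmp_path / "staging"
        write_staging(staged, d)
        loaded = read_staging(d)
        assert loaded.batches == []
        assert paths_from_staging(loaded) == []
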