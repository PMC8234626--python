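"""Annotation parsing, terminal fragments, site grouping, and classification."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apaquant import (
    TranscriptModel,
    classify_apa,
    filter_transcripts,
    group_polya_sites,
    load_annotation,
    make_terminal_fragment,
    write_terminal_fragment_fasta,
)
from apaquant.annotation import AnnotationError, _trailing_window

from conftest import make_fragment


def tx(exons, strand="+", tx_id="t1", gene="g1", tags=(), biotype="protein_coding"):
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene,
        chrom="chr1",
        strand=strand,
        exons=tuple(exons),
        tags=frozenset(tags),
        biotype=biotype,
    )


class TestLoadAnnotation:
    def test_minimal_gff3_parses_two_transcripts_under_one_gene(self, toy_gff3):
        genes = load_annotation(toy_gff3)
        assert set(genes) == {"geneA"}
        assert {t.transcript_id for t in genes["geneA"]} == {"geneA.t1", "geneA.t2"}
        t1 = next(t for t in genes["geneA"] if t.transcript_id == "geneA.t1")
        assert t1.exons == ((1, 500), (1000, 2000))
        assert t1.biotype == "protein_coding"

    def test_ill_defined_end_tag_is_captured(self, toy_gff3):
        genes = load_annotation(toy_gff3)
        t2 = next(t for t in genes["geneA"] if t.transcript_id == "geneA.t2")
        assert "mRNA_end_NF" in t2.tags

    def test_orphan_exon_raises_naming_the_exon(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\tt\ttranscript\t1\t100\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "chr1\tt\texon\t1\t100\t.\t+\t.\tID=g1.t1.e1;Parent=g1.t1\n"
            "chr1\tt\texon\t1\t50\t.\t+\t.\tID=lost.exon;Parent=absent.tx\n"
        )
        with pytest.raises(AnnotationError, match="lost.exon"):
            load_annotation(path)

    def test_undefined_strand_transcript_is_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "nostrand.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\tt\ttranscript\t1\t100\t.\t.\t.\tID=g1.t1;Parent=g1\n"
            "chr1\tt\texon\t1\t100\t.\t.\t.\tID=g1.t1.e1;Parent=g1.t1\n"
        )
        assert load_annotation(path) == {}

    def test_index_cache_is_reused_and_invalidated_on_change(self, toy_gff3):
        load_annotation(toy_gff3)
        db = toy_gff3.parent / (toy_gff3.name + ".db")
        assert db.exists()
        first_mtime = db.stat().st_mtime_ns
        load_annotation(toy_gff3)
        assert db.stat().st_mtime_ns == first_mtime  # cache hit
        toy_gff3.write_text(toy_gff3.read_text() + "\n")
        load_annotation(toy_gff3)
        assert db.stat().st_mtime_ns != first_mtime  # checksum changed


class TestFilterTranscripts:
    def test_removes_ill_defined_end_transcripts(self):
        genes = {
            "g1": [
                tx([(1, 100)], tx_id="a"),
                tx([(1, 100)], tx_id="b", tags=["mRNA_end_NF"]),
                tx([(1, 100)], tx_id="c"),
            ]
        }
        kept = filter_transcripts(genes)
        assert [t.transcript_id for t in kept["g1"]] == ["a", "c"]

    def test_protein_coding_flag_drops_other_biotypes(self):
        genes = {
            "g1": [
                tx([(1, 100)], tx_id="a", biotype="protein_coding"),
                tx([(1, 100)], tx_id="b", biotype="lncRNA"),
            ]
        }
        kept = filter_transcripts(genes, require_protein_coding=True)
        assert [t.transcript_id for t in kept["g1"]] == ["a"]

    def test_no_tags_no_flag_is_identity(self):
        genes = {"g1": [tx([(1, 100)], tx_id="a", biotype="lncRNA")]}
        assert filter_transcripts(genes) == {
            "g1": [tx([(1, 100)], tx_id="a", biotype="lncRNA")]
        }

    def test_empty_gene_is_dropped(self):
        genes = {"g1": [tx([(1, 100)], tags=["mRNA_end_NF"])]}
        assert filter_transcripts(genes) == {}


class TestTerminalFragment:
    def test_plus_strand_last_two_exons(self):
        frag = make_terminal_fragment(tx([(1, 100), (200, 300), (400, 500)]))
        assert frag.fragment_exons == ((200, 300), (400, 500))
        assert frag.three_prime_end == 500
        assert frag.fragment_length == 202

    def test_minus_strand_two_exon_transcript(self):
        frag = make_terminal_fragment(tx([(1, 100), (200, 300)], strand="-"))
        assert frag.fragment_exons == ((200, 300), (1, 100))
        assert frag.three_prime_end == 1
        assert frag.fragment_length == 201

    def test_single_exon_transcript_is_whole_transcript(self):
        frag = make_terminal_fragment(tx([(10, 60)]))
        assert frag.fragment_exons == ((10, 60),)
        assert frag.fragment_length == 51

    def test_3pseq_short_transcript_is_whole_transcript(self):
        frag = make_terminal_fragment(tx([(1, 250)]), mode="3pseq")
        assert frag.fragment_length == 250
        assert frag.fragment_exons == ((1, 250),)

    def test_3pseq_window_spans_exon_boundary(self):
        # last exon is 101 nt; the remaining 199 nt come from the middle exon
        frag = make_terminal_fragment(
            tx([(1, 1000), (2000, 2999), (4000, 4100)]), mode="3pseq"
        )
        assert frag.fragment_length == 300
        assert frag.fragment_exons == ((2801, 2999), (4000, 4100))
        assert frag.three_prime_end == 4100

    def test_3pseq_minus_strand_window(self):
        frag = make_terminal_fragment(
            tx([(100, 200), (1000, 1999)], strand="-"), mode="3pseq"
        )
        # 3' end is at coordinate 100; 101 nt from the low exon, 199 from the next
        assert frag.fragment_length == 300
        assert frag.fragment_exons == ((1000, 1198), (100, 200))
        assert frag.three_prime_end == 100

    def test_trailing_window_helper_exact_fit(self):
        assert _trailing_window([(1, 300)], "+", 300) == [(1, 300)]


class TestGroupPolyASites:
    def test_two_near_ends_group_one_far_end_separate(self):
        frags = [make_fragment(e) for e in (100, 120, 200)]
        sites = group_polya_sites(frags, window=25)
        assert [sorted(f.three_prime_end for f in s.member_fragments) for s in sites] == [
            [100, 120],
            [200],
        ]
        assert [s.m for s in sites] == [0, 1]
        assert sites[0].representative_end == 120

    def test_gap_just_over_window_splits(self):
        sites = group_polya_sites([make_fragment(100), make_fragment(126)], window=25)
        assert len(sites) == 2

    def test_gap_equal_to_window_merges(self):
        sites = group_polya_sites([make_fragment(100), make_fragment(125)], window=25)
        assert len(sites) == 1

    def test_chained_linkage_merges_transitively(self):
        sites = group_polya_sites(
            [make_fragment(e) for e in (100, 120, 140)], window=25
        )
        assert len(sites) == 1  # 100-140 span > 25 but each step <= 25

    def test_minus_strand_ordering_is_reversed(self):
        frags = [make_fragment(e, strand="-") for e in (100, 200)]
        sites = group_polya_sites(frags, window=25)
        # transcription runs high -> low: 200 is proximal, 100 distal
        assert sites[0].representative_end == 200 and sites[0].m == 0
        assert sites[1].representative_end == 100 and sites[1].m == 1

    def test_partition_invariant_to_input_order(self):
        ends = (100, 120, 200, 230, 400)
        reference = None
        for perm in itertools.permutations(ends):
            sites = group_polya_sites([make_fragment(e) for e in perm], window=25)
            key = tuple(
                tuple(sorted(f.three_prime_end for f in s.member_fragments))
                for s in sites
            )
            reference = reference or key
            assert key == reference

    def test_every_fragment_lands_in_exactly_one_site(self):
        frags = [make_fragment(e) for e in (10, 40, 80, 300, 320)]
        sites = group_polya_sites(frags, window=25)
        members = [f.transcript_id for s in sites for f in s.member_fragments]
        assert sorted(members) == sorted(f.transcript_id for f in frags)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        ends=st.lists(
            st.integers(min_value=100, max_value=10_000),
            min_size=1,
            max_size=8,
            unique=True,
        )
    )
    def test_strand_flip_reverses_site_indices(self, ends):
        # same 3'-end coordinates on the opposite strand: the clustering
        # partition is unchanged but proximal/distal ordering reverses
        plus = group_polya_sites([make_fragment(e, strand="+") for e in ends])
        minus = group_polya_sites([make_fragment(e, strand="-") for e in ends])
        n = len(plus)
        assert len(minus) == n
        for site in plus:
            ends_plus = sorted(f.three_prime_end for f in site.member_fragments)
            twin = minus[n - 1 - site.m]
            ends_minus = sorted(f.three_prime_end for f in twin.member_fragments)
            assert ends_plus == ends_minus

    def test_empty_input_gives_empty_list(self):
        assert group_polya_sites([]) == []

    def test_mixed_gene_input_rejected(self):
        with pytest.raises(AnnotationError):
            group_polya_sites(
                [make_fragment(100, gene_id="g1"), make_fragment(200, gene_id="g2")]
            )


class TestClassifyApa:
    def _site_frag(self, end, exon):
        return make_fragment(end, exon_len=exon[1] - exon[0] + 1).__class__(
            transcript_id=f"t{end}",
            gene_id="g1",
            chrom="chr1",
            strand="+",
            fragment_exons=(exon,),
            three_prime_end=end,
            fragment_length=exon[1] - exon[0] + 1,
        )

    def test_shared_terminal_exon_is_tandem_utr(self):
        # both 3' ends inside one exon footprint shared across isoforms
        frags = [
            self._site_frag(1500, (1000, 1500)),
            self._site_frag(2000, (1000, 2000)),
        ]
        sites = group_polya_sites(frags)
        assert classify_apa(sites) == "TUTR"

    def test_distinct_terminal_exons_is_ale(self):
        frags = [
            self._site_frag(1500, (1000, 1500)),
            self._site_frag(4000, (3000, 4000)),
        ]
        sites = group_polya_sites(frags)
        assert classify_apa(sites) == "ALE"

    def test_two_shared_one_separate_is_mixed(self):
        frags = [
            self._site_frag(1500, (1000, 1500)),
            self._site_frag(2000, (1000, 2000)),
            self._site_frag(5000, (4500, 5000)),
        ]
        sites = group_polya_sites(frags)
        assert len(sites) == 3
        assert classify_apa(sites) == "mixed"

    def test_single_site_gene_has_no_class(self):
        sites = group_polya_sites([make_fragment(100)])
        assert classify_apa(sites) is None

    def test_two_site_genes_are_never_mixed(self):
        # any two-site configuration must resolve to TUTR or ALE
        for exon_b in [(1000, 2000), (1600, 2000)]:
            frags = [
                self._site_frag(1500, (1000, 1500)),
                self._site_frag(2000, exon_b),
            ]
            assert classify_apa(group_polya_sites(frags)) in ("TUTR", "ALE")


class TestFragmentFasta:
    def test_plus_strand_spliced_substring(self, tmp_path, toy_genome):
        genome_path, seq = toy_genome
        frag = TestClassifyApa()._site_frag(40, (31, 40))
        frag = frag.__class__(
            transcript_id="t1",
            gene_id="g1",
            chrom="chr1",
            strand="+",
            fragment_exons=((11, 20), (31, 40)),
            three_prime_end=40,
            fragment_length=20,
        )
        out = tmp_path / "frags.fa"
        write_terminal_fragment_fasta([frag], genome_path, out)
        lines = out.read_text().splitlines()
        assert lines[0] == ">t1"
        assert lines[1] == seq[10:20] + seq[30:40]

    def test_minus_strand_reverse_complement(self, tmp_path, toy_genome):
        genome_path, seq = toy_genome
        from Bio.Seq import Seq

        frag = TranscriptModel(
            transcript_id="t1",
            gene_id="g1",
            chrom="chr1",
            strand="-",
            exons=((11, 20), (31, 40)),
        )
        fragment = make_terminal_fragment(frag)
        out = tmp_path / "frags.fa"
        write_terminal_fragment_fasta([fragment], genome_path, out)
        expected = str(Seq(seq[10:20] + seq[30:40]).reverse_complement())
        assert out.read_text().splitlines()[1] == expected

    def test_missing_chromosome_errors(self, tmp_path, toy_genome):
        genome_path, _ = toy_genome
        frag = make_fragment(40, chrom="chrMissing")
        with pytest.raises(AnnotationError, match="chrMissing"):
            write_terminal_fragment_fasta([frag], genome_path, tmp_path / "o.fa")
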