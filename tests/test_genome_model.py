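"""Genome/annotation model: coordinate conventions, coding introns, phases,
shared-intron logic, and annotation I/O round trips."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import introntrap as it
from introntrap.genome_model import (coding_introns, intron_phase,
                                     shared_coding_introns)
from introntrap.seqtools import translate


def tx(segs, strand="+", contig="c", tid="t1"):
    return it.TranscriptModel(transcript_id=tid, contig=contig, strand=strand,
                              cds_segments=segs)


class TestCodingIntrons:
    def test_plus_strand_single_intron(self):
        t = tx([(100, 200), (300, 450)])
        (i,) = coding_introns(t)
        assert (i.start, i.end) == (200, 300)
        assert i.length == 100
        assert i.upstream_cds_len == 100
        assert i.phase == 1
        assert i.transcript_order_index == 0

    def test_single_segment_yields_no_introns(self):
        assert coding_introns(tx([(100, 700)])) == []

    def test_minus_strand_intron_span_and_phase(self):
        # transcript order on the minus strand is genomically descending
        t = tx([(300, 450), (100, 200)], strand="-")
        (i,) = coding_introns(t)
        assert (i.start, i.end) == (200, 300)
        assert i.transcript_order_index == 0
        assert i.upstream_cds_len == 150
        assert i.phase == 0

    def test_overlapping_cds_segments_rejected(self):
        with pytest.raises(it.MalformedModelError):
            tx([(100, 250), (200, 300)])

    def test_phase_examples(self):
        t = tx([(0, 99), (200, 300), (400, 500)])
        i1, i2 = coding_introns(t)
        assert i1.upstream_cds_len == 99 and i1.phase == 0
        assert i2.upstream_cds_len == 199 and i2.phase == 1
        assert intron_phase(t, i1) == 0
        assert intron_phase(t, i2) == 1

    def test_intron_phase_unknown_intron_errors(self):
        t = tx([(100, 200), (300, 450)])
        other = it.CodingIntron(contig="c", start=500, end=600, strand="+",
                                transcript_order_index=0, upstream_cds_len=0)
        with pytest.raises(it.MalformedModelError):
            intron_phase(t, other)

    def test_translation_oracle_for_phases(self):
        """On a three-exon transcript the phase equals the codon offset at
        each junction of the spliced, translated CDS."""
        # spliced CDS: ATG + 19 codons + TAA = 63 nt; exons 10/29/24
        cds = "ATG" + "GCT" * 19 + "TAA"
        exons, introns = [10, 29, 24], [50, 70]
        contig = (cds[:10] + "G" * 50 + cds[10:39] + "C" * 70 + cds[39:])
        segs = [(0, 10), (60, 89), (159, 183)]
        t = tx(segs)
        assert "".join(contig[s:e] for s, e in segs) == cds
        assert translate(cds)[0] == "M" and translate(cds).endswith("*")
        for intron in coding_introns(t):
            assert intron.phase == intron.upstream_cds_len % 3

    @given(st.lists(st.tuples(st.integers(30, 200), st.integers(20, 120)),
                    min_size=2, max_size=6))
    def test_phase_telescoping_property(self, blocks):
        """phase(k+1) == (phase(k) + length of the exon between them) mod 3."""
        pos, segs = 0, []
        for elen, ilen in blocks:
            segs.append((pos, pos + elen))
            pos += elen + ilen
        t = tx(segs)
        introns = coding_introns(t)
        for a, b, (s, e) in zip(introns, introns[1:], segs[1:]):
            assert b.phase == (a.phase + (e - s)) % 3
        # span identity: first CDS start to last CDS end covers CDS + introns
        total = segs[-1][1] - segs[0][0]
        assert total == t.cds_length + sum(i.length for i in introns)


class TestSharedIntrons:
    def test_identical_transcripts_share_everything(self):
        a = tx([(0, 99), (200, 300)], tid="a")
        b = tx([(0, 99), (200, 300)], tid="b")
        g = it.GeneModel("g", "c", "+", "protein_coding", [a, b])
        shared = shared_coding_introns(g)
        assert [(i.span) for i in shared] == [(99, 200)]
        assert shared[0].support == 2

    def test_subset_intron_excluded(self):
        a = tx([(0, 99), (200, 300), (400, 500)], tid="a")
        b = tx([(0, 99), (200, 500)], tid="b")       # lacks the second intron
        g = it.GeneModel("g", "c", "+", "protein_coding", [a, b])
        assert [i.span for i in shared_coding_introns(g)] == [(99, 200)]

    def test_same_span_different_phase_excluded(self):
        # an alternative upstream exon boundary shifts the reading frame over
        # a span-identical intron; only the span-AND-phase match counts
        a = tx([(0, 99), (200, 300)], tid="a")    # intron (99,200), phase 0
        b = tx([(10, 99), (200, 300)], tid="b")   # same span, phase 89%3 == 2
        g = it.GeneModel("g", "c", "+", "protein_coding", [a, b])
        assert shared_coding_introns(g, mode="exact") == []

    def test_overlap_mode_is_more_permissive(self):
        a = tx([(0, 99), (200, 300)], tid="a")
        b = tx([(0, 99), (206, 300)], tid="b")        # shifted 3' splice site
        g = it.GeneModel("g", "c", "+", "protein_coding", [a, b])
        assert shared_coding_introns(g, mode="exact") == []
        assert [i.span for i in shared_coding_introns(g, mode="overlap")] == [(99, 200)]

    def test_shared_subset_of_every_transcript(self, genome):
        for gene in genome.genes:
            shared = {i.span for i in shared_coding_introns(gene)}
            for t in gene.transcripts:
                assert shared <= {i.span for i in coding_introns(t)}


class TestLoadAndWrite:
    def test_gff3_coordinate_conversion(self, tmp_path):
        (tmp_path / "g.fa").write_text(">chr1\n" + "ACGT" * 100 + "\n")
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t400\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t1\t400\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tx\tCDS\t101\t200\t.\t+\t0\tID=c1;Parent=t1\n"
            "chr1\tx\tCDS\t301\t400\t.\t+\t0\tID=c2;Parent=t1\n")
        g = it.load_genome(tmp_path / "g.fa", tmp_path / "g.gff3")
        (gene,) = g.genes
        assert gene.transcripts[0].cds_segments == [(100, 200), (300, 400)]

    def test_missing_contig_is_hard_error(self, tmp_path):
        (tmp_path / "g.fa").write_text(">chrX\n" + "ACGT" * 50 + "\n")
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "chr2\tx\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr2\tx\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr2\tx\tCDS\t1\t99\t.\t+\t0\tID=c1;Parent=t1\n")
        with pytest.raises(it.AnnotationError, match="chr2"):
            it.load_genome(tmp_path / "g.fa", tmp_path / "g.gff3")

    def test_orphan_cds_is_hard_error(self, tmp_path):
        (tmp_path / "g.fa").write_text(">chr1\n" + "ACGT" * 50 + "\n")
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tx\tCDS\t1\t99\t.\t+\t0\tID=c1;Parent=t1\n"
            "chr1\tx\tCDS\t120\t150\t.\t+\t0\tID=c2;Parent=ghost\n")
        with pytest.raises(it.AnnotationError, match="parent"):
            it.load_genome(tmp_path / "g.fa", tmp_path / "g.gff3")

    def test_round_trip_preserves_models_byte_exactly(self, fixture_dir, tmp_path):
        g1 = it.load_genome(fixture_dir / "genome.fa", fixture_dir / "genome.gff3")
        it.write_genome(g1, tmp_path / "r.fa", tmp_path / "r.gff3")
        assert (tmp_path / "r.fa").read_bytes() == (fixture_dir / "genome.fa").read_bytes()
        assert (tmp_path / "r.gff3").read_bytes() == (fixture_dir / "genome.gff3").read_bytes()
        g2 = it.load_genome(tmp_path / "r.fa", tmp_path / "r.gff3")
        assert [(x.gene_id, x.strand,
                 [(t.transcript_id, t.cds_segments) for t in x.transcripts])
                for x in g1.genes] == \
               [(x.gene_id, x.strand,
                 [(t.transcript_id, t.cds_segments) for t in x.transcripts])
                for x in g2.genes]

    def test_intron_table_columns_are_one_based(self, genome):
        df = it.intron_table(genome)
        row = df[(df.gene_id == "gGold150")].iloc[0]
        gold = genome.gene("gGold150")
        (i,) = shared_coding_introns(gold)[:1]
        assert row["start"] == i.start + 1 and row["end"] == i.end

    def test_strand_disagreement_rejected(self):
        a = tx([(0, 99)], strand="+", tid="a")
        with pytest.raises(it.MalformedModelError):
            it.GeneModel("g", "c", "-", "protein_coding", [a])


def test_minus_strand_spliced_cds_translates(genome):
    """The minus-strand fixture gene translates start-to-stop cleanly."""
    gene = genome.gene("gMinus")
    cds = gene.transcripts[0].spliced_cds(genome.contigs[gene.contig])
    aa = translate(cds)
    assert cds.startswith("ATG")
    assert aa.endswith("*") and "*" not in aa[:-1]
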