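"""Edited-allele simulation: HDR length accounting, strand symmetry, FLP
excision identity, RMCE truth table, T2A fusion frame logic, validation PCR."""

import pytest

import introntrap as it
from introntrap.allele_sim import ATTP_R_PRIMER, MimicInsertion
from introntrap.fixtures import FRT_SEQ
from introntrap.genome_model import coding_introns
from introntrap.seqtools import revcomp, translate


@pytest.fixture(scope="module")
def minus_bundle(genome, cassettes):
    return it.run_design(genome, "gMinus", cassettes["pM37-like-p2"])


class TestInsertionAllele:
    def test_length_accounting(self, gold_bundle, genome):
        a = gold_bundle.allele
        window = a.window_end - a.window_start
        assert len(a.sequence) == window - a.gap_length + len(a.cassette.sequence)
        assert a.gap_length < 40

    def test_flanks_match_reference(self, gold_bundle, genome):
        a = gold_bundle.allele
        wt = genome.fetch(a.contig, a.window_start, a.window_end)
        gap_s, gap_e = a.deleted_gap
        left = gap_s - a.window_start
        assert a.sequence[:left] == wt[:left]
        assert a.sequence.endswith(wt[gap_e - a.window_start:])

    def test_minus_strand_cassette_reverse_complemented(self, minus_bundle,
                                                        cassettes):
        a = minus_bundle.allele
        cass = cassettes["pM37-like-p2"]
        insert = a.sequence[a.insert_offset:a.insert_offset + len(cass.sequence)]
        assert insert == revcomp(cass.sequence)
        sa = next(f for f in a.features if f.label == "SA")
        assert sa.strand == "-"

    def test_mirrored_genome_gives_mirrored_allele(self, genome, gold_bundle):
        """Re-running the insertion on the reverse-complemented contig with
        mirrored coordinates reproduces the mirrored allele byte-exactly."""
        import dataclasses
        b = gold_bundle
        d = b.design
        seq = genome.contigs["chrSyn"]
        n = len(seq)
        mirror = it.AnnotatedGenome(contigs={"chrSyn": revcomp(seq)}, genes=[])

        def flip_arm(arm, side):
            return it.HomologyArm(side=side, contig="chrSyn",
                                  start=n - arm.end, end=n - arm.start,
                                  sequence=revcomp(arm.sequence))

        m_intron = dataclasses.replace(d.intron, start=n - d.intron.end,
                                       end=n - d.intron.start, strand="-")
        m_design = dataclasses.replace(
            d, cut_position=n - d.cut_position, gene_strand="-",
            intron=m_intron, arm_left=flip_arm(d.arm_right, "left"),
            arm_right=flip_arm(d.arm_left, "right"))
        m_allele = it.predict_insertion_allele(mirror, m_design)
        assert m_allele.sequence == revcomp(b.allele.sequence)

    def test_phase_mismatch_recorded_as_warning(self, genome, cassettes,
                                                gold_bundle):
        d = gold_bundle.design
        wrong = cassettes["pM37-like-p0"]   # intron phase is 1
        import dataclasses
        allele = it.predict_insertion_allele(
            genome, dataclasses.replace(d, cassette=wrong), cassette=wrong)
        assert allele.phase_warning is not None


class TestExcision:
    def test_scar_is_attp_frt_attp(self, gold_bundle, genome, cassettes):
        b = gold_bundle
        exc = it.simulate_flp_excision(b.allele)
        wt = genome.fetch(b.allele.contig, b.allele.window_start,
                          b.allele.window_end)
        gap_s = b.allele.deleted_gap[0] - b.allele.window_start
        gap_e = b.allele.deleted_gap[1] - b.allele.window_start
        cass = cassettes["pM37-like-p1"]
        attp_len = cass.feature("attP").length
        scar_len = 2 * attp_len + len(FRT_SEQ)
        # excised allele differs from wild type only by gap deletion + scar
        assert len(exc.sequence) == len(wt) - b.allele.gap_length + scar_len
        assert exc.sequence[:gap_s] == wt[:gap_s]
        assert exc.sequence[gap_s + scar_len:] == wt[gap_e:]
        scar = exc.sequence[gap_s:gap_s + scar_len]
        assert scar == (cass.sequence[:attp_len] + FRT_SEQ
                        + cass.sequence[-attp_len:])

    def test_frt_count_two_to_one(self, gold_bundle):
        exc = it.simulate_flp_excision(gold_bundle.allele)
        assert sum(f.label == "FRT" for f in gold_bundle.allele.features) == 2
        assert sum(f.label == "FRT" for f in exc.features) == 1

    def test_stop_cassette_without_frts_not_excisable(self, genome, cassettes,
                                                      gold_bundle):
        import dataclasses
        p36 = cassettes["pM36-like"]
        d = dataclasses.replace(gold_bundle.design, cassette=p36)
        allele = it.predict_insertion_allele(genome, d, cassette=p36)
        with pytest.raises(it.DesignError, match="not excisable"):
            it.simulate_flp_excision(allele)

    def test_inverted_frts_rejected(self, gold_bundle):
        import dataclasses
        a = gold_bundle.allele
        flipped = []
        seen = 0
        for f in a.features:
            if f.label == "FRT" and seen == 0:
                f = it.Feature("FRT", f.start, f.end, "-")
                seen = 1
            flipped.append(f)
        bad = dataclasses.replace(a, features=flipped)
        with pytest.raises(it.DesignError, match="invert"):
            it.simulate_flp_excision(bad)


class TestMimicTrojanChoice:
    def test_truth_table_all_twelve_configurations(self, genome):
        """2 MiMIC orientations x 2 gene strands x 3 phases: the splice
        acceptor must end up sense to the gene and the required phase is
        the intron phase at the insertion point."""
        cases = {"+": "gGold150", "-": "gMinus"}
        for strand, gid in cases.items():
            gene = genome.gene(gid)
            intron = coding_introns(gene.transcripts[0])[0]
            pos = (intron.start + intron.end) // 2
            for mimic_orient in "+-":
                orientation, phase = it.mimic_trojan_choice(
                    MimicInsertion("chrSyn", pos, mimic_orient), gene)
                assert phase == intron.phase
                assert orientation == ("keep" if mimic_orient == strand
                                       else "flip")

    def test_insertion_outside_coding_introns_errors(self, genome):
        gene = genome.gene("gGold150")
        with pytest.raises(it.DesignError, match="no coding intron"):
            it.mimic_trojan_choice(MimicInsertion("chrSyn", 5, "+"), gene)


class TestFusion:
    def test_in_frame_exactly_once_over_phases_and_orientations(
            self, genome, cassettes, gold_bundle):
        """3 cassette phases x 2 orientations: in-frame exactly at
        (matching phase, sense)."""
        import dataclasses
        d = gold_bundle.design
        gene = genome.gene("gGold150")
        in_frame = []
        for p in (0, 1, 2):
            for orient in ("sense", "antisense"):
                cass = cassettes[f"pM37-like-p{p}"]
                allele = it.predict_insertion_allele(
                    genome, dataclasses.replace(d, cassette=cass),
                    cassette=cass, orientation=orient)
                fusion = it.predict_fusion(allele, gene.transcripts[0],
                                           genome=genome)
                if fusion.in_frame:
                    in_frame.append((p, orient))
                # direct translation oracle for the premature-stop verdict
                if orient == "sense":
                    sa = cass.feature("SA")
                    polya = cass.feature("polyA")
                    t2a = cass.feature("T2A")
                    upstream_len = d.intron.upstream_cds_len
                    contig = genome.contigs["chrSyn"]
                    upstream = "".join(
                        contig[s:e] for s, e
                        in gene.transcripts[0].cds_segments[:1])
                    spliced = upstream + cass.sequence[sa.end:polya.start]
                    aa = translate(spliced)
                    limit = (len(upstream) + (t2a.end - sa.end) - 3) // 3
                    stop = aa.find("*")
                    assert fusion.premature_stop == (0 <= stop < limit), p
        assert in_frame == [(1, "sense")]

    def test_matched_phase_peptide_prefix_is_native(self, gold_bundle, genome):
        gene = genome.gene("gGold150")
        fusion = gold_bundle.fusion
        native = translate(gene.transcripts[0].spliced_cds(
            genome.contigs["chrSyn"]))
        k = gold_bundle.design.intron.upstream_cds_len // 3
        assert fusion.in_frame and not fusion.premature_stop
        assert fusion.upstream_peptide.startswith(native[:k])
        assert fusion.upstream_peptide.endswith("NPG")
        assert fusion.downstream_product_start.startswith("GAL4")

    def test_minus_strand_gene_fuses_in_frame(self, minus_bundle):
        assert minus_bundle.fusion.in_frame
        assert not minus_bundle.fusion.premature_stop

    def test_antisense_cassette_gives_no_fusion(self, genome, cassettes,
                                                gold_bundle):
        import dataclasses
        cass = cassettes["pM37-like-p1"]
        allele = it.predict_insertion_allele(
            genome, gold_bundle.design, orientation="antisense")
        gene = genome.gene("gGold150")
        fusion = it.predict_fusion(allele, gene.transcripts[0], genome=genome)
        assert not fusion.in_frame
        assert fusion.downstream_product_start == "none"


class TestValidationPcr:
    def test_attp_r_constant(self):
        assert ATTP_R_PRIMER == "CCCCAGTTGGGGC"

    def test_two_reactions_with_exact_amplicon_lengths(self, gold_bundle):
        """Expected sizes equal a naive in-silico PCR of the edited allele."""
        plan = gold_bundle.validation
        allele = gold_bundle.allele
        assert len(plan.reactions) == 2
        for r in plan.reactions:
            products = it.insilico_pcr(allele.sequence, r.gene_primer,
                                       ATTP_R_PRIMER)
            assert [e - s for s, e in products] == [r.expected_edited_bp]

    def test_wild_type_yields_no_product(self, gold_bundle, genome):
        a = gold_bundle.allele
        wt = genome.fetch(a.contig, a.window_start, a.window_end)
        for r in gold_bundle.validation.reactions:
            assert it.insilico_pcr(wt, r.gene_primer, ATTP_R_PRIMER) == []

    def test_minus_strand_validation_also_exact(self, minus_bundle):
        for r in minus_bundle.validation.reactions:
            products = it.insilico_pcr(minus_bundle.allele.sequence,
                                       r.gene_primer, ATTP_R_PRIMER)
            assert [e - s for s, e in products] == [r.expected_edited_bp]

    def test_attp_r_in_wildtype_window_is_hard_error(self, gold_bundle, genome):
        a = gold_bundle.allele
        doctored = dict(genome.contigs)
        s = a.window_start + 10
        doctored["chrSyn"] = (doctored["chrSyn"][:s] + ATTP_R_PRIMER
                              + doctored["chrSyn"][s + len(ATTP_R_PRIMER):])
        bad = it.AnnotatedGenome(contigs=doctored, genes=[])
        with pytest.raises(it.DesignError, match="ambiguous"):
            it.plan_validation_pcr(a, bad)
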