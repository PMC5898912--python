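"""Edited-allele simulation: HDR insertion, FLP excision, RMCE orientation
logic, truncated T2A-fusion prediction, and validation-PCR planning.

The edited allele is the genomic window around the insertion with the
inter-arm gap replaced by the cassette (oriented so the splice acceptor is
sense to the gene).  Transcription is modelled as terminating exactly at
the cassette polyA; exon skipping around the splice acceptor and polyA
read-through are deliberately not simulated and are flagged as caveats on
the prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .construct_assembly import CassetteSpec, DonorDesign, Feature
from .errors import DesignError, MalformedModelError
from .genome_model import (AnnotatedGenome, CodingIntron, GeneModel,
                           TranscriptModel, coding_introns)
from .seqtools import revcomp, translate, wallace_tm

log = logging.getLogger(__name__)

#: Constant cassette-side validation primer binding the attP sites.
ATTP_R_PRIMER = "CCCCAGTTGGGGC"

SENSE, ANTISENSE = "sense", "antisense"

CAVEATS = ("polyA read-through (masking) not modelled",
           "splice-acceptor exon skipping not modelled")


@dataclass
class EditedAllele:
    """Post-HDR locus window with its feature map (local 0-based coordinates)."""

    contig: str
    window_start: int                 # genomic coordinate of local position 0
    window_end: int
    sequence: str
    features: list[Feature]
    deleted_gap: tuple[int, int]      # genomic span removed by HDR
    cassette_orientation: str         # sense | antisense, relative to the gene
    cassette: CassetteSpec
    gene_strand: str
    intron: CodingIntron
    insert_offset: int                # local coordinate where the cassette begins
    phase_warning: str | None = None

    @property
    def gap_length(self) -> int:
        return self.deleted_gap[1] - self.deleted_gap[0]

    def cassette_feature(self, label: str, which: int = 0) -> Feature:
        hits = sorted((f for f in self.features if f.label == label),
                      key=lambda f: f.start)
        if len(hits) <= which:
            raise MalformedModelError(f"allele lacks feature {label!r} #{which}")
        return hits[which]


def predict_insertion_allele(genome: AnnotatedGenome, design: DonorDesign,
                             cassette: CassetteSpec | None = None, *,
                             flank: int = 500,
                             orientation: str = SENSE) -> EditedAllele:
    """HDR outcome: 5' context + left arm + oriented cassette + right arm + 3' context.

    The bases between the arms (< 40 bp) are deleted.  ``orientation`` is
    relative to the gene and defaults to sense (the designed outcome);
    antisense is accepted for what-if analysis.  A phase mismatch between
    cassette and intron is recorded as a warning, not an error.
    """
    cassette = cassette or design.cassette
    arm_l, arm_r = design.arm_left, design.arm_right
    if arm_r.start < arm_l.end:
        raise MalformedModelError("arms overlap")
    contig_seq = genome.contigs[design.contig]
    ws = max(0, arm_l.start - flank)
    we = min(len(contig_seq), arm_r.end + flank)

    sense_on_contig = (design.gene_strand == "+") == (orientation == SENSE)
    cass_seq = cassette.sequence if sense_on_contig else revcomp(cassette.sequence)
    if sense_on_contig:
        cass_feats = list(cassette.features)
    else:
        n = len(cassette.sequence)
        cass_feats = [Feature(f.label, n - f.end, n - f.start,
                              "-" if f.strand == "+" else "+")
                      for f in cassette.features]

    insert_offset = arm_l.end - ws
    seq = contig_seq[ws:arm_l.end] + cass_seq + contig_seq[arm_r.start:we]
    feats = [Feature("arm_left", arm_l.start - ws, arm_l.end - ws, "+")]
    feats += [f.shifted(insert_offset) for f in cass_feats]
    right_off = insert_offset + len(cass_seq)
    feats.append(Feature("arm_right", right_off, right_off + arm_r.length, "+"))

    warning = None
    if cassette.phase is not None and cassette.phase != design.intron.phase:
        warning = (f"cassette phase {cassette.phase} does not match intron phase "
                   f"{design.intron.phase}: fusion will be out of frame")
        log.warning("%s", warning)
    allele = EditedAllele(
        contig=design.contig, window_start=ws, window_end=we, sequence=seq,
        features=feats, deleted_gap=(arm_l.end, arm_r.start),
        cassette_orientation=orientation, cassette=cassette,
        gene_strand=design.gene_strand, intron=design.intron,
        insert_offset=insert_offset, phase_warning=warning)
    expect = (we - ws) - allele.gap_length + len(cass_seq)
    assert len(seq) == expect, "length accounting violated"
    return allele


def simulate_flp_excision(allele: EditedAllele) -> EditedAllele:
    """FLP/FRT excision: delete between the two direct-repeat FRTs, keep one.

    For the standard trap topology the remaining scar between the arms is
    attP + FRT + attP.  Alleles without two FRTs (stop-cassette derivatives
    that lack them) are not excisable; inverted-repeat FRTs would invert
    rather than delete and are rejected.
    """
    frts = sorted((f for f in allele.features if f.label == "FRT"),
                  key=lambda f: f.start)
    if len(frts) < 2:
        raise DesignError("not excisable: fewer than two FRT sites in the allele")
    a, b = frts[0], frts[-1]
    if a.strand != b.strand:
        raise DesignError("FRT sites are inverted repeats: FLP would invert, "
                          "not excise; refusing to simulate")
    cut_from, cut_to = a.start, b.start   # keep one FRT (the downstream copy)
    removed = cut_to - cut_from
    seq = allele.sequence[:cut_from] + allele.sequence[cut_to:]
    feats = []
    for f in allele.features:
        if f.end <= cut_from:
            feats.append(f)
        elif f.start >= cut_to:
            feats.append(f.shifted(-removed))
        # features inside the excised block are gone; the retained FRT is
        # the downstream copy, shifted onto the upstream position
    return replace(allele, sequence=seq, features=feats,
                   insert_offset=min(allele.insert_offset, cut_from))


@dataclass(frozen=True)
class MimicInsertion:
    """A pre-existing intronic docking-site insertion (MiMIC-style)."""
    contig: str
    position: int
    orientation: str   # + | - relative to the contig


def mimic_trojan_choice(insertion: MimicInsertion, gene: GeneModel
                        ) -> tuple[str, int]:
    """RMCE planning for converting an intronic docking site to a T2A-GAL4 trap.

    Returns (rmce_orientation, required_phase): "keep" when the docking
    site's orientation already places the splice acceptor sense to the
    gene, else "flip"; the required cassette phase is the phase of the
    coding intron containing the insertion.
    """
    if insertion.contig != gene.contig:
        raise DesignError("insertion and gene are on different contigs")
    for t in gene.transcripts:
        for c in coding_introns(t):
            if c.start < insertion.position < c.end:
                orientation = "keep" if insertion.orientation == gene.strand else "flip"
                return orientation, c.phase
    raise DesignError(
        f"insertion at {insertion.contig}:{insertion.position} lies in no coding "
        f"intron of {gene.gene_id}")


@dataclass
class FusionPrediction:
    truncated_transcript: str
    upstream_peptide: str
    downstream_product_start: str     # "GAL4 (with N-terminal proline)" | "none"
    in_frame: bool
    premature_stop: bool
    caveats: tuple[str, ...] = CAVEATS


def predict_fusion(allele: EditedAllele, transcript: TranscriptModel,
                   cassette: CassetteSpec | None = None,
                   genome: AnnotatedGenome | None = None) -> FusionPrediction:
    """Predict the truncated transcript and T2A fusion product of the trap.

    The truncated transcript is the native exons 5' of the insertion
    spliced onto the cassette's splice-acceptor exon, ending at the
    cassette polyA.  The upstream peptide runs from the native start codon
    to the T2A ribosomal-skip site (released before the final proline);
    translation reinitiates to yield GAL4 with an added N-terminal proline.
    In frame requires sense orientation and cassette phase equal to intron
    phase; a frameshift typically hits a premature stop in the linker.
    """
    cassette = cassette or allele.cassette
    if allele.cassette_orientation == ANTISENSE:
        return FusionPrediction(truncated_transcript="", upstream_peptide="",
                                downstream_product_start="none", in_frame=False,
                                premature_stop=False)
    introns = coding_introns(transcript)
    idx = next((k for k, c in enumerate(introns) if c.span == allele.intron.span), None)
    if idx is None:
        return FusionPrediction(truncated_transcript="", upstream_peptide="",
                                downstream_product_start="none", in_frame=False,
                                premature_stop=False)

    # native upstream exons, spliced in transcript orientation (exons beyond
    # the edited window are unedited and read from the reference genome)
    segs = [_genomic_segment(allele, s, e, genome)
            for s, e in transcript.cds_segments[:idx + 1]]
    if transcript.strand == "-":
        segs = [revcomp(s) for s in segs]
    upstream = "".join(segs)
    if not upstream.startswith("ATG"):
        raise MalformedModelError(
            f"transcript {transcript.transcript_id}: upstream CDS does not begin "
            "with a start codon")

    sa = cassette.feature("SA")
    polya = cassette.feature("polyA")
    exon = cassette.sequence[sa.end:polya.start]
    t2a = cassette.feature("T2A")
    t2a_end_in_exon = t2a.end - sa.end

    truncated = upstream + exon
    aa = translate(truncated)
    # skip releases the upstream peptide before the final proline codon of T2A
    t2a_end_nt = len(upstream) + t2a_end_in_exon
    n_aa_to_skip = (t2a_end_nt - 3) // 3
    stop_at = aa.find("*")
    premature = 0 <= stop_at < n_aa_to_skip
    in_frame = (cassette.phase is not None
                and cassette.phase == allele.intron.phase
                and allele.cassette_orientation == SENSE)
    peptide = aa[:n_aa_to_skip] if not premature else aa[:stop_at]
    product = ("GAL4 (with N-terminal proline)"
               if in_frame and not premature else "none")
    return FusionPrediction(truncated_transcript=truncated, upstream_peptide=peptide,
                            downstream_product_start=product, in_frame=in_frame,
                            premature_stop=premature)


def _genomic_segment(allele: EditedAllele, start: int, end: int,
                     genome: AnnotatedGenome | None = None) -> str:
    """Sequence of a genomic interval read through the edited-allele window."""
    ws = allele.window_start
    if start < ws or end > allele.window_end:
        if genome is not None and (end <= ws or start >= allele.window_end):
            return genome.fetch(allele.contig, start, end)
        raise MalformedModelError(
            f"CDS segment [{start},{end}) outside the edited window "
            f"[{ws},{allele.window_end}); pass the reference genome for "
            "out-of-window exons")
    gap_s, gap_e = allele.deleted_gap
    if end <= gap_s:
        return allele.sequence[start - ws:end - ws]
    if start >= gap_e:
        shift = len(allele.sequence) - (allele.window_end - ws)
        return allele.sequence[start - ws + shift:end - ws + shift]
    raise MalformedModelError(
        f"CDS segment [{start},{end}) overlaps the deleted gap/cassette")


# ---------------------------------------------------------------------------
# validation PCR


@dataclass
class ValidationReaction:
    name: str
    gene_primer: str
    gene_primer_span: tuple[int, int]   # local coordinates on the edited allele
    cassette_primer: str
    expected_edited_bp: int
    expected_wildtype: str = "no product"


@dataclass
class ValidationPlan:
    reactions: list[ValidationReaction]
    attp_r: str = ATTP_R_PRIMER


def insilico_pcr(template: str, primer_a: str, primer_b: str,
                 max_len: int | None = None) -> list[tuple[int, int]]:
    """Naive exact-match PCR: all (start, end) product spans for the pair.

    A product needs one primer annealed forward (primer equals the top
    strand) and the other reverse (reverse complement on the top strand),
    with converging 3' ends.
    """
    def sites(p):
        fwd = [i for i in range(len(template) - len(p) + 1)
               if template[i:i + len(p)] == p]
        rc = revcomp(p)
        rev = [i for i in range(len(template) - len(p) + 1)
               if template[i:i + len(rc)] == rc]
        return fwd, rev

    fa, ra = sites(primer_a)
    fb, rb = sites(primer_b)
    out = []
    for fwd_sites, rev_sites, plen_f, plen_r in ((fa, rb, len(primer_a), len(primer_b)),
                                                 (fb, ra, len(primer_b), len(primer_a))):
        for s in fwd_sites:
            for r in rev_sites:
                end = r + plen_r
                if s + plen_f <= r and (max_len is None or end - s <= max_len):
                    out.append((s, end))
    return sorted(set(out))


def _pick_outward_primer(seq: str, boundary: int, side: str, *, min_dist: int,
                         max_dist: int, min_tm: float, min_len: int,
                         max_len: int) -> tuple[str, tuple[int, int]]:
    """Deterministic gene-specific primer choice outside an arm boundary.

    side="left": forward primer with its 3' end between max_dist and
    min_dist bp left of the boundary; side="right": reverse primer
    mirrored on the other side.  Nearest feasible position first.
    """
    for d in range(min_dist, max_dist + 1):
        if side == "left":
            three_prime = boundary - d
            for k in range(min_len, max_len + 1):
                s = three_prime - k
                if s < 0:
                    break
                cand = seq[s:three_prime]
                if wallace_tm(cand) >= min_tm:
                    return cand, (s, three_prime)
        else:
            three_prime = boundary + d
            for k in range(min_len, max_len + 1):
                e = three_prime + k
                if e > len(seq):
                    break
                cand = revcomp(seq[three_prime:e])
                if wallace_tm(cand) >= min_tm:
                    return cand, (three_prime, e)
    raise DesignError(
        f"no {side}-side gene-specific primer with Tm >= {min_tm} within "
        f"{min_dist}-{max_dist} bp of the arm boundary")


def plan_validation_pcr(allele: EditedAllele, genome: AnnotatedGenome, *,
                        primer_min_dist: int = 100, primer_max_dist: int = 400,
                        min_tm: float = 58.0, primer_min_len: int = 18,
                        primer_max_len: int = 25) -> ValidationPlan:
    """Two insertion-validation reactions pairing gene-specific primers with the
    constant attP-R cassette primer.

    Left reaction: forward primer upstream of the left arm x attP-R reading
    outward from the 5' attP.  Right reaction: reverse primer downstream of
    the right arm x attP-R from the 3' attP.  Expected amplicon sizes are
    computed on the edited allele; the wild-type locus must yield nothing
    (attP-R has no genomic site).
    """
    wt_window = genome.fetch(allele.contig, allele.window_start, allele.window_end)
    if ATTP_R_PRIMER in wt_window or revcomp(ATTP_R_PRIMER) in wt_window:
        raise DesignError(
            "attP-R primer site occurs in the wild-type locus window: "
            "validation would be ambiguous")
    seq = allele.sequence
    arm_l = allele.cassette_feature("arm_left")
    arm_r = allele.cassette_feature("arm_right")

    # attP-R binding sites, located inside the two attP features
    attp_feats = sorted((f for f in allele.features if f.label == "attP"),
                        key=lambda f: f.start)
    if len(attp_feats) < 2:
        raise MalformedModelError("edited allele lacks two attP features")
    left_attp, right_attp = attp_feats[0], attp_feats[-1]

    def binding_site(feat: Feature, leftward: bool) -> tuple[int, int]:
        block = seq[feat.start:feat.end]
        target = revcomp(ATTP_R_PRIMER) if leftward else ATTP_R_PRIMER
        off = block.find(target)
        if off < 0:
            raise MalformedModelError(
                f"attP feature at {feat.start} lacks an attP-R binding site "
                f"{'(leftward)' if leftward else '(rightward)'}")
        return feat.start + off, feat.start + off + len(ATTP_R_PRIMER)

    lb = binding_site(left_attp, leftward=True)
    rb = binding_site(right_attp, leftward=False)

    fwd, fwd_span = _pick_outward_primer(
        seq, arm_l.start, "left", min_dist=primer_min_dist, max_dist=primer_max_dist,
        min_tm=min_tm, min_len=primer_min_len, max_len=primer_max_len)
    rev, rev_span = _pick_outward_primer(
        seq, arm_r.end, "right", min_dist=primer_min_dist, max_dist=primer_max_dist,
        min_tm=min_tm, min_len=primer_min_len, max_len=primer_max_len)

    reactions = [
        ValidationReaction(
            name="left-junction", gene_primer=fwd, gene_primer_span=fwd_span,
            cassette_primer=ATTP_R_PRIMER, expected_edited_bp=lb[1] - fwd_span[0]),
        ValidationReaction(
            name="right-junction", gene_primer=rev, gene_primer_span=rev_span,
            cassette_primer=ATTP_R_PRIMER, expected_edited_bp=rev_span[1] - rb[0]),
    ]
    return ValidationPlan(reactions=reactions)
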