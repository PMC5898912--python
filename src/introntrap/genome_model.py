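"""Genome + annotation model and coding-intron arithmetic.

A *coding intron* is an intron flanked by CDS on both sides within one
transcript; its *phase* is the length of CDS sequence 5' of the intron
modulo 3.  Splice-acceptor gene traps only restore the reading frame when
the cassette phase matches the intron phase, so phases are first-class
here.

Internal convention: all coordinates are 0-based half-open on the contig;
GFF3 input/output uses the standard 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd

from .errors import AnnotationError, MalformedModelError
from .seqtools import IUPAC_LETTERS, chunked_fasta, revcomp

FLYBASE_DIALECT = "flybase"


@dataclass(frozen=True)
class CodingIntron:
    """An intron flanked by CDS segments on both sides in one transcript."""

    contig: str
    start: int                  # genomic, 0-based
    end: int                    # genomic, half-open
    strand: str
    transcript_order_index: int
    upstream_cds_len: int
    support: int = 1            # transcripts agreeing on span+phase (set by shared_coding_introns)

    def __post_init__(self):
        if self.end <= self.start:
            raise MalformedModelError(
                f"intron span [{self.start},{self.end}) on {self.contig} has non-positive length")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def phase(self) -> int:
        return self.upstream_cds_len % 3

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TranscriptModel:
    """CDS structure of one transcript; segments are kept in 5'->3' transcript order."""

    transcript_id: str
    contig: str
    strand: str
    cds_segments: list[tuple[int, int]]
    complete: bool = False

    def __post_init__(self):
        segs = self.cds_segments
        for s, e in segs:
            if e <= s:
                raise MalformedModelError(
                    f"{self.transcript_id}: empty CDS segment [{s},{e})")
        ordered = sorted(segs)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise MalformedModelError(
                    f"{self.transcript_id}: overlapping CDS segments [{s1},{e1}) and [{s2},{e2})")
        expect = ordered if self.strand == "+" else ordered[::-1]
        if segs != expect:
            raise MalformedModelError(
                f"{self.transcript_id}: CDS segments not in transcript (5'->3') order "
                f"for strand {self.strand}")
        if self.complete and self.cds_length % 3 != 0:
            raise MalformedModelError(
                f"{self.transcript_id}: complete CDS length {self.cds_length} not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def genomic_span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.cds_segments),
                max(e for _, e in self.cds_segments))

    def spliced_cds(self, contig_seq: str) -> str:
        """Spliced coding sequence in translation orientation."""
        parts = [contig_seq[s:e] for s, e in sorted(self.cds_segments)]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    biotype: str
    transcripts: list[TranscriptModel]
    n_noncoding_transcripts: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise MalformedModelError(f"{self.gene_id}: bad strand {self.strand!r}")
        for t in self.transcripts:
            if t.contig != self.contig or t.strand != self.strand:
                raise MalformedModelError(
                    f"{self.gene_id}: transcript {t.transcript_id} disagrees on contig/strand")


@dataclass
class AnnotatedGenome:
    """Contig sequences plus gene models; the in-memory hub of the toolkit."""

    contigs: dict[str, str]
    genes: list[GeneModel]
    annotation_dialect: str = FLYBASE_DIALECT
    _index: dict[str, GeneModel] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.contig not in self.contigs:
                raise AnnotationError(
                    f"gene {g.gene_id} references contig {g.contig!r} absent from the sequence set")
            clen = len(self.contigs[g.contig])
            for t in g.transcripts:
                for s, e in t.cds_segments:
                    if s < 0 or e > clen:
                        raise AnnotationError(
                            f"{t.transcript_id}: CDS [{s},{e}) outside contig "
                            f"{g.contig} (length {clen})")
        for name, seq in self.contigs.items():
            bad = set(seq) - IUPAC_LETTERS
            if bad:
                raise AnnotationError(
                    f"contig {name} contains non-IUPAC letters: {sorted(bad)}")
        self._index = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._index[gene_id]
        except KeyError:
            raise AnnotationError(f"unknown gene id {gene_id!r}") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if start < 0 or end > len(seq):
            raise AnnotationError(
                f"window [{start},{end}) outside contig {contig} (length {len(seq)})")
        return seq[start:end]


# ---------------------------------------------------------------------------
# loading


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_genome(fasta_path, gff3_path, biotype_filter: str | None = "protein_coding",
                dialect: str = FLYBASE_DIALECT) -> AnnotatedGenome:
    """Load FASTA + GFF3 (FlyBase-style Parent attributes) into an AnnotatedGenome.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Only transcripts that carry CDS features
    are modelled; CDS-less transcripts of a gene are counted in
    ``n_noncoding_transcripts``.  With the default biotype filter, genes
    without any CDS-bearing transcript are dropped.
    """
    contigs = _read_fasta(fasta_path)
    if not contigs:
        raise AnnotationError(f"no sequences in {fasta_path}")

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique",
        keep_order=True, sort_attribute_values=True)

    # referential integrity: every CDS needs a resolvable parent transcript
    transcript_ids = {f.id for f in db.all_features()
                      if f.featuretype in ("mRNA", "transcript")}
    genes = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        if gf.seqid not in contigs:
            raise AnnotationError(
                f"annotation references contig {gf.seqid!r} absent from FASTA")
        transcripts = []
        n_noncoding = 0
        strand = gf.strand
        for tf in db.children(gf, level=1):
            if tf.featuretype not in ("mRNA", "transcript"):
                continue
            if tf.strand != gf.strand or tf.seqid != gf.seqid:
                raise MalformedModelError(
                    f"gene {gf.id}: transcript {tf.id} on different contig/strand")
            cds = sorted(db.children(tf, featuretype="CDS"),
                         key=lambda f: f.start)
            if not cds:
                n_noncoding += 1
                continue
            segs = [(c.start - 1, c.end) for c in cds]   # 1-based incl -> 0-based half-open
            if gf.strand == "-":
                segs = segs[::-1]
            transcripts.append(TranscriptModel(
                transcript_id=tf.id, contig=gf.seqid, strand=gf.strand,
                cds_segments=segs))
        # orphan-CDS check is global, done below; skip CDS-less genes under the filter
        biotype = (gf.attributes.get("biotype") or gf.attributes.get("gene_biotype")
                   or ["protein_coding" if transcripts else "non_coding"])[0]
        if biotype_filter and (biotype != biotype_filter or not transcripts):
            continue
        genes.append(GeneModel(
            gene_id=gf.id, contig=gf.seqid, strand=strand, biotype=biotype,
            transcripts=transcripts, n_noncoding_transcripts=n_noncoding))

    for cf in db.features_of_type("CDS"):
        parents = cf.attributes.get("Parent", [])
        if not parents or not any(p in transcript_ids for p in parents):
            raise AnnotationError(
                f"CDS feature at {cf.seqid}:{cf.start}-{cf.end} has no parent transcript")

    return AnnotatedGenome(contigs=contigs, genes=genes, annotation_dialect=dialect)


# ---------------------------------------------------------------------------
# coding introns


def coding_introns(t: TranscriptModel) -> list[CodingIntron]:
    """All CDS-flanked introns of one transcript, 5'->3' in transcript order.

    ``upstream_cds_len`` accumulates the CDS length 5' of each intron, so
    phase telescopes: phase(k+1) = (phase(k) + exon_between) mod 3.
    """
    if not t.cds_segments:
        raise MalformedModelError(f"{t.transcript_id}: no CDS segments")
    introns = []
    upstream = 0
    for idx, (a, b) in enumerate(zip(t.cds_segments, t.cds_segments[1:])):
        upstream += a[1] - a[0]
        if t.strand == "+":
            span = (a[1], b[0])
        else:
            span = (b[1], a[0])
        introns.append(CodingIntron(
            contig=t.contig, start=span[0], end=span[1], strand=t.strand,
            transcript_order_index=idx, upstream_cds_len=upstream))
    return introns


def intron_phase(t: TranscriptModel, i: CodingIntron) -> int:
    """Phase (0/1/2) of intron *i* within transcript *t*; errors if absent."""
    for c in coding_introns(t):
        if c.span == i.span:
            return c.phase
    raise MalformedModelError(
        f"intron [{i.start},{i.end}) not found in transcript {t.transcript_id}")


def shared_coding_introns(g: GeneModel, mode: str = "exact") -> list[CodingIntron]:
    """Coding introns present in *every* transcript of the gene.

    mode="exact" (default): identical genomic span in every transcript AND
    identical phase — a splice-acceptor trap behaves the same in all
    isoforms only when both boundaries and frame agree.
    mode="overlap": positional-overlap sensitivity alternative — an intron
    counts if every transcript has a coding intron overlapping it (phase
    still required to agree among the overlapping introns).
    """
    if not g.transcripts:
        raise MalformedModelError(f"{g.gene_id}: no coding transcripts")
    per_tx = [coding_introns(t) for t in g.transcripts]
    result = []
    for c in per_tx[0]:
        if mode == "exact":
            ok = all(any(o.span == c.span and o.phase == c.phase for o in others)
                     for others in per_tx[1:])
        elif mode == "overlap":
            ok = all(any(o.start < c.end and c.start < o.end and o.phase == c.phase
                         for o in others)
                     for others in per_tx[1:])
        else:
            raise ValueError(f"unknown shared-intron mode {mode!r}")
        if ok:
            result.append(replace(c, support=len(g.transcripts)))
    return result


# ---------------------------------------------------------------------------
# output


def write_genome(genome: AnnotatedGenome, fasta_path, gff3_path) -> None:
    """Write the model back out as FASTA + GFF3 (gene/mRNA/CDS, Parent links)."""
    with open(fasta_path, "w") as fh:
        for name in sorted(genome.contigs):
            fh.write(f">{name}\n")
            for line in chunked_fasta(genome.contigs[name]):
                fh.write(line + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in sorted(genome.contigs):
            fh.write(f"##sequence-region {name} 1 {len(genome.contigs[name])}\n")
        for g in genome.genes:
            spans = [t.genomic_span for t in g.transcripts]
            gs, ge = min(s for s, _ in spans), max(e for _, e in spans)
            fh.write("\t".join([g.contig, "introntrap", "gene", str(gs + 1), str(ge),
                                ".", g.strand, ".",
                                f"ID={g.gene_id};biotype={g.biotype}"]) + "\n")
            for t in g.transcripts:
                ts, te = t.genomic_span
                fh.write("\t".join([g.contig, "introntrap", "mRNA", str(ts + 1), str(te),
                                    ".", g.strand, ".",
                                    f"ID={t.transcript_id};Parent={g.gene_id}"]) + "\n")
                for k, (s, e) in enumerate(sorted(t.cds_segments)):
                    fh.write("\t".join([g.contig, "introntrap", "CDS", str(s + 1), str(e),
                                        ".", g.strand, "0",
                                        f"ID={t.transcript_id}.cds{k};Parent={t.transcript_id}"])
                             + "\n")


def intron_table(genome: AnnotatedGenome, mode: str = "exact") -> pd.DataFrame:
    """Per-transcript coding-intron table (1-based inclusive coordinates)."""
    rows = []
    for g in genome.genes:
        shared = {c.span for c in shared_coding_introns(g, mode=mode)}
        for t in g.transcripts:
            for c in coding_introns(t):
                rows.append({
                    "gene_id": g.gene_id, "transcript_id": t.transcript_id,
                    "contig": c.contig, "start": c.start + 1, "end": c.end,
                    "strand": c.strand, "length": c.length, "phase": c.phase,
                    "shared": c.span in shared})
    return pd.DataFrame(rows, columns=["gene_id", "transcript_id", "contig", "start",
                                       "end", "strand", "length", "phase", "shared"])
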