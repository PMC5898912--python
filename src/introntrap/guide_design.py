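"""SpCas9 sgRNA candidate enumeration inside a chosen intron.

The two hard constraints modelled are the ones a pre-computed sgRNA
database enforces: an NGG PAM immediately 3' of a 20-nt protospacer, and a
genome-wide unique seed (the PAM-proximal protospacer bases plus the PAM,
counted on both strands with N as a wildcard).  No efficiency score is
computed; externally supplied per-guide scores can be attached via
``rank_guides(..., scores=...)``.

Cut geometry: SpCas9 cuts bluntly 3 bp 5' of the PAM, i.e. between
protospacer positions 17 and 18; ``cut_position`` is the contig coordinate
of that inter-base boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

from .genome_model import AnnotatedGenome, CodingIntron
from .seqtools import revcomp

log = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
PAM_LEN = 3
CUT_FROM_PAM = 3   # blunt cut 3 nt 5' of the PAM


@dataclass(frozen=True)
class GuideCandidate:
    protospacer: str
    pam: str
    strand: str                       # relative to the contig
    contig: str
    protospacer_start: int            # genomic, 0-based
    protospacer_end: int              # half-open
    cut_position: int                 # inter-base boundary coordinate
    distance_to_nearest_splice_site: int
    seed_len: int = 13
    seed_unique: bool | None = None   # unset until checked
    score: float | None = None        # externally supplied efficiency score

    def __post_init__(self):
        if not re.fullmatch(r"[ACGT]GG", self.pam):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")

    @property
    def seed(self) -> str:
        """PAM-proximal protospacer bases + PAM (the uniqueness query)."""
        return self.protospacer[-self.seed_len:] + self.pam

    @property
    def guide_id(self) -> str:
        return f"{self.contig}:{self.cut_position}:{self.strand}"


def enumerate_guides(genome: AnnotatedGenome, intron: CodingIntron,
                     contig: str | None = None, min_splice_clearance: int = 50,
                     seed_len: int = 13) -> list[GuideCandidate]:
    """All 20-nt+NGG windows (both strands) whose cut falls inside the intron.

    The cut must sit strictly within the intron and at least
    ``min_splice_clearance`` bp from each splice site, keeping the repaired
    junction clear of splice signals.  Returns candidates ordered by cut
    position then strand; ``seed_unique`` is left unset.
    """
    contig = contig or intron.contig
    lo = intron.start + min_splice_clearance
    hi = intron.end - min_splice_clearance
    if hi <= lo:
        log.info("intron [%d,%d) too short for clearance %d bp: no guide candidates",
                 intron.start, intron.end, min_splice_clearance)
        return []
    seq = genome.contigs[contig]
    # a window's cut may lie inside the intron while the window overhangs it
    scan_lo = max(0, intron.start - (PROTOSPACER_LEN + PAM_LEN))
    scan_hi = min(len(seq), intron.end + PROTOSPACER_LEN + PAM_LEN)
    out = []
    for p in range(scan_lo, scan_hi - (PROTOSPACER_LEN + PAM_LEN) + 1):
        # + strand: protospacer [p, p+20), PAM [p+20, p+23)
        pam = seq[p + PROTOSPACER_LEN:p + PROTOSPACER_LEN + PAM_LEN]
        if pam[1:] == "GG" and "N" not in seq[p:p + PROTOSPACER_LEN + PAM_LEN]:
            cut = p + PROTOSPACER_LEN - CUT_FROM_PAM
            if lo <= cut <= hi and intron.start < cut < intron.end:
                out.append(GuideCandidate(
                    protospacer=seq[p:p + PROTOSPACER_LEN], pam=pam, strand="+",
                    contig=contig, protospacer_start=p,
                    protospacer_end=p + PROTOSPACER_LEN, cut_position=cut,
                    distance_to_nearest_splice_site=min(cut - intron.start,
                                                        intron.end - cut),
                    seed_len=seed_len))
        # - strand: genomic CCN prefix at p, protospacer on bottom strand
        if seq[p:p + 2] == "CC" and "N" not in seq[p:p + PROTOSPACER_LEN + PAM_LEN]:
            cut = p + PAM_LEN + CUT_FROM_PAM
            if lo <= cut <= hi and intron.start < cut < intron.end:
                proto_g = seq[p + PAM_LEN:p + PAM_LEN + PROTOSPACER_LEN]
                out.append(GuideCandidate(
                    protospacer=revcomp(proto_g), pam=revcomp(seq[p:p + PAM_LEN]),
                    strand="-", contig=contig, protospacer_start=p + PAM_LEN,
                    protospacer_end=p + PAM_LEN + PROTOSPACER_LEN, cut_position=cut,
                    distance_to_nearest_splice_site=min(cut - intron.start,
                                                        intron.end - cut),
                    seed_len=seed_len))
    out.sort(key=lambda g: (g.cut_position, g.strand))
    if not out:
        log.info("no PAM-bearing windows with cut inside intron [%d,%d)",
                 intron.start, intron.end)
    return out


def count_seed_occurrences(genome: AnnotatedGenome, seed_with_pam: str) -> int:
    """Genome-wide occurrence count of seed+NGG, both strands, N-wildcarded PAM.

    ``seed_with_pam`` is the guide's seed string (seed bases + its own PAM);
    the query replaces the PAM's first base with the N wildcard.
    """
    core = seed_with_pam[:-PAM_LEN]
    fwd = re.compile(f"(?={re.escape(core)}[ACGT]GG)")
    rc_core = revcomp(core)
    rev = re.compile(f"(?=CC[ACGT]{re.escape(rc_core)})")
    n = 0
    for seq in genome.contigs.values():
        n += sum(1 for _ in fwd.finditer(seq))
        n += sum(1 for _ in rev.finditer(seq))
    return n


def check_seed_uniqueness(guide: GuideCandidate, genome: AnnotatedGenome,
                          seed_len: int = 13) -> GuideCandidate:
    """Return the guide with ``seed_unique`` set.

    Unique means the seed+NGG pattern occurs exactly once genome-wide on
    both strands combined; the guide's own locus is that one occurrence.
    """
    if not 8 <= seed_len <= 20:
        raise ValueError("seed_len must be in [8, 20]")
    g = replace(guide, seed_len=seed_len)
    return replace(g, seed_unique=count_seed_occurrences(genome, g.seed) == 1)


def rank_guides(candidates: list[GuideCandidate]) -> list[GuideCandidate]:
    """Deterministic ranking: unique-seed guides first, then farthest from a
    splice site, then lexicographic protospacer; externally supplied scores
    (higher better) take precedence over the distance key when present."""
    have_scores = any(c.score is not None for c in candidates)

    def key(g: GuideCandidate):
        score_key = -(g.score if g.score is not None else float("-inf")) if have_scores else 0
        return (not g.seed_unique, score_key,
                -g.distance_to_nearest_splice_site, g.protospacer)

    return sorted(candidates, key=key)
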