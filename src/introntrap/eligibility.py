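"""Gene eligibility filtering, Gold/Silver/Bronze site tiers, and ortholog prioritization.

A gene is a workable gene-trap target when it has at least one coding
intron longer than 100 bp (strict) that is shared — identical span and
phase — by all of its annotated coding isoforms.  Individual candidate
introns are tiered by the fraction of the gene's transcripts they would
tag: Gold tags all, Silver more than half, Bronze half or fewer (the
exactly-50% case is conservatively Bronze and flagged as a boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import MalformedModelError
from .genome_model import (AnnotatedGenome, CodingIntron, GeneModel,
                           coding_introns, shared_coding_introns)

log = logging.getLogger(__name__)

GOLD, SILVER, BRONZE = "Gold", "Silver", "Bronze"


@dataclass(frozen=True)
class SiteClassification:
    gene_id: str
    intron: CodingIntron
    tagged_fraction: float
    tier: str
    boundary: bool = False   # true when tagged_fraction is exactly 0.5

    def __post_init__(self):
        f = self.tagged_fraction
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"tagged_fraction {f} outside [0,1]")


@dataclass
class EligibilityReport:
    threshold_bp: int
    best_intron: dict[str, CodingIntron]   # gene_id -> longest qualifying shared intron
    n_genes_scanned: int

    @property
    def eligible_gene_ids(self) -> list[str]:
        return list(self.best_intron)


def classify_site(g: GeneModel, i: CodingIntron,
                  include_noncoding: bool = False) -> SiteClassification:
    """Tier a candidate intron by the fraction of the gene's transcripts it tags.

    A transcript is tagged when it contains an intron with the same genomic
    span *and* the same phase (a phase-mismatched isoform would be trapped
    out of frame, not tagged).  With ``include_noncoding``, CDS-less
    transcripts join the denominator (they can never match).
    """
    n_tagged = 0
    for t in g.transcripts:
        if any(c.span == i.span and c.phase == i.phase for c in coding_introns(t)):
            n_tagged += 1
    if n_tagged == 0:
        raise MalformedModelError(
            f"intron [{i.start},{i.end}) is not a coding intron of any transcript "
            f"of {g.gene_id}")
    denom = len(g.transcripts) + (g.n_noncoding_transcripts if include_noncoding else 0)
    fraction = n_tagged / denom
    if fraction == 1.0:
        tier = GOLD
    elif fraction > 0.5:
        tier = SILVER
    else:
        tier = BRONZE
    return SiteClassification(gene_id=g.gene_id, intron=i, tagged_fraction=fraction,
                              tier=tier, boundary=(fraction == 0.5))


def eligible_genes(genome: AnnotatedGenome, min_intron_bp: int = 100,
                   shared_mode: str = "exact") -> EligibilityReport:
    """Apply the target filter: >=1 shared coding intron strictly longer than the threshold.

    For each eligible gene the report records the longest qualifying shared
    intron; ties break toward the most 5' intron in transcript orientation.
    """
    if min_intron_bp < 1:
        raise ValueError("min_intron_bp must be >= 1")
    best: dict[str, CodingIntron] = {}
    for g in genome.genes:
        if not g.transcripts:
            continue
        qualifying = [c for c in shared_coding_introns(g, mode=shared_mode)
                      if c.length > min_intron_bp]
        if not qualifying:
            continue
        # shared_coding_introns is already 5'->3' in transcript orientation,
        # so a stable max on length keeps the most-5' intron on ties
        best_intron = max(qualifying, key=lambda c: c.length)
        first = next(c for c in qualifying if c.length == best_intron.length)
        best[g.gene_id] = first
    return EligibilityReport(threshold_bp=min_intron_bp, best_intron=best,
                             n_genes_scanned=len(genome.genes))


def read_ortholog_scores(path) -> dict[str, int]:
    """Read a two-column TSV (gene_id, integer score); malformed rows are skipped."""
    scores: dict[str, int] = {}
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                gid, val = parts[0], int(parts[1])
                if val < 0:
                    raise ValueError
            except (IndexError, ValueError):
                skipped += 1
                continue
            scores[gid] = val
    if skipped:
        log.warning("ortholog score table: skipped %d malformed row(s)", skipped)
    return scores


def prioritize(report: EligibilityReport, ortholog_scores: dict[str, int],
               min_score: int = 4) -> list[str]:
    """Order eligible genes: high-confidence-ortholog partition (score >= min_score,
    inclusive) first, then the rest; within a partition by descending score, with the
    report's original order preserved among equal scores (stable sort)."""
    genes = report.eligible_gene_ids
    scored = [(g, ortholog_scores.get(g, 0)) for g in genes]
    priority = [x for x in scored if x[1] >= min_score]
    others = [x for x in scored if x[1] < min_score]
    key = lambda x: -x[1]
    return [g for g, _ in sorted(priority, key=key)] + [g for g, _ in sorted(others, key=key)]
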