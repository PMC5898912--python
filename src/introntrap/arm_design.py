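"""Homology-arm selection, Golden Gate enzyme choice, and Type IIS cloning primers.

Constraints modelled (all configurable, defaults as commonly practised for
this donor system): each arm 500-1200 bp, target ~1 kb; the genomic gap
between the two arms (the bases deleted upon HDR) strictly under 40 bp;
and at least one of BbsI/BsaI/BsmBI must have no recognition site in
either arm (nor in the cassette or vector bodies) — that enzyme is the
one used for assembly, since Golden Gate fails if the assembly enzyme
recuts internal sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .enzymes import DEFAULT_PREFERENCE, EnzymeSpec, find_sites, get_enzyme
from .errors import InfeasibleConstraintError
from .genome_model import AnnotatedGenome
from .seqtools import revcomp, wallace_tm


@dataclass(frozen=True)
class HomologyArm:
    side: str            # "left" | "right", genomic orientation
    contig: str
    start: int           # genomic, 0-based half-open
    end: int
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start:
            raise ValueError("arm sequence length disagrees with its genomic span")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Primer:
    name: str
    tail: str       # 5' tail: pad + Type IIS site + spacer + 4-nt fusion overhang
    priming: str    # 3' genomic-priming region, exact arm-terminus match

    @property
    def sequence(self) -> str:
        return self.tail + self.priming

    @property
    def tm_c(self) -> float:
        return wallace_tm(self.priming)


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    fusion_overhangs: tuple[str, str]   # top-strand 4-mers at (left, right) junctions


# ---------------------------------------------------------------------------
# arm search

SEARCH_STEP = 10      # bp lattice for shifting/growing windows
MAX_RADIUS = 2000     # outward search bound from the cut site


def _window_is_free(seq: str, enzyme: EnzymeSpec | None) -> bool:
    return enzyme is None or not find_sites(seq, enzyme)


def _search_one_arm(contig_seq: str, cut: int, side: str, *, offsets, min_len: int,
                    max_len: int, target_len: int, enzyme: EnzymeSpec | None):
    """First feasible (offset, length) for one arm on the deterministic lattice.

    Offsets move the arm's inner end away from the cut; lengths are tried
    closest-to-target first, shrinking before growing (tie-break toward the
    cut site).  Returns (HomologyArm, offset) or None.
    """
    lengths = [target_len]
    dev = SEARCH_STEP
    while target_len - dev >= min_len or target_len + dev <= max_len:
        if target_len - dev >= min_len:
            lengths.append(target_len - dev)
        if target_len + dev <= max_len:
            lengths.append(target_len + dev)
        dev += SEARCH_STEP
    for off in offsets:
        for ln in lengths:
            if side == "left":
                end = cut - off
                start = end - ln
            else:
                start = cut + off
                end = start + ln
            if start < 0 or end > len(contig_seq) or off + ln > MAX_RADIUS:
                continue
            window = contig_seq[start:end]
            if _window_is_free(window, enzyme):
                return HomologyArm(side=side, contig="", start=start, end=end,
                                   sequence=window), off
    return None


def propose_arms(genome: AnnotatedGenome, contig: str, cut_position: int,
                 *, min_len: int = 500, max_len: int = 1200, target_len: int = 1000,
                 max_gap: int = 39, enzyme: EnzymeSpec | None = None
                 ) -> tuple[HomologyArm, HomologyArm]:
    """Choose left/right homology arms around the cut site.

    Deterministic bounded search: inner arm ends step outward from the cut
    in 10-bp increments (joint gap < 40 bp), lengths vary around the target
    closest-first.  With ``enzyme`` given, windows containing a recognition
    site of that enzyme (either strand) are rejected.  Raises
    InfeasibleConstraintError naming the violated constraint.
    """
    seq = genome.contigs[contig]
    if cut_position - min_len < 0 or cut_position + min_len > len(seq):
        raise InfeasibleConstraintError(
            f"cut at {contig}:{cut_position} has less than {min_len} bp of flanking "
            "sequence on one side")
    offsets = list(range(0, max_gap + 1, SEARCH_STEP))
    left = _search_one_arm(seq, cut_position, "left", offsets=offsets, min_len=min_len,
                           max_len=max_len, target_len=target_len, enzyme=enzyme)
    if left is None:
        raise InfeasibleConstraintError(
            f"no site-free left arm in [{min_len},{max_len}] bp within the search "
            f"radius of {contig}:{cut_position}"
            + (f" for enzyme {enzyme.name}" if enzyme else ""))
    arm_l, off_l = left
    right_offsets = [o for o in offsets if off_l + o <= max_gap]
    right = _search_one_arm(seq, cut_position, "right", offsets=right_offsets,
                            min_len=min_len, max_len=max_len, target_len=target_len,
                            enzyme=enzyme)
    if right is None:
        raise InfeasibleConstraintError(
            f"no site-free right arm in [{min_len},{max_len}] bp with gap < "
            f"{max_gap + 1} bp at {contig}:{cut_position}"
            + (f" for enzyme {enzyme.name}" if enzyme else ""))
    arm_r, _ = right
    arm_l = HomologyArm(side="left", contig=contig, start=arm_l.start, end=arm_l.end,
                        sequence=arm_l.sequence)
    arm_r = HomologyArm(side="right", contig=contig, start=arm_r.start, end=arm_r.end,
                        sequence=arm_r.sequence)
    return arm_l, arm_r


def select_enzyme_and_arms(arm_l: HomologyArm, arm_r: HomologyArm, cassette_seq: str,
                           vector_seq: str,
                           enzymes: tuple[str, ...] = DEFAULT_PREFERENCE) -> EnzymeSpec:
    """First preference-order enzyme with no recognition site (either strand) in
    the arms, the cassette body, or the vector backbone body."""
    blocked = {}
    for name in enzymes:
        enz = get_enzyme(name)
        hits = []
        for label, seq in (("left arm", arm_l.sequence), ("right arm", arm_r.sequence),
                           ("cassette", cassette_seq), ("vector", vector_seq)):
            n = len(find_sites(seq, enz))
            if n:
                hits.append(f"{label}:{n}")
        if not hits:
            return enz
        blocked[name] = ", ".join(hits)
    detail = "; ".join(f"{k} ({v})" for k, v in blocked.items())
    raise InfeasibleConstraintError(
        "every candidate Golden Gate enzyme has internal recognition sites — "
        f"{detail}; choose a different intron or cut site")


def design_arms_and_enzyme(genome: AnnotatedGenome, contig: str, cut_position: int,
                           cassette_seq: str, vector_seq: str, *, min_len: int = 500,
                           max_len: int = 1200, target_len: int = 1000, max_gap: int = 39,
                           enzymes: tuple[str, ...] = DEFAULT_PREFERENCE
                           ) -> tuple[EnzymeSpec, HomologyArm, HomologyArm]:
    """Joint search: for each enzyme in preference order whose sites are absent
    from cassette and vector bodies, look for site-free arms; first success wins."""
    last_err = None
    for name in enzymes:
        enz = get_enzyme(name)
        if find_sites(cassette_seq, enz) or find_sites(vector_seq, enz):
            last_err = InfeasibleConstraintError(
                f"{name} cuts inside the cassette or vector body")
            continue
        try:
            arm_l, arm_r = propose_arms(
                genome, contig, cut_position, min_len=min_len, max_len=max_len,
                target_len=target_len, max_gap=max_gap, enzyme=enz)
            return enz, arm_l, arm_r
        except InfeasibleConstraintError as e:
            last_err = e
    raise InfeasibleConstraintError(
        "no enzyme/arm combination satisfies the design constraints at "
        f"{contig}:{cut_position} (last failure: {last_err})")


# ---------------------------------------------------------------------------
# primers

PRIMER_PAD = "AA"   # 5' bases ahead of the recognition site for enzyme footing


def _priming_region(terminus: str, min_len: int, max_len: int, min_tm: float,
                    what: str) -> str:
    """Shortest prefix of *terminus* in [min_len, max_len] with Wallace Tm >= min_tm."""
    for k in range(min_len, min(max_len, len(terminus)) + 1):
        if wallace_tm(terminus[:k]) >= min_tm:
            return terminus[:k]
    raise InfeasibleConstraintError(
        f"no {what} priming region of {min_len}-{max_len} nt reaches Tm "
        f">= {min_tm} C (Wallace rule)")


def design_gga_primers(arm: HomologyArm, enzyme: EnzymeSpec,
                       fusion_overhangs: tuple[str, str], *, min_tm: float = 58.0,
                       min_len: int = 18, max_len: int = 25) -> PrimerPair:
    """Primers that amplify the arm and, after Type IIS digestion, release it
    with exactly the two intended 4-nt fusion overhangs.

    The 5' tail is pad + recognition site + spacer (cut_offset_top nt) +
    overhang; the forward overhang is the product top-strand 4-mer at the
    arm's left junction, the reverse tail carries the reverse complement of
    the right-junction top-strand 4-mer.
    """
    o_left, o_right = (o.upper() for o in fusion_overhangs)
    for o in (o_left, o_right):
        if len(o) != enzyme.overhang_len:
            raise ValueError(f"fusion overhang {o!r} is not {enzyme.overhang_len} nt")
    if o_left == o_right or o_left == revcomp(o_right):
        raise ValueError("fusion overhangs must be distinct and non-complementary")
    spacer = "A" * enzyme.cut_offset_top
    fwd = Primer(name=f"{arm.side}_arm_F",
                 tail=PRIMER_PAD + enzyme.recognition + spacer + o_left,
                 priming=_priming_region(arm.sequence, min_len, max_len, min_tm,
                                         f"{arm.side}-arm forward"))
    rev = Primer(name=f"{arm.side}_arm_R",
                 tail=PRIMER_PAD + enzyme.recognition + spacer + revcomp(o_right),
                 priming=_priming_region(revcomp(arm.sequence), min_len, max_len,
                                         min_tm, f"{arm.side}-arm reverse"))
    return PrimerPair(forward=fwd, reverse=rev, fusion_overhangs=(o_left, o_right))


def simulate_pcr_amplicon(template: str, pair: PrimerPair) -> str:
    """Top strand of the tailed amplicon: fwd tail + template + rc(rev tail).

    Requires the primers' 3' regions to match the template termini exactly.
    """
    if not template.startswith(pair.forward.priming):
        raise ValueError("forward primer 3' region does not match the template start")
    if not revcomp(template).startswith(pair.reverse.priming):
        raise ValueError("reverse primer 3' region does not match the template end")
    return pair.forward.tail + template + revcomp(pair.reverse.tail)
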