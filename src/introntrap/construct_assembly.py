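"""Cassette models, Type IIS digestion, and Golden Gate donor assembly.

Digestion is simulated from first principles: every recognition-site
occurrence (both strands, IUPAC-aware) yields one staggered cut with the
enzyme's offset geometry, and fragments carry explicit 4-nt 5' overhangs.
Ligation joins fragments whose overhangs are exact complements (spelled as
equal top-strand 4-mers), so assembling the digest of a circular molecule
with all-distinct overhangs reproduces it exactly.

Overhang bookkeeping convention: a fragment's top strand runs from the
top-strand cut of its left junction to the top-strand cut of its right
junction.  ``left_overhang`` is the fragment's own protruding 5' top-strand
4-mer; ``right_overhang`` stores the top-strand spelling of the 4-mer that
protrudes on the *bottom* strand at its right end — which is exactly the
next fragment's left overhang, so junction compatibility is plain string
equality and parent reassembly is ``concat(left + body)`` in order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .enzymes import EnzymeSpec, find_sites
from .errors import AssemblyError, MalformedModelError
from .seqtools import revcomp

log = logging.getLogger(__name__)

BLUNT = "blunt"
FIVE_PRIME = "5'"

#: Fixed LOCUS date so GenBank output is byte-reproducible.
GENBANK_DATE = "01-JAN-1980"


@dataclass(frozen=True)
class Feature:
    label: str
    start: int
    end: int
    strand: str = "+"

    def shifted(self, off: int) -> "Feature":
        return replace(self, start=self.start + off, end=self.end + off)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DigestFragment:
    body: str
    left_overhang: tuple[str, str] = ("", BLUNT)    # (sequence, kind)
    right_overhang: tuple[str, str] = ("", BLUNT)
    features: tuple[Feature, ...] = ()
    circular: bool = False   # uncut circular molecule

    @property
    def top_strand(self) -> str:
        """The fragment's own top strand (left overhang + body)."""
        return self.left_overhang[0] + self.body

    @property
    def total_len(self) -> int:
        return len(self.left_overhang[0]) + len(self.body) + len(self.right_overhang[0])

    def flipped(self) -> "DigestFragment":
        total = self.total_len
        feats = tuple(Feature(f.label, total - f.end, total - f.start,
                              "-" if f.strand == "+" else "+")
                      for f in self.features)
        return DigestFragment(
            body=revcomp(self.body),
            left_overhang=(revcomp(self.right_overhang[0]), self.right_overhang[1]),
            right_overhang=(revcomp(self.left_overhang[0]), self.left_overhang[1]),
            features=feats, circular=self.circular)


# ---------------------------------------------------------------------------
# digestion


def _cut_events(seq: str, topology: str, enzyme: EnzymeSpec) -> list[tuple[int, int]]:
    """(top_cut, bottom_cut) coordinate pairs for every usable site."""
    L = enzyme.site_len
    top, bottom = enzyme.cut_offset_top, enzyme.cut_offset_bottom
    n = len(seq)
    if topology == "circular":
        ext = seq + seq[:L + bottom]
        hits = [(p, s) for p, s in find_sites(ext, enzyme) if p < n]
    else:
        hits = find_sites(seq, enzyme)
    cuts = []
    for p, strand in hits:
        if strand == "+":
            ct, cb = p + L + top, p + L + bottom
        else:
            ct, cb = p - bottom, p - top
        if topology == "linear" and (ct < 0 or cb > n):
            log.warning("site at %d (%s) cuts outside the linear molecule; skipped",
                        p, strand)
            continue
        if topology == "circular":
            ct, cb = ct % n, ct % n + (cb - ct)
        cuts.append((ct, cb))
    cuts.sort()
    for (a1, b1), (a2, b2) in zip(cuts, cuts[1:]):
        if b1 > a2:
            raise MalformedModelError(
                f"overlapping cut regions [{a1},{b1}) and [{a2},{b2})")
    return cuts


def _circ_sub(seq: str, start: int, length: int) -> str:
    n = len(seq)
    start %= n
    if start + length <= n:
        return seq[start:start + length]
    return seq[start:] + seq[:(start + length) % n]


def _features_in(features, lo: int, span: int, n: int | None) -> tuple[Feature, ...]:
    """Features (parent coords) fully inside [lo, lo+span), remapped to local coords.

    ``n`` is the parent length for circular parents (features may wrap), or
    None for linear parents.
    """
    out = []
    for f in features or ():
        if n is None:
            if lo <= f.start and f.end <= lo + span:
                out.append(f.shifted(-lo))
        else:
            local = (f.start - lo) % n
            if local + f.length <= span:
                out.append(Feature(f.label, local, local + f.length, f.strand))
    return tuple(out)


def typeIIS_digest(seq: str, topology: str, enzyme: EnzymeSpec,
                   features: list[Feature] | None = None) -> list[DigestFragment]:
    """Digest a molecule with a Type IIS enzyme into overhang-carrying fragments.

    ``topology`` is "linear" or "circular".  Features fully contained in a
    fragment are carried along in fragment-local coordinates (origin at the
    fragment's left overhang); features severed by a cut are dropped.
    """
    if topology not in ("linear", "circular"):
        raise ValueError(f"topology must be linear or circular, not {topology!r}")
    seq = seq.upper()
    n = len(seq)
    cuts = _cut_events(seq, topology, enzyme)
    if not cuts:
        return [DigestFragment(body=seq, features=tuple(features or ()),
                               circular=(topology == "circular"))]
    frags = []
    if topology == "linear":
        bounds = [(0, 0)] + cuts + [(n, n)]
        for (ct1, cb1), (ct2, cb2) in zip(bounds, bounds[1:]):
            left = seq[ct1:cb1]
            body = seq[cb1:ct2]
            right = seq[ct2:cb2]
            frags.append(DigestFragment(
                body=body,
                left_overhang=(left, FIVE_PRIME if left else BLUNT),
                right_overhang=(right, FIVE_PRIME if right else BLUNT),
                features=_features_in(features, ct1, cb2 - ct1, None)))
    else:
        for k, (ct1, cb1) in enumerate(cuts):
            ct2, cb2 = cuts[(k + 1) % len(cuts)]
            span = (ct2 - ct1) % n or n
            left = _circ_sub(seq, ct1, cb1 - ct1)
            body = _circ_sub(seq, cb1, span - (cb1 - ct1))
            right = _circ_sub(seq, ct2, cb2 - ct2)
            frags.append(DigestFragment(
                body=body, left_overhang=(left, FIVE_PRIME),
                right_overhang=(right, FIVE_PRIME),
                features=_features_in(features, ct1, span + (cb2 - ct2), n)))
    return frags


# ---------------------------------------------------------------------------
# ligation


@dataclass
class AssemblyProduct:
    topology: str
    sequence: str
    fragment_order: list[tuple[int, str]]   # (input index, "+" given / "-" flipped)
    features: list[Feature] = field(default_factory=list)

    def __len__(self):
        return len(self.sequence)


def _chain_products(fragments: list[DigestFragment]) -> list[list[tuple[int, DigestFragment]]]:
    """All circular chains using every fragment once, anchored on fragment 0
    in its given orientation (reflections/rotations are therefore not
    double-counted)."""
    orients = []
    for i, f in enumerate(fragments):
        opts = [("+", f)]
        fl = f.flipped()
        if (fl.left_overhang, fl.body) != (f.left_overhang, f.body):
            opts.append(("-", fl))
        orients.append(opts)
    chains = []

    def extend(chain, used):
        last = chain[-1][2]
        if len(chain) == len(fragments):
            if last.right_overhang[0] == chain[0][2].left_overhang[0]:
                chains.append([(i, o, f) for i, o, f in chain])
            return
        for j in range(1, len(fragments)):
            if j in used:
                continue
            for o, fj in orients[j]:
                if last.right_overhang[0] == fj.left_overhang[0] and fj.left_overhang[0]:
                    extend(chain + [(j, o, fj)], used | {j})

    extend([(0, "+", fragments[0])], {0})
    return chains


def gga_assemble(fragments: list[DigestFragment],
                 require_unique: bool = True) -> AssemblyProduct:
    """Golden Gate ligation: join fragments on exact overhang complementarity
    into the unique circular product.

    Raises AssemblyError when no circular product exists ("incompatible
    overhangs") or, with ``require_unique``, when the ligation graph admits
    more than one distinct circular product (the colliding overhang is
    named).
    """
    if len(fragments) < 2:
        raise AssemblyError("need at least two fragments to assemble")
    for f in fragments:
        if f.circular or not f.left_overhang[0] or not f.right_overhang[0]:
            raise AssemblyError("all fragments must be linear with sticky ends")
    chains = _chain_products(fragments)
    if not chains:
        raise AssemblyError("incompatible overhangs: no circular product")
    if require_unique and len(chains) > 1:
        exposure: dict[str, int] = {}
        for f in fragments:
            for ov in (f.left_overhang[0], revcomp(f.right_overhang[0])):
                exposure[ov] = exposure.get(ov, 0) + 1
        colliding = sorted(ov for ov, k in exposure.items() if k > 1)
        raise AssemblyError(
            f"ambiguous assembly: {len(chains)} circular products; "
            f"colliding overhang(s): {', '.join(colliding) or 'symmetric junctions'}")
    chain = chains[0]
    seq_parts, feats, order = [], [], []
    offset = 0
    for idx, orient, frag in chain:
        part = frag.top_strand
        feats.extend(f.shifted(offset) for f in frag.features)
        seq_parts.append(part)
        order.append((idx, orient))
        offset += len(part)
    return AssemblyProduct(topology="circular", sequence="".join(seq_parts),
                           fragment_order=order, features=feats)


# ---------------------------------------------------------------------------
# cassette and vector models

#: Required feature inventories per cassette topology class.
CASSETTE_TOPOLOGIES = {
    "pM14-like": {"attP": 2, "FRT": 2, "SA": 1, "3xSTOP": 1, "polyA": 1,
                  "3xP3-EGFP": 1, "polyA2": 1},
    "pM36-like": {"attP": 2, "FRT": 0, "SA": 1, "3xSTOP": 1, "polyA": 1,
                  "3xP3-EGFP": 1, "polyA2": 1},
    "pM37-like": {"attP": 2, "FRT": 2, "SA": 1, "T2A": 1, "GAL4": 1, "polyA": 1,
                  "3xP3-EGFP": 1, "polyA2": 1},
}


@dataclass
class CassetteSpec:
    """A swappable gene-trap cassette with its feature map.

    ``phase`` (0/1/2) is the coding-intron phase the splice-acceptor
    payload restores; None for stop-cassette types without a frame.
    """

    name: str
    cassette_type: str
    phase: int | None
    sequence: str
    features: list[Feature]

    def feature(self, label: str, which: int = 0) -> Feature:
        hits = [f for f in self.features if f.label == label]
        if len(hits) <= which:
            raise MalformedModelError(
                f"cassette {self.name}: feature {label!r} #{which} not present")
        return sorted(hits, key=lambda f: f.start)[which]


def validate_cassette(spec: CassetteSpec) -> None:
    """Check the declared topology's mandatory feature inventory."""
    if spec.cassette_type not in CASSETTE_TOPOLOGIES:
        raise MalformedModelError(
            f"unknown cassette type {spec.cassette_type!r}; "
            f"known: {sorted(CASSETTE_TOPOLOGIES)}")
    wanted = CASSETTE_TOPOLOGIES[spec.cassette_type]
    counts = {}
    for f in spec.features:
        counts[f.label] = counts.get(f.label, 0) + 1
        if not (0 <= f.start < f.end <= len(spec.sequence)):
            raise MalformedModelError(
                f"cassette {spec.name}: feature {f.label} [{f.start},{f.end}) "
                "outside sequence bounds")
    problems = []
    for label, want in wanted.items():
        have = counts.get(label, 0)
        if have != want:
            problems.append(f"{label}: expected {want}, found {have}")
    if problems:
        raise MalformedModelError(
            f"cassette {spec.name} fails {spec.cassette_type} topology: "
            + "; ".join(problems))
    if spec.cassette_type == "pM37-like" and spec.phase not in (0, 1, 2):
        raise MalformedModelError(
            f"cassette {spec.name}: pM37-like cassettes need a phase of 0, 1 or 2")


def load_cassette(source, cassette_type: str | None = None,
                  phase: int | None = None) -> CassetteSpec:
    """Load a cassette from a GenBank file (features need 'label' qualifiers).

    The topology class is inferred from the record name (pM14/pM36/pM37)
    unless given; the phase is parsed from a ``phase=N`` token in the
    record description unless given.
    """
    from Bio import SeqIO
    rec = SeqIO.read(str(source), "genbank")
    seq = str(rec.seq).upper()
    feats = []
    for sf in rec.features:
        label = (sf.qualifiers.get("label") or sf.qualifiers.get("note") or [None])[0]
        if label is None:
            continue
        feats.append(Feature(label=label, start=int(sf.location.start),
                             end=int(sf.location.end),
                             strand="-" if sf.location.strand == -1 else "+"))
    name = rec.name or rec.id
    if cassette_type is None:
        for t in CASSETTE_TOPOLOGIES:
            if t.split("-")[0].lower() in name.lower():
                cassette_type = t
                break
        else:
            raise MalformedModelError(
                f"cannot infer cassette type from record name {name!r}")
    if phase is None:
        for token in (rec.description or "").replace(";", " ").split():
            if token.startswith("phase="):
                phase = int(token.split("=", 1)[1])
    spec = CassetteSpec(name=name, cassette_type=cassette_type, phase=phase,
                        sequence=seq, features=feats)
    validate_cassette(spec)
    return spec


@dataclass
class VectorSpec:
    """A minimal circular receiving backbone: selection marker plus a stuffer
    flanked by Type IIS sites that release the backbone with fixed overhangs."""

    name: str
    sequence: str
    features: list[Feature]
    marker_label: str = "KanR"


def carrier_for(cassette: CassetteSpec, enzyme: EnzymeSpec,
                overhangs: tuple[str, str], backbone: str = "GCTTCCAT" * 8) -> tuple[str, list[Feature]]:
    """Model the cassette's carrier plasmid for a given assembly enzyme.

    Returns a circular sequence (plus features) in which the cassette is
    flanked by outward-reading enzyme sites positioned so digestion releases
    it with exactly the requested (left, right) top-strand overhangs.
    """
    o_l, o_r = overhangs
    spacer = "A" * enzyme.cut_offset_top
    seq = (o_l + cassette.sequence + o_r + spacer + revcomp(enzyme.recognition)
           + backbone + enzyme.recognition + spacer)
    feats = [f.shifted(len(o_l)) for f in cassette.features]
    feats.append(Feature("carrier-backbone",
                         len(o_l) + len(cassette.sequence) + len(o_r) + len(spacer)
                         + enzyme.site_len,
                         len(seq) - enzyme.site_len - len(spacer), "+"))
    return seq, feats


def synthetic_vector(enzyme: EnzymeSpec, overhangs: tuple[str, str],
                     backbone: str, stuffer: str, marker_span: tuple[int, int],
                     name: str = "pBH-like-synthetic") -> VectorSpec:
    """Build the synthetic receiving vector (see fixtures.make_vector).

    ``overhangs`` = (left, right) top-strand 4-mers the released backbone
    carries; ``marker_span`` locates the selection-marker block within
    ``backbone``.
    """
    o_l, o_r = overhangs
    spacer = "A" * enzyme.cut_offset_top
    seq = (o_l + backbone + o_r + spacer + revcomp(enzyme.recognition)
           + stuffer + enzyme.recognition + spacer)
    feats = [Feature("KanR", len(o_l) + marker_span[0], len(o_l) + marker_span[1], "+"),
             Feature("stuffer",
                     len(o_l) + len(backbone) + len(o_r) + len(spacer) + enzyme.site_len,
                     len(seq) - enzyme.site_len - len(spacer), "+")]
    return VectorSpec(name=name, sequence=seq, features=feats)


# ---------------------------------------------------------------------------
# donor construction


@dataclass
class DonorDesign:
    """Everything needed to build one donor plasmid in silico."""

    contig: str
    cut_position: int
    gene_strand: str
    intron: object                      # CodingIntron of the target site
    arm_left: object                    # HomologyArm
    arm_right: object
    enzyme: EnzymeSpec
    cassette: CassetteSpec
    vector: VectorSpec
    primers_left: object                # PrimerPair
    primers_right: object
    overhangs: tuple[str, str, str, str]   # O1 vector|armL, O2 armL|cassette,
                                           # O3 cassette|armR, O4 armR|vector


def plan_junction_overhangs(base: tuple[str, str, str, str], gene_strand: str
                            ) -> dict[str, tuple[str, str]]:
    """Fusion overhangs per amplicon so the cassette lands sense to the gene.

    For a minus-strand gene the cassette fragment is inserted flipped, so
    the arms must present the complements of its junction overhangs.
    """
    o1, o2, o3, o4 = base
    if gene_strand == "+":
        return {"left": (o1, o2), "right": (o3, o4), "cassette": (o2, o3)}
    return {"left": (o1, revcomp(o3)), "right": (revcomp(o2), o4),
            "cassette": (o2, o3)}


def _fragment_with_feature(frags: list[DigestFragment], label: str) -> DigestFragment:
    hits = [f for f in frags if any(ft.label == label for ft in f.features)]
    if len(hits) != 1:
        raise AssemblyError(
            f"expected exactly one digest fragment carrying feature {label!r}, "
            f"found {len(hits)}")
    return hits[0]


def build_donor(design: DonorDesign) -> AssemblyProduct:
    """Simulate arm PCR, Type IIS digestion of amplicons + cassette carrier +
    receiving vector, and one-pot Golden Gate assembly of the donor plasmid."""
    from .arm_design import simulate_pcr_amplicon

    enz = design.enzyme
    # arm amplicons -> released arm fragments
    arm_frags = {}
    for side, arm, pair in (("left", design.arm_left, design.primers_left),
                            ("right", design.arm_right, design.primers_right)):
        amplicon = simulate_pcr_amplicon(arm.sequence, pair)
        tail_len = len(pair.forward.tail)
        feats = [Feature(f"arm_{side}", tail_len, tail_len + arm.length, "+")]
        frags = typeIIS_digest(amplicon, "linear", enz, features=feats)
        if len(frags) != 3:
            raise AssemblyError(
                f"{side} arm amplicon digested into {len(frags)} fragments "
                "(internal enzyme site?)")
        arm_frags[side] = _fragment_with_feature(frags, f"arm_{side}")

    carrier_seq, carrier_feats = carrier_for(
        design.cassette, enz, plan_junction_overhangs(design.overhangs,
                                                      design.gene_strand)["cassette"])
    cass_frag = _fragment_with_feature(
        typeIIS_digest(carrier_seq, "circular", enz, features=carrier_feats), "SA")
    backbone_frag = _fragment_with_feature(
        typeIIS_digest(design.vector.sequence, "circular", enz,
                       features=design.vector.features),
        design.vector.marker_label)

    product = gga_assemble([backbone_frag, arm_frags["left"], cass_frag,
                            arm_frags["right"]])
    if find_sites(product.sequence, enz):
        raise AssemblyError(
            f"assembled donor still contains {enz.name} sites — arm/cassette/vector "
            "bodies were not clean")
    sa = [f for f in product.features if f.label == "SA"]
    want = "+" if design.gene_strand == "+" else "-"
    if sa and sa[0].strand != want:
        raise AssemblyError("cassette landed in the wrong orientation in the donor")
    return product


# ---------------------------------------------------------------------------
# GenBank I/O


def write_genbank(path, sequence: str, features: list[Feature], *,
                  name: str = "construct", topology: str = "circular",
                  description: str = "") -> None:
    """Write a GenBank flat file; features spanning the circular origin are
    emitted as origin-wrapping compound locations."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    n = len(sequence)
    rec = SeqRecord(Seq(sequence), id=name, name=name[:16], description=description)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = topology
    rec.annotations["date"] = GENBANK_DATE
    for f in sorted(features, key=lambda f: (f.start, f.end, f.label)):
        strand = -1 if f.strand == "-" else 1
        if topology == "circular":
            start = f.start % n
            end = start + (f.end - f.start)
        else:
            start, end = f.start, f.end
        if end > n:
            loc = CompoundLocation([SimpleLocation(start, n, strand),
                                    SimpleLocation(0, end - n, strand)])
        else:
            loc = SimpleLocation(start, end, strand)
        rec.features.append(SeqFeature(loc, type="misc_feature",
                                       qualifiers={"label": [f.label]}))
    from Bio import SeqIO
    with open(path, "w") as fh:
        SeqIO.write(rec, fh, "genbank")


def read_genbank(path) -> tuple[str, list[Feature], str, str]:
    """Read back (sequence, features, topology, name) from a GenBank file."""
    from Bio import SeqIO
    rec = SeqIO.read(str(path), "genbank")
    n = len(rec.seq)
    feats = []
    for sf in rec.features:
        label = (sf.qualifiers.get("label") or [sf.type])[0]
        strand = "-" if sf.location.strand == -1 else "+"
        parts = getattr(sf.location, "parts", [sf.location])
        if len(parts) == 2 and int(parts[0].end) == n and int(parts[1].start) == 0:
            feats.append(Feature(label, int(parts[0].start),
                                 n + int(parts[1].end), strand))
        else:
            feats.append(Feature(label, int(sf.location.start),
                                 int(sf.location.end), strand))
    topology = rec.annotations.get("topology", "linear")
    return str(rec.seq).upper(), feats, topology, rec.name
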