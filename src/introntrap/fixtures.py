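"""Deterministic synthetic genome, cassette and vector fixtures with truth tables.

The generator emits a small annotated genome whose gene inventory covers
the full decision space of the toolkit: intronless genes; shared introns at
exactly 100 bp (ineligible under the strict > filter) and 101 bp
(eligible); Gold/Silver/Bronze transcript-sharing patterns including the
exactly-50% boundary; both strands; all three intron phases; planted sgRNA
protospacers (one with a deliberately duplicated seed on a second contig)
and a planted Type IIS site near a cut region.  A JSON-able truth table
records every planted fact *by construction*, so downstream modules can be
checked against it without circularity.

Determinism contract: identical (config, seed) produce byte-identical
FASTA/GFF3/GenBank/JSON outputs.  Internally the generator redraws the
random background (with a salt folded into the seed) until it is free of
un-planted enzyme sites, attP-R primer sites, and seed collisions, so the
recorded truths hold for any seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .allele_sim import ATTP_R_PRIMER
from .construct_assembly import (CassetteSpec, Feature, VectorSpec,
                                 synthetic_vector, validate_cassette,
                                 write_genbank)
from .enzymes import EnzymeSpec, get_enzyme, load_enzyme_table
from .errors import DesignError
from .genome_model import (AnnotatedGenome, GeneModel, TranscriptModel,
                           write_genome)
from .seqtools import CODON_TABLE, revcomp, translate

#: canonical 34-nt FLP recombination target (real motif, not paper data)
FRT_SEQ = "GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"

#: 54-nt T2A ribosomal-skip element (EGRGSLLTCGDVEENPGP)
T2A_SEQ = "GAGGGCAGAGGAAGTCTGCTAACATGCGGTGACGTCGAGGAGAATCCTGGCCCA"

#: linker placed between the splice-acceptor exon start and T2A: stop-free in
#: frame 0, but guaranteed premature stops in both shifted frames
LINKER_SEQ = "TCTAACTGGATGAGT"

#: one stop codon in each of the three frames
TRIPLE_STOP = "TAATTAATTAA"

_NONSTOP = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")

#: default Golden Gate junction overhangs (vector|armL, armL|cassette,
#: cassette|armR, armR|vector): mutually distinct, non-self-complementary
DEFAULT_OVERHANGS = ("GGAG", "TACT", "AATG", "GCTT")

MAIN_CONTIG = "chrSyn"
SECOND_CONTIG = "chrSynB"


def _background_forbidden() -> list[str]:
    pats = []
    for enz in load_enzyme_table().values():
        pats.append(enz.recognition)
        rc = revcomp(enz.recognition)
        if rc != enz.recognition:
            pats.append(rc)
    pats += [ATTP_R_PRIMER, revcomp(ATTP_R_PRIMER)]
    return pats


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic genome.

    ``n_genes`` counts total genes; the first ten are the fixed scenario
    genes, the remainder deterministic filler genes with randomized isoform
    counts and intron lengths drawn from ``intron_menu``.
    """

    seed: int = 42
    n_genes: int = 10
    intron_menu: tuple[int, ...] = (80, 100, 101, 150, 300)
    lead_bp: int = 1400              # intergenic margin before the first gene
    gap_min_bp: int = 400            # intergenic gap between genes
    gap_extra_bp: int = 400
    min_contig_len: int = 0          # pad the main contig up to this length
    second_contig_len: int = 2000
    max_salts: int = 50


@dataclass
class _GeneBuild:
    gene_id: str
    strand: str
    seq: str                                     # genomic-strand sequence of the region
    transcripts: list[tuple[str, list[tuple[int, int]]]]   # region-relative genomic segs
    truth: dict
    guides: list[dict] = field(default_factory=list)       # region-relative
    enzyme_sites: list[dict] = field(default_factory=list)
    mutable: list[tuple[int, int]] = field(default_factory=list)  # scrubbable spans


def _rand_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _find_literal_hits(seq: str, patterns: list[str]) -> list[tuple[int, str]]:
    hits = []
    for pat in patterns:
        start = seq.find(pat)
        while start != -1:
            hits.append((start, pat))
            start = seq.find(pat, start + 1)
    return sorted(hits)


def _rand_codons(rng, n: int) -> str:
    """Stop-free codon stream, self-scrubbed of background-forbidden motifs
    (codons overlapping a motif are redrawn, preserving the reading frame)."""
    codons = [_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n)]
    patterns = _background_forbidden()
    for _ in range(200):
        seq = "".join(codons)
        hits = _find_literal_hits(seq, patterns)
        if not hits:
            return seq
        for p, pat in hits:
            for ci in range(p // 3, min(n, (p + len(pat) - 1) // 3 + 1)):
                codons[ci] = _NONSTOP[int(rng.integers(0, len(_NONSTOP)))]
    raise DesignError("could not scrub a codon stream of forbidden motifs")


def _scrub(rng, seq: str, mutable_spans: list[tuple[int, int]],
           allowed_spans: list[tuple[int, int]],
           patterns: list[str]) -> str | None:
    """Mutate single bases inside mutable spans until no forbidden motif
    occurs outside the allowed (deliberately planted) spans.

    Returns the scrubbed sequence, or None when some hit lies entirely in
    immutable sequence (caller retries with a fresh salt).
    """
    chars = list(seq)
    mut = bytearray(len(seq))
    for a, b in mutable_spans:
        for i in range(max(0, a), min(len(seq), b)):
            mut[i] = 1
    for _ in range(60):
        s = "".join(chars)
        dirty = False
        blocked_end = -1
        for p, pat in _find_literal_hits(s, patterns):
            if any(a <= p and p + len(pat) <= b for a, b in allowed_spans):
                continue
            dirty = True
            if p <= blocked_end:      # overlaps a hit mutated this sweep
                continue
            idxs = [i for i in range(p, p + len(pat)) if mut[i]]
            if not idxs:
                return None
            j = idxs[-1]
            old = chars[j]
            new = old
            while new == old:
                new = "ACGT"[int(rng.integers(0, 4))]
            chars[j] = new
            blocked_end = p + len(pat) - 1
        if not dirty:
            return s
    return None


def _truth_tier(n_tagged: int, n_tx: int) -> tuple[float, str, bool]:
    frac = n_tagged / n_tx
    tier = "Gold" if frac == 1.0 else ("Silver" if frac > 0.5 else "Bronze")
    return frac, tier, frac == 0.5


def _intron_seq(rng, length: int, plants: list[tuple[int, str]] | None = None) -> str:
    """GT ... AG intron with optional literals planted at given offsets."""
    if length < 4:
        raise DesignError(f"intron of {length} bp is too short to build")
    chars = list("GT" + _rand_seq(rng, length - 4) + "AG")
    for off, lit in plants or ():
        if off < 2 or off + len(lit) > length - 2:
            raise DesignError("planted literal overlaps splice sites")
        chars[off:off + len(lit)] = lit
    return "".join(chars)


def _map_offsets(strand: str, glen: int, a: int, b: int) -> tuple[int, int]:
    """Transcript-oriented region offsets -> genomic-strand region offsets."""
    return (a, b) if strand == "+" else (glen - b, glen - a)


def _simple_gene(rng, gene_id: str, strand: str, exon_lens: list[int],
                 intron_lens: list[int], n_tx: int = 1,
                 shifts: list[int] | None = None,
                 intron_plants: dict[int, list[tuple[int, str]]] | None = None,
                 guide_plants: list[tuple[int, int, str]] | None = None,
                 site_plants: list[tuple[int, int, str]] | None = None,
                 eligible_note: bool | None = None) -> _GeneBuild:
    """Build one gene region (transcript-oriented, then strand-mapped).

    ``shifts[k]`` moves transcript k's 3' boundary of intron 0 downstream by
    that many bases (0 = canonical structure); ``guide_plants`` are
    (intron_index, offset_in_intron, protospacer20) with an AGG PAM
    appended; ``site_plants`` are (intron_index, offset, enzyme_name).
    """
    shifts = shifts or [0] * n_tx
    assert len(shifts) == n_tx
    total = sum(exon_lens)
    if total % 3:
        raise DesignError(f"{gene_id}: CDS length {total} not a multiple of 3")
    cds = "ATG" + _rand_codons(rng, total // 3 - 2) + "TAA"

    plants: dict[int, list[tuple[int, str]]] = {k: list(v) for k, v in
                                                (intron_plants or {}).items()}
    guide_meta = []
    for ii, off, proto in guide_plants or ():
        plants.setdefault(ii, []).append((off, proto + "AGG"))
        guide_meta.append((ii, off, proto))
    site_meta = []
    for ii, off, enz_name in site_plants or ():
        site = get_enzyme(enz_name).recognition
        plants.setdefault(ii, []).append((off, site))
        site_meta.append((ii, off, enz_name))

    # transcript-oriented layout
    parts, exon_spans, intron_spans = [], [], []
    pos = 0
    cds_used = 0
    for k, elen in enumerate(exon_lens):
        parts.append(cds[cds_used:cds_used + elen])
        exon_spans.append((pos, pos + elen))
        cds_used += elen
        pos += elen
        if k < len(intron_lens):
            parts.append(_intron_seq(rng, intron_lens[k], plants.get(k)))
            intron_spans.append((pos, pos + intron_lens[k]))
            pos += intron_lens[k]
    t_seq = "".join(parts)
    glen = len(t_seq)
    g_seq = t_seq if strand == "+" else revcomp(t_seq)

    transcripts = []
    intron0 = intron_spans[0] if intron_spans else None
    for k in range(n_tx):
        segs_t = list(exon_spans)
        if shifts[k] and intron0 is not None:
            s0, e0 = segs_t[1]
            segs_t[1] = (s0 + shifts[k], e0)
        segs_g = [_map_offsets(strand, glen, a, b) for a, b in segs_t]
        transcripts.append((f"{gene_id}.t{k + 1}", segs_g))

    # truth: distinct intron-0 variants by shift; introns >=1 shared by all
    sites = []
    shared = []
    if intron_spans:
        by_shift: dict[int, int] = {}
        for s in shifts:
            by_shift[s] = by_shift.get(s, 0) + 1
        phase0 = exon_lens[0] % 3
        for s, count in sorted(by_shift.items()):
            span_t = (intron0[0], intron0[1] + s)
            span_g = _map_offsets(strand, glen, *span_t)
            frac, tier, boundary = _truth_tier(count, n_tx)
            sites.append({"span": span_g, "length": span_t[1] - span_t[0],
                          "phase": phase0, "n_tagged": count, "n_tx": n_tx,
                          "fraction": frac, "tier": tier, "boundary": boundary})
            if count == n_tx:
                shared.append({"span": span_g, "phase": phase0,
                               "length": span_t[1] - span_t[0]})
        upstream = exon_lens[0]
        for k, (a, b) in enumerate(intron_spans[1:], start=1):
            upstream += exon_lens[k]
            span_g = _map_offsets(strand, glen, a, b)
            frac, tier, boundary = _truth_tier(n_tx, n_tx)
            sites.append({"span": span_g, "length": b - a, "phase": upstream % 3,
                          "n_tagged": n_tx, "n_tx": n_tx, "fraction": frac,
                          "tier": tier, "boundary": boundary})
            shared.append({"span": span_g, "phase": upstream % 3, "length": b - a})

    eligible = any(s["length"] > 100 for s in shared)
    if eligible_note is not None:
        assert eligible == eligible_note, f"{gene_id}: scenario eligibility mismatch"
    best = max((s for s in shared if s["length"] > 100),
               key=lambda s: s["length"], default=None)
    truth = {"strand": strand, "n_tx": n_tx, "eligible": eligible,
             "shared_introns": sorted(shared, key=lambda s: s["span"]),
             "best_intron": best["span"] if best else None,
             "sites": sorted(sites, key=lambda s: s["span"])}

    # scrubbable positions: intron interiors (clear of the GT/AG dinucleotides
    # and of planted literals); everything exonic stays untouched
    mutable = []
    for k, (a, b) in enumerate(intron_spans):
        cursor = a + 2
        for off, lit in sorted(plants.get(k, [])):
            ps = a + off
            if ps > cursor:
                mutable.append(_map_offsets(strand, glen, cursor, ps))
            cursor = max(cursor, ps + len(lit))
        if b - 2 > cursor:
            mutable.append(_map_offsets(strand, glen, cursor, b - 2))

    build = _GeneBuild(gene_id=gene_id, strand=strand, seq=g_seq,
                       transcripts=transcripts, truth=truth,
                       mutable=sorted(mutable))
    for ii, off, proto in guide_meta:
        a = intron_spans[ii][0] + off   # transcript-oriented protospacer start
        if strand == "+":
            build.guides.append({"gene": gene_id, "protospacer": proto, "pam": "AGG",
                                 "strand": "+", "proto_span": (a, a + 20),
                                 "cut": a + 17})
        else:
            pam_s, _ = _map_offsets(strand, glen, a + 20, a + 23)
            build.guides.append({"gene": gene_id, "protospacer": proto, "pam": "AGG",
                                 "strand": "-", "proto_span": (pam_s + 3, pam_s + 23),
                                 "cut": pam_s + 6})
    for ii, off, enz_name in site_meta:
        a = intron_spans[ii][0] + off
        site_len = get_enzyme(enz_name).site_len
        span = _map_offsets(strand, glen, a, a + site_len)
        build.enzyme_sites.append({"enzyme": enz_name, "span": span,
                                   "strand": strand})
    return build


def _phase_mix_gene(rng, gene_id: str) -> _GeneBuild:
    """Two isoforms share an intron's span but read it in different phases
    (the second isoform has an extra 5' coding exon), so the intron must be
    excluded from the shared set."""
    e0, i0, e1, i1, e2 = 100, 90, 201, 120, 300
    # genomic layout: [E0][I0][E1][I1][E2]; tx1 uses E1+E2, tx2 uses E0+E1+E2
    seq_e0 = ("ATG" + _rand_codons(rng, 33))[:e0]
    seq_e1 = "ATG" + _rand_codons(rng, (e1 - 3) // 3)
    seq_e2 = _rand_codons(rng, e2 // 3)
    parts = [seq_e0, _intron_seq(rng, i0), seq_e1, _intron_seq(rng, i1), seq_e2]
    seq = "".join(parts)
    p_e0 = 0
    p_e1 = e0 + i0
    p_e2 = p_e1 + e1 + i1
    tx1 = (f"{gene_id}.t1", [(p_e1, p_e1 + e1), (p_e2, p_e2 + e2)])
    tx2 = (f"{gene_id}.t2", [(p_e0, p_e0 + e0), (p_e1, p_e1 + e1), (p_e2, p_e2 + e2)])
    shared_span = (p_e1 + e1, p_e2)
    sites = [
        # the common intron, counted per phase group: tx1 reads phase e1%3=0,
        # tx2 reads phase (e0+e1)%3=1 -> tagged by 1 of 2 transcripts each
        {"span": shared_span, "length": i1, "phase": e1 % 3, "n_tagged": 1,
         "n_tx": 2, "fraction": 0.5, "tier": "Bronze", "boundary": True},
        {"span": shared_span, "length": i1, "phase": (e0 + e1) % 3, "n_tagged": 1,
         "n_tx": 2, "fraction": 0.5, "tier": "Bronze", "boundary": True},
        {"span": (e0, e0 + i0), "length": i0, "phase": e0 % 3, "n_tagged": 1,
         "n_tx": 2, "fraction": 0.5, "tier": "Bronze", "boundary": True},
    ]
    truth = {"strand": "+", "n_tx": 2, "eligible": False, "shared_introns": [],
             "best_intron": None, "sites": sorted(sites, key=lambda s: (s["span"], s["phase"]))}
    return _GeneBuild(gene_id=gene_id, strand="+", seq=seq,
                      transcripts=[tx1, tx2], truth=truth,
                      mutable=[(e0 + 2, e0 + i0 - 2),
                               (p_e1 + e1 + 2, p_e2 - 2)])


def _filler_gene(rng, idx: int, cfg: FixtureConfig) -> _GeneBuild:
    strand = "+" if idx % 2 == 0 else "-"
    n_tx = 1 + idx % 3
    ilen = cfg.intron_menu[idx % len(cfg.intron_menu)]
    phase = idx % 3
    e1 = 300 + phase
    e2 = 303 - phase
    subset = n_tx > 1 and (idx // 2) % 2 == 1
    shifts = [0] * n_tx
    if subset:
        shifts[-1] = 6
    return _simple_gene(rng, f"gFill{idx:03d}", strand, [e1, e2], [ilen],
                        n_tx=n_tx, shifts=shifts)


def _core_genes(rng) -> list[_GeneBuild]:
    protoU = _rand_seq(rng, 20)
    protoD = _rand_seq(rng, 20)
    protoM = _rand_seq(rng, 20)
    protoB = _rand_seq(rng, 20)
    genes = [
        _simple_gene(rng, "gIntronless", "+", [600], [], eligible_note=False),
        _simple_gene(rng, "gExact100", "+", [300, 300], [100], eligible_note=False),
        _simple_gene(rng, "gShared101", "+", [301, 302], [101], eligible_note=True),
        _simple_gene(rng, "gGold150", "+", [301, 299], [150], n_tx=2,
                     guide_plants=[(0, 40, protoU), (0, 70, protoD)],
                     eligible_note=True),
        _simple_gene(rng, "gSilver", "+", [300, 300], [150], n_tx=4,
                     shifts=[0, 0, 0, 9], eligible_note=False),
        _simple_gene(rng, "gBronze", "+", [300, 303], [120], n_tx=5,
                     shifts=[0, 0, 6, 12, 18], eligible_note=False),
        _simple_gene(rng, "gHalfBoundary", "+", [300, 300], [130], n_tx=4,
                     shifts=[0, 0, 6, 6], eligible_note=False),
        _phase_mix_gene(rng, "gPhaseMix"),
        _simple_gene(rng, "gMinus", "-", [302, 301], [120], n_tx=2,
                     guide_plants=[(0, 33, protoM)], eligible_note=True),
        _simple_gene(rng, "gBig", "+", [300, 450, 351], [5000, 120],
                     guide_plants=[(0, 2483, protoB)],
                     site_plants=[(0, 1700, "BbsI")], eligible_note=True),
    ]
    return genes


def _assemble_contig(rng, builds: list[_GeneBuild], cfg: FixtureConfig):
    """Lay gene regions on the main contig with intergenic spacers; returns
    the raw contig, gene placements, and the scrubbable position spans."""
    parts = [_rand_seq(rng, cfg.lead_bp)]
    mutable = [(0, cfg.lead_bp)]
    pos = cfg.lead_bp
    placements = []
    for b in builds:
        placements.append((b, pos))
        parts.append(b.seq)
        mutable += [(a + pos, e + pos) for a, e in b.mutable]
        pos += len(b.seq)
        gap = cfg.gap_min_bp + int(rng.integers(0, cfg.gap_extra_bp + 1))
        parts.append(_rand_seq(rng, gap))
        mutable.append((pos, pos + gap))
        pos += gap
    if pos < cfg.min_contig_len:
        parts.append(_rand_seq(rng, cfg.min_contig_len - pos))
        mutable.append((pos, cfg.min_contig_len))
    return "".join(parts), placements, mutable


def _count_pattern(seqs: list[str], core: str) -> int:
    """Occurrences of seed-core + NGG on both strands across contigs."""
    import re
    fwd = re.compile(f"(?={re.escape(core)}[ACGT]GG)")
    rev = re.compile(f"(?=CC[ACGT]{re.escape(revcomp(core))})")
    return sum(len(fwd.findall(s)) + len(rev.findall(s)) for s in seqs)


def _validate_build(contig: str, contig2: str, truth: dict) -> bool:
    """Reject salted draws where a planted guide seed collides with the
    random background (the scrub pass already guarantees motif cleanliness)."""
    for g in truth["guides"]:
        core = g["protospacer"][-13:]
        want = 1 if g["seed_unique"] else 2
        if _count_pattern([contig, contig2], core) != want:
            return False
    return True


def make_synthetic_genome(config: FixtureConfig | None = None, outdir=None
                          ) -> tuple[AnnotatedGenome, dict]:
    """Generate the synthetic genome and its truth table; optionally write
    FASTA/GFF3/JSON fixtures into ``outdir``."""
    cfg = config or FixtureConfig()
    if cfg.n_genes < 10:
        raise DesignError("n_genes must be >= 10 (the fixed scenario genes)")
    last = None
    patterns = _background_forbidden()
    for salt in range(cfg.max_salts):
        rng = np.random.default_rng([int(cfg.seed), salt])
        builds = _core_genes(rng)
        builds += [_filler_gene(rng, i, cfg) for i in range(10, cfg.n_genes)]
        raw_contig, placements, mutable = _assemble_contig(rng, builds, cfg)

        # second contig carries the deliberate duplicate of gGold150's
        # second planted guide seed (13 nt + a different NGG)
        gold = next(b for b in builds if b.gene_id == "gGold150")
        dup_seed = gold.guides[1]["protospacer"][-13:] + "CGG"
        c2 = _rand_seq(rng, cfg.second_contig_len)
        mid = cfg.second_contig_len // 2
        raw_contig2 = c2[:mid] + dup_seed + c2[mid + len(dup_seed):]

        truth = {"config": {"seed": cfg.seed, "n_genes": cfg.n_genes},
                 "genes": {}, "guides": [], "enzyme_sites": []}
        allowed = []
        for b, off in placements:
            g = dict(b.truth)
            g["region"] = (off, off + len(b.seq))
            for key in ("shared_introns", "sites"):
                g[key] = [dict(d, span=(d["span"][0] + off, d["span"][1] + off))
                          for d in g[key]]
            g["best_intron"] = (tuple(x + off for x in g["best_intron"])
                                if g["best_intron"] else None)
            truth["genes"][b.gene_id] = g
            for gd in b.guides:
                gd = dict(gd)
                gd["proto_span"] = (gd["proto_span"][0] + off,
                                    gd["proto_span"][1] + off)
                gd["cut"] += off
                gd["contig"] = MAIN_CONTIG
                truth["guides"].append(gd)
            for es in b.enzyme_sites:
                es = dict(es)
                es["span"] = (es["span"][0] + off, es["span"][1] + off)
                es["contig"] = MAIN_CONTIG
                truth["enzyme_sites"].append(es)
                allowed.append(es["span"])

        # every planted guide is seed-unique except gGold150's second plant,
        # whose seed was copied onto the second contig
        dup_proto = gold.guides[1]["protospacer"]
        for gd in truth["guides"]:
            gd["seed_unique"] = gd["protospacer"] != dup_proto

        contig = _scrub(rng, raw_contig, mutable, allowed, patterns)
        contig2 = _scrub(rng, raw_contig2, [(0, mid), (mid + len(dup_seed),
                                                       len(raw_contig2))],
                         [], patterns)
        if contig is None or contig2 is None:
            last = salt
            continue
        if _validate_build(contig, contig2, truth):
            genes = []
            for b, off in placements:
                txs = [TranscriptModel(
                    transcript_id=tid, contig=MAIN_CONTIG, strand=b.strand,
                    cds_segments=[(s + off, e + off) for s, e in segs])
                    for tid, segs in b.transcripts]
                genes.append(GeneModel(gene_id=b.gene_id, contig=MAIN_CONTIG,
                                       strand=b.strand, biotype="protein_coding",
                                       transcripts=txs))
            genome = AnnotatedGenome(
                contigs={MAIN_CONTIG: contig, SECOND_CONTIG: contig2}, genes=genes)
            truth["salt"] = salt
            if outdir is not None:
                import os
                os.makedirs(outdir, exist_ok=True)
                write_genome(genome, f"{outdir}/genome.fa", f"{outdir}/genome.gff3")
                with open(f"{outdir}/truth.json", "w") as fh:
                    json.dump(truth, fh, indent=2, sort_keys=True)
                    fh.write("\n")
            return genome, truth
        last = salt
    raise DesignError(f"could not build a clean fixture genome in "
                      f"{cfg.max_salts} attempts (seed {cfg.seed}, last salt {last})")


# ---------------------------------------------------------------------------
# cassette and vector stand-ins


def _cassette_blocks(rng) -> dict[str, str]:
    attp = _rand_seq(rng, 20) + revcomp(ATTP_R_PRIMER) + _rand_seq(rng, 17)
    sa = _rand_seq(rng, 25) + "TTTTTTTCTTTCAG"       # branch/polyY tract + 3' AG
    gal4 = _rand_codons(rng, 40) + "TAA"
    polya = "AATAAA" + _rand_seq(rng, 24)
    marker = _rand_codons(rng, 30)
    polya2 = "AATAAA" + _rand_seq(rng, 24)
    return {"attP": attp, "SA": sa, "GAL4": gal4, "polyA": polya,
            "marker": marker, "polyA2": polya2}


def _assemble_cassette(blocks: dict[str, str], name: str, cassette_type: str,
                       phase: int | None) -> CassetteSpec:
    pad = "G" * ((3 - phase) % 3) if phase is not None else ""
    order: list[tuple[str, str, str]] = [("attP", blocks["attP"], "+")]
    if cassette_type in ("pM14-like", "pM37-like"):
        order.append(("FRT", FRT_SEQ, "+"))
    order.append(("SA", blocks["SA"], "+"))
    if cassette_type == "pM37-like":
        order.append(("_pad", pad, "+"))
        order.append(("_linker", LINKER_SEQ, "+"))
        order.append(("T2A", T2A_SEQ, "+"))
        order.append(("GAL4", blocks["GAL4"], "+"))
    else:
        order.append(("3xSTOP", TRIPLE_STOP, "+"))
    order.append(("polyA", blocks["polyA"], "+"))
    order.append(("3xP3-EGFP", blocks["marker"], "+"))
    order.append(("polyA2", blocks["polyA2"], "+"))
    if cassette_type in ("pM14-like", "pM37-like"):
        order.append(("FRT", FRT_SEQ, "+"))
    order.append(("attP", revcomp(blocks["attP"]), "-"))

    seq_parts, feats = [], []
    pos = 0
    for label, block, strand in order:
        if block and not label.startswith("_"):
            feats.append(Feature(label, pos, pos + len(block), strand))
        seq_parts.append(block)
        pos += len(block)
    spec = CassetteSpec(name=name, cassette_type=cassette_type, phase=phase,
                        sequence="".join(seq_parts), features=feats)
    validate_cassette(spec)
    return spec


def make_cassette_standins(outdir=None, seed: int = 7) -> dict[str, CassetteSpec]:
    """Synthetic stand-in cassettes with the real topologies.

    pM14-like: attP-FRT-SA-3xSTOP-polyA-marker-FRT-attP; pM36-like: the same
    without FRTs; pM37-like (phases 0/1/2): attP-FRT-SA-T2A-GAL4-polyA-
    marker-FRT-attP.  attP blocks are inverted repeats carrying the attP-R
    primer site; block sequences are labelled synthetic placeholders with
    canonical motif lengths, not the published plasmid sequences.
    """
    rng = np.random.default_rng(seed)
    blocks = _cassette_blocks(rng)
    # the stand-in blocks must not contain assembly-enzyme sites (the attP
    # blocks legitimately carry the attP-R primer site, so only enzyme
    # recognition motifs are screened here)
    enzyme_pats = [p for e in load_enzyme_table().values()
                   for p in (e.recognition, revcomp(e.recognition))]
    for pat in set(enzyme_pats):
        for block in blocks.values():
            if pat in block or pat in revcomp(block):
                return make_cassette_standins(outdir=outdir, seed=seed + 1000)
    out = {
        "pM14-like": _assemble_cassette(blocks, "pM14like", "pM14-like", None),
        "pM36-like": _assemble_cassette(blocks, "pM36like", "pM36-like", None),
    }
    for p in (0, 1, 2):
        out[f"pM37-like-p{p}"] = _assemble_cassette(
            blocks, f"pM37like_p{p}", "pM37-like", p)
    # declared-frame sanity: SA->T2A->GAL4 open reading frame is stop-free
    for p in (0, 2, 1):
        spec = out[f"pM37-like-p{p}"]
        sa_end = spec.feature("SA").end
        pad = (3 - p) % 3
        orf = spec.sequence[sa_end + pad:spec.feature("GAL4").end - 3]
        aa = translate(orf)
        assert "*" not in aa, "stand-in cassette ORF contains an internal stop"
    if outdir is not None:
        import os
        os.makedirs(outdir, exist_ok=True)
        for key, spec in sorted(out.items()):
            write_genbank(f"{outdir}/{spec.name}.gb", spec.sequence, spec.features,
                          name=spec.name, topology="linear",
                          description=("synthetic stand-in cassette"
                                       + (f" phase={spec.phase}"
                                          if spec.phase is not None else "")))
    return out


def make_vector(enzyme: EnzymeSpec | str, overhangs: tuple[str, str] | None = None,
                seed: int = 11) -> VectorSpec:
    """Synthetic receiving backbone (KanR marker + stuffer) for one assembly
    enzyme; overhangs default to the (armR|vector, vector|armL) junctions."""
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme)
    if overhangs is None:
        overhangs = (DEFAULT_OVERHANGS[3], DEFAULT_OVERHANGS[0])
    rng = np.random.default_rng(seed)
    for _ in range(100):
        backbone = _rand_codons(rng, 100)
        stuffer = _rand_seq(rng, 120)
        if not any(pat in backbone or pat in stuffer
                   for pat in _background_forbidden()):
            return synthetic_vector(enzyme, overhangs, backbone, stuffer,
                                    marker_span=(60, 240))
    raise DesignError("could not draw an enzyme-free synthetic vector backbone")
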