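# Methods

## The design problem

An intronic gene trap of the T2A-GAL4 family converts one gene into a
GAL4 driver and, usually, a severe loss-of-function allele. The cassette
(`attP-FRT-SA-T2A-GAL4-polyA-3xP3-EGFP-FRT-attP`) is inserted into an
intron by homology-directed repair at a Cas9 cut. Three facts drive every
constraint the package enforces:

1. **Splicing.** The cassette's splice acceptor (SA) must capture the
   upstream exon in *every* isoform identically, which requires an intron
   flanked by CDS on both sides whose genomic span is the same in all
   annotated transcripts.
2. **Reading frame.** Translation runs from the native start codon across
   the SA junction into the cassette. The intron *phase* — upstream CDS
   length mod 3 — must equal the cassette's declared phase (0/1/2) or the
   T2A-GAL4 ORF is frameshifted and hits a premature stop.
3. **Cloning.** The donor is built in a one-pot Golden Gate reaction, so
   the homology arms, cassette body and vector body must not contain
   internal recognition sites of the assembly enzyme.

## Models and procedures

### Coordinates and annotation

All internal coordinates are 0-based half-open; GFF3 I/O is 1-based
inclusive. Annotation follows the FlyBase dialect (gene → mRNA → CDS with
`Parent` links); other dialects must be normalized upstream. Genes whose
transcripts disagree on strand or contig are rejected. Only CDS-bearing
transcripts are modelled; CDS-less transcripts of a gene are counted and
can optionally be included in tier denominators
(`include_noncoding`). "Shared by all isoforms" means exact span identity
*and* identical phase; a positional-overlap alternative is exposed as
`shared_mode="overlap"` for sensitivity analysis, because a trap at a
span-identical intron read in two different frames tags only the
frame-matching isoforms.

### Eligibility and tiers

A gene is eligible when it has ≥ 1 shared coding intron strictly longer
than `min_intron_bp` (default 100; the boundary is read literally, so a
100-bp intron fails). Per-intron site tiers follow the transcript-tagging
fraction: Gold = 1.0, Silver ∈ (0.5, 1), Bronze ≤ 0.5. The definitions of
Silver ("more than 50%") and Bronze ("less than 50%") leave exactly 50%
unassigned; the package assigns 0.5 to Bronze (conservative) and flags it
`boundary=true`. Classification is per intron, so one gene may host sites
of different tiers. Ortholog scores (DIOPT-style) are an external input,
never computed; the priority partition uses score ≥ 4, inclusive.

### Guides

SpCas9 geometry: 20-nt protospacer, NGG PAM, blunt cut between
protospacer positions 17/18 (3 bp 5′ of the PAM) — standard biochemistry,
configurable nowhere because nothing else in the pipeline depends on it
being tunable. The cut must fall strictly inside the intron and at least
`min_splice_clearance` (default 50 bp) from each splice site so the
repaired junctions stay clear of splice signals. Specificity is modelled
as *seed uniqueness only*: the PAM-proximal `seed_len` (default 13) nt
plus NGG (N wildcarded) must occur exactly once genome-wide counting both
strands. No efficiency score is computed; externally supplied scores can
be attached and dominate the ranking. Default ranking: unique seeds
first, then distance from the nearest splice site, then lexicographic
protospacer as a deterministic tie-break.

### Arms, enzyme, primers

Arm constraints: each arm within [500, 1200] bp (target 1000), and the
genomic gap between the arms — the bases deleted on HDR — strictly
under 40 bp (arms may abut; the cut always lies in the gap interval
closure). An alternative preset (`RunConfig.results_preset()`) caps arms
at 1000 bp. The search is deterministic: inner arm ends step away from
the cut on a 10-bp lattice (joint gap < 40), lengths are tried closest to
the target first, shrinking before growing; the first feasible window
wins. A recognition site counts against a window only when fully inside
it — a site truncated at the arm boundary does not exist in the
amplified arm. Whenever the bounded search fails, an exhaustive scan over
the same lattice also finds no solution (verified in the tests).

Enzyme choice reads the "free of one or more of the three enzymes"
requirement as: at least one of BbsI/BsaI/BsmBI has no site in either arm
nor in the cassette or vector bodies, and that enzyme is the one used —
Golden Gate fails if the assembly enzyme recuts internal sites. The
preference order BbsI > BsaI > BsmBI is arbitrary but fixed and
configurable. The cut-geometry table (BsaI GGTCTC(1/5), BbsI GAAGAC(2/6),
BsmBI CGTCTC(1/5); all 4-nt 5′ overhangs) is standard biochemistry
shipped as editable package data.

Primers are tail + priming region: the 5′ tail is a 2-nt pad, the enzyme
site, a spacer of `cut_offset_top` nt and the 4-nt fusion overhang, so
that digesting the amplicon releases the arm with exactly the designed
overhangs (asserted by simulation). The 3′ priming region is the shortest
arm-terminal prefix in [18, 25] nt reaching Tm ≥ 58 °C under the Wallace
rule, Tm = 2(A+T) + 4(G+C). This replaces Primer3-grade thermodynamics
deliberately: the formula is crude but documented, monotone in length,
and exactly reproducible. No hairpin/dimer screening is attempted.

### Assembly simulation

Digestion places one staggered cut per recognition-site occurrence (both
strands, IUPAC-aware). Fragments store their top strand from left
top-strand cut to right top-strand cut; the right overhang records the
top-strand spelling of the bottom-strand protrusion, which equals the
next fragment's left overhang, so ligation compatibility is string
equality and `concat(left + body)` reassembles the parent. Ligation is
exact-complement only (no mismatch ligation); the assembler enumerates
Hamiltonian cycles over the fragments (both orientations), anchored on
the first fragment to avoid counting rotations/reflections, and demands
exactly one circular product — duplicated overhangs raise an ambiguity
error naming the collision.

Junction overhangs (vector|armL, armL|cassette, cassette|armR,
armR|vector = GGAG/TACT/AATG/GCTT by default) are data, not constants;
for a minus-strand gene the arms present the complements of the cassette
junctions so the unique assembly places the cassette sense to the gene.
One physical carrier cannot have coincident junction sites for all three
enzymes (their offsets differ), so the cassette carrier and the receiving
backbone are modelled per chosen enzyme: thin wrappers place
outward-reading sites so digestion releases the cassette/backbone with
the designed overhangs. The receiving vector is an abstract
kanamycin-marked backbone with a stuffer, standing in for a real
recipient plasmid.

### Edited allele, excision, fusion, validation

The edited allele is the genomic window `allele_flank_bp` (default 500)
beyond the arms, with the inter-arm gap replaced by the oriented
cassette; the length identity window − gap + cassette is asserted. FLP
excision deletes between the two direct-repeat FRTs and keeps one,
leaving an attP-FRT-attP scar; stop-cassette alleles without FRTs are not
excisable and inverted FRTs (which would invert, not delete) are
rejected. For converting a pre-existing intronic docking-site insertion
by RMCE, the cassette orientation is kept or flipped so the SA is sense
to the gene, and the required phase is the intron phase at the insertion
point; the trap stock phase label is mapped 1:1 to intron phase
(`phase_label_mapping="identity"` — the only mapping consistent with the
cassette construction here).

Fusion prediction splices the native exons 5′ of the insertion onto the
cassette exon (SA end → polyA start) and translates from the native
start. The upstream product ends at the T2A skip before the final
proline (…NPG); the downstream product is GAL4 with an added N-terminal
proline — the standard 2A convention, configurable as a label only.
Transcription is modelled as terminating exactly at the cassette polyA;
polyA read-through ("masking") and SA exon skipping are real biological
escape routes that are *not* simulated and are attached to every
prediction as caveats. In-frame ⇔ sense orientation and cassette phase =
intron phase; the premature-stop verdict comes from the actual
translation, and the synthetic cassettes' linker is constructed so both
shifted frames stop inside it.

Validation PCR plans two reactions against the constant attP-R primer
(`CCCCAGTTGGGGC`), which binds the two inverted attP repeats facing
outward: a gene-specific forward primer 100–400 bp upstream of the left
arm, and a reverse primer mirrored on the right. Gene-specific primers
use the same Wallace heuristic; expected amplicon sizes are computed by
coordinate arithmetic on the edited allele and cross-checked against a
naive exact-match in-silico PCR; wild type must yield no product, and an
attP-R site in the wild-type window is a hard error. Primer-site matching
is exact (no mismatch tolerance).

## The synthetic fixtures

The generator emulates multi-isoform protein-coding genes on both strands
with CDS introns of controlled lengths (menu 80/100/101/150/300/5000 bp)
and all three phases, plus intergenic background with controlled motif
content. Ten fixed scenario genes cover the decision space — intronless;
shared intron at exactly 100 bp (ineligible) and 101 bp (eligible); Gold,
Silver (3/4), Bronze (2/5) and the exactly-50% boundary; a span-shared
phase-mismatch gene; a minus-strand gene; a long-intron gene with a
planted BbsI site 800 bp from the planted cut (exercising arm
shortening) — and filler genes scale the genome to any size. Planted
protospacers (one with its seed duplicated on a second contig, under a
different NGG) pin the uniqueness logic. CDS sequence is drawn codon-wise
from the 61 non-stop codons; intron/intergenic background is scrubbed of
enzyme sites, attP-R sites and accidental seed duplicates by
deterministic single-base edits restricted to intron interiors and
intergenic spans, with a salt-and-retry fallback when a motif lands
entirely in immutable sequence — so the recorded truth table holds for
any seed, and identical (config, seed) give byte-identical FASTA, GFF3,
GenBank and JSON.

What the fixtures do **not** emulate: real base composition beyond
uniform GC, splice-site strength, repeats, heterozygosity, chromatin, or
genome-scale size. Passing tests therefore demonstrate the correctness of
the design calculus (coordinates, phases, set logic, digestion/ligation
string algebra, frame arithmetic), not guide efficacy or HDR efficiency
on real genomes. Cassette stand-ins use canonical motif lengths (34-nt
FRT, 54-nt T2A, ~50-nt attP placeholder embedding the attP-R site) so
length arithmetic is realistic, but they are labelled synthetic and are
not the published plasmid sequences, which are treated as user-supplied
inputs.

## Numerical and scale choices

Everything is exact string/integer computation; there are no tolerances
beyond float equality on transcript fractions (ratios of small
integers). Determinism is part of the contract: no randomness outside the
seeded generators, fixed GenBank LOCUS date, sorted outputs. Verification
sizes — three 50-gene genomes for truth-table recovery, one ~100-kb
contig for full-scan oracle comparisons, 100 random circular molecules
for the digest/ligate inverse property, twelve random cut positions plus
all planted ones for the arm-search oracle — were chosen so the whole
suite exercises every branch while remaining a desk-scale computation.

The eligibility filter applies unchanged to a real genome: load the
FASTA + GFF3 release, call `eligible_genes`, and the report enumerates
all qualifying genes; runtime is dominated by gffutils database
construction. No real-genome data ships with the package.

## Known limitations

- Off-target assessment is exact-seed counting only; no mismatch-tolerant
  scoring, no efficiency model.
- Golden Gate fidelity is idealized (exact complements, no ligase bias);
  ambiguity detection is combinatorial, not thermodynamic.
- The carrier/vector models are abstractions parameterized by the chosen
  enzyme; real recipient plasmids should be supplied as GenBank files.
- Single-insertion alleles only; no multi-copy or concatemer outcomes.
- Annotation is trusted as given: no repair of malformed gene models, no
  trans-splicing, no selenocysteine recoding.
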