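# introntrap

Design and in-silico verification of **intronic T2A-GAL4 gene-trap
knock-ins** (CRIMIC-style) for *Drosophila*-type annotated genomes.

A gene trap of this family inserts a swappable
`attP-FRT-SA-T2A-GAL4-polyA-3xP3-EGFP-FRT-attP` cassette into a coding
intron by CRISPR/Cas9-directed homologous recombination. The splice
acceptor (SA) captures the gene's upstream exons, the polyA arrests
transcription (a strong loss-of-function allele), and the T2A ribosomal
skip releases GAL4 under the gene's own regulatory control. For the trap
to work in every isoform, the target intron must be a **coding intron
shared — identical span and reading-frame phase — by all isoforms**, and
the cassette must carry the matching **phase** (upstream CDS length mod 3,
one of 0/1/2).

`introntrap` implements the full design calculus around that idea:

- **genome_model** — FASTA + GFF3 (FlyBase-dialect) loading; per-transcript
  coding introns with phases; shared-intron computation.
- **eligibility** — the target filter (≥ 1 shared coding intron strictly
  > 100 bp), per-site **Gold / Silver / Bronze** tiers (tags all / > 50% /
  ≤ 50% of transcripts), and DIOPT-style ortholog-score prioritization
  (score ≥ 4 partition).
- **guide_design** — SpCas9 sgRNA enumeration inside the intron (NGG PAM,
  blunt cut 3 bp 5′ of the PAM), genome-wide **seed uniqueness**
  (PAM-proximal 13 nt + NGG, both strands), deterministic ranking.
- **arm_design** — homology arms of 500–1200 bp (target ~1 kb), inter-arm
  gap < 40 bp, free of the chosen Golden Gate enzyme (BbsI/BsaI/BsmBI);
  Type IIS-tailed cloning primers with a documented Wallace-rule Tm
  heuristic.
- **construct_assembly** — cassette topology models (pM14/pM36/pM37-like),
  Type IIS digestion with explicit 4-nt overhangs, Golden Gate ligation
  with ambiguity detection, donor plasmid assembly, GenBank I/O.
- **allele_sim** — the edited allele after HDR, FLP/FRT excision
  (attP-FRT-attP scar), RMCE orientation/phase logic for converting
  pre-existing intronic docking-site insertions, truncated-transcript /
  T2A-fusion prediction by direct translation, and validation-PCR plans
  using the constant attP-R primer `5'-CCCCAGTTGGGGC-3'`.
- **fixtures** — a deterministic synthetic genome + cassette generator
  with a machine-readable truth table covering the whole decision space.

## Worked example

Generate the synthetic fixture genome and design a trap for the fixture
gene `gGold150` (two identical isoforms, one shared 150-bp phase-1
intron):

```bash
introntrap fixtures make --outdir demo
introntrap design demo/genome.fa demo/genome.gff3 gGold150 \
    --cassette demo/pM37like_p1.gb --outdir demo/design
```

`demo/design/report.txt` begins:

```
# introntrap design report: gGold150

site: intron [5748,5897] (1-based) length 150 phase 1 tier Gold (tags 1.00 of transcripts)
guide: TGGTTGCCACCTCGAATACT TGG strand - cut 5832 (of 5 candidates)
enzyme: BbsI; arms 1000+1000 bp, gap 0 bp
donor: 2867 bp circular, 13 features
fusion: in_frame=True premature_stop=False product=GAL4 (with N-terminal proline)
validation left-junction: CTCGGAGTACGCTGTGTTA x attP-R -> 1152 bp (wild-type: no product)
validation right-junction: CATAGCTATTGACGGATCTTT x attP-R -> 1154 bp (wild-type: no product)
```

Reading the numbers: the chosen intron is shared by both isoforms with
matching phase, so the site is *Gold* (fraction 1.00) and the phase-1
cassette restores the frame — `in_frame=True` with no premature stop, so
the predicted products are the truncated native N-terminal peptide
(released at the T2A, ending …NPG) plus free GAL4 with an added
N-terminal proline. The sgRNA shown is the unique-seed candidate whose
blunt cut at contig position 5832 is farthest from the splice sites. Both
homology arms hit the 1-kb target with a 0-bp gap and contain no BbsI
site, so BbsI (first in the preference order) runs the one-pot Golden
Gate; the 2867-bp circular donor is written to `donor.gb` and contains
zero surviving BbsI sites. The two validation reactions pair outward
gene-specific primers with attP-R and predict exact junction amplicons on
the edited allele (1152/1154 bp) and no product on wild type.

The run also writes `allele.gb` (edited locus), `excised.gb` (the
FLP-reverted allele, which differs from wild type only by the < 40-bp
deleted gap and the attP-FRT-attP scar), `primers.tsv` and
`validation.tsv`. Exit codes are stable: 0 success, 2 ineligible gene,
3 infeasible constraints, 1 internal error.

The same machinery is available as a library:

```python
import introntrap as it
genome, truth = it.make_synthetic_genome()
cassette = it.make_cassette_standins()["pM37-like-p1"]
bundle = it.run_design(genome, "gGold150", cassette)
print(bundle.report())
```

## Scope notes

Wet-lab outcomes (injection survival, lethality, rescue), sgRNA
efficiency scoring, and Primer3-grade thermodynamics are out of scope;
see `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
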