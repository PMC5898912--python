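"""End-to-end design pipeline: eligibility -> guide -> arms/enzyme -> donor ->
edited allele -> excision -> fusion -> validation plan, plus the design report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import allele_sim, arm_design, construct_assembly, eligibility, guide_design
from .allele_sim import (EditedAllele, FusionPrediction, ValidationPlan,
                         plan_validation_pcr, predict_fusion,
                         predict_insertion_allele, simulate_flp_excision)
from .arm_design import design_gga_primers
from .config import RunConfig
from .construct_assembly import (AssemblyProduct, CassetteSpec, DonorDesign,
                                 VectorSpec, build_donor,
                                 plan_junction_overhangs, write_genbank)
from .errors import DesignError, IneligibleGeneError
from .fixtures import make_vector
from .genome_model import AnnotatedGenome

log = logging.getLogger(__name__)


@dataclass
class DesignBundle:
    """Everything one design run produces."""

    gene_id: str
    config: RunConfig
    classification: eligibility.SiteClassification
    guide: guide_design.GuideCandidate
    n_guide_candidates: int
    design: DonorDesign
    donor: AssemblyProduct
    allele: EditedAllele
    excised: EditedAllele | None
    fusion: FusionPrediction
    validation: ValidationPlan
    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def report(self) -> str:
        lines = [f"# introntrap design report: {self.gene_id}", ""]
        c = self.classification
        lines.append(f"site: intron [{c.intron.start + 1},{c.intron.end}] "
                     f"(1-based) length {c.intron.length} phase {c.intron.phase} "
                     f"tier {c.tier} (tags {c.tagged_fraction:.2f} of transcripts)")
        g = self.guide
        lines.append(f"guide: {g.protospacer} {g.pam} strand {g.strand} "
                     f"cut {g.cut_position} (of {self.n_guide_candidates} candidates)")
        d = self.design
        lines.append(f"enzyme: {d.enzyme.name}; arms "
                     f"{d.arm_left.length}+{d.arm_right.length} bp, gap "
                     f"{d.arm_right.start - d.arm_left.end} bp")
        lines.append(f"donor: {len(self.donor.sequence)} bp circular, "
                     f"{len(self.donor.features)} features")
        lines.append(f"fusion: in_frame={self.fusion.in_frame} "
                     f"premature_stop={self.fusion.premature_stop} "
                     f"product={self.fusion.downstream_product_start}")
        for r in self.validation.reactions:
            lines.append(f"validation {r.name}: {r.gene_primer} x attP-R -> "
                         f"{r.expected_edited_bp} bp (wild-type: {r.expected_wildtype})")
        lines.append("")
        lines.append("## constraint checks")
        for name, ok, detail in self.checks:
            lines.append(f"[{'PASS' if ok else 'FAIL'}] {name}: {detail}")
        lines.append("")
        lines.append("## effective configuration")
        lines.append(self.config.to_yaml().rstrip())
        lines.append("")
        return "\n".join(lines)


def run_design(genome: AnnotatedGenome, gene_id: str, cassette: CassetteSpec,
               config: RunConfig | None = None,
               vector: VectorSpec | None = None) -> DesignBundle:
    """Design a gene-trap knock-in for one gene end to end.

    Raises IneligibleGeneError (exit 2) when the gene fails the intron
    filter and InfeasibleConstraintError (exit 3) when no guide/arm/enzyme
    combination satisfies the constraints.
    """
    cfg = config or RunConfig()
    gene = genome.gene(gene_id)

    report = eligibility.eligible_genes(genome, min_intron_bp=cfg.min_intron_bp,
                                        shared_mode=cfg.shared_mode)
    if gene_id not in report.best_intron:
        raise IneligibleGeneError(
            f"{gene_id}: no shared coding intron longer than {cfg.min_intron_bp} bp "
            "— the gene cannot be trapped by this strategy")
    intron = report.best_intron[gene_id]
    classification = eligibility.classify_site(gene, intron,
                                               include_noncoding=cfg.include_noncoding)
    log.info("eligibility\t%s intron=[%d,%d) phase=%d tier=%s", gene_id,
             intron.start, intron.end, intron.phase, classification.tier)

    candidates = guide_design.enumerate_guides(
        genome, intron, min_splice_clearance=cfg.min_splice_clearance,
        seed_len=cfg.seed_len)
    candidates = [guide_design.check_seed_uniqueness(g, genome, seed_len=cfg.seed_len)
                  for g in candidates]
    ranked = guide_design.rank_guides(candidates)
    unique = [g for g in ranked if g.seed_unique]
    if not unique:
        from .errors import InfeasibleConstraintError
        raise InfeasibleConstraintError(
            f"{gene_id}: no sgRNA with a unique seed inside the chosen intron")
    guide = unique[0]
    log.info("guide\t%s cut=%d strand=%s", guide.protospacer, guide.cut_position,
             guide.strand)

    # cassette phase must match the intron (trap stock labels map 1:1 by default)
    if cassette.phase is not None and cassette.phase != intron.phase:
        log.warning("cassette phase %s != intron phase %d", cassette.phase,
                    intron.phase)

    # the synthetic receiving backbone is built enzyme-free for whichever
    # enzyme wins, so only the cassette body constrains the enzyme choice here;
    # a user-supplied vector is validated by the assembly step itself
    enzyme, arm_l, arm_r = arm_design.design_arms_and_enzyme(
        genome, intron.contig, guide.cut_position, cassette.sequence, "",
        min_len=cfg.arm_min_bp, max_len=cfg.arm_max_bp,
        target_len=cfg.arm_target_bp, max_gap=cfg.max_gap_bp,
        enzymes=tuple(cfg.enzyme_preference))
    vec = vector or make_vector(enzyme, (cfg.overhangs[3], cfg.overhangs[0]))
    log.info("arms\t%s left=[%d,%d) right=[%d,%d)", enzyme.name, arm_l.start,
             arm_l.end, arm_r.start, arm_r.end)

    junctions = plan_junction_overhangs(cfg.overhangs, gene.strand)
    pair_l = design_gga_primers(arm_l, enzyme, junctions["left"],
                                min_tm=cfg.min_tm_c, min_len=cfg.primer_min_len,
                                max_len=cfg.primer_max_len)
    pair_r = design_gga_primers(arm_r, enzyme, junctions["right"],
                                min_tm=cfg.min_tm_c, min_len=cfg.primer_min_len,
                                max_len=cfg.primer_max_len)

    design = DonorDesign(
        contig=intron.contig, cut_position=guide.cut_position,
        gene_strand=gene.strand, intron=intron, arm_left=arm_l, arm_right=arm_r,
        enzyme=enzyme, cassette=cassette, vector=vec, primers_left=pair_l,
        primers_right=pair_r, overhangs=cfg.overhangs)
    donor = build_donor(design)
    allele = predict_insertion_allele(genome, design, flank=cfg.allele_flank_bp)
    try:
        excised = simulate_flp_excision(allele)
    except DesignError:
        excised = None
    fusion = predict_fusion(allele, gene.transcripts[0], genome=genome)
    validation = plan_validation_pcr(
        allele, genome, primer_min_dist=cfg.val_primer_min_dist,
        primer_max_dist=cfg.val_primer_max_dist, min_tm=cfg.min_tm_c,
        primer_min_len=cfg.primer_min_len, primer_max_len=cfg.primer_max_len)

    bundle = DesignBundle(
        gene_id=gene_id, config=cfg, classification=classification, guide=guide,
        n_guide_candidates=len(candidates), design=design, donor=donor,
        allele=allele, excised=excised, fusion=fusion, validation=validation)
    bundle.checks = _constraint_checks(bundle)
    return bundle


def _constraint_checks(b: DesignBundle) -> list[tuple[str, bool, str]]:
    from .enzymes import find_sites
    d, cfg = b.design, b.config
    gap = d.arm_right.start - d.arm_left.end
    checks = [
        ("intron length", d.intron.length > cfg.min_intron_bp,
         f"{d.intron.length} bp > {cfg.min_intron_bp} bp"),
        ("guide seed unique", bool(b.guide.seed_unique), b.guide.seed),
        ("arm lengths", all(cfg.arm_min_bp <= a.length <= cfg.arm_max_bp
                            for a in (d.arm_left, d.arm_right)),
         f"{d.arm_left.length}/{d.arm_right.length} in "
         f"[{cfg.arm_min_bp},{cfg.arm_max_bp}]"),
        ("arm gap", 0 <= gap <= cfg.max_gap_bp, f"{gap} bp < {cfg.max_gap_bp + 1}"),
        ("arms free of assembly enzyme",
         not find_sites(d.arm_left.sequence + d.arm_right.sequence, d.enzyme),
         d.enzyme.name),
        ("donor free of assembly enzyme",
         not find_sites(b.donor.sequence, d.enzyme), d.enzyme.name),
        ("cassette phase matches intron",
         d.cassette.phase is None or d.cassette.phase == d.intron.phase,
         f"cassette {d.cassette.phase} vs intron {d.intron.phase}"),
        ("fusion in frame", b.fusion.in_frame, b.fusion.downstream_product_start),
        ("validation reactions", len(b.validation.reactions) == 2,
         "; ".join(f"{r.name}={r.expected_edited_bp}bp"
                   for r in b.validation.reactions)),
    ]
    return checks


def write_bundle(bundle: DesignBundle, outdir) -> list[str]:
    """Write all artifacts of a design run; returns the file list."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = []

    def out(name):
        p = os.path.join(outdir, name)
        paths.append(p)
        return p

    with open(out("report.txt"), "w") as fh:
        fh.write(bundle.report())
    write_genbank(out("donor.gb"), bundle.donor.sequence, bundle.donor.features,
                  name="donor", topology="circular",
                  description=f"donor plasmid for {bundle.gene_id}")
    write_genbank(out("allele.gb"), bundle.allele.sequence, bundle.allele.features,
                  name="edited_allele", topology="linear",
                  description=f"edited locus window for {bundle.gene_id}")
    if bundle.excised is not None:
        write_genbank(out("excised.gb"), bundle.excised.sequence,
                      bundle.excised.features, name="excised_allele",
                      topology="linear",
                      description=f"FLP-excised locus window for {bundle.gene_id}")
    with open(out("primers.tsv"), "w") as fh:
        fh.write("name\tsequence\ttail\tpriming\ttm_c\n")
        for pair in (bundle.design.primers_left, bundle.design.primers_right):
            for p in (pair.forward, pair.reverse):
                fh.write(f"{p.name}\t{p.sequence}\t{p.tail}\t{p.priming}\t"
                         f"{p.tm_c:.1f}\n")
    with open(out("validation.tsv"), "w") as fh:
        fh.write("reaction\tgene_primer\tcassette_primer\texpected_edited_bp\t"
                 "expected_wildtype\n")
        for r in bundle.validation.reactions:
            fh.write(f"{r.name}\t{r.gene_primer}\t{r.cassette_primer}\t"
                     f"{r.expected_edited_bp}\t{r.expected_wildtype}\n")
    return paths
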