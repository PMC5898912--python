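"""Run configuration: every tunable with its default, YAML round-trip, and
the serialized form embedded in design reports for reproducibility."""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field

import yaml

from .fixtures import DEFAULT_OVERHANGS


@dataclass
class RunConfig:
    # eligibility
    min_intron_bp: int = 100          # shared coding intron must be strictly longer
    shared_mode: str = "exact"        # exact | overlap (sensitivity alternative)
    include_noncoding: bool = False   # count CDS-less transcripts in tier denominators
    min_ortholog_score: int = 4       # inclusive priority threshold
    # guides
    seed_len: int = 13                # PAM-proximal bases in the uniqueness query
    min_splice_clearance: int = 50    # bp between cut and each splice site
    # arms
    arm_min_bp: int = 500
    arm_max_bp: int = 1200
    arm_target_bp: int = 1000
    max_gap_bp: int = 39              # genomic bases deleted by HDR, strictly < 40
    enzyme_preference: tuple[str, ...] = ("BbsI", "BsaI", "BsmBI")
    # primers
    min_tm_c: float = 58.0            # Wallace-rule threshold
    primer_min_len: int = 18
    primer_max_len: int = 25
    # assembly
    overhangs: tuple[str, str, str, str] = DEFAULT_OVERHANGS
    # allele simulation / validation
    allele_flank_bp: int = 500
    val_primer_min_dist: int = 100    # gene-specific validation primer window
    val_primer_max_dist: int = 400
    phase_label_mapping: str = "identity"   # trap stock phase label == intron phase

    @classmethod
    def results_preset(cls) -> "RunConfig":
        """Alternative arm bounds (~500-1000 bp) sometimes used for this donor
        family, in place of the default 500-1200 bp."""
        return cls(arm_max_bp=1000, arm_target_bp=1000)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                v = data[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def setup_logging(verbose: bool = False) -> None:
    """Stage-tagged, machine-parsable log lines on stderr."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s\t%(levelname)s\t%(name)s\t%(message)s")
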