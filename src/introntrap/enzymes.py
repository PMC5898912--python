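"""Type IIS enzyme specifications and recognition-site scanning.

The cut-geometry table ships as editable package data
(``data/enzymes.tsv``); recognition-site scans are IUPAC-aware and always
cover both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .seqtools import find_matches, revcomp

#: Fixed, documented preference order for Golden Gate enzyme selection.
DEFAULT_PREFERENCE = ("BbsI", "BsaI", "BsmBI")


@dataclass(frozen=True)
class EnzymeSpec:
    """A Type IIS enzyme cutting outside its recognition site.

    ``cut_offset_top``/``cut_offset_bottom`` count nucleotides from the 3'
    end of the top-strand recognition motif to the top/bottom strand cuts;
    the difference is the (5') overhang length.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self):
        if self.cut_offset_top <= 0 or self.cut_offset_bottom <= 0:
            raise ValueError(f"{self.name}: Type IIS offsets must be positive")

    @property
    def overhang_len(self) -> int:
        return abs(self.cut_offset_bottom - self.cut_offset_top)

    @property
    def site_len(self) -> int:
        return len(self.recognition)


@lru_cache(maxsize=1)
def load_enzyme_table() -> dict[str, EnzymeSpec]:
    text = (resources.files("introntrap") / "data" / "enzymes.tsv").read_text()
    table = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, recog, top, bottom = line.split("\t")
        table[name] = EnzymeSpec(name=name, recognition=recog.upper(),
                                 cut_offset_top=int(top), cut_offset_bottom=int(bottom))
    return table


def get_enzyme(name: str) -> EnzymeSpec:
    table = load_enzyme_table()
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; known: {sorted(table)}") from None


def find_sites(seq: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    """All recognition-site occurrences of *enzyme* in *seq*, both strands.

    Returns (start, strand); a '-' hit at start s means the reverse
    complement of the recognition motif occupies seq[s:s+site_len].
    """
    hits = [(p, "+") for p in find_matches(seq, enzyme.recognition)]
    rc = revcomp(enzyme.recognition)
    if rc != enzyme.recognition:
        hits += [(p, "-") for p in find_matches(seq, rc)]
    return sorted(hits)


def is_site_free(seq: str, enzyme: EnzymeSpec) -> bool:
    return not find_sites(seq, enzyme)
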