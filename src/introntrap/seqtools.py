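"""Low-level nucleotide-string helpers shared across modules.

All sequences are plain uppercase Python strings over the IUPAC DNA
alphabet; coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import re
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

IUPAC_LETTERS = frozenset(IUPAC)

CODON_TABLE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        for _k, _c in enumerate(_BASES):
            CODON_TABLE[_a + _b + _c] = _AA[_i * 16 + _j * 4 + _k]

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC motif into a regex character-class pattern."""
    parts = []
    for ch in pattern.upper():
        expansion = IUPAC.get(ch)
        if expansion is None:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}")
        parts.append(expansion if len(expansion) == 1 else f"[{expansion}]")
    return "".join(parts)


def find_matches(seq: str, pattern: str) -> list[int]:
    """Start positions of all (overlapping) IUPAC-pattern matches on the given strand."""
    rx = re.compile(f"(?=({iupac_regex(pattern)}))")
    return [m.start() for m in rx.finditer(seq)]


def find_matches_both_strands(seq: str, pattern: str) -> list[tuple[int, str]]:
    """All (start, strand) occurrences of an IUPAC motif, counting both strands.

    A '-' strand hit at start *s* means the reverse complement of the motif
    occurs at seq[s:s+len(pattern)].
    """
    hits = [(p, "+") for p in find_matches(seq, pattern)]
    rc = revcomp(pattern)
    if rc != pattern.upper():
        hits += [(p, "-") for p in find_matches(seq, rc)]
    else:  # palindromic motif: one physical site per position
        hits = [(p, "+") for p in find_matches(seq, pattern)]
    return sorted(hits)


def translate(seq: str) -> str:
    """Translate codons to amino acids; trailing partial codon ignored; stop = '*'."""
    n = len(seq) - len(seq) % 3
    return "".join(CODON_TABLE.get(seq[i:i + 3], "X") for i in range(0, n, 3))


def wallace_tm(primer: str) -> float:
    """Wallace-rule melting temperature: 2*(A+T) + 4*(G+C), in deg C."""
    gc = primer.count("G") + primer.count("C")
    at = primer.count("A") + primer.count("T")
    return 2.0 * at + 4.0 * gc


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def least_rotation(s: str) -> str:
    """Lexicographically least rotation (Booth's algorithm), O(n)."""
    if not s:
        return s
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k:k + len(s)]


def circular_equal(a: str, b: str) -> bool:
    """True when two circular double-stranded molecules are the same, up to
    rotation and strand choice."""
    if len(a) != len(b):
        return False
    ca = min(least_rotation(a), least_rotation(revcomp(a)))
    cb = min(least_rotation(b), least_rotation(revcomp(b)))
    return ca == cb


def chunked_fasta(seq: str, width: int = 70) -> Iterator[str]:
    for i in range(0, len(seq), width):
        yield seq[i:i + width]
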