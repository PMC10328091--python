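"""Low-level nucleotide helpers shared across the package.

Everything here operates on plain upper-case strings over {A,C,G,T,N} (plus
IUPAC degeneracy codes where explicitly allowed) and on the compact uint8
encoding used by the windowed search.
"""

from __future__ import annotations

import re

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# IUPAC degeneracy codes keyed by the set of bases they cover.
IUPAC_BY_BASES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
BASES_BY_IUPAC = {code: bases for bases, code in IUPAC_BY_BASES.items()}

# uint8 encoding: A=0 C=1 G=2 T=3 N=4
_ENC_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC_TABLE[ord(_b)] = _i
N_CODE = 4


def revcomp(seq: str) -> str:
    """Reverse complement, preserving N and IUPAC codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def validate_dna(seq: str, *, where: str = "sequence") -> str:
    """Upper-case and check a sequence against {A,C,G,T,N}.

    Returns the folded sequence; raises ValueError naming the first offending
    position otherwise.
    """
    folded = seq.upper()
    for i, ch in enumerate(folded):
        if ch not in DNA_ALPHABET:
            raise ValueError(
                f"non-DNA character {ch!r} at position {i + 1} in {where}"
            )
    return folded


def encode(seq: str) -> np.ndarray:
    """Encode an {A,C,G,T,N} string as uint8 codes (A=0..T=3, N=4)."""
    arr = _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = int(np.argmax(arr == 255))
        raise ValueError(f"cannot encode character {seq[bad]!r} at position {bad + 1}")
    return arr


def iupac_regex(motif: str) -> re.Pattern:
    """Compile a degenerate motif to a regex with one character class per code."""
    parts = []
    for ch in motif.upper():
        if ch not in BASES_BY_IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
        bases = "".join(sorted(BASES_BY_IUPAC[ch]))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def find_motif(seq: str, motif: str):
    """Yield start positions of (possibly overlapping) motif matches on seq."""
    pat = iupac_regex(motif)
    pos = 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            return
        yield m.start()
        pos = m.start() + 1
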