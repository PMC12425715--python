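"""Small DNA utilities shared across modules."""

from __future__ import annotations

import re

from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")

# IUPAC degenerate codes used by the AID hotspot motifs.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "R": "AG", "Y": "CT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

STOP_CODONS = {"TAA", "TAG", "TGA"}


def check_dna(seq: str, *, allow_n: bool = True) -> str:
    """Uppercase and validate a DNA string; raise ValueError otherwise."""
    s = seq.upper()
    allowed = DNA_ALPHABET if allow_n else DNA_ALPHABET - {"N"}
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate frame 0, truncating a trailing partial codon."""
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def has_inframe_stop(seq: str) -> bool:
    return "*" in translate(seq)


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal lengths")
    return sum(x != y or x == "N" for x, y in zip(a, b))


def iupac_match(base: str, code: str) -> bool:
    """True if a concrete base satisfies an IUPAC code. N never matches."""
    return base in IUPAC.get(code, "")


def find_motif(seq: str, motif: str) -> list[int]:
    """All start offsets (possibly overlapping) of an IUPAC motif."""
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        if all(iupac_match(seq[i + k], motif[k]) for k in range(len(motif))):
            hits.append(i)
    return hits


J_ANCHOR_RE = re.compile(r"[FW]G.G")


def find_j_anchor(aa: str) -> int:
    """Offset of the J anchor [FW]GXG in a protein string, or -1."""
    m = J_ANCHOR_RE.search(aa)
    return m.start() if m else -1
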