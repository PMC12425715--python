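"""Read-level quality gates applied before V(D)J assignment.

A rearranged amplicon read with a complete structure (barcode +
upstream primer + leader + V + junction + J + partial C + downstream
primer) exceeds 400 bp, so shorter reads are discarded as likely
incomplete; reads must also carry both amplification primers.
Primer matching is Hamming-only (no indels): 5'RACE universal and
gene-specific primers are short and high fidelity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from ovig.dna import hamming, revcomp
from ovig.types import Read

DEFAULT_MIN_LEN = 400
DEFAULT_WINDOW = 60
DEFAULT_PRIMER_MM = 2

REASONS = ("too_short", "missing_fwd_primer", "missing_rev_primer")


@dataclass
class FilterReport:
    kept: int = 0
    rejected: Counter = None

    def __post_init__(self):
        if self.rejected is None:
            self.rejected = Counter()

    @property
    def total(self) -> int:
        return self.kept + sum(self.rejected.values())


def _find_primer(seq: str, primer: str, max_mm: int) -> Optional[int]:
    """Leftmost Hamming match offset of primer within seq, else None."""
    m = len(primer)
    for i in range(len(seq) - m + 1):
        if hamming(seq[i : i + m], primer) <= max_mm:
            return i
    return None


def filter_reads(
    reads: Iterable[Read],
    forward_primer: str,
    reverse_primer: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_primer_mismatches: int = DEFAULT_PRIMER_MM,
    window: int = DEFAULT_WINDOW,
    barcode_trim: int = 0,
) -> tuple[list[Read], FilterReport]:
    """Apply the length and primer gates; return kept (trimmed) reads.

    Gates in order: (1) raw length >= min_len; (2) forward primer
    within ``max_primer_mismatches`` inside the first ``window`` bases;
    (3) reverse complement of the reverse primer inside the last
    ``window`` bases. A read is charged to its first failing gate.
    Kept reads are trimmed to the insert between the primers;
    ``barcode_trim`` bases are removed from the 5' end before primer
    search (demultiplexing proper is out of scope).
    """
    if not forward_primer or not reverse_primer:
        raise ValueError("primers must be nonempty")
    if min_len < 0:
        raise ValueError("min_len must be nonnegative")
    rc_rev = revcomp(reverse_primer)
    kept: list[Read] = []
    report = FilterReport()
    for read in reads:
        seq = read.seq[barcode_trim:]
        qual = read.qual[barcode_trim:] if read.qual else None
        if len(seq) < min_len:
            report.rejected["too_short"] += 1
            continue
        head = seq[: window + len(forward_primer)]
        fwd_at = _find_primer(head, forward_primer, max_primer_mismatches)
        if fwd_at is None:
            report.rejected["missing_fwd_primer"] += 1
            continue
        tail_off = max(0, len(seq) - window - len(rc_rev))
        rev_at = _find_primer(seq[tail_off:], rc_rev, max_primer_mismatches)
        if rev_at is None:
            report.rejected["missing_rev_primer"] += 1
            continue
        start = fwd_at + len(forward_primer)
        end = tail_off + rev_at
        kept.append(
            Read(read.id, seq[start:end], qual[start:end] if qual else None)
        )
        report.kept += 1
    return kept, report
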