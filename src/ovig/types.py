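"""Domain types shared by the annotation, repertoire and SHM modules.

Coordinates are 0-based half-open throughout; GFF3 output converts to
1-based inclusive on disk. Segments located on the minus strand store
their reverse-complemented coding sequence so that downstream code never
has to re-orient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# Ordered substitution types (germline base -> read base), the 12 cells
# of every mutation spectrum in the package.
SUBSTITUTION_TYPES: tuple[str, ...] = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)

TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3")


@dataclass(frozen=True)
class RssMatch:
    """One heptamer-spacer-nonamer hit.

    ``heptamer_start`` is the leftmost forward-strand coordinate of the
    heptamer regardless of strand. ``orientation`` records which side of
    a coding segment the RSS would flank: a plus-strand pattern reads
    heptamer-first away from a segment lying to its left
    (``downstream_of_segment``), a minus-strand pattern implies a
    segment to its right (``upstream_of_segment``).
    """

    heptamer_start: int
    spacer_len: int
    spacer_class: str  # "RSS12" | "RSS23"
    strand: str  # "+" | "-"
    heptamer_mismatches: int
    nonamer_mismatches: int
    orientation: str  # "downstream_of_segment" | "upstream_of_segment"

    @property
    def span(self) -> tuple[int, int]:
        """Forward-strand half-open interval covered by the full motif."""
        if self.strand == "+":
            return self.heptamer_start, self.heptamer_start + 16 + self.spacer_len
        end = self.heptamer_start + 7
        return end - 16 - self.spacer_len, end


@dataclass
class GeneSegment:
    """An annotated germline V/D/J/C element."""

    name: str
    locus: str  # IGH | IGK | IGL
    seg_type: str  # V | D | J | C
    start: int
    end: int
    strand: str = "+"
    functionality: str = "functional"  # functional | ORF | pseudogene
    rss: list[RssMatch] = field(default_factory=list)
    subgroup: Optional[int] = None
    # Anchor/codon bookkeeping (nt offsets within the stored coding
    # sequence): V carries the two conserved cysteines and FR/CDR
    # boundaries, J carries the [FW]GXG anchor codon.
    cys1_nt: Optional[int] = None
    cys2_nt: Optional[int] = None
    j_anchor_nt: Optional[int] = None
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.name}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GermlineReference:
    """A set of germline segments plus their coding sequences."""

    segments: list[GeneSegment]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s.name for s in self.segments if s.name not in self.sequences]
        if missing:
            raise ValueError(f"segments without sequence: {missing}")

    def by_type(self, seg_type: str, locus: Optional[str] = None) -> list[GeneSegment]:
        return [
            s
            for s in self.segments
            if s.seg_type == seg_type and (locus is None or s.locus == locus)
        ]

    def get(self, name: str) -> GeneSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def seq(self, name: str) -> str:
        return self.sequences[name]

    @property
    def locus_layout(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in sorted(self.segments, key=lambda x: (x.locus, x.start)):
            out.setdefault(s.locus, []).append(s.name)
        return out


@dataclass
class Read:
    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"{self.id}: quality length != sequence length")


@dataclass
class SegmentAlignment:
    """A gapless-interval summary of one segment-to-read alignment."""

    segment_name: str
    read_start: int
    read_end: int
    germ_start: int
    germ_end: int
    score: float
    identity: float
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    # gapless aligned blocks as (read_start, read_end, germ_start, germ_end)
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)


@dataclass
class JunctionDecomposition:
    """Deletions and P/N tracts of one junction.

    Heavy chains use both gaps (V-D and D-J); light chains use the
    single-gap fields ``p1``/``n1``/``p2`` with the D fields empty.
    """

    v3_del: int = 0
    p1: str = ""
    n1: str = ""
    p2: str = ""
    d5_del: int = 0
    d_seq: str = ""
    d3_del: int = 0
    p3: str = ""
    n2: str = ""
    p4: str = ""
    j5_del: int = 0
    flagged_overlap: bool = False

    @property
    def np1(self) -> str:
        return self.p1 + self.n1 + self.p2

    @property
    def np2(self) -> str:
        return self.p3 + self.n2 + self.p4


@dataclass
class Rearrangement:
    """One read's full interpretation."""

    read_id: str
    locus: str
    v_call: str
    j_call: str
    v_aln: SegmentAlignment
    j_aln: SegmentAlignment
    d_call: Optional[str] = None
    d_aln: Optional[SegmentAlignment] = None
    junction_nt: str = ""
    cdr3_nt: Optional[str] = None
    productive: bool = False
    sample_id: str = "sample"
    sequence: str = ""
    rev_comp: bool = False
    junction: Optional[JunctionDecomposition] = None
    cdr3_fail_reason: Optional[str] = None


@dataclass
class MutationProfile:
    """Per-position, per-substitution-type mutation counts over one germline V."""

    germline_name: str
    germline_seq: str
    per_position: np.ndarray  # shape (L, 12), counts per SUBSTITUTION_TYPES
    coverage: np.ndarray  # shape (L,)
    region_labels: list[str]  # per position, FR1..FR3 or ""
    hotspot_flags: list[tuple[str, ...]]  # per position, subset of {WRCY_C, RGYW_G}

    @property
    def length(self) -> int:
        return len(self.germline_seq)

    @property
    def total_mutations(self) -> int:
        return int(self.per_position.sum())


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic repertoire.

    Defaults emulate the measured ranges of a ruminant IgH repertoire:
    3'V deletions mostly 0-4 bp, 5'J deletions 0-12 bp, untemplated
    tracts a few bases, SHM ~2% per base with a transition-heavy
    spectrum and fivefold AID hotspot enrichment.
    """

    seed: int = 0
    n_reads: int = 1000
    locus: str = "IGH"
    sample_id: str = "sample1"
    usage_weights_v: Optional[dict[str, float]] = None
    usage_weights_d: Optional[dict[str, float]] = None
    usage_weights_j: Optional[dict[str, float]] = None
    # Truncated-geometric deletion laws, per end: success prob + cap.
    del_p_v3: float = 0.35
    del_p_d5: float = 0.35
    del_p_d3: float = 0.35
    del_p_j5: float = 0.25
    del_cap_v3: int = 32
    del_cap_d5: int = 8
    del_cap_d3: int = 8
    del_cap_j5: int = 12
    p_prob: float = 0.3
    p_len_max: int = 4
    n_p: float = 0.45  # geometric parameter of the P-length law on 1..p_len_max
    n_len_p: float = 0.3  # geometric parameter of the N-length law
    n_len_max: int = 12
    n_base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    shm_rate: float = 0.02
    shm_spectrum: Optional[dict[str, float]] = None
    hotspot_multiplier: float = 5.0
    seq_error_rate: float = 0.0
    fwd_primer: str = "AAGCAGTGGTATCAACGCAGAGT"
    rev_primer: str = "ACACCAGGGGGAAGACTCTCGGG"
    fraction_missing_primer: float = 0.0
    leader_len: int = 48
    c_stub_len: int = 60
    read_len_jitter: int = 0

    def validate(self) -> None:
        probs = {
            "del_p_v3": self.del_p_v3, "del_p_d5": self.del_p_d5,
            "del_p_d3": self.del_p_d3, "del_p_j5": self.del_p_j5,
            "p_prob": self.p_prob, "n_p": self.n_p, "n_len_p": self.n_len_p,
            "shm_rate": self.shm_rate, "seq_error_rate": self.seq_error_rate,
            "fraction_missing_primer": self.fraction_missing_primer,
        }
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must lie in [0,1], got {v}")
        for name, w in (
            ("usage_weights_v", self.usage_weights_v),
            ("usage_weights_d", self.usage_weights_d),
            ("usage_weights_j", self.usage_weights_j),
        ):
            if w is not None:
                if any(x < 0 for x in w.values()) or sum(w.values()) <= 0:
                    raise ValueError(f"{name} must be nonnegative and normalizable")
        if self.shm_spectrum is not None and sum(self.shm_spectrum.values()) <= 0:
            raise ValueError("shm_spectrum must be normalizable")


@dataclass
class TruthRecord:
    """Ground truth emitted per simulated read."""

    read_id: str
    v_name: str
    j_name: str
    d_name: Optional[str]
    v3_del: int
    d5_del: int
    d3_del: int
    j5_del: int
    p1: str
    n1: str
    p2: str
    p3: str
    n2: str
    p4: str
    mutations: list[tuple[str, int, str, str, bool]]  # (segment, germ_pos, from, to, hotspot)
    seq_errors: list[tuple[int, str, str]]  # (read_pos, from, to)
    productive: bool
    ambiguous_junction: bool
    has_fwd_primer: bool
    cdr3_nt: str
    leader: str = ""
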