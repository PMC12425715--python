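"""V, (D,) J assignment of rearranged reads against a germline reference.

Candidate genes are pre-screened by edit distance (edlib, infix mode;
ties by name) and the chosen segment is then aligned with affine-gap
local alignment (match +2, mismatch -2, open -6, extend -1), so calls
are reproducible and assignment stays fast at repertoire scale. After alignment the V 3' and J 5' boundaries
are refined by a gapless walk that extends by exact match and bridges
a mismatch only when a long run of matches follows — an isolated point
mutation inside the segment is tolerated, while extension past the
true junction by chance is effectively impossible. D (heavy chains
only) is the longest exact ungapped match of any germline D inside the
V-J gap, subject to a minimum length; below it the whole gap is
treated as untemplated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import edlib
from Bio import Align

from ovig.dna import revcomp, translate
from ovig.junction import (
    MIN_D_MATCH,
    find_best_d,
    germ_to_read,
    walk_backward,
    walk_forward,
)
from ovig.types import GermlineReference, Read, Rearrangement, SegmentAlignment

V_MIN_IDENTITY = 0.70
J_MIN_IDENTITY = 0.80
CAP_V3 = 32
CAP_J5 = 12
WALK_MARGIN = 16


@dataclass(frozen=True)
class AssignmentRejection:
    read_id: str
    reason: str  # no_v | low_v_identity | no_j | low_j_identity | ordering


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -2
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    return aligner


def _blocks_of(aln) -> list[tuple[int, int, int, int]]:
    return [
        (int(qs), int(qe), int(ts), int(te))
        for (qs, qe), (ts, te) in zip(aln.aligned[0], aln.aligned[1])
    ]


def _stats_from_blocks(
    read: str, germ: str, blocks: list[tuple[int, int, int, int]]
) -> tuple[float, list[tuple[int, str, str]], int, int]:
    """(identity, mutations, matches, columns) over gapless blocks.

    Columns include interior gap columns; mutations are the mismatched
    aligned pairs as (germline_pos, germline_base, read_base).
    """
    matches = columns = 0
    mutations: list[tuple[int, str, str]] = []
    for qs, qe, ts, te in blocks:
        for k in range(qe - qs):
            g, r = germ[ts + k], read[qs + k]
            columns += 1
            if g == r:
                matches += 1
            else:
                mutations.append((ts + k, g, r))
    for k in range(1, len(blocks)):
        columns += blocks[k][0] - blocks[k - 1][1]
        columns += blocks[k][2] - blocks[k - 1][3]
    identity = matches / columns if columns else 0.0
    return identity, mutations, matches, columns


def _align_segment(
    aligner, read: str, germ: str, name: str, read_offset: int = 0
) -> Optional[SegmentAlignment]:
    sub = read[read_offset:]
    alns = aligner.align(sub, germ)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    blocks = [
        (qs + read_offset, qe + read_offset, ts, te)
        for qs, qe, ts, te in _blocks_of(aln)
    ]
    identity, mutations, _, _ = _stats_from_blocks(read, germ, blocks)
    return SegmentAlignment(
        segment_name=name,
        read_start=blocks[0][0],
        read_end=blocks[-1][1],
        germ_start=blocks[0][2],
        germ_end=blocks[-1][3],
        score=float(aln.score),
        identity=identity,
        mutations=mutations,
        blocks=blocks,
    )


def _refine_v_end(aln: SegmentAlignment, read: str, germ: str, cap: int) -> None:
    """Re-fix the V 3' boundary by the exact-extension walk."""
    g0 = max(aln.germ_start, len(germ) - (cap + WALK_MARGIN))
    r0 = None
    while g0 < aln.germ_end:
        r0 = germ_to_read(aln, g0)
        if r0 is not None:
            break
        g0 += 1
    if r0 is None:
        return
    ext = walk_forward(read, r0, germ, g0)
    aln.blocks = [b for b in aln.blocks if b[2] < g0]
    aln.blocks = [
        (qs, min(qe, qs + (g0 - ts)), ts, min(te, g0)) for qs, qe, ts, te in aln.blocks
    ]
    if ext > 0:
        aln.blocks.append((r0, r0 + ext, g0, g0 + ext))
    elif not aln.blocks:
        aln.blocks = [(r0, r0, g0, g0)]
    aln.read_start = aln.blocks[0][0]
    aln.read_end = aln.blocks[-1][1]
    aln.germ_start = aln.blocks[0][2]
    aln.germ_end = aln.blocks[-1][3]
    stats = _stats_from_blocks(read, germ, aln.blocks)
    aln.identity, aln.mutations = stats[0], stats[1]


def _refine_j_start(aln: SegmentAlignment, read: str, germ: str, cap: int) -> None:
    """Re-fix the J 5' boundary by the leftward exact-extension walk."""
    g1 = min(cap + WALK_MARGIN, aln.germ_end)
    r1 = None
    while g1 > aln.germ_start:
        m = germ_to_read(aln, g1 - 1)
        if m is not None:
            r1 = m + 1
            break
        g1 -= 1
    if r1 is None:
        return
    ext = walk_backward(read, r1, germ, g1)
    tail = [b for b in aln.blocks if b[3] > g1]
    tail = [
        (max(qs, qe - (te - g1)), qe, max(ts, g1), te) for qs, qe, ts, te in tail
    ]
    blocks = []
    if ext > 0:
        blocks.append((r1 - ext, r1, g1 - ext, g1))
    blocks.extend(tail)
    if not blocks:
        blocks = [(r1, r1, g1, g1)]
    aln.blocks = blocks
    aln.read_start = blocks[0][0]
    aln.read_end = blocks[-1][1]
    aln.germ_start = blocks[0][2]
    aln.germ_end = blocks[-1][3]
    stats = _stats_from_blocks(read, germ, blocks)
    aln.identity, aln.mutations = stats[0], stats[1]


def assign_vdj(
    read: Read,
    reference: GermlineReference,
    locus: str = "IGH",
    sample_id: str = "sample",
    v_min_identity: float = V_MIN_IDENTITY,
    j_min_identity: float = J_MIN_IDENTITY,
    min_d_match: int = MIN_D_MATCH,
    cap_v3: int = CAP_V3,
    cap_j5: int = CAP_J5,
) -> Union[Rearrangement, AssignmentRejection]:
    """Assign germline V, (D,) J to one read.

    The read orientation is fixed by the better-scoring strand of the
    best V alignment; J is sought 3' of the refined V end; D within the
    V-J gap (IGH only). Returns an :class:`AssignmentRejection` when
    identity falls below threshold or ordering fails.
    """
    v_refs = reference.by_type("V", locus)
    j_refs = reference.by_type("J", locus)
    if not v_refs or not j_refs:
        raise ValueError(f"reference lacks V or J segments for locus {locus}")
    aligner = _make_aligner()

    def prescreen(seq: str, segs, read_offset: int = 0):
        """Cheapest-edit-distance candidate (infix mode), ties by name."""
        best = None
        sub = seq[read_offset:]
        if not sub:
            return None
        for seg in segs:
            d = edlib.align(reference.seq(seg.name), sub, mode="HW")[
                "editDistance"
            ]
            if d < 0:
                continue
            if best is None or (d, seg.name) < best[:2]:
                best = (d, seg.name)
        return best

    fwd = prescreen(read.seq, v_refs)
    rc_seq = revcomp(read.seq)
    rev = prescreen(rc_seq, v_refs)
    if fwd is None and rev is None:
        return AssignmentRejection(read.id, "no_v")
    use_rev = rev is not None and (fwd is None or rev[0] < fwd[0])
    seq = rc_seq if use_rev else read.seq
    v_name = (rev if use_rev else fwd)[1]
    v_aln = _align_segment(aligner, seq, reference.seq(v_name), v_name)
    if v_aln is None:
        return AssignmentRejection(read.id, "no_v")
    v_germ = reference.seq(v_aln.segment_name)
    _refine_v_end(v_aln, seq, v_germ, cap_v3)
    if v_aln.identity < v_min_identity:
        return AssignmentRejection(read.id, "low_v_identity")

    j_pick = prescreen(seq, j_refs, read_offset=v_aln.read_end)
    if j_pick is None:
        return AssignmentRejection(read.id, "no_j")
    j_aln = _align_segment(
        aligner, seq, reference.seq(j_pick[1]), j_pick[1],
        read_offset=v_aln.read_end,
    )
    if j_aln is None:
        return AssignmentRejection(read.id, "no_j")
    j_germ = reference.seq(j_aln.segment_name)
    _refine_j_start(j_aln, seq, j_germ, cap_j5)
    if j_aln.identity < j_min_identity:
        return AssignmentRejection(read.id, "low_j_identity")
    if j_aln.read_start < v_aln.read_end:
        return AssignmentRejection(read.id, "ordering")

    d_call = d_aln = None
    d_refs = reference.by_type("D", locus)
    if d_refs:
        middle = seq[v_aln.read_end : j_aln.read_start]
        hit = find_best_d(
            middle, {s.name: reference.seq(s.name) for s in d_refs}, min_d_match
        )
        if hit is not None:
            d_name, off, d0, k = hit
            rs = v_aln.read_end + off
            d_call = d_name
            d_aln = SegmentAlignment(
                segment_name=d_name,
                read_start=rs,
                read_end=rs + k,
                germ_start=d0,
                germ_end=d0 + k,
                score=float(2 * k),
                identity=1.0,
                blocks=[(rs, rs + k, d0, d0 + k)],
            )
    return Rearrangement(
        read_id=read.id,
        locus=locus,
        v_call=v_aln.segment_name,
        j_call=j_aln.segment_name,
        v_aln=v_aln,
        j_aln=j_aln,
        d_call=d_call,
        d_aln=d_aln,
        sample_id=sample_id,
        sequence=seq,
        rev_comp=use_rev,
    )


def infer_productivity(
    rearr: Rearrangement, reference: GermlineReference
) -> bool:
    """True iff V and J are in frame across the junction with no stop.

    Frame is anchored on the germline V reading frame; the check runs
    from the first complete V codon on the read through the J anchor
    codon. The result is stored on the rearrangement.
    """
    v_seg = reference.get(rearr.v_call)
    j_seg = reference.get(rearr.j_call)
    rearr.productive = False
    if v_seg.cys2_nt is None or j_seg.j_anchor_nt is None:
        return False
    if (
        rearr.v_aln.germ_end < v_seg.cys2_nt + 3
        or rearr.j_aln.germ_start > j_seg.j_anchor_nt
    ):
        return False  # an anchor codon is not fully retained
    cys2_read = germ_to_read(rearr.v_aln, v_seg.cys2_nt)
    anchor_read = germ_to_read(rearr.j_aln, j_seg.j_anchor_nt)
    if cys2_read is None or anchor_read is None or anchor_read <= cys2_read:
        return False
    off = (3 - rearr.v_aln.germ_start % 3) % 3
    t_start = rearr.v_aln.read_start + off
    if (cys2_read - t_start) % 3 != 0 or (anchor_read - cys2_read) % 3 != 0:
        return False
    window = rearr.sequence[t_start : anchor_read + 3]
    if "*" in translate(window):
        return False
    rearr.productive = True
    return True
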