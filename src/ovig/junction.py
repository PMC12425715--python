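"""Junction decomposition, CDR3 extraction and junction statistics.

The junction of a heavy-chain rearrangement is decomposed into the five
diversity factors: exonucleolytic deletion at the V 3' end, the
P1+N1+P2 tract, the retained D core, the P3+N2+P4 tract, and deletion
at the J 5' end; light chains use a single P1+N+P2 gap. P nucleotides
are short palindromic additions templated as the reverse complement of
an *undeleted* germline end read inward, so a P field can be nonempty
only when the abutting deletion is zero. Attribution is greedy
(maximal P before N, V side before J side), which is deterministic and
mirrors IMGT-style reporting; an exhaustive enumerator quantifies the
residual ambiguity.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from ovig.dna import revcomp, translate
from ovig.types import (
    GermlineReference,
    JunctionDecomposition,
    Rearrangement,
    SegmentAlignment,
)

P_CAP = 4
MIN_D_MATCH = 5
# Exonucleolytic trimming bounds the decomposer assumes, per end.
CAP_D5 = 8
CAP_D3 = 8

# Boundary-refinement walk scoring: a mismatch can only be bridged by a
# long run of downstream matches, so chance extension past the true
# junction is vanishingly rare while isolated point mutations inside
# the segment are tolerated.
WALK_MATCH = 1
WALK_MISMATCH = -7
WALK_XDROP = 21


def germ_to_read(aln: SegmentAlignment, gpos: int) -> Optional[int]:
    """Read position aligned to germline position ``gpos``, else None."""
    for qs, qe, ts, te in aln.blocks:
        if ts <= gpos < te:
            return qs + (gpos - ts)
    return None


def walk_forward(read: str, r0: int, germ: str, g0: int) -> int:
    """Gapless extension from (r0, g0); returns the matched length.

    The returned length is the argmax of the prefix score (earliest on
    ties), i.e. maximal exact extension when no mismatch is bridged.
    """
    best, best_len, score, i = 0, 0, 0, 0
    while r0 + i < len(read) and g0 + i < len(germ):
        score += WALK_MATCH if read[r0 + i] == germ[g0 + i] else WALK_MISMATCH
        i += 1
        if score > best:
            best, best_len = score, i
        if best - score > WALK_XDROP:
            break
    return best_len


def walk_backward(read: str, r1: int, germ: str, g1: int) -> int:
    """Mirror of :func:`walk_forward`, extending leftward from (r1, g1)."""
    best, best_len, score, i = 0, 0, 0, 0
    while r1 - 1 - i >= 0 and g1 - 1 - i >= 0:
        score += WALK_MATCH if read[r1 - 1 - i] == germ[g1 - 1 - i] else WALK_MISMATCH
        i += 1
        if score > best:
            best, best_len = score, i
        if best - score > WALK_XDROP:
            break
    return best_len


def maximal_p_split(
    gap: str,
    left_end: Optional[str],
    right_start: Optional[str],
    p_cap: int = P_CAP,
) -> tuple[str, str, str]:
    """Greedy (P_left, N, P_right) split of one untemplated gap.

    ``left_end`` / ``right_start`` are the abutting germline sequences
    when that end is undeleted, else None (no P possible there). P_left
    is the maximal prefix of the gap equal to the reverse complement of
    the left germline end read inward; P_right mirrors on the suffix.
    """
    p_left = ""
    if left_end:
        kmax = min(p_cap, len(gap), len(left_end))
        for k in range(kmax, 0, -1):
            if gap[:k] == revcomp(left_end[-k:]):
                p_left = gap[:k]
                break
    rem = gap[len(p_left):]
    p_right = ""
    if right_start:
        kmax = min(p_cap, len(rem), len(right_start))
        for k in range(kmax, 0, -1):
            if rem[len(rem) - k :] == revcomp(right_start[:k]):
                p_right = rem[len(rem) - k :]
                break
    n = rem[: len(rem) - len(p_right)]
    return p_left, n, p_right


def find_best_d(
    middle: str,
    d_refs: dict[str, str],
    min_match: int = MIN_D_MATCH,
    cap_d5: int = CAP_D5,
    cap_d3: int = CAP_D3,
) -> Optional[tuple[str, int, int, int]]:
    """Best ungapped D match inside the V-J gap.

    Returns (d_name, middle_offset, d_start, match_len) of the longest
    exact common substring of any D germline and the gap, requiring at
    least ``min_match`` bases and implied end deletions within the
    per-end trimming caps; ties break by name, then by smaller d_start,
    then by smaller offset. None when no D qualifies.
    """
    best = None
    for name in sorted(d_refs):
        d = d_refs[name]
        for off in range(len(middle)):
            for d0 in range(min(len(d), cap_d5 + 1)):
                k = 0
                while (
                    off + k < len(middle)
                    and d0 + k < len(d)
                    and middle[off + k] == d[d0 + k]
                ):
                    k += 1
                if k >= min_match and len(d) - (d0 + k) <= cap_d3:
                    key = (-k, name, d0, off)
                    if best is None or key < best[0]:
                        best = (key, (name, off, d0, k))
    return best[1] if best else None


def decompose_junction(
    rearr: Rearrangement,
    reference: GermlineReference,
    p_cap: int = P_CAP,
    min_d_match: int = MIN_D_MATCH,
) -> JunctionDecomposition:
    """Decompose one rearrangement's junction.

    Region boundaries are taken from the (refined) V and J alignments;
    the retained-D interval from the D alignment when present. The
    concatenation invariant — retained V + P/N tracts + retained D +
    P/N tracts + retained J reproduces the read — holds by
    construction because every tract is carved from the actual read.
    A V/J read-interval overlap is reported as a flagged zero-length
    junction rather than an exception.
    """
    read = rearr.sequence
    v_germ = reference.seq(rearr.v_call)
    j_germ = reference.seq(rearr.j_call)
    v3_del = len(v_germ) - rearr.v_aln.germ_end
    j5_del = rearr.j_aln.germ_start
    if rearr.v_aln.read_end > rearr.j_aln.read_start:
        return JunctionDecomposition(
            v3_del=v3_del, j5_del=j5_del, flagged_overlap=True
        )
    v_left = v_germ if v3_del == 0 else None
    j_right = j_germ if j5_del == 0 else None
    if rearr.d_call is not None and rearr.d_aln is not None:
        d_germ = reference.seq(rearr.d_call)
        d5_del = rearr.d_aln.germ_start
        d3_del = len(d_germ) - rearr.d_aln.germ_end
        gap1 = read[rearr.v_aln.read_end : rearr.d_aln.read_start]
        gap2 = read[rearr.d_aln.read_end : rearr.j_aln.read_start]
        d_seq = read[rearr.d_aln.read_start : rearr.d_aln.read_end]
        p1, n1, p2 = maximal_p_split(
            gap1, v_left, d_germ if d5_del == 0 else None, p_cap
        )
        p3, n2, p4 = maximal_p_split(
            gap2, d_germ if d3_del == 0 else None, j_right, p_cap
        )
        return JunctionDecomposition(
            v3_del=v3_del, p1=p1, n1=n1, p2=p2,
            d5_del=d5_del, d_seq=d_seq, d3_del=d3_del,
            p3=p3, n2=n2, p4=p4, j5_del=j5_del,
        )
    gap = read[rearr.v_aln.read_end : rearr.j_aln.read_start]
    p1, n1, p2 = maximal_p_split(gap, v_left, j_right, p_cap)
    return JunctionDecomposition(
        v3_del=v3_del, p1=p1, n1=n1, p2=p2, j5_del=j5_del
    )


# ---------------------------------------------------------------------------
# Exhaustive decomposition enumerator (oracle; also drives the
# simulator's ambiguity flag)
# ---------------------------------------------------------------------------


class Solution(NamedTuple):
    """One valid junction decomposition, lengths only."""

    d_name: Optional[str]
    v3_del: int
    d5_del: int
    d3_del: int
    j5_del: int
    p1: int
    n1: int
    p2: int
    p3: int
    n2: int
    p4: int


def enumerate_decompositions(
    window: str,
    v_germ: str,
    g_a: int,
    j_germ: str,
    g_b: int,
    d_refs: Optional[dict[str, str]],
    cap_v3: int = 32,
    cap_d5: int = 8,
    cap_d3: int = 8,
    cap_j5: int = 12,
    p_cap: int = P_CAP,
    min_d_match: int = MIN_D_MATCH,
    parsimony_only: bool = False,
) -> list[Solution]:
    """Valid decompositions of a junction window.

    ``window`` is the read slice running from germline-V position
    ``g_a`` to germline-J position ``g_b`` (exclusive), with both
    anchors lying safely inside the aligned, unmutated segments. Every
    combination of deletions (within caps), exact retained-D placement
    (>= ``min_d_match``; or no D) and the greedy maximal-P split is
    tested; solutions are distinct length-tuples. P lengths follow the
    same maximal-extension convention as the greedy decomposer.

    Because any solution can be degraded into another by deleting more
    germline into N, the full set grows combinatorially;
    ``parsimony_only`` restricts to the minimal-v3/minimal-j5 slice,
    which is what :func:`canonical_solutions` would keep anyway.
    """
    sols: set[Solution] = set()
    v_opts = []
    for v3 in range(0, min(cap_v3, len(v_germ) - g_a) + 1):
        vc = v_germ[g_a : len(v_germ) - v3]
        if window.startswith(vc):
            v_opts.append((v3, len(vc)))
    j_opts = []
    for j5 in range(0, min(cap_j5, g_b) + 1):
        jc = j_germ[j5:g_b]
        if window.endswith(jc):
            j_opts.append((j5, len(jc)))
    if parsimony_only:
        v_opts = v_opts[:1]
        feasible = [
            (j5, jlen)
            for j5, jlen in j_opts
            if v_opts and v_opts[0][1] + jlen <= len(window)
        ]
        j_opts = feasible[:1]
    for v3, vlen in v_opts:
        v_left = v_germ if v3 == 0 else None
        for j5, jlen in j_opts:
            if vlen + jlen > len(window):
                continue
            middle = window[vlen : len(window) - jlen]
            j_right = j_germ if j5 == 0 else None
            # no-D decomposition (light chains, or heavy with an
            # untemplated middle)
            p1, n1, p2 = maximal_p_split(middle, v_left, j_right, p_cap)
            sols.add(
                Solution(None, v3, 0, 0, j5, len(p1), len(n1), len(p2), 0, 0, 0)
            )
            if not d_refs:
                continue
            for d_name in sorted(d_refs):
                d = d_refs[d_name]
                for d5 in range(0, min(cap_d5, len(d)) + 1):
                    for d3 in range(0, min(cap_d3, len(d) - d5) + 1):
                        core = d[d5 : len(d) - d3]
                        if len(core) < min_d_match:
                            continue
                        start = middle.find(core)
                        while start != -1:
                            gap1 = middle[:start]
                            gap2 = middle[start + len(core) :]
                            a1, b1, c1 = maximal_p_split(
                                gap1, v_left, d if d5 == 0 else None, p_cap
                            )
                            a2, b2, c2 = maximal_p_split(
                                gap2, d if d3 == 0 else None, j_right, p_cap
                            )
                            sols.add(
                                Solution(
                                    d_name, v3, d5, d3, j5,
                                    len(a1), len(b1), len(c1),
                                    len(a2), len(b2), len(c2),
                                )
                            )
                            start = middle.find(core, start + 1)
    return sorted(sols, key=lambda s: (s.d_name or "",) + tuple(s[1:]))


def canonical_solutions(
    sols: list[Solution], d_refs: Optional[dict[str, str]]
) -> list[Solution]:
    """The maximal-parsimony subset a greedy decomposer can report.

    Every decomposition can be degraded by deleting more germline and
    absorbing the freed bases into N, so validity alone is vacuous.
    The greedy decomposer attributes as much as possible to germline,
    in its fixed order: maximal V extension (minimal v3_del), then
    maximal J extension (minimal j5_del), then the longest retained D;
    P/N splits are already forced. The returned subset is the set of
    ties remaining after those filters — the genuine ambiguity class.
    """
    if not sols:
        return []
    m = min(s.v3_del for s in sols)
    sols = [s for s in sols if s.v3_del == m]
    m = min(s.j5_del for s in sols)
    sols = [s for s in sols if s.j5_del == m]
    d_sols = [s for s in sols if s.d_name is not None]
    if d_sols and d_refs:
        core_len = {
            id(s): len(d_refs[s.d_name]) - s.d5_del - s.d3_del for s in d_sols
        }
        best = max(core_len.values())
        return [s for s in d_sols if core_len[id(s)] == best]
    return [s for s in sols if s.d_name is None]


# ---------------------------------------------------------------------------
# CDR3 extraction
# ---------------------------------------------------------------------------


def extract_cdr3(
    rearr: Rearrangement, reference: GermlineReference
) -> tuple[Optional[str], Optional[int], Optional[str]]:
    """CDR3 between (and excluding) the V 2nd-CYS and the J [FW] anchor.

    Returns (cdr3_nt, cdr3_len, fail_reason). Anchor positions come
    from the germline annotation and are mapped through the alignments;
    the CDR3 is undefined (reason ``missing_anchor``) when either
    anchor is unmapped or its read codon has mutated to a stop. As a
    side effect the junction_nt (anchors included) and cdr3 fields of
    the rearrangement are filled in.
    """
    v_seg = reference.get(rearr.v_call)
    j_seg = reference.get(rearr.j_call)
    if v_seg.cys2_nt is None or j_seg.j_anchor_nt is None:
        rearr.cdr3_fail_reason = "missing_anchor"
        return None, None, "missing_anchor"
    if (
        rearr.v_aln.germ_end < v_seg.cys2_nt + 3
        or rearr.j_aln.germ_start > j_seg.j_anchor_nt
    ):
        rearr.cdr3_fail_reason = "missing_anchor"
        return None, None, "missing_anchor"
    cys2_read = germ_to_read(rearr.v_aln, v_seg.cys2_nt)
    anchor_read = germ_to_read(rearr.j_aln, j_seg.j_anchor_nt)
    read = rearr.sequence
    if (
        cys2_read is None
        or anchor_read is None
        or anchor_read + 3 > len(read)
        or anchor_read <= cys2_read
    ):
        rearr.cdr3_fail_reason = "missing_anchor"
        return None, None, "missing_anchor"
    if translate(read[cys2_read : cys2_read + 3]) == "*" or (
        translate(read[anchor_read : anchor_read + 3]) == "*"
    ):
        rearr.cdr3_fail_reason = "missing_anchor"
        return None, None, "missing_anchor"
    cdr3 = read[cys2_read + 3 : anchor_read]
    rearr.cdr3_nt = cdr3
    rearr.junction_nt = read[cys2_read : anchor_read + 3]
    rearr.cdr3_fail_reason = None
    return cdr3, len(cdr3), None


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

HIST_STATS = ("v3_del", "np1_len", "d_len", "np2_len", "j5_del", "cdr3_len")


def junction_histograms(
    rearrangements: list[Rearrangement],
) -> dict[str, pd.DataFrame]:
    """Frequency tables of the junction diversity factors, per sample.

    For each of v3_del, |P1+N1+P2|, |D|, |P3+N2+P4|, j5_del and
    cdr3_len a table of counts and fractions is returned, plus a
    ``summary`` table with mean and sd of CDR3 length and of the
    retained-D contribution.
    """
    rows = []
    for r in rearrangements:
        if r.junction is None:
            continue
        j = r.junction
        rows.append(
            {
                "sample_id": r.sample_id,
                "v3_del": j.v3_del,
                "np1_len": len(j.np1),
                "d_len": len(j.d_seq),
                "np2_len": len(j.np2),
                "j5_del": j.j5_del,
                "cdr3_len": len(r.cdr3_nt) if r.cdr3_nt is not None else np.nan,
            }
        )
    out: dict[str, pd.DataFrame] = {}
    if not rows:
        for stat in HIST_STATS:
            out[stat] = pd.DataFrame(
                columns=["sample_id", "value", "count", "fraction"]
            )
        out["summary"] = pd.DataFrame(
            columns=["sample_id", "statistic", "mean", "sd", "max"]
        )
        return out
    df = pd.DataFrame(rows)
    for stat in HIST_STATS:
        sub = df.dropna(subset=[stat])
        g = (
            sub.groupby(["sample_id", stat])
            .size()
            .rename("count")
            .reset_index()
            .rename(columns={stat: "value"})
        )
        g["fraction"] = g.groupby("sample_id")["count"].transform(
            lambda c: c / c.sum()
        )
        out[stat] = g.sort_values(["sample_id", "value"]).reset_index(drop=True)
    summaries = []
    for sample, sub in df.groupby("sample_id"):
        for stat in ("cdr3_len", "d_len"):
            vals = sub[stat].dropna()
            summaries.append(
                {
                    "sample_id": sample,
                    "statistic": stat,
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "max": float(vals.max()) if len(vals) else np.nan,
                }
            )
    out["summary"] = pd.DataFrame(summaries)
    return out
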