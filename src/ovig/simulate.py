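"""Synthetic V(D)J repertoire generator with per-read ground truth.

Each read is built V -> (P,N,P) -> D -> (P,N,P) -> J (heavy chains;
light chains use a single gap), wrapped in a random leader, a
constant-region stub and the amplification primers, then subjected to
hotspot-biased somatic hypermutation and optional sequencing error.
Deletion lengths follow truncated geometric laws per end; untemplated
(N) tract lengths likewise; P tracts appear with a configurable
probability at undeleted ends only, as the reverse complement of the
abutting germline end.

The emitted truth record stores the drawn decomposition; a read is
flagged ``ambiguous_junction`` when the exhaustive decomposer — the
same one used as the analysis oracle — admits more than one valid
decomposition of the junction window, or when its unique solution
differs from the drawn one (e.g. a drawn N base happens to extend a
palindrome). All randomness flows from one seeded generator in fixed
stream order, so outputs are byte-identical across runs and platforms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ovig.dna import revcomp, translate
from ovig.junction import (
    MIN_D_MATCH,
    Solution,
    canonical_solutions,
    enumerate_decompositions,
)
from ovig.shm import hotspot_mask
from ovig.types import (
    SUBSTITUTION_TYPES,
    GeneSegment,
    GermlineReference,
    Read,
    RssMatch,
    SimulationConfig,
    TruthRecord,
)

BASES = "ACGT"

# Default 12-type substitution weights: transition-heavy, A>G first,
# G>A second, T>A last (the ordering a ruminant IgH spectrum shows).
DEFAULT_SPECTRUM = {
    "A>G": 0.18, "G>A": 0.15, "C>T": 0.12, "T>C": 0.10,
    "T>G": 0.08, "A>C": 0.05, "C>A": 0.06, "G>C": 0.06,
    "A>T": 0.06, "C>G": 0.05, "G>T": 0.05, "T>A": 0.04,
}

STOP_FREE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA", "TGT", "TGC")
]
# Cys codons are excluded from the random pool so the two conserved
# cysteines placed explicitly stay unique anchors.

V_LAYOUT = {
    # codon intervals (half-open) of the IMGT-style regions
    "FR1": (0, 25),
    "CDR1": (25, 33),
    "FR2": (33, 50),
    "CDR2": (50, 58),
    "FR3": (58, 96),
}
V_CYS1_CODON = 21
V_CYS2_CODON = 95
V_TAIL_CODONS = 2  # germline bases past the 2nd-CYS codon
J_PRE_ANCHOR_CODONS = 5
J_TOTAL_CODONS = 16

YG_MOTIF_NT = "AGCTATTATAGTGGTTATGGTTATGCTTATGGTTAT"  # SYYSGYGYAYGY

LOCUS_HAS_D = {"IGH": True, "IGK": False, "IGL": False}
J_ANCHOR_AA = {"IGH": "W", "IGK": "F", "IGL": "F"}
LOCUS_RSS_SPACERS = {
    "IGH": {"V": 23, "D": 12, "J": 23},
    "IGK": {"V": 12, "J": 23},
    "IGL": {"V": 23, "J": 12},
}


def _rand_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(STOP_FREE_CODONS), size=n)
    return "".join(STOP_FREE_CODONS[i] for i in idx)


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _exact_rss(spacer: int) -> RssMatch:
    return RssMatch(0, spacer, f"RSS{spacer}", "+", 0, 0, "downstream_of_segment")


def make_toy_germline(
    seed: int,
    locus: str = "IGH",
    n_v: int = 4,
    n_d: int = 4,
    n_j: int = 2,
    n_c: int = 1,
    include_yg_d: bool = True,
) -> GermlineReference:
    """Random but anchor-correct germline reference for one locus.

    V segments carry both conserved cysteines and FR/CDR region labels;
    J segments exactly one [FW]GXG anchor; D segments (IGH only) a
    12-spacer RSS on both sides; ``include_yg_d`` embeds a
    (YG)n-motif D akin to the ruminant DH2. Segments are laid out on a
    virtual contig with 300-bp spacing so a planted genome can be
    assembled around them.
    """
    rng = np.random.default_rng(seed)
    spacers = LOCUS_RSS_SPACERS[locus]
    segments: list[GeneSegment] = []
    sequences: dict[str, str] = {}
    cursor = 300

    def place(seg: GeneSegment, seq: str):
        nonlocal cursor
        seg.start = cursor
        seg.end = cursor + len(seq)
        cursor = seg.end + 300
        segments.append(seg)
        sequences[seg.name] = seq

    for i in range(n_v):
        codons = [
            _rand_codons(rng, 1) for _ in range(V_CYS2_CODON + 1 + V_TAIL_CODONS)
        ]
        codons[V_CYS1_CODON] = "TGT" if rng.random() < 0.5 else "TGC"
        codons[V_CYS2_CODON] = "TGT" if rng.random() < 0.5 else "TGC"
        seq = "".join(codons)
        seg = GeneSegment(
            name=f"{locus}V{i + 1}", locus=locus, seg_type="V",
            start=0, end=1, strand="+",
            rss=[_exact_rss(spacers["V"])],
            cys1_nt=V_CYS1_CODON * 3, cys2_nt=V_CYS2_CODON * 3,
            regions={k: (a * 3, b * 3) for k, (a, b) in V_LAYOUT.items()},
        )
        place(seg, seq)
    if LOCUS_HAS_D[locus]:
        d_lens = [12, 15, 18, 24, 10, 21]
        for i in range(n_d):
            if include_yg_d and i == 1:
                seq = YG_MOTIF_NT
            else:
                seq = _rand_dna(rng, d_lens[i % len(d_lens)])
            seg = GeneSegment(
                name=f"{locus}D{i + 1}", locus=locus, seg_type="D",
                start=0, end=1, strand="+",
                rss=[_exact_rss(spacers["D"]), _exact_rss(spacers["D"])],
            )
            place(seg, seq)
    anchor_aa = J_ANCHOR_AA[locus]
    anchor_codon = {"W": "TGG", "F": "TTC"}[anchor_aa]
    for i in range(n_j):
        while True:
            pre = _rand_codons(rng, J_PRE_ANCHOR_CODONS)
            x = _rand_codons(rng, 1)
            tail = _rand_codons(rng, J_TOTAL_CODONS - J_PRE_ANCHOR_CODONS - 4)
            seq = pre + anchor_codon + "GGT" + x + "GGC" + tail
            aa = translate(seq)
            if len(re.findall(r"[FW]G.G", aa)) == 1:
                break
        seg = GeneSegment(
            name=f"{locus}J{i + 1}", locus=locus, seg_type="J",
            start=0, end=1, strand="+",
            rss=[_exact_rss(spacers["J"])],
            j_anchor_nt=J_PRE_ANCHOR_CODONS * 3,
        )
        place(seg, seq)
    for i in range(n_c):
        seg = GeneSegment(
            name=f"{locus}C{i + 1}", locus=locus, seg_type="C",
            start=0, end=1, strand="+",
        )
        place(seg, _rand_dna(rng, 120))
    return GermlineReference(segments=segments, sequences=sequences)


def make_toy_genome(
    reference: GermlineReference, seed: int, spacer: int = 300
) -> str:
    """Assemble a planted genome: segments in layout order with proper
    RSS flanks embedded in random spacer sequence."""
    from ovig.germline import HEPTAMER, NONAMER

    rng = np.random.default_rng(seed)

    def rss_fwd(slen: int) -> str:
        return HEPTAMER + _rand_dna(rng, slen) + NONAMER

    parts: list[str] = []
    for locus, names in reference.locus_layout.items():
        spacers = LOCUS_RSS_SPACERS[locus]
        for name in names:
            seg = reference.get(name)
            seq = reference.seq(name)
            parts.append(_rand_dna(rng, spacer))
            if seg.seg_type == "V":
                parts.append(seq + rss_fwd(spacers["V"]))
            elif seg.seg_type == "D":
                parts.append(
                    revcomp(rss_fwd(spacers["D"])) + seq + rss_fwd(spacers["D"])
                )
            elif seg.seg_type == "J":
                parts.append(revcomp(rss_fwd(spacers["J"])) + seq)
            else:
                parts.append(seq)
    parts.append(_rand_dna(rng, spacer))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------


def _trunc_geom_pmf(p: float, cap: int) -> np.ndarray:
    """Normalized pmf of a geometric(p) law truncated to {0..cap}."""
    if cap <= 0:
        return np.array([1.0])
    if p <= 0:
        return np.full(cap + 1, 1.0 / (cap + 1))
    k = np.arange(cap + 1)
    w = p * (1 - p) ** k
    return w / w.sum()


def _draw(rng: np.random.Generator, pmf: np.ndarray) -> int:
    return int(rng.choice(len(pmf), p=pmf))


def _weights_vector(
    weights: Optional[dict[str, float]], names: list[str]
) -> np.ndarray:
    if weights is None:
        return np.full(len(names), 1.0 / len(names))
    w = np.array([float(weights.get(n, 0.0)) for n in names])
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("usage weights must be nonnegative and normalizable")
    return w / w.sum()


def _spectrum_rows(spectrum: dict[str, float]) -> dict[str, tuple[list[str], np.ndarray]]:
    rows = {}
    for b in BASES:
        targets = [t for t in BASES if t != b]
        w = np.array([spectrum.get(f"{b}>{t}", 0.0) for t in targets])
        if w.sum() <= 0:
            w = np.ones(3)
        rows[b] = (targets, w / w.sum())
    return rows


def expected_spectrum(
    config: SimulationConfig,
    reference: GermlineReference,
    seg_types: tuple[str, ...] = ("V",),
    v_5p_margin: int = 0,
    v_3p_margin: int = 0,
) -> dict[str, float]:
    """Closed-form marginal substitution-type distribution the generator
    implies, given the germline base/hotspot composition.

    Per position the mutation rate is ``shm_rate`` (times the hotspot
    multiplier at flagged C/G) and the target base is drawn from the
    spectrum row of the source base, so the marginal fraction of type
    b>t is proportional to the sum over germline positions with base b
    of rate(pos) * w(b>t)/rowsum(b). ``seg_types`` and the V margins
    let the composition window match how mutation profiles are tallied
    (V-only, boundary margins excluded).
    """
    spectrum = config.shm_spectrum or DEFAULT_SPECTRUM
    rows = _spectrum_rows(spectrum)
    acc = {t: 0.0 for t in SUBSTITUTION_TYPES}
    segs = [
        s for t in seg_types for s in reference.by_type(t, config.locus)
    ]
    for seg in segs:
        germ = reference.seq(seg.name)
        mask = hotspot_mask(germ)
        lo = v_5p_margin if seg.seg_type == "V" else 0
        hi = len(germ) - (v_3p_margin if seg.seg_type == "V" else 0)
        for i in range(lo, hi):
            b = germ[i]
            rate = config.shm_rate * (
                config.hotspot_multiplier if mask[i] else 1.0
            )
            targets, w = rows[b]
            for t, wt in zip(targets, w):
                acc[f"{b}>{t}"] += rate * wt
    total = sum(acc.values())
    return {k: v / total for k, v in acc.items()} if total else acc


@dataclass
class _Core:
    seq: str
    v_len: int  # retained V length
    j_off: int  # offset of retained J within seq
    truth: TruthRecord


def simulate_repertoire(
    config: SimulationConfig, reference: GermlineReference
) -> tuple[list[Read], list[TruthRecord]]:
    """Generate reads and matching truth records.

    Draw order per read is fixed (gene choice, deletions, P/N tracts,
    leader, SHM, sequencing error, primer dropout), so a given seed
    yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    locus = config.locus
    has_d = LOCUS_HAS_D[locus]
    v_names = sorted(s.name for s in reference.by_type("V", locus))
    j_names = sorted(s.name for s in reference.by_type("J", locus))
    d_names = sorted(s.name for s in reference.by_type("D", locus)) if has_d else []
    if not v_names or not j_names or (has_d and not d_names):
        raise ValueError(f"reference lacks required segment types for {locus}")
    wv = _weights_vector(config.usage_weights_v, v_names)
    wj = _weights_vector(config.usage_weights_j, j_names)
    wd = _weights_vector(config.usage_weights_d, d_names) if has_d else None
    pmf_v3 = _trunc_geom_pmf(config.del_p_v3, config.del_cap_v3)
    pmf_d5 = _trunc_geom_pmf(config.del_p_d5, config.del_cap_d5)
    pmf_d3 = _trunc_geom_pmf(config.del_p_d3, config.del_cap_d3)
    pmf_j5 = _trunc_geom_pmf(config.del_p_j5, config.del_cap_j5)
    pmf_plen = _trunc_geom_pmf(config.n_p, config.p_len_max - 1)  # 1..max
    pmf_nlen = _trunc_geom_pmf(config.n_len_p, config.n_len_max)
    n_base_w = np.array(config.n_base_weights, dtype=float)
    n_base_w = n_base_w / n_base_w.sum()
    spectrum = config.shm_spectrum or DEFAULT_SPECTRUM
    spec_rows = _spectrum_rows(spectrum)
    c_segs = reference.by_type("C", locus)
    c_stub = (
        reference.seq(c_segs[0].name)[: config.c_stub_len]
        if c_segs
        else _rand_dna(np.random.default_rng(config.seed + 10_000), config.c_stub_len)
    )
    masks = {
        name: hotspot_mask(reference.seq(name)) for name in v_names + j_names
    }
    d_refs = {n: reference.seq(n) for n in d_names}

    reads: list[Read] = []
    truths: list[TruthRecord] = []
    for idx in range(config.n_reads):
        rid = f"{config.sample_id}_read{idx:05d}"
        v_name = v_names[_draw(rng, wv)]
        j_name = j_names[_draw(rng, wj)]
        d_name = d_names[_draw(rng, wd)] if has_d else None
        v = reference.seq(v_name)
        j = reference.seq(j_name)
        v3 = min(_draw(rng, pmf_v3), len(v) - 1)
        j5 = min(_draw(rng, pmf_j5), len(j) - 1)
        if has_d:
            d = d_refs[d_name]
            d5 = min(_draw(rng, pmf_d5), len(d))
            d3 = min(_draw(rng, pmf_d3), len(d) - d5)
        else:
            d = ""
            d5 = d3 = 0

        def p_tract(end_seq: str, deleted: int, side: str) -> str:
            if deleted != 0 or not end_seq or config.p_prob <= 0:
                # burn a draw only when eligibility is decided by chance
                return ""
            if rng.random() >= config.p_prob:
                return ""
            k = 1 + _draw(rng, pmf_plen)
            k = min(k, len(end_seq))
            return (
                revcomp(end_seq[-k:]) if side == "left" else revcomp(end_seq[:k])
            )

        def n_tract() -> str:
            k = _draw(rng, pmf_nlen)
            return "".join(BASES[_draw(rng, n_base_w)] for _ in range(k))

        v_ret = v[: len(v) - v3]
        j_ret = j[j5:]
        if has_d:
            d_ret = d[d5 : len(d) - d3]
            p1 = p_tract(v_ret, v3, "left")
            p2 = p_tract(d, d5, "right")
            n1 = n_tract()
            p3 = p_tract(d, d3, "left") if d_ret else ""
            p4 = p_tract(j, j5, "right")
            n2 = n_tract()
            core = v_ret + p1 + n1 + p2 + d_ret + p3 + n2 + p4 + j_ret
            j_off = len(core) - len(j_ret)
        else:
            d_ret = ""
            p1 = p_tract(v_ret, v3, "left")
            p2 = p_tract(j, j5, "right")
            n1 = n_tract()
            p3 = p4 = n2 = ""
            core = v_ret + p1 + n1 + p2 + j_ret
            j_off = len(core) - len(j_ret)

        # ambiguity: enumerate all valid decompositions of the window
        g_a = max(0, len(v) - config.del_cap_v3 - 4)
        g_b = min(len(j), config.del_cap_j5 + 4)
        window = core[g_a : j_off + (g_b - j5)]
        sols = enumerate_decompositions(
            window, v, g_a, j, g_b, d_refs if has_d else None,
            cap_v3=config.del_cap_v3, cap_d5=config.del_cap_d5,
            cap_d3=config.del_cap_d3, cap_j5=config.del_cap_j5,
            parsimony_only=True,
        )
        if has_d and len(d_ret) >= MIN_D_MATCH:
            truth_sol = Solution(
                d_name, v3, d5, d3, j5,
                len(p1), len(n1), len(p2), len(p3), len(n2), len(p4),
            )
        elif has_d:
            # retained D below the callable minimum: the decomposition a
            # caller can recover is no-D, so the drawn truth is
            # unrecoverable by definition
            truth_sol = None
        else:
            truth_sol = Solution(
                None, v3, 0, 0, j5, len(p1), len(n1), len(p2), 0, 0, 0
            )
        canon = canonical_solutions(sols, d_refs if has_d else None)
        ambiguous = (
            truth_sol is None or len(canon) != 1 or canon[0] != truth_sol
        )

        leader_len = config.leader_len
        if config.read_len_jitter:
            leader_len += int(
                rng.integers(-config.read_len_jitter, config.read_len_jitter + 1)
            )
            leader_len = max(0, leader_len)
        leader = _rand_dna(rng, leader_len)
        has_fwd = rng.random() >= config.fraction_missing_primer
        prefix = (config.fwd_primer if has_fwd else "") + leader
        seq = prefix + core + c_stub + revcomp(config.rev_primer)

        # somatic hypermutation over the retained V and J
        mutations: list[tuple[str, int, str, str, bool]] = []
        seq_list = list(seq)
        core_off = len(prefix)
        for seg_label, name, germ, ret_start, ret_len, read_off in (
            ("V", v_name, v, 0, len(v_ret), core_off),
            ("J", j_name, j, j5, len(j_ret), core_off + j_off),
        ):
            mask = masks[name]
            for k in range(ret_len):
                g = ret_start + k
                hot = bool(mask[g])
                rate = config.shm_rate * (
                    config.hotspot_multiplier if hot else 1.0
                )
                if rate > 0 and rng.random() < min(rate, 0.95):
                    src = germ[g]
                    targets, w = spec_rows[src]
                    new = targets[_draw(rng, w)]
                    seq_list[read_off + k] = new
                    mutations.append((seg_label, g, src, new, hot))
        seq = "".join(seq_list)

        # productivity and true CDR3 (post-SHM, pre-sequencing-error)
        cys2 = reference.get(v_name).cys2_nt
        anchor = reference.get(j_name).j_anchor_nt
        productive = False
        cdr3 = ""
        if (
            cys2 is not None
            and anchor is not None
            and cys2 + 3 <= len(v_ret)
            and j5 <= anchor
        ):
            cys2_read = core_off + cys2
            anchor_read = core_off + j_off + (anchor - j5)
            if (anchor_read - cys2_read) % 3 == 0:
                if "*" not in translate(seq[core_off : anchor_read + 3]):
                    productive = True
            cdr3 = seq[cys2_read + 3 : anchor_read]

        errors: list[tuple[int, str, str]] = []
        if config.seq_error_rate > 0:
            seq_list = list(seq)
            hits = np.nonzero(
                rng.random(len(seq_list)) < config.seq_error_rate
            )[0]
            for pos in hits:
                old = seq_list[pos]
                new = BASES[(BASES.index(old) + int(rng.integers(1, 4))) % 4]
                seq_list[pos] = new
                errors.append((int(pos), old, new))
            seq = "".join(seq_list)

        reads.append(Read(rid, seq))
        truths.append(
            TruthRecord(
                read_id=rid, v_name=v_name, j_name=j_name, d_name=d_name,
                v3_del=v3, d5_del=d5, d3_del=d3, j5_del=j5,
                p1=p1, n1=n1, p2=p2, p3=p3, n2=n2, p4=p4,
                mutations=mutations, seq_errors=errors,
                productive=productive, ambiguous_junction=ambiguous,
                has_fwd_primer=has_fwd, cdr3_nt=cdr3,
                leader=leader,
            )
        )
    return reads, truths


def reconstruct_read(
    truth: TruthRecord, reference: GermlineReference, config: SimulationConfig
) -> str:
    """Rebuild a read byte-for-byte from its truth record."""
    v = reference.seq(truth.v_name)
    j = reference.seq(truth.j_name)
    v_ret = v[: len(v) - truth.v3_del]
    j_ret = j[truth.j5_del :]
    if truth.d_name is not None:
        d = reference.seq(truth.d_name)
        d_ret = d[truth.d5_del : len(d) - truth.d3_del]
        core = (
            v_ret + truth.p1 + truth.n1 + truth.p2
            + d_ret + truth.p3 + truth.n2 + truth.p4 + j_ret
        )
    else:
        core = v_ret + truth.p1 + truth.n1 + truth.p2 + j_ret
    j_off = len(core) - len(j_ret)
    prefix = (config.fwd_primer if truth.has_fwd_primer else "") + truth.leader
    c_segs = reference.by_type("C", config.locus)
    c_stub = (
        reference.seq(c_segs[0].name)[: config.c_stub_len]
        if c_segs
        else _rand_dna(np.random.default_rng(config.seed + 10_000), config.c_stub_len)
    )
    seq = list(prefix + core + c_stub + revcomp(config.rev_primer))
    core_off = len(prefix)
    for seg_label, g, _src, new, _hot in truth.mutations:
        if seg_label == "V":
            seq[core_off + g] = new
        else:
            seq[core_off + j_off + (g - truth.j5_del)] = new
    for pos, _old, new in truth.seq_errors:
        seq[pos] = new
    return "".join(seq)
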