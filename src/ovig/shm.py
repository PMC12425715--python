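"""Somatic hypermutation profiling against the germline V.

SHM frequency is (mutated bases) / (total sequenced bases) x 100%.
Only substitutions are counted; alignment gaps are excluded from both
numerator and denominator. The 12-type substitution spectrum, the
per-position mutation map with FR/CDR labels, and mutation counts at
the AID hotspot motifs WRCY (mutable C at motif offset 2) and RGYW
(mutable G at offset 1; the reverse-complement motif of WRCY) are all
derived from per-germline :class:`~ovig.types.MutationProfile` objects.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

import numpy as np
import pandas as pd

from ovig.dna import find_motif
from ovig.types import (
    SUBSTITUTION_TYPES,
    TRANSITIONS,
    GermlineReference,
    MutationProfile,
    Rearrangement,
)

SUB_INDEX = {t: i for i, t in enumerate(SUBSTITUTION_TYPES)}


def shm_frequency(mutated_bases: int, total_bases: int) -> float:
    """Percent mutated bases: 100 x mutated / total."""
    if not 0 <= mutated_bases <= total_bases:
        raise ValueError("need 0 <= mutated <= total")
    if total_bases == 0:
        raise ZeroDivisionError("SHM frequency undefined for zero bases")
    return 100.0 * mutated_bases / total_bases


def hotspot_mask(germline: str) -> list[tuple[str, ...]]:
    """Per-position AID hotspot flags over a germline sequence.

    A position is flagged ``WRCY_C`` when it is the C of a WRCY motif
    and ``RGYW_G`` when it is the G of an RGYW motif; a base inside
    both contexts carries both flags. The mask is strand-dual: it
    equals the reverse-complemented mask with the two flags swapped.
    """
    flags: list[set] = [set() for _ in germline]
    for i in find_motif(germline, "WRCY"):
        flags[i + 2].add("WRCY_C")
    for i in find_motif(germline, "RGYW"):
        flags[i + 1].add("RGYW_G")
    return [tuple(sorted(f)) for f in flags]


def build_profiles(
    rearrangements: Iterable[Rearrangement],
    reference: GermlineReference,
    collapse_by_junction: bool = False,
    v_5p_margin: int = 4,
    v_3p_margin: int = 48,
) -> dict[str, MutationProfile]:
    """Accumulate mutation profiles per germline V from assigned reads.

    Coverage counts each aligned (non-gap) read base per germline
    position; mutation counts come from the alignment's substitution
    list. Positions inside the 5'/3' margins are excluded from the
    tally unconditionally: alignment end-trimming and junction-boundary
    refinement drop terminal bases *conditionally on their being
    mutated*, so including those zones would bias every rate estimate
    downward, while excluding them outright leaves the estimators
    unbiased. The 3' margin covers the V-deletion range the junction
    boundary walk operates over. ``collapse_by_junction`` optionally
    deduplicates reads with an identical junction before tallying
    (clonal collapsing).
    """
    profiles: dict[str, MutationProfile] = {}
    seen: set[tuple[str, str]] = set()
    for r in rearrangements:
        if collapse_by_junction:
            key = (r.v_call, r.junction_nt)
            if key in seen:
                continue
            seen.add(key)
        name = r.v_call
        if name not in profiles:
            germ = reference.seq(name)
            seg = reference.get(name)
            labels = [""] * len(germ)
            for region, (a, b) in seg.regions.items():
                for k in range(a, min(b, len(germ))):
                    labels[k] = region
            profiles[name] = MutationProfile(
                germline_name=name,
                germline_seq=germ,
                per_position=np.zeros(
                    (len(germ), len(SUBSTITUTION_TYPES)), dtype=np.int64
                ),
                coverage=np.zeros(len(germ), dtype=np.int64),
                region_labels=labels,
                hotspot_flags=hotspot_mask(germ),
            )
        prof = profiles[name]
        lo = v_5p_margin
        hi = prof.length - v_3p_margin
        for qs, qe, ts, te in r.v_aln.blocks:
            a, b = max(ts, lo), min(te, hi)
            if b > a:
                prof.coverage[a:b] += 1
        for gpos, gbase, rbase in r.v_aln.mutations:
            if not lo <= gpos < hi:
                continue
            sub = f"{gbase}>{rbase}"
            if sub in SUB_INDEX:  # skips N-containing columns
                prof.per_position[gpos, SUB_INDEX[sub]] += 1
    return profiles


def profile_totals(profiles: Iterable[MutationProfile]) -> tuple[int, int]:
    """(mutated bases, total aligned bases) across profiles."""
    mutated = total = 0
    for p in profiles:
        mutated += int(p.per_position.sum())
        total += int(p.coverage.sum())
    return mutated, total


def substitution_spectrum(
    profiles: Iterable[MutationProfile],
) -> pd.DataFrame:
    """Fraction of total mutations per ordered substitution type.

    Returns a 12-row table (substitution, count, fraction, class) where
    class is transition or transversion; fractions sum to 1. An empty
    table (flagged by zero rows) is returned when no mutations exist.
    """
    counts = np.zeros(len(SUBSTITUTION_TYPES), dtype=np.int64)
    for p in profiles:
        counts += p.per_position.sum(axis=0)
    total = counts.sum()
    if total == 0:
        return pd.DataFrame(
            columns=["substitution", "count", "fraction", "class"]
        )
    return pd.DataFrame(
        {
            "substitution": SUBSTITUTION_TYPES,
            "count": counts,
            "fraction": counts / total,
            "class": [
                "transition" if t in TRANSITIONS else "transversion"
                for t in SUBSTITUTION_TYPES
            ],
        }
    )


def hotspot_mutations(profile: MutationProfile) -> dict:
    """Mutation tallies of C/G inside WRCY/RGYW hotspots.

    Returns per-motif, per-target-base counts (C>T/C>G/C>A under WRCY;
    G>A/G>C/G>T under RGYW), the total hotspot mutation count (a base
    inside both contexts counts once), the fraction of all mutated
    bases falling in hotspots, and hotspot-vs-background per-base
    mutation rates.
    """
    wrcy = Counter()
    rgyw = Counter()
    hotspot_mut = 0
    hotspot_cov = 0
    bg_mut = 0
    bg_cov = 0
    for i, flags in enumerate(profile.hotspot_flags):
        site_mut = int(profile.per_position[i].sum())
        if flags:
            hotspot_mut += site_mut
            hotspot_cov += int(profile.coverage[i])
        else:
            bg_mut += site_mut
            bg_cov += int(profile.coverage[i])
        if "WRCY_C" in flags:
            for t in "TGA":
                wrcy[f"C>{t}"] += int(profile.per_position[i, SUB_INDEX[f"C>{t}"]])
        if "RGYW_G" in flags:
            for t in "ACT":
                rgyw[f"G>{t}"] += int(profile.per_position[i, SUB_INDEX[f"G>{t}"]])
    total_mut = profile.total_mutations
    return {
        "germline_name": profile.germline_name,
        "wrcy": dict(wrcy),
        "rgyw": dict(rgyw),
        "hotspot_mutations": hotspot_mut,
        "total_mutations": total_mut,
        "hotspot_fraction": hotspot_mut / total_mut if total_mut else 0.0,
        "hotspot_rate": hotspot_mut / hotspot_cov if hotspot_cov else 0.0,
        "background_rate": bg_mut / bg_cov if bg_cov else 0.0,
    }


def position_map(profile: MutationProfile) -> pd.DataFrame:
    """One row per germline position: coverage, counts, region, hotspot."""
    rows = {
        "germline_name": profile.germline_name,
        "position": np.arange(profile.length),
        "germline_base": list(profile.germline_seq),
        "coverage": profile.coverage,
        "mutations": profile.per_position.sum(axis=1),
        "region": profile.region_labels,
        "hotspot": ["+".join(f) for f in profile.hotspot_flags],
    }
    df = pd.DataFrame(rows)
    for k, t in enumerate(SUBSTITUTION_TYPES):
        df[t] = profile.per_position[:, k]
    return df


def spectrum_rank_order(spectrum: pd.DataFrame) -> list[str]:
    """Substitution types by descending frequency (name-stable ties)."""
    if spectrum.empty:
        return []
    s = spectrum.sort_values(
        ["fraction", "substitution"], ascending=[False, True]
    )
    return list(s["substitution"])
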