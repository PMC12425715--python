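"""End-to-end orchestration: filter -> assign -> junction -> SHM -> summarize.

Each stage's outputs are written before the next starts; the returned
manifest maps every produced file to its row count. All outputs are
deterministic for fixed inputs, so a rerun is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from ovig import io as ovio
from ovig.assign import AssignmentRejection, assign_vdj, infer_productivity
from ovig.filtering import filter_reads
from ovig.junction import decompose_junction, extract_cdr3, junction_histograms
from ovig.shm import (
    build_profiles,
    hotspot_mutations,
    position_map,
    profile_totals,
    shm_frequency,
    substitution_spectrum,
)
from ovig.stats import cdr3_stats, recombination_types, sankey_flows, usage_frequencies
from ovig.types import GermlineReference, Read, Rearrangement

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    locus: str = "IGH"
    sample_id: str = "sample1"
    fwd_primer: str = "AAGCAGTGGTATCAACGCAGAGT"
    rev_primer: str = "ACACCAGGGGGAAGACTCTCGGG"
    min_len: int = 400
    max_primer_mismatches: int = 2
    v_min_identity: float = 0.70
    j_min_identity: float = 0.80
    min_d_match: int = 5
    collapse_by_junction: bool = False
    skip_filter: bool = False


def analyze_reads(
    reads: list[Read],
    reference: GermlineReference,
    config: PipelineConfig,
) -> dict:
    """Run the in-memory analysis and return all result objects.

    Returns a dict with kept reads, the filter report, assigned
    rearrangements (junction-decomposed, CDR3-extracted, productivity
    called), rejections, SHM profiles and every summary table.
    """
    if config.skip_filter:
        kept, report = list(reads), None
    else:
        kept, report = filter_reads(
            reads,
            config.fwd_primer,
            config.rev_primer,
            min_len=config.min_len,
            max_primer_mismatches=config.max_primer_mismatches,
        )
    rearrangements: list[Rearrangement] = []
    rejections: list[AssignmentRejection] = []
    for read in kept:
        result = assign_vdj(
            read,
            reference,
            locus=config.locus,
            sample_id=config.sample_id,
            v_min_identity=config.v_min_identity,
            j_min_identity=config.j_min_identity,
            min_d_match=config.min_d_match,
        )
        if isinstance(result, AssignmentRejection):
            rejections.append(result)
            continue
        result.junction = decompose_junction(
            result, reference, min_d_match=config.min_d_match
        )
        extract_cdr3(result, reference)
        infer_productivity(result, reference)
        rearrangements.append(result)
    profiles = build_profiles(
        rearrangements, reference, collapse_by_junction=config.collapse_by_junction
    )
    mutated, total = profile_totals(profiles.values())
    return {
        "kept": kept,
        "filter_report": report,
        "rearrangements": rearrangements,
        "rejections": rejections,
        "profiles": profiles,
        "shm_frequency_pct": shm_frequency(mutated, total) if total else None,
        "spectrum": substitution_spectrum(profiles.values()),
        "hotspots": [hotspot_mutations(p) for p in profiles.values()],
        "histograms": junction_histograms(rearrangements),
        "usage": {
            t: usage_frequencies(rearrangements, t, reference)
            for t in ("V", "D", "J")
            if reference.by_type(t, config.locus)
        },
        "recomb": recombination_types(rearrangements),
        "cdr3_stats": cdr3_stats(rearrangements),
        "sankey": sankey_flows(rearrangements),
    }


def run_pipeline(
    reads: list[Read],
    reference: GermlineReference,
    out_dir,
    config: Optional[PipelineConfig] = None,
) -> dict[str, int]:
    """Run the full analysis and write every declared artifact.

    Returns the manifest {relative path: row count}. Written files:
    the kept-read FASTA, filter report, AIRR rearrangement TSV, six
    junction histogram CSVs, the 12-type spectrum CSV, hotspot CSV,
    per-germline position maps, usage tables, recombination-type
    tables, CDR3 summary and Sankey flow export.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = analyze_reads(reads, reference, config)
    manifest: dict[str, int] = {}

    def put(name: str, df: pd.DataFrame):
        df.to_csv(out / name, index=False)
        manifest[name] = len(df)

    ovio.write_reads(res["kept"], out / "kept.fasta")
    manifest["kept.fasta"] = len(res["kept"])
    if res["filter_report"] is not None:
        rep = res["filter_report"]
        rows = [{"reason": "kept", "count": rep.kept}] + [
            {"reason": k, "count": v} for k, v in sorted(rep.rejected.items())
        ]
        put("filter_report.csv", pd.DataFrame(rows))
    ovio.write_airr(res["rearrangements"], out / "rearrangements.tsv")
    manifest["rearrangements.tsv"] = len(res["rearrangements"])
    if res["rejections"]:
        put(
            "assignment_rejections.csv",
            pd.DataFrame(
                [{"read_id": r.read_id, "reason": r.reason} for r in res["rejections"]]
            ),
        )
    for stat, df in res["histograms"].items():
        put(f"hist_{stat}.csv", df)
    put("shm_spectrum.csv", res["spectrum"])
    hot_rows = []
    for h in res["hotspots"]:
        row = {
            "germline_name": h["germline_name"],
            "hotspot_mutations": h["hotspot_mutations"],
            "total_mutations": h["total_mutations"],
            "hotspot_fraction": h["hotspot_fraction"],
            "hotspot_rate": h["hotspot_rate"],
            "background_rate": h["background_rate"],
        }
        for k, v in sorted(h["wrcy"].items()):
            row[f"WRCY_{k}"] = v
        for k, v in sorted(h["rgyw"].items()):
            row[f"RGYW_{k}"] = v
        hot_rows.append(row)
    put("shm_hotspots.csv", pd.DataFrame(hot_rows))
    if res["profiles"]:
        pm = pd.concat(
            [position_map(p) for p in res["profiles"].values()],
            ignore_index=True,
        )
        put("shm_position_map.csv", pm)
    for t, df in res["usage"].items():
        put(f"usage_{t}.csv", df)
    table, summary = res["recomb"]
    put("recombination_types.csv", table)
    put("recombination_summary.csv", summary)
    put("cdr3_stats.csv", res["cdr3_stats"])
    put("sankey_flows.csv", res["sankey"])
    mf = pd.DataFrame(
        sorted(manifest.items()), columns=["file", "rows"]
    )
    mf.to_csv(out / "manifest.csv", index=False)
    return manifest
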