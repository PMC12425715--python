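"""Format adapters: FASTA/FASTQ, GFF3, AIRR rearrangement TSV, truth TSV.

All writers are deterministic (stable ordering, fixed float formats)
and all readers are exact inverses on files this package writes. GFF3
uses 1-based inclusive coordinates on disk and feature types
``V_gene_segment`` / ``D_gene_segment`` / ``J_gene_segment`` /
``C_gene_segment``; internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ovig.dna import check_dna
from ovig.types import (
    GeneSegment,
    GermlineReference,
    Read,
    Rearrangement,
    RssMatch,
    SimulationConfig,
    TruthRecord,
)

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def read_reads(path: PathLike) -> list[Read]:
    """Load FASTA or FASTQ (optionally gzipped); validates the alphabet."""
    p = str(path)
    fmt = "fastq" if p.replace(".gz", "").endswith(("fastq", "fq")) else "fasta"
    reads = []
    with _open_text(p) as fh:
        for rec in SeqIO.parse(fh, fmt):
            try:
                seq = check_dna(str(rec.seq))
            except ValueError as exc:
                raise ValueError(f"record {rec.id!r} in {p}: {exc}") from exc
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            reads.append(Read(rec.id, seq, qual))
    return reads


def write_reads(reads: Iterable[Read], path: PathLike) -> None:
    p = str(path)
    fmt = "fastq" if p.replace(".gz", "").endswith(("fastq", "fq")) else "fasta"
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        if fmt == "fastq":
            qual = r.qual or "I" * len(r.seq)
            rec.letter_annotations["phred_quality"] = [
                ord(c) - 33 for c in qual
            ]
        records.append(rec)
    with _open_text(p, "wt") as fh:
        SeqIO.write(records, fh, fmt)


# ---------------------------------------------------------------------------
# Germline reference: FASTA + GFF3
# ---------------------------------------------------------------------------


def _rss_to_str(r: RssMatch) -> str:
    return (
        f"{r.heptamer_start}:{r.spacer_len}:{r.spacer_class}:{r.strand}:"
        f"{r.heptamer_mismatches}:{r.nonamer_mismatches}:{r.orientation}"
    )


def _rss_from_str(s: str) -> RssMatch:
    hs, sl, cls, strand, hm, nm, orient = s.split(":")
    return RssMatch(int(hs), int(sl), cls, strand, int(hm), int(nm), orient)


def write_germline(
    reference: GermlineReference, prefix: PathLike, seqid: str = "contig"
) -> tuple[Path, Path]:
    """Write ``<prefix>.fasta`` and ``<prefix>.gff3``."""
    prefix = Path(prefix)
    fasta = prefix.with_suffix(".fasta")
    gff = prefix.with_suffix(".gff3")
    segs = sorted(reference.segments, key=lambda s: (s.locus, s.start, s.name))
    records = [
        SeqRecord(Seq(reference.seq(s.name)), id=s.name, description="")
        for s in segs
    ]
    with open(fasta, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for s in segs:
            attrs = [f"ID={s.name}", f"locus={s.locus}",
                     f"functionality={s.functionality}"]
            if s.subgroup is not None:
                attrs.append(f"subgroup={s.subgroup}")
            if s.rss:
                attrs.append(
                    "rss_spacer=" + ",".join(str(r.spacer_len) for r in s.rss)
                )
                attrs.append("rss=" + ",".join(_rss_to_str(r) for r in s.rss))
            if s.cys1_nt is not None:
                attrs.append(f"cys1={s.cys1_nt}")
            if s.cys2_nt is not None:
                attrs.append(f"cys2={s.cys2_nt}")
            if s.j_anchor_nt is not None:
                attrs.append(f"j_anchor={s.j_anchor_nt}")
            if s.regions:
                attrs.append(
                    "regions="
                    + "|".join(
                        f"{k}:{a}-{b}" for k, (a, b) in sorted(s.regions.items())
                    )
                )
            fh.write(
                "\t".join(
                    [
                        seqid, "ovig", f"{s.seg_type}_gene_segment",
                        str(s.start + 1), str(s.end), ".", s.strand, ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    return fasta, gff


def read_germline(prefix: PathLike) -> GermlineReference:
    """Inverse of :func:`write_germline`."""
    prefix = Path(prefix)
    fasta = prefix.with_suffix(".fasta")
    gff = prefix.with_suffix(".gff3")
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
    }
    segments: list[GeneSegment] = []
    with open(gff) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start, end, _, strand, _, attr_str = fields
            attrs = dict(
                kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv
            )
            seg = GeneSegment(
                name=attrs["ID"],
                locus=attrs["locus"],
                seg_type=ftype.split("_")[0],
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                functionality=attrs.get("functionality", "functional"),
            )
            if "subgroup" in attrs:
                seg.subgroup = int(attrs["subgroup"])
            if "rss" in attrs:
                seg.rss = [_rss_from_str(x) for x in attrs["rss"].split(",")]
            if "cys1" in attrs:
                seg.cys1_nt = int(attrs["cys1"])
            if "cys2" in attrs:
                seg.cys2_nt = int(attrs["cys2"])
            if "j_anchor" in attrs:
                seg.j_anchor_nt = int(attrs["j_anchor"])
            if "regions" in attrs:
                for part in attrs["regions"].split("|"):
                    k, span = part.split(":")
                    a, b = span.split("-")
                    seg.regions[k] = (int(a), int(b))
            segments.append(seg)
    return GermlineReference(segments=segments, sequences=sequences)


# ---------------------------------------------------------------------------
# AIRR rearrangement TSV
# ---------------------------------------------------------------------------

AIRR_COLUMNS = [
    "sequence_id", "sample_id", "locus", "sequence", "rev_comp",
    "v_call", "d_call", "j_call", "productive",
    "v_identity", "j_identity",
    "junction", "cdr3", "cdr3_length",
    "v_3p_del", "np1_length", "d_sequence", "np2_length", "j_5p_del",
]


def rearrangements_to_frame(rearrangements: Iterable[Rearrangement]) -> pd.DataFrame:
    rows = []
    for r in rearrangements:
        j = r.junction
        rows.append(
            {
                "sequence_id": r.read_id,
                "sample_id": r.sample_id,
                "locus": r.locus,
                "sequence": r.sequence,
                "rev_comp": "T" if r.rev_comp else "F",
                "v_call": r.v_call,
                "d_call": r.d_call or "",
                "j_call": r.j_call,
                "productive": "T" if r.productive else "F",
                "v_identity": round(r.v_aln.identity, 6),
                "j_identity": round(r.j_aln.identity, 6),
                "junction": r.junction_nt,
                "cdr3": r.cdr3_nt or "",
                "cdr3_length": len(r.cdr3_nt) if r.cdr3_nt is not None else "",
                "v_3p_del": j.v3_del if j else "",
                "np1_length": len(j.np1) if j else "",
                "d_sequence": j.d_seq if j else "",
                "np2_length": len(j.np2) if j else "",
                "j_5p_del": j.j5_del if j else "",
            }
        )
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def write_airr(
    rearrangements: Iterable[Rearrangement], path: PathLike
) -> pd.DataFrame:
    df = rearrangements_to_frame(rearrangements)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_airr(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)


# ---------------------------------------------------------------------------
# Truth TSV
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "read_id", "v_name", "d_name", "j_name",
    "v3_del", "d5_del", "d3_del", "j5_del",
    "p1", "n1", "p2", "p3", "n2", "p4",
    "mutations", "seq_errors", "productive", "ambiguous_junction",
    "has_fwd_primer", "cdr3_nt", "leader",
]


def write_truth(truths: Iterable[TruthRecord], path: PathLike) -> None:
    rows = []
    for t in truths:
        rows.append(
            {
                "read_id": t.read_id,
                "v_name": t.v_name,
                "d_name": t.d_name or "",
                "j_name": t.j_name,
                "v3_del": t.v3_del, "d5_del": t.d5_del,
                "d3_del": t.d3_del, "j5_del": t.j5_del,
                "p1": t.p1, "n1": t.n1, "p2": t.p2,
                "p3": t.p3, "n2": t.n2, "p4": t.p4,
                "mutations": ";".join(
                    f"{seg}:{pos}:{a}>{b}:{int(hot)}"
                    for seg, pos, a, b, hot in t.mutations
                ),
                "seq_errors": ";".join(
                    f"{pos}:{a}>{b}" for pos, a, b in t.seq_errors
                ),
                "productive": "T" if t.productive else "F",
                "ambiguous_junction": "T" if t.ambiguous_junction else "F",
                "has_fwd_primer": "T" if t.has_fwd_primer else "F",
                "cdr3_nt": t.cdr3_nt,
                "leader": t.leader,
            }
        )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path: PathLike) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out = []
    for _, row in df.iterrows():
        mutations = []
        if row["mutations"]:
            for item in row["mutations"].split(";"):
                seg, pos, sub, hot = item.split(":")
                a, b = sub.split(">")
                mutations.append((seg, int(pos), a, b, bool(int(hot))))
        errors = []
        if row["seq_errors"]:
            for item in row["seq_errors"].split(";"):
                pos, sub = item.split(":")
                a, b = sub.split(">")
                errors.append((int(pos), a, b))
        out.append(
            TruthRecord(
                read_id=row["read_id"],
                v_name=row["v_name"],
                d_name=row["d_name"] or None,
                j_name=row["j_name"],
                v3_del=int(row["v3_del"]), d5_del=int(row["d5_del"]),
                d3_del=int(row["d3_del"]), j5_del=int(row["j5_del"]),
                p1=row["p1"], n1=row["n1"], p2=row["p2"],
                p3=row["p3"], n2=row["n2"], p4=row["p4"],
                mutations=mutations, seq_errors=errors,
                productive=row["productive"] == "T",
                ambiguous_junction=row["ambiguous_junction"] == "T",
                has_fwd_primer=row["has_fwd_primer"] == "T",
                cdr3_nt=row["cdr3_nt"],
                leader=row["leader"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Simulation config
# ---------------------------------------------------------------------------


def load_sim_config(path: PathLike) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "n_base_weights" in data:
        data["n_base_weights"] = tuple(data["n_base_weights"])
    cfg = SimulationConfig(**data)
    cfg.validate()
    return cfg
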