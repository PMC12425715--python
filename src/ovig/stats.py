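"""Usage frequencies, recombination-type tables and cross-sample summaries.

Counts are raw read counts — no deduplication — and every table is
deterministically ordered (descending fraction, ties by name) so runs
are reproducible byte-for-byte.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ovig.types import GermlineReference, Rearrangement

RARE_TYPE_THRESHOLD = 0.01


def usage_frequencies(
    rearrangements: Iterable[Rearrangement],
    seg_type: str,
    reference: Optional[GermlineReference] = None,
    by_subgroup: bool = False,
) -> pd.DataFrame:
    """Per-sample fraction of reads using each segment (or subgroup).

    Segments present in the reference but unused are reported with
    frequency 0. ``by_subgroup`` aggregates V calls by their germline
    subgroup label (requires a reference).
    """
    call_attr = {"V": "v_call", "D": "d_call", "J": "j_call"}[seg_type]
    rows = []
    for r in rearrangements:
        call = getattr(r, call_attr)
        if call is None:
            continue
        if by_subgroup:
            if reference is None:
                raise ValueError("subgroup usage requires a reference")
            call = f"subgroup{reference.get(call).subgroup}"
        rows.append({"sample_id": r.sample_id, "segment": call})
    if not rows:
        return pd.DataFrame(columns=["sample_id", "segment", "count", "fraction"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["sample_id", "segment"]).size().rename("count").reset_index()
    )
    if reference is not None and not by_subgroup:
        all_names = [s.name for s in reference.by_type(seg_type)]
        full = pd.MultiIndex.from_product(
            [sorted(df["sample_id"].unique()), sorted(all_names)],
            names=["sample_id", "segment"],
        )
        out = (
            out.set_index(["sample_id", "segment"])
            .reindex(full, fill_value=0)
            .reset_index()
        )
    out["fraction"] = out.groupby("sample_id")["count"].transform(
        lambda c: c / c.sum() if c.sum() else 0.0
    )
    return out.sort_values(
        ["sample_id", "fraction", "segment"], ascending=[True, False, True]
    ).reset_index(drop=True)


def recombination_types(
    rearrangements: Iterable[Rearrangement],
    rare_threshold: float = RARE_TYPE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distinct (V, D, J) (or (V, J)) combinations per sample.

    Returns (table, summary): the table lists each combination with
    count and fraction sorted by descending fraction; the summary
    gives, per sample, the number of distinct types and how many fall
    below the rare-type reporting threshold (default 1%).
    """
    rows = []
    for r in rearrangements:
        rows.append(
            {
                "sample_id": r.sample_id,
                "v_call": r.v_call,
                "d_call": r.d_call if r.d_call is not None else "",
                "j_call": r.j_call,
            }
        )
    if not rows:
        empty = pd.DataFrame(
            columns=["sample_id", "v_call", "d_call", "j_call", "count", "fraction"]
        )
        return empty, pd.DataFrame(
            columns=["sample_id", "n_types", "n_rare_types", "n_reads"]
        )
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["sample_id", "v_call", "d_call", "j_call"])
        .size()
        .rename("count")
        .reset_index()
    )
    table["fraction"] = table.groupby("sample_id")["count"].transform(
        lambda c: c / c.sum()
    )
    table = table.sort_values(
        ["sample_id", "fraction", "v_call", "d_call", "j_call"],
        ascending=[True, False, True, True, True],
    ).reset_index(drop=True)
    summary = (
        table.groupby("sample_id")
        .agg(
            n_types=("count", "size"),
            n_rare_types=("fraction", lambda f: int((f < rare_threshold).sum())),
            n_reads=("count", "sum"),
        )
        .reset_index()
    )
    return table, summary


def sankey_flows(rearrangements: Iterable[Rearrangement]) -> pd.DataFrame:
    """Three-column (source, target, weight) V->D and D->J flow export."""
    rows = []
    for r in rearrangements:
        if r.d_call is not None:
            rows.append((r.sample_id, r.v_call, r.d_call))
            rows.append((r.sample_id, r.d_call, r.j_call))
        else:
            rows.append((r.sample_id, r.v_call, r.j_call))
    if not rows:
        return pd.DataFrame(columns=["sample_id", "source", "target", "weight"])
    df = pd.DataFrame(rows, columns=["sample_id", "source", "target"])
    return (
        df.groupby(["sample_id", "source", "target"])
        .size()
        .rename("weight")
        .reset_index()
        .sort_values(["sample_id", "source", "target"])
        .reset_index(drop=True)
    )


def trunc_geom_pmf(p: float, cap: int) -> np.ndarray:
    """Geometric(p) pmf truncated and renormalized on {0..cap}."""
    if cap <= 0:
        return np.array([1.0])
    k = np.arange(cap + 1)
    w = p * (1 - p) ** k if p > 0 else np.ones(cap + 1)
    return w / w.sum()


def fit_geometric_deletion(
    measured: Iterable[int], cap: int, q: float = 0.25
) -> dict[str, float]:
    """Bias-corrected fit of a truncated-geometric deletion law.

    A maximal-parsimony junction decomposer re-attributes a deleted
    germline base to the segment whenever the adjacent untemplated base
    matches it by chance (probability ``q``, 1/4 for uniform N
    composition), so measured deletions are stochastically shorter than
    the generative draws: E[measured] = mu(p) - sum_{j>=1} q^j S(j; p)
    with S the survival function of the truncated geometric law. This
    inverts that relation by the method of moments, returning the
    fitted parameter and the implied generative mean.
    """
    from scipy.optimize import brentq

    vals = np.asarray(list(measured), dtype=float)
    if vals.size == 0:
        raise ValueError("no measured deletions")
    obs = float(vals.mean())

    def predicted(p: float) -> float:
        pmf = trunc_geom_pmf(p, cap)
        k = np.arange(cap + 1)
        mu = float((k * pmf).sum())
        surv = np.cumsum(pmf[::-1])[::-1]  # S(j) = P(X >= j)
        c = sum(q**j * surv[j] for j in range(1, cap + 1))
        return mu - c

    lo, hi = 1e-6, 1 - 1e-6
    if obs >= predicted(lo):
        p_hat = lo
    elif obs <= predicted(hi):
        p_hat = hi
    else:
        p_hat = brentq(lambda p: predicted(p) - obs, lo, hi)
    pmf = trunc_geom_pmf(p_hat, cap)
    k = np.arange(cap + 1)
    return {
        "p_hat": float(p_hat),
        "mean_hat": float((k * pmf).sum()),
        "mean_observed": obs,
    }


def cdr3_stats(rearrangements: Iterable[Rearrangement]) -> pd.DataFrame:
    """Mean, sd and max of CDR3 length (nt) per sample."""
    rows = [
        {"sample_id": r.sample_id, "cdr3_len": len(r.cdr3_nt)}
        for r in rearrangements
        if r.cdr3_nt is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["sample_id", "mean", "sd", "max", "n"])
    df = pd.DataFrame(rows)
    return (
        df.groupby("sample_id")["cdr3_len"]
        .agg(
            mean="mean",
            sd=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
            max="max",
            n="size",
        )
        .reset_index()
    )
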