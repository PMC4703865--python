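"""Pausing indices, expression filtering and condition contrasts.

The pausing index (PI) quantifies net movement of Pol II from the TSS
region into the gene body: the ratio of read density in the TSS-proximal
window to read density in the gene body.  High PI means paused; a PI
decrease on stimulation means pause release.  Because numerator and
denominator share the library's scale factor, PI is invariant to library
scaling, and the PI ratio between conditions is invariant to each
library's factor separately.

The PI is sensitive in genes with low Pol II occupancy, so genes whose
gene-body read density does not exceed a threshold (default 0.05 reads
per bp, scaled counts) are filtered out before any pausing statistic.

A gene counts as *activated* (pause released) in a baseline-vs-induced
contrast when PI(baseline) / PI(induced) exceeds a twofold threshold —
identically, when the PI drops by at least 50% on induction.  An
optional extra gate additionally requires the scaled gene-body count to
increase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "pausing_index",
    "pausing_table",
    "filter_expressed",
    "build_contrast",
    "classify_activated",
    "occupancy_change_pct",
]


def pausing_index(tss_density: float, body_density: float) -> float:
    """PI = TSS-proximal density / gene-body density.

    Undefined (error) at zero body density; such genes must be removed
    by the expression filter first.
    """
    if body_density <= 0:
        raise ValueError("pausing index undefined for body_density <= 0")
    return tss_density / body_density


def pausing_table(density_df: pd.DataFrame, mark: str = "PolII") -> pd.DataFrame:
    """Per-gene, per-condition pausing records from a tidy density table.

    Expects columns gene_id, condition, mark, window_kind, density,
    scaled_count.  Returns one row per (gene_id, condition) with
    tss_density, body_density, tss_count, body_count and pausing_index
    (NaN where the body density is zero or missing).
    """
    sub = density_df[density_df["mark"] == mark]
    wide = sub.pivot_table(
        index=["gene_id", "condition"],
        columns="window_kind",
        values=["density", "scaled_count"],
        aggfunc="first",
    )
    out = pd.DataFrame(
        {
            "tss_density": wide[("density", "tss")],
            "body_density": wide[("density", "body")],
            "tss_count": wide[("scaled_count", "tss")],
            "body_count": wide[("scaled_count", "body")],
        }
    ).reset_index()
    body = out["body_density"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = out["tss_density"].to_numpy(dtype=float) / body
    pi[~(body > 0)] = np.nan
    out["pausing_index"] = pi
    return out


def filter_expressed(
    pausing_df: pd.DataFrame,
    threshold: float = 0.05,
    policy: str = "any",
    conditions: list[str] | None = None,
) -> set[str]:
    """Genes whose body density exceeds the threshold, by condition policy.

    ``policy='any'`` (default) passes a gene expressed above threshold in
    at least one condition under comparison — an 'all' rule would exclude
    genes silent at baseline, which are exactly the inducible genes of
    interest.  ``policy='all'`` requires every condition.
    """
    df = pausing_df
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
    passed = df.assign(ok=df["body_density"] > threshold).groupby("gene_id")["ok"]
    if policy == "any":
        mask = passed.any()
    elif policy == "all":
        mask = passed.all()
    else:
        raise ValueError(f"unknown filter policy: {policy!r}")
    return set(mask[mask].index)


def occupancy_change_pct(
    count_a,
    count_b,
    pseudocount: float = 1.0,
    scale_factor: float = 1.0,
):
    """Percent change of scaled counts from condition A to B.

    ``100 * (B - A) / max(A, pseudocount * scale_factor)``: the scaled
    pseudocount floor keeps the denominator positive for silent genes.
    Accepts scalars or arrays.
    """
    a = np.asarray(count_a, dtype=float)
    b = np.asarray(count_b, dtype=float)
    denom = np.maximum(a, pseudocount * scale_factor)
    out = 100.0 * (b - a) / denom
    return out if out.ndim else float(out)


def build_contrast(
    pausing_df: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    density_threshold: float = 0.05,
    filter_policy: str = "any",
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
    require_body_increase: bool = False,
    gene_universe: set[str] | None = None,
) -> pd.DataFrame:
    """Contrast condition A (baseline) against B (induced) per gene.

    Returns one row per gene with PIs, ``pi_ratio = PI(A)/PI(B)`` (values
    above 1 mean pause release on induction), TSS/body percent occupancy
    changes, the expression-filter flag and the activated classification.
    ``gene_universe`` optionally restricts to e.g. peak-gated genes.
    """
    a = pausing_df[pausing_df["condition"] == cond_a].set_index("gene_id")
    b = pausing_df[pausing_df["condition"] == cond_b].set_index("gene_id")
    genes = a.index.intersection(b.index)
    if gene_universe is not None:
        genes = genes.intersection(sorted(gene_universe))
    passing = filter_expressed(
        pausing_df, threshold=density_threshold, policy=filter_policy,
        conditions=[cond_a, cond_b],
    )
    out = pd.DataFrame(index=genes)
    out.index.name = "gene_id"
    out["pi_a"] = a.loc[genes, "pausing_index"]
    out["pi_b"] = b.loc[genes, "pausing_index"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pi_ratio"] = out["pi_a"] / out["pi_b"]
    out["tss_change_pct"] = occupancy_change_pct(
        a.loc[genes, "tss_count"].to_numpy(), b.loc[genes, "tss_count"].to_numpy(),
        pseudocount=pseudocount,
    )
    out["body_change_pct"] = occupancy_change_pct(
        a.loc[genes, "body_count"].to_numpy(), b.loc[genes, "body_count"].to_numpy(),
        pseudocount=pseudocount,
    )
    out["body_increased"] = b.loc[genes, "body_count"] > a.loc[genes, "body_count"]
    out["filter_pass"] = [g in passing for g in genes]
    out = out.reset_index()
    out["activated"] = classify_activated(
        out, fold_threshold=fold_threshold, require_body_increase=require_body_increase
    )
    return out


def classify_activated(
    contrast_df: pd.DataFrame,
    fold_threshold: float = 2.0,
    require_body_increase: bool = False,
) -> np.ndarray:
    """Boolean activated flag: PI ratio above the fold threshold.

    ``pi_ratio > fold_threshold`` with defined PIs and a passed
    expression filter; at the default threshold 2 this is exactly the
    'at least 50% PI reduction' criterion.  The optional body-increase
    gate additionally requires more scaled gene-body signal on induction.
    """
    ratio = contrast_df["pi_ratio"].to_numpy(dtype=float)
    ok = contrast_df["filter_pass"].to_numpy(dtype=bool)
    act = ok & np.isfinite(ratio) & (ratio > fold_threshold)
    if require_body_increase:
        act &= contrast_df["body_increased"].to_numpy(dtype=bool)
    return act
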