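"""End-to-end contrast orchestration.

``run_contrast`` executes the full downstream analysis for one
baseline-vs-induced condition pair: annotation parsing, optional peak
gating, read assignment under the single-gene rule, library scaling to
the smallest library, density computation, primary-transcript selection
by maximum body density, the body-density expression filter, per-
condition pausing indices, contrast classification, cohort bootstrap
effect sizes, and report output (per-gene TSV, cohort-statistics JSON,
TSS-centred profile matrices, bedGraph tracks, run log).

Cohort statistics computed when the inputs allow:

* bootstrap CIs for the median TSS / gene-body percent occupancy change
  on the activated set;
* a bootstrap CI for the median PI ratio of the activated set;
* the difference of median gene-body coverage depth between induced and
  baseline conditions (one-sided, greater);
* for each additional (DDR) mark, the gene-body percent change CI on
  the activated set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bootstrap_stats, coverage, pausing, peaks as peaks_mod
from .coverage import ReadSet, load_reads
from .gene_models import (
    TranscriptModel,
    derive_windows,
    gene_spans,
    parse_annotation,
    select_primary_transcript,
)

__all__ = ["ContrastConfig", "RunResult", "run_contrast", "read_library_sheet"]

logger = logging.getLogger(__name__)


@dataclass
class ContrastConfig:
    """Parameters of one contrast run (baseline condition A vs induced B)."""

    sheet_path: str
    annotation_path: str
    condition_a: str
    condition_b: str
    marks: tuple[str, ...] = ("PolII",)
    density_threshold: float = 0.05
    filter_policy: str = "any"
    fold_threshold: float = 2.0
    require_body_increase: bool = False
    peak_gating: bool = False
    peak_min_fold: float = 4.0
    peak_fdr: float = 0.001
    peak_slop: int = 2000
    n_boot: int = 100_000
    seed: int = 0
    bin_size: int = 50
    profile_genes: int = 100
    write_tracks: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("density_threshold", "fold_threshold", "peak_min_fold", "peak_fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class RunResult:
    config: ContrastConfig
    genes: pd.DataFrame  # per-gene report table
    densities: pd.DataFrame  # tidy density table
    pausing: pd.DataFrame
    contrast: pd.DataFrame
    stats: dict
    scale_factors: dict[str, float]
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    peak_genes: set[str] | None = None


def read_library_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "condition", "mark", "path"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"library sheet missing columns: {sorted(missing)}")
    return sheet


def _require_libraries(sheet: pd.DataFrame, config: ContrastConfig) -> pd.DataFrame:
    conds = {config.condition_a, config.condition_b}
    sub = sheet[sheet["condition"].isin(conds) & sheet["mark"].isin(set(config.marks) | {"input"})]
    for cond in conds:
        for mark in config.marks:
            if sub[(sub["condition"] == cond) & (sub["mark"] == mark)].empty:
                raise ValueError(f"library sheet lacks {cond} x {mark}")
    return sub


def run_contrast(config: ContrastConfig) -> RunResult:
    """Run the full contrast pipeline; see the module docstring."""
    sheet = read_library_sheet(config.sheet_path)
    sub = _require_libraries(sheet, config)

    transcripts_by_gene = parse_annotation(config.annotation_path)
    logger.info("annotation: %d genes", len(transcripts_by_gene))

    read_sets: dict[str, ReadSet] = {}
    meta: dict[str, tuple[str, str]] = {}
    for _, row in sub.iterrows():
        rs = load_reads(row["path"])
        read_sets[row["library_id"]] = rs
        meta[row["library_id"]] = (row["condition"], row["mark"])

    totals = {lib: rs.total_mapped_reads for lib, rs in read_sets.items()}
    scale_factors = coverage.library_scale_factors(totals)

    # --- optional peak gating on Pol II vs matched input, either condition ---
    peak_genes: set[str] | None = None
    if config.peak_gating:
        peak_genes = set()
        all_transcripts = [t for ts in transcripts_by_gene.values() for t in ts]
        for cond in (config.condition_a, config.condition_b):
            ip = _find_library(meta, cond, "PolII")
            ctrl = _find_library(meta, cond, "input")
            if ip is None or ctrl is None:
                raise ValueError(f"peak gating needs PolII and input libraries for {cond}")
            called = peaks_mod.call_peaks(
                read_sets[ip].reads,
                read_sets[ctrl].reads,
                min_fold=config.peak_min_fold,
                fdr=config.peak_fdr,
            )
            peak_genes |= peaks_mod.genes_with_peak(called, all_transcripts, slop=config.peak_slop)
        logger.info("peak gating retains %d genes", len(peak_genes))

    # --- primary transcript per gene: maximum body density over the two
    # contrast conditions' Pol II libraries (scaled counts) ---
    spans = gene_spans(transcripts_by_gene)
    polii_libs = [
        lib for lib, (cond, mark) in meta.items()
        if mark == "PolII" and cond in (config.condition_a, config.condition_b)
    ]
    primaries = _select_primaries(transcripts_by_gene, spans, read_sets, scale_factors, polii_libs)
    window_sets = {g: derive_windows(t) for g, t in primaries.items()}

    # --- assignment, scaling, densities per library ---
    frames = []
    for lib in read_sets:
        cond, mark = meta[lib]
        res = coverage.assign_reads(read_sets[lib].reads, window_sets, spans)
        dens = coverage.window_density(res.counts, scale_factors[lib])
        dens["library_id"] = lib
        dens["condition"] = cond
        dens["mark"] = mark
        frames.append(dens)
        logger.info(
            "%s: %d reads, %d discarded (multi-gene), %d assigned",
            lib, res.total_reads, res.n_discarded_multi_gene, res.n_assigned,
        )
    densities = pd.concat(frames, ignore_index=True)

    # --- pausing and contrast on the Pol II mark ---
    ptable = pausing.pausing_table(densities, mark="PolII")
    contrast = pausing.build_contrast(
        ptable,
        config.condition_a,
        config.condition_b,
        density_threshold=config.density_threshold,
        filter_policy=config.filter_policy,
        fold_threshold=config.fold_threshold,
        require_body_increase=config.require_body_increase,
        gene_universe=peak_genes,
    )
    activated = contrast[contrast["activated"]]

    # --- per-gene mean body depth per condition (Pol II) ---
    depth_rows = []
    for lib in polii_libs:
        cond, _ = meta[lib]
        for gene_id, ws in window_sets.items():
            if not ws.body_valid or ws.body_window is None:
                continue
            depth_rows.append(
                {
                    "gene_id": gene_id,
                    "condition": cond,
                    "mean_body_depth": coverage.mean_body_depth(
                        read_sets[lib].reads, ws.body_window, scale_factors[lib]
                    ),
                }
            )
    body_depth = pd.DataFrame(depth_rows)

    # --- DDR-mark gene-body contrasts on the activated set ---
    ddr_changes: dict[str, pd.Series] = {}
    for mark in config.marks:
        if mark == "PolII":
            continue
        mtable = pausing.pausing_table(densities, mark=mark)
        mcontrast = pausing.build_contrast(
            mtable, config.condition_a, config.condition_b,
            density_threshold=0.0, filter_policy="any",
        )
        mcontrast = mcontrast.set_index("gene_id")
        shared = [g for g in activated["gene_id"] if g in mcontrast.index]
        ddr_changes[mark] = mcontrast.loc[shared, "body_change_pct"]

    stats = _cohort_stats(config, contrast, activated, body_depth, ddr_changes)

    genes_report = _gene_report(contrast, ptable, primaries, config)
    profiles = _profiles(config, read_sets, meta, scale_factors, window_sets, ptable)

    result = RunResult(
        config=config,
        genes=genes_report,
        densities=densities,
        pausing=ptable,
        contrast=contrast,
        stats=stats,
        scale_factors=scale_factors,
        profiles=profiles,
        peak_genes=peak_genes,
    )
    if config.outdir is not None:
        _write_outputs(result, read_sets, meta)
    return result


def _find_library(meta, condition: str, mark: str) -> str | None:
    for lib, (cond, m) in meta.items():
        if cond == condition and m == mark:
            return lib
    return None


def _select_primaries(
    transcripts_by_gene, spans, read_sets, scale_factors, polii_libs
) -> dict[str, TranscriptModel]:
    """Primary transcript per gene by maximum scaled body density."""
    # body windows of *all* transcripts, assigned under the gene-level
    # single-gene rule
    all_window_sets = {}
    tx_index = {}
    for gene_id, models in transcripts_by_gene.items():
        for t in models:
            all_window_sets[t.transcript_id] = derive_windows(t)
            tx_index[t.transcript_id] = t
    body_density: dict[str, float] = {tx: 0.0 for tx in all_window_sets}
    for lib in polii_libs:
        res = coverage.assign_reads(read_sets[lib].reads, all_window_sets, spans)
        dens = coverage.window_density(res.counts, scale_factors[lib])
        body = dens[dens["window_kind"] == "body"]
        for tx, d in zip(body["transcript_id"], body["density"].fillna(0.0)):
            body_density[tx] += d
    primaries = {}
    for gene_id, models in transcripts_by_gene.items():
        chosen = select_primary_transcript(models, body_density)
        primaries[gene_id] = tx_index[chosen]
    return primaries


def _cohort_stats(config, contrast, activated, body_depth, ddr_changes) -> dict:
    stats: dict = {
        "condition_a": config.condition_a,
        "condition_b": config.condition_b,
        "n_genes": int(len(contrast)),
        "n_filter_pass": int(contrast["filter_pass"].sum()),
        "n_activated": int(len(activated)),
        "seed": config.seed,
        "n_boot": config.n_boot,
        "effects": {},
    }
    if len(activated) == 0:
        logger.warning("empty activated set; cohort bootstrap statistics skipped")
        return stats
    eff = stats["effects"]
    eff["tss_change_pct"] = bootstrap_stats.bootstrap_median(
        activated["tss_change_pct"].to_numpy(), n_boot=config.n_boot,
        seed=config.seed, alternative="greater",
    ).to_dict()
    eff["body_change_pct"] = bootstrap_stats.bootstrap_median(
        activated["body_change_pct"].to_numpy(), n_boot=config.n_boot,
        seed=config.seed, alternative="greater",
    ).to_dict()
    eff["pi_ratio"] = bootstrap_stats.bootstrap_median(
        activated["pi_ratio"].to_numpy(), n_boot=config.n_boot,
        seed=config.seed, alternative="greater",
    ).to_dict()
    if len(body_depth):
        act_genes = set(activated["gene_id"])
        sub = body_depth[body_depth["gene_id"].isin(act_genes)]
        grp_b = sub[sub["condition"] == config.condition_b]["mean_body_depth"].to_numpy()
        grp_a = sub[sub["condition"] == config.condition_a]["mean_body_depth"].to_numpy()
        if len(grp_a) and len(grp_b):
            eff["mean_body_depth"] = bootstrap_stats.bootstrap_effect(
                grp_b, grp_a, n_boot=config.n_boot, seed=config.seed,
                alternative="greater",
            ).to_dict()
    for mark, changes in ddr_changes.items():
        if len(changes):
            eff[f"{mark}_body_change_pct"] = bootstrap_stats.bootstrap_median(
                changes.to_numpy(), n_boot=config.n_boot, seed=config.seed,
                alternative="greater",
            ).to_dict()
    return stats


def _gene_report(contrast, ptable, primaries, config) -> pd.DataFrame:
    report = contrast.copy()
    report.insert(1, "transcript_id", [primaries[g].transcript_id for g in report["gene_id"]])
    wide = ptable.pivot_table(
        index="gene_id",
        columns="condition",
        values=["tss_density", "body_density", "pausing_index"],
        aggfunc="first",
    )
    wide.columns = [f"{v}_{c}" for v, c in wide.columns]
    return report.merge(wide.reset_index(), on="gene_id", how="left")


def _profiles(config, read_sets, meta, scale_factors, window_sets, ptable) -> dict[str, pd.DataFrame]:
    """TSS-centred matrices, rows sorted descending by induced body density."""
    induced = ptable[ptable["condition"] == config.condition_b]
    order = (
        induced.sort_values(["body_density", "gene_id"], ascending=[False, True])
        ["gene_id"].head(config.profile_genes).tolist()
    )
    order = [g for g in order if g in window_sets]
    out = {}
    for lib, (cond, mark) in meta.items():
        if mark == "input" or cond not in (config.condition_a, config.condition_b):
            continue
        key = f"{mark}_{cond.replace('+', '_')}"
        out[key] = coverage.profile_matrix(
            read_sets[lib].reads, window_sets, order,
            bin_size=config.bin_size, scale_factor=scale_factors[lib],
        )
    return out


def _write_outputs(result: RunResult, read_sets, meta) -> None:
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    result.densities.to_csv(outdir / "window_densities.tsv", sep="\t", index=False)
    with open(outdir / "cohort_stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for key, mat in result.profiles.items():
        mat.to_csv(outdir / f"profile_{key}.tsv", sep="\t")
    if result.config.write_tracks:
        tracks = outdir / "tracks"
        tracks.mkdir(exist_ok=True)
        for lib, rs in read_sets.items():
            bg = coverage.coverage_bedgraph(
                rs.reads, bin_size=result.config.bin_size,
                scale_factor=result.scale_factors[lib],
            )
            (tracks / f"{lib}.bedGraph").write_text(bg)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("pausekit contrast run\n")
        for k, v in vars(result.config).items():
            fh.write(f"{k} = {v!r}\n")
        for lib, factor in sorted(result.scale_factors.items()):
            fh.write(f"scale_factor[{lib}] = {factor}\n")
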