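"""Stage orchestration over a synthetic (or user-supplied) study bundle.

Directory layout of a run:

    run_dir/
      bundle/            simulator output (genomes, gene tables, BEDs, counts)
      features/          per-cell architecture features + promoter BED
      de/                per-condition DE tables
      coverage/          per-condition stranded damage/repair coverage
      stratified/        tertile comparisons and correlations
      motif/             enrichment JSON + null-ratio histogram
      report.json
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .coverage import add_normalization, transcribed_strand_coverage
from .de import build_status_grid, condition_overlap, consistency_sets, nb_de_test
from .features import compute_features, extract_promoters, tertile_assign
from .models import GeneModel
from .motifs import PWM, permutation_test, write_meme
from .simulate import SimConfig, simulate_study
from .stats import rank_compare, spearman

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["length_bp", "gc_fraction", "exon_fraction"]


def default_motif() -> PWM:
    """Built-in example motif for synthetic runs (8 bp, strongly informative)."""
    consensus = "TGACCTTT"
    probs = np.full((len(consensus), 4), 0.05)
    for i, base in enumerate(consensus):
        probs[i, "ACGT".index(base)] = 0.85
    return PWM(name="example_motif", probs=probs)


def run_features(run_dir: Path, manifest: dict, flank_bp: int = 3000) -> None:
    fdir = run_dir / "features"
    fdir.mkdir(exist_ok=True)
    for cell, entry in manifest["files"].items():
        sequences = tio.read_fasta(run_dir / "bundle" / entry["genome"])
        genes = tio.read_gene_table(run_dir / "bundle" / entry["genes"])
        feats = compute_features(genes, sequences)
        pd.DataFrame(
            [
                {
                    "gene_id": f.gene_id,
                    "length_bp": f.length_bp,
                    "gc_fraction": f.gc_fraction,
                    "exon_fraction": f.exon_fraction,
                }
                for f in feats
            ]
        ).to_csv(fdir / f"{cell}.tsv", sep="\t", index=False, float_format="%.6g")
        chrom_sizes = {c: len(s) for c, s in sequences.items()}
        promoters = extract_promoters(genes, chrom_sizes, flank_bp=flank_bp)
        tio.write_bed6(fdir / f"{cell}.promoters.bed", promoters)


def run_de(run_dir: Path, manifest: dict) -> None:
    ddir = run_dir / "de"
    ddir.mkdir(exist_ok=True)
    for cell, entry in manifest["files"].items():
        for agent, cond in entry["conditions"].items():
            control = tio.read_counts(run_dir / "bundle" / cond["counts_control"])
            treated = tio.read_counts(run_dir / "bundle" / cond["counts_treated"])
            table = nb_de_test(
                control.to_numpy(), treated.to_numpy(), gene_ids=control.index
            )
            tio.write_de_table(ddir / f"{cell}_{agent}.tsv", table)


def run_coverage(run_dir: Path, manifest: dict) -> None:
    cdir = run_dir / "coverage"
    cdir.mkdir(exist_ok=True)
    skip_reports = {}
    for cell, entry in manifest["files"].items():
        genes = tio.read_gene_table(run_dir / "bundle" / entry["genes"])
        for agent, cond in entry["conditions"].items():
            for kind in ("damage", "repair"):
                reads = tio.read_bed6(run_dir / "bundle" / cond[kind])
                profiles, report = transcribed_strand_coverage(reads, genes)
                library = max(len(reads), 1)
                add_normalization(profiles, genes, library)
                pd.DataFrame(
                    [
                        {
                            "gene_id": gid,
                            "ts_count": p.ts_count,
                            "nts_count": p.nts_count,
                            "ts_norm": p.ts_norm,
                            "nts_norm": p.nts_norm,
                        }
                        for gid, p in sorted(profiles.items())
                    ]
                ).to_csv(
                    cdir / f"{cell}_{agent}_{kind}.tsv", sep="\t", index=False, float_format="%.6g"
                )
                skip_reports[f"{cell}_{agent}_{kind}"] = report
    with open(cdir / "skip_report.json", "w") as fh:
        json.dump(skip_reports, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_stratify(run_dir: Path, manifest: dict) -> None:
    sdir = run_dir / "stratified"
    sdir.mkdir(exist_ok=True)
    stat_rows = []
    box_rows = []
    for cell, entry in manifest["files"].items():
        feats = pd.read_csv(run_dir / "features" / f"{cell}.tsv", sep="\t")
        for agent in entry["conditions"]:
            de = tio.read_de_table(run_dir / "de" / f"{cell}_{agent}.tsv")
            merged = feats.merge(de, on="gene_id")
            cov = pd.read_csv(run_dir / "coverage" / f"{cell}_{agent}_damage.tsv", sep="\t")
            merged = merged.merge(cov[["gene_id", "ts_count", "ts_norm"]], on="gene_id")
            # correlations of fold change with architecture and damage load
            for feature in FEATURE_COLUMNS + ["ts_norm"]:
                x = merged[feature].to_numpy()
                y = merged["log2fc"].to_numpy()
                try:
                    rho, p = spearman(x, y)
                except ValueError:
                    rho, p = float("nan"), float("nan")
                stat_rows.append(
                    {
                        "cell": cell,
                        "agent": agent,
                        "comparison": f"spearman:{feature}~log2fc",
                        "statistic": rho,
                        "raw_p": p,
                        "adj_p": float("nan"),
                        "n": len(merged),
                    }
                )
            # tertile group comparisons per architecture feature
            for feature in FEATURE_COLUMNS:
                labels, bounds = tertile_assign(merged[feature].to_numpy())
                merged[f"{feature}_bin"] = labels
                groups = {
                    lab: merged.loc[merged[f"{feature}_bin"] == lab, "log2fc"].to_numpy()
                    for lab in ("low", "mid", "high")
                }
                groups = {k: v for k, v in groups.items() if v.size > 0}
                if len(groups) < 2:
                    continue
                comp = rank_compare(groups)
                for pair in comp.pairs:
                    stat_rows.append(
                        {
                            "cell": cell,
                            "agent": agent,
                            "comparison": f"ranksum:{feature}:{pair.group_a}-vs-{pair.group_b}",
                            "statistic": pair.u_statistic,
                            "raw_p": pair.p_raw,
                            "adj_p": pair.p_adj,
                            "n": comp.groups[pair.group_a].n + comp.groups[pair.group_b].n,
                        }
                    )
                for lab, summ in comp.groups.items():
                    box_rows.append(
                        {
                            "cell": cell,
                            "agent": agent,
                            "feature": feature,
                            "bin": lab,
                            "boundary_low": bounds[0],
                            "boundary_high": bounds[1],
                            "n": summ.n,
                            "median": summ.median,
                            "q1": summ.q1,
                            "q3": summ.q3,
                        }
                    )
    pd.DataFrame(stat_rows).to_csv(sdir / "statistics.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(box_rows).to_csv(sdir / "boxplot_stats.tsv", sep="\t", index=False, float_format="%.6g")


def _load_grid(run_dir: Path, manifest: dict, lfc_threshold: float, alpha: float):
    tables = {}
    for cell, entry in manifest["files"].items():
        for agent in entry["conditions"]:
            tables[f"{cell}_{agent}"] = tio.read_de_table(run_dir / "de" / f"{cell}_{agent}.tsv")
    return build_status_grid(tables, lfc_threshold=lfc_threshold, alpha=alpha)


def run_motif(
    run_dir: Path,
    manifest: dict,
    pwm: PWM | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    p_cut: float = 1e-4,
    k_min: int = 5,
    lfc_threshold: float = 0.7,
    alpha: float = 0.05,
) -> None:
    mdir = run_dir / "motif"
    mdir.mkdir(exist_ok=True)
    if pwm is None:
        pwm = default_motif()
    write_meme(mdir / "motif.meme", [pwm])
    grid = _load_grid(run_dir, manifest, lfc_threshold, alpha)
    k = min(k_min, grid.shape[1])
    consist, _ = consistency_sets(grid, k)
    targets = list(consist["gene_id"])
    if not targets:
        up_any, _ = consistency_sets(grid, 1)
        targets = list(up_any["gene_id"])
    results = {}
    if not targets:
        results["status"] = "skipped: no up-regulated genes"
    else:
        # scan each cell's promoter universe separately
        for cell, entry in manifest["files"].items():
            sequences = tio.read_fasta(run_dir / "bundle" / entry["genome"])
            promoters = tio.read_bed6(run_dir / "features" / f"{cell}.promoters.bed")
            universe = {
                p.name: sequences[p.chrom][p.start : p.end] for p in promoters
            }
            present = [t for t in targets if t in universe]
            if not present:
                results[cell] = {"status": "skipped: targets lack promoters"}
                continue
            res = permutation_test(
                present, universe, pwm, n_iter=n_iter, seed=seed, p_cut=p_cut
            )
            results[cell] = res.to_dict() | {"n_targets": len(present)}
            hist, edges = np.histogram(res.null_ratios, bins=20, range=(0.0, 1.0))
            pd.DataFrame(
                {"bin_low": edges[:-1], "bin_high": edges[1:], "count": hist}
            ).to_csv(mdir / f"{cell}.null_hist.tsv", sep="\t", index=False, float_format="%.6g")
    with open(mdir / "enrichment.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")


def build_report(
    run_dir,
    k_min: int = 5,
    lfc_threshold: float = 0.7,
    alpha: float = 0.05,
) -> dict:
    """Aggregate per-condition DEG counts, Venn regions, consistency sets,
    correlations, and enrichment p-values; missing stages are flagged."""
    run_dir = Path(run_dir)
    with open(run_dir / "bundle" / "manifest.json") as fh:
        manifest = json.load(fh)
    report: dict = {"missing_sections": []}

    if (run_dir / "de").is_dir():
        grid = _load_grid(run_dir, manifest, lfc_threshold, alpha)
        report["deg_counts"] = {
            cond: {
                "up": int((grid[cond] == "up").sum()),
                "down": int((grid[cond] == "down").sum()),
            }
            for cond in grid.columns
        }
        venn = {}
        for cell, entry in manifest["files"].items():
            conds = [f"{cell}_{a}" for a in entry["conditions"]]
            if len(conds) == 3:
                regions, triple = condition_overlap(grid, conds)
                venn[cell] = {"regions": regions, "triple_n": len(triple)}
        report["venn"] = venn
        k = min(k_min, grid.shape[1])
        consist, stringent = consistency_sets(grid, k)
        report["consistency"] = {
            "k_min": k,
            "n_genes": int(len(consist)),
            "stringent_n": len(stringent),
        }
    else:
        report["missing_sections"].append("de")

    stats_path = run_dir / "stratified" / "statistics.tsv"
    if stats_path.exists():
        stats = pd.read_csv(stats_path, sep="\t")
        corr = stats[stats["comparison"].str.startswith("spearman:")]
        report["correlations"] = [
            {
                "cell": r.cell,
                "agent": r.agent,
                "comparison": r.comparison,
                "rho": None if pd.isna(r.statistic) else float(r.statistic),
                "p": None if pd.isna(r.raw_p) else float(r.raw_p),
            }
            for r in corr.itertuples(index=False)
        ]
    else:
        report["missing_sections"].append("stratified")

    enrich_path = run_dir / "motif" / "enrichment.json"
    if enrich_path.exists():
        with open(enrich_path) as fh:
            report["enrichment"] = json.load(fh)
    else:
        report["enrichment"] = "skipped"
        report["missing_sections"].append("motif")
    return report


def run_all(
    config: SimConfig,
    run_dir,
    flank_bp: int = 3000,
    lfc_threshold: float = 0.7,
    alpha: float = 0.05,
    n_iter: int = 1000,
    p_cut: float = 1e-4,
    k_min: int = 5,
    pwm: PWM | None = None,
    skip_motif: bool = False,
) -> dict:
    """Simulate a study bundle and execute every stage in dependency order."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = simulate_study(config, run_dir / "bundle")
    run_features(run_dir, manifest, flank_bp=flank_bp)
    run_de(run_dir, manifest)
    run_coverage(run_dir, manifest)
    run_stratify(run_dir, manifest)
    if not skip_motif:
        run_motif(
            run_dir,
            manifest,
            pwm=pwm,
            n_iter=n_iter,
            seed=config.seed,
            p_cut=p_cut,
            k_min=k_min,
            lfc_threshold=lfc_threshold,
            alpha=alpha,
        )
    report = build_report(run_dir, k_min=k_min, lfc_threshold=lfc_threshold, alpha=alpha)
    with open(run_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
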