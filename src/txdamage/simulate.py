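"""Forward simulator of the damage -> repair -> transcription causal model.

Synthetic genes are laid out on one chromosome per cell type with
controllable length, GC, and exon composition. Agent-specific target sites
(dipyrimidines for UV; guanines for cisplatin/BPDE) are damaged
independently per site; exonic damages are repaired with a boosted
probability; residual transcribed-strand damage suppresses the treated
expression mean exponentially. Every stage records full ground truth so
downstream estimators can be checked for parameter recovery.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .models import GeneModel, StrandedInterval

AGENTS = ("UV", "cisplatin", "BPDE")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PYRIMIDINES = frozenset("CT")


class ConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 100
    length_lognorm_mu: float = 8.0
    length_lognorm_sigma: float = 0.6
    exon_fraction_range: tuple = (0.1, 0.9)
    gc_range: tuple = (0.35, 0.6)
    agent: str = "UV"
    damage_rate: float = 0.01
    repair_prob_base: float = 0.5
    exon_repair_factor: float = 1.0
    suppression_beta: float = 0.1
    induced_gene_ids: frozenset = frozenset()
    induction_factor: float = 2.0
    nb_dispersion: float = 0.05
    baseline_mean_range: tuple = (50.0, 500.0)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "induced_gene_ids", frozenset(self.induced_gene_ids))
        self.validate()

    def validate(self):
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for nm in ("exon_fraction_range", "gc_range", "baseline_mean_range"):
            lo, hi = getattr(self, nm)
            if lo > hi:
                raise ConfigError(f"{nm}: low {lo} > high {hi}")
        for nm in ("exon_fraction_range", "gc_range"):
            lo, hi = getattr(self, nm)
            if lo < 0 or hi > 1:
                raise ConfigError(f"{nm} must lie in [0, 1]")
        if self.agent not in AGENTS:
            raise ConfigError(f"unknown agent {self.agent!r}; expected one of {AGENTS}")
        if self.damage_rate < 0:
            raise ConfigError("damage_rate must be >= 0")
        if not 0 <= self.repair_prob_base <= 1:
            raise ConfigError("repair_prob_base must be in [0, 1]")
        if self.exon_repair_factor < 0:
            raise ConfigError("exon_repair_factor must be >= 0")
        if self.suppression_beta < 0:
            raise ConfigError("suppression_beta must be >= 0")
        if self.induction_factor <= 0:
            raise ConfigError("induction_factor must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.baseline_mean_range[0] <= 0:
            raise ConfigError("baseline means must be > 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")


TRUTH_COLUMNS = [
    "gene_id",
    "n_target_sites_ts",
    "n_target_sites_nts",
    "damages_ts",
    "damages_nts",
    "repaired_ts",
    "repaired_nts",
    "residual_ts",
    "residual_nts",
    "baseline_mean",
    "expected_log2fc",
    "induced",
]


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _random_composition(rng: np.random.Generator, total: int, k: int) -> list:
    """Split `total` into k positive integer parts, uniformly at random."""
    if k == 0:
        return []
    if total < k:
        raise ValueError("total must be >= k")
    if k == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=k - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [total]])
    return np.diff(bounds).astype(int).tolist()


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _build_exons(rng: np.random.Generator, start: int, length: int, frac: float) -> tuple:
    exon_bp = int(round(frac * length))
    exon_bp = max(1, min(length, exon_bp))
    if exon_bp == length:
        return ((start, start + length),)
    intron_bp = length - exon_bp
    max_exons = min(8, exon_bp, intron_bp + 1)
    n_ex = int(rng.integers(1, max_exons + 1))
    exon_lens = _random_composition(rng, exon_bp, n_ex)
    if n_ex == 1:
        offset = int(rng.integers(0, intron_bp + 1))
        return ((start + offset, start + offset + exon_bp),)
    intron_lens = _random_composition(rng, intron_bp, n_ex - 1)
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < n_ex - 1:
            pos += intron_lens[i]
    return tuple(exons)


def simulate_genome(config: SimConfig, chrom: str = "chrS"):
    """One synthetic chromosome with non-overlapping genes.

    Returns (sequences, genes): sequences maps chrom -> str; genes is a list
    of GeneModel with gene ids g0000, g0001, ... Deterministic given
    config.seed.
    """
    config.validate()
    rng = child_rng(config.seed, "genome")
    lengths = np.maximum(
        200,
        np.round(
            rng.lognormal(config.length_lognorm_mu, config.length_lognorm_sigma, config.n_genes)
        ).astype(int),
    )
    gcs = rng.uniform(*config.gc_range, size=config.n_genes)
    fracs = rng.uniform(*config.exon_fraction_range, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    gaps = rng.integers(200, 1000, size=config.n_genes + 1)
    inter_gc = float(np.mean(config.gc_range))

    parts = []
    genes = []
    pos = 0
    for i in range(config.n_genes):
        gap = int(gaps[i])
        parts.append(_random_sequence(rng, gap, inter_gc))
        pos += gap
        length = int(lengths[i])
        start, end = pos, pos + length
        exons = _build_exons(rng, start, length, float(fracs[i]))
        parts.append(_random_sequence(rng, length, float(gcs[i])))
        genes.append(
            GeneModel(
                gene_id=f"g{i:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=str(strands[i]),
                exons=exons,
            )
        )
        pos = end
    parts.append(_random_sequence(rng, int(gaps[-1]), inter_gc))
    return {chrom: "".join(parts)}, genes


def enumerate_target_sites(sequence: str, strand: str, agent: str) -> list:
    """0-based plus-strand start positions of damage-target sites.

    UV targets dipyrimidine dinucleotides (both bases pyrimidines);
    cisplatin/BPDE target G. The minus strand is assessed on the reverse
    complement and positions are mapped back to plus-strand starts.
    Positions are sorted and unique.
    """
    if agent not in AGENTS:
        raise ValueError(f"unknown agent {agent!r}")
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    seq = sequence.upper()
    width = target_width(agent)
    if strand == "-":
        seq = reverse_complement(seq)
    n = len(seq)
    positions = []
    if agent == "UV":
        for i in range(n - 1):
            if seq[i] in _PYRIMIDINES and seq[i + 1] in _PYRIMIDINES:
                positions.append(i)
    else:
        positions = [i for i, b in enumerate(seq) if b == "G"]
    if strand == "-":
        positions = sorted(n - p - width for p in positions)
    return positions


def target_width(agent: str) -> int:
    return 2 if agent == "UV" else 1


def simulate_damage(
    genes: Sequence[GeneModel], sequences: Mapping[str, str], config: SimConfig
):
    """Independent per-site damage at probability min(1, damage_rate).

    Target sites are enumerated on both genomic strands within each gene
    body; each damage emits one stranded interval (name = host gene).
    Returns (damages, truth) where truth is a DataFrame with per-gene target
    and damage counts split into transcribed (template) vs non-transcribed
    strand.
    """
    config.validate()
    rng = child_rng(config.seed, f"damage-{config.agent}")
    p_dam = min(1.0, config.damage_rate)
    w = target_width(config.agent)
    damages = []
    rows = []
    for g in genes:
        body = sequences[g.chrom][g.start : g.end]
        counts = {}
        for genomic_strand in ("+", "-"):
            sites = enumerate_target_sites(body, genomic_strand, config.agent)
            hit = rng.random(len(sites)) < p_dam if sites else np.array([], dtype=bool)
            n_dam = int(hit.sum())
            for off, is_hit in zip(sites, hit):
                if is_hit:
                    damages.append(
                        StrandedInterval(
                            g.chrom,
                            g.start + off,
                            g.start + off + w,
                            name=g.gene_id,
                            score=0,
                            strand=genomic_strand,
                        )
                    )
            side = "nts" if genomic_strand == g.strand else "ts"
            counts[f"n_target_sites_{side}"] = len(sites)
            counts[f"damages_{side}"] = n_dam
        rows.append({"gene_id": g.gene_id, **counts})
    truth = pd.DataFrame(rows)
    return damages, truth


def _merged_exons(gene: GeneModel) -> list:
    from .features import merge_intervals

    return merge_intervals(gene.exons)


def simulate_repair(
    damages: Sequence[StrandedInterval],
    genes: Sequence[GeneModel],
    config: SimConfig,
):
    """Bernoulli repair with exon enhancement; conservation holds exactly.

    A damage whose start lies in an exon of its host gene is repaired with
    probability min(1, exon_repair_factor * repair_prob_base), otherwise
    with repair_prob_base. Each repaired damage emits one repair read.
    Returns (repair_reads, repair_truth) with per-gene repaired/residual
    counts per strand side.
    """
    config.validate()
    rng = child_rng(config.seed, f"repair-{config.agent}")
    gene_by_id = {g.gene_id: g for g in genes}
    exons_by_id = {g.gene_id: _merged_exons(g) for g in genes}
    p_exon = min(1.0, config.exon_repair_factor * config.repair_prob_base)
    p_base = config.repair_prob_base

    tallies = {
        g.gene_id: {"repaired_ts": 0, "repaired_nts": 0, "residual_ts": 0, "residual_nts": 0}
        for g in genes
    }
    reads = []
    for d in damages:
        g = gene_by_id[d.name]
        exonic = any(s <= d.start < e for s, e in exons_by_id[d.name])
        p_rep = p_exon if exonic else p_base
        side = "nts" if d.strand == g.strand else "ts"
        if rng.random() < p_rep:
            tallies[d.name][f"repaired_{side}"] += 1
            reads.append(d)
        else:
            tallies[d.name][f"residual_{side}"] += 1
    truth = pd.DataFrame(
        [{"gene_id": gid, **t} for gid, t in sorted(tallies.items())]
    )
    return reads, truth


def simulate_expression(
    genes: Sequence[GeneModel],
    residual_ts: Mapping[str, int],
    config: SimConfig,
):
    """NB counts for control and treated replicates.

    Control mean is a per-gene baseline; the treated mean is the baseline
    times exp(-beta * residual_ts) times the induction factor for induced
    genes. Only transcribed-strand residual damage suppresses expression.
    Returns (control, treated, expr_truth) with count matrices of shape
    (n_genes, n_replicates) in gene order.
    """
    config.validate()
    rng = child_rng(config.seed, f"expression-{config.agent}")
    n = len(genes)
    baseline = rng.uniform(*config.baseline_mean_range, size=n)
    resid = np.array([residual_ts[g.gene_id] for g in genes], dtype=float)
    induced = np.array([g.gene_id in config.induced_gene_ids for g in genes])
    treated_mean = (
        baseline
        * np.exp(-config.suppression_beta * resid)
        * np.where(induced, config.induction_factor, 1.0)
    )
    expected_log2fc = np.log2(treated_mean / baseline)

    def draw(means: np.ndarray) -> np.ndarray:
        r = 1.0 / config.nb_dispersion
        mu = means[:, None] * np.ones((1, config.n_replicates))
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    control = draw(baseline)
    treated = draw(treated_mean)
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "baseline_mean": baseline,
            "expected_log2fc": expected_log2fc,
            "induced": induced,
        }
    )
    return control, treated, truth


def simulate_condition(config: SimConfig, genes, sequences):
    """Damage, repair, and expression for one (cell type, agent) condition."""
    damages, dam_truth = simulate_damage(genes, sequences, config)
    reads, rep_truth = simulate_repair(damages, genes, config)
    truth = dam_truth.merge(rep_truth, on="gene_id")
    residual = dict(zip(truth["gene_id"], truth["residual_ts"]))
    control, treated, expr_truth = simulate_expression(genes, residual, config)
    truth = truth.merge(expr_truth, on="gene_id")[TRUTH_COLUMNS]
    return {
        "damages": damages,
        "repair_reads": reads,
        "control": control,
        "treated": treated,
        "truth": truth,
    }


def simulate_study(
    config: SimConfig,
    outdir,
    cell_types: Sequence[str] = ("cellA", "cellB"),
    agents: Sequence[str] = AGENTS,
) -> dict:
    """Full 2-cell-type x 3-agent bundle written as plain-text files.

    Per cell type: FASTA genome and gene table; per condition: damage BED6,
    repair BED6, control/treated count TSVs, truth TSV. A manifest JSON
    lists every file with the seeds used. Gene ids are shared across cell
    types so cross-condition consistency scoring applies.
    """
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "root_seed": config.seed,
        "cell_types": list(cell_types),
        "agents": list(agents),
        "n_genes": config.n_genes,
        "n_replicates": config.n_replicates,
        "files": {},
    }
    for ci, cell in enumerate(cell_types):
        cell_seed = config.seed * 1000 + ci
        cell_cfg = replace(config, seed=cell_seed)
        sequences, genes = simulate_genome(cell_cfg)
        cdir = outdir / cell
        cdir.mkdir(exist_ok=True)
        tio.write_fasta(cdir / "genome.fa", sequences)
        tio.write_gene_table(cdir / "genes.tsv", genes)
        entry = {
            "seed": cell_seed,
            "genome": str(Path(cell) / "genome.fa"),
            "genes": str(Path(cell) / "genes.tsv"),
            "conditions": {},
        }
        gene_ids = [g.gene_id for g in genes]
        samples_c = [f"ctrl_{r + 1}" for r in range(config.n_replicates)]
        samples_t = [f"trt_{r + 1}" for r in range(config.n_replicates)]
        for agent in agents:
            cond_cfg = replace(cell_cfg, agent=agent)
            res = simulate_condition(cond_cfg, genes, sequences)
            adir = cdir / agent
            adir.mkdir(exist_ok=True)
            tio.write_bed6(adir / "damage.bed", res["damages"])
            tio.write_bed6(adir / "repair.bed", res["repair_reads"])
            tio.write_counts(adir / "counts_control.tsv", gene_ids, res["control"], samples_c)
            tio.write_counts(adir / "counts_treated.tsv", gene_ids, res["treated"], samples_t)
            res["truth"].to_csv(adir / "truth.tsv", sep="\t", index=False)
            entry["conditions"][agent] = {
                "seed": cell_seed,
                "damage": str(Path(cell) / agent / "damage.bed"),
                "repair": str(Path(cell) / agent / "repair.bed"),
                "counts_control": str(Path(cell) / agent / "counts_control.tsv"),
                "counts_treated": str(Path(cell) / agent / "counts_treated.tsv"),
                "truth": str(Path(cell) / agent / "truth.tsv"),
            }
        manifest["files"][cell] = entry
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
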