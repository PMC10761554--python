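import math

import numpy as np
import pandas as pd
import pytest

from txdamage import io as tio
from txdamage.features import exon_fraction, gc_fraction
from txdamage.simulate import (
    ConfigError,
    SimConfig,
    enumerate_target_sites,
    reverse_complement,
    simulate_damage,
    simulate_expression,
    simulate_genome,
    simulate_repair,
    simulate_study,
    target_width,
)


class TestSimConfig:
    def test_invalid_range_raises(self):
        with pytest.raises(ConfigError):
            SimConfig(gc_range=(0.7, 0.3))

    def test_invalid_agent(self):
        with pytest.raises(ConfigError):
            SimConfig(agent="gamma")

    def test_negative_damage_rate(self):
        with pytest.raises(ConfigError):
            SimConfig(damage_rate=-0.1)

    def test_probability_bounds(self):
        with pytest.raises(ConfigError):
            SimConfig(repair_prob_base=1.5)


class TestSimulateGenome:
    def test_degenerate_exon_range_full_span(self):
        cfg = SimConfig(n_genes=15, exon_fraction_range=(1.0, 1.0), seed=2)
        _, genes = simulate_genome(cfg)
        for g in genes:
            assert g.exons == ((g.start, g.end),)
            assert exon_fraction(g) == 1.0

    def test_degenerate_gc_range_at_only(self):
        cfg = SimConfig(n_genes=10, gc_range=(0.0, 0.0), seed=3)
        sequences, genes = simulate_genome(cfg)
        for g in genes:
            body = sequences[g.chrom][g.start : g.end]
            assert set(body) <= {"A", "T"}

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(n_genes=12, seed=5)
        out = []
        for run in ("a", "b"):
            sequences, genes = simulate_genome(cfg)
            fa = tmp_path / f"{run}.fa"
            gt = tmp_path / f"{run}.tsv"
            tio.write_fasta(fa, sequences)
            tio.write_gene_table(gt, genes)
            out.append((fa.read_bytes(), gt.read_bytes()))
        assert out[0] == out[1]

    def test_genes_non_overlapping(self, small_genome):
        _, _, genes = small_genome
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_realized_exon_fraction_near_target(self):
        cfg = SimConfig(n_genes=40, exon_fraction_range=(0.3, 0.3), seed=6)
        _, genes = simulate_genome(cfg)
        for g in genes:
            # placement granularity is 1 bp of rounding on the gene length
            assert exon_fraction(g) == pytest.approx(0.3, abs=1.0 / g.length_bp + 1e-9)

    def test_realized_gc_within_sampling_noise(self):
        cfg = SimConfig(n_genes=30, gc_range=(0.5, 0.5), seed=7)
        sequences, genes = simulate_genome(cfg)
        for g in genes:
            body = sequences[g.chrom][g.start : g.end]
            se = math.sqrt(0.25 / g.length_bp)
            assert abs(gc_fraction(body) - 0.5) < 5 * se


class TestEnumerateTargetSites:
    def test_uv_dipyrimidine_by_hand(self):
        assert enumerate_target_sites("TTAG", "+", "UV") == [0]

    def test_cisplatin_single_g(self):
        assert enumerate_target_sites("TTAG", "+", "cisplatin") == [3]

    def test_no_pyrimidine_dimers(self):
        assert enumerate_target_sites("AAAA", "+", "UV") == []

    def test_minus_strand_revcomp(self):
        assert enumerate_target_sites("AAAA", "-", "cisplatin") == []
        assert enumerate_target_sites("CCCC", "-", "cisplatin") == [0, 1, 2, 3]

    def test_minus_strand_uv_mapped_to_plus_coords(self):
        # revcomp of TTAG is CTAA: dipyrimidine CT at revcomp offset 0
        # maps to plus-strand start 4 - 0 - 2 = 2
        assert enumerate_target_sites("TTAG", "-", "UV") == [2]

    def test_unknown_agent_raises(self):
        with pytest.raises(ValueError):
            enumerate_target_sites("ACGT", "+", "xray")

    def test_sorted_unique(self):
        pos = enumerate_target_sites("GGGGTTTT", "-", "UV")
        assert pos == sorted(set(pos))

    def test_bpde_same_targets_as_cisplatin(self):
        seq = "GATTGGC"
        assert enumerate_target_sites(seq, "+", "BPDE") == enumerate_target_sites(
            seq, "+", "cisplatin"
        )

    def test_widths(self):
        assert target_width("UV") == 2
        assert target_width("cisplatin") == 1


def test_reverse_complement():
    assert reverse_complement("ACGTN") == "NACGT"


class TestSimulateDamage:
    def test_zero_rate_no_damage(self, small_genome):
        cfg, sequences, genes = small_genome
        damages, truth = simulate_damage(genes, sequences, SimConfig(
            n_genes=cfg.n_genes, seed=cfg.seed, damage_rate=0.0))
        assert damages == []
        assert (truth[["damages_ts", "damages_nts"]] == 0).all().all()

    def test_saturation(self, small_genome):
        cfg, sequences, genes = small_genome
        damages, truth = simulate_damage(genes, sequences, SimConfig(
            n_genes=cfg.n_genes, seed=cfg.seed, damage_rate=1.0))
        assert (truth["damages_ts"] == truth["n_target_sites_ts"]).all()
        assert (truth["damages_nts"] == truth["n_target_sites_nts"]).all()

    def test_binomial_expectation(self):
        # aggregate over seeds: total damages near rate * sites within 3 SD
        cfg0 = SimConfig(n_genes=40, seed=0, agent="cisplatin")
        sequences, genes = simulate_genome(cfg0)
        rate = 0.1
        totals, n_sites = [], None
        for seed in range(5):
            cfg = SimConfig(n_genes=40, seed=seed, agent="cisplatin", damage_rate=rate)
            damages, truth = simulate_damage(genes, sequences, cfg)
            totals.append(len(damages))
            n_sites = int(truth[["n_target_sites_ts", "n_target_sites_nts"]].sum().sum())
        total, n = sum(totals), n_sites * len(totals)
        sd = math.sqrt(n * rate * (1 - rate))
        assert abs(total - n * rate) < 3 * sd

    def test_truth_consistent_with_intervals(self, small_genome):
        cfg, sequences, genes = small_genome
        damages, truth = simulate_damage(genes, sequences, SimConfig(
            n_genes=cfg.n_genes, seed=cfg.seed, damage_rate=0.05))
        by_gene = {g.gene_id: g for g in genes}
        recount = {gid: [0, 0] for gid in by_gene}
        for d in damages:
            g = by_gene[d.name]
            side = 1 if d.strand == g.strand else 0  # [ts, nts]
            recount[d.name][side] += 1
        for row in truth.itertuples(index=False):
            assert recount[row.gene_id] == [row.damages_ts, row.damages_nts]

    def test_monotone_in_damage_rate(self, small_genome):
        cfg, sequences, genes = small_genome
        totals = []
        for rate in (0.01, 0.05, 0.2, 0.8):
            d, _ = simulate_damage(genes, sequences, SimConfig(
                n_genes=cfg.n_genes, seed=99, damage_rate=rate))
            totals.append(len(d))
        assert totals == sorted(totals)


class TestSimulateRepair:
    def _damaged(self, seed=13, rate=0.3, **kw):
        cfg = SimConfig(n_genes=40, seed=seed, damage_rate=rate, **kw)
        sequences, genes = simulate_genome(cfg)
        damages, dam_truth = simulate_damage(genes, sequences, cfg)
        return cfg, genes, damages, dam_truth

    def test_complete_repair_no_residual(self):
        cfg, genes, damages, _ = self._damaged(repair_prob_base=1.0)
        _, truth = simulate_repair(damages, genes, cfg)
        assert (truth["residual_ts"] == 0).all()
        assert (truth["residual_nts"] == 0).all()

    def test_conservation_exact(self):
        cfg, genes, damages, dam_truth = self._damaged(repair_prob_base=0.4)
        reads, truth = simulate_repair(damages, genes, cfg)
        merged = dam_truth.merge(truth, on="gene_id")
        assert (
            merged["repaired_ts"] + merged["residual_ts"] == merged["damages_ts"]
        ).all()
        assert (
            merged["repaired_nts"] + merged["residual_nts"] == merged["damages_nts"]
        ).all()
        assert len(reads) == int(truth[["repaired_ts", "repaired_nts"]].sum().sum())

    def test_cap_rule_exonic_always_repaired(self):
        cfg, genes, damages, _ = self._damaged(
            repair_prob_base=0.5, exon_repair_factor=2.0
        )
        from txdamage.features import merge_intervals

        _, truth = simulate_repair(damages, genes, cfg)
        exons = {g.gene_id: merge_intervals(g.exons) for g in genes}
        residual_names = set()
        reads, truth = simulate_repair(damages, genes, cfg)
        repaired_set = {(r.chrom, r.start, r.strand, r.name) for r in reads}
        for d in damages:
            exonic = any(s <= d.start < e for s, e in exons[d.name])
            if exonic:
                assert (d.chrom, d.start, d.strand, d.name) in repaired_set

    def test_no_enhancement_equal_proportions(self):
        # rho=1: exon vs intron repair proportions differ by < 3 SE
        cfg, genes, damages, _ = self._damaged(
            seed=21, rate=0.5, repair_prob_base=0.5, exon_repair_factor=1.0
        )
        from txdamage.features import merge_intervals

        reads, _ = simulate_repair(damages, genes, cfg)
        repaired_set = {(d.chrom, d.start, d.strand, d.name) for d in reads}
        exons = {g.gene_id: merge_intervals(g.exons) for g in genes}
        tallies = {True: [0, 0], False: [0, 0]}  # exonic -> [repaired, total]
        for d in damages:
            exonic = any(s <= d.start < e for s, e in exons[d.name])
            tallies[exonic][1] += 1
            tallies[exonic][0] += (d.chrom, d.start, d.strand, d.name) in repaired_set
        p_ex = tallies[True][0] / tallies[True][1]
        p_in = tallies[False][0] / tallies[False][1]
        se = math.sqrt(
            0.25 / tallies[True][1] + 0.25 / tallies[False][1]
        )
        assert abs(p_ex - p_in) < 3 * se


class TestSimulateExpression:
    def _setup(self, **kw):
        cfg = SimConfig(n_genes=20, seed=31, **kw)
        _, genes = simulate_genome(cfg)
        return cfg, genes

    def test_null_model_zero_lfc(self):
        cfg, genes = self._setup(suppression_beta=0.0)
        residual = {g.gene_id: 5 for g in genes}
        _, _, truth = simulate_expression(genes, residual, cfg)
        assert np.allclose(truth["expected_log2fc"], 0.0)

    def test_induced_gene_log2(self):
        cfg, genes = self._setup(
            induced_gene_ids={"g0000"}, induction_factor=2.0
        )
        residual = {g.gene_id: 0 for g in genes}
        _, _, truth = simulate_expression(genes, residual, cfg)
        row = truth.set_index("gene_id").loc["g0000"]
        assert row["expected_log2fc"] == pytest.approx(1.0)
        assert bool(row["induced"])

    def test_suppression_arithmetic(self):
        cfg, genes = self._setup(suppression_beta=0.1)
        residual = {g.gene_id: 10 for g in genes}
        _, _, truth = simulate_expression(genes, residual, cfg)
        assert np.allclose(truth["expected_log2fc"], -10 * 0.1 / math.log(2))
        assert truth["expected_log2fc"].iloc[0] == pytest.approx(-1.4427, abs=1e-4)

    def test_counts_shape_and_determinism(self):
        cfg, genes = self._setup(n_replicates=4)
        residual = {g.gene_id: 0 for g in genes}
        c1, t1, _ = simulate_expression(genes, residual, cfg)
        c2, t2, _ = simulate_expression(genes, residual, cfg)
        assert c1.shape == (20, 4)
        assert np.array_equal(c1, c2) and np.array_equal(t1, t2)

    def test_counts_track_expected_means(self):
        cfg, genes = self._setup(
            n_replicates=50, nb_dispersion=0.01, suppression_beta=0.2
        )
        residual = {g.gene_id: i for i, g in enumerate(genes)}
        control, treated, truth = simulate_expression(genes, residual, cfg)
        emp_lfc = np.log2((treated.mean(axis=1) + 0.5) / (control.mean(axis=1) + 0.5))
        rho = np.corrcoef(emp_lfc, truth["expected_log2fc"])[0, 1]
        assert rho > 0.95


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(n_genes=10, n_replicates=2, seed=17, damage_rate=0.02)
    manifest = simulate_study(cfg, outdir)
    return outdir, manifest


class TestSimulateStudy:
    def test_manifest_lists_existing_files(self, bundle):
        outdir, manifest = bundle
        for cell, entry in manifest["files"].items():
            assert (outdir / entry["genome"]).exists()
            assert (outdir / entry["genes"]).exists()
            for cond in entry["conditions"].values():
                for key in ("damage", "repair", "counts_control", "counts_treated", "truth"):
                    assert (outdir / cond[key]).exists()

    def test_roundtrip_through_readers(self, bundle):
        outdir, manifest = bundle
        for entry in manifest["files"].values():
            sequences = tio.read_fasta(outdir / entry["genome"])
            genes = tio.read_gene_table(outdir / entry["genes"])
            assert len(genes) == 10
            for cond in entry["conditions"].values():
                tio.read_bed6(outdir / cond["damage"])
                tio.read_bed6(outdir / cond["repair"])
                c = tio.read_counts(outdir / cond["counts_control"])
                assert c.shape == (10, 2)

    def test_cell_types_share_gene_ids(self, bundle):
        outdir, manifest = bundle
        ids = []
        for entry in manifest["files"].values():
            genes = tio.read_gene_table(outdir / entry["genes"])
            ids.append([g.gene_id for g in genes])
        assert ids[0] == ids[1]

    def test_truth_residual_recomputable_from_beds(self, bundle):
        outdir, manifest = bundle
        for entry in manifest["files"].values():
            genes = {g.gene_id: g for g in tio.read_gene_table(outdir / entry["genes"])}
            for cond in entry["conditions"].values():
                damage = tio.read_bed6(outdir / cond["damage"])
                repair = tio.read_bed6(outdir / cond["repair"])
                truth = pd.read_csv(outdir / cond["truth"], sep="\t")
                tally = {gid: 0 for gid in genes}
                for d in damage:
                    if d.strand != genes[d.name].strand:  # template strand
                        tally[d.name] += 1
                for r in repair:
                    if r.strand != genes[r.name].strand:
                        tally[r.name] -= 1
                for row in truth.itertuples(index=False):
                    assert tally[row.gene_id] == row.residual_ts

    def test_study_determinism(self, tmp_path):
        import hashlib

        cfg = SimConfig(n_genes=8, n_replicates=2, seed=23)
        digests = []
        for run in ("r1", "r2"):
            d = tmp_path / run
            simulate_study(cfg, d)
            h = hashlib.sha256()
            for f in sorted(p for p in d.rglob("*") if p.is_file()):
                h.update(f.relative_to(d).as_posix().encode())
                h.update(f.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]
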