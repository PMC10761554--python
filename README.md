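# txdamage

Tools for analysing the transcriptional response to transcription-blocking
(bulky) DNA damage, plus a forward simulator of the underlying
damage → repair → transcription causal model so every analysis stage can be
verified against ground truth without external data.

The package covers:

- **`txdamage.simulate`** — synthetic genomes with controllable gene length,
  GC, and exon composition; agent-specific damage target sites
  (dipyrimidines for UV, guanines for cisplatin/BPDE) damaged independently
  per site; exon-enhanced repair; negative-binomial counts whose treated
  mean decays exponentially with unrepaired transcribed-strand damage, with
  an optional induced-gene program. Full per-gene ground truth is recorded.
- **`txdamage.features`** — gene length, GC fraction, merged exon fraction,
  tertile binning (with externally supplied boundaries supported), and
  strand-aware upstream promoter extraction.
- **`txdamage.de`** — up/down/ns classification at strict thresholds
  (|log2FC| > 0.7, padj < 0.05 by default), 3-way Venn regions, and
  cross-condition consistency sets (genes up-regulated in ≥ k of the
  cell-type × agent conditions). A minimal NB Wald test (median-of-ratios
  normalization, method-of-moments dispersion, BH correction) is included
  as plumbing for the synthetic end-to-end path.
- **`txdamage.coverage`** — strand-specific read counting over gene bodies
  (template-strand vs sense-strand) with RPKM-style normalization.
- **`txdamage.stats`** — tie-corrected Spearman (exact permutation p for
  n ≤ 9), pairwise Mann–Whitney rank-sum tests (exact enumeration for small
  groups) with Bonferroni correction, and a one-sample signed-rank mode.
- **`txdamage.motifs`** — PWM log-odds scanning of both strands with an
  exact convolution-calibrated score threshold, and the empirical
  permutation test of motif enrichment in target promoters (size-matched
  resampling, optional GC matching).
- **`txdamage.pipeline` / CLI** — orchestration and report aggregation.

## CLI

```sh
# full synthetic study: 2 cell types x 3 agents, all stages, one seed
txdamage run-all --outdir out/run --seed 7 --n-genes 200

# individual stages on your own files
txdamage simulate --outdir out/bundle --seed 7 --n-genes 100
txdamage features --fasta genome.fa --genes genes.tsv --out features.tsv \
    --promoters-out promoters.bed --flank-bp 3000
txdamage de --control counts_control.tsv --treated counts_treated.tsv --out de.tsv
txdamage coverage --reads damage.bed --genes genes.tsv --out coverage.tsv
txdamage motif --fasta genome.fa --promoters promoters.bed \
    --motif motif.meme --targets up_genes.txt --out enrichment.json \
    --n-iter 1000 --seed 7
txdamage report --run-dir out/run --out summary.json
```

Gene tables are TSV with 0-based half-open coordinates
(`gene_id, chrom, start, end, strand, exon_starts, exon_ends`); BED12 is
accepted for `features`. Reads and promoters are BED6. Motifs are
MEME-minimal or 4-column PFM TSV. All outputs are plain TSV/JSON.

A JSON config file (keys matching `SimConfig` fields) can seed `simulate` /
`run-all`; explicit flags override it. Identical config + seed reproduce
byte-identical outputs.

## Conventions

- Coordinates are 0-based, half-open throughout (BED semantics).
- The transcribed (template) strand of a gene is the strand opposite its
  annotation; a read on the opposite strand of a gene counts toward
  `ts_count` (flippable via `ts_is_antisense`).
- Empirical enrichment p-values are `#(null ratio ≥ observed) / n_iter`;
  zero exceedances are reported as 0 alongside `p_upper = 1/n_iter`.

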