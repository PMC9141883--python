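# sexscan

Pool-seq genome scans for sex-linked regions.

Many fish, amphibian and invertebrate lineages turn over their sex
chromosomes rapidly: a young sex-determining region may sit on any
chromosome and show only kilobases-to-megabases of X/Y or Z/W
differentiation.  A cheap and powerful way to find such regions is
**pooled sequencing by sex**: sequence one DNA pool of females and one of
males, align both to a reference, and look for sites where the two pools
disagree in a sex-specific way.  `sexscan` implements that analysis for
anyone with two-pool allele counts (Popoolation2 `sync` files or two-sample
text pileups), plus a synthetic pool-seq generator for calibration and
testing.

## The statistics

For each site with allele counts in both pools:

* **Nucleotide diversity** of a pool with counts `c_A..c_T` and coverage
  `C`: `Π = 1 − Σ_a c_a(c_a−1) / [C(C−1)]` — the probability two reads
  drawn without replacement differ.
* **F_ST** between the pools: `F_ST = (Π_total − Π_within)/Π_total`, with
  `Π_within` the mean of the per-pool Π and `Π_total` the Π of the summed
  counts.
* **XY-patterned SNP**: one allele fixed in the female pool while the male
  pool is polymorphic for the alternate allele (expected at frequency 0.5
  if it is Y-linked).  **ZW-patterned SNP**: the mirror image.  "Fixed" and
  "polymorphic" are configurable thresholds (defaults: 0 minor reads
  tolerated; polymorphic band [0.3, 0.7]; ≥ 10× coverage per pool; ≥ 2
  minor reads to call a SNP at all).

Sex-patterned SNPs are then counted in non-overlapping 100-kb windows, the
top 1% of windows by XY- (or ZW-) count is selected, summarized per
chromosome (window count, SNP total, fold enrichment over the chromosome's
window share), and near-adjacent top windows are merged into candidate
sex-determining regions.

## Worked example

Simulate a 3 × 1 Mb genome whose second chromosome carries a 300-kb ZW
region, then scan it:

```bash
sexscan simulate --out-dir demo --seed 7 --chroms 3x1000000 \
    --truth sim2:400000-700000:ZW --n-females 20 --n-males 20
sexscan scan --sync demo/pools.sync --chrom-sizes demo/chrom.sizes \
    --out-dir demo/results --top-fraction 0.1
```

The log reports `simulated 15831 sites on 3 chromosomes (seed=7)` and
`scan: 15831 sites, 590 patterned`.  The per-chromosome summary of the top
ZW windows (`demo/results/summary_zw.tsv`) is

```
chrom   n_top_windows   total_patterned_snps    fold_enrichment
sim1    0       0       0.0
sim2    3       581     3.0
sim3    0       0       0.0
```

— all three top windows land on `sim2` with 581 ZW-patterned SNPs, a
3-fold enrichment over its one-third share of the genome's windows
(the maximum possible here), and the merged candidate region
(`demo/results/regions_zw.bed`)

```
sim2    400000  700000  ZW_region       581
```

recovers the planted 400–700 kb interval exactly.  `sexscan plot` then
renders the three-panel genome scan (F_ST; Y-allele frequency in the male
pool at XY sites; W-allele frequency in the female pool at ZW sites) and
the per-chromosome top-window barplot; `sexscan report` writes a Markdown
run report.

The same scan runs on real data: convert your alignments to a two-pool
mpileup, filter/convert to sync, and point `sexscan scan` at it with
`--female-col/--male-col` naming the pool columns.  (A two-sample text
pileup can also be read directly with PHRED ≥ 20 base filtering.)

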