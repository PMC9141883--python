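# Methods

## The analysis model

`sexscan` assumes a standard sex-pooled sequencing design: two libraries,
one from n_f females and one from n_m males, aligned to a common reference
and reduced to per-site allele counts (sync or two-pool pileup).  Only
counts are observed — individual genotypes are not — so every statistic is
defined at the read level.

**Π and F_ST.**  Per-pool diversity is the without-replacement estimator
Π = 1 − Σ_a c_a(c_a−1)/[C(C−1)] over the four nucleotides; N and deletion
reads are excluded throughout (the statistics are nucleotide-only, and
deletion placeholders carry no allele information).  Site F_ST is the
classical Π-based form (Π_T − Π_S)/Π_T with Π_S the unweighted mean of the
two per-pool Π.  This estimator applies no haploid-pool-size correction
beyond the read-level one: pool sizes enter the design (and the simulator)
but not the estimator, which keeps F_ST a pure function of the observed
counts.  Negative estimates (possible when within-pool diversity exceeds
total) are clamped to 0; Π_T = 0 returns F_ST = 0.  F_ST is reported per
site, not in windows — the window statistic of this pipeline is the
sex-patterned SNP count, which is less sensitive to depth heterogeneity.

**Sex-patterned SNP classification.**  The major and minor allele are
defined over the combined pools (ties broken alphabetically; only the top
two alleles of a tri-allelic site are used).  A site is XY-patterned when
the female pool is fixed — minor-allele frequency ≤ `fixed_max_minor` —
and the male pool carries the alternate allele at a frequency inside
[`poly_min`, `poly_max`]; ZW-patterned is the mirror.  Because
`fixed_max_minor < poly_min` is enforced, no site can satisfy both
definitions.  Defaults and rationale:

| parameter | default | why |
|---|---|---|
| `fixed_max_minor` | 0.0 | strict fixation is the conservative default; raise to ~0.05 to tolerate contamination or mapping error |
| `poly_min`, `poly_max` | 0.3, 0.7 | a Y/W-linked allele sits at 0.5 in the heterogametic pool; the band absorbs binomial read noise at ~40× |
| `min_cov` | 10 per pool | below ~10 reads a pool can look "fixed" by chance alone; such sites are flagged `low_coverage` and left uncalled, not errored — genome-scale data always has coverage holes |
| `min_minor_reads` | 2 | a single minor read is indistinguishable from a sequencing error |

These thresholds are explicit assumptions, not estimates: tools in this
space do not agree on them and the right values depend on depth and pool
size, so all are exposed on `Thresholds` and the CLI.

**Windows and top sets.**  Windows are non-overlapping 100-kb tiles (last
window truncated), so per-chromosome window counts sum over the genome.
The top set is the fixed number k = ⌈q·N⌉ of windows ranked by one
pattern's count, ties broken by genome position, giving a reproducible set
of exactly k windows rather than an unstable "all windows above a
threshold".  q·N is evaluated with a 1e−9 tolerance because decimal
fractions like 0.01 are not float-exact.  By default the cut is applied to
all windows; `nonzero_only` restricts it to windows holding at least one
patterned SNP.  XY and ZW top sets are computed independently, since a
genome can carry both signals at once.  Fold enrichment of a chromosome is
(top-window share)/(all-window share).  Candidate regions merge top
windows on one chromosome separated by at most `max_gap_windows` (default
1) missing windows: real contiguous regions are patchy at the window level
(repeats, coverage holes), and bridging single dropouts reconstructs them
without inventing long-range joins.

**Coordinates.**  sync/pileup positions are 1-based; windows, BED and
truth regions are 0-based half-open.  Structural-variant length is the
plain breakpoint difference (right − left), with no ±1 adjustment.

## The simulator

`simpool` emulates the statistical structure the scan assumes, at the
allele-count level (no reads, no alignment):

* background SNPs at `snp_density`/bp, minor-allele frequency uniform on
  [`maf_low`, `maf_high`]; each individual's genotype is binomial at the
  population frequency, identically in both sexes, so finite pool size
  contributes variance exactly as in real pool-seq;
* XY truth regions: sex-linked sites where every male is heterozygous
  (Y carries the alternate) and every female homozygous reference; ZW
  mirrored;
* W-deleted strata: the whole segment is hemizygous in females, whose
  reads are drawn from n_f source chromosomes instead of 2·n_f.  Sex-linked
  sites there model the transmission structure of a full-sib pooled family
  — a daughter's single Z is paternal, while sons also carry the maternal
  Z — so maternal-Z variants are heterozygous in every male and absent from
  every female, and surface as XY-patterned SNPs inside a ZW region.  This
  is the signature by which degenerate strata betray themselves in
  sex-pool scans.  In a random-mating population the same geometry arises
  only through drift in the halved female copy number and is far weaker;
  the family model is used because sex pools are typically built from
  families, and because it reproduces the qualitative phenomenon the scan
  must detect.  Background sites inside a stratum keep shared polymorphism
  but sample the females' n_f copies.  `stratum_Y_deleted` mirrors all of
  this;
* reads: depth ~ Poisson(`mean_depth`) per pool per site, each read drawn
  uniformly from the pool's source chromosomes, then miscalled to a
  uniform other nucleotide with probability `error_rate`.

Defaults (30 females / 28 males, 40× depth, 0.2% error, SNP every 200 bp,
sex-linked site every 500 bp inside truth regions) describe a realistic
modern sex-pool experiment; the sex-linked density matches the ~1 SNP/kb
seen in strongly differentiated ZW blocks after upstream filtering.
Output is deterministic given the seed (byte-identical sync), and the sync
header echoes the full configuration.

What the simulator does **not** model: reference/mapping bias, repeat
collapse, indels, coverage autocorrelation, linkage between background
SNPs, and B-chromosome sequence content (a feminizing B is a pooling
decision, not a sequence signal, so it appears only in how a user labels
pools).  Passing tests therefore demonstrate correctness of the statistics
and the recovery machinery under the stated sampling model, not robustness
to alignment artifacts in real data.

## Test and default problem sizes

The end-to-end studies use a 5 × 2 Mb genome — large enough for ~50,000
SNPs and stable window statistics while keeping a full simulate→scan cycle
around a second.  At that scale the genome holds 100 windows of 100 kb, so
a top-1% set is a single window; a multi-window truth region (e.g. 300 kb)
can then be recovered with perfect precision but window-level recall
capped at 1/3 by the size of the top set — a size effect of small
simulated genomes, not of the method, which is why the worked example in
the README uses a larger top fraction and why null-calibration checks pool
top windows across seeds before comparing chromosome shares.

## Known limitations

* Pool-size (haploid count) corrections to F_ST are deliberately omitted;
  absolute F_ST values are therefore comparable within a dataset, less so
  across designs with very different pool sizes.
* The classifier is biallelic: additional alleles beyond the top two are
  ignored, which slightly undercounts patterned SNPs at genuinely
  multi-allelic sites.
* Pileup reading filters on base quality only; no mapping-quality filter
  is applied (apply one upstream when generating the pileup if needed).
* Region bounds come from merged top windows, so they are quantized to the
  window grid; SNP-level extremes inside a region can be read from the
  per-site table.
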