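# poolsex

Pooled-sequencing analysis of sex chromosomes: detect sex-patterned SNPs
from male/female pool allele counts, test genomic windows for enrichment,
intersect sex-patterned sites across species against a null expectation,
merge conserved copy-number variants across comparisons, and scan SNP
flanks for transcription-factor binding sites gained or lost between the
X and Y alleles.

## The problem

In many fishes (tilapias are the motivating case) the sex chromosomes are
homomorphic and recombination is suppressed around the sex-determination
locus, so the locus cannot be fine-mapped by ordinary linkage analysis.
An alternative is whole-genome sequencing of a male pool and a female
pool from one family. In an XY system every male is X/Y, so a Y-linked
variant sits at frequency ~0.5 among male-pool chromosomes and is absent
from the female pool. A **sex-patterned SNP** is the read-count signature
of that configuration: one allele fixed or nearly fixed in the
homogametic (XX) pool and the other allele at intermediate frequency in
the heterogametic (XY) pool. Comparing two species that inherited the
same ancestral sex-determination region, the handful of sex-patterned
SNPs shared by both — far more than expected by chance — are candidates
for the ancestral sex-determining mutation.

## What it computes

Per site, from pool allele counts (alt-allele frequencies `p_x` in the
heterogametic and `p_y` in the homogametic pool, pool depths `n`):

- **F_ST** — π-based estimator: `π_pool = n/(n−1) · 2p(1−p)`, `π_T` from
  the summed counts, `F_ST = (π_T − π_S)/π_T`, truncated to [0, 1];
  undefined (reported `NA`) when `π_T = 0` or depth < 2.
- **d_xy** `= p_x(1−p_y) + p_y(1−p_x)` and **d_a** `= d_xy − (π_x+π_y)/2`.
- **Nei's D** `= −ln I`, `I = Σx_i y_i / √(Σx_i² Σy_i²)`; at
  alternatively fixed sites frequencies 0/1 are clamped to
  `1/max_coverage` so D stays finite.
- **C_P** `= Σ ½|x_i − y_i|` — 0 for identical pools, 1 for disjoint
  allele support.
- The sex-pattern call itself: homogametic major-allele frequency
  ≥ 0.9, the other allele in [0.3, 0.7] in the heterogametic pool with
  ≥ 2 reads, both pools at depth ≥ 10 (all thresholds are parameters).

Above the per-site layer: 10 kb non-overlapping windows with gap-aware
effective lengths and an enrichment call (≥ 10 sex-patterned SNPs);
two-sided Mann–Whitney U region comparisons with a Bonferroni threshold
(`α/m`, default 0.05/12 = 0.004167); cross-species intersection with
X/Y-consistency classes (conserved / switched / same-X-different-Y) and
the null expectation `n_a·n_b/L` for shared counts; conserved CNVs as
maximal intervals covered same-direction (|log2 ratio| ≥ 0.2) in every
VarScan-style comparison; and PWM scans of allele-substituted flanks at a
JASPAR relative-score threshold of 0.80.

A synthetic-data module generates pooled counts (21-male/22-female pools,
~35× Poisson depth, binomial read sampling), species pairs with
conserved/switched/Y-replaced fates of ancestral sex-patterned sites, and
CNV tracks — all with truth tables, so every stage is testable offline.

## Worked example

The numbered drivers under `analysis/` replay the full study design on a
simulated 1 Mb chromosome whose 400–600 kb interval is a shared
sex-determination region (fates of ancestral sex-patterned sites:
50 % conserved, 31 % switched, 19 % Y-replaced):

```sh
python analysis/01_simulate.py
python analysis/02_find_sex_snps.py
python analysis/03_window_enrichment.py
python analysis/04_shared_snps.py
python analysis/05_cnv_conservation.py
python analysis/06_tfbs_scan.py
python analysis/07_report.py
```

Output from a run (seed 20161018):

```
species_a: 373 sex-patterned of 1361 sites; recall 0.987, precision 0.997 vs truth
species_a: SD region vs rest, U=1600.0, p=3.71e-22 -> significant at alpha/12 = 0.004167
shared sex-patterned SNPs: 365 (179 conserved X/Y, 115 switched, 71 same-X/different-Y, 0 other)
null expectation in sd_region: 0.69 (372 x 370 / 200000 bp); observed 365 (530.4x the chance expectation)
3 conserved CNVs across 2 comparisons
conserved-CNV density, SD region vs rest: U=920.0, p=0.000492 -> significant at alpha/12 = 0.004167
```

Reading: the detector recovers 98.7 % of the simulated Y-linked sites at
35× with 0.3 % false calls; the sex-determination region is significantly
enriched for sex-patterned SNPs and for conserved CNVs at the
Bonferroni-corrected threshold; and the observed shared-SNP count vastly
exceeds the chance expectation `n_a·n_b/L`, as it must when the region is
truly ancestral. The same functions are available as `poolsex`
subcommands (`simulate`, `find-snps`, `windows`, `shared`, `cnv`, `tfbs`,
`run`) for file-to-file use.

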