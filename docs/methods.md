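# Methods

## Study design emulated

The package models a paired-tissue study of chronic colitis in mouse colon:
for each mouse, the colon mucosa (the tissue exposed to inflammation) and
the muscularis mucosae of the same animal are exome-sequenced, so that
variants present in both tissues can be treated as germline and removed,
leaving mucosa-specific somatic variants.  In parallel, whole-genome
bisulfite sequencing of a control and a treated methylome supports
differential methylation analysis at base resolution.  All analyses here run
on synthetic cohorts with planted ground truth; the generator is a
first-class, tested module, and every downstream claim in the test suite is
a recovery statement against what was planted.

## Synthetic methylome model

CpG methylation in mammalian tissue is bimodal and spatially organised:
most individual CpGs are either nearly fully methylated or nearly
unmethylated, and methylated CpGs cluster in domains while CpG-island-like
regions stay unmethylated.  The generator reproduces this with a
domain/desert architecture:

- **CG context.** Methylation states are drawn per CpG dyad (the plus- and
  minus-strand cytosines of one CpG share their state, as symmetric CpG
  methylation does).  Non-overlapping ~2 kb "domains" are placed so that
  they cover a fraction `phi = (baseline - 0.02) / (0.95 - 0.02)` of each
  chromosome; dyads inside a domain are methylated with probability 0.95,
  outside with probability 0.02.  The genome-wide mean CG level therefore
  equals the configured `baseline_level_cg` while leaving long deserts in
  which adjacent methylated sites are typically further apart than the
  200-bp chaining distance of the DMR caller.  A fully methylated state
  emits methylated reads with probability 1 (bisulfite protects methylated
  cytosines); adding partial methylation within states is possible but was
  not needed for any property tested here.
- **CHG/CHH contexts.** States are independent per site at their (low)
  baselines, 0.05 and 0.02 by default, matching the rarity of non-CpG
  methylation in somatic mammalian tissue.
- **Shared states between conditions.** Outside planted DMRs the control and
  treated methylomes share the same true state at every site; only the read
  counts are drawn independently.  This is the correct null: two methylomes
  of the same tissue differ by sampling noise, not by independent
  re-draws of biology, and it is what makes the chi-square criterion's
  type-I rate interpretable (see calibration below).
- **Planted DMRs.** Planted regions are continuous-level intervals: every
  site of the region's context has true level `baseline` in the control and
  `baseline + dmr_delta` (clipped to [0, 1]) in the treated sample, with
  reads drawn independently per condition.  With the default baseline 0.2
  and delta +0.4 the true regional fold change is 3, comfortably above the
  caller's threshold of 2 by construction.  Regions are placed either in a
  host gene's up2k/body/down2k zone or in intergenic gaps, always inside
  methylation deserts with a 500-bp cleared margin, so each planted region
  chains in isolation.  Each host gene contributes each of its three zones
  exactly once across the three contexts, which keeps all planted intervals
  mutually non-overlapping; a consequence of this scheme is that under the
  defaults the up2k, body and down2k DMR-gene sets coincide (every host is
  hit once per zone).
- **Coverage and error.** Per-site coverage is negative binomial with
  configurable mean (default 30) and dispersion (default 0.1; dispersion 0
  degenerates to Poisson).  Bisulfite non-conversion (default 0.005) is
  modelled only as false methylation on unmethylated cytosines, the dominant
  artifact in real WGBS; over-conversion of methylated cytosines is out of
  scope.

A spatially uniform site-level model (every CG at level 0.2) is *not* used,
deliberately: under the caller's rules every covered site would be flagged
methylated, all flagged sites would chain into one chromosome-length
candidate, and the 10-kb length ceiling would discard it — no DMR could ever
be called, and any region-level fold change would be diluted toward 1 by the
uniform background.  The domain/desert model is both the more realistic
description of a methylome and the one under which a chaining-based caller
is a sensible instrument.

## Methylated-cytosine calling

A site with coverage `n` and methylated count `m` is called methylated when
the one-sided binomial tail `P(X >= m | n, e)` under the non-conversion
error `e` survives Benjamini–Hochberg correction across all covered sites at
alpha = 0.05, with at least one methylated read and coverage >= 4.  The
binomial-against-error test with FDR control is the standard WGBS
methylation call; the error rate, alpha and coverage floor are all
parameters.

## DMR identification

DMRs between two samples are called per context (CG, CHG, CHH) under six
simultaneous criteria: (1) at least 5 methylated cytosines in at least one
sample; (2) coverage >= 10 at every member cytosine in both samples and
>= 4 methylated reads at every methylated cytosine; (3) length between
40 bp and 10 kb; (4) adjacent methylated sites < 200 bp apart; (5) fold
change of the pooled methylation level > 2; (6) Pearson chi-square p <= 0.05
on the pooled 2x2 read table (1 df, no continuity correction).

Implementation decisions where the procedure leaves room:

- *Threshold strictness.* The count thresholds are applied inclusively
  (>= 5 sites, >= 10 coverage, >= 4 methylated reads); fold is strict
  (> 2) and the p threshold inclusive (<= 0.05).  All are configurable.
- *Seed screening.* A site failing the coverage screen is excluded from the
  region (in both samples) rather than voiding the region.
- *Region level.* The per-sample level is the read-pooled mean
  `sum(m_i) / sum(n_i)` over member sites — the same pooled counts that
  enter the chi-square table, so criteria 5 and 6 test the same quantity.
- *Zero denominator.* If one sample's pooled level is exactly 0 and the
  other's is positive, the fold criterion passes (fold recorded as inf).
- *Chains outside the length window are discarded whole*, not split; the
  length bound is stated without a splitting rule and splitting would
  manufacture boundaries the data do not support.
- *No multiple-testing correction across regions* by default (raw
  p <= 0.05); a BH option exists (`bh_across_regions`).
- *Degenerate tables* (a zero marginal) give chi2 = 0, p = 1 — a rejection,
  not an exception; expected counts below 5 produce a logged warning rather
  than a Fisher substitution, since the procedure specifies chi-square.

**Calibration.** With delta = 0 the planted regions become true nulls with
independent binomial reads at equal levels, and the background's shared
states make non-DMR candidates null as well (fully methylated domains yield
degenerate tables with p = 1, which only lowers the pass rate).  The
acceptance test measures the chi-square pass rate among evaluated candidates
and bounds it by alpha + 3·SE; observed rates sit near or below alpha.

## Metagene profiles

Gene flanks of 2 kb are binned at 100 bp (20 bins per side) and gene bodies
into 20 equal fractions, all in 5'→3' gene orientation: upstream bin 0 is
the flank edge farthest from the TSS, so a site 150 bp upstream of a
minus-strand gene's TSS (i.e. 150 bp to the right of its rightmost
coordinate) falls in upstream bin 18.  Bin values are means of site levels,
averaged across genes; bins with no covered site in a gene are excluded from
that gene's contribution rather than zero-filled, which would bias means
downward at low coverage.  Genes shorter than the number of body bins are
skipped with a warning.

## Somatic variant accounting

Raw calls are filtered with the strict inequalities mapping quality > 20 and
depth > 4, exactly as printed in the procedure this reproduces (a record at
MQ = 20 or DP = 4 is removed).  Somatic variants are mucosa records whose
exact key (chrom, pos, ref, alt) is absent from the matched muscularis; no
position-tolerance window or indel re-normalisation is applied, so input
VCFs are expected to be left-aligned — a documented limitation.  The
per-sample "frequency SUM" statistic is the sum of somatic allele fractions
(AF), reported to 3 decimals; the source material never defines the unit of
its frequency sum, and the AF reading is the one under which the statistic
weights mutation burden by clonality.  Variants map to every gene whose
whole interval contains their position (functional-consequence annotation is
out of scope), and multi-mouse gene sets are intersected exactly.

The generator plants germline variants (AF 0.5 or 1.0, present in both
tissues, always passing filters) and mucosa-only somatic variants (AF
uniform on [0.05, 0.5], subclonal), at 300 and 80 per mouse by default —
desk-scale counts chosen so every set operation is exactly checkable; the
deposited-cohort counts (hundreds to thousands per exome) are not
reproducible without the original sequencing data.  A configurable fraction
(default 0.1) of somatic variants is pushed below the MQ/depth thresholds;
these are recorded in the truth object, and recovery is then expected to be
truth minus exactly those records.  Sub-threshold injection applies to
somatic variants only: a germline record failing filters in a single tissue
would leak into the somatic set and make "recovery = truth minus designed
failures" false, which is a property of the paired design, not of the code.
Three hotspot genes receive one somatic variant in every mucosa so the
multi-sample gene intersection is non-trivially exercised.

## Pathway enrichment

A DMR is assigned to every (gene, zone) interval it overlaps by >= 1 bp,
zones being the strand-aware 2-kb upstream flank, gene body and 2-kb
downstream flank; DMRs hitting no zone are intergenic.  Enrichment of a
pathway with K members among n DMR-hit genes in a background of N genes is
the hypergeometric upper tail P(X >= k), corrected across pathways with
Benjamini–Hochberg (configurable) and flagged significant at q < 0.05.  The
background is all genes of the supplied annotation (the "whole genome
background"), not only tested genes.  The generator's designated pathway
contains 90% of the DMR host genes plus a sprinkle of others, so on the
default cohort it must surface at rank 1.

## Default problem sizes

Two 300-kb chromosomes (GC 0.42), 60 genes of 2–6 kb with >= 4.2-kb
spacing, 20 planted DMRs per context (300–800 bp), coverage 30, four mice
with 300 germline and 80 somatic variants each.  These sizes give
~250,000 cytosine records per methylome — enough for the binomial means,
FDR behaviour and recovery rates to be tight — while keeping a full
pipeline run in seconds.

## What passing tests do and do not show

The synthetic data exercise the arithmetic, the set logic and the
statistical calibration of every stage under a model whose truth is known.
They do not emulate: read-level artifacts (M-bias, duplicate reads,
mapping bias into repeats), biological replicate dispersion (one methylome
per condition, as in the design this follows), realistic CpG-island
sequence composition (the genome is i.i.d. at a fixed GC), indel
representation ambiguity in VCFs, or annotation complexity (overlapping
isoforms, TEs).  Accession-scale headline numbers from the original cohort
(somatic counts, frequency sums, the 48-gene intersection, mCG shares of
~82/81%) depend on those upstream realities and on specific caller
versions, and are therefore reference points, not targets, for this
package: the pipeline reports their synthetic-cohort analogues instead.
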