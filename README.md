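# inflammeth

Genetic and epigenetic profiling of chronically inflamed colon mucosa, as a
reusable analysis pipeline.  The scientific question is whether chronic
inflammation (a DSS-colitis model) leaves marks on the mucosal genome and
methylome: somatic SNP/InDel accumulation measured against the muscularis of
the same animal as a germline reference, and differentially methylated
regions (DMRs) between a control and a treated whole-genome bisulfite
methylome, carried through to pathway enrichment.  Everything runs on a
synthetic cohort with planted ground truth, so each stage's output is
checkable against what was planted.

## What the package computes

- **Somatic variant accounting** (`inflammeth.somatic`): filter calls with
  MQ > 20 and depth > 4 (strict), subtract germline by exact key
  (mucosa \ muscularis of the same mouse), count SNPs/InDels, accumulate the
  *frequency SUM* = Σᵢ AFᵢ over somatic variants, assign variants to genes
  by containment and intersect gene sets across mice.
- **Methylome statistics** (`inflammeth.methylome`): classify each cytosine
  into CG/CHG/CHH from the reference (strand-aware); call a site methylated
  when the one-sided binomial tail P(X ≥ m | n, e) against the non-conversion
  error e = 0.005 survives BH correction at α = 0.05; report mC-type ratios
  (mCG : mCHG : mCHH), per-chromosome mC densities, the 4×9 base-frequency
  matrix at offsets −4..+4 around (methylated) CG sites, and metagene
  profiles with 2-kb flanks binned at 100 bp (20 bins per side) plus 20
  gene-body bins.
- **DMR calling** (`inflammeth.dmrcall`): regions satisfying, jointly,
  (1) ≥ 5 methylated cytosines in ≥ 1 sample, (2) coverage ≥ 10 per cytosine
  in both samples and ≥ 4 methylated reads per methylated cytosine,
  (3) length in [40 bp, 10 kb], (4) adjacent methylated sites < 200 bp,
  (5) pooled-level fold change > 2, (6) Pearson χ² (1 df, pooled 2×2 read
  table) p ≤ 0.05.
- **Pathway enrichment** (`inflammeth.enrich`): DMRs → strand-aware gene
  zones (up2k / body / down2k, ≥ 1 bp overlap), then per pathway the
  hypergeometric upper tail p = P(X ≥ k) for k hits among n DMR genes,
  pathway size K, background N, BH-corrected; significant at q < 0.05.
- **Synthetic cohort** (`inflammeth.simdata`): genome, gene models,
  two-condition methylomes with planted context-specific DMRs
  (domain/desert CpG architecture, shared background states between
  conditions — see `docs/methods.md`), paired mucosa/muscularis VCFs with
  known germline/somatic keys, and a gene→pathway map with one designated
  over-represented pathway.

## Worked example

```sh
python analysis/01_simulate_cohort.py  --seed 1 --outdir results/run
python analysis/02_methylome_profiles.py --seed 1 --outdir results/run
python analysis/03_call_dmrs.py        --seed 1 --outdir results/run
python analysis/04_somatic_variants.py --seed 1 --outdir results/run
python analysis/05_pathway_enrichment.py --seed 1 --outdir results/run
python analysis/06_report.py           --outdir results/run
```

Output of steps 3–5 (seed 1):

```
60 DMRs called ({'CHG': 20, 'CHH': 20, 'CG': 20})
CG: sensitivity 1.000, precision 1.000
CHG: sensitivity 1.000, precision 1.000
CHH: sensitivity 1.000, precision 1.000

  sample  n_total  n_somatic  n_snp  n_indel  freq_sum  n_genes  n_intergenic
mucosa_1      372         72     60       12    19.696       25            44
mucosa_2      372         72     55       17    19.228       30            37
mucosa_3      372         72     58       14    19.149       25            35
mucosa_4      372         72     52       20    20.352       26            38
genes with somatic variants in every colitis mucosa: 10 (...)

combined: top pathway P01 (planted) k=16/K=20, q=5.03e-09
```

Reading this: all 60 planted DMRs (20 per context) are recovered with no
false positives; each mouse's filtered mucosa carries 372 variants of which
72 are somatic after germline subtraction (80 were planted, 8 per sample
deliberately below the MQ/depth filters), with the frequency SUM ≈ 20
reflecting subclonal allele fractions; and the pathway planted to be
over-represented among DMR-hosting genes ranks first with q ≪ 0.05.

The same stages are available as a CLI (`inflammeth simulate|methylome|dmr|
somatic|enrich|run|report`); `inflammeth run --config cfg.yaml --outdir DIR`
executes everything from one YAML config and writes a checksummed
`manifest.json`, so identical config + seed reproduces identical files.

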