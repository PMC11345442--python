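# eccdna-charter

Characterization and outcome-association analysis of extrachromosomal
circular DNA (eccDNA) catalogs.

Circle-seq experiments yield, per sample, a catalog of genomic intervals
called as circular DNA. This package implements the downstream analysis
such a study needs, as a tested, reproducible pipeline for

* **catalog statistics** — normalized abundance (EPM: eccDNAs per
  million mapped reads), size distributions, per-chromosome per-Mb
  frequencies, gene-derivation counts (distinct eccDNA species per gene,
  genes spanned per species), and per-window correlations of eccDNA
  frequency against gene or Alu density;
* **GC context** — locus GC against the immediate 1-kb flanks and a
  constructed null of 1000 random genome stretches of equivalent length
  per record, with a calibrated rank test for GC enrichment;
* **element mapping** — an exclusive genomic-region partition
  (CDS/exon/UTR/intron/intergenic) and, for repeat families, the
  genome-composition-normalized mapping ratio
  `ratio_c = observed share / genome share` (1 under uniform placement),
  with bootstrap CIs;
* **genome instability** — the weighted genome instability index
  (wGII: mean over chromosomes of the fraction of bases at a copy number
  different from sample ploidy), NMF stratification of samples into
  high/low (H/L) eccDNA-abundance groups, and the wGII–abundance
  association;
* **outcome association** — H-vs-L differential expression (fold-change
  rule with optional rank-sum gating), a top-100 up-gene panel, ssGSEA
  panel scoring, optimal-cutoff Kaplan–Meier dichotomization
  (maximally selected log-rank with a permutation-corrected p), and
  marker ROC/AUC with DeLong CIs;
* **synthetic data** — a first-class generator that plants every
  statistical structure above (GC-biased and density-coupled placement,
  sub-100-bp size mode, H/L abundance split, wGII split, fold-change
  structure, survival hazard ratio) with truth tables, so every
  estimator is exercised against known ground truth.

`docs/methods.md` gives the full model and estimator details.

## Worked example

Simulate a study (18 samples, 9 high- and 9 low-abundance) and run the
full pipeline:

```sh
eccdna-charter simulate --seed 5 --outdir study/
eccdna-charter run-all \
    --genome study/genome.fa --catalog-dir study/catalogs \
    --samples study/samples.tsv --genes study/genes.bed \
    --repeats study/repeats.bed --cn study/cn_segments.tsv \
    --expression study/expression.tsv --survival study/survival.tsv \
    --out report/ --seed 11
```

`report/` then contains TSVs (each with a `#` preamble recording
version, seed and parameters). From one such run:

```
$ cat report/density_corr.tsv
covariate  window   r        p
gene       100000   0.935    1.2e-18
Alu        100000   0.579    9.2e-05

$ cat report/survival_comparison.tsv
cutoff   chi2    logrank_p  permutation_p  hr     n_high  n_low
0.0269   13.32   2.6e-04    5.0e-03        1.60   150     150
```

The first report says per-100-kb-window eccDNA frequency correlates
positively with protein-coding gene density (r = 0.93) and Alu density
(r = 0.58) — recovering the coupling the simulation planted. The second
says the score cutoff maximizing the log-rank statistic splits the
cohort 150/150 with χ² = 13.3; the honest significance after correcting
for having optimized the cutoff is the permutation p = 0.005 (the naive
2.6e-04 overstates it). `report/gc_profile.tsv` shows each sample's mean
locus GC exceeding the length-matched random background (excess ≈ 0.03
under the default planted bias), and `report/groups.tsv` carries the NMF
H/L labels with per-sample wGII and EPM.

Every stage is also invocable on its own (`characterize`, `gc-profile`,
`elements`, `group`, `survival`) with identical results to the pipeline
run, and the library functions are importable directly from
`eccdna_charter`.

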