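# sc3dmulti

Analysis toolkit for joint single-cell chromatin-conformation + DNA-methylation
(snm3C-like) data, bundled with a synthetic cohort generator so that every
stage is testable end-to-end without external downloads.

## What it does

* **synthetic_data** — multi-cell-type cohorts on a toy chromosome (default
  20 Mb) with planted loops, domain boundaries, compartment checkerboards and
  a methylome whose loop-anchor mCG loss trails loop gain by a configurable
  pseudotime lag; everything planted is recorded in a truth ledger.
* **contact_distance** — 143-bin logarithmic contact-distance histograms,
  SE/LE/INT conformation classes (|log2 ratio| threshold 0.4), k-means
  conformation clusters, cluster enrichment and similarity counts.
* **matrix_core** — per-cell matrix imputation (box filter + random walk with
  restart), per-diagonal z-scoring (E), local ring-background subtraction (T),
  diagonal shuffling, six-matrix pseudobulks {Q, Q2, E, E2, T, T2}, and the
  SVD cell embedding.
* **loop_analysis** — pseudobulk t statistics, empirical FDR against shuffled
  nulls, four local fold-change filters, loop calls and summits, ANOVA F from
  summary statistics, differential-loop selection (z > 1.036), promoter
  cumulative loop scores, half-Gaussian SIP test (p < 0.001).
* **domain_analysis** — insulation scores (window 10), per-cell boundary
  calls, boundary probabilities, chi-square differential boundaries with BH
  FDR, peak merging and the z/fold-change/probability-range filters.
* **compartment_analysis** — O/E, GC-signed compartment eigenvectors at 1 Mb,
  saddle sums, compartment strength and dominance, A↔B transition methylation.
* **methylome_features** — cell QC (mCCC < 0.03, mCG > 0.5, mCH < 0.2,
  contacts > 100k), methylation feature matrices with the coverage filter /
  imputation rule, 3C gene scores (3CGS), feature correlations.
* **metacell_dynamics** — k-NN meta-cells (k = 20, self-included), overlap
  deduplication (max 5 shared), pooled profiles, and the loop-strength vs
  anchor-mCG cross-correlation lag analysis.
* **regulatory_overlap** — loop-connected DMRs, hypergeometric motif
  enrichment (±250 bp extensions), Fisher fine-mapped SNP overlap, SNP–gene
  linking through loops, and the jackknife-SE enrichment-difference t-test
  (d.f. = 398).

## CLI

```bash
sc3dmulti simulate --seed 1 --out cohort/        # demo cohort (or --config cfg.json)
sc3dmulti distance --cohort cohort/ --out dist.tsv
sc3dmulti loops --cohort cohort/ --out loops.tsv
sc3dmulti domains --cohort cohort/ --out boundaries.tsv
sc3dmulti compartments --cohort cohort/ --out tracks.tsv
sc3dmulti methylome --cohort cohort/ --out qc.tsv
sc3dmulti metacells --cohort cohort/ --out shifts.tsv
sc3dmulti overlap --cohort cohort/ --out overlap.json
```

A cohort directory holds `contacts.tsv` (cell_id, chrom, pos1, pos2; 1-based),
`allc/<cell>.tsv` (7-column allc), BED annotations, `config.json` and
`truth.json`.

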