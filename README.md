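# promaff

Analysis pipeline for regulatory promoter variants that change the affinity
of the TATA-binding protein (TBP) for human core promoters.

Given a variant's ancestral (wt) and minor allele sequences, the package:

1. estimates −ln K_D (K_D in nM) for each allele with a three-component
   linear model of TBP–promoter recognition (duplex-opening "sliding" term,
   15-bp TATA position-weight-matrix "site" term, and a dinucleotide
   bending-propensity term), calibrated by least squares against the
   packaged K_D anchor catalog;
2. turns the pair of estimates into a decision: Z statistic
   (|Δln K_D| over the root of the summed squared SDs), a two-sided normal
   significance α, a heuristic rank A (strongest) … E (insignificant), and
   an expression-direction call (higher K_D ⇒ lower expected expression);
3. classifies the 90-row curated marker catalog (packaged as
   `src/promaff/data/markers.tsv`, checksum-verified) into candidate/known
   markers and summarizes candidate counts per gene group;
4. runs the selection-pressure statistics: exact one-sided binomial
   lower-tail tests (computed in log space) of the familial-AD gene group's
   expression-decreasing proportion against the other-diseases group and
   against the genome-wide 2:1 reference, plus a Fisher-exact companion;
5. provides a predicted-vs-measured concordance suite (Pearson r, Spearman
   R, Kendall τ-b, Goodman–Kruskal γ, and χ²/Fisher on a median-split 2×2
   table);
6. generates synthetic promoters with planted TATA elements and
   truth-labelled SNPs so the whole pipeline is testable offline.

## Command line

```sh
promaff analyze --fixture --out results.tsv        # score the packaged catalog
promaff analyze --fasta promoters.fasta --snps snps.tsv --out results.tsv
promaff reproduce --out report.json                # headline counts + binomial bounds
promaff synth --n 90 --seed 1 --out-dir synth/     # synthetic benchmark set
promaff calibrate --out coeffs.cfg                 # refit model coefficients
promaff fixtures --out markers.tsv                 # export the catalog
promaff concordance --pairs pairs.tsv              # agreement statistics
```

The SNP table is TSV with columns `snp_id, gene, flank5, wt, minors,
flank3` (`-` marks an absent allele; multi-allele cells are comma
separated). A minimal VCF subset (CHROM, POS, ID, REF, ALT) plus a BED of
promoter intervals is also accepted programmatically
(`promoter_io.read_vcf_subset`).

## Model provenance

The model tables (`data/model_tables.cfg`) and calibrated coefficients
(`data/model_coeffs.cfg`) are plain-text configs, hashed into every results
header. `scripts/freeze_calibration.py` regenerates them together with
`data/frozen_metrics.json`, the regression-pinned quality metrics (anchor
Spearman correlation, direction-concordance set, Z-scale agreement rate,
synthetic recovery rates) that the test suite enforces bit-for-bit.
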