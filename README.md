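# mitoflex

Analysis toolkit for muscle lipid handling in age x diet mouse cohorts:

* **`mitoflex.betaox`** — deterministic kinetic model of mitochondrial
  long-chain fatty-acid beta-oxidation (chain lengths C16..C4 with explicit
  dehydrogenase / hydratase+HAD / thiolase steps, CPT1B entry with
  competitive malonyl-CoA inhibition, lumped CACT/CPT2 import, conserved
  CoA and carnitine pools, first-order acetyl-CoA sink) plus a stiff
  steady-state solver; the steady-state CPT1 rate is the pathway flux
  readout.
* **`mitoflex.parameterization`** — liver-anchored catalytic constants
  (`k_cat = Vmax / concentration`) applied to targeted-proteomics tables to
  build one kinetic model per animal; peptide-to-protein quantification
  from endogenous/standard transition areas; citrate-synthase enrichment
  correction.
* **`mitoflex.mca`** — metabolic control analysis: flux-control
  coefficients by a scaled forward finite difference (relative Vmax
  perturbation 1e-6), FCC-vs-substrate profiles, summation-theorem checks,
  cohort simulations with group mean +/- SEM.
* **`mitoflex.ogtt`** — double-exponential OGTT curve fitting
  (deterministic multi-start least squares with a nested-model guard for
  the weakly identified slow term), the muscle insulin sensitivity index
  (maximal post-peak glucose decline over mean insulin), and mouse-adjusted
  HOMA-IR (glucose[mM] x insulin[mU/L] / 14.1).
* **`mitoflex.omics`** — lipid class-standard normalization; differential
  abundance (log2, mean-centring, Student's t, FDR Q=5%, fold-change gates
  1.5 / 0.66); diet-response scatter normalization; Pearson correlation
  against per-sample indices; two-factor (age x diet) screen with Type-II
  sums of squares and Tukey-Kramer pairwise contrasts.
* **`mitoflex.synth`** — seed-deterministic synthetic cohort generator
  (2x2 age x diet design, 16 beta-oxidation + 31 glucose-metabolism
  proteins, 443 lipid species with class labels and internal standards,
  OGTT curves) with planted, configurable group effects so every stage is
  testable without external data.
* **`mitoflex.io` / `mitoflex.pipeline` / `mitoflex.cli`** — delimited-text
  readers/writers, YAML pipeline configuration and the umbrella CLI.

## CLI

```sh
mitoflex synth --seed 1 --out cohort/              # synthetic cohort tables
mitoflex parameterize --proteomics cohort/proteomics.tsv \
    --samples cohort/samples.tsv --out cohort/params/
mitoflex simulate --params cohort/params/YL01.ini \
    --substrate-min 0.1 --substrate-max 10 --points 25 --malonyl 0.2 \
    --out scan.tsv
mitoflex fcc --cohort cohort/params --samples cohort/samples.tsv \
    --enzymes CPT1B,MCKAT --malonyl 0,0.2 --grid-log 0.1:10:25 --out fcc.tsv
mitoflex fit-ogtt --in cohort/ogtt.tsv --out indices.tsv
mitoflex lipidiff --table cohort/lipidomics.tsv --classes cohort/lipid_classes.tsv \
    --samples cohort/samples.tsv --standards cohort/lipid_standards.tsv \
    --age old --fdr bh --out diff_old.tsv
mitoflex scatter --table cohort/proteomics.tsv --samples cohort/samples.tsv \
    --out scatter.tsv
mitoflex correlate --table cohort/lipidomics.tsv --samples cohort/samples.tsv \
    --index indices.tsv --out correlations.tsv
mitoflex run --seed 1 --out results/                # full pipeline
```

Exit codes: 0 success, 1 validation error, 2 runtime failure.

## Data formats

All I/O is plain tab-separated text with one header row; `#` comment lines
may declare units. Analyte matrices put identifiers in the first column and
samples in the remaining columns; group labels live only in the sample
sheet (`sample`, `age`, `diet`). Kinetic parameters use INI files with
`[vmax]`, `[km]`, `[conserved]`, `[chains]` and `[options]` sections (see
`mitoflex/betaox/params_io.py` for the schema and units).
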