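# immunomir

Analysis pipeline linking serum miRNA levels to innate-immune subgroups
(defined by monocyte IL-1b/IL-10 ratios) and to mitochondrial respiration,
with a seeded synthetic cohort generator so the whole pipeline is testable
without any external data.

Stages:

1. **synthetic cohort** (`immunomir.simulate`) — log-normal cytokine
   production under four culture conditions (medium, LPS, zymosan, CL097)
   with subgroup-dependent IL-1b/IL-10 shifts; 4-phase OCR traces (3
   measurements per phase); negative-binomial miRNA counts with a planted
   differential-expression pattern; rank correlations planted through a
   Gaussian copula. Ground truth is carried in a `truth` bundle.
2. **subgroup classification** (`immunomir.subgroups`) — per-subject,
   per-condition IL-1b/IL-10 ratios classified as high / normal / low
   against control mean ± SD thresholds, with rule-gap and conflict
   policies, multi-timepoint reconciliation, and a full audit log.
3. **respiration** (`immunomir.respiration`) — basal, ATP-linked (ALR),
   proton-leak (PLR), maximal (MRC), reserve (RC) and non-mitochondrial
   OCR plus ALR/PLR and MRC/PLR efficiency ratios, with QC flags.
4. **differential expression** (`immunomir.de`) — CPM, low-count filtering
   anchored to the smallest library, TMM normalization, common-dispersion
   estimation by conditional maximum likelihood, the conditional NB exact
   test, and Benjamini–Hochberg adjustment. All re-implemented and checked
   against enumeration oracles.
5. **association screens** (`immunomir.screen`) — tie-corrected Spearman
   (exact permutation p for n ≤ 9), Mann–Whitney / Kruskal–Wallis / Fisher
   exact / chi-square, stratified correlation screens with tiered
   reporting, and a GLM covariate screen.
6. **pipeline + CLI** (`immunomir.pipeline`, `immunomir.cli`).

## CLI

```sh
# write a synthetic cohort (TSV tables + truth.json)
immunomir simulate --seed 7 --outdir cohort/

# full pipeline on a fresh simulation (or --input-dir cohort/)
immunomir run --seed 7 --outdir out/

# individual stages against a cohort directory
immunomir classify  --input-dir cohort/ --outdir out/
immunomir respire   --input-dir cohort/ --outdir out/
immunomir de        --input-dir cohort/ --outdir out/
immunomir associate --input-dir cohort/ --outdir out/
```

`run` writes `subgroups.tsv`, `classification_audit.jsonl`,
`respiration.tsv`, per-comparison `de_*.tsv` + volcano tables,
`de_summary.tsv`, `correlations.tsv` / `correlations_significant.tsv`,
`covariate_screen.tsv`, and a machine-readable `summary.json`. A simulation
config may be passed as YAML (`--config`); see
`immunomir.config.SimulationConfig` for the fields.

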