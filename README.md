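# lymphosc

Single-cell lymphoma analysis toolkit: quality control and clustering of gene
x cell count matrices, per-cell ABC/GCB cell-of-origin classification,
light-chain allelic-exclusion and windowed CNV evidence of malignancy,
cross-sample consensus-NMF meta-program discovery, binned-control signature
scoring, intratumor-heterogeneity and repertoire-diversity statistics, and
signature-score survival stratification. A bundled synthetic-cohort generator
provides ground truth for every stage, so the whole pipeline is testable
without any external download.

## Modules

| module | contents |
| --- | --- |
| `lymphosc.syndata` | multi-sample NB cohort generator (programs, CNV blocks, light-chain restriction, COO shifts, QC violators), TCR repertoire and survival generators, MTX/CSV writers |
| `lymphosc.qcnorm` | MTX + TSV I/O, QC filters (gene >= 50 cells; cell 500-6000 genes, mito < 15%, counts < 50,000), normalize-to-10,000 + log1p, HVG/PCA/Leiden clustering |
| `lymphosc.malignancy` | kappa/lambda allelic-exclusion calls, reference-relative windowed CNV profiles, exact hypergeometric set-overlap test |
| `lymphosc.coo` | quantile-normalize -> log2 -> z -> mean-z ABC/GCB scoring with the 0.25/0.75 threshold rules |
| `lymphosc.programs` | per-sample consensus NMF, cross-sample meta-programs (recurrence >= 4), binned-control signature scores, DEPTH2 and Hill-number diversity |
| `lymphosc.repertoire` | 10x/AIRR contig parsing, CDR3-nt clonotypes with the multi-chain filter, expansion fraction (clone size > 10), Morisita-Horn, Berger-Parker |
| `lymphosc.outcomes` | Wilcoxon + BH differential expression (adj P <= 0.01, FC >= 1.5), exhaustion-score comparisons, minprop-constrained optimal cutpoint, KM + log-rank |

## CLI

```sh
lymphosc simulate --config cohort.yaml --outdir out --seed 7
lymphosc qc --indir out --outdir out/qc
lymphosc cluster --indir out/qc --resolution 0.05 --seed 0
lymphosc coo --indir out/qc --abc-genes abc.tsv --gcb-genes gcb.tsv
lymphosc mp discover --indir out/qc --k 7 --restarts 50 --min-recurrence 4 --seed 0
lymphosc mp score --indir out/qc --signature metaprograms.gmt
lymphosc clonotypes --contigs out/filtered_contig_annotations.csv
lymphosc survival --table out/survival.csv --minprop 0.3
lymphosc deg --indir out --group-a malignant --group-b cd8_T
```

The simulate config is YAML mirroring `lymphosc.syndata.SimConfig`; see
`tests/test_cli.py` for a complete example.

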