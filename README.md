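# idletrace

Quantitative tools for studying drug-tolerant persister (DTP) cancer-cell
populations that survive targeted therapy in an "idling" state — dividing
and dying at balanced, non-zero rates so the population neither expands nor
regresses. The package is written for computational biologists analysing
clonal lineage-tracing experiments (ClonMapper-style gRNA barcodes read out
by amplicon sequencing and scRNA-seq capture) together with the functional
assays that accompany them: drug-response growth kinetics and
store-operated calcium entry (SOCE) measurements.

Five analysis layers, each usable on its own:

* **Population simulation** — exact (Gillespie) and tau-leaping simulation
  of lineages occupying phenotypic states with state-specific division,
  death and transition rates; treatment is a landscape switch with a
  configurable state map. The analytic oracle is the branching-process
  mean `E[n(t)] = exp(tA) n(0)`.
* **Barcode counting** — SW-patterned barcode design (2^16 complexity),
  extraction from flanked amplicon reads, RPM normalisation, the 100-CPM
  abundance filter, per-barcode log2 fold-changes, and complexity/sharing
  statistics.
* **Lineage mapping** — cell-to-lineage assignment by distinct-UMI
  majority over a transcript-ID join, lineage composition across clusters
  and slow (G1) / fast (S-G2-M) cycle classes, and the Pearson correlation
  between a lineage's fast-dividing fraction and its abundance
  fold-change: the clone-fitness readout.
* **Functional assays** — DIP (drug-induced proliferation) rates as the
  OLS slope of log2 cell counts; 4-parameter log-logistic dose-response
  `E(d) = Emax + (E0 - Emax)/(1 + (d/EC50)^h)` with DIP rate as the
  effect, IC50 fold-shift comparisons with bootstrap CIs; SOCE trace
  normalisation (baseline -> 0, ionomycin max -> 1) and two-peak
  quantification with group mean +/- SEM.
* **Synthetic data** — seeded generators for every input above, each
  emitting ground truth, so the full pipeline is testable end to end with
  no downloads. Also exposed via `idletrace synth`.

Supporting utilities: depth scaling of count matrices, Tirosh-style
bin-matched gene-signature scores, cell-cycle slow/fast calls, baseline
log2 fold-change tables, and Spearman concordance of -log10 p across two
GO-enrichment analyses.

## Worked example

Does a lineage's occupancy of the fast-dividing persister state predict its
fitness under drug? `examples/03_lineage_correlation.py` simulates barcoded
lineages entering a drug-modified landscape, samples reads and single-cell
records, assigns lineages by UMI majority and correlates fast fraction with
fold-change:

```text
fitness-coupled landscape: Pearson r = +0.958 over 24 lineages (permutation p = 0.000)
neutral landscape: Pearson r = -0.038 over 24 lineages (permutation p = 0.860)
```

When the fast state grows (+0.02 log-cells/h) and the slow state regresses
(-0.02), lineages enriched for fast cells gain abundance and the
correlation is strongly positive; on the neutral landscape (every state
division = death) the identical pipeline returns a correlation the
permutation test cannot distinguish from zero.

`examples/04_dose_response.py` shows the dose-response layer:

```text
    idling: EC50 =  0.303 uM, E0 = +0.0299, Emax = -0.0301, h = 2.00
 untreated: EC50 =  0.897 uM, E0 = +0.0300, Emax = -0.0299, h = 1.99
   rescued: EC50 =  0.897 uM, E0 = +0.0300, Emax = -0.0300, h = 2.00

idling vs untreated IC50 fold-shift: 2.96 (bootstrap 95% CI 2.89-3.01)
rescued vs untreated fold-shift:     1.00 (CI contains 1: True)
```

DIP rates fitted from noisy twice-daily growth curves recover the
generating parameters; the idling condition is ~3-fold more sensitive by
potency, and the rescue condition's fold-shift CI contains 1. The other
examples cover the simulator vs its mean-field oracle, barcode counting
and filtering, SOCE quantification, and GO concordance.

A thin CLI mirrors the file-driven workflows
(`idletrace simulate|barcodes|lineage|scores|dip|calcium|synth|run`); see
`idletrace --help`. Interchange formats are headered TSV/CSV, FASTQ
(plain/gz), YAML/JSON configs.

## Further reading

`docs/methods.md` describes the model and its assumptions, the default
parameters and why they were chosen, what the generators do and do not
emulate, numerical choices, and known limitations.
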