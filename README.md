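# acetylscope

Integration of promoter histone-acetylation ChIP-seq with expression
microarrays, for studies that ask whether a treatment's transcriptional
response is accompanied by changes in an activating chromatin mark around
transcription start sites (TSSs).

The package targets a four-group pretreatment × challenge design —
chronic saline or drug followed by an acute saline or drug injection
(groups SS, SM, MS, MM) — and provides every stage of the analysis as a
tested library plus a thin CLI:

- **Synthetic data** with known ground truth: gene annotations, a
  four-group expression matrix with planted fold changes (including a
  blunted response in the pretreated contrast), and single-position ChIP
  tag libraries whose TSS-centred enrichment couples log-linearly to
  expression over a uniform background.
- **Tag quantification**: tags-per-million normalization
  (`10^6 / N_total`), nearest-TSS ("nearest promoter") assignment with
  deterministic tie-breaking, TSS metagene profiles, a sliding-window
  Poisson enrichment caller against the input control, site→gene
  annotation, and Venn partitions of gene sets across conditions.
- **Expression**: median ("global") normalization, differential calling
  at a fold-change/p-value cut-off (default |FC| ≥ 1.7 and p < 0.01,
  Welch's t on log₂ intensities), and per-gene Z scores.
- **Integration**: genes sorted by expression Z score are binned into
  groups of 100; the per-bin mean normalized promoter tag count is
  regressed on the per-bin mean Z by ordinary least squares, reporting
  the slope and R². Per-gene binding fold change after input correction
  is `((IP_B + c)/(input_B + c)) / ((IP_A + c)/(input_A + c))`, reported
  in the signed convention (−1.85 means a 1.85-fold decrease). Each
  differentially expressed gene is then classified as binding
  **increased**, **decreased**, **NC** (no change) or **absent** (not
  detected on the ChIP platform), producing up/down × binding
  concordance tables.

Two packaged fixtures transcribe published concordance tables
(`acetylscope/data/table1_fixture.tsv`, `table2_fixture.tsv`) so the
classifier can be validated row by row against printed results.

## Worked example

Reclassify the packaged acute-treatment concordance table through the
generic classifier:

```python
from acetylscope import fixture_concordance
records, table, totals = fixture_concordance("table1")
print(table)
print("both-platform totals:", totals)
```

```
      increased  decreased  NC  absent
up           29          0   3       9
down          0          2   3       7
both-platform totals: {'up': 32, 'down': 5}
```

Of the 32 upregulated genes detected on both platforms, 29 show
increased promoter acetylation and 3 no change; of the 5 downregulated
genes on both platforms, 2 show decreased binding and 3 no change.

Run the full simulated pipeline (1000 genes, 10⁵ tags per library):

```python
from acetylscope import PipelineConfig, run_pipeline
rep = run_pipeline(PipelineConfig(seed=1, outdir="demo_run"))
c = rep["conditions"]["SS"]["regression"]
print("SS regression: slope=%.1f r_squared=%.3f n_bins=%d"
      % (c["slope"], c["r_squared"], c["n_bins"]))
print("DE SM_vs_SS:", rep["differential_expression"]["SM_vs_SS"])
print("DE MM_vs_MS:", rep["differential_expression"]["MM_vs_MS"])
```

```
SS regression: slope=470.4 r_squared=0.884 n_bins=10
DE SM_vs_SS: {'n_up': 60, 'n_down': 26}
DE MM_vs_MS: {'n_up': 17, 'n_down': 46}
```

The positive slope with R² ≈ 0.88 over ten 100-gene bins recovers the
planted expression–binding coupling; the acute contrast calls 60 up / 26
down in drug-naive animals and a mostly-down, blunted response in the
pretreated contrast, matching the planted design. The same run is
available from the shell:

```sh
acetylscope demo --out demo_run --seed 1
acetylscope integrate table-check --fixture table1
```

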