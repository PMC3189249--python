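# promethylome

Promoter DNA-methylation analysis of MeDIP tiling-array data, with a
planted-truth simulator for end-to-end validation.

## The problem

Methylated-DNA immunoprecipitation (MeDIP) on a promoter tiling array
compares an immunoprecipitated channel against input DNA, duplicated per
sample, across a developmental panel: ES cells, ES-derived germ layers
(ectoderm, endoderm, paraxial mesoderm), adult somatic tissues and sperm.
The analysis questions are the classic ones of developmental epigenomics:
which promoters are methylated at all, which CpG islands become methylated
after differentiation, how methylation is distributed around transcription
start sites, which methylated regions are *common* to all somatic lineages
versus tissue-specific (T-DMRs), whether commonly methylated promoters
belong to testis/germline-specific genes, and how promoter methylation
relates to H3K4me3/H3K27me3 histone states.

`promethylome` implements that full analysis for anyone who wants a
transparent, reproducible, fully specified version of the MeDIP-chip
promoter pipeline — plus a synthetic-data generator that plants ground
truth, so every stage is testable without any external download.

## The method in brief

* **Probe score.** Arrays are robust-standardised on the log2 scale
  (median-centred, scaled by 1.4826·MAD). Per probe, MeDIP − input-mean
  differences are pooled over a ±400 bp window across replicates; the
  score is the 10%-trimmed mean × √(effective count) — a windowed,
  standardised enrichment statistic.
* **Empirical FDR.** FDR%(s) = 100 · min(1, #null ≥ s / #observed ≥ s)
  with a null track from an input-replicate label swap.
* **Candidate methylated regions (CMRs).** Runs of probes scoring > 2.5
  are merged across samples, then gated: region CpG density > 5% (the
  analysis is restricted to CpG-rich promoters) and score > 3.0 in at
  least one sample. Per-sample calls are tri-state: > 2.5 methylated,
  < 1.5 hypomethylated, otherwise indeterminate.
* **Cross-sample comparison.** TSS-distance methylation-frequency
  profiles (methylated probes / total probes per position), CpG-island
  and promoter-zone tables, commonality categories (methylated in all
  samples / all non-sperm samples / all somatic samples / germ layers
  only) and T-DMR extraction with pairwise contrasts.
* **Enrichment.** Genes ranked by testis specificity
  (testis / max somatic expression, floored) are tested for enrichment of
  the commonly methylated gene set with the weighted KS running-sum
  statistic and a 1000-fold gene-permutation null (NES, nominal p).
* **Histone integration.** Promoter states {K4, K27, bivalent, none} from
  peak overlap with TSS ± 2 kb, percentage methylated per state,
  state-transition tables between samples, and Welch t-tests of
  expression between gene groups.

See `docs/methods.md` for the model details, parameter defaults and the
design rationale.

## Worked example

```python
from promethylome import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(sim=SimulationConfig(n_genes=2000, seed=1), seed=1)
res = run_pipeline(cfg, out_dir="demo_run")

print(res.commonality.to_string(index=False))
e = res.enrichment
print(f"\ncommonly methylated set: {e.set_size} genes, "
      f"NES = {e.nes:.2f}, p = {e.p_value:.4g}")
print("\n% methylated by histone state (Ect):")
print(res.meth_by_state["Ect"].to_string(index=False))
prof = res.profiles["Ect"]
print(f"\nTSS profile minimum at {prof.loc[prof['smoothed'].idxmin(), 'position']:+.0f} bp")
```

prints

```
                 category  total  core  not_core
                    total    227    25       202
             all_positive     15     3        12
sperm_any_others_positive     39     4        35
           somatic_common     77     8        69
          early_diff_only      0     0         0
                 variable     56     7        49
                    other     40     3        37

commonly methylated set: 77 genes, NES = 2.05, p = 0.000999

% methylated by histone state (Ect):
   state  n_genes  n_methylated  pct_methylated
      K4     1342             0        0.000000
     K27       99             6        6.060606
bivalent      252             5        1.984127
    none      307            21        6.840391

TSS profile minimum at +125 bp
```

Reading it: of 227 CMRs, most methylated regions are shared across every
somatic lineage (`somatic_common`), only a handful are germ-layer
specific, and few sit in the core promoter. The commonly methylated gene
set is strongly enriched among testis-specific genes (positive NES,
p ≈ 0.001). Methylation is rarest at H3K4me3-marked promoters and the
methylation-frequency profile dips at the TSS — the hypomethylated core
promoter.

The same run is available from a shell:

```sh
promethylome run --out demo_run --seed 1
```

which writes per-stage TSV/BED tables (probe scores, FDR curves, CMR
calls, commonality and zone tables, TSS profiles, GSEA results, histone
cross-tabs) plus a `manifest.json` recording seeds and a parameter hash;
reruns with the same configuration are byte-identical.

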