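# mirdecay

Direct measurement of microRNA repression from transcription-shutdown
RNA-seq time courses, with a ground-truthed simulator for validating every
step.

## The scientific problem

The conventional way to quantify how strongly a miRNA represses its targets
is to compare steady-state expression between a wild-type (WT) and a
miRNA-knockout (KO) animal. But steady-state abundance is a ratio of two
rates,

```
X = B / D        (synthesis B, degradation D)
```

so an equilibrium comparison confounds them. If losing the miRNA also
changes a target's synthesis — through feedback, or because the miRNA
represses an upstream regulator — the observed expression change can
drastically understate the direct effect on degradation. The identity

```
D_wt / D_ko = (X_ko / X_wt) × (B_wt / B_ko)
```

makes the bias explicit: an apparent 10% equilibrium de-repression
(X_ko/X_wt = 1.1) combined with a two-fold synthesis coupling
(B_wt/B_ko = 2) means the miRNA actually raised the degradation rate by
**120%**, not 10%.

The remedy is to measure D directly. After blocking transcription
(Actinomycin D), abundance decays as `x(t) = X·exp(−D·t)`, so a log-linear
regression of expression on time yields D in each genotype, and the WT/KO
ratio of decay rates isolates the miRNA's direct contribution
(D_wt = d + m in WT, D_ko = d in KO).

`mirdecay` implements that measurement end to end for a WT-vs-KO design
(modeled on the *Drosophila* miR-310s cluster knockout):

- **`io_formats`** — expression matrices (TSV), sample designs, region
  FASTA (5'UTR/CDS/exon/intron/3'UTR), miRNA tables; strict validation.
- **`decay_model`** — reference-gene normalization, per-transcript
  log-linear decay fits, expression (FPKM ≥ 5) and half-life (≤ 15 h)
  filters, KDE-mode normalization of decay rates across genotypes.
- **`target_sites`** — canonical seed-match scanning (8mer-1a, 7mer-m8,
  7mer-1a), conservation-gated target calling across ortholog sequences,
  and the binary group labels (seed type, upstream poly(A) signal /
  APA, co-targeting by abundant miRNAs, 3'UTR isoform length).
- **`motif_scan`** — the nine W-degenerate AU-/GU-/U-rich destabilizing
  element patterns, with the all-five-regions flagging rule.
- **`group_compare`** — percent changes (two orientations, two aggregation
  schemes), exact small-sample Wilcoxon rank-sum, ECDFs, 1D/2D KDE modes.
- **`synthetic_data`** — a simulator with complete ground truth: gamma
  basal decay rates, lognormal expression and measurement noise, library
  scale factors, planted seed sites / APA hexamers / ARE motifs across
  three species, and an explicit synthesis-coupling effect model.
- **`pipeline` / `cli`** — the staged workflow
  `simulate → fit → targets → compare → report`, importable or as the
  `mirdecay` command.

## Worked example

`examples/03_bias_demo.py` demonstrates the headline identity end to end —
a noiseless simulation with synthesis coupling B_wt/B_ko = 2 and apparent
equilibrium change X_ko/X_wt = 1.1, pushed through the full pipeline
(reference normalization, per-genotype fits, filters):

```
$ python examples/03_bias_demo.py
analytic bias identity: D_wt/D_ko = 1.1 * 2 = 2.2

end-to-end on 38 kept simulated targets:
  equilibrium-based estimate (t=0 KO/WT - 1): 10.0%
  decay-based measurement    (WT/KO D - 1)  : 120.0%
```

`examples/01_fit_decay_rates.py` fits a small noisy cohort:

```
$ python examples/01_fit_decay_rates.py
transcripts fit (WT):      408
kept after filters (both): 321
decay-rate mode WT:        0.1320 /h
decay-rate mode KO:        0.1188 /h
median relative error of fitted KO decay rates: 5.7%
median fitted KO half-life: 5.30 h
```

`examples/02_scan_target_sites.py` shows the site scanner on a toy 3'UTR,
and `examples/04_full_pipeline.py` runs all four file-based stages on a
1,500-transcript cohort; its comparison block ends with, e.g.:

```
UTR3: 118 conserved targets
  UTR3:equilibrium_per_target:equilibrium         +12.7%
  UTR3:degradation_per_target:degradation         +10.2%
  ...
CDS: 74 conserved targets
  CDS:equilibrium_per_target:equilibrium          +10.2%
  CDS:degradation_per_target:degradation           +6.4%
```

(simulated with δ = 0.1 and no synthesis coupling, so both estimates
hover near the true 10%).

## Command line

```bash
mirdecay simulate --outdir run/ --seed 7      # ground-truthed inputs
mirdecay fit      --outdir run/               # normalize + fit + filter
mirdecay targets  --outdir run/               # scan + classify
mirdecay compare  --outdir run/               # WT-vs-KO statistics
mirdecay report   --outdir run/               # merged JSON summaries
```

All thresholds and simulator parameters live in a YAML config
(`--config`); defaults reproduce the study conditions (t = 0/2/4/8 h,
2 replicates, FPKM ≥ 5, half-life ≤ 15 h).

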