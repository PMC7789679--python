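# secretoscope

Peptide-level label-free quantification (LFQ) analysis of cell
secretomes, built around the study design in which mesenchymal stromal
cells (MSCs) from 12 donors were stimulated with conditioned medium from
healthy, traumatic, or degenerative intervertebral discs (or IL-1β as a
pro-inflammatory control) and the released proteins were profiled by
LC-MS/MS against an unstimulated baseline. The package is for proteomics
analysts who have a searched peptide intensity matrix (e.g. MaxQuant
`peptides.txt`) plus a sample design and want reproducible
condition-vs-baseline fold changes, enrichment results, and secretome
set comparisons — and for methodologists who want the whole pipeline
testable on synthetic data with known ground truth.

## What it computes

Given peptide intensities *x(i,s)* for peptide *i* in sample *s*, with
samples annotated by donor, condition and MS batch (baseline measured in
every batch):

1. **Quantification filters** — keep a peptide only if it is observed in
   **more than 50%** of the samples of at least one condition (strict
   inequality: 7 of 12 qualifies, 6 of 12 does not); then keep only
   proteins with ≥ 2 quantified peptides.
2. **Normalization** — a rescaled per-sample z-score of the log2
   intensities:
   `x′(i,s) = ((log2 x(i,s) − μ_s)/σ_s)·σ̄ + μ̄`,
   where μ_s, σ_s are the observed-cell moments of sample *s* and σ̄, μ̄
   are their averages over samples; every sample ends up with mean μ̄
   and SD σ̄.
3. **Differential abundance** — per protein, a linear mixed model on
   normalized log2 peptide intensities,
   `y = β₀ + β_condition + β_batch + u_donor + u_peptide + ε`,
   with random intercepts for donor (repeated measures) and peptide
   (ionization offsets), REML-fitted; `β_condition` is the log2 fold
   change vs baseline, tested with a t-statistic at
   Satterthwaite-approximated degrees of freedom, with
   Benjamini-Hochberg q-values per contrast. Singular fits fall back
   deterministically (drop donor term → fixed-effects OLS with peptide
   covariates).
4. **Preranked GSEA** — proteins ranked by estimated log2FC; weighted
   running-sum enrichment score (hits add |score|/Σ_set|score|, misses
   subtract 1/(N−N_set)); gene-label permutation null (default 1000),
   sign-normalized NES, permutation p, tail-ratio FDR; sets with fewer
   than 10 in-list members are skipped.
5. **Set analysis** — per-condition sets of upregulated proteins
   (log2FC ≥ 1.5, p < 0.05 by default), full Venn decomposition,
   pairwise overlaps, Table-style membership lists, six-way functional
   category composition (ECM / anabolic / catabolic / growth factor /
   immune system / other), and plain id lists for network tools.
6. **Companion assays** — DNA-normalized per-donor immunoassay fold
   changes vs baseline, LDH cytotoxicity
   (`100·(sample − neg)/(pos − neg)`), and a normality-gated group test
   (ANOVA if no normality test rejects in any group, else
   Kruskal-Wallis).

A synthetic-data module generates the whole study design — peptide-level
intensities with protein/peptide/donor/batch/condition effects, MCAR and
intensity-dependent (MNAR) dropout, gene sets with planted enrichment,
and immunoassay plates — with ground truth for every quantity, so all of
the above is testable offline.

## Worked example

Simulate a dataset with 120 proteins (15 truly differential at ±2 log2
units) and run the full pipeline:

```bash
secretoscope simulate --seed 7 --n-proteins 120 --n-de 15 --out demo/sim
secretoscope run --peptides demo/sim/peptides.tsv \
    --design demo/sim/design.tsv --gmt demo/sim/genesets.gmt \
    --permutations 200 --min-set-size 8 --fc-threshold 1.0 \
    --out demo/results
```

`demo/results/effects.tsv` then starts:

```
protein    condition  log2fc    se      df   p   q  n_peptides fit_note
  P0001         IL1b  -2.291 0.086 275.516 0.0 0.0           5     full
  P0001 degenerative  -2.178 0.084 276.032 0.0 0.0           5     full
  P0001      healthy  -2.151 0.084 275.890 0.0 0.0           5     full
  P0001    traumatic  -2.172 0.087 276.362 0.0 0.0           5     full
```

P0001 was planted as downregulated by 2 log2 units in every stimulated
condition; the fitted log2FC of about −2.2 ± 0.09 recovers it (the
`full` note says the complete donor+peptide random-effect structure
converged). Applying the |log2FC| ≥ 1.0, p < 0.05 rule yields 56
significant protein×condition rows (14 proteins × 4 conditions; the
15th planted protein is a low-abundance casualty of the
intensity-dependent dropout and the quantification filters, so it never
reaches the model), and
`pairwise.tsv` shows each pair of conditions sharing the same 10
upregulated proteins — as expected, since simulated effects are shared
across conditions.

The packaged reference table of upregulated secretome proteins is
available too:

```python
from secretoscope.datasets import load_msc_secretome_memberships
from secretoscope.sets import build_partition

part = build_partition(load_msc_secretome_memberships())
part.intersection("traumatic", "degenerative")   # -> 38
```

## Layout

- `secretoscope.simulate` — study-design generator with ground truth
- `secretoscope.io` — MaxQuant-style/long peptide TSV, design TSV, GMT,
  category map, assay CSV, results bundle with provenance metadata
- `secretoscope.filtering`, `.normalize`, `.differential`, `.gsea` —
  scikit-learn-style estimators (`fit`/`transform`, fitted attributes)
  plus functional wrappers
- `secretoscope.sets`, `.assays` — set algebra and assay statistics
- `secretoscope.pipeline` — end-to-end orchestration and
  simulation-based calibration studies
- `secretoscope.cli` — `secretoscope simulate|run|gsea|sets|assay|calibrate`

See `docs/methods.md` for the statistical model, defaults, and known
limitations.
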