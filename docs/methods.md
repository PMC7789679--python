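# Methods

This note records the statistical model behind `secretoscope`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter when
reading results.

## Study design assumed

The pipeline targets a repeated-measures LFQ design: MSC secretomes from
N donors (default 12) under five stimulation conditions — an
unstimulated **baseline** plus healthy / traumatic / degenerative
conditioned-medium stimuli and an IL-1β control — acquired in two MS
batches (one 48-sample batch with baseline + traumatic + degenerative +
IL-1β, one 24-sample batch with baseline + healthy). Baseline samples
appear in **every** batch; this is what makes the batch shift a fixed
effect the model can estimate rather than a confounder, because the
healthy condition exists only in the second batch.

## Quantification filters

A peptide is *quantified* if observed in strictly more than 50% of the
samples of at least one condition; a qualifying peptide keeps all of its
measurements in all samples. Occupancy is evaluated per condition pooled
across batches (baseline is one condition even though it spans both
batches); a `per_batch` switch evaluates (condition, batch) cells
instead. Proteins then need at least two quantified peptides. Both rules
are idempotent and monotone (adding an observation can never drop a
peptide), which the property tests assert. No imputation is performed at
any point: the mixed model consumes observed cells only.

## Normalization

Per-sample loading differences are removed by a rescaled z-score of the
log2 intensities computed over observed cells (sample SD, ddof = 1):

    x'(i,s) = ((log2 x(i,s) − μ_s) / σ_s) · σ̄ + μ̄

with σ̄ and μ̄ the across-sample means of σ_s and μ_s. After the
transform every sample has observed-cell mean μ̄ and SD σ̄ exactly (to
1e-9 in the contract tests). Re-adding the pooled location μ̄ keeps the
values on a recognisable intensity scale; since μ̄ is one constant for
all samples it cancels in every baseline-referenced contrast, and the
fold-change invariance to this choice is unit-tested. A sample with zero
variance of observed values is a hard error naming the sample.

**Known limitation.** The transform assumes all samples share one true
spread. If a large fraction of proteins carries strong condition
effects, condition samples genuinely have larger spread; z-scoring then
shrinks them toward the common scale and attenuates contrasts by an
amount proportional to each protein's offset from the sample mean. At
realistic differential fractions (a few hundred of thousands of
peptides) the distortion is negligible, but calibration studies with
dense planted effects must account for it (see below).

## Differential model

For each protein, normalized log2 peptide intensities y follow

    y = β₀ + β_condition + β_batch + u_donor + u_peptide + ε,

with condition contrasts against baseline, batch as a fixed effect, and
independent random intercepts for donor and peptide. Donors are the
repeated-measures unit; peptides of one protein differ systematically in
ionization efficiency, which the peptide intercept absorbs. The model is
REML-fitted (statsmodels `MixedLM`, donor and peptide as crossed
variance components in a single group). The response is centered before
fitting, which makes estimates exactly invariant to any location shift
of the input.

The reported log2 fold change is the condition coefficient; its p-value
uses a t-statistic with **Satterthwaite** degrees of freedom computed
in-package from closed-form REML quantities: ν = 2f²/(gᵀAg) with
f = c′(X′Σ⁻¹X)⁻¹c, g its analytic gradient in the variance parameters,
and A the inverse REML expected information. On a reference protein this
agrees with R's `lmerTest` to ~1e-6 in estimates/SE and a fraction of a
unit in df (cross-checked in the test suite by calling `Rscript`).

Degenerate fits fall down a fixed ladder: optimizer failure or
non-finite estimates drop the donor intercept (`reduced`), then fall
back to fixed-effects least squares with peptide as a covariate
(`ols_fallback`). Two-peptide proteins land there regularly; it is part
of the method. Boundary REML solutions (variance components estimated at
zero) are accepted as valid fits rather than demoted — the optimizer's
success flag alone is not treated as ground truth. Data that the
saturated fixed-effects model fits exactly (residual variance ≈ 0) are
answered by that exact fit directly, with the convention p = 1 when the
estimated contrast is 0 and SE is 0 (no evidence against the null, no
NaN propagation). Proteins observed in fewer than two conditions, or
without baseline observations, are excluded with a logged reason; one
protein's failure never aborts the batch.

Benjamini-Hochberg q-values are computed per contrast across proteins
and reported **alongside** raw p. The default significance rule is raw
p < 0.05 with |log2FC| ≥ 1.5 (inclusive ≥; a strict-mode switch exists),
and `use_absolute=False` restricts to upregulated proteins for
membership lists. The default uses raw p because that is the rule the
supported study design applies; q is there for users who want the
modern default.

## Preranked GSEA

Proteins are ranked by estimated log2FC, ties broken on id so the
ranking is deterministic. The enrichment score is the classic weighted
running sum (weight exponent 1 by default): hits add
|score|^w / Σ_set |score|^w, misses subtract 1/(N − N_set); ES is the
running-sum value of maximal absolute deviation, with exact magnitude
ties resolved toward the positive deviation. The single-set path and the
vectorized permutation path share one ES implementation, so they agree
bitwise; gseapy's prerank ES matches to < 1e-6 on tie-free lists
(cross-checked in tests).

The null is gene-label permutation: each of n_perm (default 1000)
iterations draws one relabeling shared by all sets. NES divides ES by
the mean |ES| of same-sign permutations; p is the same-sign tail
frequency with add-one smoothing; FDR is the standard ratio of permuted
to observed NES tail fractions, clipped to [0, 1]. Sets with fewer than
`min_set_size` (default 10) members in the ranked list are skipped with
a reason. For tiny lists an exact mode enumerates all C(N, k) member
placements instead of sampling. Everything is deterministic given the
seed.

GO-term results on real data depend on the gene-set snapshot supplied by
the caller (GMT input); the package neither downloads nor versions
ontologies, so published NES/FDR values for specific GO terms are not
reproduction targets — the GSEA stage is instead validated by exact
enumeration, null calibration (fraction of uniform sets with p < 0.05 ≈
0.05), and planted-set recovery.

## Set analysis and categories

Upregulated sets per condition feed an exact Venn decomposition (2^k − 1
disjoint cells whose union is conserved — asserted against brute force),
pairwise overlap counts derived two independent ways, a protein →
condition-membership listing, and category composition over the six-way
secretome classification (ECM, anabolic, catabolic, growth factor,
immune system, other). Category assignment is input data: annotations
are version-dependent, so no annotation source is bundled or downloaded.
The packaged reference table of upregulated MSC secretome proteins
(`secretoscope/data/msc_secretome_upregulated.tsv`) carries gene id,
UniProt accession, and the conditions each protein was upregulated in;
pairwise overlaps derived from its row-level memberships are the
acceptance anchor for the set algebra.

## Companion assays

Immunoassay concentrations are normalized per sample to DNA content,
then expressed per donor as fold change vs that donor's baseline.
Undetected values are excluded, never zero-imputed; a donor without a
detected baseline is excluded for that analyte, and an analyte
undetected in ≥ 90% of samples (configurable) is dropped entirely. LDH
cytotoxicity is 100·(sample − neg)/(pos − neg), anchoring the negative
control at 0% and the lysed positive control at 100%; it is affine
invariant by construction. Group comparisons are gated on normality:
each group is screened with D'Agostino-Pearson (needs n ≥ 8),
Shapiro-Wilk (n ≥ 3), and Lilliefors (n ≥ 4) at α = 0.05. The default
gate is the strictest combination — any rejecting test in any group
routes to Kruskal-Wallis, otherwise one-way ANOVA — because the three
tests come without a stated combination rule; `gate='all'` relaxes it.
Under a Gaussian null the gated procedure's type-I error stays near
nominal (asserted at 500 replicates).

## Synthetic-data generator

Peptide log2 intensities are additive: protein base abundance
(log-uniform over ~5 log2 units, default [22, 27], so the occupancy
filter sees a realistic dynamic range) + peptide offset (SD 1.0) + donor
effect (SD 0.3, drawn once per donor and shared across conditions) +
batch shift (+0.5 for batch 2) + the true condition effect + Gaussian
noise (SD 0.4). Missingness combines MCAR (default rate 0.05) and MNAR
dropout whose probability is logistic-decreasing in intensity (slope 0.8
per log2 unit, midpoint at the 2.5% quantile of the clean intensities),
together yielding roughly 8-12% missing cells — chosen once as typical
for peptide-level LFQ. Identical configs (including seed) produce
identical tables. Gene sets are drawn over the simulated proteins, with
planted sets sampled from the pool with the requested effect sign.
Immunoassay concentrations scale with the per-sample DNA content, so DNA
normalization cancels exactly and the noise-free fold change equals the
condition multiplier.

What the generator does **not** emulate: correlated peptide noise within
a run, retention-time or charge-state structure, interference/co-elution,
razor-peptide ambiguity, or heavy-tailed contamination. Passing tests
therefore demonstrate correctness of the statistical machinery under the
model's own assumptions, not robustness to every artifact of real
LC-MS/MS data.

## Calibration studies (problem sizes and choices)

- **Type-I error**: one all-null simulation at the full design defaults
  (500 proteins, 12 donors, 2 batches, default noise and missingness),
  run through the complete pipeline including normalization; the
  per-protein, per-contrast rejection rate at α = 0.05 is required to
  sit in [0.03, 0.08].
- **Recovery**: 200 protein replicates at true effects
  {−2, −1, 0, +1, +2} (40 each) within one study design, uniform 4
  peptides per protein and a sign-balanced grid so condition and
  baseline samples are exchangeable up to the planted effects. This
  study isolates the estimator: normalization is not applied (the
  generator plants no loading differences, and dense ±2 effects would
  feed the z-score a spread structure that violates its assumption — see
  the normalization limitation above), and dropout is MCAR-only, since
  intensity-dependent dropout censors the signal itself and is covered
  by its own monotonicity tests. Requirements: |bias| < 0.05 per effect
  and pooled, ±2·SE coverage ≥ 90%.
- **GSEA null calibration**: 200 uniform sets of 20 over a 500-gene
  noise ranking at 1000 permutations; fraction with p < 0.05 in
  [0.03, 0.07].
- **Planted-set recovery**: 50 seeds; per seed a 150-gene ranking built
  from truth (+2 effects for 40 genes) plus estimation noise (SD 0.3,
  the typical fitted SE scale), 3 planted and 17 uniform sets, 200
  permutations; a seed succeeds when every planted set's NES exceeds the
  mean uniform NES; ≥ 90% of seeds must succeed.

These sizes keep the full suite and the acceptance script within a few
minutes on one CPU while leaving the binomial tolerance bands
meaningful.

## Numerical conventions

- Intensity 0 on input means "not observed" and becomes missing; raw
  intensities must otherwise be positive.
- All randomness flows through `numpy.random.default_rng` seeds;
  per-stage seeds in the pipeline derive from the root seed via CRC32 of
  the stage label (stable across processes).
- Ranked-list and output orderings use stable sorts with id tie-breaks;
  re-running a pipeline with identical inputs and seeds reproduces
  byte-identical TSVs, and the results bundle records a config hash
  (excluding the output directory), the seed, and library versions.
- ES magnitude ties (positive vs negative deviation equal to float
  precision) resolve to the positive side everywhere.
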