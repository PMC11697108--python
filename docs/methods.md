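# Methods

This note records the statistical models, decision rules, parameter defaults
and numerical choices implemented in `symbiotrans`, and the known limits of
the synthetic data generators used to validate them.

## 1. Consensus transporter catalog (`catalog.py`)

Annotation hits from multiple sources are merged per protein, keeping the best
E-value per (protein, source, accession). A protein is flagged:

- **transporter** when any annotation matches a transporter keyword:
  carrier, transport, channel, permease, symporter, exchanger, antiporter,
  periplasmic, facilitator;
- **sugar transporter** when it is a transporter (or hits a core sugar Pfam)
  *and* matches a sugar keyword (disaccahride, carbohydrate, sugar, ose,
  saccharide, glucose, polysaccharide) or hits one of the eight core sugar
  Pfam families PF00083, PF03083, PF03151, PF04142, PF07690, PF00230,
  PF13347, PF00474. The "disaccahride" spelling is kept deliberately: it
  matches the misspelling that occurs in common annotation databases.

Keyword matching is token-based by default (`keyword_token_mode=True`): a
keyword matches when it is a substring of an alphanumeric token of the
lower-cased description, except `ose`, which must be a suffix of a token at
least four letters long (so "glucose" and "hexose" match but "close" and
"ose" alone do not match spurious contexts like "dose" only as designed).
A bare-substring mode is provided for comparison; token mode is the default
because bare substrings flag decoys such as "DNA transposase"-adjacent text
via accidental overlaps.

**Transmembrane consensus.** With TM-domain counts n₁, n₂ from two
predictors, a protein passes iff min(n₁, n₂) ≥ `tm_min` (default 2) and
|n₁ − n₂| ≤ `tm_diff_max` (default 2). The rule is symmetric in the tools;
missing predictions fail.

**Subfamily assignment.** Only members of the sugar-porter parent families
PF00083 and PF07690 receive a subfamily. The best subfamily HMM hit with
E ≤ `subfamily_evalue` (default 10⁻²³) wins; exact E-value ties break
lexicographically on the accession for determinism. Labels: IPR002439 → GLUT,
IPR044775 → ERD6/Tret1, IPR045262 → STP/PLT, IPR044740 → SLC37.

**Localization consensus.** Five predictors vote after their raw labels are
harmonized through a compartment map (`data/compartments.yaml`). A compartment
is assigned on a strict plurality with ≥ 2 votes. When the Deeploc-role tool
is among the winning voters its score must exceed `deeploc_min` (default 0.5);
with `deeploc_strict_and=True` Deeploc must itself vote for the winner with a
passing score. Ties between top compartments give `unassigned`. Unmapped raw
labels raise rather than silently dropping votes.

## 2. Differential expression (`de.py`)

**Size factors** are DESeq-style median-of-ratios: with geometric-mean
reference rᵍ over genes positive in all samples, sample j's factor is
median_g(c_gj / r_g), computed in log space. Factors are defined only up to a
global constant (the reference itself rescales with the data), so invariance
properties are stated on factor *ratios*. The implementation matches the
pydeseq2 reimplementation of DESeq2 at rtol 10⁻¹⁰ (cross-checked in tests).

**Quantile normalization** maps each column's order statistics onto the
vector of row means of the column-sorted matrix. Ties share the mean of their
tied target slots (run-based averaging). Idempotence holds exactly only for
tie-free input: the tie rule feeds averaged values back into the target on a
second pass (reference implementations such as preprocessCore behave the same
way).

**Dispersion.** Per condition, the method-of-moments estimate
α̂ = (s² − μ)/μ² is pooled across conditions with df-weights and floored at
`dispersion_floor` = 10⁻⁸. No empirical-Bayes shrinkage is applied.

**Wald test.** For conditions a, b with normalized means μ̂_a, μ̂_b computed
with pseudocount 0.5, the statistic is log2FC / SE with the delta-method
variance Var(log μ_c) ≈ (1/μ_c + α̂)/n_c, summed over the two conditions and
converted to log2. No fold-change shrinkage is applied; acceptance is judged
on parameter recovery and calibration (type-I error at p < 0.05 measured at
0.056 on 2000 null genes at 9 vs 17 replicates), not on equality with any
particular reference tool. P-values are BH-adjusted
(`statsmodels.stats.multitest`, NaNs propagate).

**Classification.** A gene is *expressed* in a condition when its replicate
sum strictly exceeds `expressed_threshold` (default 10). Genes expressed in
both conditions are up/down when |log2FC| ≥ `lfc_min` (default 2) and
Padj < `alpha` (default 0.05), else neutral; genes expressed in exactly one
condition are exclusive to it; the rest are not expressed.

## 3. Housekeeping ratios (`metaratio.py`)

TPM tables are compositional: each sample is closed to 10⁶, so abundance
changes of unrelated community members distort every gene and induce spurious
correlations. Normalization divides by the geometric mean of housekeeping
genes selected by four sequential criteria:

1. **Detection**: keep samples where ≥ `min_detect` (default 20%) of the
   reference transcriptome is detected (TPM > 0); keep genes detected in all
   retained samples.
2. **Stability**: CV (percent) < `cv_max` (default 200) and two-sided fold
   change from the mean, max(x/mean, mean/x), < `fc_max` (default 2) in every
   sample.
3. **Annotation**: a housekeeping-style annotation (ribosomal protein,
   tubulin, actin, ATP synthase, elongation factor, histone, ubiquitin, ...).
4. **Co-expression**: k-means (k = `k`, default 8; standardized log1p
   profiles; fixed seed, 10 restarts) and, within the cluster holding the
   most members of mean pairwise Pearson r > `r_min` (default 0.5), keep
   exactly those members.

The ratio of a gene to the housekeeping geometric mean is computed as the
geometric mean of the per-gene quotients x/h, so a per-sample scale cancels
inside each quotient *before* any rounding. The ratio table is therefore
bitwise invariant under power-of-two per-sample rescaling (exact in IEEE 754)
and invariant to ~10⁻¹² relative error for arbitrary scales, where the one
rounding in the multiplication itself is the only source of difference.
Samples with any zero housekeeping TPM are dropped with a warning (the
geometric mean is undefined there).

Fraction comparison reports per-gene mean ratios in the small and large size
fractions and a strict `higher_in_large` flag. The flag is a bare mean
comparison by design — about half of null genes land on either side — so it
is a screening output, not a test.

## 4. Temporal dynamics (`temporal.py`)

All samples (morning, evening, dark-evening) are normalized jointly with a
single median-of-ratios fit. Venn classes use the strict rules: expressed in
a condition when the replicate sum > 10, exclusive to it when all other
conditions are < 10; a gene at exactly 10 elsewhere is expressed in one
condition but not exclusive, and keeps a single-condition non-exclusive
label. The dark response is the dark/evening ratio of pseudocounted (0.5)
means: down when ≤ 1/`fc_cut_dark`, up when ≥ `fc_cut_dark` (default 2).
Per-Pfam modulation applies Wilcoxon rank-sum tests on per-gene condition
means (evening vs dark for light response, morning vs evening for
time-of-day), requiring ≥ 3 genes per family; classes are light /
period_of_day / both / neither / untested.

## 5. Synthetic data generators (`synthetic.py`)

All generators draw from `numpy.random.Generator` streams fanned out from a
single seed via `SeedSequence(entropy=seed, spawn_key=(stream,))`, so stages
are independently reproducible and the whole pipeline is deterministic per
seed.

- **Annotations**: template descriptions for transporters, sugar transporters
  (sugar keyword plus a core Pfam hit) and decoys, including near-miss decoys
  ("DNA transposase", "transcription factor bZIP") that token-mode keyword
  matching must reject.
- **TM counts**: transporters draw 2 + Poisson(6) domains, others
  Poisson(0.5); the second tool adds rounded N(0, `disagreement_sd`) noise.
- **Counts**: NB with mean 2^U(3, 10), planted signed log2 fold changes on a
  `frac_de` subset, per-sample library-size factors U(0.5, 2), variance
  μ + αμ².
- **Metatranscriptome**: planted stable genes (log-normal sd `hk_sigma`
  = 0.05) with housekeeping annotations plus annotated decoys with variable
  profiles; planted fraction-enriched genes (×2^`enrich_lfc`, large fraction
  only); and a compositional "bloom" — a gene subset holding `bloom_share` of
  the baseline column total, inflated by a per-sample factor before each
  column is re-closed to 10⁶. Defaults (`bloom_share` = 0.1,
  `compositional_factor` ~ log-U[1, 8], `var_sigma` = 1.0) give a realistic,
  modest closure artifact. Validation of the spurious-correlation property
  uses a deliberately strong, low-noise regime (`bloom_share` = 0.5,
  `var_sigma` = 0.4, factors geomspaced over [1, 3], 12 samples per fraction,
  full detection) because at default noise the closure signal is small
  relative to sampling noise at ~14 samples; the stronger regime makes the
  reduction detectable on every seed without weakening the pipeline defaults.

**Realism limits.** Annotations are drawn from short template lists, not real
database output; TM counts ignore topology; counts share one dispersion;
TPM profiles are log-normal without taxonomic structure; the bloom is a
single co-inflated block rather than a community. These are sufficient for
planted-truth recovery and calibration, not for benchmarking against real
datasets.

## 6. Numerical and reporting choices

- Percentages are rounded half-up (`decimal.ROUND_HALF_UP`), not banker's
  rounding, at the reported precision; every reported percentage carries its
  numerator and denominator so it can be recomputed from the report alone.
- All report JSON is written with sorted keys and no timestamps, so identical
  config + seed gives byte-identical reports.
- Count matrices are validated as non-negative integers on read; TPM matrices
  as non-negative reals; ragged rows and missing cells are errors rather than
  NaN fills.

## 7. Limitations

- The Wald SE ignores uncertainty in α̂ and the size factors; with few
  replicates the test is mildly anti-conservative at extreme means (observed
  type-I error 0.056 at nominal 0.05).
- Housekeeping selection optimizes precision, not recall: the co-expression
  criterion keeps one cluster, so typically ~20–60% of planted stable genes
  are returned. Ratios need a correct denominator, not a complete one.
- `higher_in_large` is a descriptive flag without error control.
- Subfamily assignment covers only the four sugar-porter subfamilies listed
  above; other members of PF00083/PF07690 remain unlabeled.
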