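# Methods

## The linear predictor

Predicted expression of gene *s* is `Y_s = Σ_k w_{k,s} X_k`: the dosage
`X_k ∈ [0, 2]` counts copies of the model's **effect allele**.  Published
descriptions of this class of predictor sometimes speak of "minor alleles";
we follow the effect-allele convention of the trained weight tables, since
the two differ only when the effect allele happens to be the major allele,
and we make no attempt at frequency-based re-polarization.  Matching between
model, frequency table and dosage file is exact string equality on
`chr_pos_ref_alt_build` tokens — no strand flipping, liftover or rsID
mapping, which keeps the arithmetic auditable and pushes harmonization to
upstream tools where it belongs.

Model variants absent from a genotype file are, under the default
`wild_type_zero` policy, treated as homozygous reference and contribute
`weight × 0` to the sum; the `error` policy aborts with the complete list of
missing ids.  Duplicate (gene, variant) records in a model file are an
error, never merged: silent aggregation would corrupt the sum.

The rank-based inverse normal transform uses the Blom offset,
`Φ⁻¹((rank − 3/8)/(n + 1/4))` with average ranks for ties — the standard
choice in expression-QTL normalization.  Constant input is rejected
(degenerate ranks), as is n < 2.

## Differentiation test

The per-variant test is the pooled two-proportion chi-square with 1 df and
no continuity correction:
`χ² = (p₁ − p₂)² / (p̄(1 − p̄)(1/AN₁ + 1/AN₂))` with `p̄` the pooled
frequency, p-value from the χ²₁ survival function.  At biobank-scale allele
numbers (AN ~ 10⁴–10⁵) the continuity correction is negligible, and the
closed form is verified in the tests against an independent hand-computed
z² oracle.  A degenerate pooled frequency (0 or 1) yields χ² = 0, p = 1.

A variant is called *population differentiated* when `p < 5e-8` **and**
`|AF₁ − AF₂| > 0.05`, both strict — a gap of exactly 0.05 is not flagged
regardless of p.  Variants lacking allele information in either population
are excluded and counted rather than tested.  The test needs counts: when a
record carries AF and AN but no AC we reconstruct `AC = round(AF·AN)`;
AF alone (no AN) is excluded.

## Simulation grid

|Weight| values are pooled over every weight row of every tissue model
(absolute value so positive and negative effects do not cancel; no
deduplication), stably sorted, and cut into five contiguous segments whose
sizes differ by at most one (remainder r goes to the first r segments —
verified exhaustively for small pools).  Segments 1, 3, 5 are the low,
medium and high weight levels.

The grid crosses 4 variant counts (1, 30, 200, 430 — the published minimum,
average, large and maximum per-gene counts of the tissue models) × 5 MAFs
(0.05 + 0.1·i, generated by index to avoid floating-point drift) × 9
differentiated proportions (0.05·i, i = 0..8) × 3 weight levels = 540
scenarios.  Per scenario, `n_diff = round(prop × n_variants)` (half-up,
reproducing the 30 × 0.1 → 3 worked case) variants draw weights uniformly
with replacement from the chosen level and the rest from the low level;
weights are drawn **once** and held fixed while dosages are redrawn
Binomial(2, MAF) for each of the 500 repetitions.  With one variant, every
proportion ≤ 0.4 rounds to n_diff = 0; such scenarios are flagged
`degenerate` and coincide with the baseline.  Scenario seeds derive from
`SeedSequence([master_seed, scenario_index])`, so each scenario is
independently reproducible and the full grid is bit-identical under a fixed
master seed.  Summaries report each scenario's mean, its difference from,
and its ratio to, the zero-proportion baseline of its (n_variants, MAF,
level) stratum; the ratio is withheld when the baseline mean is below 1e-12
in magnitude.

We deliberately do not target the published peak mean differences
(0.74/4.95/11.5, ~30× ratio): those numbers depend on the real tissue
weight pools, which are external data.  The tests instead assert the
structural claims — distributional separation (KS D > 0.5 between the 0.4-
and 0.0-proportion scenarios at 200 variants, MAF 0.45, high level) and
mean ordering high > medium > low.

## Reference panel

Each repetition is one pseudo-individual drawn under Hardy–Weinberg from
the population's allele frequencies, variants independent (no LD — the
procedure uses only marginal AFs).  The panel stores all n_reps = 500 draws
per gene plus mean, sample SD (n−1) and the count of frequency-matched
variants.  Model variants without a frequency record are dropped and
counted; genes losing every variant are omitted and counted.  Draws for
different populations use independent streams (pairing them would only
reduce the variance of a contrast the method never forms).

Kolmogorov–Smirnov comparisons use the asymptotic two-sample p-value
(n = 500 per side makes exact computation unnecessary).  Three significance
conventions coexist, selected by call/config because they serve different
questions: fixed 5e-8 for per-gene population differences in evaluation
reports, Bonferroni 1/m for the dataset-level survey, and 0.05/m for the
stability check (at a 7252-gene tissue that is 6.89E-06 to 3 s.f.).  The
stability null — a 500-rep vs a 2000-rep panel from the same generator
showing zero Bonferroni-significant genes — is a family-wise-error-0.05
event, i.e. it holds with probability ≥ 95 % per run, which is what the
seeded tests pin down.

## Evaluation

Percentile rank is the counting definition with inclusive ties,
`100 × #{reference ≤ value}/n`, giving the 100/n granularity (multiples of
0.2 at n = 500) seen in published report screenshots.  Whether the original
implementation used strict `<` was not determinable; inclusive `≤` is our
choice.  The "confidence interval" of a gene is the empirical central
interval of its reference draws (linear-interpolation quantiles, closed at
both ends, level 0.95 by default) — no normality assumption.  Because the
draws are discrete sums, closed endpoints make same-population coverage
land slightly **above** the nominal level (≈ 0.96 at 0.95); the calibration
test's 0.95 ± 0.03 band reflects that.

The subject-level report shows the population-level percent mean difference
`(mean_A − mean_B)/|mean_B| × 100` (absent when |mean_B| < 1e-12) next to
each gene's Sig./Nonsig. flag, and additionally a subject-level deviation
column `value − ref_mean`, since the two readings of "mean difference" are
both useful.  Ranks and ratios are printed at 4 decimals; full precision is
retained in memory.

## Synthetic data

The generator's defaults emulate the published model-shape regime:
per-gene variant counts log-uniform with mean ≈ 30 (upper end 150 chosen so
the law's mean `(u−1)/ln u` lands at 30; counts clamped to [1, 430]),
signed weights Laplace(0, 0.02) — zero-centered and heavy-tailed, with |w|
quintile boundaries of the same order of magnitude as published weight-level
thresholds but not calibrated to them.  Population-1 AFs are
Uniform(0.05, 0.5); an exact `round(f·n)` subset of variants gets
population-2 AF shifted by ±δ (clamped to [0.001, 0.999]); allele counts
are Binomial(AN, AF) with AN = 20 000 per population so tables carry
realistic sampling noise; cohort fixtures default to 61 subjects.

What passing tests therefore show: the pipeline's arithmetic, its
calibration under its own generative assumptions (independent
Hardy–Weinberg dosages), and recovery of constructed differentiation.  What
they cannot show: behavior under LD, realistic site-frequency spectra, or
tissue-sharing of effects — none of which the reference-panel procedure
models either.

## Problem sizes and numerical choices

The default acceptance run uses 1000 genes for the stability null, 1000
subjects × 100 genes for calibration, 1000+ variants per recovery setting,
and the full 540-scenario × 500-rep grid; all complete in seconds on one
CPU.  Matrix TSVs are written at full float precision (`repr`) so
round-trips are exact; panel files store every draw.  Mean/SD of a panel
row are recomputable from its stored values to 1e-9.
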