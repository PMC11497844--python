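# popexpress

Population-diversity toolkit for linear TWAS expression predictors.

Transcriptome-wide association studies impute a gene's expression from
genotypes as a weighted sum of cis-variant dosages,

    Y_s = Σ_k  w_{k,s} · X_k ,

where `w_{k,s}` is the trained weight of variant *k* for gene *s* (a
PredictDB-style elastic-net model) and `X_k` is the subject's dosage (0–2
copies of the effect allele).  Because these weights are trained almost
exclusively on European-ancestry reference cohorts, predictions for
subjects of other ancestries — East Asian in the motivating use case — are
shifted wherever variant allele frequencies differ between populations.

`popexpress` quantifies and works around that shift for users of
PrediXcan-style predictors:

* **simulate** — a four-parameter simulation grid (number of variants, MAF,
  proportion of population-differentiated variants, weight level of those
  variants) measuring how much each factor moves predicted expression
  relative to a no-differentiation baseline, using weight levels derived by
  pooling |weight| across tissue models into quintile segments.
* **popdiff** — a genome-wide per-variant differentiation test: pooled
  two-proportion chi-square (1 df) on gnomAD-style AC/AN tables; a variant
  is *population differentiated* when p < 5×10⁻⁸ and |ΔAF| > 0.05 (both
  strict).
* **reference** — an allele-frequency-driven empirical reference panel:
  for each of 500 repetitions every model variant gets a Hardy–Weinberg
  dosage ~ Binomial(2, AF_pop), giving each gene an empirical distribution
  of predicted expression (mean, SD, variant count) for that population,
  no individual genotypes required.  Panels from two populations are
  compared gene-by-gene with two-sample Kolmogorov–Smirnov tests; the same
  machinery checks panel stability across repetition counts.
* **evaluate** — scores user predictions against a panel: percentile rank
  of each predicted value among the 500 reference draws, per-gene
  Sig./Nonsig. population-difference flags with percent mean differences,
  and a dataset-level per-gene summary (empirical 95 % interval coverage,
  SNP-availability ratios).
* **engine / model_io / synthetic** — the linear predictor itself (with
  wild-type substitution of unobserved model variants and a rank-based
  inverse normal transform), bit-stable TSV/SQLite readers and writers, and
  a synthetic-data generator with controlled population structure so the
  whole pipeline is testable without external downloads.

## Worked example

```python
from popexpress import synthetic, simulate, reference, popdiff, evaluate

cfg = synthetic.SyntheticConfig(n_tissues=2, n_genes=30, diff_fraction=0.5,
                                delta_af=0.15, n_subjects=61, seed=7)
models = synthetic.make_models(cfg)
freq = synthetic.make_frequencies(models, cfg)

calls = popdiff.classify_differentiated(freq)
pool = simulate.build_weight_pool(models)
eas = reference.build_reference(models[0], freq, "pop1", n_reps=500, seed=1)
nfe = reference.build_reference(models[0], freq, "pop2", n_reps=500, seed=2)
comp = reference.compare_populations(eas, nfe)

geno = synthetic.make_genotypes(freq, "pop1", cfg.n_subjects, seed=3)
pred = synthetic.make_predictions(models[0], geno)
rows, unmatched = evaluate.make_report(pred, eas, comp)

print(f"differentiated: {calls.n_differentiated}/{calls.n_tested} "
      f"({calls.fraction:.1%}), excluded: {calls.n_excluded}")
print("weight-level bounds:",
      {k: tuple(round(x, 4) for x in v) for k, v in pool.group_bounds().items()})
print(f"genes with significant population difference: "
      f"{comp.n_significant}/{len(comp.table)} at p < {comp.threshold:g}")
r = rows[0]
print(f"{r.family_id} {r.individual_id} {r.gene_id}: value={r.predicted_value:.3f} "
      f"rank={r.percentile_rank:.1f} ref_mean={r.ref_mean:.3f} "
      f"ref_sd={r.ref_sd:.3f} {r.pop_diff_flag} mean_diff_pct={r.mean_diff_pct:.1f}")
```

prints:

```
differentiated: 838/1681 (49.9%), excluded: 0
weight-level bounds: {'low': (0.0, 0.0046), 'medium': (0.0102, 0.0186), 'high': (0.0331, 0.1333)}
genes with significant population difference: 11/30 at p < 5e-08
F1 S1 gene_0001: value=0.127 rank=98.8 ref_mean=-0.045 ref_sd=0.080 Sig. mean_diff_pct=45.9
```

Half the synthetic variants were built with a 0.15 allele-frequency gap and
the differentiation test recovers 49.9 % of them; 11 of 30 genes show
significantly different expression distributions between the two
populations' panels; the first subject's first gene sits at percentile rank
98.8 of the population-1 reference (unusually high for that population),
and that gene's population-1 panel mean is 45.9 % above the population-2
mean.

The same workflow is available from the shell:

```sh
popexpress synth --config cfg.yaml --out-dir fixtures/
popexpress diff-test --freq fixtures/frequencies.tsv --out calls.tsv
popexpress build-ref --model fixtures/model_tissue_1.tsv \
    --freq fixtures/frequencies.tsv --population pop1 --out panel.tsv
popexpress evaluate --pred fixtures/predictions_pop1.tsv \
    --panel panel.tsv --out report.tsv
```

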