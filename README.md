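# dfctest

Distributional fold change (DFC) testing for two-class expression data
(bulk or single-cell, log2 scale). Instead of judging each feature in
isolation, the DFC test estimates the null distribution of the log fold
change — its scale `sigma0(mu)` and the total-variance threshold
`LV_Th(mu)` — *as a function of average expression* from the whole feature
population, then:

* scores every feature with a signal-to-noise statistic
  `Z_d = (d - d0(mu)) / sqrt(v_s(d) + sigma0(mu)^2)` (between a normal Z
  and a t statistic) and ranks by `|Z_d|`;
* selects features whose `|logFC|` clears an expression-dependent
  significance threshold `delta1 = sigma0(mu) * Phi^-1(1 - alpha/2)` plus a
  power threshold `delta2 = s * T^-1(1 - beta_th, df)`, optionally
  intersected with the variance filter `LV > LV_Th(mu)`;
* reports per-feature conditional Type II error and the expression-dependent
  p-value bound every selected feature satisfies.

The package also ships the evaluation machinery used to benchmark rankers
(ROC with exact tie handling, AUC = Mann–Whitney probability, standardized
partial AUC, Youden index, paired AUC comparisons on logit-transformed
values), a Welch t / `|d|` baseline pair, and a seeded synthetic-data
generator with expression-dependent variance trends and FFPE-style
fold-change compression.

## CLI

```sh
# simulate a two-class dataset (TSV matrix + truth sidecar)
dfc simulate --n-features 5000 --pi 0.02 --profile mas5 --seed 1 --outdir sim/

# run the DFC test; writes results.tsv, null_model.tsv, null_model_bins.tsv,
# run_metadata.json
dfc run --input sim/expression.tsv --alpha 0.05 --beta 0.2 --outdir out/

# label assignment: inline or two-column TSV (defaults to A*/B* prefixes)
dfc run --input expr.tsv --labels 1,1,1,2,2,2 --outdir out/
dfc run --input raw.tsv --log2 --floor 1 --labels labels.tsv --outdir out/

# evaluate any score vector against truth flags (ROC/AUC/SPA/Youden)
dfc evaluate --scores scores.tsv --truth sim/truth.tsv --outdir eval/

# paired AUC comparison across datasets, plus cross-condition
# logit-AUC correlations
dfc compare --aucs mas5_aucs.tsv --reference dfc --correlate-with rma_aucs.tsv \
    --outdir cmp/
```

Exit codes: 0 success, 1 user error (bad input/parameters), 2 internal
error. For ranking/ROC work use `--alpha 1.0 --beta 0.5
--no-variance-filter` so every feature stays in the list.

## Library

```python
import dfctest as dfc

dataset, truth = dfc.generate_dataset(dfc.SimulationConfig(seed=1))
summ = dfc.summarize_features(dataset)
model = dfc.estimate_null_model(summ)
result = dfc.select_and_rank(summ, model, dfc.DfcParameters(alpha=0.05, beta_th=0.2))
table = result.to_frame(summ)  # feature_id, d, z_score, p_value, rank, ...
```

Module map: `core_stats` (per-feature summaries, stabilized variances, the
score), `null_model` (binned/smoothed `LV_Th`, `sigma0`, `d0` curves),
`selection` (thresholds, selection rule, ranking), `evaluation`
(ROC/AUC/SPA/Youden, paired comparisons), `baselines` (Welch t, `|d|`),
`synthetic` (seeded generator, variance profiles), `benchmarks` (packaged
reference tables), `io`/`cli`.

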