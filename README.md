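# radpool

Patient-level pooling of per-lesion radiomic features, and survival
benchmarking of the pooling rules, for cohorts with multifocal cancer.

## The problem

Radiomic features — quantitative size, shape, intensity and texture
descriptors extracted from medical images — are computed **per tumor**, but
prognosis is a **per patient** question. When a patient carries many lesions
(most patients with brain metastases do), some rule must combine the
per-lesion feature vectors into one patient-level vector before a survival
model can use them. `radpool` implements and benchmarks six such rules:

| label | rule |
|---|---|
| `unweighted_average` | additive features summed, intensive features averaged over all lesions |
| `weighted_average` | intensive features averaged with weights w_i = v_i / Σ_j v_j (lesion volumes v) |
| `weighted_top_k` | same, restricted to the k largest lesions (default k = 3) |
| `largest_plus_count` | largest lesion's features plus the lesion count as an extra covariate |
| `largest_only` | largest lesion's features |
| `smallest_only` | smallest lesion's features (negative control) |

"Additive" features (size/shape) scale with tumor burden and are summed;
"intensive" features (intensity/texture) describe tumor quality and are
averaged. The feature schema carries this classification.

Downstream, each patient-level matrix is reduced (top-20 greedy
minimum-redundancy-maximum-relevance features by default; PCA at 90%
retained variance or no reduction as alternatives) and fed to three survival
models — Cox proportional hazards (Efron ties), LASSO-penalized Cox, and a
random survival forest — whose discrimination is measured by Harrell's
concordance index

C = Σ_{(i,j): t_i < t_j, δ_i = 1} [ 1(r_i > r_j) + ½·1(r_i = r_j) ] / #pairs,

over censoring-comparable pairs (pairs with tied observed times are not
comparable), with a bootstrap of repeated 50% subsampling: fit on the
subsample, score the held-out half, summarize 100 replicate C values by
their mean and 2.5/97.5 percentiles. Sub-group analyses repeat the
comparison within metastasis-count bins (<5, 5–10, 11+) and largest-lesion
volume bins (<0.200, 0.200–0.700, >0.700 cc).

Because clinical imaging cohorts of this kind are private, the package
ships a synthetic-cohort generator (`radpool.synthetic`) that reproduces
the structure such an analysis assumes — multifocal patients in realistic
count strata, log-normal lesion volumes, block-correlated volume-coupled
features, Weibull proportional-hazards survival with ~31% right-censoring —
with the ground-truth risk driven by a configurable aggregation rule, so
every stage is testable end to end.

## Worked example

```python
import radpool as rp

cohort = rp.simulate_cohort(rp.GeneratorConfig(n_patients=1000, seed=2026))
plan = rp.AnalysisPlan(models=("cox",), n_replicates=100, seed=1)
table = rp.run_comparison(cohort, plan)
print(table[["aggregation", "mean_c", "ci_low", "ci_high"]].to_string(index=False))
```

prints

```
       aggregation   mean_c   ci_low  ci_high
unweighted_average 0.601357 0.576885 0.627877
  weighted_average 0.637860 0.617385 0.664914
    weighted_top_k 0.641385 0.621078 0.662397
largest_plus_count 0.627249 0.604787 0.653796
      largest_only 0.626779 0.603896 0.651659
     smallest_only 0.550959 0.529328 0.577351
```

Each row is one aggregation method benchmarked with the Cox model: the mean
held-out concordance over 100 bootstrap subsamples and its percentile
interval. This cohort's true risk was generated from the volume-weighted
average of the three largest lesions, and that method indeed attains the
highest mean C (0.641); the smallest-lesion control trails far behind
(0.551), and methods that ignore multifocality entirely (largest-only,
unweighted average) sit in between — the qualitative pattern this kind of
analysis is designed to detect.

The same pipeline is scriptable from the shell:

```bash
radpool simulate --n-patients 831 --seed 11 --out-dir cohort/
radpool summarize --tumors cohort/tumors.csv --outcomes cohort/outcomes.csv --schema cohort/schema.csv
radpool benchmark --tumors cohort/tumors.csv --outcomes cohort/outcomes.csv \
    --schema cohort/schema.csv --seed 1 --out results.csv
```

(`subgroup`, `sensitivity`, `aggregate` and `select` subcommands cover the
remaining analyses.)

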