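# Methods

## Aggregation model

A patient's lesions are feature vectors x_1 … x_m with volumes v_1 … v_m
(cc). Features are classified by the schema as *additive* (size/shape:
they grow with tumor burden) or *intensive* (intensity/texture: they
describe tumor quality). For an included lesion set S:

- additive feature f:  X_f = Σ_{i∈S} x_{i,f}  (unweighted sum over S);
- intensive feature f: X_f = Σ_{i∈S} w_i x_{i,f} with w_i = v_i / Σ_{j∈S} v_j
  (volume-share weights; the unweighted variant uses w_i = 1/|S|).

The six methods differ only in S and the weighting: all lesions
(unweighted or volume-weighted), the k largest by volume (volume-weighted;
patients with fewer than k lesions contribute all of theirs), or a single
extreme lesion (largest or smallest, the latter as a negative control),
optionally augmented with the lesion count as a separate covariate.
"Largest" means largest segmented volume; volume ties are broken by
lexicographic tumor id so every method is a deterministic, permutation-
invariant function of the lesion set. Dimensionless shape descriptors are
summed when the schema classes them additive — the schema is data, so a
physically-motivated reclassification is a one-line change for the caller.

## Feature selection

*mRMR.* Greedy forward selection. Relevance of feature f is |C(f) − 0.5|,
where C(f) is the concordance index of f used directly as a risk score
against the censored outcome — a censoring-aware association measure that
needs no discretization. Redundancy of f against the selected set is the
mean absolute Pearson correlation. Features are added by the difference
criterion (relevance − redundancy); the first pick maximizes relevance
alone; score ties keep the earliest column, so rankings are reproducible.
Zero-variance columns are excluded with a warning. By default selection is
fitted once on the full cohort ("global" scope); a per-replicate scope that
refits selection inside every bootstrap training split is available where
leakage-free estimates are wanted.

*PCA.* Columns are z-scored (correlation-matrix PCA) and the minimal number
of leading components whose explained-variance ratios sum to the retained
threshold (default 0.90) is kept; new data are standardized with the
training statistics and projected onto that basis.

A metastasis-count covariate, when present, bypasses both reducers and is
re-attached raw: it is a deliberate clinical addition, not a radiomic
feature, and models receive it unstandardized.

## Survival models and evaluation

- **cox** — Cox proportional hazards via lifelines, Efron approximation for
  tied event times (ties are guaranteed at month resolution). The design is
  z-scored with training-split statistics; a rank-deficient standardized
  design raises a *collinear* degeneracy flag instead of a coefficient
  estimate.
- **cox_lasso** — L1-penalized Cox via the scikit-survival coxnet path.
  The penalty is chosen from a log-spaced grid (default 20 points over
  [1e−3, 10]) by mean five-fold cross-validated concordance; ties prefer
  the stronger penalty.
- **rsf** — random survival forest (scikit-survival), hyperparameters
  (trees ∈ {200, 500}, minimum terminal node ∈ {5, 15}, features per split
  ∈ {√p, p/3} by default) chosen by the same CV; all tree randomness is
  seeded. The grids are configuration, not claims about optimality.

*Concordance.* Harrell's C over comparable pairs (t_i < t_j and patient i
died); risk ties score ½; pairs with tied observed times are not
comparable; an empty comparable set returns 0.5 with a warning. This tie
convention is pinned by the package's own implementation (library
implementations differ on tied times) and is verified in the tests against
exhaustive pair enumeration, and against lifelines on tie-free data where
the conventions coincide.

*Bootstrap.* Each replicate samples ⌊N/2⌋ patients without replacement as
a training set, fits the full model (including selection when per-replicate
scope is on), scores the held-out patients, and records their C. The cell
summary is the mean of valid replicates with the 2.5/97.5 percentile
interval of the replicate distribution (reported as such). An
evaluate-only mode (fit once, re-evaluate C per subsample) covers the
alternative reading of a subsampled evaluation protocol. Degenerate
replicates are recorded as missing; a cell with no valid replicate is
emitted as a flagged row with no numeric C. Within one comparison run,
every aggregation method is evaluated on the *same* replicate splits (the
subsampling seed depends only on the model), so method contrasts are
paired rather than confounded with resampling noise.

## Synthetic cohort generator

The generator emulates the structure of a multifocal brain-metastasis SRS
cohort; it is the package's test bed, not a claim about any real dataset.

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 831 | cohort size |
| `strata_probs` | 0.653 / 0.258 / 0.089 | share of patients with <5, 5–10, 11+ lesions |
| `strata_bounds`, `count_geom_p` | (1–4, 5–10, 11–30), 0.35 | zero-truncated geometric lesion count within the stratum's bounds |
| `volume_log_mean`, `volume_log_sd` | −1.9, 1.2 (log cc) | i.i.d. log-normal lesion volumes; chosen so the largest-lesion volume thirds near 0.2 and 0.7 cc are roughly balanced |
| `n_features`, `n_additive` | 48, 12 | feature count; additive = size+shape families |
| `block_rho` | 0.5 | within-family shared-factor loading (radiomic features are collinear; mRMR is pointless without redundancy) |
| `volume_coupling` | 0.4 | correlation strength between log-volume and every feature |
| `noise_sd` | 0.5 | per-lesion measurement noise |
| `informative_features`, `effect_vector` | 6 intensive features, ‖β‖ ≈ 0.93 | log-hazard effects applied to the patient-level aggregate |
| `true_aggregation`, `true_k` | `weighted_top_k`, 3 | rule generating the ground-truth linear predictor |
| `weibull_shape`, `weibull_scale` | 1.2, 16.3 mo | baseline with 12-month median survival at zero linear predictor |
| `followup_horizon` | 36 mo | administrative censoring horizon |
| `target_censored_fraction` | 0.31 | expected right-censored share |

Feature values per lesion are
x = c·z_vol + √(1−c²)·(√ρ·g_family + √(1−ρ)·ε) + σ_noise·η
with standardized log-volume z_vol, family factor g, and independent
Gaussians ε, η — so `volume_coupling = 0` makes features exactly
volume-independent, and families are equicorrelated blocks. The true
linear predictor is β applied to the configured aggregate, centered so the
Weibull baseline keeps its median; survival times follow the proportional-
hazards inverse-CDF transform. Censoring is the minimum of the horizon and,
with probability p, a Uniform(0, horizon) dropout time; because the
expected censored fraction is linear in p, the calibrating root is solved
in closed form from the simulated death times (clipped to [0,1] with a
warning when the target is unreachable — e.g. long horizons cannot produce
heavy censoring under a 12-month-median baseline, which is why the default
horizon is 36 months). All draws descend from one seed through
per-patient sub-streams, so cohorts are bit-reproducible.

What the generator does **not** emulate: scanner/segmentation effects,
non-proportional hazards, informative censoring, feature distributions
with realistic skew, the full ~850-feature radiomic catalogue (48
block-correlated features stand in for it), or clinical covariates. Tests
passing on these cohorts demonstrate that the pipeline's machinery is
correct and that its rankings recover a known ground truth — not that any
particular aggregation method is superior on real images.

## Numerical and design choices

- Patients with fewer than k lesions under `weighted_top_k` contribute all
  their lesions — the only consistent reading when most patients have <5.
- Half-open bins: counts [1,5), [5,11), [11,∞); largest-lesion volumes
  [0,0.2), [0.2,0.7), [0.7,∞) cc. Percentages round half-up to one decimal.
- Sub-group runs offset the parent seed by the bin index, re-run feature
  selection within each bin, and default to the Cox model.
- Constant columns are zeroed by the standardizer and caught by the rank
  check (Cox) or tolerated (penalized/forest models).
- Weights within an included lesion set always sum to 1 within 1e−12;
  intensive aggregates are convex combinations and stay inside the
  per-patient feature range.
- Scaled-down problem sizes are used for the shipped analyses: the
  six-method Cox benchmark runs at n = 1000 patients with 100 replicates,
  and the full 6×3 determinism check at n = 160 with reduced grids —
  byte-identity and ranking recovery are properties that do not require
  the full study size.

## Known limitations

- The mRMR estimator pair (concordance relevance, |Pearson| redundancy,
  difference criterion) is one deliberate instantiation of the mRMR family;
  ensemble and mutual-information variants would rank differently.
- Percentile intervals of subsampled C values understate uncertainty
  relative to proper bootstrap CIs of a single statistic; they are labeled
  as replicate-distribution percentiles, not inferential CIs.
- With mostly-unifocal cohorts the all-lesion and top-3 volume-weighted
  averages nearly coincide (small lesions carry little weight), so their
  ranking margin is intrinsically thin — a near-tie between them on any
  one synthetic cohort is expected behavior, not a pipeline defect.
- `smallest_only` sub-group cells are frequently flagged collinear in
  small bins; this mirrors how degenerate designs are reported rather than
  silently scored.
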