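# Methods

This note documents the statistical model behind `sleepphen`, the default
parameter values and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions adopted where the design
was genuinely open.

## 1. Data model

The unit of raw data is a *participant-night*: ten features — NREM, REM,
light-sleep and WASO durations in seconds, and min/avg/max nocturnal heart
rate (beats/min) and respiratory rate (breaths/min) — or a wholly missing
night. Two cohort roles exist: a small clinical cohort (PLWD — people living
with dementia or MCI) and a large general-population (GP) pool.

The unit of *analysis* is the per-participant, per-30-night-window median
10-vector. Medians over 30 nights suppress night-to-night variability and
outliers; four consecutive windows per participant capture stable individual
patterns while contributing longitudinal replicates.

## 2. Preprocessing rules

- **Windows**: half-open intervals `[start + i·30, start + (i+1)·30)` nights,
  i = 0…3. The anchor is the participant's first recorded night by default
  (`analysis_start_date` pins a calendar anchor instead; the original
  protocol used fixed calendar spans, which a synthetic cohort has no use
  for).
- **Exclusion**: a participant is dropped iff some window has
  ≥ `ceil(0.4 × 30) = 12` missing nights. The threshold is a config value;
  `ceil` reproduces the "12 or more of 30" rule exactly.
- **Imputation**: missing nights are filled per feature with the mean of
  observed values in a centred 7-night window (edge-truncated); if that
  window is empty, the observed mean of the 30-night window, then of the
  whole span. Observed values are never modified, which makes the operation
  idempotent. The 7-night width balances temporal locality against the
  chance of an empty window at the permitted missingness levels; the width
  is configurable because the protocol fixes only "rolling mean".
- **Winsorisation and scaling**: per fold, the combined clinical + GP matrix
  is clipped to the 5%/95% column quantiles and z-scored (population SD).
  Statistics are fit on the combined matrix — fitting per cohort would erase
  exactly the between-cohort differences the clustering is meant to find.
  Constant columns map to zeros with a warning.

## 3. Fold design

The clinical cohort is fixed; GP participants are drawn into
`n_folds = 5` disjoint folds of `per_fold = 50` without replacement
(a with-replacement mode exists behind a flag). Each fold is stratified on
5-year age bins to match the *clinical* cohort's age histogram, with
largest-remainder rounding of per-bin quotas (deterministic, sums exactly to
50, ties broken by bin order). Insufficient bins raise an error naming the
bin.

Degenerate but important special case: when the GP pool size equals
`n_folds × per_fold` exactly (the default synthetic world: 250), every pool
member must be used once, so age quotas cannot bind; the pool is partitioned
uniformly at random. True age matching against an older clinical reference
needs a pool far larger than the demand — of the order of the original
study's 5 580 — which is why the scaled synthetic world relies on the
exhaustive path.

## 4. Clustering and model selection

Three families, one per broad class: K-means (k-means++ init, 10 restarts,
tol 1e-4), full-covariance Gaussian mixture (EM, `reg_covar = 1e-6`, 3
inits, hard labels by maximum responsibility) and Ward agglomerative
clustering. Centroids are always *member means* in the scaled space so that
label harmonisation treats all algorithms identically.

Internal validity indices are implemented directly (exact Euclidean
distances) with the following conventions: silhouette assigns 0 to
singleton-cluster points and to the all-singleton partition; Calinski–
Harabasz returns +inf for zero within-cluster scatter and is undefined at
k = n; Davies–Bouldin raises a degenerate-clustering error on coincident
centroids. Each (algorithm, k) cell is refit on 15 bootstrap resamples
(rows resampled with replacement, same n; resamples yielding an empty
cluster are redrawn with a retry cap) and scored *on the resample*;
percentile 95% CIs summarise the runs.

Selection ranks the mean-over-runs SC (higher better) averaged across folds.
Because continuous scores never tie exactly, scores within 0.005 of the
maximum — half a unit of the two-decimal precision such indices are
conventionally reported at — count as tied and are ranked by CH (higher),
then DB (lower), then by the order the algorithms are listed (k-means, GMM,
agglomerative). On well-separated Gaussian phenotypes, k-means and the GMM
converge to near-identical partitions; their SC difference is resampling
noise at the 1e-4 level, and the tolerance prevents that noise from deciding
the selection.

**Harmonisation**: within each fold, clusters are relabelled 1…k by
ascending centroid-to-origin distance in the z-scored space (a flag
inverts the order; ties break on the first centroid coordinate and are
logged). This is an unsupervised alignment — it works when the phenotypes'
distances from the population mean are distinct, and can swap two clusters
whose norms are close (see §7).

## 5. Profiling statistics

Per fold and harmonized cluster: cohort %, sex % and mean age over the
cluster's window-sample rows; these fold values are averaged and reported
± SEM, with SEM = sample SD (n−1) across folds / √(folds present). A cluster
missing from a fold contributes nothing for that fold and the denominator
shrinks.

Comparisons: one-way ANOVA (F = MS_between/MS_within, df (k−1, N−k); F = 0,
p = 1 when all groups are identical); Tukey–Kramer post-hoc via the
studentized range (scipy), adjusted within each feature's pairwise family
only — no cross-feature correction is applied because none is part of the
protocol; two-sided independent t-tests (pooled variance by default, Welch
optional); and a hand-implemented two-way mixed-design ANOVA (between =
cluster, within = sleep metric, subjects nested in clusters) whose
between-effect error term is subject-within-groups variation and whose
within/interaction error is the subject × metric residual. With a single
within level the partition collapses *exactly* to the one-way ANOVA — this
falls out of the sums of squares rather than being special-cased.
`pingouin.mixed_anova` serves as an independent oracle in the test suite.
An MMSE-by-cluster comparison reuses the one-way ANOVA on clinical rows.

## 6. Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, not
the physics of a pressure sensor: it starts at the nightly-summary level.

- **Phenotypes.** Three planted phenotypes, expressed as shifts of a common
  baseline (NREM 4200 s, REM 5400 s, light 14400 s, WASO 3600 s; HR
  52/62/78 bpm; RR 12.5/15.5/19 breaths/min) in units of the
  between-participant SD (durations 600–900 s, HR 4–5 bpm, RR 1–1.2):
  - *Phenotype 1* (dementia-like, magnitude 2.2): +light, +WASO, −REM,
    −NREM, +HR, +RR — the most extreme profile;
  - *Phenotype 2* (deep sleeper, 1.7): +NREM, +REM, −WASO, −light, plus
    raised minimum/average HR and minimum RR;
  - *Phenotype 3* (quiet, 1.1): everything moderately low.
  Within-participant nightly SD equals the between-participant SD (night-to-
  night variability comparable to between-person differences). The pairwise
  Mahalanobis separations are then 8.7 / 9.5 / 6.6 in within-SD units — a
  well-separated regime in which the pipeline demonstrably recovers the
  planted structure (fold ARI ≥ 0.94 across a 20-seed validation scan).
  The graded magnitudes (2.2/1.7/1.1) were chosen jointly so that (a) the
  silhouette criterion is maximised at k = 3 rather than merging the two
  closest phenotypes at k = 2, and (b) the three centroid norms are distinct
  enough for stable cross-fold harmonisation; uniform magnitudes fail (b)
  because the extreme and the quiet phenotype sit nearly antipodal around
  the population mean.
- **Sampling.** Cohort-specific phenotype weights (PLWD ≈ .428/.375/.196,
  GP ≈ .166/.438/.396) are derived from the reported per-cluster cohort
  splits (72/46/33% clinical) and cluster shares; in a balanced 50+50 fold,
  phenotype 1 is clinical with probability ≈ 0.72. Ages are normal per
  phenotype (means 78.0/73.5/71.9, SD 6.6), truncated to 60–98; sex from
  per-phenotype female fractions (.41/.19/.16); MMSE (clinical only) from a
  diagnosis-band mixture (Alzheimer's 55% with 13.3 ± 5.9, vascular 15% with
  21.8 ± 3.5, …), clipped to 0–30.
- **Nights.** Personal mean = phenotype mean + between-participant noise;
  each night adds independent Gaussian within-participant noise (an AR(1)
  option exists, default off). Min/avg/max triplets are repaired around the
  average (min = avg − |δ|, max = avg + |δ|) and durations truncated at 0.
- **Missingness.** Whole-night MCAR; each participant's rate is drawn
  uniformly from (0.08, 0.12) — mean 10%. The range is deliberately
  narrower than (0.05, 0.15): at a 0.15 rate a participant crosses the
  12-missing-nights exclusion threshold often enough that the
  exactly-exhaustive 250-strong GP pool loses a member in a sizeable
  fraction of replicates, making the 5 × 50 disjoint fold demand
  infeasible. A `frac_excludable` fraction of participants can be forced
  over the threshold (their first 12 nights are blanked) to exercise the
  exclusion logic.
- **Determinism.** One seed; independent sub-streams for participants,
  nights and missingness via `SeedSequence.spawn`.

What a green test on this generator does **not** establish: robustness to
non-Gaussian or heavy-tailed nightly noise, temporal trends (circadian,
seasonal, disease progression), informative (non-MCAR) missingness,
feature correlations within a night beyond the phenotype structure, or
sensor-level artefacts. The generator is a validation harness for the
pipeline's logic, not a model of real sleep data.

## 7. Known limitations

- **Norm-based harmonisation is inherently fragile** when two clusters have
  similar distances from the origin; with the default phenotypes the modal
  fold-mapping is consistent in ≥ 4/5 folds in ~95% of replicates, not all.
- **Between-fold SEM understates total uncertainty for the clinical
  cohort**: the same 50 clinical participants appear in every fold, so the
  sampling noise of that single cohort draw (≈ 5 percentage points on a
  cluster's cohort split at n = 50) shifts all folds together and is
  invisible to the across-fold SEM. Cluster-composition point estimates
  track the *realized* planted composition closely, but a ±2 SEM band
  around a *nominal* population value covers it in only ~75% of replicates.
- **The exactly-exhaustive GP pool** (250 for 5 × 50 folds) leaves no slack:
  a single filtered-out GP participant makes fold construction impossible,
  and genuine age-quota matching requires a pool an order of magnitude
  larger than the demand.
- K-means vs GMM selection on Gaussian synthetic data is a coin flip at
  noise level; only the selected k is a robust outcome.
- The two-way mixed ANOVA assumes complete within-factor coverage per
  subject and does not apply sphericity corrections.
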