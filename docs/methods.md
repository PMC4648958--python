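# Methods

## Problem and data model

Each patient contributes two MRI series with rater-drawn tumor masks: a
post-contrast T1 (T1C) image with a binary *tumor bulk* mask covering both
the dark necrotic and bright contrast-enhancing tumor, and a T2-FLAIR image
with a binary *total tumor* mask covering the bulk plus the surrounding
hyperintense signal (edema envelope and nonenhancing tumor, which FLAIR
cannot distinguish). The two series are **not** required to share a grid:
every downstream quantity is a volume, so each mask is only validated
against its own reference image, volumes are measured per series
(voxel count × voxel size, in mm³) and combined as scalars. Orientation
and affine rotation are ignored for the same reason — volumes are
rotation invariant. Masks with labelled (non-binary) values are coerced to
{0, 1} with a warning rather than rejected, tolerating common mask
dialects.

## Bulk stratification by exact 1-D two-class K-means

The in-mask T1C intensities are partitioned into a dark (necrosis) and a
bright (contrast-enhancing) class by two-class K-means. In one dimension
the optimal two-class K-means partition is a contiguous split of the
sorted values, so the implementation scans all admissible split points
with prefix sums and returns the global minimum of the total
within-cluster sum of squares — no initialization, no seed, no local
optima. Numerical choices:

- Splits are placed only between *distinct* sorted values, so voxels with
  equal intensity are never divided across classes; the output is a
  threshold partition (max necrosis intensity ≤ min enhancing intensity)
  and is invariant to voxel ordering and to positive affine intensity
  transforms.
- Exact SSE ties between splits break toward the larger dark cluster — a
  fixed, testable rule.
- Spatial regularization and partial-volume modelling are intentionally
  absent: the clustering is intensity-only, keeping the step exactly
  reproducible.
- Degenerate bulks: an empty or single-voxel bulk is an error attributed
  to the patient; a constant-intensity bulk cannot be split, so the
  pipeline assigns the whole bulk to the enhancing compartment (necrosis
  = 0 mm³), preserving volume additivity, and flags the patient with
  `constant_bulk_all_enhancing`.

## The 11-feature panel

Five volumes — necrosis *N*, contrast-enhancing *CE*, FLAIR
hyperintensity *H*, bulk *B* = *N* + *CE* (exact, same grid), total *T*
(FLAIR grid) with *H* = *T* − *B* by scalar subtraction — and six ratios
*N*/*CE*, *CE*/*B*, *CE*/*T*, *N*/*T*, *H*/*T*, *B*/*T*. A negative
derived *H* (possible across two independently drawn masks) flags the
patient `hyperintensity_negative` and excludes them from association
analysis by default, a documented policy choice. Ratios with zero
denominators are stored as missing (never 0 or ∞) and dropped per
feature per patient in the statistics; complement identities
(*CE*/*B* + *N*/*B* = 1, *H*/*T* + *B*/*T* = 1) hold whenever defined.

## Association statistics

Genes mutated in at least `min_mut` (default 5) of the analyzed patients
are tested against each feature:

- **Group difference** — two-sided pooled-variance Student's *t* test
  (df = n₁ + n₀ − 2); positive *t* means the mutant mean exceeds the
  wild-type mean, and the sign of the reported mean difference always
  matches the sign of *t*. A Welch option exists behind a flag.
- **Prediction** — ROC AUC with mutated = positive class and higher
  feature values scoring positive, computed from midranks (equivalently,
  concordant + half of tied pairs over n₁·n₀). Reported as the absolute
  AUC 0.5 + |AUC − 0.5|, with the raw AUC retained for direction.
- **AUC inference** — p-value for H0: AUC = 0.5 from the tie-corrected,
  continuity-corrected normal approximation to the Mann-Whitney *U*
  statistic (the convention of R's `wilcox.test`; the correction keeps the
  approximation within ~0.006 of the exact permutation p at n = 15/15). A
  seeded exact-permutation alternative is provided and recommended when
  the smaller class has fewer than 10 members. The 95% CI uses the DeLong
  variance estimator, centred on the folded AUC so the reported value
  always lies inside its own interval, clipped to [0, 1].
- **Multiplicity** — none by default (each test at α = 0.05); a
  Benjamini-Hochberg switch adds adjusted p-values and bases the
  significance flags on them.
- **Normality screen** — Shapiro-Wilk W and p per feature across all
  patients, reported for inspection; p ≥ α is read as non-rejection of
  normality. (The screen reports; it does not gate the t tests.)
- **Correlation structure** — pairwise-complete Pearson correlations of
  the 11 features; zero-variance features get flagged NaN rows/columns.
- **Patient clustering** — features are z-scored across patients and the
  patients grouped by Ward-linkage hierarchical clustering (Euclidean
  distance) cut at two clusters. Each clinical variable is cross-tabulated
  against the grouping and tested with a chi-squared test of independence;
  KPS is snapped to its displayed levels {40, 60, 80, 100} and age binned
  by decade (both configurable); missing clinical values are excluded per
  variable. Note that the greedy agglomerative 2-cut is not guaranteed to
  attain the globally optimal minimum-SSE 2-partition; it is used as the
  field-standard exploratory grouping, and the tests assert only that it
  never *beats* the exhaustive optimum and that clearly separated groups
  are recovered.

## Synthetic cohorts

Each phantom patient is three nested ellipsoids (voxel-center-in-ellipsoid
rasterization): necrotic core ⊂ bulk ⊂ total extent. T1C intensity means
are background 30, necrosis 40, enhancing 160; FLAIR shows the total
extent at 150 over background 30; i.i.d. Gaussian noise (default sd 12,
i.e. 10% of the 120-unit necrosis/enhancing separation) is added per
image. Ellipsoids are used deliberately: every measured feature is a
volume or ratio, both shape-agnostic, and ellipsoids admit the analytic
oracle 4⁄3·π·abc. Ground-truth masks and volumes are exact by
construction and satisfy the same additivity identities as the measured
panel.

A cohort (default n = 76 on a 64³ unit-voxel grid; an anisotropic
0.94 × 0.94 × 5.0 mm setting exercises voxel-size handling) draws per
patient:

- per-gene mutation status, independent Bernoulli draws with frequencies
  emulating a 76-patient adult-GBM cohort (expected counts: TP53 26,
  PTEN 24, EGFR 24, NF1 9, PIK3R1 8, RB1 8, IDH1 7, PIK3CA 6, PDGFRA 6);
- a shared log-normal size factor (sd 0.10, clipped at ±3 sd) times an
  independent log-normal per-compartment factor (sd 0.06) applied to the
  semi-axes. The shared factor makes compartment volumes positively
  correlated, as in real tumors; the per-compartment factor gives the
  ratio features genuine between-patient variance. Log-normal jitter
  keeps volumes positive and near-normal at these sd values;
- clinical variables (gender, disease-free status, KPS ∈ {40, 60, 80,
  100}, age 21–85, ~5% missing) drawn independently of the imaging
  features — a null association by construction, so the clustering
  chi-squared checks have a known truth.

Mutated genes multiply the (core, bulk, total) semi-axes; multiple
mutations compose multiplicatively, and nesting is re-clipped defensively.
Per-patient random streams are derived from the master seed and patient
index (`SeedSequence([master, index, stream])`), so outputs are
bit-reproducible and independent of generation order. Presets:

| preset | effect (semi-axis multipliers on mutants) |
|---|---|
| `null` | none — all 1.0 |
| `tp53_like` | core and bulk × 0.86 (volume × 0.64 ≈ −1.0 pooled SD on enhancing volume at the default jitter) |
| `rb1_like` | total extent × 0.85 (smaller edema envelope at similar bulk) |
| `egfr_like` | core × 1.18 inside an unchanged bulk (higher necrosis/enhancing ratio at similar total volume) |

## Problem sizes used in tests

Calibration and power studies (200 cohorts of n = 76 each) run the
association stage on exact truth volumes at 32³; this is the package's
chosen study size — segmentation fidelity is established separately by the
Dice checks, and at these noise levels the measured and true volumes are
essentially identical, so the statistical conclusions transfer. The
end-to-end determinism check runs the full imaging path at 64³.

## What the synthetic cohorts do and do not show

Passing tests demonstrate that the pipeline recovers planted volumetric
effects with calibrated error rates under the generator's assumptions:
ellipsoidal single-focus tumors, spatially white Gaussian noise, perfectly
drawn input masks, and mutation effects that act multiplicatively on
compartment size. They do not validate performance under real-data
complications that are out of scope here: rater variability in the input
contours, bias fields and acquisition artifacts, partial-volume voxels at
compartment boundaries, multifocal tumors, or registration issues between
series (irrelevant to volumes, but relevant to any future voxelwise
extension). Agreement in distribution with any particular clinical cohort
is likewise not claimed.

## Known limitations

- The intensity-only two-class split assumes necrosis and enhancement are
  separable by a single threshold within the bulk; strong bias fields
  would violate this.
- The AUC normal approximation is asymptotic; for genes near the
  five-mutation inclusion floor the seeded permutation option is the more
  defensible p-value.
- DeLong CIs are clipped to [0, 1] and are degenerate when a feature
  separates the classes perfectly.
- The exploratory two-group clustering depends on the z-scoring
  population and the Ward heuristic; it is a descriptive device, not an
  inferential one.
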