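# Methods

## Territory model

The myocardial territory computation treats the coronary tree as a set of
curves and the LV myocardium as a voxel set. Because tessellating against
sparse polyline *nodes* would bias territories toward node-dense regions,
every edge is first subdivided so consecutive samples are at most
`max_spacing` apart (default `0.5 × min voxel spacing`, which puts seed
density below grid resolution; halving it further changes MMAR by < 1% on
the test fixtures). Each foreground voxel is then assigned to the sample
minimizing Euclidean distance between the voxel center (world mm,
voxel-center convention, 0-based indices) and the sample position, via a
k-d tree. Exact two-way distance ties are broken to the lowest sample id
for determinism; three-way exact float ties are not specially handled
(measure zero). Background voxels are never claimed.

A lesion is a point on the tree: either an original node id or a
`(branch, arc-length)` pair, snapped to the nearest densified sample
at-or-distal to the requested arc length so the downstream set is well
defined. "Distal" is along-tree reachability away from the root, including
all downstream side branches. MMAR is the voxel count of the distal set's
territory times the voxel volume (ml); an optional gram conversion uses
density 1.05 g/ml but ml is the default reporting unit. Two exact
invariants follow from integer voxel counting and are tested: per-sample
territory volumes sum to the total LV volume, and the three ostial
territories partition the ventricle (%MMAR summing to 100).

## Statistical conventions

* AUC is the tie-adjusted Mann–Whitney statistic (midranks); its variance
  comes from DeLong structural components, with the 95% CI formed on the
  logit scale and back-transformed so bounds stay in [0, 1]. Degenerate
  zero-variance cases (AUC = 1) return a point interval with a warning.
  Correlated AUCs on the same cases are compared with the full component
  covariance.
* The optimal cut-off maximizes Youden's J (ties resolved to the lowest
  cut-off); closest-to-(0,1) is available behind a flag. Predicted-positive
  is score ≥ cut-off everywhere, including `classify` on MMAR/MLD.
* NRI is the continuous (category-free) variant with the asymptotic
  variance of its component proportions; a categorical NRI is available
  when risk thresholds are supplied. IDI is computed literally as the
  difference of discrimination slopes, so that identity is exact.
* Risk models are logistic (IRLS via GLM): base covariate DS, extended
  DS + MMAR/MLD, outcome FFR ≤ 0.8. Separation is flagged with a warning
  rather than raised.
* Mann–Whitney U counts (a > b) pairs; the p-value is exact for
  `n_a·n_b ≤ 400` without ties, otherwise a tie-corrected normal
  approximation without continuity correction. Chi-squared uses no
  continuity correction. All p-values are two-sided; quartiles use linear
  interpolation between order statistics (type 7).

## Synthetic data: what it emulates, and what it does not

The LV phantom is a truncated half-ellipsoid shell — outer semi-axes
(35, 35, 55) mm, 10 mm wall, cut at 70% of the long axis from the apex,
1 mm isotropic voxels — giving ≈ 123 ml of myocardium, a plausible human
LV volume. The coronary tree places RCA/LAD/LCx main branches exactly on
the outer surface, descending from base toward apex with seeded azimuthal
drift, plus 2–3 side branches per artery.

Lesion geometry is log-normal with medians/IQRs matching an
intermediate-lesion FFR cohort: MLD 1.39 (1.04–1.69) mm,
RD 2.65 (2.26–3.10) mm, length 12.0 (7.6–15.8) mm, truncated to MLD < RD;
artery frequencies 18/61/21% (RCA/LAD/LCx). Lesions sit uniformly on the
proximal quarter of the main branch — territory mass concentrates in the
basal band of the shell, so this placement yields the target median MMAR
(~33 ml, inside the reference 21.9–44.3 ml interquartile band) with ~36%
of lesions labelled proximal.

FFR comes from classic stenosis fluid mechanics: hyperemic flow
`Q = q·MMAR` (q = 1.5 ml/min per ml), pressure loss
`ΔP = Kv·(L/MLD⁴)·Q + Ke·(1/MLD² − 1/RD²)²·Q²` (Kv = 0.045, Ke = 0.018),
`FFR = (Pa − ΔP)/Pa + ε` with Pa = 90 mmHg and ε ~ N(0, 0.045), clamped to
(0, 1]. The coefficients were calibrated once so that roughly 38–42% of
lesions fall at FFR ≤ 0.8; the resulting FFR distribution is more
left-skewed than a clinical cohort's (median ≈ 0.85 rather than 0.82, with
a long low tail from small-MLD lesions), a known simplification. All draws
come from one seeded generator in documented order, so cohorts are
bit-reproducible.

Because the synthetic FFR is *generated* from MMAR and MLD, discrimination
on synthetic cohorts is stronger than clinically realistic (AUCs ~0.9+
versus ~0.75 in patient data). Passing tests therefore demonstrate the
correctness and direction-of-effect of the chain — negative MMAR/MLD–FFR
correlation dominating DS, positive AUC/IDI gain from the extended model —
not clinical effect sizes. Real data also differ in ways the phantom does
not attempt: papillary muscles and trabeculation, non-elliptical ventricles,
lumen-surface (rather than centerline) tessellation, diffuse and tandem
disease, and measurement error in QCA.

## Numerical and design choices

* Distances are Euclidean in world millimetres (isotropic physical
  distance); the mask's affine may be anisotropic.
* Zero-length centerline edges are skipped with a warning; the child node
  aliases its parent's sample.
* Supplied `ds_pct` is always recomputed from MLD and RD; a deviation over
  one percentage point warns (rounded published values need not compose)
  but does not error.
* Subgroup ROC rows with fewer than 5 cases in either class are flagged as
  unstable rather than suppressed.
* Problem sizes used by the test suite and the acceptance script — 300–500
  lesion cohorts, 20 replication seeds, 500 coverage simulations at
  60 + 60 scores, 100 random tessellation instances at ≤ 16³ voxels — were
  chosen to make Monte-Carlo checks stable at desk scale; the full suite
  runs in well under a minute on one core.

## Known limitations

* Centerline (not lumen-surface) tessellation; whole supplied mask as the
  %MMAR denominator (no papillary exclusion).
* The FFR model ignores serial lesions, collaterals, microvascular
  resistance, and pressure-flow autoregulation.
* The continuous NRI's asymptotic CI is one of several published NRI
  estimators; results are labelled as such and not comparable across
  variants.
* Left-ventricular territories only; no right-ventricular or whole-heart
  partition.
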