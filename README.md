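# mmar — myocardial mass at risk and the MMAR/MLD index

Anatomy alone is a poor predictor of whether a coronary stenosis actually
starves the myocardium: fractional flow reserve (FFR, the ratio of distal
coronary to aortic pressure under hyperemia) is the invasive reference, with
FFR ≤ 0.8 defining a functionally significant lesion. The discordance
between angiographic severity and FFR is driven largely by the amount of
myocardium the lesion subtends — a tight stenosis feeding a small territory
may be benign, a moderate one feeding a large territory may not.

This package implements the computational chain for a non-invasive surrogate
built from that idea, for researchers evaluating anatomy-based FFR
prediction:

* **Territories.** The LV myocardium (a voxel mask) is partitioned by
  Voronoi tessellation against the densified coronary centerline tree: each
  voxel joins its nearest centerline sample in world millimetres. The
  **myocardial mass at risk** distal to a lesion point is
  `MMAR = Σ voxels whose nearest sample lies in the lesion's downstream
  subtree × voxel volume` (ml), and `%MMAR = 100 · MMAR / LV volume`.
* **Index.** With the minimal lumen diameter from quantitative coronary
  angiography, `MMAR/MLD` (ml/mm) expresses demand over supply; values at or
  above a cut-off (29.5 ml/mm) predict FFR ≤ 0.8. Diameter stenosis is
  `DS = (1 − MLD/RD) × 100`.
* **Statistics.** ROC analysis with DeLong variance (logit-scale 95% CIs,
  correlated-AUC comparison), Youden-optimal cut-offs with
  sensitivity/specificity/PPV/NPV, Pearson correlations, Mann–Whitney and
  chi-squared group tests, logistic risk models, and continuous NRI / IDI
  for the gain of adding MMAR/MLD to DS.
* **Synthetic cohorts.** An LV-shell phantom, three-artery epicardial trees,
  log-normal lesion geometry, and a stenosis pressure-loss FFR model
  (viscous + expansion losses, flow proportional to subtended mass) provide
  fully reproducible desk-scale cohorts; see `docs/methods.md`.

## Worked example

```bash
python analysis/01_simulate_inputs.py      # shell + tree + 300-lesion cohort
python analysis/02_single_lesion_example.py
python analysis/03_discrimination_analysis.py
```

The single-lesion step prints:

```
lesion: LAD main branch, 5 mm from ostium; MLD 1.39 mm
MMAR 41.9 ml, %MMAR 33.9% of 123.5 ml LV
MMAR/MLD 30.1 ml/mm -> predicted functionally significant (cut-off 29.5 ml/mm)
```

i.e. the territory distal to the proximal-LAD point is 41.9 ml (33.9% of the
left ventricle); divided by the 1.39 mm minimal lumen diameter it exceeds
the 29.5 ml/mm cut-off, so the lesion is predicted to have FFR ≤ 0.8. The
discrimination step then reports, on the simulated cohort, the correlation
of each variable with FFR (MMAR/MLD strongest and negative, r ≈ −0.83), ROC
tables per artery subgroup, and the base-vs-extended model comparison
(adding MMAR/MLD to DS raised the AUC from 0.881 to 0.965 with IDI 0.283 on
the seed-1 cohort).

The same machinery is scriptable via the `mmar-study` CLI (`run`, `mmar`,
`simulate`, `stats` subcommands) or the library API
(`mmar.mmar_for_lesion`, `mmar.run_study`, ...). Patient-style inputs are
accepted as NIfTI masks, a documented centerline JSON schema, and a lesion
CSV.

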