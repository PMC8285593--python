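# wmhh — multi-site harmonisation for white-matter-hyperintensity measures

White-matter hyperintensities (WMHs) are bright lesions on FLAIR MRI and a
core marker of cerebral small-vessel disease.  When a study spans several
scanners — an upgrade mid-study, or a merge of independently-acquired
cohorts — the measured WMH load mixes biology with scanner effects: RF-coil
bias fields, intensity gain/offset, noise, and the habits of whoever drew
the training masks.  `wmhh` implements, end to end, a harmonisation
pipeline for this setting and the statistical battery that decides whether
it worked, exercised on a synthetic multi-site cohort generator with known
ground truth so that every stage is testable without access to any real
imaging study.

The pipeline's segmenter is a BIANCA-style supervised k-nearest-neighbour
voxel classifier: each candidate voxel carries per-modality intensity and
patch-mean features (z-scored per subject) plus spatially-weighted
coordinates, and its lesion probability is the fraction of lesion labels
among its k = 40 nearest training points; thresholding gives the lesion
mask and the WMH volume as % of total brain volume.  Harmonisation success
is judged by:

* **overlap metrics** (Dice, voxel- and cluster-level FPR/FNR) across
  sites and analysis options, with a two-way mixed ANOVA;
* an **ANCOVA** of WMH% on demeaned age with site as factor — equal slopes
  (age × site interaction) and equal intercepts at the mean age — plus the
  **Johnson–Neyman** region of ages where sites do not differ
  significantly: for a fitted between-site difference γ + δ·(age − ā),
  the closed-form solution of |t(age)| = t_crit;
* an **Elastic-Net** multivariate model predicting WMH% from non-imaging
  covariates plus a scanner indicator: the variance fraction β̂²/Var(y)
  attributed to the scanner is the headline harmonisation score;
* a declarative **non-imaging unit harmonisation** engine (h/week vs
  day/week × min/day, m vs cm, binary vs multi-class categories) with
  t / chi-square cohort comparisons.

Two scenarios are orchestrated: a two-site *scanner upgrade* compared
across five analysis options (bias correction on/off × single-site /
site-specific / mixed training × FA included/excluded), and a three-site
*retrospective merge* comparing site-specific against mixed training.

## Worked example

```python
from wmhh import experiments as ex

report = ex.run_scenario(ex.default_upgrade_config(seed=1))
for oid, o in report["options"].items():
    print(oid, round(o["elastic_net"]["site_fraction"], 4),
          round(o["ancova"]["slope_p"], 3))
```

prints (option, scanner-attributed variance fraction, ANCOVA slope p):

```
A 0.0796 0.213
B 0.0 0.289
C 0.0072 0.285
D 0.0 0.199
E 0.0 0.688
```

Option A (no bias correction, single-site training) attributes ~8 % of the
WMH-volume variance to the scanner; with bias correction (B) the scanner
contribution collapses, and mixed training (D/E) keeps it at zero while
site-specific training (C) lets per-site rater and scanner idiosyncrasies
back in.  The same report carries the per-option overlap metrics, the
Johnson–Neyman intervals and the mixed-ANOVA table; `ex.save_report`
writes it as deterministic JSON + CSV.

The numbered drivers under `analysis/` walk the full study:

```sh
python analysis/01_generate_cohorts.py        # cohorts + ground truth
python analysis/02_bias_field_correction.py   # traveling heads, field recovery
python analysis/03_rater_effect.py            # manual vs automated consistency
python analysis/04_scenario_upgrade.py        # options A-E
python analysis/05_scenario_merge.py          # site-specific vs mixed
python analysis/06_nonimaging_harmonisation.py
```

Each writes its tables under `results/`.  There is also a thin CLI
(`wmhh generate | preproc | segment via run | evaluate | stats |
nonimaging | run`), e.g.

```sh
wmhh run --scenario merge --seed 7 --out results/merge
wmhh evaluate --auto auto.nii.gz --ref ref.nii.gz
```

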