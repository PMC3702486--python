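# mclegz

Infarct-heterogeneity analysis for late-gadolinium-enhancement (LGE) cardiac
MR, for imaging scientists and cardiology researchers studying the
arrhythmogenic substrate after myocardial infarction.

After an infarct, LGE imaging distinguishes densely scarred **core**, viable
**healthy** myocardium, and an intermediate-enhancement **peri-infarct gray
zone (GZ)** — a putative substrate for ventricular arrhythmia and a candidate
predictor of appropriate ICD therapy. This package quantifies core and gray
zone two ways, scores papillary-muscle (PM) infarct involvement, and runs the
two-group cohort statistics those measures feed:

* **FWHM method** (conventional single-TI LGE, IR-FGRE): with remote-ROI
  statistics (Mean_remote, Peak_remote, SD_remote), candidate infarct is
  myocardial signal above Peak_remote, the core is
  `SI > 0.5 · Peak_infarct`, and the gray zone is
  `Peak_remote < SI ≤ 0.5 · Peak_infarct`.
* **Multi-contrast (MCLE) method**: each voxel of a multi-inversion-time
  series is fitted with the inversion-recovery model
  `S(t) = A − B·e^(−t/T1*)`; fuzzy C-means clusters the (T1*, A) scatter
  into {infarct, healthy, blood}, and the gray zone is the band of voxels
  with infarct membership between 25% and 75%.
* **PM-MI score**: 2, 1 or 0 papillary muscles infarcted.
* **Quantification**: masses in grams (voxel volume × 1.05 g/cm³) and as %
  of LV myocardial mass; summation-of-disks LV volumes, EF and mass.
* **Cohort statistics**: pooled two-sample Student t-tests (from raw values
  or printed `mean ± SD (n)` summaries) and two-sided Fisher exact tests.

Because patient data are not distributable, a **synthetic LV phantom**
(annular myocardium, blood pool, infarct wedge with gray-zone rim, two
papillary muscles, per-tissue (A, T1*) signal tables, Gaussian noise) and a
**cohort simulator** provide ground truth for every stage.

## Worked example

Run the full phantom pipeline (phantom → simulate MCLE + IR-FGRE → fit
T1*/steady-state maps → FCM and FWHM segmentation → quantify):

```python
from mclegz.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig(out_dir="run0", seed=42))
print(res["mcle"])        # MCLE-path heterogeneity measures
print(res["pm_score_mcle"], res["dice"])
```

Output (noiseless default phantom):

```
{'core_g': 10.3194, 'gz_g': 1.134, 'total_g': 11.4534, 'lvm_g': 40.1436,
 'core_pct': 25.706..., 'gz_pct': 2.8248..., 'total_pct': 28.531...}
1 {'core': 1.0, 'gray_zone': 1.0, 'healthy': 1.0}
```

Reading: the classified infarct core is 10.32 g (25.7% of the 40.1 g LV
mass), the gray-zone rim 1.13 g (2.8%), and one of the two papillary
muscles is infarcted (PM-MI score 1).  Dice of 1.0 against the phantom's
ground-truth labels means the noiseless classification is voxel-perfect;
the run directory also contains the fitted maps, the class map as NIfTI,
and per-slice color maps (yellow gray zone, green core, red blood, blue
healthy myocardium).

The same stages are exposed on the command line:

```bash
mcle-gz run --seed 42 --out run0
mcle-gz simulate-cohort --seed 1 --out cohort.csv
mcle-gz cohort-stats --cohort cohort.csv --out report.csv
mcle-gz t-from-summary --m1 1.67 --s1 0.49 --n1 12 --m2 1.00 --s2 0.93 --n2 13
# -> t = 2.2244, df = 23, two-sided p = 0.03621
```

Model-style estimator objects are available for the two fitting stages:
`relaxometry.InversionRecoveryModel(series, mask).fit()` returns results
with parameter maps and a `summary()`; `mcle.FuzzyCMeans(x).fit(seed)`
returns memberships, centroids and the objective trace.

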