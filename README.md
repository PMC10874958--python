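# octlayers

Retinal-layer irregularity biomarkers from OCT B-scans.

Diabetic retinopathy changes the fine structure of the retina before it is
obvious on fundus examination.  On a spectral-domain OCT cross-section the
inner plexiform layer (IPL) and ellipsoid zone (EZ) appear as thin bright
lines and the outer plexiform layer (OPL) as a bright band; as retinopathy
progresses these boundaries become irregular and the nuclear layers between
them change in area.  `octlayers` implements a fully automated measurement
chain for these biomarkers, aimed at researchers studying structural OCT
biomarkers of diabetic retinopathy (normal vs non-proliferative vs
proliferative, NPDR/PDR):

1. **Preprocess** — Gaussian denoise (11 x 11), Gabor-bank enhancement of
   the retinal band, optic-disc trimming of horizontal scans.
2. **Segment** — per-column sub-pixel candidate detection (parametric
   profile fits) for the IPL line, the OPL band borders and the EZ line,
   then epsilon-insensitive support vector regression with a wavelet kernel
   `K(u,v) = cos(1.75 d/a) exp(-d^2/2a^2)`, `d = u - v`, including
   mislabel replacement and layer-ordering repair.
3. **Quantify** — locate the fovea, split the scan into nasal / foveal
   (central 20% of columns) / temporal zones (superior/inferior for
   vertical scans), and compute per zone the smoothness index

       SI = LL / CL

   (straight-line endpoint distance over polyline arc length; 1 = perfectly
   smooth) for the IPL, the upper OPL border and the EZ, plus the
   trapezoidal areas S of the INL, OPL and ONL bands.
4. **Compare** — GEE group comparisons with patient-level clustering
   (fellow eyes are correlated) adjusted for age and sex, pairwise Wald
   contrasts, ROC/AUC with DeLong 95% CI, Spearman correlations.

Because no public dataset pairs raw B-scans with per-eye retinopathy
grades, the package ships a synthetic cohort generator with exact ground
truth: layered B-scans with a foveal pit, per-zone boundary irregularity
calibrated to target SI values, per-zone inter-layer areas, multiplicative
speckle, and a three-group cohort (33/36/15 eyes, ~47% of patients
contributing both eyes) whose biomarker distributions follow configurable
group means/SDs.  Every stage is validated against this ground truth.

## Worked example

The `analysis/` scripts run the whole study end to end (from the repository
root):

```bash
python analysis/01_simulate_cohort.py    # 168 scans, 84 eyes, 3 groups
python analysis/02_segment_layers.py     # boundaries for every scan
python analysis/03_compute_biomarkers.py # per-eye SI and area table
python analysis/04_group_statistics.py   # GEE, ROC, Spearman
```

On the default cohort (seed 20240218) this prints, among other things:

```
simulated 168 scans: 84 eyes from 56 patients ({'NPDR': 72, 'PDR': 30, 'normal': 66})
boundary RMSE vs ground truth: median 0.25 px, worst 0.39 px
wrote results/biomarkers.csv: 84 eyes x 36 biomarkers
       SI_IPL.H.Nasal         S_INL.H.fovea
                 mean     std          mean       std
NPDR           0.9289  0.0112     1991.7310  267.4749
PDR            0.8963  0.0298     2137.0681  474.2816
normal         0.9305  0.0120     1559.5497  303.0813
GEE comparisons: 36 biomarkers, 19 with overall p < 0.05
best discriminator diabetic_vs_normal: S_INL.H.fovea AUC 86.3% (CI 0.780-0.946)
best discriminator PDR_vs_NPDR: SI_IPL.H.Temporal AUC 98.5% (CI 0.961-1.000)
```

Reading this: every boundary is recovered to sub-pixel accuracy; the nasal
IPL smoothness index separates PDR (0.896) from NPDR/normal (0.93), while
the foveal INL area separates diabetic from normal eyes — the two patterns
the biomarkers are designed to capture.  Tables land in `results/`
(`biomarkers.csv`, `group_comparisons.csv`, `roc_results.csv`,
`age_correlations.csv`); images and per-scan boundary files live under
`scratch/` and are fully regenerable.

The same pipeline is scriptable (`octlayers simulate|segment|analyze|all
--seed N --outdir DIR [--config cfg.yaml]`) and usable as a library:

```python
from octlayers import (CohortParams, generate_cohort, denoise,
                       trim_optic_disc, segment_layers, locate_fovea,
                       partition_zones, compute_record)

scan = generate_cohort(CohortParams(n_eyes={"normal": 1, "NPDR": 0, "PDR": 0}))[0]
img, offset = trim_optic_disc(denoise(scan.image))
layers = segment_layers(img)                       # four boundary curves
fovea = locate_fovea(layers)
zones = partition_zones((0, layers.end), fovea.column, "horizontal",
                        disc_side=scan.covariates["disc_side"])
record = compute_record(layers, zones)             # 18 biomarkers
```

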