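# ccvoids

Widefield choriocapillaris flow-deficit quantification on en face OCT-angiography
images, with a ground-truth synthetic angiogram generator for validation.

## The problem

The choriocapillaris (CC) is the ~10-µm capillary monolayer of the inner choroid.
On an en face OCTA slab it appears as a bright granular flow texture interrupted
by dark **signal voids** (flow deficits) — regions with absent or
below-detection flow. Their total area, as a percentage of the analyzed region,
is a widely used biomarker of choroidal perfusion; in highly myopic eyes
(axial length > 26 mm) it is elevated, with a distinct topographic gradient
across the fundus. This package implements the full quantification chain for
widefield (12 × 12 mm, 500 × 500 px, five gaze-tiled scans per eye) imaging:

1. **Quality control** — scans with signal strength index (SSI) < 8 are excluded.
2. **Binarization** — the CC slab, normalized to [0, 1], is split into
   flow/void with the **Phansalkar local threshold**: for each pixel, with
   *m* and *s* the mean and standard deviation over a circular window of
   radius *R* (default 15 px ≈ 360 µm),

   *t* = *m* · (1 + *p*·e^(−*q*·*m*) + *k*·(*s*/*r* − 1)),  (k = 0.25, r = 0.5, p = 2, q = 10)

   and a pixel is flow iff its intensity exceeds *t*.
3. **Vessel exclusion** — the CC directly beneath major superficial retinal
   vessels is excluded (Otsu segmentation of the SCP slab, small-component
   removal, 2-px dilation) to suppress shadow/projection artifacts.
4. **Regions** — signal voids are measured inside: macular subfields (foveal
   1.5-mm, parafoveal 2.5-mm, perifoveal 6-mm diameters), a 500-µm-wide
   peripapillary annulus around the optic disc, and three 4.5-mm-diameter
   near/mid-peripheral circles tangent to the macula (superior, inferior,
   temporal).
5. **Metrics** — 8-connected void components per region (the ImageJ
   "Analyze Particles" equivalent): total void area % of analyzable area,
   void count, per-void areas in µm².
6. **Statistics** — Shapiro-Wilk normality gate, two-sided Mann-Whitney U
   group comparisons (median/IQR tables), Spearman correlation with choroidal
   thickness, one-way ANOVA between repeat sessions, and Monte-Carlo power
   for the study design.

No patient data ship with the package. The `synthetic` module generates CC/SCP
scan pairs and whole cohorts with *known* per-region void fractions, calibrated
to published group medians/IQRs, so every stage can be validated against ground
truth.

## Worked example

```python
from ccvoids import CohortGenParams, generate_cohort, run_cohort_analysis

params = CohortGenParams(n_myopic=5, n_control=5, pixels_per_side=250, seed=0)
eyes, truth = generate_cohort(params)          # 10 eyes, 5 gaze CC+SCP pairs each
report = run_cohort_analysis(eyes)             # full image + statistics chain
print(report.comparisons[["region", "myopic_median", "control_median",
                          "p_value"]].round(3).to_string(index=False))
```

prints

```
         region  myopic_median  control_median  p_value
          fovea         21.920          13.115    0.008
      parafovea         20.882          14.986    0.032
      perifovea         21.654          12.304    0.008
  peripapillary         23.545          18.056    0.056
periph_superior         24.552          12.898    0.008
periph_inferior         22.184          11.419    0.008
periph_temporal         20.576           9.751    0.008
         macula         21.450          12.522    0.008
      periphery         22.378          11.435    0.008
```

Each row is one analysis region: the group medians of total signal-void area
(percent of analyzable area, vessels excluded) and the two-sided Mann-Whitney
p-value. Even at this toy sample size the simulated myopic group shows the
expected ~8–10-percentage-point excess of flow deficits in every region
(exact-test p-values are bounded below by the 5-vs-5 design). `macula` and
`periphery` are analyzable-area-weighted totals of their subfields.

The same chain is available from the shell:

```bash
ccvoids simulate --n-myopic 30 --n-control 50 --seed 1 --out cohort/
ccvoids analyze cohort/ --out report/
ccvoids report cohort/ M001 --out overlays/   # QC overlay TIFFs
```

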