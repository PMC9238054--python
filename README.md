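# lsfg-superpix

Quantifying retinal and choroidal blood flow in laser speckle flowgraphy
(LSFG) scans, for studies that compare a treated eye against the patient's
own fellow eye — the motivating application is detecting early microvascular
injury after ¹²⁵I-plaque brachytherapy for uveal melanoma.

LSFG reports, per pixel, a *mean blur rate* (MBR, arbitrary units)
proportional to relative blood-flow velocity. The package implements two
complementary readouts of a composite MBR map plus the cohort statistics on
top of them:

1. **Peripapillary annulus analysis** (the standard LSFG readout). Two
   concentric circles are centred on the optic nerve head: the inner on the
   disc margin (radius *r*), the outer one disc radius further out (2*r*).
   Pixels in the ring are split by Otsu's 256-bin histogram threshold into
   a high-flow compartment, mean **MV** (superficial retinal arterioles and
   venules), and a low-flow compartment, mean **MT** (choroidal tissue).
2. **Whole-scan superpixel analysis.** The full frame is partitioned into
   ≈1500 SLIC superpixels (compactness 50); each superpixel is summarised
   by its mean MBR and assigned to one of five categorical flow ranges —
   <5, 5–10, 10–15, 15–20, ≥20 AU. The headline measures are
   **%superpixels ≥ 20** (retinal-vessel flow area) and
   **%superpixels < 5** (lowest choroidal flow area).
3. **Paired-eye cohort statistics.** Per-eye values are the means of three
   repeat scans. The model runs paired two-tailed t-tests (irradiated vs
   fellow eye), per-patient differences, OLS regressions of each measure on
   time from treatment (slope β per month with its p), ocular perfusion
   pressure OPP = ⅔·MAP − IOP with MAP = DBP + (SBP − DBP)/3, and a
   two-tailed Spearman correlation matrix over measures and treatment
   covariates.

Because no patient LSFG dataset is publicly available, the package ships a
fully seeded synthetic cohort generator: paired eyes × 3 scans, branching
vessel trees over a spatially correlated choroidal background, a high-flow
disc, undefined pixels, and a programmable irradiation effect
m(t) = max(m_min, 1 − k·t) that scales the treated eye's flow down with
months from treatment while the fellow eye stays flat.

## Worked example

```python
from lsfg_superpix import CohortFlowModel
from lsfg_superpix.synthetic import (
    CohortGeometry, EffectModel, generate_cohort, to_cohort_patients,
)

geom = CohortGeometry.for_shape((64, 128))   # reduced frame, same composition
entries = generate_cohort(8, EffectModel(), seed=42, geometry=geom)
model = CohortFlowModel.from_cohort(
    to_cohort_patients(entries, geom),
    n_superpixels=geom.matched_n_superpixels(),
)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Paired two-tailed t-tests (irradiated vs fellow eye)
----------------------------------------------------------------
  measure       t   p_value  n  mean_irradiated  mean_fellow  n_decreased
       mv  -8.039 8.834e-05  8            12.14        24.84            8
       mt  -7.196 0.0001781  8            4.709        9.689            8
 pct_ge20  -14.31 1.938e-06  8           0.7674         9.03            8
  pct_lt5   5.246  0.001191  8            53.05          3.9            0

Linear regression vs time from treatment (slope per month)
----------------------------------------------------------------
 measure      group      slope  intercept  p_value  n
      mv irradiated   -0.09187      19.98 0.002398  8
      mv     fellow -0.0005942      24.89   0.6074  8
 pct_lt5 irradiated     0.5505       6.06 0.001686  8
 pct_lt5     fellow  3.937e-05      3.897   0.9961  8
```

Reading it: every one of the 8 simulated patients shows lower retinal
vessel flow (MV, −8 t-statistic) and a smaller high-flow area (pct_ge20)
in the treated eye; the lowest-flow area (pct_lt5) rises from 3.9% to 53%
of superpixels; treated-eye measures drift with time from treatment while
fellow-eye slopes are flat and non-significant — the injury the generator
programmed, recovered by the analysis.

The same pipeline runs from the shell:

```bash
lsfg-superpix simulate --n-patients 25 --seed 7 --out cohort/ --dialect csv
lsfg-superpix analyze --cohort cohort/cohort.csv --scans cohort/ --out results/
```

`analyze` writes tidy CSV tables (per-eye measures, paired tests,
regressions, Spearman matrix in long format, five-range histograms), a
text summary, figures (paired scatter, per-patient difference bars,
flow-vs-time trends, correlation heatmap) and a manifest recording the
seed and config hash.

## Layout

| module | contents |
| --- | --- |
| `lsfg_superpix.synthetic` | effect model, vessel-tree/scan/cohort generators |
| `lsfg_superpix.scan_io` | CSV + float-TIFF scan dialects, cohort tables |
| `lsfg_superpix.peripapillary` | annulus geometry, Otsu MV/MT split |
| `lsfg_superpix.superpixel` | SLIC segmentation, flow ranges, range maps |
| `lsfg_superpix.perfusion` | MAP and OPP arithmetic |
| `lsfg_superpix.stats` | paired t, OLS vs time, Spearman matrix |
| `lsfg_superpix.model` | `CohortFlowModel` / `CohortFlowResults` + plots |
| `lsfg_superpix.studies` | replicate recovery and type-I error studies |
| `lsfg_superpix.pipeline`, `.cli` | end-to-end runs, `lsfg-superpix` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
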