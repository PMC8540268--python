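# peritex

Texture analysis of **peritumoral breast adipose tissue** on FDG PET/CT for
predicting axillary lymph-node metastasis.

Breast cancer cells metabolically reprogram nearby adipocytes, and that
reprogramming shows up on PET as a more heterogeneous FDG-uptake pattern in
the fat around the tumour. `peritex` is a reusable pipeline for quantifying
that heterogeneity and evaluating it as a diagnostic marker:

1. **ROI construction** — from a paired SUV/HU volume and a tumour mask, the
   peritumoral region is the tissue within 10 mm of the tumour margin
   (Euclidean distance in physical mm on the native grid), restricted to the
   adipose CT window −200 … −50 HU (inclusive), with a configurable guard
   distance / SUV cap against tracer spill-in from the hot tumour. A mirrored
   volume across the midsagittal plane gives a contralateral reference region.
2. **Texture features** — 38 features of the discretised SUV field over the
   adipose mask: 7 first-order (min, max, mean, SD, skewness, kurtosis,
   histogram entropy), 6 GLCM (homogeneity, energy, contrast, correlation,
   entropy, dissimilarity), 3 NGLDM (coarseness, contrast, busyness),
   11 GLRLM and 11 GLZLM features. GLCM entropy,
   −Σᵢⱼ p(i,j) log₂ p(i,j) over the pooled symmetric co-occurrence matrix
   (distance 1, 13 directions), is the headline marker.
3. **Diagnostic statistics** — Mann–Whitney AUC with DeLong confidence
   intervals, Youden-index cutoffs with sensitivity/specificity/PPV/NPV,
   paired DeLong tests with Bonferroni adjustment, combination stratification
   (texture cutoff × node finding), and the classical group-comparison
   battery (paired/two-sample t, Kruskal–Wallis with Dunn post-hoc, Spearman,
   chi-square).
4. **Synthetic phantoms and cohorts** — because no patient data ship with the
   package, a generator produces paired SUV/HU digital phantoms (HU-banded
   breast slabs, a spheroid tumour, a one-dial spatially correlated
   heterogeneity field in the fat) and feature-level cohorts drawn from the
   class-conditional group statistics of the clinical study this pipeline
   models, so every stage is testable end to end.

Intended users: nuclear-medicine / radiomics researchers who want a
transparent, fully tested reference implementation of this analysis rather
than a GUI workstation workflow.

## Worked example

Simulate a 326-patient cohort whose per-patient GLCM entropy is drawn from
the four visual-read outcome groups (TN n=194: 2.79±0.78, FN n=55:
3.48±0.72, TP n=64: 4.05±0.76, FP n=13: 2.79±0.55; metastatic = TP∪FN),
then evaluate the marker:

```python
from peritex import CohortSimSpec, simulate_feature_cohort, roc_summary, stratify_combination

df = simulate_feature_cohort(CohortSimSpec(rng_seed=42))
s = roc_summary(df["glcm_entropy"].to_numpy(), df["label_metastasis"].to_numpy())
print(f"AUC {s.auc:.3f} ({s.ci_low:.3f}-{s.ci_high:.3f}), cutoff {s.cutoff:.2f}")
print(f"sens {s.sensitivity:.1f}%  spec {s.specificity:.1f}%  PPV {s.ppv:.1f}%  NPV {s.npv:.1f}%")
```

prints

```
AUC 0.807 (0.757-0.857), cutoff 3.21
sens 74.8%  spec 75.4%  PPV 63.6%  NPV 83.9%
```

— one replicate's AUC for discriminating metastatic patients, its DeLong 95%
CI, and the operating point chosen by the Youden index. Combining the
texture cutoff with the visual node reading stratifies risk strongly:

```python
tab = stratify_combination(df["glcm_entropy"], s.cutoff, df["visual_read"], df["label_metastasis"])
print(tab.round(1).to_string(index=False))
```

```
feature_stratum node_finding  metastatic  total  rate_pct
     <= 3.21366     negative          21    167      12.6
     <= 3.21366     positive           9     19      47.4
      > 3.21366     negative          34     82      41.5
      > 3.21366     positive          55     58      94.8
```

Patients with a positive node reading *and* high peritumoral-fat entropy are
almost all metastatic; double-negative patients rarely are.

The full imaging pipeline (phantoms → segmentation → 38 features → ROC
tables → Markdown report) runs from the command line:

```bash
peritex run-all --seed 5 --out demo/
peritex simulate --mode feature --seed 1 --out sim/   # table-only cohort
peritex segment --suv suv.nii.gz --hu hu.nii.gz --tumor-mask tumor.nii.gz --out seg/
peritex extract --suv suv.nii.gz --hu hu.nii.gz --mask seg/peritumoral_at.nii.gz --out features.csv
peritex analyze --cohort sim/cohort.csv --out analysis/
```

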