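# mplesion

Computer-aided segmentation and diagnosis of breast lesions from
co-registered multiparametric PET/MRI — dynamic contrast-enhanced MRI
(DCE-MRI), diffusion-weighted imaging (DWI/ADC) and ¹⁸F-FDG-PET.

The package is aimed at researchers in quantitative breast imaging who
want to study *which* imaging modalities and features carry diagnostic
information. It provides:

* **Voxel-wise lesion segmentation** — a random forest over a 62-feature
  per-voxel table (26 DCE frame intensities, 25 time-normalised frame
  differences, the normalised enhancement sum, pre/peak/post
  high-resolution intensities and their differences, DWI b0/b850/ADC, and
  PET uptake), with a training-set DSC-maximising probability threshold
  and 6-connected-component post-processing.
* **Lesion-level benign/malignant classification** — a 143-feature vector
  per lesion: the characteristic kinetic curve (CKC, the fastest-enhancing
  fuzzy-c-means cluster-centre curve, 25 points + 21 four-frame
  differences), the parameters and summaries of a kinetic regression
  model, 6 blocks of 13 Haralick statistics from 128-bin 26-neighbour
  spatial and spatio-temporal grey-level co-occurrence matrices, the
  lowest-ADC / highest-PET 5-cluster centres, and shape descriptors.
* **Feature-contribution analysis** — Gini importance and
  minimum-redundancy-maximum-relevance (mRMR) rankings, incremental
  top-k performance curves, and modality-ablation experiments, all under
  leave-one-out cross-validation with in-fold ranking (no leakage).
* **A seeded synthetic phantom cohort** that emulates the study inputs
  with known ground truth: spherical lesions with class-specific
  enhancement kinetics, reduced ADC and elevated PET uptake in malignant
  lesions, vessel-like enhancing distractors, and additive noise.

## The kinetic model

Lesion contrast enhancement is modelled as an asymmetric generalised
logistic function times an exponential envelope:

```
C(t) = G · (1 − (1 + (2^α − 1) · exp((t − t½)/τ))^(−1/α)) · exp(β · t^k)
```

with scale `G`, asymmetry `α`, steepness `τ`, half-maximum time `t½`, and
washout parameters `β`, `k`. Fast wash-in (small `t½`, `τ`) followed by
washout (`β < 0`) is the malignant pattern; slow persistent enhancement
(`β = 0`) the benign one. The fitted curve yields the summaries `AuC`,
`Cmax`, `Tmax`, `T1/2` and `MDER` (maximum analytic derivative) over a
7-minute window from contrast arrival.

## Worked example

```python
import mplesion as mp

config = mp.PhantomConfig(n_patients=6, seed=7)
cohort = [study for study, _ in mp.make_cohort(config)]
metrics = mp.loocv_segmentation(cohort, seed=0)
lesions = metrics[metrics.lesion_id > 0]
print(f"mean DSC {lesions.dsc.mean():.3f}, "
      f"detected {int(lesions.detected.sum())}/{len(lesions)}")
```

prints

```
mean DSC 1.000, detected 6/6
```

i.e. on this high-contrast noise-calibrated phantom cohort every lesion is
detected and the predicted masks coincide with the annotations (on
clinical data the same harness reports the usual fractional DSC). The
scripts under `examples/` walk through each capability — phantom
simulation, kinetic curve fitting, texture analysis, segmentation LOOCV,
and classification with feature ranking — and print the numbers they
compute together with what they mean.

A thin CLI wraps the same functions for shell use:

```bash
mplesion simulate --out scratch/cohort --seed 1 --n-patients 4
mplesion segment --cohort scratch/cohort --out scratch/seg.csv
mplesion classify --cohort scratch/cohort --out scratch/cls.json --repeats 3
```

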