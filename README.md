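# radstab

Robustness of CT density and texture features across dose and reconstruction
conditions.

## The problem

Radiomic quantification of lung nodules — first-order HU statistics and
gray-level co-occurrence (GLCM) texture features computed inside a 3D
contour — is increasingly used for diagnosis and treatment response. But CT
images of the *same* object change substantially with acquisition dose and
reconstruction kernel: sharper kernels and lower dose mean more noise, with a
different spatial texture. If a feature changes more between two scanner
settings than it changes between two contours of the same image, observed
"changes" in a patient may reflect physics, not physiology.

`radstab` is a tested implementation of that robustness analysis for people
who work on radiomics stability: the complete feature battery, the Q
stability statistic, condition/feature rankings — plus a synthetic CT
generator (water phantom and heterogeneous lung nodules over dose × kernel
grids) so the entire pipeline runs and is testable without patient data.

## What it computes

**Feature battery** (80 values per contour):

* 8 histogram features over the raw HU values in the ROI Ω: mean
  μ = (1/|Ω|) Σ I(x), median, standard deviation σ, variance σ², skewness,
  kurtosis, entropy −Σ Pᵢ log₂ Pᵢ (one bin per integer HU) and energy Σ Pᵢ².
* 18 GLCM features — mean μₓ, variance σₓ², energy/angular 2nd moment ΣP²,
  entropy −ΣP ln P, contrast Σ(i−j)²P, correlation, dissimilarity,
  homogeneity, information correlations A and B, maximal correlation
  coefficient (second eigenvalue of U(i,j) = Σₖ P(i,k)P(j,k)/(Pₓ(i)P_y(k))),
  and the sum/difference distribution statistics — each summarised by its
  **mean** and **range** over the 13 canonical 3D offsets (26-connectivity
  modulo antipodal symmetry), at 25 and 32 quantization levels
  (equal-width bins over the ROI's [min, max]).

**Q statistic.** For feature f and condition r versus the reference
condition 0, with contours Φᵢ drawn on the reference image and repeat
contours Φᵢ′ for a subset of cases:

    Q(f; r) = S( f_r(Φᵢ) − f₀(Φᵢ) ; i = 1…N ) / S( f₀(Φᵢ) − f₀(Φᵢ′) ; i = 1…M )

where S is the (sample) standard deviation. Q ≤ 1 means the condition change
perturbs the feature no more than re-contouring does. Features are ranked by
the number of conditions with Q ≤ 1; conditions by the number of features
with Q ≤ 1 (ties broken by descending max Q).

**Synthetic study.** A water-phantom grid (3 dose levels × 8 kernels, four
FBP B10f–B70f and four iterative I26f\5–I70f\1) and a nodule grid (100%,
25%, 10%, 3% of clinical dose × B45f, I44f\3, I50f\3; reference B45f@100).
Kernels are modelled by an in-plane noise-correlation scale and a noise
gain; noise scales as 1/√dose; reduced doses are simulated by image-domain
correlated-noise addition. Nodules are ellipsoids (7–46 mm, mean 18 mm) with
anisotropic multi-scale internal texture, contoured by Otsu-initialised
segmentation; repeat contours are seeded boundary flips.

## Worked example

```python
from radstab import StudyConfig, run_study

result = run_study(StudyConfig(mode="nodule", n_cases=12, n_repeat=6, seed=1))
print(result.condition_ranking[["rank", "condition", "mean_q", "n_q_le_1"]].head(3))
print(result.condition_ranking[["rank", "condition", "mean_q", "n_q_le_1"]].tail(3))
```

prints (from `examples/full_study.py`):

```
 rank  condition   mean_q  n_q_le_1
    1 I44f\3@100 0.666901        65
    2 I50f\3@100 0.709242        64
    3  I44f\3@25 0.714150        55
 ...
    9     B45f@3 1.791804        26
   10   I44f\3@3 1.702821        26
   11   I50f\3@3 1.549020        25
```

Reading: under the full-dose iterative reconstructions, 64–65 of the 80
features stay within re-contouring variability of the reference (Q ≤ 1); at
3% dose every condition ranks last with only ~25 robust features, i.e. most
texture features there say more about the acquisition than about the nodule.
The histogram mean stays robust under every condition (its Q never reaches
1), because CT numbers are calibrated to water and zero-mean noise averages
out over the ROI.

Other entry points: `examples/extract_features.py` (the 80-row battery for
one nodule), `examples/water_phantom_noise.py` (noise vs dose/kernel),
`examples/q_statistic.py` (Q recovers an engineered noise ratio: median Q =
0.504, 1.009, 2.017, 4.034 for true ratios 0.5, 1, 2, 4). A thin CLI wraps
the same pipeline: `radstab run --mode nodule --seed 1 --out out/`, with
`simulate` / `extract` / `analyze` / `report` stages for on-disk studies.

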