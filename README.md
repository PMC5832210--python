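# nodal-petrad

FDG-PET radiomics of primary tumors **and metastatic lymph nodes** for
overall-survival prognosis in node-positive NSCLC, built as a tested,
reusable pipeline and exercised end-to-end on synthetic PET phantoms
with known ground truth.

Most PET prognostic models look only at the primary tumor. This package
implements the full workflow needed to ask whether the metabolic
signal of the metastatic lymph nodes adds prognostic value:

1. **Feature extraction** — 118 features per region of interest, in four
   families: 16 first-order SUV statistics, 13 shape/size descriptors,
   45 intensity-volume-histogram (IVH) descriptors, and 44 texture
   features from grey-level co-occurrence (22), run-length (11) and
   size-zone (11) matrices. SUVs are discretized with a fixed bin width
   *W* = 0.5:

   ```
   I_D(x) = ceil(I(x)/W) − min_ROI ceil(I(x)/W) + 1
   ```

   Voxels are neighbors under 26-connectivity; GLCM and GLRLM are
   averaged over the 13 unique directions at distance one voxel.

2. **Nodal structures** — per patient, the individual node masks are
   combined into `LN_merged` (union of all nodes, the structure actually
   modeled), `LN_volume` (largest node) and `LN_max` (most FDG-avid
   node), plus tumor load = tumor volume + node volume.

3. **Feature pre-selection** — robustness: keep features with
   intraclass correlation ICC(2,1) > 0.85 in both a test-retest and an
   inter-observer replicate-segmentation context; surrogacy: keep a
   merged-node feature only if it agrees with both single-node
   structures (ICC > 0.85 and Bland-Altman 95% limits of agreement
   within ±10%).

4. **Survival modeling** — univariable Cox screens; three prognostic
   models selected by 10-fold cross-validated LASSO-Cox (model 1: tumor
   features; model 2: node features; model 3: union), refit unpenalized;
   Harrell's C-index (0.5 random → 1 perfect) with 95% CI, internal and
   external; AIC = 2k − 2·log PL model comparison (lower preferred);
   penalized-spline log-linearity and Schoenfeld-residual proportional-
   hazards diagnostics.

Because the original patient images cannot ship with the code, the
`synthetic` module generates the study conditions: heterogeneous tumor
and 1–5 lymph-node blobs on a PET grid at 4.0728 × 4.0728 × 3 mm voxel
spacing, replicate segmentations for the ICC stage, and right-censored
Weibull survival whose log-hazard is linear in chosen ground-truth
features. Every stage is therefore testable against known truth.

## Worked example

The numbered drivers under `analysis/` run the whole study (262
development + 50 validation synthetic patients, seed 17) and write
their tables under `results/`:

```bash
python analysis/01_simulate_and_extract.py
python analysis/02_preselect_features.py
python analysis/03_fit_models.py
python analysis/04_validate_and_report.py
```

Output of the run used while developing this package:

```
dev: 262 patients, 183 deaths (30% censored), median follow-up 16.3 months
robustness: 73/118 tumor features pass ICC > 0.85 in both contexts
surrogacy: 2/73 merged-node features are surrogates of both the largest and most active node
model tumor:    internal C-index 0.556 [0.511-0.601], AIC 1861.1
model ln:       internal C-index 0.722 [0.683-0.761], AIC 1765.7
model combined: internal C-index 0.734 [0.696-0.771], AIC 1761.2
model combined: external C 0.706   model ln: external C 0.695   model tumor: external C 0.646
AIC ordering (preferred first): combined < ln < tumor
```

Reading: the ground truth of this synthetic cohort puts most of the
prognostic signal in the nodes (merged-node mean SUV and GLCM entropy,
plus a weaker protective tumor run-length effect), and the pipeline
recovers exactly that structure — the tumor-only model is barely better
than random, the node model discriminates well, and adding tumor
information to the node model gives the best (lowest-AIC) fit. The
common-descriptor screen shows the same asymmetry patient-wise: tumor
SUV descriptors are not significant (p ≈ 0.2–0.6, C ≈ 0.51–0.53) while
every node SUV descriptor is strongly prognostic (p < 0.001,
C ≈ 0.73).

The same stages are scriptable through one CLI
(`nodal-petrad simulate|extract|preselect|model|validate|run`), e.g.

```bash
nodal-petrad extract --image pat_suv.nii.gz --mask pat_tumor.nii.gz --out features.csv
nodal-petrad run --config run.yaml
```

and accept user-supplied NIfTI images and masks in place of phantoms.

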