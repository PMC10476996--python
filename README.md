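# oarsort

Image-based classification of radiotherapy organ-at-risk (OAR) delineations
by delineation guideline, plus a demonstration that mixed-guideline training
data degrades segmentation quality.

Structures are classified from two aligned 3D channels: the normalized CT and
an **AddMap** — `(body mask + structure mask) / 2`, i.e. 1 where body and
structure overlap, 0.5 inside the body only, 0 in the background. A per-fold
classifier ensemble votes on every structure; an optional keyword list forces
suspicious structure names (e.g. containing `ptv`, `ring`, `dose`) to the
catch-all class `Other`. Everything runs on synthetic pelvic phantoms, so no
clinical data is required.

## Modules

| module | purpose |
| --- | --- |
| `oarsort.rtstruct_io` | CT + structure-set I/O (NIfTI canonical; minimal DICOM CT/RT-STRUCT codec), body detection, sorted copies |
| `oarsort.preprocess` | z-score normalization, resampling, body masking/cropping, AddMap, slice-cap eligibility, structure-centered windowing, padding/downscale |
| `oarsort.phantom_factory` | synthetic pelvic CT phantoms with organs in two guideline variants + nuisance structures, cohort writer with label manifest |
| `oarsort.backbone` | compact 3D CNN (numpy, hand-written backprop, Adam) behind a pluggable backbone contract |
| `oarsort.classifier_training` | balanced class weights, weighted cross entropy, custom precision (sum of non-`Other` precisions), augmentation, patient-level 5-fold training |
| `oarsort.guideline_inference` | per-fold prediction, majority vote, name exclusion, batch classification with report + sorted copies |
| `oarsort.eval_metrics` | classification report / confusion matrices; DSC, HD95, MSD with superior truncation; Wilcoxon signed-rank |
| `oarsort.mixed_guideline_demo` | coherent-vs-mixed guideline segmentation experiment on phantoms |

## CLI

```bash
oarsort make-phantoms --n 25 --seed 0 --out cohort/
oarsort train --input cohort/ --profile phantom --seed 0 --out model/
oarsort classify --model model/ --input cohort/ --profile phantom \
    --exclusion on --out predictions/
oarsort demo-mixed --seed 0 --out demo/
```

`classify` writes `predictions.tsv` (one row per structure with per-fold
labels, mean probabilities, voted and final label) and copies each structure
file under `predictions/sorted/<final label>/<patient>/`. `demo-mixed` writes
per-case DSC/HD95/MSD tables, cohort summaries and Wilcoxon p-values
comparing coherent against mixed training for both guidelines.

Preprocessing profiles: `bowel` (184×280×96 voxels at 2×2×3 mm, 96-slice cap
= 288 mm supported extent), `pelvis` (200×328×96), and the desk-scale
`phantom` profile (48×64×24 at 4×4×6 mm).

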