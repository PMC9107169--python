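# ctqc — automated quality control of CT series

Clinical-trial imaging cores and PACS pipelines receive thousands of CT
series whose first quality check is mundane but mandatory: *is this the body
part the protocol asked for, and was contrast given?* `ctqc` automates that
check. It converts each 3D CT series into 2D representative images,
classifies **body part** (brain, neck, chest, abdomen, abdomen–pelvis) and
**contrast enhancement** (present / absent) with per-plane classifiers, and
combines them by soft voting into a batch QC report with thumbnails an
analyst can audit at a glance.

## Method

For a volume *V* indexed (z, y, x), three conversion methods produce a 2D
representative image in each of the three anatomical planes (nine images per
series):

* **MIP** — maximum intensity projection: per-ray max along the collapsed axis;
* **AIP** — average intensity projection: per-ray mean;
* **mid-plane** — the single central slice, index ⌊n/2⌋.

Projections are computed in Hounsfield units, windowed with level 50 HU /
width 1000 HU to [0, 1], rescaled to 512 × 512, written as 8-bit grayscale
PNG, and replicated into three identical channels (299 × 299 × 3) as
classifier input.

Each of two modules combines m = 3 per-plane classifiers by **soft voting**:

```
y = argmax_i  Σ_{j=1..m} p_ij
```

where *p_ij* is member *j*'s probability for class *i* (i ranges over 5
body-part classes or 2 contrast classes). The body-part module votes over
the three **MIP** classifiers; the contrast module over the three
**mid-plane** classifiers. Sums are reported unnormalized; ties resolve to
the lowest class index and are flagged.

The per-plane classifier is a compact seeded convolutional network (three
conv/ReLU/max-pool blocks, global average pooling, softmax) implemented on
numpy and trained with Adam on images expanded eightfold by the
rotation (±20°) / horizontal-flip / vertical-flip augmentation set. Any
object exposing `predict_proba` over model inputs can stand in as a member.

Because clinical data cannot ship with the package, a built-in **phantom
generator** produces labeled synthetic CT series for all ten
(body part × contrast) cells, with class-separating geometry and Gaussian HU
noise, written as ordinary DICOM series. See `docs/methods.md` for the full
model and its limitations.

## Worked example

A complete session on synthetic phantoms (3 series per cell → 30 series,
64 × 96 × 96 voxels, 10 HU noise):

```sh
ctqc generate-phantoms --n-per-class 3 --noise-sigma 10 --seed 7 --out data
ctqc train --manifest data/manifest.csv --model-dir models --seed 7
ctqc run data --model-dir models --out report
ctqc evaluate --manifest data/manifest.csv --report report/qc_report.json --out metrics
```

prints, after about two minutes of CPU training:

```
wrote 30 series (3 per cell) to data
wrote 6 model artifacts to models
classified 30 series; report in report
overall 100.0% | body part 100.0% | contrast 100.0%
```

`report/qc_report.csv` holds one row per series — predicted body part,
contrast state, tie flags, and the two audit thumbnails (mid-coronal and
MIP-coronal PNG):

```
series_id,body_part,contrast,body_tie,contrast_tie,thumbnail_mid,thumbnail_mip
phantom_abdomen_ce_s70056_r0,abdomen,contrast,0,0,thumbnails/..._MID_coronal.png,thumbnails/..._MIP_coronal.png
```

`report/qc_report.json` additionally records every member's probability
vector, so each vote can be audited. `metrics/overall.json` summarizes
accuracy; *overall* counts a series correct only when **both** labels match:

```json
{
  "overall_accuracy_pct": 100.0,
  "body_part_accuracy_pct": 100.0,
  "contrast_accuracy_pct": 100.0,
  "n_series": 30
}
```

The library API mirrors the CLI: `generate_labeled_volumes`,
`train_two_module_system`, `run_imageqc`, `evaluate_dataset`.

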