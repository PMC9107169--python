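# Methods

## Pipeline model

A CT series is treated as a calibrated HU volume `voxels[z, y, x]` with
slices sorted ascending by longitudinal position, so classification is
invariant to file naming and transfer order. Two independent decisions are
made per series — body part (5 classes) and contrast enhancement (2
classes) — each by a soft-voting ensemble of three per-plane classifiers:

    y = argmax_i Σ_{j=1..3} p_ij

The body-part module uses the MIP projections (bone and lung silhouettes
carry the anatomy), the contrast module the mid-plane slices (vascular
enhancement is a local, interior feature that projections dilute). Summed
scores are reported unnormalized in [0, m]; a tie resolves to the lowest
class index and sets a tie flag in the QC result, so downstream consumers
can treat tied calls as low-confidence rather than silently trusting them.
By default one global contrast triple serves all body parts; per-body-part
triples with routing by the predicted body part are supported
(`per_body_part=True`), since contrast appearance differs by region — with
a `"global"` fallback triple for unrouted labels.

## Preprocessing

* **Projection** in raw HU: MIP = per-ray max, AIP = per-ray mean, MID =
  slice ⌊n/2⌋ (0-based; a fixed convention for even n). Axial collapses z,
  sagittal x (left–right), coronal y (anterior–posterior). No spacing-aware
  resampling is performed before projection; rays follow the voxel grid.
* **Windowing** after projection: `clamp((v − (level − width/2))/width, 0, 1)`
  with level 50 HU, width 1000 HU — a window spanning [−450, 550] HU that
  keeps air black, saturates bone, and spreads soft tissue and enhanced
  vessels over mid-grays. Windowing after projection preserves MIP
  semantics (the max is taken in HU, not in display units).
* **Resize** to 512 × 512 by bilinear interpolation (value-range
  preserving; constants stay constant) for the PNG export; the classifier
  input is formed from that image by a further bilinear resize and
  replication into three identical channels at 299 × 299.

## Phantom generator

The generator emulates only what the task needs: ten separable
(body part × contrast) cells on an air background (−1000 HU) with soft
tissue 40 HU, lung −700 HU, bone 700 HU, liver 60 HU (120 HU when
enhanced), vessel 300 HU — round values inside physiologic ranges that
remain separated under the 50/1000 window. Geometry per class: brain =
ellipsoidal skull shell around soft tissue with short longitudinal extent;
neck = narrow cylinder with a posterior bone column; chest = broad torso
with two lung ellipsoids and a rib shell; abdomen = broad torso with a
liver-like blob; abdomen–pelvis = abdomen plus paired iliac wings in the
caudal third. Contrast adds an axial vessel tube and raises the liver.
Gaussian HU noise (default σ = 10 HU) is added last and clamped to the
12-bit CT storage range [−1024, 3071].

A rule-based oracle (lung-component count, body extent, in-plane area,
caudal bone maximum, soft-tissue HU maximum) recovers both labels for every
generated phantom at σ ≤ 20 HU; the test suite asserts this, which
certifies that the classes are separable *before* any learning. Passing the
end-to-end tests therefore shows the pipeline is wired correctly — it does
**not** show the classifier would reach clinical accuracy: the phantoms
lack patient variability, pathology, metal artifacts, scanner spectra,
oblique orientations and field-of-view truncation. Defaults: grid
64 × 96 × 96 at (2, 1, 1) mm spacing, 10 HU noise; per-series seeds are
`(master·10007 + ordinal) mod 2³¹`, so one integer reproduces a corpus.

## Training

Augmentation expands each training image exactly eightfold:
{identity, R, H, V, R∘H, R∘V, H∘V, R∘H∘V}, with one rotation angle drawn
uniformly from ±20° per source image (seeded) and bilinear rotation filling
exposed corners with 0 (air after windowing). Held-out and tuning images
are never augmented, and cross-validation augments training folds only —
the suite checks that no transformed copy of a test image reaches training.

Stratified k-fold (default k = 5) guarantees exactly-once test membership
and per-class fold counts differing by ≤ 1; classes smaller than k fall
back to seeded round-robin with a warning.

The reference classifier is a seeded numpy CNN: three 3 × 3 conv blocks
(8/16/32 filters, ReLU, 2 × 2 max-pool), global average pooling, softmax;
~6k parameters. Defaults: 64 × 64 input (bilinearly reduced from the
299 × 299 model input — the class-separating geometry survives easily at
this scale and CPU training stays in minutes), Adam at learning rate 1e-3,
batch 16, up to 30 epochs with early stop once training accuracy holds at
100% with loss < 0.05 for two consecutive epochs. The backbone is pluggable
behind the `PlaneModel` probability contract (non-negative vector summing
to 1 within 1e-6); a `pretrained_backbone` config value is reserved but no
pretrained weights are bundled. Larger inputs and a transfer-learning
backbone would be the natural upgrades for clinical data.

## Evaluation conventions

Per-class precision, recall and F1 use the standard one-vs-rest
definitions; overall accuracy is correct/total. Aggregates are
macro-averaged by default (micro is available via `metrics(cm,
average="micro")`). Ratios with zero denominators are reported as 0 and
flagged rather than propagating NaN. Values are kept unrounded internally
and rounded half-up only at report rendering. Dataset-level *overall*
accuracy counts a series correct only when both labels match, so it is
bounded above by each module's own accuracy.

## Validation experiment

`ctqc.validation.held_out_phantom_validation` trains the two-module system
on 10 phantoms per cell (100 series) and scores 5 per cell (50 series)
generated with offset seeds, at the generator defaults. Both modules
recover 100% of labels; `scripts/acceptance.py` reports the body-part
figure. Problem sizes were chosen once as the package's desk-scale study
conditions.

## Known limitations

* Single-frame axial DICOM only; no compressed transfer syntaxes, oblique
  orientations, multi-frame objects or non-CT modalities.
* Non-uniform slice spacing is recorded but not resampled.
* No probability calibration or abstention: every series receives a label;
  only tie flags mark degenerate votes.
* The numpy CNN is a correctness-first reference, not a performance
  implementation; it is deterministic single-threaded but makes no
  cross-platform bit-reproducibility guarantee beyond identical
  library builds.
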