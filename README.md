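# wbcseg

Segmentation and classification of white blood cells (WBCs, leukocytes) in
stained blood-smear microscope images.

Peripheral-blood smear analysis underpins screening for acute lymphoblastic
leukemia (ALL): an expert inspects stained WBCs and judges whether they are
healthy or blasts. `wbcseg` implements the image-analysis half of that
workflow for researchers building computer-aided diagnosis pipelines:

* **Segmentation** by *triple thresholding*: the RGB image is converted to
  HSV and the hue plane extracted (basophilic nuclear stain renders WBC
  nuclei purple — high hue — against pale red erythrocytes and plasma).
  Gaussian smoothing and Otsu thresholding are applied three times; each
  round removes one pixel population (erythrocytes, their boundary blends,
  residual clutter) and restricts the next round's histogram to the
  survivors. A 13×13 morphological opening with two iterations removes small
  objects, and cell contours can be traced back onto the original image.
* **Evaluation**: pixel accuracy, structural similarity (SSIM) and the Dice
  similarity coefficient between predicted and ground-truth masks, plus
  accuracy/precision/recall from TP/TN/FP/FN confusion counts.
* **Classification**: a minimal transfer-learning head — resize to 150×150,
  normalize to (−1, 1), extract features with any pluggable backbone, global
  average pooling, then a single sigmoid dense unit (d + 1 = 2049 trainable
  parameters at feature depth 2048). A prediction over 0.5 is read as
  *healthy*, otherwise *ALL*.
* **Synthetic smears**: a seeded generator producing ALL-IDB2-like scenes
  (one WBC among elliptical RBCs, uneven illumination, blur, sensor noise)
  with pixel-exact WBC masks, so every stage is testable without access to
  the registration-gated ALL-IDB dataset.

Otsu's threshold is computed from its definition: the smallest `t` in
[0, 255] maximizing the between-class variance

```
σ_b²(t) = w₀(t) · w₁(t) · (μ₀(t) − μ₁(t))²
```

with class 0 the pixels ≤ t, and Dice is `2|A∩B| / (|A|+|B|) =
2TP / (2TP + FP + FN)`.

## Worked example

`examples/01_segment_synthetic_smear.py` builds one seeded scene (1 WBC,
15 RBCs, mild blur and noise), segments it and scores the result:

```
Per-round Otsu thresholds (hue, half-degree units):
  round 1: t= 73  kept 'above' side
  round 2: t=114  kept 'above' side
  round 3: t=124  kept 'above' side

Foreground pixels: 7123 (truth: 7706)
Pixel accuracy : 0.9912
SSIM           : 0.9642
Dice           : 0.9607
```

Round 1 splits the bimodal hue histogram between the pale red/pink
population (hue ≈ 9–17) and the purple WBC (hue ≈ 127–135) and keeps the
high-hue side; rounds 2–3 shave off the blur halo around the cell. A Dice of
0.96 means the predicted mask almost exactly overlaps the generator's
pixel-exact ground truth. `examples/02_batch_evaluation.py` repeats this
over 20 scenes and prints the mean-score table (accuracy 0.9905, SSIM
0.9662, Dice 0.9435 under default degradations); `03` trains the classifier
head; `04` writes a labelled dataset with the canonical 208/26/26-style
train/validation/test split.

The same operations are scriptable from the shell:

```bash
wbcseg simulate -n 10 --outdir smears --seed 1
wbcseg segment 'smears/scene_*[0-9].png' --outdir out
wbcseg evaluate eval_manifest.csv --outdir metrics --chart
wbcseg classify features.csv labels.csv --outdir clf --seed 1
```

Every command honors `--seed` and writes a `run_manifest.json` sufficient to
replay it bit-exactly.

## Scope notes

The pretrained backbone (e.g. InceptionV3) is *not* bundled: the head
accepts any feature extractor satisfying the `image -> FeatureMap` contract,
and a deterministic toy extractor (seeded random projection) is included for
tests and examples. Backbone fine-tuning, watershed splitting of touching
cells, stain normalization and vendor microscope formats are out of scope.
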