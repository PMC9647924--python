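# dentalchart

Automated charting of dental radiographs. Given grayscale radiographs
(panoramic, periapical, bitewing) and binary segmentation masks for
teeth, bone area, and the cementoenamel junction (CEJ) line, the
pipeline:

1. cleans the masks (Gaussian denoising of probability rasters,
   small-component removal, sliding-window connection of fragmented CEJ
   lines into a single polyline);
2. extracts per-tooth bounding boxes — contour extents on panoramics,
   four-point boxes (left/right tooth–CEJ intersections + root apex) on
   intraoral images;
3. assigns each extracted tooth an FDI number by multi-scale
   zero-normalized cross-correlation (ZNCC) matching against a labeled
   tooth repository, or against the patient's own panoramic radiograph,
   with majority voting over the top-10 match scores;
4. determines each intraoral radiograph's position (maxilla / mandible /
   bitewing) from bone-area and CEJ geometry and arranges a set of
   radiographs into the standard 3-row full-mouth-series (FMS) template;
5. measures radiographic bone loss (RBL) per tooth side and assigns
   2018-classification periodontal stages, producing a per-tooth report.

Segmentation models themselves are out of scope: any model can be
plugged in through the `SegmentationAdapter` interface (image → raw
tooth/bone/CEJ rasters). A seeded phantom generator
(`dentalchart.phantom`) renders synthetic radiograph-like cases with
gold masks, boxes, FDI labels, positions, and known bone-level
fractions, so the whole pipeline is testable end to end without any
clinical data.

## The core quantities

- **Matching score.** A tooth crop `T` resized by scale `s` is slid over
  a repository entry `E`; the score is the maximum zero-normalized
  cross-correlation over shifts, maximized over a scale grid
  (0.5–1.5, step 0.1). The crop's FDI number is the majority vote of the
  top *k* = 10 entries (ties broken by mean, then best, score).
- **Detection / numbering evaluation.** Predicted and gold boxes are
  paired greedily by descending Jaccard index (JI); a pair with JI > 0.7
  is a successful match. Detection precision = successful / detected,
  detection recall = successful / gold; numbering precision and recall
  use correctly numbered successful matches in the numerator.
- **Radiographic bone loss.** For landmarks CEJ point `c`, alveolar
  crest point `b`, and root apex `a` on one tooth side:

      RBL% = 100 · ⟨b − c, a − c⟩ / |a − c|²

  i.e. the crest offset projected on the CEJ→apex axis as a percentage
  of root length. Stages: RBL < 15% → Stage 1, 15% ≤ RBL ≤ 33% →
  Stage 2, RBL > 33% → Stage 3.

## Worked example

Everything below runs on synthetic phantom data generated on the fly.
Build a repository from three phantom panoramics, then chart a fourth
"patient" whose teeth were generated with a 25% bone-level fraction:

```bash
dentalchart simulate --seed 101 --out demo/case101
dentalchart simulate --seed 102 --out demo/case102
dentalchart simulate --seed 103 --out demo/case103
dentalchart simulate --seed 7 --bone-level 0.25 --out demo/patient
dentalchart build-repo demo/case101 demo/case102 demo/case103 --out demo/repo
# -> repository with 96 entries
dentalchart run demo/patient --repo demo/repo --out demo/out
```

`demo/out/evaluation.json` (predictions scored against the phantom's
gold annotations):

```json
{
 "detection_precision": 1.0,
 "detection_recall": 1.0,
 "n_detected": 52,
 "n_gold": 52,
 "n_successful": 52,
 "n_true_number": 52,
 "numbering_accuracy": 1.0,
 "numbering_precision": 1.0,
 "numbering_recall": 1.0,
 "position_accuracy": 1.0
}
```

All 52 intraoral teeth (32 from 14 periapicals, 20 from 4 bitewings)
are detected (JI > 0.7 against gold boxes), numbered correctly, and all
18 radiographs are positioned correctly. `demo/out/rbl_report.csv`
starts:

```
   image  fdi   side  rbl_percent  stage
pa_max_1   18 mesial        24.55      2
pa_max_1   18 distal        24.55      2
pa_max_1   17 mesial        23.28      2
pa_max_1   17 distal        23.28      2
```

The measured RBL of ~24.6% recovers the generator's 25% bone-level
fraction to within the raster quantization, and every site lands in
Stage 2 (15–33%), as it should. `demo/out/fms_template.json` holds the
3-row FMS arrangement (7 maxillary / 4 bitewing / 7 mandibular slots,
ordered patient-right to patient-left), with `fms_montage.png` as a
visual composite.

The same steps are available as library calls (`PhantomConfig`,
`generate_phantom_case`, `build_repository`, `chart_case`); see the
module docstrings.

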