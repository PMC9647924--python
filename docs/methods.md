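# Methods

This note documents the models, rules, and numerical choices behind
`dentalchart`, what the phantom generator does and does not emulate, and
the design decisions taken where the design was genuinely open.

## Pipeline model

The pipeline assumes three binary masks per intraoral radiograph —
tooth, bone area, and CEJ line — produced upstream by any segmentation
model (the `SegmentationAdapter` protocol is the only contact point;
phantom gold masks stand in throughout the test suite). All reasoning
downstream of segmentation is deterministic image analysis:

- **Mask cleaning** (`masks.clean_mask`): probability rasters are
  Gaussian-smoothed (σ = 1 px at 512×512) and thresholded at 0.5;
  strictly binary inputs skip the smoothing step, which makes the
  operation idempotent (smoothing a hard mask would erode corners on
  every pass without removing any noise). Components smaller than
  50 px are dropped; the threshold scales with image area if a
  different working resolution is used. These defaults were chosen to
  kill speckle without eroding thin root apices.
- **CEJ connection** (`masks.connect_cej`): an 8-column window slides
  across the mask; populated windows contribute their pixel centroid,
  and gaps up to 3 windows wide are bridged linearly. Longer gaps split
  the line; the longest segment is kept with a warning. The output has
  one point per covered column, so x is strictly increasing and, for
  the near-horizontal CEJ courses this is designed for, consecutive
  points are 8-connected.
- **Tooth extraction** (`extraction`): panoramic teeth are boxed by
  their contour extents. Intraoral teeth are boxed by four landmarks:
  the leftmost and rightmost points where the tooth contour crosses the
  CEJ polyline (crossings are interpolated between contour vertices
  whose signed distance to the line changes sign; a 3-row tolerance
  band catches grazing contacts) and the root apex (the contour's
  rootward y-extreme). The box is the axis-aligned extent of those
  points padded by 2 px, so it spans the root from CEJ to apex — the
  region bone-loss assessment needs. Merged mask components are not
  split: two touching teeth yield one box, a documented limitation.
  Bitewings are handled per half, split at the midline between the two
  CEJ branches.

## Numbering by multi-scale matching

Similarity is zero-normalized cross-correlation (ZNCC), maximized over
shifts and over a scale grid of 0.5–1.5 in steps of 0.1 applied to the
crop. ZNCC is invariant to affine intensity changes of either patch;
crops and entries are additionally histogram-equalized inside
`assign_number` to damp exposure differences between intraoral and
panoramic sources (`match_score` itself scores raw patches). For
tooth-sized patches the correlation surface is evaluated directly with
sliding windows, which is an order of magnitude faster than FFT-based
matching at these sizes and agrees with it to machine precision (both
are covered by tests, including a brute-force exhaustive-shift oracle).

The FDI decision is a majority vote over the top-10 entries by best
score; ties are broken by the larger mean score among tied labels, then
by the single best score, which makes the assignment invariant to
repository ordering.

In panoramic-view mode a transient repository is built from the
patient's own panoramic: extracted boxes are split into two rows at the
widest vertical gap between box centers, ordered left to right, and
mapped onto the arch sequences 18…11, 21…28 (maxilla) and 48…41, 31…38
(mandible). An inter-box gap wider than 1.5× the median gap advances
the sequence past the estimated number of missing teeth (gap divided by
median tooth pitch). Interior missing teeth are therefore handled;
missing teeth at the very ends of an arch are not detectable from gaps
alone and are a known limitation.

## Position and FMS arrangement

Position rules are applied in order: (a) two bone components whose
centroid rows differ by at least 20% of the image height → bitewing
(the separation requirement avoids classifying a split bone band as a
bitewing); (b) otherwise the largest bone component's centroid above
the CEJ mean row → maxilla; (c) below → mandible.

Rows of the FMS template are ordered by the mean arch-order index of
each radiograph's assigned FDI numbers, where arch order counts 0–15
from the patient's right within each arch (maxilla: universal − 1;
mandible: 32 − universal). Using one right-to-left key for both arches
keeps all three rows running patient-right → patient-left; a plain
ascending universal-number key would reverse the mandibular row. Using
the *mean* of the assigned numbers makes the ordering robust to a
minority of mis-numbered teeth in an image. Radiographs with zero
assignments are reported in an `unplaced` list rather than dropped;
overlapping tooth coverage between neighboring slots is kept and
flagged.

## Bone loss and staging

RBL is the projection of the CEJ→crest vector on the CEJ→apex axis,
as a percentage of the CEJ→apex length, clipped to [0, 100]. Landmarks
are localized rule-based from the masks: the CEJ point sits on the
polyline at the box's mesial/distal edge (2 px inset); the crest is the
first bone-mask pixel met walking the CEJ→apex ray (sampling at
half-pixel steps), which keeps numerator and denominator measured along
the same axis; the apex is the rootward pixel extreme within the
tooth's own side of the box (mesial site → mesial root apex), keeping
the measurement axis near-parallel to the root on two-rooted molars.
Stages follow the 2018 periodontitis classification with boundaries at
exactly 15 (inclusive into Stage 2) and 33 (inclusive into Stage 2).
Records are emitted per side (mesial/distal); consumers wanting a
per-tooth value can take the per-tooth maximum.

## Evaluation metrics

DSC and JI are plain pixel-count ratios, both defined as 1.0 when both
masks are empty, and satisfy DSC = 2·JI/(1+JI). Box IoU is closed-form
and equals the rasterized JI. Detection evaluation pairs boxes greedily
by descending JI (one-to-one); "JI over 0.7" is strict inequality.
Ratios with zero denominators are reported as `None`, never 0.
Sensitivity is the standard TP/(TP+FN) one-vs-rest reduction and
specificity TN/(TN+FP).

## The phantom generator

Phantom cases emulate the structure the pipeline consumes, not the
appearance of real radiographs:

- **Glyphs.** Four shape archetypes (incisor, canine, premolar, molar)
  parameterized by crown width, root count (molars show two roots), and
  crown notching; each of the eight positions within a quadrant carries
  a fixed smooth texture field so all 32 FDI classes are pairwise
  discriminable under ZNCC (asserted by a 32×32 score-matrix test).
  Left quadrants are exact horizontal mirrors of right ones; mandibular
  quadrants are vertically flipped. Asymmetric intensity ramps and a
  slight root curvature break the mirror/flip symmetries so 11 vs 21
  and 11 vs 41 remain distinguishable. The seed adds a small secondary
  texture so repository entries and query crops from different cases
  are similar but not identical.
- **Geometry.** A case holds one panoramic (two arches of 16 glyphs in
  image-left-to-right FDI order), 14 periapicals (7 per arch, the
  standard molar/premolar/canine/incisor partition), and 4 bitewings
  (2 per side). Maxillary images place the bone band above the CEJ
  line, mandibular below, bitewings both; the gold CEJ is a polyline in
  its own mask, never burned into the image (it is an annotation, not a
  visible edge). Gray levels: background 0, bone 0.4, teeth ≈ 0.8.
- **Bone level.** Each tooth's bone-level fraction f places the crest
  at distance f × root length from the CEJ along the root, so computed
  RBL should recover 100·f; the default 0.10 keeps default phantoms
  below the Stage-2 threshold (healthy). Gold intraoral boxes use the
  same CEJ-to-apex + 2 px pad convention as the extractor, so gold and
  detected boxes are directly comparable under the JI rule.
- **Variation.** `missing_fdi` removes teeth while preserving arch
  spacing (the gap the panoramic labeler must detect);
  `quadrants_present` drops whole quadrants; `scale_jitter` and
  `position_jitter` perturb per-tooth scale and placement;
  `noise_sigma` adds Gaussian pixel noise. Everything is driven by a
  single config seed: identical configs regenerate byte-identical PNGs.

What passing phantom tests does **not** show: robustness to real
radiographic appearance (soft-tissue shadows, exposure gradients,
overlapping proximal contacts, restorations, implants), to imperfect
segmentation masks, or to incorrectly oriented images. The phantom's
role is to verify the charting logic — extraction geometry, matching
and voting, position rules, arrangement, and the RBL rule — under
controlled, known ground truth.

## Problem sizes and test design

The suite exercises: the 32×32 glyph score matrix; 100+ intraoral
images across six seeded cases for detection precision/recall and
position accuracy (both must be perfect under the JI > 0.7 rule on
no-jitter cases); one full no-jitter case charted in repository mode
against a 96-entry repository built from three other phantom cases
(numbering accuracy must be 1.0); two 10%-scale-jitter cases (≥ 0.9
accuracy over 100+ teeth); 50+ teeth with randomized bone-level
fractions in [0.02, 0.6] for RBL recovery within 2 percentage points;
and bit-identical reruns of the whole pipeline. Randomized property
tests are seeded; hypothesis runs derandomized.

## Known limitations

- Merged tooth components are not split; two touching teeth produce one
  box and count against detection recall.
- Edge-of-arch missing teeth are invisible to the gap-based panoramic
  labeler.
- The ZNCC scale grid and histogram equalization are this package's
  re-specification of the matching step; both are config-exposed.
- Staging uses the RBL rule only; no learned stage classifier is
  included, and the report schema reserves a `caries` field for an
  external detector rather than shipping one.
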