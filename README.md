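# acumap

Landmark-based acupoint localization and evaluation.

`acumap` maps anatomical landmark sets — 21-slot hands and 468-slot faces,
as produced by common real-time landmark detectors — to named acupuncture
point (acupoint) coordinates using declarative proportional-geometry rules,
gated by a posture classifier. It ships a 38-point default catalog (18 hand,
20 face) and a full evaluation stack: pixel distance errors, pixel↔physical
calibration from a reference object, object keypoint similarity (OKS),
precision/recall/mAP, confidence intervals, and per-axis Kolmogorov–Smirnov
comparisons. A seeded synthetic-fixture generator makes the whole pipeline
testable without any image data.

## How it works

1. **Posture gating.** A hand set is classified into one of four views
   (front / back / inside / outside) from the angle between the palm-plane
   normal (cross product of two palm vectors) and the optical axis; a face
   set into center / left / right from a signed nose-to-contour asymmetry
   ratio. Only the rules defined for the classified view fire.
2. **Proportional mapping.** Each acupoint carries a small declarative rule
   (`anchor` / `midpoint` / `fraction` / `toward` steps) evaluated against
   the landmark set. Example: one palm point is located by taking the
   midpoint of slots 13 and 17 and moving 1/5 of the slot-5-to-slot-17
   distance toward the wrist. Rules are data (a versioned YAML table), so
   constants are reviewable and replaceable. Rules are authored for right
   hands; left hands are mirrored in and out automatically.
3. **Evaluation.** Predictions are compared to COCO-keypoint ground truth:
   Euclidean errors, OKS-thresholded greedy matching, 101-point
   interpolated AP averaged over categories (mAP@50 and mAP@50–95), normal
   95% CIs, two-sample KS per axis, and optional mm conversion via a
   cm-per-pixel factor from a reference object of known length.

## CLI

```sh
# cm-per-pixel factor from a reference object (truncated at 4 decimals)
acumap calibrate --ref-cm 80 --ref-px 1488       # -> 0.0537

# inspect / validate / export the shipped 38-point rule table
acumap registry --export summary.csv

# generate a synthetic annotated scene (landmark JSONs + COCO ground truth)
cat > spec.yaml <<EOF
n_images: 20
region: hand
posture_mix: {front: 0.5, back: 0.5}
jitter_sd: 2.0
seed: 7
EOF
acumap synth --spec spec.yaml --out scene/

# map one landmark file to predicted acupoints (CSV + COCO-style JSON)
acumap map --landmarks scene/landmarks_00000.json \
           --out preds.csv --out-json preds.json

# compare predictions against ground truth
acumap evaluate --pred preds.json --gt scene/ground_truth.json \
                --ref-cm 80 --ref-px 1488 --out report.json
```

Exit codes: 0 success, 1 processing error, 2 usage error. Logs go to
stderr. Thresholds (posture angle cut-offs, face yaw threshold, OKS `k`,
OKS thresholds) are overridable via `--config config.yaml`; unknown keys
are rejected.

## File formats

- **Landmarks** — JSON, schema `acumap-landmarks/1`: `region`
  (`hand`/`face`), optional `handedness`, `space` (`pixel`/`normalized`),
  optional `image_size` `[w, h]`, and `points` (exactly 21 or 468 entries,
  each `[x, y, z]` or `null`).
- **Ground truth** — standard COCO keypoint JSON; one category per region
  whose ordered keypoint names are the acupoint codes.
- **Predictions** — CSV (`code, x, y, posture, visible`) and COCO-style
  results JSON.
- **Rule table** — YAML, schema `acumap-rules/1`; see the step-language
  comment at the top of `src/acumap/data/acupoint_rules.yaml`.

## Caveats

Except for the single published worked example on the palm, the
proportional constants in the default rule table are package
approximations of standard anatomical descriptions (marked in each rule's
`provenance` field) — they define a reproducible geometry, not clinically
validated locations. Posture thresholds and the face-yaw criterion are
likewise documented package conventions.
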