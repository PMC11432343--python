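# beeforage

Quantify bumblebee foraging behaviour on flower patches from video: from
per-frame bounding-box detections and a calibrated recording geometry,
through HSV flower-colour segmentation, to per-video behavioural
statistics and a linear / mixed-model selection ladder.

## What it does

- **geometry** — scale-bar calibration (mm per pixel), digital placement of
  the 60 × 60 cm analysis quadrat, and the 640 px tiling scheme used for
  detection, with its inverse box mapping.
- **detections** — post-processing of raw tiled detector output:
  inclusive confidence filtering (species defaults 0.7 / 0.8), duplicate-box
  merging by centroid distance (transitive closure; default distance = half
  a bumblebee body, 15 mm), quadrat clipping by box centroid, and F1
  evaluation (`2TP / (2TP + FP + FN)`) against manual annotations.
- **colour** — per-species HSB colour bands (0–255 scale, hue period 256,
  inverted channels supported), flower-cover estimation, the "optimal
  flower colour" (median in-band pixel colour), circular-hue colour-distance
  heatmaps with bee boxes excluded, and deviation histograms.
- **metrics** — patch attractiveness (detections per frame), flower-cover
  standardised carrying capacity, on-flower time proportion (≥ 20 %
  flower pixels in a bee-free reference frame), and simultaneity statistics.
- **models** — simple linear vs crossed-random-intercept mixed models,
  selected by AIC with a singular-fit guard; Shapiro–Wilk and
  Goldfeld–Quandt residual diagnostics; HC3 robust standard errors under
  heteroscedasticity; sqrt / cube-root / power response transformations.
- **synthetic** — seed-controlled scene and detection-stream generators
  with exact ground truth (cover, counts, on-flower labels, duplicates at
  known offsets), used throughout the test suite.

## CLI

```sh
# render a synthetic scene and emit a detection stream with ground truth
beeforage simulate --scene scene.yaml --stream stream.yaml --seed 3 --out sim/

# filter + merge + quadrat-clip raw detections into per-frame counts
beeforage postprocess --detections sim/detections.csv --calibration cal.json \
    --species lotus --out counts.csv

# per-video behavioural metrics row (+ QC of unresolved on-flower calls)
beeforage metrics --detections dets.csv --frames frames/ \
    --colour-config bands.yaml --calibration cal.json --species lotus \
    --out metrics.csv
```

Calibration records are JSON/YAML with `scalebar_px`, `scalebar_mm`,
`quadrat_corner_xy`, `side_mm`, `fps` and frame dimensions.  Colour
configs hold `lower`/`upper` HSB triplets (plus optional
`inverted_channels`); the shipped defaults cover the three study species.

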