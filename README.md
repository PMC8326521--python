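# isletflow

Counting and mass quantification of pancreatic islets from flow-channel video.

Isolated human islets are released for transplantation on the basis of their
mass, purity, and morphology. The standard assessment — manually sizing
dithizone-stained islets under a microscope and converting to islet
equivalents (IEq) — is subjective and operator-dependent. `isletflow`
implements the video-analysis alternative: islets are pumped single-file
through a microfluidic channel and filmed from above; the software detects
every islet in every frame, links detections across frames so each physical
islet is counted exactly once, and reports a multi-parameter mass panel in
physical units.

It is aimed at islet-isolation labs and at anyone building imaging
flow-cytometry pipelines who needs a tested reference for watershed
segmentation, detection linking, and IEq scoring.

## Method

Per frame, over a static background B with frame F (grayscale, low-pass
filtered):

1. **Detection** — foreground |F − B|, thresholded by Otsu's method plus a
   signed bias (with an absolute contrast floor so object-free frames stay
   empty).
2. **Segmentation** — Euclidean distance transform; seeds where the distance
   exceeds a fraction of each blob's distance maximum; morphological opening
   removes tissue-fragment seeds; watershed on the inverted distance
   transform splits touching islets.
3. **Tracking** — between consecutive frames each detection pair is scored
   with a weighted L2 cost

   J = w_x·|x₁−x₂|/min(r₁,r₂) + w_y·|y₁−y₂|/min(r₁,r₂) + w_a·|a₁−a₂|/min(a₁,a₂),

   weights (1, 0.5, 1); pairs with J ≤ J_max are linked greedily in
   ascending cost. A finalized track = one counted islet.
4. **Feature extraction** — per islet, frame-averaged:
   equivalent spherical diameter D = 2√(A/π)·δ (δ = µm/px from the chip's
   embedded scale marker); ellipsoid-fitting volume V = (4/3)π·Ma²·Mi
   (or (4/3)π·Ma·Mi² — both variants computed) from a least-squares ellipse
   fit; circularity 4πA/P²; solidity A/A_hull; DTZ⁺ purity ratio = fraction
   of islet pixels with HSV hue in 310–360°.
5. **Report** — islet count, total IEq (eight 50-µm diameter classes with
   multipliers 0.167 … 22.750), IEqV = IEq × (4/3)π·75³ µm³, total EFV,
   per-metric mean ± SD, and histograms.

No public islet videos exist, so the package ships a synthetic scene
generator (`isletflow.synthgen`) that renders flowing, partially stained
elliptical islets with exact per-pixel ground truth; the test suite validates
counting and parameter recovery against it.

## Worked example

```
$ isletflow synth --n-islets 12 --seed 3 --out fixture \
      --frame-width 480 --frame-height 270
wrote 44 frames, 12 islets to fixture

$ isletflow analyze --input fixture/frames --background fixture/background.png \
      --out results --delta 2.1739
islets: 12  total IEq: 2.504  IEqV: 4.425e+06 um^3  EFV: 4.176e+06 um^3
```

All 12 ground-truth islets are counted exactly once. `results/report.json`
holds the full panel; for this sample it reports a mean diameter of
80.7 ± 12.9 µm (small islets, hence the sub-IEq multipliers summing to
2.504), mean circularity 0.961 ± 0.019 and solidity 0.999 ± 0.001 (the
rendered islets are smooth ellipses), and an area-weighted DTZ⁺ ratio of
0.705 — matching the generator's stain fractions. IEqV exceeds total EFV
slightly (4.43 vs 4.18 × 10⁶ µm³) because IEq binning rounds every islet up
to its class representative.

`results/islets.csv` has one row per islet (diameter, both volume variants,
circularity, solidity, DTZ⁺ ratio, IEq bin), `results/tracks.csv` the raw
per-frame positions.

Library use mirrors the CLI:

```python
from isletflow import SceneConfig, make_scene, analyze_frames, validate_config

cfg = validate_config({"scale": {"marker_px": 460, "marker_um": 1000}})
frames, background, truth = make_scene(SceneConfig(n_islets=50, seed=1))
tracks, records, report = analyze_frames(frames, background, cfg)
assert report.islet_count == 50
```

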