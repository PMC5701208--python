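# pfl — pore-free island landscape analysis

`pfl` is a statistical image-analysis toolkit for *pore-free islands*:
subdomains of the nuclear envelope (NE) that lack mature nuclear pore
complexes (NPCs) and harbour single-nucleoporin foci thought to be NPC
assembly intermediates.  From two-channel immunofluorescence images of the
NE bottom surface (a pan-NPC stain plus a single-Nup counterstain, with a
nucleus-ROI mask), it

1. **recognizes pore-free islands** by K-means clustering of three
   per-pixel image-moment features (window mean, variance, and the
   intensity-normalized second-order central spatial moment), with the
   cluster number k chosen automatically as the first local minimum of the
   island-class within-class variation, WCV(k), over k = 2..20
   (Diff(k) = WCV(k+1) − WCV(k) changing sign from − to +);
2. **detects Nup foci** inside the islands by translating the counterstain
   into mean curvature H of the intensity surface z = I(x, y), regulating
   −H to 8 bits, and thresholding with Otsu's method;
3. **quantifies** island size (um^2), focus appearance frequency
   (foci/um^2), and the distribution of focus distances to the
   pore-free/pore-rich boundary (Euclidean distance transform, unit-width
   bins, per-island frequencies averaged and normalized to sum 1.0);
4. **tests spatial bias** against a complete-spatial-randomness null —
   the observed focus count per island re-placed uniformly at random
   (MT19937, 33,029 repetitions per island by default) — and compares
   conditions and observed-vs-simulated regional shares with the
   **Brunner–Munzel** rank test (p̂ = P(X<Y) + ½P(X=Y), Satterthwaite df,
   ladder ***P<0.001 / *P<0.05 / N.S.).

It is aimed at cell biologists quantifying NE subdomain dynamics (e.g.
CDK-dependent island disappearance) and at image analysts who need a
reproducible, testable reference implementation of this pipeline.  A
ground-truth synthetic generator (`pfl.synth`) makes every stage testable
without microscope data.

## Worked example

```python
import pfl

# a synthetic cell under the standard study conditions
params = pfl.SynthParams(seed=1)
channel_a, channel_b, truth = pfl.make_sample(params)

# 1) recognize islands on the pan-NPC channel
seg = pfl.IslandSegmenter(window=5, restarts=3,
                          min_island_area_px=2.0 / params.pixel_size**2)
seg.fit(channel_a, truth.roi_mask)
print(f"selected k = {seg.k_}, islands found = {len(seg.island_masks_)}")

# 2) detect counterstain foci inside them
foci = pfl.detect_foci(channel_b, seg.island_masks_)
for i, mask in enumerate(seg.island_masks_):
    rec = pfl.island_metrics(mask, foci.count_in_island(i), params.pixel_size)
    print(f"island {i}: {rec.area_um2:.1f} um^2, {rec.n_foci} foci, "
          f"{rec.frequency:.3f} foci/um^2")
```

Output:

```
selected k = 12, islands found = 2
island 0: 20.8 um^2, 6 foci, 0.288 foci/um^2
island 1: 20.4 um^2, 6 foci, 0.295 foci/um^2
```

The selected k is the first sign change of Diff_WCV; each island row gives
the recognized size and the appearance frequency (focus count divided by
island area), the two quantities compared across drug conditions in a full
run.

## Batch runs

The batch interface is a samplesheet CSV (`sample_id, channel_a_path,
channel_b_path, mask_path, inhibitor, treatment_hours, antibody,
pixel_size_um`) plus an optional TOML config mirroring `pfl.RunConfig`:

```bash
pfl run --samplesheet sheet.csv --config cfg.toml --out results/
pfl synth --out synthetic/ --n 8 --seed 1     # synthetic data + ground truth
pfl simulate --island-mask islands.tif --n-foci 5 --out null.csv
```

`pfl run` writes `islands.csv`, `profiles.csv` (observed and simulated
boundary-distance profiles), `stats.csv` (Brunner–Munzel comparisons),
`qc.csv` (saturation / edge-blur / minute-island flags for every input
sample), per-sample island label masks (TIFF) and overlay images (PNG),
and `run.log`.  Outputs are byte-identical across runs given the same
inputs and seeds.

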