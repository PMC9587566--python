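# spotcoloc

Semi-automated **2D object-based co-localization analysis** for dual-channel
fluorescence microscopy z-stacks.

Pixel-correlation measures (Pearson, Manders) summarize how two fluorescent
labels covary, but for punctate structures — P-bodies, stress granules and
other ribonucleoprotein condensates — the biological question is usually a
*count*: how many discrete puncta carry both markers, per cell?  spotcoloc
answers that question by detecting the puncta in each channel as objects and
pairing them across channels, rather than correlating intensities.

## Who it is for

Cell biologists quantifying punctate co-localization in 3-channel confocal
stacks (two signal channels plus a nuclear counterstain, 8-bit, up to 30
focal planes), in batches, without manual counting.

## The method

For each image the pipeline computes, in order:

1. **Projection.** Each channel's z-stack is collapsed by summation.  The
   *saturated* projection (sum clipped at 255) amplifies weakly stained
   regions and is the segmentation substrate; the sum divided by the number
   of planes is the detection substrate.
2. **ROI segmentation.** Whole-cell bodies ("cyto") or nuclei ("nuclei")
   are labeled — by default with a deterministic Otsu → hole-filling →
   distance-watershed segmenter; a Cellpose adapter is available as an
   optional extra.  Signal outside the ROI is masked to zero.
3. **De-noising.** Wavelet background-and-noise subtraction (B3-spline
   à-trous decomposition; the coarsest approximation is background, the
   finest detail level is noise), Gaussian smoothing with user σ, and a
   percentile cut that removes the dimmest *p* % of the remaining positive
   pixels.
4. **Spot detection.** Crocker–Grier centroid localization: band-pass,
   local-maxima candidates, iterative intensity-weighted centroid
   refinement to sub-pixel precision, and an integrated-brightness
   (`minmass`) filter.
5. **Matching.** Particles in the two channels are paired one-to-one.
   Writing `x_i^A`, `x_j^B` for the detected centers, the matching
   maximizes the number of pairs with `‖x_i^A − x_j^B‖ ≤ r_max` and, among
   those, minimizes `Σ ‖x_i^A − x_j^B‖²` (Hungarian algorithm).  The
   maximum displacement `r_max` defaults to the particle diameter.  The
   pair count `n_coloc` is the co-localization readout.
6. **Cell counting.** Nuclei clipped by the image border count as
   `min(area / Ā, 1)` where `Ā` is the mean area of fully contained
   nuclei, so the per-cell statistic `n_coloc / n_cells` is not biased by
   partial cells.

Because per-channel particle counts grow roughly linearly as the percentile
cut is relaxed while the matched count flattens once all genuine pairs are
found, the `sweep` command scans a percentile grid and reports the plateau
of `n_coloc` — the recommended operating estimate.

A ground-truthed synthetic scene generator (`spotcoloc simulate`) renders
nuclei, cytoplasmic halos and PSF-blurred puncta with a controllable
co-localized fraction, Poisson shot noise and Gaussian read noise, so the
whole pipeline can be validated without real data.

## Worked example

```bash
spotcoloc simulate --seed 7 --coloc-fraction 0.5 --out scene.ome.tif --truth truth.csv
spotcoloc run --input scene.ome.tif --out-dir out
```

which prints

```
Simulated scene written: scene.ome.tif (24+24 spots, 12 true pairs)
Analysis complete — output files are available: out/spotcoloc_results.csv
```

and `out/spotcoloc_results.csv` contains

```
image_id,series,n_cells,n_particles_a,n_particles_b,n_coloc,coloc_per_cell,percentile,sigma,diameter,max_displacement
scene,0,6.000,24,24,12,2.000,90.000,1.000,9,9.000
```

The scene contained 6 cells with 24 puncta per channel of which 12 were
truly coincident; the pipeline detected all 24 spots per channel, matched
exactly the 12 true pairs within the 9 px maximum displacement, counted 6
cells, and reports 2.0 co-localized puncta per cell.
`out/spotcoloc_scene.pdf` shows each channel with red circles at the
detections and a merged page marking matched pairs.

The same analysis is available as a library:

```python
from spotcoloc import RunConfig, SceneParams, analyze_stack, generate_scene

stack, truth = generate_scene(SceneParams(seed=7))
record, artifacts = analyze_stack(stack, RunConfig())
print(record.n_coloc, truth.n_true_pairs)   # 12 12
```

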