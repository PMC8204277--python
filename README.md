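# slimaps

Parameter maps and crossing nerve-fiber directions from **Scattered Light
Imaging (SLI)** measurements of brain sections.

In SLI, a thin, unstained brain section is illuminated obliquely from a
sequence of azimuthal positions φ (0° at twelve o'clock, rotating
clockwise, typically in 15° steps) and the normally transmitted light is
recorded with a camera. Each image pixel then carries an azimuthal
intensity profile *I(φ)*. Because myelinated nerve fibers scatter light
predominantly perpendicular to their axis, an in-plane fiber bundle with
direction φ_f produces a pair of profile peaks near φ_f ± 90°; two or
three crossing bundles superimpose their pairs into 4 or 6 peaks, and
out-of-plane (inclined) bundles show peak pairs that move together,
broaden, and eventually merge. `slimaps` turns raw SLI image stacks into
per-pixel parameter maps and up to three crossing in-plane fiber
directions — information that transmission-based techniques such as 3D-PLI
cannot disentangle in crossing regions.

## Method

Per pixel, on the 360°-periodic profile:

1. **Normalization** — divide *I(φ)* by its mean over all azimuths.
2. **Peak detection** — circular local maxima (plateau-aware,
   wrap-around-aware).
3. **Prominence** — vertical distance between a peak top and the higher of
   its two flanking minima, expressed relative to the signal amplitude
   (I_max − I_min); peaks below 8 % relative prominence are treated as
   noise and discarded.
4. **Width** — full width at the height (peak − prominence/2), by circular
   linear interpolation.
5. **Position correction** — the raw sample position is replaced by the
   circular midpoint of the two flank crossings of a cut placed 6 % of the
   amplitude below the peak tip. This shrinks the discretization error of
   15° sampling from a uniform ±7.5° to a roughly Gaussian spread well
   inside ±2.4°.
6. **Direction rules** — 1 peak: φ_f = peak position (mod 180°); 2 peaks:
   circular pair midpoint (mod 180°); 4 or 6 peaks paired by sorted order
   (i with i+n/2): if every pair is 180° ± 35° apart, each pair midpoint is
   one crossing direction; anything else yields no direction.

The whole-image driver assembles nine maps: average intensity, peak counts
(all / prominent), mean prominence and width of prominent peaks, two-peak
distance, and `dir_1`–`dir_3` (sentinel −1 where undefined). An axial 3×3
median filter and vector-overlay rendering support visualization, and a
`compare` module scores SLI against scatterometry line profiles and
reference (e.g. 3D-PLI) direction maps, including the retardation model
|sin(arcsin(ret_max)·cos²α)| that links retardation to fiber inclination α.

A fully seeded synthetic generator produces profiles and crossing-band
phantom stacks (wrapped-Gaussian peak pairs, optional multiplicative
noise) with pixel-level ground truth for validation.

## Worked example

Generate a two-band phantom crossing at 70° (band directions 55° and
125°), analyze it, and inspect the result:

```bash
slimaps synth --preset cross2 --angle 70 --rows 24 --cols 24 --seed 7 -o phantom.tif
slimaps analyze phantom.tif -o maps
```

`maps/` now holds nine float32 TIFFs plus `slix_report.json`, which
summarizes each map. For this phantom the report shows

```
distance  {'defined_fraction': 0.61, 'min': 180.0, 'max': 180.0, 'mean': 180.0}
dir_1     {'defined_fraction': 0.78, 'min': 56.17, 'max': 123.83, 'mean': 82.64}
dir_2     {'defined_fraction': 0.17, 'min': 123.28, 'max': 123.28, 'mean': 123.28}
```

Single-band pixels show two prominent peaks exactly 180° apart
(`distance` = 180°, in-plane fibers) and one direction (56.2° or 123.8°,
i.e. the true 55°/125° within the correction tolerance). In the 100
crossing pixels, four prominent peaks pair up into two directions, 56.7°
and 123.3° — the two bundles are separated rather than averaged. A quick
look:

```bash
slimaps viz maps --stride 2 -o overlay.png
```

Python access mirrors the CLI:

```python
from slimaps import cross2, synth_stack, build_parameter_maps

stack, truth = synth_stack(cross2(70.0, shape=(24, 24), seed=7))
maps = build_parameter_maps(stack)
maps.dir_1.data  # axial directions in [0, 180), -1 where undefined
```

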