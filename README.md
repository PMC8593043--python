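# axisbreak

Broken-axis figures for scientific data: **gap plots** with one or several
missing axis ranges, **axis cuts** that divide an axis into contiguous
slices with per-slice zoom, and **wrapping** of a long x-axis over multiple
rows. The package serves the figures where these transforms are standard —
long per-residue profiles along a protein, phylograms with an outlier
outgroup branch, Manhattan plots whose significant region needs room for
labels, and skewed microbial-abundance bar charts where one genus dwarfs
the rest.

## Who it is for

Anyone who needs a discontinuous or folded axis *and* still wants to add
annotation layers afterwards. Most gap-plot utilities bake the break into
the drawing, so a label placed later lands at a stretched or shifted
position. `axisbreak` instead resolves the break into an explicit layout
object, and every layer — added before or after the transform, from any
data table — is routed through the same clipping machinery into the right
panels.

## The layout model

A transform on one axis resolves to an ordered list of visible **slices**.
Slice *i* covers the closed data interval [*a*ᵢ, *b*ᵢ] and owns a **band**
[*c*ᵢ, *d*ᵢ] of the normalised canvas axis [0, 1], with fixed blank
spacing *s* between bands:

  Σᵢ (*d*ᵢ − *c*ᵢ) + *s* (*n* − 1) = 1.

For a **break**, bands are allotted proportionally to weights
*w*₁ = *b*₁ − *a*₁ and *w*ᵢ₊₁ = (*b*ᵢ₊₁ − *a*ᵢ₊₁) · *k*ᵢ, where *k*ᵢ is the
zoom scale attached to the *i*-th gap; all *k*ᵢ = 1 reproduces
span-proportional layout. For a **cut**, the slices are contiguous and
bands follow explicit weights (or spans, for `"proportional"`). The
piecewise-linear transform

  *T*(*x*) = *c*ᵢ + zoomᵢ · (*x* − *a*ᵢ),  zoomᵢ = (*d*ᵢ − *c*ᵢ)/(*b*ᵢ − *a*ᵢ)

maps data to canvas; zoomᵢ is the magnification of slice *i*. Gaps are
open intervals, slices closed, so a datum exactly on a break boundary is
drawn at the adjoining panel edge. Geometry is clipped exactly: segments
are cut with linear interpolation at slice boundaries, bars become one
fragment per intersected slice, and annotation anchored inside a removed
range is dropped with a warning.

## Worked example

Generate the skewed two-group abundance table (one dominant genus) and
render it with two gaps on the value axis:

```sh
axisbreak fixtures abundance --seed 1 --out abundance.csv
axisbreak render --data abundance.csv --config config.yaml \
    --output gapped.svg --verbose
```

with `config.yaml`:

```yaml
plot:
  x_label: relative abundance (%)
  y_label: genus
  layers:
    - geom: bar
      source: abundance
      mapping: {x: abundance, y: taxon_index}
      style: {orientation: h, width: 0.38}
transform:
  kind: break
  axis: x
  gaps: [[6, 30], [35, 70]]
output: {format: svg}
```

This prints:

```
layout mode: break on x, 3 panel(s)
  slice [-0.3, 6] -> band [0.0000, 0.2189] zoom 0.03474
  slice [30, 35] -> band [0.2389, 0.4126] zoom 0.03474
  slice [70, 86.334] -> band [0.4326, 1.0000] zoom 0.03474
wrote gapped.svg (29354 bytes)
```

Two gaps produce three panels. Each line shows one slice's data interval
(the outer edges carry the 5% padding, hence −0.3 and 86.3), the canvas
band it occupies, and its zoom factor — equal here because all gap scales
default to 1, so every panel keeps the same number of data units per unit
of canvas while 59 units of empty axis vanish into the two 0.02-wide
spacings. The dominant bar (≈ 78%) is clipped into three fragments, one
per panel, with break glyphs marking the discontinuities.

The same figure in Python:

```python
import pandas as pd
from axisbreak import AxisBreakSpec, Layer, PlotSpec, build_figure, render_svg

df = pd.read_csv("abundance.csv")
plot = PlotSpec(layers=[
    Layer("bar", df, {"x": "abundance", "y": "taxon_index"},
          {"orientation": "h", "width": 0.38}, source_id="abundance"),
])
fig = build_figure(plot, AxisBreakSpec(axis="x", gaps=((6, 30), (35, 70))))
open("gapped.svg", "wb").write(render_svg(fig))
```

Rendering is deterministic: the same spec always yields byte-identical
SVG. Four ready-made case studies (`axisbreak.fixtures.case_study`) cover
wrap, break-on-segments, cut and multi-gap bars.

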