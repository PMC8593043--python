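# Methods

## The layout model

All three axis transforms resolve to the same structure, a `SliceLayout`:
an ordered list of visible slices, each pairing a closed data interval
[aᵢ, bᵢ] with a canvas band [cᵢ, dᵢ] ⊂ [0, 1], plus a fixed blank spacing
`space` between consecutive bands. The data→canvas map is piecewise
linear, T(x) = cᵢ + zoomᵢ(x − aᵢ) with zoomᵢ = (dᵢ − cᵢ)/(bᵢ − aᵢ), and is
strictly increasing on visible data. Its inverse is defined on band
interiors; a canvas coordinate in the spacing maps to a between-panels
sentinel, a data value inside a removed range to an in-gap sentinel.
Everything downstream — clipping, ticks, panel placement — consumes this
one object, which is what makes post-transform layering work: a layer
added later is routed through the same map as the original plot.

**Break.** Gaps are open intervals, slices closed: a datum exactly on a
break boundary belongs to the adjoining visible slice and is drawn at the
panel edge rather than silently vanishing. Gaps must be strictly interior
to the data range (a break needs visible data on both sides); overlapping
or touching gaps are merged with a warning rather than rejected, which is
forgiving to programmatically generated gap lists. Bands are allotted in
proportion to weights w₁ = span₁ and wᵢ₊₁ = spanᵢ₊₁·kᵢ, where kᵢ is the
zoom scale attached to gap i (a scalar broadcasts to all gaps; default 1,
i.e. span-proportional layout). The canvas available after spacing is
1 − space(n − 1); non-positive available canvas is a layout-infeasibility
error, not a silent renormalisation.

**Cut.** Division points split the axis into contiguous closed slices; no
data is removed. Band extents follow explicit per-slice weights, or the
spans themselves under the `"proportional"` sentinel (constant zoom
everywhere). Unequal weights are exactly how a region is magnified: the
per-slice zoom factor is extent/span.

**Wrap.** The x range is split into n equal-width contiguous sub-ranges;
each row maps its sub-range onto the full [0, 1] width. The lowest
sub-range is displayed as the top row, so position increases down the
page, matching how long sequences read. Wrap is the one mode where the
shared-canvas conservation law does not apply (every band is (0, 1)), and
the canvas coordinate of a value is its within-row coordinate.

**Expansion.** When enabled (default), 5% multiplicative padding is added
to the *outer* edges of the outermost slices, before band allocation, so
padding competes for canvas like data. Inner break edges are never padded
— padding a break edge would reopen the space the gap removed. Wrap rows
are not padded, keeping the equal-data-width guarantee exact.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `space` | canvas fraction per inter-panel gap | 0.02 | visually separates panels without wasting canvas; capped at 0.2 |
| `scales` | per-gap zoom of the following slice | 1 | span-proportional layout unless the user asks for zoom |
| `expand` | 5% outer-edge padding | on | conventional grammar-of-graphics padding; identity layout then matches a plain plot |
| tick `target_count` | ticks per slice | 5 × n × band extent, min 2 | zoomed-out slices get proportionally fewer ticks so narrow panels stay legible |
| break glyph | 45° double stroke | 6 px | a fixed visual constant; two pairs per gap, one at each adjoining panel edge, on the broken axis line only |

## Ticks

Default positions use the classical nice-number scheme: step =
nice(span/(target − 1)) with nice rounding to {1, 2, 5}·10ᵏ (thresholds
1.5/3/7), stepped down the 5–2–1 ladder until at least two multiples land
in the closed slice; the count never exceeds twice the target. Labels are
the shortest decimal representation that round-trips the value, switching
to scientific notation at |exponent| ≥ 5 — deterministic formatting is a
requirement of snapshot-testable SVG. Explicit (position, label) overrides
replace a slice's defaults; overrides falling in a removed range are
dropped with a warning listing them. In cut mode a tick exactly on a
shared boundary is kept only in the lower slice (transferred there if the
lower slice lacks it); in break mode both edge ticks are kept because they
label different data values.

## Geometry clipping

Segments are parameterised and cut at slice boundaries with exact linear
interpolation; interpolated endpoints are clamped onto the boundary so a
one-ulp overshoot can never place them inside the open gap. Bars are
clipped, never rescaled: a bar spanning a gap appears as one fragment per
intersected slice with a visible break between, and the total drawn extent
equals the bar extent minus its overlap with the gaps. Point-like geometry
(markers, text anchors) inside a removed range is dropped and counted,
with a summary warning — relocating an annotation would falsify it. A
reference line perpendicular to the broken axis is replicated into every
panel; one parallel to it appears only in the slice containing its
coordinate.

## Rendering

Panels are matplotlib axes placed manually from the band coordinates, so
pixel extents are proportional to bands by construction. The non-broken
axis shares identical limits and tick sets across panels; only the outer
panel draws its tick labels. Output SVG is deterministic: the creation
date is suppressed and element ids derive from a fixed hash salt, so two
renders of one spec are byte-identical — this is what the snapshot-style
tests rely on. Log₁₀ scaling is applied to the data before layout; the
slice transform itself stays linear in transformed space, and axis values
are then in log units.

## Synthetic case studies

The fixtures module generates four tables that reproduce the statistical
shape — not the content — of the situations each transform exists for:

- **hydro**: a centred moving average (window 9) of uniform(−4.5, 4.5)
  draws over 4374 positions, the numeric range of a per-residue hydropathy
  scale; wrapped over 4 rows.
- **segments**: exponential branch lengths with the longest multiplied by
  20, giving a guaranteed dominant branch; an x break removes the middle
  of that branch and shrinks the tip slice to 2% of the main panel's
  canvas share, derived from the generated lengths.
- **manhattan**: −log₁₀ of uniform p-values clamped below the suggestive
  line at 5 (p = 10⁻⁵), with exactly `n_hits` SNPs boosted above it; a y
  cut at 5 with weights (1, 2) gives the sparse significant region at
  least twice the pixels-per-unit of the dense bulk.
- **abundance**: two groups of log-normal abundances normalised to 100%
  per group, the first taxon's control value multiplied by 50; two gaps
  are placed in the empty run between the bulk bars and the dominant bar,
  derived from the generated values, with significance labels superposed
  as a separate text layer after the break.

All generators are pure functions of their arguments including the seed
(numpy `default_rng`, i.e. PCG64 — a named, versioned, cross-platform
generator), so tables are bit-identical across runs. What they do *not*
emulate: real residue-level autocorrelation structure, linkage
disequilibrium between SNPs, tree topology (only branch-length geometry),
or compositional covariance between taxa. Passing tests therefore
demonstrate the layout algebra and rendering pipeline on realistically
shaped inputs, not any biological inference.

## Numerical choices

- Band-edge lookups in the inverse transform tolerate ~10⁻¹² absolute
  noise and clamp the result into the slice, so round trips of boundary
  values never fall into the spacing.
- Zero-length clipped fragments (parameter extent ≤ 10⁻¹²) are dropped.
- Zero-span slices cannot arise: gaps and cuts are validated strictly
  interior upstream.
- Degenerate data ranges (single value) are padded symmetrically; layers
  with empty tables render axes only, with a warning.
- At a shared cut boundary the lower slice wins membership, consistent
  with the tick-dedupe rule.

## Known limitations

Breaks on both axes of one figure, discrete/categorical axis breaks, and
date/time axes are out of scope (callers convert to numeric). Polygon and
spline geometry are not clipped — only points, lines, segments, bars,
rects, text and reference lines. Within-slice transforms are linear only;
log scaling happens in data space. Theming is fixed-minimal, and composite
multi-figure layout belongs to external tools.
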