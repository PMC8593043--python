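"""Synthetic generators for the four canonical broken-axis case studies.

Real uses of axis breaks cluster into a few shapes: a long windowed series
(hydropathy profile along a protein) that wants wrapping; a segment set
with one outlier long branch (an outgroup on a phylogram) that wants an
x gap; a Manhattan-style GWAS scatter whose significant upper region wants
zooming via a y cut; and a heavily skewed two-group abundance bar table
(one dominant genus) that wants multiple gaps plus superposed significance
labels.  These generators reproduce those statistical shapes from a seed —
pure functions of their arguments, using numpy's default PCG64 generator,
so every table is bit-identical across runs and platforms.

``case_study`` assembles each fixture into a ready-to-render
(PlotSpec, transform) pair matching the figure each shape calls for.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .break_model import AxisBreakSpec, AxisCutSpec, Interval, WrapSpec
from .figure import Layer, PlotSpec

__all__ = [
    "gen_hydro_series",
    "gen_skewed_abundance",
    "gen_manhattan",
    "gen_outlier_segments",
    "case_study",
    "CASE_STUDIES",
]

#: Manhattan suggestive significance threshold on the -log10(p) scale (p = 1e-5)
SUGGESTIVE_LINE = 5.0


def gen_hydro_series(length: int, window: int = 9, seed: int = 0) -> pd.DataFrame:
    """Windowed hydropathy-like profile: a smoothed bounded random series.

    Scores are a centred moving average (window ``window``, partial windows
    at the edges) of i.i.d. uniform(-4.5, 4.5) draws — the numeric range of
    the Kyte-Doolittle scale — over ``length`` residue positions, so the
    output is mean-zero in expectation and bounded by [-4.5, 4.5].
    ``window=1`` returns the raw draws.
    """
    if window < 1 or length < window:
        raise ValueError(f"need length >= window >= 1, got length={length}, window={window}")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(-4.5, 4.5, size=length)
    score = (
        pd.Series(raw).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return pd.DataFrame({"position": np.arange(1, length + 1), "score": score})


def gen_skewed_abundance(
    n_taxa: int = 15, outlier_factor: float = 50.0, seed: int = 0
) -> pd.DataFrame:
    """Two-group relative-abundance table with one dominant taxon.

    Abundances are log-normal (sigma = 1); the first taxon's abundance in
    the control group is multiplied by ``outlier_factor`` before
    normalising each group to sum to 100 (percent relative abundance), so
    one bar dominates the rest by orders of magnitude — the shape that
    makes an unbroken bar chart unreadable.  Per-taxon significance labels
    are attached for the annotation layer.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    if outlier_factor < 1:
        raise ValueError(f"outlier_factor must be >= 1, got {outlier_factor}")
    rng = np.random.default_rng(seed)
    sig_choices = np.array(["***", "**", "*", "ns"])
    sig = rng.choice(sig_choices, size=n_taxa, p=[0.3, 0.3, 0.3, 0.1])
    rows = []
    for gi, group in enumerate(("Control", "Treatment")):
        ab = rng.lognormal(mean=0.0, sigma=1.0, size=n_taxa)
        if group == "Control":
            ab[0] *= outlier_factor
        ab = 100.0 * ab / ab.sum()
        for t in range(n_taxa):
            rows.append(
                {
                    "taxon": f"Genus{t + 1:02d}",
                    "taxon_index": float(t) + (0.2 if gi == 0 else -0.2),
                    "group": group,
                    "abundance": ab[t],
                    "significance_label": sig[t],
                }
            )
    return pd.DataFrame(rows)


def gen_manhattan(
    n_snps: int = 5000, n_chrom: int = 10, n_hits: int = 8, seed: int = 0
) -> pd.DataFrame:
    """Manhattan-style scatter: -log10 p-values by genomic position.

    Background scores are ``-log10(uniform(0, 1))`` clamped strictly below
    the suggestive line at 5 (p = 1e-5); exactly ``n_hits`` designated SNPs
    are boosted into (5.5, 8).  Chromosomes are contiguous position blocks
    with an alternating color key.
    """
    if n_hits > n_snps:
        raise ValueError(f"n_hits ({n_hits}) cannot exceed n_snps ({n_snps})")
    rng = np.random.default_rng(seed)
    neglog = -np.log10(rng.uniform(0.0, 1.0, size=n_snps))
    neglog = np.minimum(neglog, SUGGESTIVE_LINE - 0.05)
    if n_hits:
        hits = rng.choice(n_snps, size=n_hits, replace=False)
        neglog[hits] = rng.uniform(SUGGESTIVE_LINE + 0.5, 8.0, size=n_hits)
    chrom = (np.arange(n_snps) * n_chrom) // n_snps + 1
    return pd.DataFrame(
        {
            "chrom": chrom,
            "position": np.arange(1, n_snps + 1),
            "neglog10p": neglog,
            "color_key": chrom % 2,
        }
    )


def gen_outlier_segments(
    n_branches: int = 10, outlier_length_factor: float = 20.0, seed: int = 0
) -> pd.DataFrame:
    """Horizontal segments with one outlier long branch.

    Lengths are exponential(1) draws; the longest draw is multiplied by
    ``outlier_length_factor``, guaranteeing the longest segment exceeds the
    runner-up by at least that factor — a stand-in for a phylogram whose
    outgroup branch dwarfs the main clade.
    """
    if n_branches < 2:
        raise ValueError(f"n_branches must be >= 2, got {n_branches}")
    if outlier_length_factor < 1:
        raise ValueError(f"outlier_length_factor must be >= 1, got {outlier_length_factor}")
    rng = np.random.default_rng(seed)
    lengths = rng.exponential(1.0, size=n_branches)
    lengths[np.argmax(lengths)] *= outlier_length_factor
    return pd.DataFrame(
        {
            "x0": np.zeros(n_branches),
            "y0": np.arange(n_branches, dtype=float),
            "x1": lengths,
            "y1": np.arange(n_branches, dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# assembled case-study figures

Transform = Union[AxisBreakSpec, AxisCutSpec, WrapSpec]


def _case_wrap(seed: int) -> tuple[PlotSpec, Transform]:
    df = gen_hydro_series(length=4374, window=9, seed=seed)
    plot = PlotSpec(
        layers=[
            Layer("line", df, {"x": "position", "y": "score"},
                  {"color": "#4C72B0", "size": 0.8}, source_id="hydropathy"),
        ],
        x_label="residue position",
        y_label="hydropathy score",
        title="Windowed hydropathy profile, wrapped",
    )
    return plot, WrapSpec(n_rows=4)


def _case_segments(seed: int) -> tuple[PlotSpec, Transform]:
    df = gen_outlier_segments(n_branches=10, outlier_length_factor=20.0, seed=seed)
    tip = float(df["x1"].max())
    main_max = float(df["x1"].drop(df["x1"].idxmax()).max())
    # remove nearly the whole outlier branch: gap from past the main clade
    # to just short of the outlier tip; shrink the tip slice to 2% of the
    # main panel's canvas share regardless of how long the outlier is
    gap = Interval(main_max * 1.3, tip * 0.98)
    scale = 0.02 * gap.lo / (tip - gap.hi)
    plot = PlotSpec(
        layers=[
            Layer("segment", df,
                  {"x": "x0", "y": "y0", "xend": "x1", "yend": "y1"},
                  {"color": "#333333", "size": 1.2}, source_id="branches"),
        ],
        x_label="branch length",
        y_label="branch",
        title="Outlier long branch, shrunk by an x break",
    )
    return plot, AxisBreakSpec(axis="x", gaps=(gap,), scales=scale)


def _case_manhattan(seed: int) -> tuple[PlotSpec, Transform]:
    df = gen_manhattan(n_snps=5000, n_chrom=10, n_hits=8, seed=seed)
    layers = []
    for key, color in ((0, "#4C72B0"), (1, "#64B5CD")):
        sub = df[df["color_key"] == key]
        layers.append(
            Layer("point", sub, {"x": "position", "y": "neglog10p"},
                  {"color": color, "size": 2.0}, source_id=f"snps-{key}")
        )
    layers.append(
        Layer("hline", df.iloc[:1], {}, {"value": SUGGESTIVE_LINE,
                                         "linetype": "dashed",
                                         "color": "#C44E52"},
              source_id="suggestive-line")
    )
    plot = PlotSpec(
        layers=layers,
        x_label="genomic position",
        y_label="-log10(p)",
        title="Manhattan plot with the significant region zoomed in",
    )
    # give the sparse significant region twice the weight of the dense bulk
    return plot, AxisCutSpec(axis="y", cuts=(SUGGESTIVE_LINE,), weights=(1.0, 2.0))


def _case_abundance(seed: int) -> tuple[PlotSpec, Transform]:
    df = gen_skewed_abundance(n_taxa=15, outlier_factor=50.0, seed=seed)
    outlier = float(df["abundance"].max())
    bulk = float(df["abundance"].drop(df["abundance"].idxmax()).max())
    # two gaps in the empty run between the bulk bars and the dominant bar;
    # if the draw is barely skewed, fall back to the dominant bar's upper run
    lo = bulk * 1.1
    hi = outlier * 0.95
    if hi <= lo * 1.05:
        lo = outlier * 0.3
    run = hi - lo
    gaps = (
        Interval(lo, lo + 0.45 * run),
        Interval(lo + 0.55 * run, hi),
    )
    ctrl = df[df["group"] == "Control"]
    trt = df[df["group"] == "Treatment"]
    labels = ctrl[["taxon_index", "significance_label"]].copy()
    labels["label_x"] = outlier * 1.02
    labels["label_y"] = labels["taxon_index"] - 0.2  # centred between the pair
    plot = PlotSpec(
        layers=[
            Layer("bar", ctrl, {"x": "abundance", "y": "taxon_index"},
                  {"orientation": "h", "width": 0.38, "color": "#4C72B0",
                   "label": "Control"}, source_id="control"),
            Layer("bar", trt, {"x": "abundance", "y": "taxon_index"},
                  {"orientation": "h", "width": 0.38, "color": "#DD8452",
                   "label": "Treatment"}, source_id="treatment"),
            Layer("text", labels,
                  {"x": "label_x", "y": "label_y", "label": "significance_label"},
                  {"size": 8.0}, source_id="significance"),
        ],
        x_label="relative abundance (%)",
        y_label="genus",
        title="Skewed abundances with a two-gap x axis",
    )
    return plot, AxisBreakSpec(axis="x", gaps=gaps, scales=(1.0, 1.0))


CASE_STUDIES = {
    "hydro_wrap": _case_wrap,
    "outlier_segments": _case_segments,
    "manhattan_cut": _case_manhattan,
    "abundance_gaps": _case_abundance,
}

GENERATORS = {
    "hydro": gen_hydro_series,
    "abundance": gen_skewed_abundance,
    "manhattan": gen_manhattan,
    "segments": gen_outlier_segments,
}


def case_study(name: str, seed: int = 0) -> tuple[PlotSpec, Transform]:
    """Build the (PlotSpec, transform) pair for one named case study."""
    try:
        builder = CASE_STUDIES[name]
    except KeyError:
        raise ValueError(
            f"unknown case study {name!r}; choose from {sorted(CASE_STUDIES)}"
        ) from None
    return builder(seed)
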