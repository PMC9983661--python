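"""Figure idioms of the analysis: occupancy bar charts and entropy scatter.

The occupancy bar chart stacks each sample's occupation rates (sorted
descending within the sample) into a unit-height bar, so a differentiated
sample shows a few dominant segments while a dedifferentiated sample is a
fine-grained stack. The entropy scatter plots per-sample entropy against
a covariate (dose or culture hours) with an optional fitted line.

Every plot function returns its render data (segment heights, point
coordinates) alongside the figure so tests verify the drawing numerically
rather than by pixel comparison. Saved SVGs are byte-reproducible: the
hash salt is pinned and the date metadata stripped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diversity import occupation_rates
from .errors import ValidationError
from .io import CountMatrix, SampleSheet
from .stats import SlopeTest, run_paper_contrasts

__all__ = ["PlotSpec", "plot_occupancy", "plot_entropy_scatter", "save_figure"]

_SVG_HASHSALT = "liberality"


@dataclass(frozen=True)
class PlotSpec:
    """Options for a plot: kind, output path, and rendering choices."""

    kind: str  # "occupancy_bars" | "entropy_scatter"
    out_path: str | None = None
    image_format: str = "svg"
    max_segments: int = 60
    covariate: str = "dose"
    fit_line: bool = True
    title: str = ""
    xlabel: str = ""
    ylabel: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("occupancy_bars", "entropy_scatter"):
            raise ValidationError(f"unknown plot kind {self.kind!r}")
        if self.image_format not in ("svg", "png"):
            raise ValidationError(f"unsupported image format {self.image_format!r}")


def save_figure(fig, out_path: str | Path, image_format: str | None = None) -> Path:
    """Save a figure deterministically (fixed SVG hash salt, no timestamps)."""
    out_path = Path(out_path)
    fmt = image_format or out_path.suffix.lstrip(".").lower() or "svg"
    with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
        if fmt == "svg":
            fig.savefig(out_path, format="svg", metadata={"Date": None})
        else:
            fig.savefig(out_path, format=fmt)
    return out_path


def plot_occupancy(
    matrix: CountMatrix, spec: PlotSpec | None = None
) -> tuple["plt.Figure", dict[str, np.ndarray]]:
    """Stacked occupancy bar chart, one unit-height bar per sample.

    Segments are the sample's occupation rates sorted descending; colors
    are deterministic by rank. Only the top ``spec.max_segments`` genes
    are drawn individually — the long tail is aggregated into a single
    black segment, which is also how the real charts read: thousands of
    low-abundance genes merge into a black region. The returned render
    data maps each sample id to its FULL descending occupation-rate
    vector; segment heights per bar sum to 1.
    """
    spec = spec or PlotSpec(kind="occupancy_bars")
    if matrix.n_samples < 1:
        raise ValidationError("need at least one sample to plot")
    render: dict[str, np.ndarray] = {}
    for sid in matrix.sample_ids:
        p = occupation_rates(matrix.column(sid), matrix.gene_ids, sample_id=sid).p
        render[sid] = np.sort(p)[::-1]

    fig, ax = plt.subplots(figsize=(max(4, 0.6 * matrix.n_samples + 1.5), 5))
    cmap = plt.get_cmap("viridis")
    kmax = spec.max_segments
    for x, sid in enumerate(matrix.sample_ids):
        heights = render[sid]
        top = heights[:kmax]
        tail = heights[kmax:].sum()
        bottom = 0.0
        for rank, h in enumerate(top):
            if h <= 0:
                break
            ax.bar(
                x,
                h,
                bottom=bottom,
                width=0.8,
                color=cmap(rank / max(kmax - 1, 1)),
                linewidth=0,
            )
            bottom += h
        if tail > 0:
            ax.bar(x, tail, bottom=bottom, width=0.8, color="black", linewidth=0)
    ax.set_xticks(range(matrix.n_samples))
    ax.set_xticklabels(matrix.sample_ids, rotation=90, fontsize=7)
    ax.set_ylim(0, 1)
    ax.set_ylabel(spec.ylabel or "occupation rate")
    ax.set_title(spec.title or "Gene occupation rates per transcriptome")
    fig.tight_layout()
    if spec.out_path:
        save_figure(fig, spec.out_path, spec.image_format)
    return fig, render


def plot_entropy_scatter(
    results: pd.DataFrame,
    sheet: SampleSheet,
    spec: PlotSpec | None = None,
    strain: str | None = None,
    treatments: tuple[str, ...] | None = None,
) -> tuple["plt.Figure", dict]:
    """Scatter of per-sample entropy against dose or culture time.

    One point per sample at (covariate, H_bits); if ``spec.fit_line`` and
    the subset supports a regression, the least-squares line from the
    slope test is overlaid and its :class:`SlopeTest` is included in the
    render data under ``"fit"`` (None when no line is drawn).
    """
    spec = spec or PlotSpec(kind="entropy_scatter")
    covariate = spec.covariate
    if covariate not in ("dose", "time_h"):
        raise ValidationError(f"covariate must be 'dose' or 'time_h', got {covariate!r}")
    res = results.copy()
    res["sample_id"] = res["sample_id"].astype(str)
    missing = set(res["sample_id"]) - set(sheet.sample_ids)
    if missing:
        raise ValidationError(f"samples absent from the sheet: {sorted(missing)}")
    merged = res.merge(sheet.data, on="sample_id", how="inner")
    if strain is not None:
        merged = merged[merged["strain"] == strain]
    if treatments is not None:
        merged = merged[merged["treatment"].isin(treatments)]
    if merged.empty:
        raise ValidationError("no samples selected for the scatter plot")
    x = merged[covariate].to_numpy(float)
    y = merged["H_bits"].to_numpy(float)

    fit: SlopeTest | None = None
    if spec.fit_line and len(merged) >= 3 and np.ptp(x) > 0:
        fit = run_paper_contrasts(
            res, sheet, covariate=covariate, strain=strain, treatments=treatments
        )

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, color="tab:blue", zorder=3)
    if fit is not None:
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, fit.intercept_hat + fit.beta_hat * xs, color="tab:red", lw=1)
    default_xlabel = (
        "extract dose (dilution fraction)" if covariate == "dose" else "culture time (h)"
    )
    ax.set_xlabel(spec.xlabel or default_xlabel)
    ax.set_ylabel(spec.ylabel or "transcriptome entropy (bits)")
    ax.set_title(spec.title or "Entropy vs " + covariate)
    fig.tight_layout()
    render = {
        "x": x,
        "y": y,
        "sample_ids": list(merged["sample_id"]),
        "fit": fit,
    }
    if spec.out_path:
        save_figure(fig, spec.out_path, spec.image_format)
    return fig, render
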