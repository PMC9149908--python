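"""Render organellar-map figures.

Overlay points are drawn at their map coordinates with point size
encoding the abundance (or fold-change) bin; the full reference map can
be drawn beneath as small grey points; annotated regions appear as
k-sigma ellipses.  Rendering is deterministic: identical inputs produce
byte-identical SVG output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from lopitmap.overlay import OverlayResult, UNBINNED
from lopitmap.reference_map import COMPARTMENTS, ReferenceMap, RegionAnnotation

logger = logging.getLogger(__name__)

#: Compartment palette.  The verbal scheme (light blue cytosol, dark
#: blue ER, ..., grey unknown) is conventional for these maps; the hex
#: values are this package's constants.
DEFAULT_PALETTE: dict[str, str] = {
    "cytosol": "#7fc8f5",
    "endoplasmic reticulum": "#1f3d99",
    "golgi": "#90ee90",
    "lysosome": "#1a6b2a",
    "mitochondria": "#f781bf",
    "nucleus": "#d62728",
    "nucleus-chromatin": "#ffc680",
    "peroxisome": "#e06f00",
    "plasma membrane": "#c09bf0",
    "proteasome": "#5e2d91",
    "ribosome 40S": "#e6d800",
    "ribosome 60S": "#8c564b",
    "unknown": "#9e9e9e",
}

ROLE_COLORS = {"enriched-marker": "green", "background-contaminant": "red",
               "neutral": "black"}


def default_size_map(n_bins: int = 5, base: float = 8.0, step: float = 14.0) -> dict[int, float]:
    """Point area per bin, linear in bin index (monotone by construction)."""
    sizes = {b: base + step * (b - 1) for b in range(1, n_bins + 1)}
    sizes[UNBINNED] = base
    return sizes


@dataclass
class PlotSpec:
    """Everything needed to render one map figure."""

    overlay: OverlayResult
    refmap: ReferenceMap | None = None
    highlights: Mapping[str, str] = field(default_factory=dict)
    regions: Sequence[RegionAnnotation] = ()
    size_map: Mapping[int, float] | None = None
    palette: Mapping[str, str] | None = None
    color_by_compartment: bool = True
    title: str = ""
    draw_background: bool = True


def _deterministic_save(fig, out_path: Path, dpi: int) -> None:
    # fixed hashsalt + stripped date metadata => byte-identical SVG
    with plt.rc_context({"svg.hashsalt": "lopitmap"}):
        if out_path.suffix.lower() == ".svg":
            fig.savefig(out_path, format="svg", metadata={"Date": None}, dpi=dpi)
        else:
            fig.savefig(out_path, dpi=dpi)


def render_map(spec: PlotSpec, out_path: str | Path, dpi: int = 150) -> Path:
    """Render an overlay on the organellar map to SVG or PNG.

    Raises ``ValueError`` on an empty overlay.  Highlight accessions not
    present in the overlay are skipped with a warning.
    """
    out_path = Path(out_path)
    points = spec.overlay.points
    if len(points) == 0:
        raise ValueError("cannot render an empty overlay")
    palette = dict(spec.palette or DEFAULT_PALETTE)
    size_map = dict(spec.size_map or default_size_map())

    missing_sizes = set(points["bin"].unique()) - set(size_map)
    if missing_sizes:
        raise ValueError(f"size_map lacks entries for bins {sorted(missing_sizes)}")

    fig, ax = plt.subplots(figsize=(7, 7))
    if spec.refmap is not None and spec.draw_background:
        bg = spec.refmap.table
        ax.scatter(bg["x"], bg["y"], s=3, c="#d9d9d9", linewidths=0, zorder=1)

    colors = (
        [palette[c] for c in points["compartment"]]
        if spec.color_by_compartment
        else "#2c6fbb"
    )
    sizes = [size_map[int(b)] for b in points["bin"]]
    ax.scatter(points["x"], points["y"], s=sizes, c=colors, linewidths=0,
               alpha=0.85, zorder=2)

    for acc, color in spec.highlights.items():
        if acc not in points.index:
            warnings.warn(f"highlight accession {acc!r} not in overlay; skipped",
                          stacklevel=2)
            continue
        row = points.loc[acc]
        ax.scatter([row["x"]], [row["y"]], s=90, facecolors="none",
                   edgecolors=color, linewidths=1.8, zorder=4)

    for region in spec.regions:
        _draw_region(ax, region)

    if spec.refmap is not None:
        xmin, xmax, ymin, ymax = spec.refmap.bounding_box()
        pad_x = 0.05 * (xmax - xmin or 1.0)
        pad_y = 0.05 * (ymax - ymin or 1.0)
        ax.set_xlim(xmin - pad_x, xmax + pad_x)
        ax.set_ylim(ymin - pad_y, ymax + pad_y)
    ax.set_xlabel("map dimension 1")
    ax.set_ylabel("map dimension 2")
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    _deterministic_save(fig, out_path, dpi)
    plt.close(fig)
    logger.info("wrote map figure %s (%d points)", out_path, len(points))
    return out_path


def _draw_region(ax, region: RegionAnnotation) -> None:
    cov = np.asarray(region.covariance, dtype=float)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    width, height = 2.0 * np.sqrt(eigvals[::-1])  # major axis first
    angle = float(np.degrees(np.arctan2(eigvecs[1, -1], eigvecs[0, -1])))
    color = ROLE_COLORS.get(region.role, "black")
    ax.add_patch(
        Ellipse(region.center, width, height, angle=angle, fill=False,
                edgecolor=color, linewidth=1.6, zorder=3)
    )
    ax.annotate(region.region_id, region.center, color=color, fontsize=11,
                ha="center", va="center", zorder=5)


def render_comparison(spec: PlotSpec, out_path: str | Path, dpi: int = 150) -> Path:
    """Render a fold-change overlay (point size = binned ratio).

    Thin alias of :func:`render_map`: a comparison figure is an overlay
    whose values are between-fraction ratios rather than abundances.
    """
    return render_map(spec, out_path, dpi=dpi)
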