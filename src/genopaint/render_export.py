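"""Rendering of figure plans to PNG/PDF via matplotlib.

This is the only module that touches a graphics backend.  It consumes the
backend-free :class:`~genopaint.layout_engine.FigurePlan` objects plus a
:class:`~genopaint.io_formats.ColorSet` and draws each chromosome as two
adjacent narrow vertical rectangles (one per haplotype track), with height
proportional to chromosome length in bp.

Output naming: normal mode writes ``<stem>_<sample>.png`` (one figure per
sample); compare and zoomed modes write ``<stem>.png``.  A vector PDF with
the same stem is written additionally when requested.  PNG resolution is
controlled by dpi (default 300).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Rectangle  # noqa: E402

from .genotype_core import GenotypeError  # noqa: E402
from .io_formats import ColorSet, load_color_sets  # noqa: E402
from .layout_engine import (  # noqa: E402
    ChromosomePaint,
    FigurePanel,
    FigurePlan,
    PaintSegment,
    RenderConfig,
    resolve_rgb,
)

logger = logging.getLogger("genopaint")

PathLike = Union[str, Path]

DEFAULT_STEM = "genopaint_output"

#: above this many marker labels per chromosome, only every k-th is drawn
MAX_LABELS_PER_CHROM = 50

# layout constants (axis units; x is abstract, y is bp)
_TRACK_W = 0.38
_TRACK_GAP = 0.06
_ENTRY_W = 2 * _TRACK_W + _TRACK_GAP  # one sample's two tracks
_ENTRY_GAP = 0.35
_PANEL_GAP = 1.1


def _mpl_color(rgb: tuple[int, int, int]) -> tuple[float, float, float]:
    return tuple(c / 255 for c in rgb)  # type: ignore[return-value]


def resolve_color_set(name: str,
                      registry: Optional[dict[str, ColorSet]] = None) -> ColorSet:
    """Look up a color set by name, erroring with the available names."""
    if registry is None:
        registry = load_color_sets()
    try:
        return registry[name]
    except KeyError:
        raise GenotypeError(
            f"unknown color set {name!r}; available: "
            f"{sorted(registry)}") from None


def _draw_track(ax: plt.Axes, x: float, segments: Sequence[PaintSegment],
                color_set: ColorSet) -> None:
    for seg in segments:
        ax.add_patch(Rectangle(
            (x, seg.start), _TRACK_W, seg.end - seg.start,
            facecolor=_mpl_color(resolve_rgb(seg.role, color_set)),
            edgecolor="none", linewidth=0, antialiased=False))


def _draw_entry(ax: plt.Axes, x: float, paint: ChromosomePaint,
                color_set: ColorSet, label: Optional[str],
                y_max: int) -> None:
    _draw_track(ax, x, paint.track1, color_set)
    _draw_track(ax, x + _TRACK_W + _TRACK_GAP, paint.track2, color_set)
    # thin outline so pale tracks remain visible against the background
    ax.add_patch(Rectangle((x, 0), _ENTRY_W, paint.length, fill=False,
                           edgecolor="0.35", linewidth=0.4))
    if label:
        ax.text(x + _ENTRY_W / 2, -0.015 * y_max, label,
                ha="center", va="top", fontsize=7, rotation=90)


def _draw_marker_labels(ax: plt.Axes, x: float, paint: ChromosomePaint,
                        window: tuple[int, int]) -> None:
    lo, hi = window
    ticks = [(p, n) for p, n in paint.marker_ticks if lo <= p < hi]
    step = 1
    if len(ticks) > MAX_LABELS_PER_CHROM:
        step = math.ceil(len(ticks) / MAX_LABELS_PER_CHROM)
        logger.info("%s: %d marker labels, drawing every %d-th",
                    paint.chrom, len(ticks), step)
    for p, name in ticks[::step]:
        ax.plot([x, x + 0.12], [p, p], color="0.2", linewidth=0.4)
        ax.text(x + 0.16, p, name, ha="left", va="center", fontsize=5)


def _panel_width(panel: FigurePanel, labels: bool) -> float:
    w = len(panel.entries) * (_ENTRY_W + _ENTRY_GAP) - _ENTRY_GAP
    return w + (0.9 if labels else 0.0)


def render(plan: FigurePlan, config: RenderConfig, out_path: PathLike,
           color_registry: Optional[dict[str, ColorSet]] = None) -> list[Path]:
    """Render one figure plan; returns the paths written.

    ``out_path`` is the output stem (an existing ``.png``/``.pdf`` suffix is
    stripped); the mode-dependent naming convention above determines the
    final file names.
    """
    if not plan.panels or not any(p.entries for p in plan.panels):
        raise GenotypeError("empty figure plan: nothing to render")
    color_set = resolve_color_set(config.color_set, color_registry)

    stem = Path(out_path)
    if stem.suffix.lower() in (".png", ".pdf"):
        stem = stem.with_suffix("")

    zoom = plan.mode == "zoomed"
    if zoom:
        _, z_start, z_end = config.region
        y_lo, y_hi = z_start, z_end
    else:
        y_lo, y_hi = 0, max(e[1].length for p in plan.panels
                            for e in p.entries)
    span = y_hi - y_lo

    labels_on = config.display_marker_names
    widths = [_panel_width(p, labels_on) for p in plan.panels]
    total_w = sum(widths) + _PANEL_GAP * (len(plan.panels) - 1)

    fig_w = max(3.0, min(0.9 * total_w, 60.0))
    fig_h = 7.0
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    ax.set_xlim(-0.3, total_w + 0.3)
    ax.set_ylim(y_hi + 0.02 * span, y_lo - 0.1 * span)  # bp 0 (or start) at top
    ax.set_axis_off()

    show_sample_labels = plan.mode in ("compare", "zoomed")
    cursor = 0.0
    for panel, pw in zip(plan.panels, widths):
        ax.text(cursor + pw / 2, y_lo - 0.04 * span, panel.label,
                ha="center", va="bottom", fontsize=9)
        x = cursor
        for sample, paint in panel.entries:
            _draw_entry(ax, x, paint, color_set,
                        sample if show_sample_labels else None, span)
            x += _ENTRY_W + _ENTRY_GAP
        if labels_on and panel.entries:
            _draw_marker_labels(ax, x - _ENTRY_GAP + 0.05,
                                panel.entries[-1][1], (y_lo, y_hi))
        cursor += pw + _PANEL_GAP

    if plan.mode == "normal":
        fig.suptitle(plan.label, fontsize=11)

    if plan.mode == "normal":
        base = stem.parent / f"{stem.name}_{plan.label}"
    else:
        base = stem
    base.parent.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    png = base.with_suffix(".png")
    fig.savefig(png, dpi=config.dpi)
    written.append(png)
    if config.pdf:
        pdf = base.with_suffix(".pdf")
        fig.savefig(pdf)
        written.append(pdf)
    plt.close(fig)
    logger.info("wrote %s", ", ".join(str(p) for p in written))
    return written


def render_track_png(track: Sequence[PaintSegment], length: int,
                     color_set: ColorSet, out_path: PathLike,
                     width_px: int = 400, height_px: int = 40) -> Path:
    """Render a single haplotype track, border- and label-free, to a PNG of
    exactly ``width_px`` x ``height_px`` pixels.

    The x axis maps [0, length) bp linearly onto the full image width and
    rectangles are drawn without antialiasing, so the pixel at the centre of
    any segment carries exactly that segment's resolved RGB color.  Used for
    pixel-level verification of paint plans; also handy as a compact
    stand-alone strip rendering.
    """
    dpi = 100
    fig = plt.figure(figsize=(width_px / dpi, height_px / dpi), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, length)
    ax.set_ylim(0, 1)
    ax.set_axis_off()
    for seg in track:
        ax.add_patch(Rectangle(
            (seg.start, 0), seg.end - seg.start, 1,
            facecolor=_mpl_color(resolve_rgb(seg.role, color_set)),
            edgecolor="none", linewidth=0, antialiased=False))
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=dpi)
    plt.close(fig)
    return out
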