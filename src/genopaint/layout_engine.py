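"""Backend-free layout: genotype calls -> colored segment plans.

Each chromosome of each sample is painted as two haplotype tracks, each an
ordered list of colored genomic segments in 0-based half-open bp
coordinates (so segment lengths sum exactly to the chromosome length when
fill is on).  Marker positions are 1-based bp and become the segment
boundaries.

Fill semantics: with fill on, the interval between two adjacent markers is
painted one uniform color that reflects both neighbours -- the per-channel
mean of their colors (a blend), collapsing to the shared color when the
neighbouring genotypes are equal, so runs of identical genotype merge into
solid blocks.  The chromosome ends beyond the terminal markers extend the
terminal markers' colors.  A gap adjacent to a missing call is painted in
the missing color (unknown data does not bleed a parental color).  With
fill off, only a narrow line is drawn at each marker position.

Coloring modes: ``2-color`` puts each haplotype's own parental color on its
track, so phased heterozygotes show which haplotype carries which allele;
``3-color`` paints heterozygous calls in a dedicated third color on both
tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genotype_core import AlleleState, Call, GenotypeError, GenotypeTable, Marker
from .io_formats import ChromLengthDB, ColorSet

logger = logging.getLogger("genopaint")

DRAWING_MODES = ("normal", "compare", "zoomed")
COLORING_MODES = ("2-color", "3-color")

#: rule-of-thumb marker density above which filled plots get muddy
FILL_ADVICE_THRESHOLD = 100


# ---------------------------------------------------------------------------
# color roles


@dataclass(frozen=True)
class ColorRole:
    """A paintable role: one of the four base roles or a blend of two.

    ``pair`` is set only for kind ``"BLEND"`` and holds the two distinct
    non-missing base roles being blended, in a canonical order so that
    blends compare equal regardless of argument order.
    """

    kind: str  # "A" | "B" | "HET" | "MISSING" | "BLEND"
    pair: Optional[tuple["ColorRole", "ColorRole"]] = None

    def __repr__(self) -> str:
        if self.kind == "BLEND":
            return f"BLEND({self.pair[0].kind},{self.pair[1].kind})"
        return self.kind


ROLE_A = ColorRole("A")
ROLE_B = ColorRole("B")
ROLE_HET = ColorRole("HET")
ROLE_MISSING = ColorRole("MISSING")

_BASE_ORDER = {"A": 0, "B": 1, "HET": 2, "MISSING": 3}


def blend_role(x: ColorRole, y: ColorRole) -> ColorRole:
    """The role of a gap between two base roles (fill=on).

    Equal roles collapse to themselves; a missing neighbour makes the gap
    missing; otherwise a symmetric BLEND of the two roles.
    """
    if x.kind == "BLEND" or y.kind == "BLEND":
        raise GenotypeError("cannot blend an already-blended role")
    if x == y:
        return x
    if ROLE_MISSING in (x, y):
        return ROLE_MISSING
    lo, hi = sorted((x, y), key=lambda r: _BASE_ORDER[r.kind])
    return ColorRole("BLEND", (lo, hi))


def resolve_rgb(role: ColorRole, color_set: ColorSet) -> tuple[int, int, int]:
    """Resolve a role to its 24-bit RGB color under a color set."""
    if role.kind == "BLEND":
        return blend(role.pair[0], role.pair[1], color_set)
    return {
        "A": color_set.colorA,
        "B": color_set.colorB,
        "HET": color_set.colorHet,
        "MISSING": color_set.colorMissing,
    }[role.kind]


def blend(role_x: ColorRole, role_y: ColorRole,
          color_set: ColorSet) -> tuple[int, int, int]:
    """Per-channel mean of two roles' colors, rounded to nearest (ties up)."""
    a = resolve_rgb(role_x, color_set)
    b = resolve_rgb(role_y, color_set)
    # channels are ints, so the mean is k or k+0.5; (a+b+1)//2 rounds .5 up
    return tuple((ca + cb + 1) // 2 for ca, cb in zip(a, b))  # type: ignore[return-value]


def assign_roles(call: Call, coloring_mode: str) -> tuple[ColorRole, ColorRole]:
    """Roles for (track1, track2) of one call.

    Homozygotes and missing calls are symmetric.  Heterozygotes: 3-color
    mode paints both tracks HET; 2-color mode paints each track with its own
    haplotype's role, so a phased ``1|0`` puts B on track 1 and A on track 2
    (and the canonical unphased het renders A on track 1, B on track 2).
    """
    if coloring_mode not in COLORING_MODES:
        raise GenotypeError(f"unknown coloring mode {coloring_mode!r}; "
                            f"expected one of {COLORING_MODES}")
    if call.is_missing:
        return ROLE_MISSING, ROLE_MISSING
    base = {AlleleState.A: ROLE_A, AlleleState.B: ROLE_B}
    if call.is_het and coloring_mode == "3-color":
        return ROLE_HET, ROLE_HET
    return base[call.hap1], base[call.hap2]


# ---------------------------------------------------------------------------
# paint plans


@dataclass(frozen=True)
class PaintSegment:
    """A colored genomic interval, 0-based half-open [start, end)."""

    start: int
    end: int
    role: ColorRole

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenotypeError(
                f"invalid segment [{self.start}, {self.end})")


@dataclass
class ChromosomePaint:
    """Render plan for one sample x chromosome: two tracks of segments."""

    chrom: str
    length: int
    track1: list[PaintSegment]
    track2: list[PaintSegment]
    marker_ticks: list[tuple[int, str]] = field(default_factory=list)

    def tracks(self) -> tuple[list[PaintSegment], list[PaintSegment]]:
        return self.track1, self.track2


@dataclass
class RenderConfig:
    """The full user-visible option set for drawing.

    ``region`` is (chrom, start bp, end bp), required (with start < end)
    when ``drawing_mode`` is ``zoomed``.  ``marker_line_bp`` overrides the
    fill=off line width, which otherwise defaults to
    ``max(1, round(length / 1000))`` bp so lines stay visible at genome
    scale.
    """

    species: str
    drawing_mode: str = "normal"
    coloring_mode: str = "2-color"
    fill: bool = True
    color_set: str = "normal"
    display_marker_names: bool = True
    region: Optional[tuple[str, int, int]] = None
    dpi: int = 300
    pdf: bool = False
    marker_line_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.drawing_mode not in DRAWING_MODES:
            raise GenotypeError(f"unknown drawing mode {self.drawing_mode!r}; "
                                f"expected one of {DRAWING_MODES}")
        if self.coloring_mode not in COLORING_MODES:
            raise GenotypeError(f"unknown coloring mode {self.coloring_mode!r}; "
                                f"expected one of {COLORING_MODES}")
        if self.dpi < 1:
            raise GenotypeError("dpi must be a positive integer")
        if self.drawing_mode == "zoomed":
            if self.region is None:
                raise GenotypeError(
                    "zoomed mode requires a region (--chr/--start/--end)")
            _, start, end = self.region
            if not start < end:
                raise GenotypeError(
                    f"zoomed region must have start < end, got "
                    f"[{start}, {end}]")


def _merge(segments: list[PaintSegment]) -> list[PaintSegment]:
    out: list[PaintSegment] = []
    for seg in segments:
        if out and out[-1].role == seg.role and out[-1].end == seg.start:
            out[-1] = PaintSegment(out[-1].start, seg.end, seg.role)
        else:
            out.append(seg)
    return out


def _fill_track(boundaries: list[int], roles: list[ColorRole],
                length: int) -> list[PaintSegment]:
    """One track under fill=on: ends extended, gaps blended, runs merged."""
    segs: list[PaintSegment] = []

    def add(start: int, end: int, role: ColorRole) -> None:
        if start < end:
            segs.append(PaintSegment(start, end, role))

    add(0, boundaries[0], roles[0])
    for i in range(len(boundaries) - 1):
        add(boundaries[i], boundaries[i + 1],
            blend_role(roles[i], roles[i + 1]))
    add(boundaries[-1], length, roles[-1])
    return _merge(segs)


def _line_track(boundaries: list[int], roles: list[ColorRole],
                length: int, width: int) -> list[PaintSegment]:
    """One track under fill=off: one centered line segment per marker."""
    segs = []
    for pos, role in zip(boundaries, roles):
        start = pos - width // 2
        start = max(0, min(start, length - width))
        segs.append(PaintSegment(start, start + width, role))
    return segs


def compute_tracks(calls: Sequence[tuple[Marker, Call]], length: int,
                   config: RenderConfig, chrom: Optional[str] = None) -> ChromosomePaint:
    """Paint plan for one sample on one chromosome.

    ``calls`` are (marker, call) pairs in ascending position order.  A
    chromosome with no markers is drawn full-length in the missing color
    (kept rather than omitted so compare-mode panels stay aligned).
    """
    if not calls:
        name = chrom or "?"
        logger.info("chromosome %s: no markers; drawn as missing", name)
        full = [PaintSegment(0, length, ROLE_MISSING)]
        return ChromosomePaint(chrom=name, length=length,
                               track1=list(full), track2=list(full))
    chrom = chrom or calls[0][0].chrom
    for m, _ in calls:
        if m.position > length:
            raise GenotypeError(
                f"marker {m.name!r} at {m.chrom}:{m.position} exceeds the "
                f"database chromosome length {length} bp for species "
                f"{config.species!r}; check the species/assembly")

    boundaries = [m.position for m, _ in calls]
    role_pairs = [assign_roles(c, config.coloring_mode) for _, c in calls]
    ticks = [(m.position, m.name) for m, _ in calls]

    if config.fill:
        t1 = _fill_track(boundaries, [r[0] for r in role_pairs], length)
        t2 = _fill_track(boundaries, [r[1] for r in role_pairs], length)
    else:
        width = (config.marker_line_bp if config.marker_line_bp is not None
                 else max(1, round(length / 1000)))
        t1 = _line_track(boundaries, [r[0] for r in role_pairs], length, width)
        t2 = _line_track(boundaries, [r[1] for r in role_pairs], length, width)
    return ChromosomePaint(chrom=chrom, length=length, track1=t1, track2=t2,
                           marker_ticks=ticks)


def clip_paint(paint: ChromosomePaint, start: int, end: int) -> ChromosomePaint:
    """Intersect a paint plan with [start, end); pure clipping.

    Marker ticks outside the window are dropped.  A window that contains no
    marker still yields a valid (single-blend) plan, with a logged warning.
    """
    if not (0 <= start < end <= paint.length):
        raise GenotypeError(
            f"clip window [{start}, {end}) outside chromosome "
            f"[0, {paint.length})")

    def clip_track(track: list[PaintSegment]) -> list[PaintSegment]:
        out = []
        for seg in track:
            s, e = max(seg.start, start), min(seg.end, end)
            if s < e:
                out.append(PaintSegment(s, e, seg.role))
        return out

    ticks = [(p, n) for p, n in paint.marker_ticks if start <= p < end]
    if paint.marker_ticks and not ticks:
        logger.warning("zoom window %s:[%d, %d) contains no markers",
                       paint.chrom, start, end)
    return ChromosomePaint(chrom=paint.chrom, length=paint.length,
                           track1=clip_track(paint.track1),
                           track2=clip_track(paint.track2),
                           marker_ticks=ticks)


def density_advice(markers_per_chromosome: int, fill: bool) -> Optional[str]:
    """Advisory (non-fatal) when a filled plot has too many markers.

    Triggered strictly above :data:`FILL_ADVICE_THRESHOLD` markers per
    chromosome and only when fill is on.
    """
    if fill and markers_per_chromosome > FILL_ADVICE_THRESHOLD:
        msg = (f"{markers_per_chromosome} markers on one chromosome with "
               f"fill on; consider --fill off above "
               f"{FILL_ADVICE_THRESHOLD} markers per chromosome")
        logger.warning(msg)
        return msg
    return None


# ---------------------------------------------------------------------------
# figure planning


@dataclass
class FigurePanel:
    """One aligned panel: a chromosome label plus (sample, paint) entries."""

    label: str
    entries: list[tuple[str, ChromosomePaint]]


@dataclass
class FigurePlan:
    """A complete figure: mode, identifying label, ordered panels."""

    mode: str
    label: str
    panels: list[FigurePanel]


def _table_chromosomes_in_db_order(table: GenotypeTable, db: ChromLengthDB,
                                   species: str) -> list[str]:
    entry = db[species]
    present = set(table.chromosomes())
    missing = [c for c in present if c not in entry]
    if missing:
        raise GenotypeError(
            f"chromosome(s) {sorted(missing)} not in the {species!r} database "
            f"entry; database chromosomes: {list(entry)}")
    return [c for c in entry if c in present]


def plan_figures(table: GenotypeTable, db: ChromLengthDB,
                 config: RenderConfig) -> list[FigurePlan]:
    """Figure plans for a whole table under the configured drawing mode.

    normal  -> one figure per sample, chromosomes in database order;
    compare -> one figure, one panel per chromosome holding every sample's
               copy of that chromosome side by side;
    zoomed  -> one figure showing every sample clipped to ``config.region``.
    """
    entry = db[config.species]
    chroms = _table_chromosomes_in_db_order(table, db, config.species)
    if not chroms:
        raise GenotypeError("table contains no chromosomes to draw")

    for chrom in chroms:
        n = sum(1 for m in table.markers if m.chrom == chrom)
        density_advice(n, config.fill)

    def paint(sample: str, chrom: str) -> ChromosomePaint:
        return compute_tracks(table.chromosome_calls(chrom, sample),
                              entry[chrom], config, chrom=chrom)

    if config.drawing_mode == "normal":
        return [
            FigurePlan(mode="normal", label=sample, panels=[
                FigurePanel(label=c, entries=[(sample, paint(sample, c))])
                for c in chroms
            ])
            for sample in table.samples
        ]

    if config.drawing_mode == "compare":
        panels = [
            FigurePanel(label=c,
                        entries=[(s, paint(s, c)) for s in table.samples])
            for c in chroms
        ]
        return [FigurePlan(mode="compare", label="compare", panels=panels)]

    # zoomed
    chrom, start, end = config.region  # validated by RenderConfig
    if chrom not in entry:
        raise GenotypeError(
            f"zoom chromosome {chrom!r} not in the {config.species!r} "
            f"database entry; database chromosomes: {list(entry)}")
    if end > entry[chrom]:
        raise GenotypeError(
            f"zoom window end {end} exceeds {chrom} length {entry[chrom]}")
    panels = [FigurePanel(
        label=f"{chrom}:{start}-{end}",
        entries=[(s, clip_paint(paint(s, chrom), start, end))
                 for s in table.samples])]
    return [FigurePlan(mode="zoomed", label=f"{chrom}_{start}_{end}",
                       panels=panels)]
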