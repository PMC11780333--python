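"""Layout engine: role assignment, blending, paint plans, figure planning."""

from __future__ import annotations

import pytest

from genopaint import (
    Call,
    EncodingDialect,
    GenotypeError,
    Marker,
    RenderConfig,
    SimulationParams,
    assign_roles,
    blend,
    blend_role,
    clip_paint,
    compute_tracks,
    density_advice,
    plan_figures,
    resolve_rgb,
    simulate_table,
)
from genopaint.layout_engine import (
    ROLE_A,
    ROLE_B,
    ROLE_HET,
    ROLE_MISSING,
    PaintSegment,
)
from conftest import A, B, N, make_table

ROLES = (ROLE_A, ROLE_B, ROLE_HET, ROLE_MISSING)


def mk(chrom, pos, call):
    return (Marker(chrom=chrom, name=f"{chrom}_{pos}", position=pos), call)


def flatten(track, length):
    """Per-bp role sequence of a fill=on track (the brute-force view)."""
    out = [None] * length
    for seg in track:
        for x in range(seg.start, seg.end):
            out[x] = seg.role
    return out


def pointwise_oracle(positions, roles, length):
    """Independent per-bp evaluation of the fill rule: before the first
    marker and after the last, the terminal marker's role; between markers
    i and i+1, the gap role of that pair."""
    out = []
    for x in range(length):
        if x < positions[0]:
            out.append(roles[0])
        elif x >= positions[-1]:
            out.append(roles[-1])
        else:
            for i in range(len(positions) - 1):
                if positions[i] <= x < positions[i + 1]:
                    out.append(blend_role(roles[i], roles[i + 1]))
                    break
    return out


class TestAssignRoles:
    @pytest.mark.parametrize("call,mode,expected", [
        (Call(A, A, True), "2-color", (ROLE_A, ROLE_A)),
        (Call(A, A, True), "3-color", (ROLE_A, ROLE_A)),
        (Call(B, B, True), "2-color", (ROLE_B, ROLE_B)),
        (Call(N, N), "2-color", (ROLE_MISSING, ROLE_MISSING)),
        (Call(N, N), "3-color", (ROLE_MISSING, ROLE_MISSING)),
        # phased 1|0: B on track 1, A on track 2 -- phase is depicted
        (Call(B, A, True), "2-color", (ROLE_B, ROLE_A)),
        (Call(A, B, True), "2-color", (ROLE_A, ROLE_B)),
        (Call(B, A, True), "3-color", (ROLE_HET, ROLE_HET)),
        # canonical unphased het: fixed convention A/B on tracks 1/2
        (Call(A, B, False), "2-color", (ROLE_A, ROLE_B)),
    ])
    def test_role_assignment(self, call, mode, expected):
        assert assign_roles(call, mode) == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(GenotypeError):
            assign_roles(Call(A, A), "4-color")


class TestBlend:
    def test_channel_mean_ties_round_up(self, color_registry):
        from genopaint import ColorSet
        cs = ColorSet(name="t", colorA=(255, 0, 0), colorB=(0, 0, 255),
                      colorHet=(0, 255, 0), colorMissing=(128, 128, 128))
        assert blend(ROLE_A, ROLE_B, cs) == (128, 0, 128)  # #800080

    @pytest.mark.parametrize("role", ROLES)
    def test_blend_with_self_is_identity(self, role, normal_colors):
        assert blend(role, role, normal_colors) == resolve_rgb(role, normal_colors)

    @pytest.mark.parametrize("x", ROLES)
    @pytest.mark.parametrize("y", ROLES)
    def test_commutative(self, x, y, normal_colors):
        assert blend(x, y, normal_colors) == blend(y, x, normal_colors)
        if x != y and ROLE_MISSING not in (x, y):
            assert blend_role(x, y) == blend_role(y, x)

    def test_gap_role_collapses_when_equal(self):
        assert blend_role(ROLE_A, ROLE_A) == ROLE_A

    def test_gap_next_to_missing_is_missing(self):
        assert blend_role(ROLE_A, ROLE_MISSING) == ROLE_MISSING


class TestComputeTracksFill:
    def test_single_marker_paints_whole_chromosome(self, base_config):
        paint = compute_tracks([mk("c", 500, Call(A, A, True))], 1000,
                               base_config)
        for tr in paint.tracks():
            assert tr == [PaintSegment(0, 1000, ROLE_A)]

    def test_two_marker_worked_example(self, base_config):
        """Markers (100, A/A) and (300, B/B) on a 400 bp chromosome:
        [0,100)=A, [100,300)=blend(A,B), [300,400)=B on both tracks."""
        paint = compute_tracks(
            [mk("c", 100, Call(A, A, True)), mk("c", 300, Call(B, B, True))],
            400, base_config)
        expected = [PaintSegment(0, 100, ROLE_A),
                    PaintSegment(100, 300, blend_role(ROLE_A, ROLE_B)),
                    PaintSegment(300, 400, ROLE_B)]
        assert paint.track1 == expected and paint.track2 == expected
        for tr in paint.tracks():
            assert sum(s.end - s.start for s in tr) == 400

    def test_equal_neighbours_merge_into_solid_block(self, base_config):
        paint = compute_tracks(
            [mk("c", 100, Call(A, A, True)), mk("c", 300, Call(A, A, True))],
            400, base_config)
        assert paint.track1 == [PaintSegment(0, 400, ROLE_A)]

    def test_marker_ticks_populated(self, base_config):
        paint = compute_tracks(
            [mk("c", 100, Call(A, A, True)), mk("c", 300, Call(B, B, True))],
            400, base_config)
        assert paint.marker_ticks == [(100, "c_100"), (300, "c_300")]

    def test_marker_beyond_chromosome_end_is_an_error(self, base_config):
        with pytest.raises(GenotypeError, match=r"c_500.*toy"):
            compute_tracks([mk("c", 500, Call(A, A, True))], 400, base_config)

    def test_zero_markers_drawn_as_missing(self, base_config):
        paint = compute_tracks([], 1000, base_config, chrom="cX")
        for tr in paint.tracks():
            assert tr == [PaintSegment(0, 1000, ROLE_MISSING)]

    def test_oracle_equivalence_small_chromosomes(self, base_config):
        """fill=on tracks agree per-bp with the pointwise rule for every
        genotype pattern of up to 5 markers (both tracks, both modes)."""
        import itertools
        calls = [Call(A, A, True), Call(B, B, True), Call(B, A, True),
                 Call(N, N)]
        length = 60
        for n in (1, 2, 3, 5):
            positions = [10 * (i + 1) for i in range(n)]
            for pattern in itertools.product(calls, repeat=n):
                pairs = [mk("c", p, c) for p, c in zip(positions, pattern)]
                for mode in ("2-color", "3-color"):
                    cfg = RenderConfig(species="toy", coloring_mode=mode)
                    paint = compute_tracks(pairs, length, cfg)
                    for track_idx, tr in enumerate(paint.tracks()):
                        roles = [assign_roles(c, mode)[track_idx]
                                 for c in pattern]
                        assert flatten(tr, length) == pointwise_oracle(
                            positions, roles, length)


class TestComputeTracksLines:
    def test_one_segment_per_marker_centered(self):
        cfg = RenderConfig(species="toy", fill=False)
        paint = compute_tracks(
            [mk("c", 100, Call(A, A, True)), mk("c", 300, Call(B, B, True))],
            1000, cfg)
        for tr in paint.tracks():
            assert len(tr) == 2
            for seg, pos in zip(tr, (100, 300)):
                assert seg.end - seg.start == max(1, round(1000 / 1000))
                assert seg.start <= pos <= seg.end

    def test_line_width_default_and_override(self):
        cfg = RenderConfig(species="toy", fill=False)
        paint = compute_tracks([mk("c", 5000, Call(A, A, True))], 10_000, cfg)
        assert paint.track1[0].end - paint.track1[0].start == 10
        cfg2 = RenderConfig(species="toy", fill=False, marker_line_bp=3)
        paint2 = compute_tracks([mk("c", 5000, Call(A, A, True))], 10_000, cfg2)
        assert paint2.track1[0].end - paint2.track1[0].start == 3

    def test_lines_clamped_inside_chromosome(self):
        cfg = RenderConfig(species="toy", fill=False, marker_line_bp=10)
        paint = compute_tracks([mk("c", 1, Call(A, A, True)),
                                mk("c", 1000, Call(B, B, True))], 1000, cfg)
        for tr in paint.tracks():
            assert all(0 <= s.start < s.end <= 1000 for s in tr)


class TestClipPaint:
    @pytest.fixture
    def three_seg_paint(self, base_config):
        return compute_tracks(
            [mk("c", 100, Call(A, A, True)), mk("c", 300, Call(B, B, True))],
            400, base_config)

    def test_identity_clip(self, three_seg_paint):
        clipped = clip_paint(three_seg_paint, 0, 400)
        assert clipped.track1 == three_seg_paint.track1
        assert clipped.marker_ticks == three_seg_paint.marker_ticks

    def test_worked_interval_intersection(self, three_seg_paint):
        clipped = clip_paint(three_seg_paint, 150, 350)
        assert clipped.track1 == [
            PaintSegment(150, 300, blend_role(ROLE_A, ROLE_B)),
            PaintSegment(300, 350, ROLE_B)]
        assert sum(s.end - s.start for s in clipped.track1) == 200

    def test_window_between_markers_is_single_blend(self, three_seg_paint):
        clipped = clip_paint(three_seg_paint, 150, 250)
        assert clipped.track1 == [
            PaintSegment(150, 250, blend_role(ROLE_A, ROLE_B))]
        assert clipped.marker_ticks == []

    def test_bad_window_rejected(self, three_seg_paint):
        with pytest.raises(GenotypeError):
            clip_paint(three_seg_paint, 300, 300)
        with pytest.raises(GenotypeError):
            clip_paint(three_seg_paint, 0, 500)


class TestDensityAdvice:
    @pytest.mark.parametrize("count,fill,expect", [
        (101, True, True),
        (100, True, False),   # boundary: not exceeding
        (10_000, False, False),
        (0, True, False),
    ])
    def test_threshold(self, count, fill, expect):
        advice = density_advice(count, fill)
        assert (advice is not None) == expect


class TestPlanFigures:
    def test_normal_one_plan_per_sample(self, toy_table, toy_db, base_config):
        plans = plan_figures(toy_table, toy_db, base_config)
        assert [p.label for p in plans] == toy_table.samples
        assert all(p.mode == "normal" for p in plans)
        assert all(len(p.panels) == 2 for p in plans)

    def test_compare_groups_chromosomes(self, toy_table, toy_db):
        cfg = RenderConfig(species="toy", drawing_mode="compare")
        plans = plan_figures(toy_table, toy_db, cfg)
        assert len(plans) == 1
        plan = plans[0]
        assert [p.label for p in plan.panels] == ["chrT1", "chrT2"]
        for panel in plan.panels:
            assert [s for s, _ in panel.entries] == toy_table.samples

    def test_zoomed_equals_clipping_the_full_plan(self, toy_table, toy_db):
        """Cross-code-path consistency: the zoomed plan's paints equal
        clip_paint applied to the full-chromosome compare-mode paints."""
        window = ("chrT1", 200_000, 600_000)
        zoom_cfg = RenderConfig(species="toy", drawing_mode="zoomed",
                                region=window)
        full_cfg = RenderConfig(species="toy", drawing_mode="compare")
        zoom = plan_figures(toy_table, toy_db, zoom_cfg)[0]
        full = plan_figures(toy_table, toy_db, full_cfg)[0]
        full_chrT1 = {s: p for s, p in full.panels[0].entries}
        for sample, zpaint in zoom.panels[0].entries:
            manual = clip_paint(full_chrT1[sample], 200_000, 600_000)
            assert zpaint.track1 == manual.track1
            assert zpaint.track2 == manual.track2
            assert zpaint.marker_ticks == manual.marker_ticks

    def test_chromosomes_follow_db_order_not_lexicographic(self, toy_lengths):
        from genopaint import ChromLengthDB
        rows = [("Chr10", "a", 100, [Call(A, A, True)]),
                ("Chr2", "b", 100, [Call(B, B, True)])]
        table = make_table(rows, ["S1"])
        db = ChromLengthDB(entries={"toy": {"Chr2": 1000, "Chr10": 1000}})
        plans = plan_figures(table, db, RenderConfig(species="toy"))
        assert [p.label for p in plans[0].panels] == ["Chr2", "Chr10"]

    def test_unknown_species_lists_available(self, toy_table, toy_db):
        with pytest.raises(GenotypeError, match="toy"):
            plan_figures(toy_table, toy_db, RenderConfig(species="nope"))

    def test_chromosome_missing_from_db_entry(self, toy_db):
        rows = [("chrZZ", "m", 100, [Call(A, A, True)])]
        table = make_table(rows, ["S1"])
        with pytest.raises(GenotypeError, match="chrT1"):
            plan_figures(table, toy_db, RenderConfig(species="toy"))

    def test_zoomed_requires_region(self):
        with pytest.raises(GenotypeError, match="region"):
            RenderConfig(species="toy", drawing_mode="zoomed")
        with pytest.raises(GenotypeError, match="start < end"):
            RenderConfig(species="toy", drawing_mode="zoomed",
                         region=("chrT1", 500, 500))


class TestPaintInvariants:
    @pytest.mark.parametrize("seed", range(20))
    def test_partition_on_randomized_tables(self, seed, toy_lengths):
        """fill=on segments are sorted, non-overlapping and sum exactly to
        the chromosome length on randomized synthetic tables."""
        table = simulate_table(SimulationParams(
            n_samples=2, chrom_lengths=dict(toy_lengths),
            markers_per_chrom=5 + seed % 11, missing_rate=0.15, seed=seed,
            random_marker_positions=bool(seed % 2)))
        cfg = RenderConfig(species="toy",
                           coloring_mode="2-color" if seed % 2 else "3-color")
        for chrom, length in toy_lengths.items():
            for sample in table.samples:
                paint = compute_tracks(table.chromosome_calls(chrom, sample),
                                       length, cfg)
                for tr in paint.tracks():
                    assert all(s.end > s.start for s in tr)
                    assert all(tr[i].end == tr[i + 1].start
                               for i in range(len(tr) - 1))
                    assert tr[0].start == 0 and tr[-1].end == length
                    assert sum(s.end - s.start for s in tr) == length

    def test_phase_symmetry_in_three_color_mode(self, toy_lengths):
        """Flipping every phased het (1|0 <-> 0|1) leaves 3-color plans
        identical, since both haplotype orders map to the het color."""
        table = simulate_table(SimulationParams(
            n_samples=2, chrom_lengths=dict(toy_lengths),
            markers_per_chrom=12, het_fraction=1.0, missing_rate=0.1, seed=9))
        flipped_calls = [
            [Call(c.hap2, c.hap1, c.phased) if c.is_het else c for c in row]
            for row in table.calls]
        flipped = type(table)(markers=table.markers, samples=table.samples,
                              calls=flipped_calls, dialect=table.dialect)
        cfg = RenderConfig(species="toy", coloring_mode="3-color")
        for chrom, length in toy_lengths.items():
            for s in table.samples:
                p1 = compute_tracks(table.chromosome_calls(chrom, s),
                                    length, cfg)
                p2 = compute_tracks(flipped.chromosome_calls(chrom, s),
                                    length, cfg)
                assert p1.track1 == p2.track1 and p1.track2 == p2.track2

    def test_haplotype_swap_swaps_tracks_in_two_color_mode(self, toy_lengths):
        table = simulate_table(SimulationParams(
            n_samples=2, chrom_lengths=dict(toy_lengths),
            markers_per_chrom=12, het_fraction=1.0, missing_rate=0.1, seed=13))
        swapped_calls = [[Call(c.hap2, c.hap1, c.phased) for c in row]
                         for row in table.calls]
        swapped = type(table)(markers=table.markers, samples=table.samples,
                              calls=swapped_calls, dialect=table.dialect)
        cfg = RenderConfig(species="toy", coloring_mode="2-color")
        for chrom, length in toy_lengths.items():
            for s in table.samples:
                p1 = compute_tracks(table.chromosome_calls(chrom, s),
                                    length, cfg)
                p2 = compute_tracks(swapped.chromosome_calls(chrom, s),
                                    length, cfg)
                assert p1.track1 == p2.track2 and p1.track2 == p2.track1

    def test_layout_is_deterministic(self, toy_table, toy_db, base_config):
        a = plan_figures(toy_table, toy_db, base_config)
        b = plan_figures(toy_table, toy_db, base_config)
        for pa, pb in zip(a, b):
            for qa, qb in zip(pa.panels, pb.panels):
                for (sa, ca), (sb, cb) in zip(qa.entries, qb.entries):
                    assert sa == sb and ca.track1 == cb.track1 \
                        and ca.track2 == cb.track2
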