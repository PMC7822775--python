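"""Geometry-panel character recognition and its intensity invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xrnav import (
    CArmConfig,
    CArmGeometry,
    PanelLayout,
    binarize_cell,
    classify_glyph,
    default_layout,
    read_geometry,
    to_carm_geometry,
)
from xrnav.panel import display_reading, round_half_away
from xrnav.phantom import PhantomScene, render_frame, render_frame_pair

EMPTY = PhantomScene()

FD_PITCH = {15: 0.1445, 20: 0.184, 25: 0.216, 31: 0.2716, 40: 0.308, 48: 0.3672}
CONFIG = CArmConfig(label="frontal", spd_mm=810.0, fd_pixel_pitch_mm=FD_PITCH)


def read_merged(geom, layout=None, gain=1.0, offset=0.0):
    fa, fb = render_frame_pair(EMPTY, geom, layout, gain=gain, offset=offset)
    la = layout or default_layout()
    return read_geometry(fa.raster, la).merge(read_geometry(fb.raster, la))


class TestBinarizeCell:
    def test_constant_cell_is_blank(self):
        assert not binarize_cell(np.full((7, 5), 42.0)).any()

    def test_affine_intensity_invariance_of_rendered_glyph(self, layout):
        glyph = layout.glyphs["7"].astype(float)
        cell = 20.0 + 180.0 * glyph
        for gain, offset in ((1.0, 0.0), (0.3, 40.0), (0.2, 80.0)):
            assert np.array_equal(
                binarize_cell(gain * cell + offset), binarize_cell(cell)
            )

    def test_rejects_empty_cell(self):
        with pytest.raises(ValueError):
            binarize_cell(np.empty((0, 0)))


class TestClassifyGlyph:
    def test_exact_glyph_distance_zero(self, layout):
        for ch, g in layout.glyphs.items():
            got, dist, ambiguous = classify_glyph(g, layout.glyphs)
            assert got == ch
            assert dist == 0.0
            assert not ambiguous

    def test_blank_cell_is_empty_character(self, layout):
        got, _, _ = classify_glyph(np.zeros((7, 5), dtype=bool), layout.glyphs)
        assert got == " "

    def test_confusion_matrix_is_diagonal(self, layout):
        # every glyph of the shipped font against every other: nearest
        # template must always be itself, with positive margin
        chars = sorted(layout.glyphs)
        for ch in chars:
            dists = {
                other: np.linalg.norm(
                    layout.glyphs[ch].astype(float) - layout.glyphs[other].astype(float)
                )
                for other in chars
            }
            assert dists[ch] == 0.0
            assert min(d for o, d in dists.items() if o != ch) > 1.0

    def test_size_mismatch_rejected(self, layout):
        with pytest.raises(ValueError, match="shape"):
            classify_glyph(np.zeros((3, 3), dtype=bool), layout.glyphs)


class TestReadGeometry:
    def test_registration_set2_frontal_values(self):
        # RAO 26 / CAUD 0, table long/lat/vert -64/-7/6 cm, SID 120, FD 15
        geom = CArmGeometry(
            primary_angle=-26.0, secondary_angle=0.0, table=(-70.0, 60.0, -640.0),
            sid=1200.0, fd=150.0, spd=810.0,
        )
        r = read_merged(geom)
        assert r.complete
        assert r.primary_deg == -26  # RAO sign negative
        assert r.secondary_deg == 0
        assert (r.table_long_cm, r.table_lat_cm, r.table_vert_cm) == (-64, -7, 6)
        assert (r.sid_cm, r.fd_cm) == (120, 15)

    def test_lao_90_reads_positive(self):
        geom = CArmGeometry(primary_angle=90.0, sid=1300.0, fd=150.0, spd=765.0)
        assert read_merged(geom).primary_deg == 90

    def test_half_centimeter_rounds_away_from_zero(self):
        geom = CArmGeometry(table=(0.0, 0.0, 64.0), sid=1200.0, fd=150.0, spd=810.0)
        assert read_merged(geom).table_long_cm == 6  # 6.4 cm -> "6"
        assert round_half_away(6.5) == 7 and round_half_away(-6.5) == -7

    def test_single_page_reading_flags_other_page_invalid(self, layout):
        geom = CArmGeometry(sid=1200.0, fd=150.0, spd=810.0)
        frame = render_frame(EMPTY, geom, layout, page="angulation")
        r = read_geometry(frame.raster, layout)
        assert r.valid["primary_deg"] and r.valid["sid_cm"]
        assert not r.valid["fd_cm"] and not r.valid["table_long_cm"]
        assert not r.complete

    def test_inverted_polarity_flagged_not_misread(self, layout):
        geom = CArmGeometry(sid=1200.0, fd=150.0, spd=810.0)
        frame = render_frame(EMPTY, geom, layout, page="angulation")
        inverted = 255.0 - frame.raster.astype(float)
        r = read_geometry(inverted, layout)
        truth = display_reading(geom)
        for f in ("primary_deg", "secondary_deg", "sid_cm"):
            assert (not r.valid[f]) or getattr(r, f) == getattr(truth, f)
        assert not r.complete

    def test_recognition_invariant_to_gain_and_offset(self, rng):
        geom = CArmGeometry(
            primary_angle=-137.0, secondary_angle=42.0, table=(310.0, -80.0, 950.0),
            sid=1234.0, fd=250.0, spd=810.0,
        )
        base = read_merged(geom)
        assert base.complete
        for _ in range(10):
            gain = rng.uniform(0.2, 1.0)
            offset = rng.uniform(0.0, 80.0)
            r = read_merged(geom, gain=gain, offset=offset)
            assert r.to_json() == base.to_json()

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        primary=st.integers(-185, 185),
        secondary=st.integers(-90, 90),
        long_cm=st.integers(-99, 99),
        lat_cm=st.integers(-99, 99),
        vert_cm=st.integers(-99, 99),
        sid_cm=st.integers(90, 130),
        fd_cm=st.sampled_from(sorted(FD_PITCH)),
        gain=st.floats(0.2, 1.0),
        offset=st.floats(0.0, 80.0),
    )
    def test_render_read_round_trip_over_vendor_range(
        self, primary, secondary, long_cm, lat_cm, vert_cm, sid_cm, fd_cm, gain, offset
    ):
        """read_geometry(render(g)) == round_to_display(g) across the range."""
        if sid_cm * 10 <= 810:
            sid_cm = 90  # frontal SPD bound; SID 90 cm is still > SPD
        geom = CArmGeometry(
            primary_angle=float(primary), secondary_angle=float(secondary),
            table=(lat_cm * 10.0, vert_cm * 10.0, long_cm * 10.0),
            sid=sid_cm * 10.0, fd=fd_cm * 10.0, spd=810.0,
        )
        r = read_merged(geom, gain=gain, offset=offset)
        truth = display_reading(geom)
        assert r.complete
        for f in ("primary_deg", "secondary_deg", "table_long_cm", "table_lat_cm",
                  "table_vert_cm", "sid_cm", "fd_cm"):
            assert getattr(r, f) == getattr(truth, f)


class TestToCArmGeometry:
    def test_unit_conversion_and_config(self):
        geom_in = CArmGeometry(
            primary_angle=-26.0, table=(-70.0, 60.0, -640.0),
            sid=1200.0, fd=150.0, spd=810.0,
        )
        r = read_merged(geom_in)
        geom = to_carm_geometry(r, CONFIG)
        assert geom.sid == 1200.0  # SID 120 cm -> 1200 mm
        assert geom.table == (-70.0, 60.0, -640.0)
        assert geom.primary_angle == -26.0
        assert geom.spd == 810.0

    def test_fd_override_sets_calibrated_pitch(self):
        geom_in = CArmGeometry(sid=1200.0, fd=150.0, spd=810.0)
        geom = to_carm_geometry(read_merged(geom_in), CONFIG)
        assert geom.pitch == FD_PITCH[15]
        assert geom.pitch != geom.fd / np.hypot(geom.n_u, geom.n_v)

    def test_unknown_fd_rejected(self):
        geom_in = CArmGeometry(sid=1200.0, fd=170.0, spd=810.0)
        with pytest.raises(ValueError, match="FD 17"):
            to_carm_geometry(read_merged(geom_in), CONFIG)

    def test_incomplete_reading_rejected(self, layout):
        geom_in = CArmGeometry(sid=1200.0, fd=150.0, spd=810.0)
        frame = render_frame(EMPTY, geom_in, layout, page="table")
        r = read_geometry(frame.raster, layout)
        with pytest.raises(ValueError, match="invalid fields"):
            to_carm_geometry(r, CONFIG)

    def test_geometry_render_read_convert_round_trip(self, rng):
        for _ in range(5):
            geom_in = CArmGeometry(
                primary_angle=float(rng.integers(-185, 186)),
                secondary_angle=float(rng.integers(-90, 91)),
                table=tuple(10.0 * rng.integers(-99, 100, 3)),
                sid=10.0 * float(rng.integers(90, 131)),
                fd=150.0,
                spd=810.0,
            )
            geom_out = to_carm_geometry(read_merged(geom_in), CONFIG)
            assert geom_out.primary_angle == geom_in.primary_angle
            assert geom_out.secondary_angle == geom_in.secondary_angle
            assert geom_out.table == geom_in.table
            assert geom_out.sid == geom_in.sid


class TestPanelLayout:
    def test_json_round_trip(self, layout, tmp_path):
        layout.save(tmp_path / "layout.json")
        again = PanelLayout.load(tmp_path / "layout.json")
        assert again.cells == layout.cells
        for ch in layout.glyphs:
            assert np.array_equal(again.glyphs[ch], layout.glyphs[ch])
        assert again.field_cells == layout.field_cells
        assert np.array_equal(again.degree_mark, layout.degree_mark)

    def test_thirteen_cells_enforced(self, layout):
        assert len(layout.cells) == 13
        with pytest.raises(ValueError, match="13"):
            PanelLayout(
                cells=layout.cells[:-1],
                glyphs=layout.glyphs,
                letter_glyphs=layout.letter_glyphs,
                field_cells=layout.field_cells,
                degree_mark_pos=layout.degree_mark_pos,
                degree_mark=layout.degree_mark,
                sign_cells=layout.sign_cells,
                word_positions=layout.word_positions,
            )
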