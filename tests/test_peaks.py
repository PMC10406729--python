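"""Peak-table parsing and image rasterization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsqcnet.peaks import (
    DEFAULT_BOUNDS,
    GRID_SIZE,
    Peak,
    PeakList,
    Phase,
    SpectrumBounds,
    parse_peak_table,
    rasterize,
    remove_peak,
    serialize_peak_table,
)


class TestParsing:
    def test_two_column_table(self):
        pl = parse_peak_table("6.30\t92.9\n6.19\t97.8")
        assert len(pl) == 2
        assert (pl[0].h_shift, pl[0].c_shift) == (6.30, 92.9)
        assert (pl[1].h_shift, pl[1].c_shift) == (6.19, 97.8)
        assert pl[0].phase is Phase.UNKNOWN and pl[0].intensity == 1.0

    def test_empty_table_is_empty_list_not_error(self):
        assert len(parse_peak_table("")) == 0
        assert len(parse_peak_table("\n  \n# only a comment\n")) == 0

    def test_phase_and_intensity_columns(self):
        pl = parse_peak_table("4.30\t102.0\t+1\t0.5")
        assert len(pl) == 1
        assert pl[0].phase is Phase.POSITIVE
        assert pl[0].intensity == 0.5

    @pytest.mark.parametrize(
        "token,phase",
        [("+1", Phase.POSITIVE), ("-1", Phase.NEGATIVE), ("CH2", Phase.NEGATIVE),
         ("CH", Phase.POSITIVE), ("CH3", Phase.POSITIVE)],
    )
    def test_phase_tokens(self, token, phase):
        assert parse_peak_table(f"1.0\t20.0\t{token}")[0].phase is phase

    @pytest.mark.parametrize("text", ["1.0,20.0\n2.0,40.0", "1.0 20.0\n2.0 40.0"])
    def test_csv_and_whitespace_delimiters(self, text):
        pl = parse_peak_table(text)
        assert [(p.h_shift, p.c_shift) for p in pl] == [(1.0, 20.0), (2.0, 40.0)]

    def test_header_and_comments_skipped(self):
        pl = parse_peak_table("# edited HSQC\nH_ppm\tC_ppm\n6.30\t92.9\n")
        assert len(pl) == 1

    def test_malformed_numeric_names_line(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_peak_table("6.30\t92.9\n6.1x\t97.8")

    def test_order_preserved_and_roundtrip(self):
        pl = parse_peak_table("2.2\t30.0\t-1\t0.25\n1.1\t20.0\t+1\t1.0")
        rt = parse_peak_table(serialize_peak_table(pl), edited=pl.edited)
        assert [(p.h_shift, p.c_shift, p.phase, p.intensity) for p in rt] == [
            (p.h_shift, p.c_shift, p.phase, p.intensity) for p in pl
        ]

    @given(
        st.lists(
            st.tuples(
                st.decimals(min_value=0, max_value=13, places=4),
                st.decimals(min_value=0, max_value=230, places=4),
                st.sampled_from(list(Phase)),
                st.decimals(min_value=0, max_value=10, places=4),
            ),
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_serialization_roundtrip_property(self, rows):
        pl = PeakList(
            peaks=tuple(
                Peak(h_shift=float(h), c_shift=float(c), phase=ph, intensity=float(i))
                for h, c, ph, i in rows
            )
        )
        rt = parse_peak_table(serialize_peak_table(pl, precision=4))
        assert len(rt) == len(pl)
        for a, b in zip(pl, rt):
            assert a.h_shift == pytest.approx(b.h_shift, abs=5e-5)
            assert a.c_shift == pytest.approx(b.c_shift, abs=5e-5)
            assert a.intensity == pytest.approx(b.intensity, abs=5e-5)


class TestValidation:
    def test_nonfinite_shift_rejected(self):
        with pytest.raises(ValueError):
            Peak(h_shift=float("nan"), c_shift=1.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            Peak(h_shift=1.0, c_shift=1.0, intensity=-0.1)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            SpectrumBounds(h_min=5.0, h_max=1.0, c_min=0.0, c_max=230.0)


class TestRasterize:
    def test_pixel_mapping_formula(self):
        # row = floor(128*(230-92.9)/230) = 76, col = floor(128*(12.8-6.30)/12.8) = 65
        pl = PeakList(peaks=(Peak(h_shift=6.30, c_shift=92.9),))
        img = rasterize(pl)
        assert img.grid.shape == (128, 128, 1)
        assert img.grid[76, 65, 0] == 1.0
        assert np.count_nonzero(img.grid) == 1

    def test_empty_list_gives_zero_image(self):
        img = rasterize(PeakList())
        assert img.grid.shape == (128, 128, 1)
        assert not img.grid.any()

    def test_same_pixel_max_combine(self):
        pl = PeakList(
            peaks=(
                Peak(h_shift=2.0, c_shift=40.0, intensity=0.4),
                Peak(h_shift=2.0, c_shift=40.0, intensity=0.9),
            )
        )
        img = rasterize(pl)
        assert img.grid.max() == pytest.approx(0.9)

    def test_out_of_frame_peaks_clamp_to_edges(self):
        pl = PeakList(peaks=(Peak(h_shift=-5.0, c_shift=500.0),
                             Peak(h_shift=99.0, c_shift=-50.0)))
        img = rasterize(pl)
        assert img.grid[0, 127, 0] == 1.0   # c above frame -> row 0; h below -> col 127
        assert img.grid[127, 0, 0] == 1.0

    def test_edited_phases_split_channels(self):
        pl = PeakList(
            peaks=(
                Peak(h_shift=2.0, c_shift=30.0, phase=Phase.NEGATIVE),
                Peak(h_shift=7.0, c_shift=120.0, phase=Phase.POSITIVE),
                Peak(h_shift=4.0, c_shift=70.0, phase=Phase.UNKNOWN),
            ),
            edited=True,
        )
        img = rasterize(pl)
        assert img.grid.shape == (128, 128, 2)
        assert np.count_nonzero(img.grid[:, :, 0]) == 2  # positive + unknown
        assert np.count_nonzero(img.grid[:, :, 1]) == 1  # negative

    def test_permutation_invariance_equal_intensities(self):
        peaks = tuple(
            Peak(h_shift=h, c_shift=c)
            for h, c in [(1.0, 20.0), (3.3, 77.0), (6.3, 92.9), (8.1, 140.0)]
        )
        a = rasterize(PeakList(peaks=peaks))
        b = rasterize(PeakList(peaks=peaks[::-1]))
        np.testing.assert_array_equal(a.grid, b.grid)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=12.8, allow_nan=False),
                st.floats(min_value=0, max_value=230, allow_nan=False),
                st.sampled_from(list(Phase)),
            ),
            max_size=20,
        ),
        st.booleans(),
    )
    @settings(max_examples=50, deadline=None)
    def test_nonzero_cells_bounded_by_peak_count(self, rows, edited):
        pl = PeakList(
            peaks=tuple(Peak(h_shift=h, c_shift=c, phase=p) for h, c, p in rows),
            edited=edited,
        )
        img = rasterize(pl)
        assert np.count_nonzero(img.grid) <= len(pl)
        assert (img.grid >= 0).all()

    def test_blur_spreads_impulse(self):
        pl = PeakList(peaks=(Peak(h_shift=6.3, c_shift=92.9),))
        img = rasterize(pl, blur_sigma=1.0)
        assert np.count_nonzero(img.grid) > 1
        assert img.grid.max() == pytest.approx(1.0)


class TestRemovePeak:
    def test_removes_indexed_peak(self):
        pl = parse_peak_table("6.30\t92.9\n6.19\t97.8")
        out = remove_peak(pl, 0)
        assert len(out) == 1 and out[0].h_shift == 6.19
        assert len(pl) == 2  # input unchanged

    def test_single_peak_to_empty(self):
        assert len(remove_peak(parse_peak_table("6.30\t92.9"), 0)) == 0

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            remove_peak(parse_peak_table("6.30\t92.9"), 1)

    def test_commutes_with_rasterize(self):
        pl = parse_peak_table("6.30\t92.9\n6.19\t97.8\n1.2\t22.0")
        reduced = PeakList(peaks=pl.peaks[:1] + pl.peaks[2:])
        np.testing.assert_array_equal(
            rasterize(remove_peak(pl, 1)).grid, rasterize(reduced).grid
        )
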