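import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoscape.metrics import (
    annual_absolute_change,
    annual_percent_change,
    build_sf_matrix,
    core_share,
    patch_stats,
    sf_change_table,
)
from morphoscape.mspa import MspaParams, MspaSegmentation, segment
from morphoscape.nomenclature import FUNCTION_NAMES, MSPA_CODES, STRUCTURE_NAMES

STAGES = [("urbanisation", 1949, 1974), ("suburbanisation", 1974, 1999),
          ("counter_urbanisation", 1999, 2016)]


def seg_from_types(types):
    return MspaSegmentation(types=np.asarray(types, dtype=np.uint8), params=MspaParams())


class TestPatchStats:
    def test_single_core_patch(self):
        types = np.zeros((5, 5), dtype=int)
        types[1:4, 1:4] = MSPA_CODES["core"]
        stats = patch_stats(seg_from_types(types), cell_size=100)
        row = stats.set_index("morphology").loc["core"]
        assert row.patch_count == 1
        assert row.total_area_ha == 9.0
        assert row.mean_patch_size_ha == 9.0

    def test_empty_segmentation_all_zero(self):
        stats = patch_stats(seg_from_types(np.zeros((4, 4), dtype=int)))
        assert (stats.patch_count == 0).all()
        assert (stats.mean_patch_size_ha == 0).all()

    def test_two_islets_mean(self):
        types = np.zeros((6, 8), dtype=int)
        types[0, 0:2] = MSPA_CODES["islet"]  # 2 px
        types[4, 4:6] = MSPA_CODES["islet"]
        types[5, 4:6] = MSPA_CODES["islet"]  # 4 px together
        stats = patch_stats(seg_from_types(types), cell_size=100)
        row = stats.set_index("morphology").loc["islet"]
        assert row.patch_count == 2
        assert row.mean_patch_size_ha == 3.0

    def test_mean_times_count_equals_total(self, rng):
        types = rng.integers(0, 8, size=(15, 15))
        stats = patch_stats(seg_from_types(types), cell_size=50)
        recon = stats.mean_patch_size_ha * stats.patch_count
        np.testing.assert_allclose(recon, stats.total_area_ha, atol=1e-9)


class TestCoreShare:
    def test_square_with_edge(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        assert core_share(segment(mask)) == pytest.approx(100 * 9 / 25)

    def test_single_pixel_no_core(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        assert core_share(segment(mask)) == 0.0

    def test_all_foreground_open_border_is_100(self):
        seg = segment(np.ones((4, 4), dtype=bool), MspaParams(border_condition="foreground"))
        assert core_share(seg) == 100.0

    def test_empty_foreground_fails(self):
        with pytest.raises(ValueError, match="empty"):
            core_share(seg_from_types(np.zeros((3, 3), dtype=int)))


class TestChangeRates:
    def test_linear_convention_matches_printed_core_share_rates(self):
        # arable land urbanisation and crop-mosaic counter-urbanisation
        assert annual_percent_change(61.6, 50.4, 25) == pytest.approx(-0.73, abs=0.005)
        assert annual_percent_change(4.2, 5.4, 17) == pytest.approx(1.68, abs=0.005)

    def test_no_change_is_zero(self):
        assert annual_percent_change(5.0, 5.0, 10) == 0.0
        assert annual_absolute_change(5.0, 5.0, 10) == 0.0

    def test_absolute_convention_matches_printed_patch_size_rates(self):
        assert annual_absolute_change(20.3, 23.3, 25) == pytest.approx(0.12, abs=0.005)
        assert annual_absolute_change(73.2, 35.7, 25) == pytest.approx(-1.50, abs=0.005)

    def test_compound_mode(self):
        # doubling over 10 years is ~7.18%/yr compound
        assert annual_percent_change(1, 2, 10, compound=True) == pytest.approx(7.177, abs=0.001)

    def test_zero_start_fails(self):
        with pytest.raises(ValueError):
            annual_percent_change(0.0, 1.0, 10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=-1e3, max_value=1e3),
        st.floats(min_value=-1e3, max_value=1e3),
        st.integers(min_value=1, max_value=100),
    )
    def test_absolute_rate_antisymmetric(self, v0, v1, dt):
        assert annual_absolute_change(v0, v1, dt) == pytest.approx(
            -annual_absolute_change(v1, v0, dt), abs=1e-9
        )


class TestSfMatrix:
    def test_single_row_single_cell(self):
        stats = pd.DataFrame(
            [{"year": 1999, "land_use": "arable", "morphology": "core",
              "patch_count": 1, "total_area_ha": 5.0, "mean_patch_size_ha": 5.0}]
        )
        mat = build_sf_matrix(stats, 1999)
        assert mat.shape == (9, 7)
        assert mat.loc["arable", "core"] == 5.0
        assert mat.to_numpy().sum() == 5.0

    def test_row_order_irrelevant(self, rng):
        rows = [
            {"year": 2000, "land_use": f, "morphology": s,
             "patch_count": 1, "total_area_ha": v, "mean_patch_size_ha": v}
            for v, (f, s) in enumerate(
                (f, s) for f in FUNCTION_NAMES for s in STRUCTURE_NAMES
            )
        ]
        stats = pd.DataFrame(rows)
        shuffled = stats.sample(frac=1, random_state=7)
        pd.testing.assert_frame_equal(build_sf_matrix(stats, 2000), build_sf_matrix(shuffled, 2000))

    def test_printed_1949_block_reproduced(self, patch_tables):
        # keyed reconstruction from long-format rows matches the year table
        long = []
        for f in FUNCTION_NAMES:
            for s in STRUCTURE_NAMES:
                long.append({"year": 1949, "land_use": f, "morphology": s,
                             "patch_count": 1, "total_area_ha": np.nan,
                             "mean_patch_size_ha": patch_tables[1949].loc[f, s]})
        mat = build_sf_matrix(pd.DataFrame(long), 1949)
        pd.testing.assert_frame_equal(mat, patch_tables[1949], check_names=False)


class TestFullTableRegression:
    def test_absolute_rates_reproduce_printed_change_table(self, patch_tables, printed_changes):
        """(v1-v0)/dt applied to every mean-patch-size cell pair matches the
        printed per-stage change table to +/-0.01 (7x9x3 cells)."""
        for stage, y0, y1 in STAGES:
            dt = y1 - y0
            printed = printed_changes[printed_changes.stage == stage].set_index(["function", "structure"])
            for f in FUNCTION_NAMES:
                for s in STRUCTURE_NAMES:
                    got = annual_absolute_change(
                        patch_tables[y0].loc[f, s], patch_tables[y1].loc[f, s], dt
                    )
                    want = printed.loc[(f, s), "annual_change_ha"]
                    assert got == pytest.approx(want, abs=0.01), (stage, f, s)

    def test_sf_change_table_matches_cellwise_rates(self, patch_tables):
        windows = [(lbl, y0, y1) for lbl, y0, y1 in STAGES]
        table = sf_change_table(patch_tables, windows).set_index(["stage", "function", "structure"])
        assert len(table) == 3 * 63
        got = table.loc[("urbanisation", "built_up", "core"), "annual_change_ha"]
        assert got == pytest.approx((23.3 - 20.3) / 25)
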