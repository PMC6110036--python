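import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselmorph.morphometry import (
    INDEX_COLUMNS,
    areas_from_contours,
    compute_indices,
    indices_from_areas,
    polygon_area,
    summarize,
)

PI = math.pi


def regular_polygon(radius, n=128, center=(0.0, 0.0), phase=0.0):
    theta = np.linspace(0, 2 * PI, n, endpoint=False) + phase
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


def regular_polygon_area(radius, n):
    # closed-form area of a regular n-gon with circumradius r
    return 0.5 * n * radius**2 * math.sin(2 * PI / n)


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == 1.0

    def test_orientation_reversal(self):
        assert polygon_area([(0, 1), (1, 1), (1, 0), (0, 0)]) == 1.0

    def test_explicitly_closed(self):
        assert polygon_area([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]) == 1.0

    def test_1024_gon_approximates_circle(self):
        area = polygon_area(regular_polygon(1.0, n=1024))
        assert area == pytest.approx(regular_polygon_area(1.0, 1024), rel=1e-12)
        assert area == pytest.approx(PI, rel=1e-4)

    def test_too_few_vertices(self):
        with pytest.raises(ValueError, match="3 distinct"):
            polygon_area([(0, 0), (1, 1)])

    def test_degenerate_duplicates(self):
        with pytest.raises(ValueError, match="3 distinct"):
            polygon_area([(0, 0), (0, 0), (1, 1), (1, 1)])

    def test_self_intersection(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            polygon_area([(0, 0), (1, 1), (1, 0), (0, 1)])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.floats(min_value=-100, max_value=100),
        st.floats(min_value=-100, max_value=100),
        st.floats(min_value=0, max_value=2 * PI),
        st.integers(min_value=0, max_value=63),
    )
    def test_rigid_motion_and_cyclic_invariance(self, dx, dy, phase, shift):
        base = regular_polygon(2.0, n=64)
        moved = regular_polygon(2.0, n=64, center=(dx, dy), phase=phase)
        rolled = np.roll(base, shift, axis=0)
        expected = polygon_area(base)
        assert polygon_area(moved) == pytest.approx(expected, rel=1e-9)
        assert polygon_area(rolled) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance_relation(self):
        # halving the length scale quarters areas
        big = regular_polygon(2.0, n=64)
        assert polygon_area(big / 2) == pytest.approx(polygon_area(big) / 4, rel=1e-12)


class TestComputeIndices:
    def test_concentric_radii_3_2_1(self):
        rec = compute_indices(9 * PI, 4 * PI, PI)
        assert rec.MA == pytest.approx(5 * PI)
        assert rec.IA == pytest.approx(3 * PI)
        assert rec.MT == pytest.approx(1.0)
        assert rec.IT == pytest.approx(2.0)  # printed mode: outer membrane reference
        assert rec.HRIA == pytest.approx(0.375)
        assert rec.HRIT == pytest.approx(2 / 3)

    def test_anatomical_mode_it(self):
        rec = compute_indices(9 * PI, 4 * PI, PI, mode="anatomical")
        assert rec.IT == pytest.approx(1.0)

    def test_degenerate_denominators_yield_zero(self):
        rec = compute_indices(4 * PI, 4 * PI, 4 * PI)
        assert rec.IA == 0 and rec.IT == 0
        assert rec.HRIA == 0.0 and rec.HRIT == 0.0

    def test_no_intima_with_media(self):
        rec = compute_indices(4 * PI, PI, PI)
        assert rec.HRIA == 0.0
        # printed-mode IT spans the media too, so HRIT = MT/(MT+MT) here
        assert rec.HRIT == pytest.approx(0.5)
        assert compute_indices(4 * PI, PI, PI, mode="anatomical").HRIT == 0.0

    def test_nesting_violation_names_slice(self):
        with pytest.raises(ValueError, match="slice model/3/2"):
            compute_indices(1.0, 2.0, 0.5, label="model/3/2")

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            compute_indices(3.0, 2.0, 1.0, mode="hybrid")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.floats(min_value=0.01, max_value=50),
        st.floats(min_value=0.0, max_value=50),
        st.floats(min_value=0.01, max_value=50),
    )
    def test_monotone_in_a_iel(self, a_lumen, intima, media):
        a_iel = a_lumen + intima
        a_eel = a_iel + media
        lo = compute_indices(a_eel, a_iel, a_lumen)
        hi = compute_indices(a_eel, min(a_iel + 0.5 * media, a_eel), a_lumen)
        assert hi.IA >= lo.IA
        assert hi.MA <= lo.MA
        assert hi.HRIA >= lo.HRIA

    def test_units_scaling(self):
        # quartering areas (halving lengths) halves thicknesses, fixes ratios
        rec = compute_indices(9 * PI, 4 * PI, PI)
        half = compute_indices(9 * PI / 4, PI, PI / 4)
        assert half.MT == pytest.approx(rec.MT / 2)
        assert half.IT == pytest.approx(rec.IT / 2)
        assert half.HRIA == pytest.approx(rec.HRIA)
        assert half.HRIT == pytest.approx(rec.HRIT)


class TestAreasFromContours:
    @staticmethod
    def contour_frame(radii_by_slice):
        rows = []
        for slice_id, radii in radii_by_slice.items():
            for ring, r in zip(("EEL", "IEL", "LUMEN"), radii):
                poly = regular_polygon(r, n=128)
                for i, (x, y) in enumerate(poly):
                    rows.append(
                        {
                            "group": "g",
                            "animal": 1,
                            "slice": slice_id,
                            "ring": ring,
                            "vertex_index": i,
                            "x_um": x,
                            "y_um": y,
                        }
                    )
        return pd.DataFrame(rows)

    def test_fast_path_matches_validated_path(self):
        frame = self.contour_frame({1: (3, 2, 1), 2: (4, 3, 2)})
        fast = areas_from_contours(frame, validate=False)
        slow = areas_from_contours(frame, validate=True)
        pd.testing.assert_frame_equal(fast, slow)

    def test_areas_match_closed_form(self):
        frame = self.contour_frame({1: (3, 2, 1)})
        areas = areas_from_contours(frame)
        assert areas.loc[0, "a_eel_um2"] == pytest.approx(regular_polygon_area(3, 128))
        assert areas.loc[0, "a_lumen_um2"] == pytest.approx(regular_polygon_area(1, 128))

    def test_missing_ring_errors(self):
        frame = self.contour_frame({1: (3, 2, 1)})
        with pytest.raises(ValueError, match="LUMEN"):
            areas_from_contours(frame[frame.ring != "LUMEN"])

    def test_missing_column_errors(self):
        with pytest.raises(ValueError, match="missing columns"):
            areas_from_contours(pd.DataFrame({"group": []}))


class TestSummarize:
    @staticmethod
    def slice_frame(values_by_animal):
        rows = []
        for animal, values in values_by_animal.items():
            for i, v in enumerate(values):
                rows.append({"group": "g", "animal": animal, "slice": i, "HRIA": v})
        return pd.DataFrame(rows)

    def test_animal_mean_over_slices(self):
        per_animal, _ = summarize(self.slice_frame({1: [0.3, 0.5]}), ("HRIA",))
        assert per_animal.loc[0, "HRIA"] == pytest.approx(0.4)

    def test_group_sd_zero_for_identical_animals(self):
        _, per_group = summarize(self.slice_frame({1: [0.4], 2: [0.4], 3: [0.4]}), ("HRIA",))
        assert per_group.loc[0, "HRIA_mean"] == pytest.approx(0.4)
        assert per_group.loc[0, "HRIA_sd"] == pytest.approx(0.0)
        assert per_group.loc[0, "n"] == 3

    def test_group_sample_sd(self):
        # hand arithmetic: {0.2, 0.4, 0.6} -> mean 0.4, sample SD 0.2
        _, per_group = summarize(self.slice_frame({1: [0.2], 2: [0.4], 3: [0.6]}), ("HRIA",))
        assert per_group.loc[0, "HRIA_mean"] == pytest.approx(0.4)
        assert per_group.loc[0, "HRIA_sd"] == pytest.approx(0.2)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no records"):
            summarize(pd.DataFrame(columns=["group", "animal", "HRIA"]), ("HRIA",))


class TestClosedFormPipeline:
    def test_concentric_fixture_all_indices(self):
        # noise-free concentric circles, radii 3/2/1 um, 128-gon discretization
        frame = TestAreasFromContours.contour_frame({1: (3, 2, 1)})
        per_slice = indices_from_areas(areas_from_contours(frame))
        row = per_slice.iloc[0]
        expected = {"MA": 5 * PI, "IA": 3 * PI, "MT": 1.0, "IT": 2.0, "HRIA": 0.375, "HRIT": 2 / 3}
        for index in INDEX_COLUMNS:
            assert row[index] == pytest.approx(expected[index], rel=1e-3), index
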