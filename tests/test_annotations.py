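"""Geometry, normalization and series assembly."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sharkheal.annotations import (
    AnchorScale,
    Polygon,
    WoundAnnotation,
    build_series,
    load_cases_csv,
    load_cases_json,
    measurements_frame,
    normalized_extent,
    polygon_area,
    polygon_perimeter,
)
from sharkheal.errors import (
    AmbiguousDateError,
    InsufficientDataError,
    InvalidGeometryError,
)

UNIT_SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]
TRIANGLE_345 = [(0, 0), (4, 0), (0, 3)]


def _annotation(day, sections, anchor=None, injury="inj1", shark="WS1"):
    return WoundAnnotation(
        shark_id=shark,
        injury_id=injury,
        sighting_date=date(2016, 1, 1) + __import__("datetime").timedelta(days=day),
        sections=tuple(Polygon(s) for s in sections),
        anchor=AnchorScale(Polygon(anchor or [(0, 0), (5, 0), (5, 5), (0, 5)])),
    )


@pytest.mark.parametrize(
    "verts, area, perim",
    [
        (UNIT_SQUARE, 1.0, 4.0),
        (TRIANGLE_345, 6.0, 12.0),
        (list(reversed(UNIT_SQUARE)), 1.0, 4.0),  # orientation-independent
    ],
)
def test_area_and_perimeter_closed_forms(verts, area, perim):
    p = Polygon(verts)
    assert polygon_area(p) == pytest.approx(area)
    assert polygon_perimeter(p) == pytest.approx(perim)


def test_regular_hexagon_perimeter():
    hexagon = Polygon(
        [(math.cos(k * math.pi / 3), math.sin(k * math.pi / 3)) for k in range(6)]
    )
    assert polygon_perimeter(hexagon) == pytest.approx(6.0, abs=1e-9)


def test_pentagon_area_matches_monte_carlo_oracle(rng):
    verts = [(0, 0), (5, 1), (6, 4), (2, 6), (-1, 3)]
    xs, ys = zip(*verts)
    n = 10**6
    px = rng.uniform(min(xs), max(xs), n)
    py = rng.uniform(min(ys), max(ys), n)
    from matplotlib.path import Path

    inside = Path(verts).contains_points(np.column_stack([px, py]))
    box = (max(xs) - min(xs)) * (max(ys) - min(ys))
    mc_area = inside.mean() * box
    assert polygon_area(Polygon(verts)) == pytest.approx(mc_area, rel=0.005)


@pytest.mark.parametrize(
    "verts",
    [
        [(0, 0), (1, 1)],  # too few vertices
        [(0, 0), (0, 0), (1, 1), (1, 0)],  # consecutive duplicate
        [(0, 0), (2, 2), (2, 0), (0, 2)],  # bow-tie self-intersection
        [(0, 0), (1, 0), (2, 0)],  # collinear, zero area
    ],
)
def test_degenerate_polygons_rejected(verts):
    with pytest.raises(InvalidGeometryError):
        Polygon(verts)


def test_normalized_extent_single_and_summed_sections():
    # one section 100 px² against a 25 px² anchor
    big = [(0, 0), (10, 0), (10, 10), (0, 10)]
    anchor = [(0, 0), (5, 0), (5, 5), (0, 5)]
    m = normalized_extent(_annotation(0, [big], anchor))
    assert m.area_ratio == pytest.approx(4.0)
    # two sections 30 + 20 px² against the same anchor
    s1 = [(0, 0), (6, 0), (6, 5), (0, 5)]
    s2 = [(20, 0), (24, 0), (24, 5), (20, 5)]
    m2 = normalized_extent(_annotation(0, [s1, s2], anchor))
    assert m2.area_ratio == pytest.approx(2.0)


@given(scale=st.floats(min_value=0.01, max_value=100.0))
@settings(deadline=None, max_examples=50)
def test_ratios_invariant_under_pixel_density(scale):
    wound = [(0, 0), (10, 0), (10, 10), (0, 10)]
    anchor = [(20, 20), (25, 20), (25, 25), (20, 25)]
    base = normalized_extent(_annotation(0, [wound], anchor))
    scaled = normalized_extent(
        _annotation(
            0,
            [[(x * scale, y * scale) for x, y in wound]],
            [(x * scale, y * scale) for x, y in anchor],
        )
    )
    assert scaled.area_ratio == pytest.approx(base.area_ratio, rel=1e-9)
    assert scaled.perimeter_ratio == pytest.approx(base.perimeter_ratio, rel=1e-9)


@given(
    dx=st.floats(-1e3, 1e3),
    dy=st.floats(-1e3, 1e3),
    theta=st.floats(0, 2 * math.pi),
)
@settings(deadline=None, max_examples=50)
def test_area_perimeter_rigid_motion_invariant(dx, dy, theta):
    verts = [(0, 0), (5, 1), (6, 4), (2, 6), (-1, 3)]
    c, s = math.cos(theta), math.sin(theta)
    moved = [(c * x - s * y + dx, s * x + c * y + dy) for x, y in verts]
    assert polygon_area(Polygon(moved)) == pytest.approx(
        polygon_area(Polygon(verts)), rel=1e-9
    )
    assert polygon_perimeter(Polygon(moved)) == pytest.approx(
        polygon_perimeter(Polygon(verts)), rel=1e-9
    )


@given(cut=st.floats(min_value=0.1, max_value=9.9))
@settings(deadline=None, max_examples=50)
def test_section_split_conserves_area(cut):
    whole = Polygon([(0, 0), (10, 0), (10, 4), (0, 4)])
    left = Polygon([(0, 0), (cut, 0), (cut, 4), (0, 4)])
    right = Polygon([(cut, 0), (10, 0), (10, 4), (cut, 4)])
    total = polygon_area(left) + polygon_area(right)
    assert abs(total - polygon_area(whole)) < 1e-9 * polygon_area(whole)


def test_build_series_day_offsets_and_ordering():
    wound = [(0, 0), (10, 0), (10, 10), (0, 10)]
    anns = [_annotation(d, [wound]) for d in (159, 0, 16)]  # unordered input
    series = build_series(anns)
    assert series.day_offsets == (0, 16, 159)
    assert len(series) == 3


def test_build_series_rejects_bad_inputs():
    wound = [(0, 0), (10, 0), (10, 10), (0, 10)]
    with pytest.raises(InsufficientDataError):
        build_series([_annotation(0, [wound])])
    with pytest.raises(AmbiguousDateError):
        build_series([_annotation(3, [wound]), _annotation(3, [wound])])
    with pytest.raises(ValueError):
        build_series(
            [_annotation(0, [wound], injury="a"), _annotation(5, [wound], injury="b")]
        )


def test_json_round_trip(tmp_path, small_cohort):
    path = tmp_path / "cohort.json"
    small_cohort.to_json(path)
    cases = load_cases_json(path)
    assert set(cases) == set(small_cohort.annotations)
    orig = measurements_frame(small_cohort.series_list())
    loaded = measurements_frame(
        build_series(v) for v in (cases[k] for k in sorted(cases))
    )
    assert np.allclose(
        orig.sort_values(["injury_id", "day_offset"])["area_ratio"].to_numpy(),
        loaded.sort_values(["injury_id", "day_offset"])["area_ratio"].to_numpy(),
    )


def test_csv_loader(tmp_path):
    rows = ["injury_id,shark_id,date,image_id,role,x,y"]
    for role, verts in [
        ("anchor", [(0, 0), (5, 0), (5, 5), (0, 5)]),
        ("section_0", [(0, 0), (10, 0), (10, 10), (0, 10)]),
    ]:
        for day in ("2016-01-01", "2016-01-11"):
            for x, y in verts:
                rows.append(f"c1,WS9,{day},img,{role},{x},{y}")
    f = tmp_path / "case.csv"
    f.write_text("\n".join(rows))
    cases = load_cases_csv(f)
    series = build_series(cases["c1"])
    assert series.day_offsets == (0, 10)
    assert series.measurements[0].area_ratio == pytest.approx(4.0)
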