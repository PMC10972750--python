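"""Distance engine: gap distances, vessel capsules, morphometry, tracks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from marrowmap.errors import EmptyTargetError, MarrowError
from marrowmap.geometry import (
    CellRecord,
    TissueVolume,
    VesselNetwork,
    VesselSegment,
    cells_dataframe,
    daughter_separation,
    distance_to_vessel,
    distance_to_vessels,
    gap_distance_cells,
    measure_vessels,
    nearest_by_type,
    nearest_gap,
)


def _cell(cid, cell_type, centre, radius):
    return CellRecord(id=cid, cell_type=cell_type, centre=tuple(centre),
                      radius_um=radius)


# ---------------------------------------------------------------------------
# cell–cell gaps
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "c1,r1,c2,r2,expected",
    [
        ((0, 0, 0), 5.0, (20, 0, 0), 5.0, 10.0),        # plain separation
        ((1, 2, 3), 4.0, (1, 2, 3), 6.0, -10.0),        # coincident centres
        ((0, 0, 0), 3.0, (0, 3, 4), 2.0, 0.0),          # exactly touching
    ],
)
def test_gap_distance_examples(c1, r1, c2, r2, expected):
    a = _cell(1, "CFU-E", c1, r1)
    b = _cell(2, "CFU-E", c2, r2)
    assert gap_distance_cells(a, b) == pytest.approx(expected)


def test_self_distance_is_undefined():
    a = _cell(1, "CLP", (0, 0, 0), 3.0)
    b = _cell(1, "CLP", (5, 0, 0), 3.0)
    with pytest.raises(MarrowError):
        gap_distance_cells(a, b)


@settings(max_examples=200, deadline=None)
@given(
    p=st.tuples(*[st.floats(-500, 500) for _ in range(3)]),
    q=st.tuples(*[st.floats(-500, 500) for _ in range(3)]),
    r1=st.floats(0.5, 20),
    r2=st.floats(0.5, 20),
)
def test_gap_is_symmetric_and_matches_direct_formula(p, q, r1, r2):
    a = _cell(1, "CFU-E", p, r1)
    b = _cell(2, "CLP", q, r2)
    expected = math.dist(p, q) - r1 - r2
    assert gap_distance_cells(a, b) == pytest.approx(expected, abs=1e-9)
    assert gap_distance_cells(a, b) == pytest.approx(
        gap_distance_cells(b, a), abs=1e-12
    )


def test_thousand_random_pairs_match_bruteforce_oracle():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        p, q = rng.uniform(0, 300, 3), rng.uniform(0, 300, 3)
        r1, r2 = rng.uniform(1, 10, 2)
        a = _cell(1, "CFU-E", p, r1)
        b = _cell(2, "pre B", q, r2)
        oracle = math.sqrt(sum((x - y) ** 2 for x, y in zip(p, q))) - r1 - r2
        assert abs(gap_distance_cells(a, b) - oracle) < 1e-9


# ---------------------------------------------------------------------------
# nearest-neighbour queries
# ---------------------------------------------------------------------------

def test_nearest_by_type_single_pair():
    cells = cells_dataframe(
        [
            _cell(1, "CLP", (0, 0, 0), 5.0),
            _cell(2, "pre B", (50, 0, 0), 5.0),
        ]
    )
    out = nearest_by_type(cells, "CLP", "pre B")
    assert len(out) == 1
    assert out["gap_um"].iloc[0] == pytest.approx(40.0)
    assert out["nearest_id"].iloc[0] == 2


def test_same_type_query_never_returns_self():
    cells = cells_dataframe(
        [
            _cell(i, "CFU-E", (10.0 * i, 0, 0), 5.0)
            for i in range(3)
        ]
    )
    out = nearest_by_type(cells, "CFU-E", "CFU-E")
    assert (out["nearest_id"] != out["id"]).all()
    assert out["gap_um"].tolist() == pytest.approx([0.0, 0.0, 0.0])


def test_empty_target_raises_distinct_error():
    cells = cells_dataframe([_cell(1, "CLP", (0, 0, 0), 5.0)])
    with pytest.raises(EmptyTargetError):
        nearest_by_type(cells, "CLP", "pre B")


def _bruteforce_nearest(sources, targets):
    spos = sources[["x_um", "y_um", "z_um"]].to_numpy()
    tpos = targets[["x_um", "y_um", "z_um"]].to_numpy()
    out = []
    for i in range(len(sources)):
        best = math.inf
        for j in range(len(targets)):
            if targets["id"].iloc[j] == sources["id"].iloc[i]:
                continue
            g = (
                math.dist(spos[i], tpos[j])
                - sources["radius_um"].iloc[i]
                - targets["radius_um"].iloc[j]
            )
            best = min(best, g)
        out.append(best)
    return np.asarray(out)


def test_nearest_gap_matches_allpairs_oracle_on_500_cells():
    rng = np.random.default_rng(3)
    records = [
        _cell(i, "CFU-E" if i % 2 else "pre B",
              rng.uniform(0, 400, 3), rng.uniform(2, 8))
        for i in range(500)
    ]
    cells = cells_dataframe(records)
    src = cells[cells["cell_type"] == "CFU-E"]
    tgt = cells[cells["cell_type"] == "pre B"]
    fast = nearest_gap(src, tgt)["gap_um"].to_numpy()
    assert np.allclose(fast, _bruteforce_nearest(src, tgt), atol=1e-9)


def test_kdtree_path_agrees_with_bruteforce():
    # > 1500 targets activates the accelerated path; radii vary so the
    # radius-corrected minimum differs from the centre-distance minimum
    rng = np.random.default_rng(4)
    targets = cells_dataframe(
        [_cell(i, "pre B", rng.uniform(0, 200, 3), rng.uniform(1, 10))
         for i in range(1700)]
    )
    sources = cells_dataframe(
        [_cell(10_000 + i, "CLP", rng.uniform(0, 200, 3), 4.0)
         for i in range(40)]
    )
    fast = nearest_gap(sources, targets)["gap_um"].to_numpy()
    assert np.allclose(fast, _bruteforce_nearest(sources, targets), atol=1e-9)


def test_adding_a_target_never_increases_nearest_distance():
    rng = np.random.default_rng(5)
    targets = [
        _cell(i, "pre B", rng.uniform(0, 100, 3), 3.0) for i in range(20)
    ]
    sources = cells_dataframe(
        [_cell(100 + i, "CLP", rng.uniform(0, 100, 3), 4.0) for i in range(10)]
    )
    before = nearest_gap(sources, cells_dataframe(targets))["gap_um"]
    extended = cells_dataframe(targets + [_cell(999, "pre B", (50, 50, 10), 3.0)])
    after = nearest_gap(sources, extended)["gap_um"]
    assert (after <= before + 1e-12).all()


# ---------------------------------------------------------------------------
# vessel distances
# ---------------------------------------------------------------------------

def _straight(sid="s0", radius=10.0, vclass="sinusoid"):
    return VesselSegment(
        id=sid, points=np.array([[0.0, 0, 0], [100.0, 0, 0]]),
        radius_um=radius, vclass=vclass,
    )


def test_perpendicular_gap_to_straight_vessel():
    net = VesselNetwork([_straight()])
    cell = _cell(1, "CFU-E", (50, 20, 0), 5.0)
    res = distance_to_vessel(cell, net, "sinusoid")
    assert res.gap_um == pytest.approx(5.0)
    assert res.nearest_id == "s0"


def test_cell_on_vessel_axis_has_fully_negative_gap():
    net = VesselNetwork([_straight(radius=10.0)])
    cell = _cell(1, "CFU-E", (50, 0, 0), 5.0)
    res = distance_to_vessel(cell, net, "sinusoid")
    assert res.gap_um == pytest.approx(-15.0)


def test_missing_vessel_class_raises():
    net = VesselNetwork([_straight()])
    cell = _cell(1, "CLP", (0, 0, 0), 4.0)
    with pytest.raises(EmptyTargetError):
        distance_to_vessel(cell, net, "arteriole")


def test_vessel_distance_matches_dense_sampling_oracle():
    rng = np.random.default_rng(9)
    pts = np.cumsum(rng.uniform(-15, 15, size=(8, 3)), axis=0) + 100.0
    seg = VesselSegment(id="t", points=pts, radius_um=6.0, vclass="sinusoid")
    net = VesselNetwork([seg])
    cells = cells_dataframe(
        [_cell(i, "CFU-E", rng.uniform(60, 160, 3), 5.0) for i in range(60)]
    )
    got = distance_to_vessels(cells, net, "sinusoid")["gap_um"].to_numpy()
    # oracle: dense sampling of the polyline at 0.05 µm steps
    dense = []
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(2, int(math.dist(a, b) / 0.05))
        dense.append(np.linspace(a, b, n))
    dense = np.concatenate(dense)
    pos = cells[["x_um", "y_um", "z_um"]].to_numpy()
    oracle = (
        np.min(
            np.linalg.norm(pos[:, None, :] - dense[None, :, :], axis=2), axis=1
        )
        - 6.0
        - 5.0
    )
    assert np.allclose(got, oracle, atol=0.01)


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

def test_single_segment_morphometry():
    net = VesselNetwork([_straight(radius=8.0)])
    table, n_branches = measure_vessels(net)
    assert len(table) == 1
    assert table["length_um"].iloc[0] == pytest.approx(100.0)
    assert table["diameter_um"].iloc[0] == pytest.approx(16.0)
    assert n_branches == 0


def test_y_network_has_three_vessels_and_one_branch():
    j = [50.0, 0.0, 0.0]
    net = VesselNetwork(
        [
            VesselSegment("a", np.array([[0, 0, 0], j]), 5.0, "sinusoid"),
            VesselSegment("b", np.array([j, [100, 40, 0]]), 5.0, "sinusoid"),
            VesselSegment("c", np.array([j, [100, -40, 0]]), 5.0, "sinusoid"),
        ]
    )
    table, n_branches = measure_vessels(net)
    assert len(table) == 3
    assert n_branches == 1


def test_degree_two_join_is_one_continuous_vessel():
    net = VesselNetwork(
        [
            VesselSegment("a", np.array([[0, 0, 0], [50.0, 0, 0]]), 4.0,
                          "sinusoid"),
            VesselSegment("b", np.array([[50.0, 0, 0], [120.0, 0, 0]]), 6.0,
                          "sinusoid"),
        ]
    )
    table, n_branches = measure_vessels(net)
    assert len(table) == 1
    assert table["length_um"].iloc[0] == pytest.approx(120.0)
    assert table["diameter_um"].iloc[0] == pytest.approx(12.0)  # largest
    assert n_branches == 0


def test_arc_length_equals_independent_chord_sum():
    rng = np.random.default_rng(12)
    pts = np.cumsum(rng.uniform(-20, 20, size=(12, 3)), axis=0)
    seg = VesselSegment("t", pts, 5.0, "arteriole")
    table, _ = measure_vessels(VesselNetwork([seg]))
    oracle = sum(math.dist(a, b) for a, b in zip(pts[:-1], pts[1:]))
    assert table["length_um"].iloc[0] == pytest.approx(oracle, abs=1e-9)


def test_zero_length_polyline_is_skipped_with_warning():
    good = _straight("ok")
    bad = VesselSegment("bad", np.array([[5.0, 5, 5], [5.0, 5, 5]]), 3.0,
                        "sinusoid")
    with pytest.warns(UserWarning, match="zero-length"):
        table, _ = measure_vessels(VesselNetwork([good, bad]))
    assert table["vessel_id"].nunique() == 1


# ---------------------------------------------------------------------------
# daughter separation
# ---------------------------------------------------------------------------

def _track(points):
    return np.asarray(points, dtype=float)


def test_colocated_stationary_daughters_are_not_separated():
    a = _track([[0, 10, 10, 10], [1, 10, 10, 10], [2, 10, 10, 10]])
    sep, separated = daughter_separation(a, a.copy(), 2.0)
    assert sep == 0.0 and not separated


def test_separation_uses_strict_50um_threshold():
    a = _track([[0, 0, 0, 0], [2, 0, 0, 0]])
    b = _track([[0, 0, 0, 0], [2, 60, 0, 0]])
    sep, separated = daughter_separation(a, b, 2.0)
    assert sep == pytest.approx(60.0) and separated
    b50 = _track([[0, 0, 0, 0], [2, 50, 0, 0]])
    _, separated50 = daughter_separation(a, b50, 2.0)
    assert not separated50


def test_interpolation_between_adjacent_frames_only():
    a = _track([[0, 0, 0, 0], [1, 10, 0, 0], [2, 20, 0, 0]])
    b = _track([[0, 0, 0, 0], [1, 0, 0, 0], [2, 0, 0, 0]])
    sep, _ = daughter_separation(a, b, 1.5)
    assert sep == pytest.approx(15.0)
    gap_track = _track([[0, 0, 0, 0], [3, 30, 0, 0]])  # dropped frames
    with pytest.raises(MarrowError):
        daughter_separation(gap_track, b, 1.5)


def test_cohort_separated_fraction_matches_per_track_enumeration():
    rng = np.random.default_rng(21)
    n = 30
    tracks = []
    for _ in range(n):
        steps_a = rng.normal(0, 15, size=(3, 3))
        steps_b = rng.normal(0, 15, size=(3, 3))
        pa = np.concatenate([[np.zeros(3)], np.cumsum(steps_a, axis=0)])
        pb = np.concatenate([[np.zeros(3)], np.cumsum(steps_b, axis=0)])
        t = np.arange(4.0)[:, None]
        tracks.append((np.hstack([t, pa]), np.hstack([t, pb])))
    got = sum(
        daughter_separation(a, b, 3.0)[1] for a, b in tracks
    )
    oracle = sum(
        1 for a, b in tracks if math.dist(a[-1, 1:], b[-1, 1:]) > 50.0
    )
    assert got == oracle


# ---------------------------------------------------------------------------
# tissue volume
# ---------------------------------------------------------------------------

def test_volume_contains_and_endosteum_distance():
    vol = TissueVolume((100.0, 80.0, 35.0))
    assert vol.area_mm2 == pytest.approx(100 * 80 / 1e6)
    inside = vol.contains(np.array([[10, 10, 10], [101, 10, 10]]))
    assert inside.tolist() == [True, False]
    d = vol.endosteum_distance(np.array([[50, 10, 5], [50, 70, 5]]))
    assert d.tolist() == [10.0, 10.0]
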