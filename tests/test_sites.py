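"""Production-site detection: strings, B sites, myeloid sites, census."""

import math

import numpy as np
import pytest

from marrowmap import (
    DegenerateDataError,
    EmptyTargetError,
    TissueVolume,
    build_volume,
)
from marrowmap.geometry import CellRecord, VesselNetwork, VesselSegment, cells_dataframe
from marrowmap.sites import (
    ProductionSite,
    SiteParams,
    assemble_erythroid_sites,
    census,
    detect_b_sites,
    detect_cfu_e_strings,
    detect_myeloid_sites,
)

from conftest import derive_scene_seeds, small_config

R_CFUE = 12.67 / 2
R_EB = 7.92 / 2


def _net(radius=8.0):
    """One straight sinusoid along x at y=0, z=0."""
    return VesselNetwork(
        [VesselSegment("s0", np.array([[0.0, 0, 0], [600.0, 0, 0]]),
                       radius, "sinusoid")]
    )


def _cell(cid, cell_type, centre, radius):
    return CellRecord(id=cid, cell_type=cell_type, centre=tuple(centre),
                      radius_um=radius)


def _string_cells(n, radius=8.0, start_x=50.0, spacing=12.7, cid0=0):
    """CFU-E touching the vessel surface (gap 0), spaced one diameter."""
    y = radius + R_CFUE  # surface contact
    return [
        _cell(cid0 + i, "CFU-E", (start_x + i * spacing, y, 0.0), R_CFUE)
        for i in range(n)
    ]


def test_five_contiguous_cfue_form_one_string_of_five():
    cells = cells_dataframe(_string_cells(5))
    strings = detect_cfu_e_strings(cells, _net(), SiteParams())
    assert len(strings) == 1
    assert len(strings[0].members["CFU-E"]) == 5


def test_two_cfue_below_minimum_are_not_a_string():
    cells = cells_dataframe(_string_cells(2))
    assert detect_cfu_e_strings(cells, _net(), SiteParams()) == []


def test_detached_cfue_are_excluded_from_strings():
    detached = _cell(99, "CFU-E", (300.0, 80.0, 0.0), R_CFUE)
    cells = cells_dataframe(_string_cells(4) + [detached])
    strings = detect_cfu_e_strings(cells, _net(), SiteParams())
    assert len(strings) == 1
    assert 99 not in strings[0].members["CFU-E"]


def test_no_sinusoids_is_an_empty_target_error():
    cells = cells_dataframe(_string_cells(4))
    art_only = VesselNetwork(
        [VesselSegment("a", np.array([[0.0, 0, 0], [100.0, 0, 0]]), 5.0,
                       "arteriole")]
    )
    with pytest.raises(EmptyTargetError):
        detect_cfu_e_strings(cells, art_only, SiteParams())


def test_gap_in_string_splits_components():
    left = _string_cells(3, start_x=50.0)
    right = _string_cells(3, start_x=50.0 + 3 * 12.7 + 40.0, cid0=10)
    strings = detect_cfu_e_strings(
        cells_dataframe(left + right), _net(), SiteParams()
    )
    assert sorted(len(s.members["CFU-E"]) for s in strings) == [3, 3]


@pytest.mark.parametrize("gap,attached", [(49.0, True), (51.0, False)])
def test_erythroblast_capture_boundary(gap, attached):
    string = _string_cells(3)
    # erythroblast at a controlled surface gap from the first string member
    cx, cy, cz = string[0].centre
    eb = _cell(50, "early erythroblast",
               (cx, cy + R_CFUE + R_EB + gap, cz), R_EB)
    cells = cells_dataframe(string + [eb])
    strings = detect_cfu_e_strings(cells, _net(), SiteParams())
    sites = assemble_erythroid_sites(strings, cells, SiteParams())
    got = 50 in sites[0].members.get("early erythroblast", [])
    assert got is attached


def test_two_distant_strings_partition_their_output():
    net = VesselNetwork(
        [
            VesselSegment("s0", np.array([[0.0, 0, 0], [300.0, 0, 0]]), 8.0,
                          "sinusoid"),
            VesselSegment("s1", np.array([[0.0, 400, 0], [300.0, 400, 0]]),
                          8.0, "sinusoid"),
        ]
    )
    a = _string_cells(4, start_x=50.0)
    b = [
        _cell(20 + i, "CFU-E", (50.0 + i * 12.7, 400 - 8.0 - R_CFUE, 0.0),
              R_CFUE)
        for i in range(4)
    ]
    rng = np.random.default_rng(1)
    ebs = [
        _cell(100 + i, "late erythroblast",
              rng.uniform([30, -40, -10], [150, 40, 10]), R_EB)
        for i in range(10)
    ]
    cells = cells_dataframe(a + b + ebs)
    strings = detect_cfu_e_strings(cells, net, SiteParams())
    sites = assemble_erythroid_sites(strings, cells, SiteParams())
    # exhaustive assignment oracle: each erythroblast belongs to exactly the
    # nearest in-range string, never to both
    assigned = [
        cid for s in sites for cid in s.members.get("late erythroblast", [])
    ]
    assert len(assigned) == len(set(assigned))
    for site in sites:
        for cid in site.members.get("late erythroblast", []):
            eb = cells[cells["id"] == cid].iloc[0]
            gaps = {}
            for other in sites:
                members = cells[cells["id"].isin(other.members["CFU-E"])]
                d = [
                    math.dist(
                        (eb.x_um, eb.y_um, eb.z_um), (m.x_um, m.y_um, m.z_um)
                    ) - eb.radius_um - m.radius_um
                    for m in members.itertuples()
                ]
                gaps[other.site_id] = min(d)
            assert min(gaps, key=gaps.get) == site.site_id
            assert gaps[site.site_id] <= 50.0


# ---------------------------------------------------------------------------
# B sites
# ---------------------------------------------------------------------------

def test_b_site_counts_within_150um():
    rng = np.random.default_rng(2)
    clp = _cell(0, "CLP", (200.0, 200, 15), 3.7)
    cells = [clp]
    cid = 1
    for stage, count in (("pre-pro B", 2), ("pro B", 3), ("pre B", 16)):
        for _ in range(count):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cells.append(
                _cell(cid, stage, np.asarray(clp.centre) + u * rng.uniform(20, 120),
                      4.0)
            )
            cid += 1
    sites = detect_b_sites(cells_dataframe(cells), None, SiteParams())
    assert len(sites) == 1
    counts = sites[0].output_counts
    assert (counts["pre-pro B"], counts["pro B"], counts["pre B"]) == (2, 3, 16)


def test_cell_between_two_clps_goes_to_the_nearer_one():
    clp_a = _cell(0, "CLP", (0.0, 0, 0), 3.7)
    clp_b = _cell(1, "CLP", (100.0, 0, 0), 3.7)
    preb = _cell(2, "pre B", (40.0, 0, 0), 3.05)
    sites = detect_b_sites(cells_dataframe([clp_a, clp_b, preb]), None,
                           SiteParams())
    assert sites[0].members.get("pre B") == [2]
    assert "pre B" not in sites[1].members


def test_equidistant_cell_breaks_tie_to_lowest_site():
    clp_a = _cell(0, "CLP", (0.0, 0, 0), 3.7)
    clp_b = _cell(1, "CLP", (100.0, 0, 0), 3.7)
    preb = _cell(2, "pre B", (50.0, 0, 0), 3.05)
    sites = detect_b_sites(cells_dataframe([clp_a, clp_b, preb]), None,
                           SiteParams())
    assert sites[0].members.get("pre B") == [2]


def test_b_sites_report_arteriole_proximity_but_never_filter_on_it():
    art = VesselNetwork(
        [VesselSegment("a", np.array([[0.0, 0, 0], [200.0, 0, 0]]), 5.0,
                       "arteriole")]
    )
    near = _cell(0, "CLP", (50.0, 10, 0), 3.7)
    far = _cell(1, "CLP", (50.0, 800, 0), 3.7)
    sites = detect_b_sites(cells_dataframe([near, far]), art, SiteParams())
    assert len(sites) == 2  # the far CLP still forms a candidate site
    assert sites[0].attributes["arteriole_gap_um"] < sites[1].attributes[
        "arteriole_gap_um"
    ]


# ---------------------------------------------------------------------------
# myeloid sites
# ---------------------------------------------------------------------------

def test_gp_on_sinusoid_with_six_pn_is_one_site():
    net = _net()
    gp = _cell(0, "GP", (100.0, 8.0 + 11.70 / 2, 0.0), 11.70 / 2)
    rng = np.random.default_rng(3)
    pns = [
        _cell(1 + i, "PN",
              np.asarray(gp.centre) + rng.normal(0, 12, 3), 10.21 / 2)
        for i in range(6)
    ]
    sites, unanchored = detect_myeloid_sites(
        cells_dataframe([gp] + pns), net, SiteParams(), "neutrophil"
    )
    assert len(sites) == 1 and not unanchored
    assert sites[0].output_counts["PN"] == 6


def test_gp_without_sinusoid_contact_is_unanchored():
    gp = _cell(0, "GP", (100.0, 200.0, 0.0), 11.70 / 2)
    sites, unanchored = detect_myeloid_sites(
        cells_dataframe([gp]), _net(), SiteParams(), "neutrophil"
    )
    assert sites == [] and unanchored == [0]


def test_monodc_site_reports_fate_ratio():
    net = _net()
    mdp = _cell(0, "MDP", (100.0, 8.0 + 12.13 / 2, 0.0), 12.13 / 2)
    rng = np.random.default_rng(4)
    prog = [
        _cell(1 + i, "cDC" if i < 2 else "monocyte",
              np.asarray(mdp.centre) + rng.normal(0, 10, 3), 5.0)
        for i in range(6)
    ]
    sites, _ = detect_myeloid_sites(
        cells_dataframe([mdp] + prog), net, SiteParams(), "monoDC"
    )
    assert sites[0].attributes["cdc_fraction"] == pytest.approx(2 / 6)


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def test_census_density_is_count_over_projected_area():
    vol = TissueVolume((2000.0, 1000.0, 35.0))  # 2 mm²
    sites = [
        ProductionSite(site_id=f"e{i}", lineage="erythroid", anchor=0,
                       members={"CFU-E": [i]})
        for i in range(4)
    ]
    table = census(sites, vol)
    ery = table[table["lineage"] == "erythroid"].iloc[0]
    assert ery["n_sites"] == 4
    assert ery["density_per_mm2"] == pytest.approx(2.0)


def test_census_of_empty_site_list_is_zero():
    table = census([], TissueVolume((1000.0, 1000.0, 35.0)))
    assert (table["n_sites"] == 0).all()
    assert (table["density_per_mm2"] == 0).all()


# ---------------------------------------------------------------------------
# properties on generated scenes
# ---------------------------------------------------------------------------

def test_capture_radius_monotonicity(small_scene):
    params_small = SiteParams(erythroid_capture_um=40.0)
    params_large = SiteParams(erythroid_capture_um=60.0)
    strings = detect_cfu_e_strings(small_scene.cells, small_scene.vessels)
    small_sites = assemble_erythroid_sites(strings, small_scene.cells,
                                           params_small)
    large_sites = assemble_erythroid_sites(strings, small_scene.cells,
                                           params_large)
    for a, b in zip(small_sites, large_sites):
        assert b.output_total() >= a.output_total()


def test_same_lineage_sites_partition_members(small_scene):
    strings = detect_cfu_e_strings(small_scene.cells, small_scene.vessels)
    sites = assemble_erythroid_sites(strings, small_scene.cells)
    all_ids = [cid for s in sites for cid in s.member_ids]
    assert len(all_ids) == len(set(all_ids))


def test_detected_sites_match_planted_truth_over_seeds():
    matched = 0
    planted = 0
    detected_total = 0
    for seed in derive_scene_seeds(123, 3):
        scene = build_volume(small_config(), seed=seed)
        params = SiteParams()
        strings = detect_cfu_e_strings(scene.cells, scene.vessels, params)
        truth_strings = {
            frozenset(s["members"]["CFU-E"])
            for s in scene.truth["sites"] if s["lineage"] == "erythroid"
        }
        det = {frozenset(s.members["CFU-E"]) for s in strings}
        matched += len(det & truth_strings)
        planted += len(truth_strings)
        detected_total += len(det)
    assert planted > 0
    assert matched / planted >= 0.95
    assert detected_total == planted  # no splits or merges


def test_bad_site_params_rejected():
    with pytest.raises(DegenerateDataError):
        SiteParams(min_string_size=1)
    with pytest.raises(DegenerateDataError):
        SiteParams(erythroid_capture_um=0.0)
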