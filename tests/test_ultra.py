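"""Ultrastructure quantification: filters, docked geometry, NN statistics."""

import numpy as np
import pytest

from tauhcn import ultra
from tauhcn.synth import VESICLE_PRESETS, generate_vesicle_map
from tauhcn.ultra import (NNResult, VesicleMap, filter_synapses,
                          group_nn_summary, nn_analysis, synapse_density,
                          synapse_metrics)

AZ = np.array([[0.0, 0.0], [500.0, 0.0]])


def _map(coords, diameters=None, is_dcv=None, psd=True, sid="s"):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return VesicleMap(
        synapse_id=sid, coords=coords,
        diameters=np.full(n, 40.0) if diameters is None else np.asarray(diameters),
        is_dcv=np.zeros(n, bool) if is_dcv is None else np.asarray(is_dcv),
        active_zone=AZ, presyn_area=0.35, psd_defined=psd,
    )


def _grid_map(n, spacing=60.0, **kw):
    side = int(np.ceil(np.sqrt(n)))
    pts = [(spacing * (i % side), 100.0 + spacing * (i // side))
           for i in range(n)]
    return _map(pts, **kw)


# ------------------------------------------------------------------ filter

@pytest.mark.parametrize("n,kept", [(9, False), (10, True), (250, True),
                                    (251, False)])
def test_sv_count_inclusion_boundaries(n, kept):
    maps = [_grid_map(n)]
    assert (len(filter_synapses(maps)) == 1) is kept


def test_undefined_psd_is_excluded_regardless_of_count():
    assert filter_synapses([_grid_map(100, psd=False)]) == []


def test_dcvs_do_not_count_toward_the_sv_filter():
    m = _grid_map(12, is_dcv=np.array([True] * 3 + [False] * 9))
    assert m.sv_count == 9
    assert filter_synapses([m]) == []


def test_filter_bounds_are_configurable():
    maps = [_grid_map(220)]
    assert len(filter_synapses(maps, max_sv=200)) == 0
    assert len(filter_synapses(maps, max_sv=250)) == 1


# ----------------------------------------------------------------- metrics

def test_docked_when_membrane_gap_within_2nm():
    """Radius-20 vesicle centred 21 nm from the AZ line: gap 1 nm -> docked;
    centred 23 nm: gap 3 nm -> not docked."""
    docked = _map([(250.0, 21.0)] + [(60.0 * i, 300.0) for i in range(10)])
    sm = synapse_metrics(docked)
    assert sm.docked_pct == pytest.approx(100.0 / 11)
    undocked = _map([(250.0, 23.0)] + [(60.0 * i, 300.0) for i in range(10)])
    assert synapse_metrics(undocked).docked_pct == 0.0


def test_no_dcvs_means_has_dcv_false():
    sm = synapse_metrics(_grid_map(12))
    assert not sm.has_dcv
    sm2 = synapse_metrics(_grid_map(12, is_dcv=np.array([True] + [False] * 11)))
    assert sm2.has_dcv


def test_docked_pct_agrees_with_bruteforce_geometry(rng):
    """Docked classification equals an exhaustive point-segment distance
    check on random maps."""
    for _ in range(10):
        pts = rng.uniform([0, 5], [500, 400], size=(40, 2))
        diam = rng.normal(40, 4, 40).clip(20)
        m = _map(pts, diameters=diam)
        sm = synapse_metrics(m)
        a, b = AZ
        count = 0
        for p, d in zip(pts, diam):
            t = np.clip(np.dot(p - a, b - a) / np.dot(b - a, b - a), 0, 1)
            dist = np.linalg.norm(p - (a + t * (b - a)))
            if dist - d / 2.0 <= 2.0:
                count += 1
        assert sm.docked_pct == pytest.approx(100.0 * count / 40)


# --------------------------------------------------------------------- NN

def test_two_vesicles_have_symmetric_nn_distance():
    res = nn_analysis(_map([(100.0, 100.0), (140.0, 100.0)]))
    assert np.allclose(res.nn_distances, [40.0, 40.0])
    assert res.mean_nn == pytest.approx(40.0)


def test_nn_matches_all_pairs_bruteforce(rng):
    """KD-tree nearest neighbours equal the O(n^2) all-pairs oracle."""
    pts = rng.uniform(0, 500, size=(50, 2))
    res = nn_analysis(_map(pts))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    assert np.allclose(res.nn_distances, d.min(axis=1))


def test_nn_requires_two_svs():
    with pytest.raises(ValueError):
        nn_analysis(_map([(100.0, 100.0)]))


def test_nn_invariant_under_rigid_motion(rng):
    pts = rng.uniform(0, 400, size=(30, 2))
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    moved = pts @ R.T + np.array([123.0, -55.0])
    a = nn_analysis(_map(pts))
    b = nn_analysis(_map(moved))
    assert np.allclose(np.sort(a.nn_distances), np.sort(b.nn_distances))


def test_ecdf_is_nondecreasing_and_reaches_one():
    m = generate_vesicle_map(VESICLE_PRESETS["WT-4mo"], 3)
    res = nn_analysis(m)
    assert np.all(np.diff(res.ecdf) >= 0)
    assert res.ecdf[-1] == pytest.approx(1.0)
    assert np.all(res.nn_distances > 0)


# ------------------------------------------------------------ group summary

def test_identical_synapses_average_to_themselves():
    maps = [_grid_map(20, sid=f"s{i}") for i in range(4)]
    results = [nn_analysis(m) for m in maps]
    mean_ecdf, group_mean, per = group_nn_summary(results)
    assert np.allclose(mean_ecdf, results[0].ecdf)
    assert group_mean == pytest.approx(results[0].mean_nn)
    assert per.size == 4


def test_unweighted_convention_on_unbalanced_counts():
    """Per-synapse-then-average: a 4-vesicle synapse counts as much as a
    100-vesicle synapse; the vesicle-weighted pooled mean differs."""
    tight = _grid_map(100, spacing=45.0, sid="tight")
    loose = _map([(0, 100), (150, 100), (300, 100), (450, 100)], sid="loose")
    ra, rb = nn_analysis(tight), nn_analysis(loose)
    _, unweighted, _ = group_nn_summary([ra, rb])
    pooled = np.concatenate([ra.nn_distances, rb.nn_distances]).mean()
    assert unweighted == pytest.approx((ra.mean_nn + rb.mean_nn) / 2)
    assert abs(unweighted - pooled) > 1.0


def _pair_map(separations, sid="pairs"):
    """Isolated vesicle pairs (>=300 nm apart) with known NN separations."""
    pts = []
    for j, sep in enumerate(separations):
        y = 100.0 + 300.0 * j
        pts += [(0.0, y), (sep, y)]
    return _map(pts, sid=sid)


def test_mean_ecdf_median_differs_from_pooled_median():
    """Reading the median off the averaged ECDF is not the pooled-distance
    median on unbalanced synapses: the per-synapse-then-average convention
    weights the small synapse up."""
    ra = nn_analysis(_pair_map([30, 40, 50, 60, 70], sid="a"))
    rb = nn_analysis(_pair_map([110, 130], sid="b"))
    mean_ecdf, _, _ = group_nn_summary([ra, rb])
    grid = ra.ecdf_grid
    median_avg = grid[np.searchsorted(mean_ecdf, 0.5)]
    pooled = np.median(np.concatenate([ra.nn_distances, rb.nn_distances]))
    assert pooled == pytest.approx(60.0)
    assert median_avg == pytest.approx(70.0)


# ----------------------------------------------------------------- density

def test_synapse_density_examples():
    assert synapse_density([(i, i) for i in range(10)], 100.0) == pytest.approx(0.1)
    assert synapse_density([], 50.0) == 0.0
    assert synapse_density([(i, 0) for i in range(25)], 125.0) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        synapse_density([(0, 0)], 0.0)


def test_group_means_agree_between_identical_presets():
    """Two cohorts from the same preset differ by sampling noise only: the
    group mean NN difference stays within 3 SE (no spurious effect)."""
    a = [nn_analysis(m) for m in
         (generate_vesicle_map(VESICLE_PRESETS["WT-4mo"], 100 + i)
          for i in range(12))]
    b = [nn_analysis(m) for m in
         (generate_vesicle_map(VESICLE_PRESETS["WT-4mo"], 900 + i)
          for i in range(12))]
    _, ma, pa = group_nn_summary(a)
    _, mb, pb = group_nn_summary(b)
    se = np.sqrt(pa.var(ddof=1) / pa.size + pb.var(ddof=1) / pb.size)
    assert abs(ma - mb) < 3 * se


def test_map_io_roundtrip(tmp_path):
    m = generate_vesicle_map(VESICLE_PRESETS["Tau35-10mo"], 5, synapse_id="rt")
    ultra.write_vesicle_map(m, tmp_path / "rt.csv")
    back = ultra.read_vesicle_map(tmp_path / "rt.csv")
    assert back.synapse_id == "rt"
    assert np.allclose(back.coords, m.coords)
    assert np.array_equal(back.is_dcv, m.is_dcv)
    assert back.psd_defined == m.psd_defined
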