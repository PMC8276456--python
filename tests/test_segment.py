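import numpy as np
import pytest

import tadstorm as ts
from oracles import brute_force_two_radius_dbscan
from tadstorm.model import GeometryError


def _table(points):
    points = np.asarray(points, dtype=float)
    return ts.LocalizationTable.from_arrays(points[:, 0], points[:, 1])


# ---------------------------------------------------------------------------
# two-radius DBSCAN

def test_chain_of_three_forms_one_cluster():
    clusters, labels = ts.dbscan(
        _table([(0, 0), (0, 1), (0, 2)]),
        ts.DBSCANParams(r=1.5, n_min=1, r_ref=1.5))
    assert list(labels) == [0, 0, 0]
    assert clusters[0].n_detections == 3


def test_isolated_point_is_noise():
    clusters, labels = ts.dbscan(
        _table([(0, 0), (1000, 1000)]),
        ts.DBSCANParams(r=10, n_min=2))
    assert clusters == [] and list(labels) == [-1, -1]


def test_planted_blobs_recovered_exactly(rng):
    a = rng.normal(0, 5, (50, 2))
    b = rng.normal(0, 5, (50, 2)) + [500, 0]
    clusters, labels = ts.dbscan(_table(np.vstack([a, b])),
                                 ts.DBSCANParams(r=25, n_min=3, r_ref=50))
    assert len(clusters) == 2
    assert set(labels[:50]) == {0} and set(labels[50:]) == {1}


def test_empty_table_is_empty_result():
    clusters, labels = ts.dbscan(np.empty((0, 2)),
                                 ts.DBSCANParams(r=1, n_min=1))
    assert clusters == [] and len(labels) == 0


@pytest.mark.parametrize("trial", range(25))
def test_dbscan_matches_bruteforce_reference(trial):
    """The kd-tree implementation agrees with an O(n^2) reference."""
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(5, 201))
    if trial % 3 == 1:
        k = int(rng.integers(1, 5))
        pts = (rng.uniform(0, 100, (k, 2))[rng.integers(0, k, n)]
               + rng.normal(0, 3, (n, 2)))
    else:
        pts = rng.uniform(0, 60, (n, 2))
    r, rr = float(rng.uniform(2, 12)), float(rng.uniform(2, 12))
    nm = int(rng.integers(1, 8))
    _, labels = ts.dbscan(pts, ts.DBSCANParams(r=r, n_min=nm, r_ref=rr))
    ref = brute_force_two_radius_dbscan(pts, r, nm, rr)
    np.testing.assert_array_equal(labels, ref)


def test_dbscan_permutation_invariant(rng):
    pts = rng.uniform(0, 50, (120, 2))
    params = ts.DBSCANParams(r=6, n_min=3, r_ref=6)
    _, labels = ts.dbscan(pts, params)
    perm = rng.permutation(len(pts))
    _, plabels = ts.dbscan(pts[perm], params)
    # compare as partitions: same noise set, same grouping
    def partition(lab):
        groups = {}
        for i, l in enumerate(lab):
            groups.setdefault(l, set()).add(i)
        return {frozenset(v) for k, v in groups.items() if k >= 0}, \
            frozenset(i for i, l in enumerate(lab) if l < 0)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    orig, noise0 = partition(labels)
    permd, noise1 = partition([plabels[inv[i]] for i in range(len(pts))])
    assert orig == permd and noise0 == noise1


# ---------------------------------------------------------------------------
# automatic thresholds

def test_auto_thresholds_match_poisson_expectation(rng):
    """On an even field the core threshold equals the expected neighbor
    count within r at the global density (within +-1)."""
    s = 10.0
    g = np.stack(np.meshgrid(np.arange(40.0), np.arange(40.0)),
                 -1).reshape(-1, 2) * s
    g += rng.normal(0, 0.01, g.shape)
    params = ts.auto_thresholds(_table(g))
    from scipy.spatial import ConvexHull
    rho = len(g) / ConvexHull(g).volume
    assert abs(params.n_min - rho * np.pi * params.r ** 2) <= 1.0
    assert params.r_ref == params.r


def test_auto_thresholds_scale_equivariant(rng):
    pts = rng.uniform(0, 100, (500, 2))
    p1 = ts.auto_thresholds(_table(pts))
    p2 = ts.auto_thresholds(_table(pts * 2))
    assert np.isclose(p2.r, 2 * p1.r)
    assert np.isclose(p2.r_ref, 2 * p1.r_ref)
    assert p2.n_min == p1.n_min


def test_auto_thresholds_need_ten_points():
    with pytest.raises(ValueError):
        ts.auto_thresholds(_table(np.random.default_rng(0)
                                  .uniform(0, 1, (5, 2))))


# ---------------------------------------------------------------------------
# Voronoi density segmentation

def test_regular_grid_yields_no_clusters():
    """Every interior cell of a square grid has exactly the mean density,
    so no point exceeds 3x the average."""
    g = np.stack(np.meshgrid(np.arange(20.0), np.arange(20.0)),
                 -1).reshape(-1, 2) * 10
    clusters, _ = ts.voronoi_density_segment(
        _table(g), ts.VoronoiParams(density_factor=3.0, min_detections=1))
    assert clusters == []


def test_planted_blob_recovered(rng):
    blob = rng.normal(0, 10, (100, 2)) + [500, 500]
    background = rng.uniform(0, 1000, (100, 2))
    clusters, labels = ts.voronoi_density_segment(
        _table(np.vstack([blob, background])),
        ts.VoronoiParams(density_factor=3.0, min_detections=10))
    assert len(clusters) >= 1
    biggest = max(clusters, key=lambda c: c.n_detections)
    assert np.sum(np.isin(biggest.indices, np.arange(100))) >= 90


def test_voronoi_rejects_degenerate_input():
    with pytest.raises(GeometryError):
        ts.voronoi_density_segment(_table(np.empty((0, 2)).reshape(0, 2)),
                                   ts.VoronoiParams())
    line = np.column_stack([np.arange(10.0), np.arange(10.0)])
    with pytest.raises(GeometryError, match="collinear"):
        ts.voronoi_density_segment(_table(line), ts.VoronoiParams())


def test_raising_density_factor_shrinks_selection(rng):
    pts = np.vstack([rng.normal(0, 10, (100, 2)) + [300, 300],
                     rng.uniform(0, 600, (150, 2))])
    sizes = []
    for delta in (2.0, 5.0, 20.0):
        _, labels = ts.voronoi_density_segment(
            _table(pts), ts.VoronoiParams(density_factor=delta,
                                          min_detections=1))
        sizes.append(np.sum(labels >= 0))
    assert sizes[0] >= sizes[1] >= sizes[2]


def test_voronoi_clusters_are_disjoint_subsets(rng):
    pts = np.vstack([rng.normal(0, 8, (80, 2)) + [200, 200],
                     rng.normal(0, 8, (80, 2)) + [800, 800],
                     rng.uniform(0, 1000, (100, 2))])
    clusters, _ = ts.voronoi_density_segment(
        _table(pts), ts.VoronoiParams(density_factor=3.0, min_detections=5))
    seen = set()
    for c in clusters:
        idx = set(int(i) for i in c.indices)
        assert not (seen & idx)
        assert idx <= set(range(len(pts)))
        seen |= idx


# ---------------------------------------------------------------------------
# cluster metrics

def test_metrics_unit_square():
    c = ts.cluster_metrics(np.array([(0.0, 0.0), (1, 0), (0, 1), (1, 1)]))
    np.testing.assert_allclose(c.barycenter, [0.5, 0.5])
    assert np.isclose(c.rg, np.sqrt(0.5))
    assert np.isclose(c.diameter, np.sqrt(2))


def test_metrics_two_points():
    c = ts.cluster_metrics(np.array([(0.0, 0.0), (2.0, 0.0)]))
    np.testing.assert_allclose(c.barycenter, [1.0, 0.0])
    assert np.isclose(c.rg, 1.0)
    assert np.isclose(c.diameter, 2.0)
    assert np.isclose(c.major_axis, 4.0)   # 4 sigma along PC1


def test_metrics_single_point():
    c = ts.cluster_metrics(np.array([(3.0, 4.0)]))
    assert c.major_axis == 0.0 and c.diameter == 0.0
    assert np.isnan(c.density)


def test_uniform_disk_closed_forms(rng):
    """Uniform disk: Rg -> R/sqrt(2), diameter -> 2R."""
    from tadstorm.simulate import sample_uniform_ball
    R = 300.0
    pts = sample_uniform_ball(rng, 10_000, R, ndim=2)
    c = ts.cluster_metrics(pts)
    assert abs(c.rg - R / np.sqrt(2)) < 0.01 * R / np.sqrt(2)
    assert abs(c.diameter - 2 * R) < 0.02 * 2 * R


def test_rg_squared_identity(rng):
    pts = rng.normal(0, 50, (500, 2))
    c = ts.cluster_metrics(pts)
    msd = np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1))
    assert abs(c.rg ** 2 - msd) / msd < 1e-12
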