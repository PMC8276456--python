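import numpy as np
import pytest

import tadstorm as ts
from tadstorm.simulate import sample_uniform_ball
from tadstorm.spatstats import _ANALYTIC


def _cluster(points):
    return ts.cluster_metrics(np.asarray(points, dtype=float))


# ---------------------------------------------------------------------------
# barycenter and Rg

def test_barycenter_basics():
    np.testing.assert_allclose(ts.barycenter(np.array([[3.0, 4.0]])), [3, 4])
    np.testing.assert_allclose(
        ts.barycenter(np.array([[0.0, 0.0], [2.0, 2.0]])), [1, 1])
    with pytest.raises(ValueError):
        ts.barycenter(np.empty((0, 2)))


def test_barycenter_translation_equivariant(rng):
    pts = rng.normal(0, 10, (50, 2))
    shift = np.array([12.5, -7.0])
    np.testing.assert_allclose(ts.barycenter(pts + shift),
                               ts.barycenter(pts) + shift)


def test_rg_hand_values():
    assert ts.radius_of_gyration(np.array([[5.0, 5.0]])) == 0.0
    sq = np.array([(0.0, 0.0), (1, 0), (0, 1), (1, 1)])
    assert np.isclose(ts.radius_of_gyration(sq), np.sqrt(0.5))


# ---------------------------------------------------------------------------
# assignment rule

def test_coincident_focus_assigned(rng):
    tad = _cluster(rng.normal(0, 50, (500, 2)))
    focus = _cluster(rng.normal(0, 5, (50, 2)) + tad.barycenter)
    pairs, unassigned = ts.assign_foci([focus], [tad])
    assert pairs and not unassigned


def test_far_focus_excluded(rng):
    tad = _cluster(rng.normal(0, 50, (500, 2)))
    offset = 0.6 * tad.major_axis
    focus = _cluster(rng.normal(0, 5, (50, 2)) + tad.barycenter
                     + [offset, 0.0])
    pairs, unassigned = ts.assign_foci([focus], [tad])
    assert not pairs and unassigned == [0]


def test_equidistant_tie_breaks_to_lower_index(rng):
    base = rng.normal(0, 150, (1000, 2))    # half major axis ~ 300 nm
    tad_a = _cluster(base + [-200, 0])
    tad_b = _cluster(base + [200, 0])       # translated: same shape
    focus = _cluster(np.zeros((10, 2)))     # exactly between the centers
    pairs, _ = ts.assign_foci([focus], [tad_a, tad_b])
    assert pairs == [(0, 0)]


def test_no_tads_leaves_all_unassigned():
    focus = _cluster(np.random.default_rng(0).normal(0, 5, (20, 2)))
    pairs, unassigned = ts.assign_foci([focus], [])
    assert pairs == [] and unassigned == [0]


# ---------------------------------------------------------------------------
# barycenter distance

def test_coincident_barycenters_zero(rng):
    pts = rng.normal(0, 50, (500, 2))
    tad = _cluster(pts)
    focus = _cluster(rng.normal(0, 5, (50, 2))
                     - rng.normal(0, 5, (50, 2)).mean(0) + tad.barycenter)
    for conv in ("half_major_axis", "rg"):
        raw, norm = ts.barycenter_distance(focus, tad, conv)
        assert norm < 0.02


def test_convention_rescales_but_preserves_order(rng):
    tad = _cluster(rng.normal(0, 50, (2000, 2)))
    ratio = (tad.major_axis / 2) / tad.rg
    values = []
    for k in range(20):
        focus = _cluster(rng.normal(0, 3, (30, 2)) + tad.barycenter
                         + [k * 7.0, 0.0])
        _, n_half = ts.barycenter_distance(focus, tad, "half_major_axis")
        _, n_rg = ts.barycenter_distance(focus, tad, "rg")
        assert np.isclose(n_rg, n_half * ratio)
        values.append((n_half, n_rg))
    a, b = zip(*values)
    assert list(np.argsort(a)) == list(np.argsort(b))   # rank corr 1.0


def test_single_point_tad_rejected():
    tad = _cluster(np.array([(0.0, 0.0)]))
    focus = _cluster(np.array([(1.0, 0.0), (2.0, 0.0)]))
    with pytest.raises(ValueError):
        ts.barycenter_distance(focus, tad)


# ---------------------------------------------------------------------------
# random-placement null

def test_analytic_null_table():
    """The closed forms: in-plane ball mean 3*pi/16, 3D ball mean 3/4 and
    median 2^(-1/3), disk mean 2/3 and median sqrt(1/2)."""
    assert np.isclose(ts.null_distance("uniform_ball_projected").value,
                      3 * np.pi / 16)
    assert np.isclose(ts.null_distance("uniform_ball_3d").value, 0.75)
    assert np.isclose(
        ts.null_distance("uniform_ball_3d", "median").value, 0.5 ** (1 / 3))
    assert np.isclose(ts.null_distance("uniform_disk").value, 2 / 3)
    assert np.isclose(ts.null_distance("uniform_disk", "median").value,
                      np.sqrt(0.5))


def test_unsupported_analytic_combination_errors():
    with pytest.raises(ValueError, match="monte_carlo"):
        ts.null_distance("uniform_ball_projected", "median")
    r = ts.null_distance("uniform_ball_projected", "median",
                         method="monte_carlo", n_draws=10_000, seed=0)
    assert 0.5 < r.value < 0.7 and r.se > 0


def test_monte_carlo_matches_analytic_within_3se():
    for (geom, stat), expected in _ANALYTIC.items():
        r = ts.null_distance(geom, stat, method="monte_carlo",
                             n_draws=200_000, seed=42)
        assert abs(r.value - expected) < 3 * r.se, (geom, stat)


def test_rg_normalizer_scales_null():
    r = ts.null_distance("uniform_ball_3d", "median", normalizer="rg")
    assert np.isclose(r.value, 0.5 ** (1 / 3) / np.sqrt(3 / 5))


# ---------------------------------------------------------------------------
# radial density distribution

def test_rdd_zero_at_barycenter(rng):
    tad = _cluster(rng.normal(0, 50, (500, 2)))
    members = np.tile(tad.barycenter, (10, 1))
    assert ts.rdd(members, tad) == 0.0


def test_rdd_uniform_ball_closed_form(rng):
    """Median radial distance over Rg for a uniform ball:
    2^(-1/3) / sqrt(3/5) ~ 1.0247."""
    pts = sample_uniform_ball(rng, 50_000, 200.0, ndim=3)
    tad = ts.cluster_metrics(pts, dims="3d")
    val = ts.rdd(pts, tad, tendency="median", normalizer="rg", dims="3d")
    expected = 0.5 ** (1 / 3) / np.sqrt(3 / 5)
    assert abs(val - expected) < 0.01 * expected


@pytest.mark.parametrize("seed", range(5))
def test_rdd_monotone_in_planted_depth(seed):
    """Peripheral foci always score a larger RDD than interior foci."""
    spec = ts.TadSpec()
    vals = {}
    for d in (0.2, 1.0):
        fspec = ts.FocusSpec(parent=spec, n_foci=7, radial_fraction=d,
                             locs_per_focus=200)
        table, truth = ts.simulate_foci(fspec, seed=seed)
        tad_tab, _ = ts.simulate_tad(spec, seed=seed + 1000)
        tad = ts.cluster_metrics(tad_tab, dims="3d")
        vals[d] = ts.rdd(table, tad, dims="3d")
    assert vals[1.0] > vals[0.2]


# ---------------------------------------------------------------------------
# subsampling robustness

def test_full_fraction_is_degenerate(rng):
    pts = rng.normal(0, 50, (400, 2))
    df = ts.subsample_robustness(pts, fractions=(1.0,), reps=5, seed=0)
    assert df.rg_std.iloc[0] == 0.0
    assert np.isclose(df.rg_mean.iloc[0], ts.radius_of_gyration(pts))


def test_quarter_noisier_than_half_in_expectation():
    spec = ts.TadSpec()
    stds = {0.5: [], 0.25: []}
    for seed in range(20):
        table, _ = ts.simulate_tad(spec, seed=seed)
        df = ts.subsample_robustness(table, fractions=(0.5, 0.25),
                                     reps=10, seed=seed, dims="3d")
        for _, row in df.iterrows():
            stds[row.fraction].append(row.rg_std)
    assert np.mean(stds[0.25]) > np.mean(stds[0.5])


def test_tiny_fraction_rejected(rng):
    with pytest.raises(ValueError):
        ts.subsample_robustness(rng.normal(0, 1, (10, 2)),
                                fractions=(0.1,), reps=3, seed=0)


# ---------------------------------------------------------------------------
# invariances

def test_normalized_distance_rotation_and_scale_invariant(rng):
    tad_pts = rng.normal(0, 50, (1000, 2))
    focus_pts = rng.normal(0, 5, (100, 2)) + [60, 20]
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    scale = 3.7
    _, base = ts.barycenter_distance(_cluster(focus_pts), _cluster(tad_pts))
    _, moved = ts.barycenter_distance(
        _cluster(scale * focus_pts @ rot.T + [100, -30]),
        _cluster(scale * tad_pts @ rot.T + [100, -30]))
    assert np.isclose(base, moved, rtol=1e-9)
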