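"""Circular densities, toroidal clustering, water coordinates, residence."""

import numpy as np
import pytest
from scipy import special, stats

from peroxosite.ensemble import (
    TorsionSeries,
    TorsionSpec,
    circular_density_1d,
    cluster_label_array,
    cluster_torsions_2d,
    density_modes,
    residence_trace,
    state_coupling,
    torsion_density_2d,
    torsion_series,
    water_site_coordinates,
)
from peroxosite.geometry import wrap_degrees
from peroxosite.structure_io import StructureModel
from peroxosite.synthetic import (
    EnsembleSpec,
    ToyActiveSiteSpec,
    build_toy_active_site,
    sample_torsion_mixture,
)

from conftest import random_rigid_motion


def _series(values, label="t"):
    values = np.asarray(values, float)
    return TorsionSeries(label, values, np.arange(len(values)))


THR_SPEC = TorsionSpec("thr", (("B", 57, "CA"), ("B", 57, "CB"),
                               ("B", 57, "OG1"), ("B", 57, "DG1")))
WATER_ROLES = (("A", 400, "C4"), ("A", 400, "C5"), ("S", 601, "O"),
               ("S", 601, "D1"), ("S", 601, "D2"))


# ---------------------------------------------------------------------------
# torsion series


def test_static_ensemble_gives_constant_series(toy_site):
    model, manifest = toy_site
    static = StructureModel(model.atoms,
                            np.repeat(model.coords, 5, axis=0))
    s = torsion_series(static, THR_SPEC)
    assert len(s) == 5
    assert np.allclose(s.values, manifest["torsions"]["THR57_CA-CB-OG1-DG1"],
                       atol=1e-9)


def test_planted_torsions_recovered(medium_ensemble):
    ens, manifest = medium_ensemble
    s = torsion_series(ens, THR_SPEC)
    err = np.abs(wrap_degrees(s.values - manifest["thr_torsion_deg"].values))
    assert np.max(err) < 1e-6


def test_unresolvable_torsion_spec_errors(toy_site):
    model, _ = toy_site
    bad = TorsionSpec("x", (("B", 57, "CA"), ("B", 57, "CB"),
                            ("B", 57, "OG1"), ("B", 57, "NOPE")))
    with pytest.raises(ValueError, match="not found"):
        torsion_series(model, bad)


# ---------------------------------------------------------------------------
# 1D circular densities


def test_single_observation_peaks_at_value():
    d = circular_density_1d(_series([10.3]), concentration=20.0)
    modes = density_modes(d)
    assert len(modes) == 1
    assert abs(modes[0][0] - 10.3) <= d.step
    total = d.values.sum() * d.step
    assert total == pytest.approx(1.0, abs=1e-9)


def test_density_normalization_and_shift_invariance(rng):
    x = np.degrees(rng.vonmises(0.5, 4.0, size=2000))
    d = circular_density_1d(_series(x), concentration=30.0)
    assert d.values.sum() * d.step == pytest.approx(1.0, abs=1e-9)
    # rotating all angles rotates the density but keeps its shape
    shift = 77.0
    d2 = circular_density_1d(_series(wrap_degrees(x + shift)),
                             concentration=30.0)
    k = int(round(shift / d.step))
    assert np.allclose(np.roll(d.values, k), d2.values, atol=1e-12)


def test_kde_converges_to_von_mises_closed_form(rng):
    """Sup-norm error against the closed-form sampling density shrinks
    as n grows (plug-in bandwidth tightens with n)."""
    mu, kappa = np.radians(40.0), 6.0
    errs = []
    for n in (500, 50_000):
        x = np.degrees(rng.vonmises(mu, kappa, size=n))
        d = circular_density_1d(_series(x))
        grid_rad = np.radians(d.grid[0])
        truth = np.exp(kappa * np.cos(grid_rad - mu)) / (
            2 * np.pi * special.i0(kappa)) * np.pi / 180.0
        errs.append(np.max(np.abs(d.values - truth)))
    # peak density is ~1.7e-2 per degree; the large-n error is far below it
    assert errs[1] < errs[0]
    assert errs[1] < 5e-4


def test_mixture_shows_dominant_mode_and_shoulder(rng):
    """An 80:20 von Mises mixture at -72/-135 degrees yields a dominant
    mode near -72 and a shoulder mode near -135."""
    x = sample_torsion_mixture(
        [(0.8, -72.0, 12.0), (0.2, -135.0, 20.0)], 100_000, rng)
    d = circular_density_1d(_series(x))
    modes = density_modes(d)
    assert abs(wrap_degrees(modes[0][0] + 72.0)) <= 3.0
    assert len(modes) >= 2
    assert abs(wrap_degrees(modes[1][0] + 135.0)) <= 5.0


def test_density_modes_uniform_and_ordering():
    from peroxosite.ensemble import CircularDensity
    grid = -180.0 + 1.0 * (np.arange(360) + 0.5)
    flat = CircularDensity((grid,), np.full(360, 1 / 360.0), (1.0,), 1.0)
    assert density_modes(flat) == []
    two = np.full(360, 1e-4)
    two[90] = 3e-3
    two[270] = 2e-3
    bumps = CircularDensity((grid,), two / (two.sum() * 1.0), (1.0,), 1.0)
    modes = density_modes(bumps)
    assert [m[0] for m in modes] == [grid[90], grid[270]]


def test_density_rejects_bad_inputs():
    with pytest.raises(ValueError):
        circular_density_1d(_series([1.0]), concentration=-3.0)
    with pytest.raises(ValueError):
        circular_density_1d(_series([]))


# ---------------------------------------------------------------------------
# 2D toroidal densities and clustering


def test_constant_pair_gives_single_sharp_peak():
    a = _series(np.full(50, 30.0))
    b = _series(np.full(50, -60.0))
    d = torsion_density_2d(a, b, concentration=(50.0, 50.0))
    i, j = np.unravel_index(np.argmax(d.values), d.values.shape)
    assert abs(wrap_degrees(d.grid[0][i] - 30.0)) <= d.step
    assert abs(wrap_degrees(d.grid[1][j] + 60.0)) <= d.step
    assert d.values.sum() * d.step**2 == pytest.approx(1.0, abs=1e-9)


def test_independent_uniform_pair_is_flat(rng):
    """Chi-square uniformity over coarse toroidal cells is not rejected."""
    n = 100_000
    a = _series(rng.uniform(-180, 180, n))
    b = _series(rng.uniform(-180, 180, n))
    d = torsion_density_2d(a, b, concentration=(20.0, 20.0))
    # smoothed density is close to flat everywhere
    flat = 1.0 / 360.0**2
    assert np.max(np.abs(d.values - flat)) < 0.2 * flat
    # raw counts pass a chi-square uniformity test on coarse toroidal cells
    counts, _, _ = np.histogram2d(a.values, b.values,
                                  bins=(np.linspace(-180, 180, 7),) * 2)
    p = stats.chisquare(counts.ravel()).pvalue
    assert p > 0.01


def test_planted_four_component_mixture_peaks(rng):
    spec = EnsembleSpec()
    centers = [(c[1], c[2]) for c in spec.asn_components]
    xs, ys, labels = [], [], []
    for k, (cx, cy) in enumerate(centers):
        xs.append(np.degrees(rng.vonmises(np.radians(cx), 40.0, 2500)))
        ys.append(np.degrees(rng.vonmises(np.radians(cy), 40.0, 2500)))
        labels.append(np.full(2500, k))
    a = _series(wrap_degrees(np.concatenate(xs)))
    b = _series(wrap_degrees(np.concatenate(ys)))
    truth = np.concatenate(labels)
    clusters = cluster_torsions_2d(a, b)
    assert len(clusters) == 4
    # every planted center matched by some cluster within 5 degrees
    for cx, cy in centers:
        best = min(
            max(abs(wrap_degrees(c.center[0] - cx)),
                abs(wrap_degrees(c.center[1] - cy)))
            for c in clusters
        )
        assert best <= 5.0
    # labels agree with brute-force nearest-planted-center assignment
    lab = cluster_label_array(clusters, len(a))

    def toro_d2(x, y, cx, cy):
        return wrap_degrees(x - cx) ** 2 + wrap_degrees(y - cy) ** 2

    nearest = np.argmin(
        np.stack([toro_d2(a.values, b.values, cx, cy) for cx, cy in centers]),
        axis=0,
    )
    assigned = lab >= 0
    # map cluster ids to planted ids by majority vote
    agree = 0
    for c in clusters:
        vals, cnt = np.unique(nearest[c.labels_mask], return_counts=True)
        agree += cnt.max()
    assert agree / assigned.sum() >= 0.99
    assert (truth[assigned] == nearest[assigned]).mean() >= 0.99


def test_two_separated_blobs_two_clusters(rng):
    a = _series(np.r_[np.degrees(rng.vonmises(0.0, 80.0, 500)),
                      np.degrees(rng.vonmises(np.pi, 80.0, 500))])
    b = _series(np.r_[np.degrees(rng.vonmises(0.0, 80.0, 500)),
                      np.degrees(rng.vonmises(np.pi, 80.0, 500))])
    clusters = cluster_torsions_2d(a, b, concentration=(30.0, 30.0))
    assert len(clusters) == 2
    assert sum(c.population for c in clusters) <= 1.0


def test_degenerate_identical_input_single_cluster():
    a = _series(np.full(100, 42.0))
    b = _series(np.full(100, -17.0))
    clusters = cluster_torsions_2d(a, b, concentration=(40.0, 40.0))
    assert len(clusters) == 1
    assert clusters[0].population == pytest.approx(1.0)
    assert abs(wrap_degrees(clusters[0].center[0] - 42.0)) < 1e-9


def test_cluster_seedless_determinism(medium_ensemble):
    ens, _ = medium_ensemble
    c1s = torsion_series(ens, TorsionSpec("chi1", (("B", 254, "N"), ("B", 254, "CA"),
                                                   ("B", 254, "CB"), ("B", 254, "CG"))))
    c2s = torsion_series(ens, TorsionSpec("chi2", (("B", 254, "CA"), ("B", 254, "CB"),
                                                   ("B", 254, "CG"), ("B", 254, "ND2"))))
    r1 = cluster_torsions_2d(c1s, c2s)
    r2 = cluster_torsions_2d(c1s, c2s)
    assert [c.center for c in r1] == [c.center for c in r2]
    assert all(np.array_equal(x.labels_mask, y.labels_mask)
               for x, y in zip(r1, r2))


# ---------------------------------------------------------------------------
# water coordinates and residence


def test_water_coordinates_on_crystal_frame(toy_site):
    model, manifest = toy_site
    wc = water_site_coordinates(model, *WATER_ROLES)
    assert wc.r[0] == pytest.approx(manifest["water_sites"]["W1"]["r_A"],
                                    abs=1e-9)
    assert wc.theta[0] == pytest.approx(
        manifest["water_sites"]["W1"]["theta_deg"], abs=1e-9)


def test_water_coordinates_arbitrary_planting():
    model, manifest = build_toy_active_site(
        ToyActiveSiteSpec(w1_r=4.30, w1_theta=240.0, w1_tilt=None,
                          d_thr_dg1_w1o=2.4, pi_site=None))
    wc = water_site_coordinates(model, *WATER_ROLES)
    assert wc.r[0] == pytest.approx(4.30, abs=1e-9)
    assert wc.theta[0] == pytest.approx(wrap_degrees(240.0), abs=1e-9)


def test_water_coordinates_rigid_motion_invariant(toy_site, rng):
    model, _ = toy_site
    rot, tr = random_rigid_motion(rng)
    moved = StructureModel(model.atoms, model.coords @ rot.T + tr)
    a = water_site_coordinates(model, *WATER_ROLES)
    b = water_site_coordinates(moved, *WATER_ROLES)
    assert b.r[0] == pytest.approx(a.r[0], abs=1e-9)
    assert b.theta[0] == pytest.approx(a.theta[0], abs=1e-9)


def test_water_coordinates_missing_hydrogen_errors(toy_site):
    model, _ = toy_site
    bad = (("A", 400, "C4"), ("A", 400, "C5"), ("S", 601, "O"),
           ("S", 601, "D1"), ("S", 601, "D9"))
    with pytest.raises(ValueError, match="not found"):
        water_site_coordinates(model, *bad)


def test_residence_trivial_and_brute_force(rng):
    from peroxosite.ensemble import WaterSiteCoordinate

    r = np.full(100, 3.5)
    wc = WaterSiteCoordinate(r, np.zeros(100), np.arange(100))
    tr = residence_trace(wc, 4.0)
    assert tr.occupancy == 1.0
    assert len(tr.segments) == 1 and tr.mean_inside_segment == 100

    r2 = rng.uniform(3.0, 5.0, size=1000)
    wc2 = WaterSiteCoordinate(r2, np.zeros(1000), np.arange(1000))
    tr2 = residence_trace(wc2, 4.0)
    assert tr2.occupancy == np.mean(r2 <= 4.0)  # exact brute-force count
    assert sum(ln for _, ln, _ in tr2.segments) == 1000
    with pytest.raises(ValueError):
        residence_trace(wc2, -1.0)


def test_residence_planted_dwell_segments():
    from peroxosite.ensemble import WaterSiteCoordinate

    r = np.r_[np.full(40, 3.5), np.full(10, 4.5), np.full(50, 3.5)]
    wc = WaterSiteCoordinate(r, np.zeros(100), np.arange(100))
    tr = residence_trace(wc, 4.0)
    assert [(s, ln, f) for s, ln, f in tr.segments] == [
        (0, 40, True), (40, 10, False), (50, 50, True)]
    assert tr.mean_inside_segment == pytest.approx(45.0)


def test_state_coupling_null_and_perfect(rng):
    from peroxosite.ensemble import WaterSiteCoordinate

    n = 20_000
    labels = rng.integers(0, 2, n)
    inside = rng.random(n) < 0.7  # independent of labels
    wc = WaterSiteCoordinate(np.where(inside, 3.5, 4.5), np.zeros(n),
                             np.arange(n))
    tr = residence_trace(wc, 4.0)
    res = state_coupling(labels, tr)
    assert 0.9 < res["odds_ratio_major_inside"] < 1.1
    assert res["cramers_v"] < 0.03

    perfect = np.where(inside, 0, 1)
    res2 = state_coupling(perfect, tr)
    assert res2["odds_ratio_degenerate"]
    assert res2["odds_ratio_major_inside"] == np.inf
    # counts match brute force exactly
    assert res2["table_inside"][0] == int(inside.sum())
    assert res2["table_outside"][1] == int((~inside).sum())


def test_state_coupling_matches_brute_force_counts(medium_ensemble):
    ens, manifest = medium_ensemble
    wc = water_site_coordinates(ens, *WATER_ROLES)
    tr = residence_trace(wc, 4.0)
    labels = (manifest["state"].values == "minor").astype(int)
    res = state_coupling(labels, tr)
    for k, c in enumerate(res["clusters"]):
        assert res["table_inside"][k] == int(
            np.sum((labels == c) & tr.inside))
        assert res["table_outside"][k] == int(
            np.sum((labels == c) & ~tr.inside))
    assert res["odds_ratio_major_inside"] > 10  # strong planted coupling
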