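import math

import numpy as np
import pytest

import protacsol as ps
from protacsol.errors import DomainError, InsufficientDataError, ParameterizationError
from protacsol.psa3d import (
    VDW_RADII,
    Conformer,
    compute_3d_psa,
    representative_psa_regressions,
    sphere_points,
    summarize_ensemble,
)

R_O = VDW_RADII["O"]
R_N = VDW_RADII["N"]
R_C = VDW_RADII["C"]


def grid_psa_oracle(conformer, n_theta=400, n_phi=800):
    """Brute-force latitude-longitude surface integration, independent of
    the spiral sampler: area elements r^2 sin(theta) dtheta dphi on each
    polar atom, kept if outside every other atom."""
    from protacsol.psa3d import polar_atom_mask

    coords = conformer.coords
    radii = np.array([VDW_RADII[e] for e in conformer.elements])
    mask = polar_atom_mask(conformer)
    theta = (np.arange(n_theta) + 0.5) * math.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * math.pi / n_phi
    st_, ct = np.sin(theta), np.cos(theta)
    total = 0.0
    for i in np.flatnonzero(mask):
        r = radii[i]
        d_area = r * r * st_ * (math.pi / n_theta) * (2 * math.pi / n_phi)  # (n_theta,)
        pts = coords[i] + r * np.stack(
            [st_[:, None] * np.cos(phi)[None, :],
             st_[:, None] * np.sin(phi)[None, :],
             ct[:, None] * np.ones_like(phi)[None, :]], axis=-1)
        exposed = np.ones((n_theta, n_phi), dtype=bool)
        for j in range(len(radii)):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=-1)
            exposed &= d2 >= radii[j] ** 2
        total += float(np.sum(d_area[:, None] * exposed))
    return total


class TestCompute3dPsa:
    def test_isolated_oxygen_full_sphere(self):
        conf = Conformer(elements=("O",), coords=[[0.0, 0.0, 0.0]])
        assert compute_3d_psa(conf) == pytest.approx(4 * math.pi * R_O ** 2, rel=1e-12)

    def test_additive_at_infinite_separation(self):
        conf = Conformer(elements=("O", "O"), coords=[[0, 0, 0], [100.0, 0, 0]])
        assert compute_3d_psa(conf) == pytest.approx(2 * 4 * math.pi * R_O ** 2, rel=1e-12)

    def test_methane_has_no_polar_surface(self):
        coords = [[0, 0, 0], [0.63, 0.63, 0.63], [-0.63, -0.63, 0.63],
                  [-0.63, 0.63, -0.63], [0.63, -0.63, -0.63]]
        conf = Conformer(elements=("C", "H", "H", "H", "H"), coords=coords)
        assert compute_3d_psa(conf) == 0.0

    def test_occluded_pair_matches_grid_oracle(self):
        conf = Conformer(elements=("O", "C"), coords=[[0, 0, 0], [1.43, 0, 0]])
        mine = compute_3d_psa(conf, n_points=3840)
        oracle = grid_psa_oracle(conf)
        assert mine == pytest.approx(oracle, rel=0.005)
        # closed form: exposed area of a sphere cut by one other sphere
        d = 1.43
        cos_alpha = (d * d + R_O * R_O - R_C * R_C) / (2 * d * R_O)
        analytic = 2 * math.pi * R_O ** 2 * (1 + cos_alpha)
        assert mine == pytest.approx(analytic, rel=0.005)

    def test_polar_hydrogen_counts_carbon_hydrogen_does_not(self):
        # O-H: both polar; C-H: neither H nor C polar
        oh = Conformer(elements=("O", "H"), coords=[[0, 0, 0], [0.96, 0, 0]])
        ch = Conformer(elements=("C", "H"), coords=[[0, 0, 0], [1.09, 0, 0]])
        assert compute_3d_psa(oh) > 4 * math.pi * R_O ** 2 * 0.8
        assert compute_3d_psa(ch) == 0.0

    def test_unknown_element_raises(self):
        conf = Conformer(elements=("Xx",), coords=[[0, 0, 0]])
        with pytest.raises(ParameterizationError):
            compute_3d_psa(conf)

    def test_rotation_translation_invariance(self):
        ens = ps.generate_toy_ensemble(1, seed=5, jitter=0.2)
        conf = ens.conformers[0]
        base = compute_3d_psa(conf, n_points=3840)
        rng = np.random.default_rng(11)
        for _ in range(3):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            moved = Conformer(elements=conf.elements,
                              coords=conf.coords @ q.T + rng.normal(size=3))
            assert compute_3d_psa(moved, n_points=3840) == pytest.approx(base, rel=0.005)

    def test_bounded_by_isolated_sphere_sum_and_converges(self):
        ens = ps.generate_toy_ensemble(3, seed=2, jitter=0.1)
        upper = 4 * math.pi * (R_O ** 2 + R_N ** 2)
        coarse_step = fine_step = 0.0
        for conf in ens.conformers:
            coarse = compute_3d_psa(conf, n_points=240)
            fine = compute_3d_psa(conf, n_points=960)
            finest = compute_3d_psa(conf, n_points=3840)
            assert finest <= upper
            coarse_step += abs(coarse - fine)
            fine_step += abs(fine - finest)
        # refinement steps shrink as the point count quadruples
        assert fine_step <= coarse_step + 1e-9


class TestSummarizeEnsemble:
    def test_linear_interpolation_quantiles(self):
        dist = summarize_ensemble(list(range(1, 101)))
        assert dist.median == pytest.approx(50.5)
        assert dist.q1 == pytest.approx(25.75)
        assert dist.q3 == pytest.approx(75.25)

    def test_upper_fence_excludes_outlier(self):
        dist = summarize_ensemble([10, 12, 14, 16, 100])
        assert dist.upper_adjacent == 16
        assert dist.lower_adjacent == 10

    def test_single_value_degenerate(self):
        dist = summarize_ensemble([42.0])
        assert (dist.lower_adjacent, dist.q1, dist.median, dist.q3,
                dist.upper_adjacent) == (42.0,) * 5

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            summarize_ensemble([])

    def test_permutation_invariant(self):
        values = [3.0, 9.0, 1.0, 14.0, 6.0, 2.0]
        a = summarize_ensemble(values)
        b = summarize_ensemble(values[::-1])
        assert (a.median, a.q1, a.q3, a.lower_adjacent, a.upper_adjacent) == \
               (b.median, b.q1, b.q3, b.lower_adjacent, b.upper_adjacent)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            dist = summarize_ensemble(rng.lognormal(3, 1, size=25))
            assert (dist.lower_adjacent <= dist.q1 <= dist.median
                    <= dist.q3 <= dist.upper_adjacent)


class TestRepresentativeRegressions:
    def _distributions(self, medians):
        out = {}
        for i, m in enumerate(medians):
            vals = [m - 5, m - 1, m, m + 1, m + 5]
            out[f"C{i}"] = summarize_ensemble(vals)
        return out

    def test_exactly_linear_median_gives_r2_one(self):
        medians = [100.0, 150.0, 200.0, 250.0]
        dists = self._distributions(medians)
        log_s = {f"C{i}": -0.01 * m - 3.0 for i, m in enumerate(medians)}
        table = representative_psa_regressions(dists, log_s)
        median_row = table[table.statistic == "median"].iloc[0]
        assert median_row.r2 == pytest.approx(1.0, abs=1e-12)
        assert median_row.slope == pytest.approx(-0.01, abs=1e-12)

    def test_order_invariance_and_ols_oracle(self):
        from tests.conftest import ols_oracle

        rng = np.random.default_rng(3)
        medians = rng.uniform(100, 300, size=6)
        dists = self._distributions(medians)
        log_s = {f"C{i}": float(-0.01 * m - 3 + rng.normal(0, 0.3)) for i, m in enumerate(medians)}
        table = representative_psa_regressions(dists, log_s)
        reversed_table = representative_psa_regressions(
            dict(reversed(list(dists.items()))), log_s)
        assert np.allclose(table.slope, reversed_table.slope)
        ids = sorted(dists)
        slope, intercept, r2 = ols_oracle([dists[i].median for i in ids],
                                          [log_s[i] for i in ids])
        row = table[table.statistic == "median"].iloc[0]
        assert row.slope == pytest.approx(slope, abs=1e-10)
        assert row.r2 == pytest.approx(r2, abs=1e-10)

    def test_insufficient_pairs(self):
        dists = self._distributions([100.0, 200.0])
        with pytest.raises(InsufficientDataError):
            representative_psa_regressions(dists, {"C0": -4.0, "C1": -5.0})


def test_sphere_points_are_unit_and_deterministic():
    pts = sphere_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.array_equal(pts, sphere_points(960))
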