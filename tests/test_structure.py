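"""Structural observables: SASA, pair selection, geometry histograms."""

import numpy as np
import pytest

from halosynergy.structure import (GeomHistogram, Structure, Trajectory,
                                   hbond_geometry_histogram,
                                   histogram_difference, minimum_image,
                                   pair_distance_histogram,
                                   select_acidic_pairs, shrake_rupley_sasa,
                                   sphere_points)
from halosynergy.synth import (gen_gaussian_pair_trajectory, gen_hbond_frames,
                               gen_toy_structures)


def atoms(names, xyz, resname="UNK", **kw):
    n = len(names)
    return Structure(names=names, resnames=[resname] * n, resids=[1] * n,
                     chains=["A"] * n, xyz=np.asarray(xyz, float), **kw)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        s = atoms(["O"], [[0.0, 0.0, 0.0]])
        area = shrake_rupley_sasa(s).iloc[0]
        assert area == pytest.approx(4 * np.pi * (1.52 + 1.4) ** 2, rel=1e-9)

    def test_burial_is_monotone(self):
        single = shrake_rupley_sasa(atoms(["C"], [[0, 0, 0]])).iloc[0]
        close = atoms(["C", "C"], [[0, 0, 0], [0.5, 0, 0]])
        far = atoms(["C", "C"], [[0, 0, 0], [3.0, 0, 0]])
        assert shrake_rupley_sasa(close).sum() < shrake_rupley_sasa(far).sum()
        assert shrake_rupley_sasa(far).sum() < 2 * single

    def test_three_atom_monte_carlo_oracle(self):
        xyz = np.array([[0.0, 0.0, 0.0], [1.8, 0.4, 0.0], [0.6, 1.5, 0.9]])
        s = atoms(["C", "O", "N"], xyz)
        impl = shrake_rupley_sasa(s, n_sphere_points=960).sum()

        # dense random-point oracle, independent of the spiral point set
        rng = np.random.default_rng(12345)
        radii = {"C": 1.70, "O": 1.52, "N": 1.55}
        r_ext = np.array([radii[e] + 1.4 for e in ("C", "O", "N")])
        total = 0.0
        for i in range(3):
            pts = rng.normal(size=(100_000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            surf = xyz[i] + r_ext[i] * pts
            exposed = np.ones(len(surf), dtype=bool)
            for j in range(3):
                if j == i:
                    continue
                exposed &= (np.linalg.norm(surf - xyz[j], axis=1) >= r_ext[j])
            total += 4 * np.pi * r_ext[i] ** 2 * exposed.mean()
        assert impl == pytest.approx(total, rel=0.02)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        st, _ = gen_toy_structures([[0, 0, 0], [6, 0, 0]], seed=0)
        base = shrake_rupley_sasa(st, n_sphere_points=240)
        # random rotation (QR of a Gaussian matrix) plus translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = Structure(names=st.names, resnames=st.resnames,
                          resids=st.resids, chains=st.chains,
                          xyz=st.xyz @ q.T + np.array([5.0, -3.0, 11.0]))
        rotated = shrake_rupley_sasa(moved, n_sphere_points=240)
        np.testing.assert_allclose(base.values, rotated.values, rtol=0.02)

    def test_unknown_element_requires_override(self):
        s = atoms(["XX"], [[0, 0, 0]])
        with pytest.raises(KeyError, match="radius"):
            shrake_rupley_sasa(s)
        assert shrake_rupley_sasa(s, radii={"X": 1.0}).iloc[0] > 0

    def test_sphere_points_on_unit_sphere(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


class TestPairSelection:
    def test_three_acid_example(self):
        st, _ = gen_toy_structures(
            [[0, 0, 0], [5, 0, 0], [-1.375, 6.353, 0]], seed=3)
        pairs = select_acidic_pairs(st, sasa_min=50, dmax=7)
        got = sorted((p.residue_a[1], p.residue_b[1]) for p in pairs)
        assert got == [(1, 2), (1, 3)]  # distances 5 and 6.5; 9 Å excluded

    def test_sasa_filter_drops_pairs(self):
        st, _ = gen_toy_structures([[0, 0, 0], [5, 0, 0]], seed=3)
        assert len(select_acidic_pairs(st, sasa_min=0, dmax=7)) == 1
        assert len(select_acidic_pairs(st, sasa_min=1e4, dmax=7)) == 0

    def test_no_thresholds_gives_all_pairs(self):
        st, _ = gen_toy_structures(np.random.default_rng(0).uniform(
            0, 40, size=(5, 3)), seed=1)
        pairs = select_acidic_pairs(st, sasa_min=0.0, dmax=np.inf)
        assert len(pairs) == 5 * 4 // 2

    def test_matches_brute_force_on_random_structures(self):
        rng = np.random.default_rng(2024)
        for trial in range(100):
            n = int(rng.integers(2, 6))
            positions = rng.uniform(0, 25, size=(n, 3))
            try:
                st, _ = gen_toy_structures(positions, seed=trial)
            except ValueError:
                continue  # overlapping placement rejected by the generator
            sasa = shrake_rupley_sasa(st, n_sphere_points=120)
            got = {(p.residue_a[1], p.residue_b[1])
                   for p in select_acidic_pairs(st, sasa_min=50, dmax=7,
                                                sasa=sasa)}
            cg = {key[1]: st.xyz[idx[list(st.names[idx]).index("CG")]]
                  for key, idx in st.residues()}
            expect = set()
            for a in range(1, n + 1):
                for b in range(a + 1, n + 1):
                    d = np.linalg.norm(cg[a] - cg[b])
                    sa = sasa.xs(a, level="resid").iloc[0]
                    sb = sasa.xs(b, level="resid").iloc[0]
                    if d < 7 and sa >= 50 and sb >= 50:
                        expect.add((a, b))
            assert got == expect

    def test_missing_carboxylate_carbon_raises(self):
        s = Structure(names=["CB"], resnames=["ASP"], resids=[1],
                      chains=["A"], xyz=[[0, 0, 0]])
        with pytest.raises(KeyError, match="carboxylate carbon"):
            select_acidic_pairs(s, sasa_min=0)


class TestDistanceHistograms:
    def test_static_structure_single_bin(self):
        st, _ = gen_toy_structures([[0, 0, 0], [5, 0, 0]], seed=0)
        traj = Trajectory.from_structures([st])
        pairs = select_acidic_pairs(st, sasa_min=0)
        h = next(iter(pair_distance_histogram(traj, pairs).values()))
        assert np.max(h.p) == 1.0 and h.p.sum() == pytest.approx(1.0)

    def test_two_frames_half_and_half(self):
        st, _ = gen_toy_structures([[0, 0, 0], [5, 0, 0]],
                                   directions=[[0, 0, 1], [0, 0, 1]], seed=0)
        shifted = Structure(names=st.names, resnames=st.resnames,
                            resids=st.resids, chains=st.chains,
                            xyz=st.xyz + np.where(
                                (st.resids == 2)[:, None], [1.0, 0, 0], 0.0))
        traj = Trajectory.from_structures([st, shifted])
        pairs = select_acidic_pairs(st, sasa_min=0)
        h = next(iter(pair_distance_histogram(traj, pairs,
                                              bin_width=1.0).values()))
        occupied = np.sort(h.p[h.p > 0])
        np.testing.assert_allclose(occupied, [0.5, 0.5])

    def test_gaussian_distance_recovery(self):
        traj, truth = gen_gaussian_pair_trajectory(mu=6.0, sigma=0.5,
                                                   n_frames=10_000, seed=11)
        pairs = select_acidic_pairs(traj.frame(0), sasa_min=0)
        h = next(iter(pair_distance_histogram(traj, pairs,
                                              bin_width=0.25).values()))
        # binning adds at most half a bin of distortion to the mean
        assert h.mean(0) == pytest.approx(truth["distances"].mean(), abs=0.13)

    def test_frame_order_permutation_invariance(self):
        traj, _ = gen_gaussian_pair_trajectory(n_frames=500, seed=1)
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = Trajectory(names=traj.names, resnames=traj.resnames,
                              resids=traj.resids, chains=traj.chains,
                              coords=traj.coords[perm], box=traj.box)
        pairs = select_acidic_pairs(traj.frame(0), sasa_min=0)
        edges = [np.arange(3.0, 9.01, 0.25)]
        h1 = next(iter(pair_distance_histogram(traj, pairs, range=(3, 9),
                                               bin_width=0.25).values()))
        h2 = next(iter(pair_distance_histogram(shuffled, pairs, range=(3, 9),
                                               bin_width=0.25).values()))
        np.testing.assert_array_equal(h1.p, h2.p)

    def test_minimum_image_bound(self):
        rng = np.random.default_rng(4)
        box = np.array([20.0, 30.0, 40.0])
        d = minimum_image(rng.uniform(-100, 100, size=(1000, 3)), box)
        assert np.all(np.abs(d) <= box / 2 + 1e-12)


class TestHbondHistograms:
    def test_linear_bond_lands_at_cos_minus_one(self):
        st, _ = gen_toy_structures([[0, 0, 0]], directions=[[0, 0, 1]],
                                   waters=[(0, 2.7, -1.0)], seed=1)
        h = hbond_geometry_histogram(Trajectory.from_structures([st]))
        assert h.n_samples == 1
        i, j = np.unravel_index(np.argmax(h.p), h.p.shape)
        assert h.centers[0][i] == pytest.approx(2.7, abs=0.05)
        assert h.centers[1][j] == pytest.approx(-1.0, abs=0.05)

    def test_perpendicular_geometry_at_cos_zero(self):
        st, _ = gen_toy_structures([[0, 0, 0]], directions=[[0, 0, 1]],
                                   waters=[(0, 2.0, 0.0)], seed=1)
        h = hbond_geometry_histogram(Trajectory.from_structures([st]))
        assert h.n_samples == 1
        _, j = np.unravel_index(np.argmax(h.p), h.p.shape)
        assert abs(h.centers[1][j]) <= 0.05

    def test_marginal_means_recovered(self):
        traj, truth = gen_hbond_frames(n_waters=400, seed=5)
        h = hbond_geometry_histogram(traj)
        assert h.n_samples == 400
        assert h.mean(0) == pytest.approx(truth["d_mean"], abs=0.03)
        assert h.mean(1) == pytest.approx(truth["cos_mean"], abs=0.03)

    def test_acceptor_restriction(self):
        st, _ = gen_toy_structures([[0, 0, 0], [20, 0, 0]],
                                   directions=[[0, 0, 1], [0, 0, 1]],
                                   waters=[(0, 2.7, -1.0)], seed=1)
        traj = Trajectory.from_structures([st])
        h_all = hbond_geometry_histogram(traj)
        h_far = hbond_geometry_histogram(traj, acceptor_residues=[("A", 2)])
        assert h_all.n_samples == 1 and h_far.n_samples == 0

    def test_malformed_water_raises(self):
        s = Structure(names=["O", "H1"], resnames=["HOH"] * 2, resids=[1] * 2,
                      chains=["W"] * 2, xyz=[[0, 0, 0], [1, 0, 0]])
        acid, _ = gen_toy_structures([[5, 5, 5]], seed=0)
        merged = Structure(
            names=np.concatenate([acid.names, s.names]),
            resnames=np.concatenate([acid.resnames, s.resnames]),
            resids=np.concatenate([acid.resids, s.resids + 10]),
            chains=np.concatenate([acid.chains, s.chains]),
            xyz=np.concatenate([acid.xyz, s.xyz]))
        with pytest.raises(ValueError, match="malformed water"):
            hbond_geometry_histogram(Trajectory.from_structures([merged]))


class TestHistogramDifference:
    def make_hist(self, samples):
        edges = [np.arange(0.0, 4.01, 0.5), np.arange(-1.0, 1.01, 0.5)]
        return GeomHistogram.from_samples(np.asarray(samples), edges,
                                          ("d", "cos_theta"))

    def test_identical_histograms_zero(self):
        h = self.make_hist([[1.0, -0.9], [2.0, 0.1]])
        diff = histogram_difference(h, h)
        np.testing.assert_array_equal(diff.dp, 0.0)

    def test_difference_sums_to_zero(self):
        rng = np.random.default_rng(0)
        a = self.make_hist(np.column_stack([rng.uniform(0, 4, 500),
                                            rng.uniform(-1, 1, 500)]))
        b = self.make_hist(np.column_stack([rng.uniform(0, 4, 500),
                                            rng.uniform(-1, 1, 500)]))
        assert abs(histogram_difference(a, b).dp.sum()) < 1e-9

    def test_tighter_distribution_shows_signed_structure(self):
        """Stronger/more linear bonds → positive mass at small d, cosθ≈−1."""
        traj_a, _ = gen_hbond_frames(n_waters=400, d_mean=2.6, cos_mean=-0.95,
                                     seed=1)
        traj_b, _ = gen_hbond_frames(n_waters=400, d_mean=3.0, cos_mean=-0.75,
                                     seed=2)
        h_a = hbond_geometry_histogram(traj_a)
        h_b = hbond_geometry_histogram(traj_b)
        diff = histogram_difference(h_a, h_b)
        d_c, cos_c = np.meshgrid(*h_a.centers, indexing="ij")
        tight = (d_c < 2.8) & (cos_c < -0.9)
        loose = (d_c > 2.8) & (cos_c > -0.85)
        assert diff.dp[tight].sum() > 0.2
        assert diff.dp[loose].sum() < -0.2

    def test_mismatched_bins_rejected(self):
        h = self.make_hist([[1.0, -0.9]])
        other = GeomHistogram.from_samples(
            np.array([[1.0, -0.9]]),
            [np.arange(0.0, 4.01, 1.0), np.arange(-1.0, 1.01, 0.5)],
            ("d", "cos_theta"))
        with pytest.raises(ValueError, match="mismatched"):
            histogram_difference(h, other)
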