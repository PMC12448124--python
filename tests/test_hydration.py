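import numpy as np
import pytest

import photokin as pk
from photokin.hydration import Frame

from oracles import mc_pocket_volume, projection_dihedral


def make_frame(coords, roles, elements=None, ids=None):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    roles = np.asarray(roles)
    if elements is None:
        elements = np.where(roles == "HOH", "O", "C")
    return Frame(
        np.arange(n) if ids is None else np.asarray(ids),
        roles, np.asarray(elements), coords,
    )


def fibonacci_sphere(n, radius):
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5)) * i
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


class TestPocketRegion:
    def test_empty_space_gives_search_sphere_volume(self):
        frame = make_frame(np.zeros((1, 3)), ["HOH"])  # waters do not occlude
        grid = pk.GridSpec(spacing=0.4, search_radius=6.0)
        res = pk.pocket_region(frame, (0.0, 0.0, 0.0), grid)
        assert res.volume == pytest.approx(4 / 3 * np.pi * 6.0**3, rel=0.05)

    def test_tightly_caged_seed_single_cell(self):
        # dense shell just outside vdW+probe: every neighbour cell occluded
        shell = fibonacci_sphere(400, 3.4)
        frame = make_frame(shell, ["OCC"] * 400)
        grid = pk.GridSpec(spacing=0.4, search_radius=5.0)
        res = pk.pocket_region(frame, (0.0, 0.0, 0.0), grid)
        assert res.volume == pytest.approx(0.4**3)
        assert res.mask.sum() == 1

    def test_occluded_seed_rejected(self):
        frame = make_frame([[0.5, 0.0, 0.0]], ["OCC"])
        with pytest.raises(ValueError, match="seed"):
            pk.pocket_region(frame, (0.0, 0.0, 0.0), pk.GridSpec())

    def test_matches_monte_carlo_rejection_oracle(self):
        """Flood-fill volume within 3% of a large rejection-sampling
        estimate for a random, non-enclosing occluder configuration."""
        rng = np.random.default_rng(8)
        n_atoms = 5
        direction = rng.normal(size=(n_atoms, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        occ = direction * rng.uniform(3.5, 6.0, n_atoms)[:, None]
        frame = make_frame(occ, ["OCC"] * n_atoms)
        grid = pk.GridSpec(spacing=0.4, search_radius=7.0)
        res = pk.pocket_region(frame, (0.0, 0.0, 0.0), grid)
        radii = np.full(n_atoms, 1.7)
        vol_mc = mc_pocket_volume(
            occ, radii, np.zeros(3), 7.0, 1.4, 600_000, np.random.default_rng(9)
        )
        assert res.volume == pytest.approx(vol_mc, rel=0.03)

    def test_volume_monotone_in_probe_and_search_radius(self):
        rng = np.random.default_rng(10)
        occ = rng.uniform(-4, 4, size=(6, 3))
        occ = occ[np.linalg.norm(occ, axis=1) > 3.2]
        frame = make_frame(occ, ["OCC"] * len(occ))
        vols_probe = [
            pk.pocket_region(
                frame, (0, 0, 0), pk.GridSpec(0.4, 6.0, probe_radius=p)
            ).volume
            for p in (1.0, 1.2, 1.4, 1.6)
        ]
        assert all(a >= b for a, b in zip(vols_probe, vols_probe[1:]))
        vols_search = [
            pk.pocket_region(frame, (0, 0, 0), pk.GridSpec(0.4, r)).volume
            for r in (4.0, 5.0, 6.0)
        ]
        assert all(a <= b for a, b in zip(vols_search, vols_search[1:]))

    def test_spacing_refinement_converges(self):
        occ = fibonacci_sphere(40, 6.5)
        frame = make_frame(occ, ["OCC"] * 40)
        v_coarse = pk.pocket_region(frame, (0, 0, 0), pk.GridSpec(0.4, 5.0)).volume
        v_fine = pk.pocket_region(frame, (0, 0, 0), pk.GridSpec(0.2, 5.0)).volume
        assert v_coarse == pytest.approx(v_fine, rel=0.05)


class TestPocketWaters:
    def test_no_waters_counts_zero(self):
        frame = make_frame([[4.0, 0, 0]], ["OCC"])
        region = pk.pocket_region(frame, (0, 0, 0), pk.GridSpec(0.4, 5.0))
        assert pk.count_pocket_waters(frame, region) == 0

    def test_inside_and_outside_waters_separated(self):
        inside = np.array([[0.5, 0, 0], [0, 1, 0], [-1, 0, 0.5], [0, -1, -1], [1, 1, 0]])
        outside = np.array([[9.0, 0, 0], [0, 9.0, 0], [0, 0, 9.0]])
        coords = np.vstack([inside, outside])
        frame = make_frame(coords, ["HOH"] * 8)
        region = pk.pocket_region(frame, (0, 0, 0), pk.GridSpec(0.4, 5.0))
        assert pk.count_pocket_waters(frame, region) == 5
        assert set(region.water_ids) == {0, 1, 2, 3, 4}

    def test_brute_force_cell_membership(self, toy_traj_stepped):
        """Counting agrees with an independent per-cell membership test."""
        grid = pk.GridSpec(0.4, toy_traj_stepped.meta["suggested_search_radius"])
        seed = np.array(toy_traj_stepped.meta["seed_point"])
        for frame in toy_traj_stepped.frames[::7]:
            region = pk.pocket_region(frame, seed, grid)
            count = 0
            for w in frame.select("HOH"):
                idx = np.rint((w - region.origin) / region.spacing).astype(int)
                if np.all(idx >= 0) and np.all(idx < region.mask.shape[0]):
                    count += bool(region.mask[tuple(idx)])
            assert pk.count_pocket_waters(frame, region) == count


class TestRDF:
    def test_ideal_gas_is_unity(self):
        """Uniform targets in a periodic box: g(r) ~ 1 away from r=0."""
        rng = np.random.default_rng(12)
        box = np.array([20.0, 20.0, 20.0])
        n_t, n_frames = 10_000, 50
        frames = []
        roles = np.array(["REF"] + ["HOH"] * n_t)
        elements = np.array(["N"] + ["O"] * n_t)
        ids = np.arange(n_t + 1)
        for _ in range(n_frames):
            coords = np.vstack([[10.0, 10.0, 10.0], rng.uniform(0, 20, (n_t, 3))])
            frames.append(Frame(ids, roles, elements, coords))
        traj = pk.Trajectory(frames, box=box)
        out = pk.rdf(traj, "REF", "HOH", dr=0.2, r_max=9.0)
        sel = (out.r_centers >= 3.0) & (out.r_centers <= 4.5)
        assert np.mean(np.abs(out.g[sel] - 1.0)) < 0.05
        assert out.reference_density == pytest.approx(n_t / 20.0**3)

    def test_no_targets_gives_zero(self):
        frame = make_frame([[0, 0, 0]], ["REF"])
        traj = pk.Trajectory([frame], box=np.array([10.0, 10.0, 10.0]))
        out = pk.rdf(traj, "REF", "HOH", dr=0.2, r_max=4.0)
        assert np.all(out.g == 0.0)

    def test_hand_counted_shells(self):
        # one reference, two waters at 1.05 and 2.55 A, user-supplied density
        coords = [[0, 0, 0], [1.05, 0, 0], [0, 2.55, 0]]
        frame = make_frame(coords, ["REF", "HOH", "HOH"])
        rho = 0.01
        out = pk.rdf(
            pk.Trajectory([frame]), "REF", "HOH", dr=0.5, r_max=3.0,
            bulk_density=rho,
        )
        expected = np.zeros(6)
        for r in (1.05, 2.55):
            k = int(r / 0.5)
            expected[k] += 1.0 / (4 * np.pi * out.r_centers[k] ** 2 * 0.5 * rho)
        assert np.allclose(out.g, expected)

    def test_no_box_requires_density(self):
        frame = make_frame([[0, 0, 0], [1, 0, 0]], ["REF", "HOH"])
        with pytest.raises(ValueError, match="bulk_density"):
            pk.rdf(pk.Trajectory([frame]), "REF", "HOH")


class TestDistanceSeries:
    def test_static_frames_constant(self):
        frame = make_frame([[0, 0, 0], [4.2, 0, 0]], ["REF", "PRB"])
        traj = pk.Trajectory([frame, frame, frame])
        assert np.allclose(pk.distance_series(traj, "REF", "PRB"), 4.2)

    def test_two_single_atoms_both_metrics(self):
        frame = make_frame([[0, 0, 0], [4.2, 0, 0]], ["REF", "PRB"])
        traj = pk.Trajectory([frame])
        assert pk.distance_series(traj, "REF", "PRB", "centroid")[0] == pytest.approx(4.2)
        assert pk.distance_series(traj, "REF", "PRB", "min_heavy")[0] == pytest.approx(4.2)

    def test_min_heavy_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 2, (5, 3))
        b = rng.normal(6, 2, (7, 3))
        frame = make_frame(np.vstack([a, b]), ["REF"] * 5 + ["PRB"] * 7)
        got = pk.distance_series(pk.Trajectory([frame]), "REF", "PRB", "min_heavy")[0]
        brute = min(
            np.linalg.norm(pa - pb) for pa in a for pb in b
        )
        assert got == pytest.approx(brute, abs=1e-12)

    def test_missing_role_rejected(self):
        frame = make_frame([[0, 0, 0]], ["REF"])
        with pytest.raises(ValueError, match="PRB"):
            pk.distance_series(pk.Trajectory([frame]), "REF", "PRB")

    def test_toy_schedule_reproduced(self, toy_traj_stepped):
        d = pk.distance_series(toy_traj_stepped, "REF", "PRB")
        sched = np.concatenate([np.full(30, 4.2), np.full(30, 6.5)])
        assert np.all(np.abs(d - sched) < 3 * 0.15 + 1e-9)

    def test_coupled_occupancy_larger_in_open_state(self, toy_traj_stepped):
        grid = pk.GridSpec(0.4, toy_traj_stepped.meta["suggested_search_radius"])
        seed = np.array(toy_traj_stepped.meta["seed_point"])
        counts = np.array(
            [
                pk.count_pocket_waters(f, pk.pocket_region(f, seed, grid))
                for f in toy_traj_stepped.frames
            ]
        )
        assert counts[30:].mean() > counts[:30].mean()


class TestDihedral:
    def test_coplanar_cis_is_zero(self):
        frame = make_frame(
            [[-2.1, 0.7, 0], [-0.7, 0, 0], [0.7, 0, 0], [2.1, 0.7, 0]],
            ["REF"] * 4,
        )
        assert pk.dihedral(frame, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_twist_is_ninety_degrees(self):
        frame = make_frame(
            [[1.0, 0, -1.0], [0, 0, 0], [0, 0, 1.0], [0, 1.0, 2.0]],
            ["REF"] * 4,
        )
        assert abs(pk.dihedral(frame, 0, 1, 2, 3)) == pytest.approx(90.0, abs=1e-9)

    def test_matches_projection_oracle_on_random_geometries(self):
        rng = np.random.default_rng(17)
        n_ok = 0
        while n_ok < 100:
            p = rng.normal(0, 3, (4, 3))
            try:
                got = pk.dihedral(make_frame(p, ["REF"] * 4), 0, 1, 2, 3)
            except ValueError:
                continue
            ref = projection_dihedral(p)
            diff = (got - ref + 180.0) % 360.0 - 180.0
            assert abs(diff) < 1e-9
            n_ok += 1

    def test_matches_mdanalysis_convention(self):
        """Same sign convention as MDAnalysis (single-precision internals
        limit the agreement to ~1e-4 deg)."""
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(19)
        for _ in range(25):
            p = rng.normal(0, 2, (4, 3))
            got = pk.dihedral(make_frame(p, ["REF"] * 4), 0, 1, 2, 3)
            ref = float(
                np.degrees(
                    calc_dihedrals(p[0][None], p[1][None], p[2][None], p[3][None])
                )[0]
            )
            diff = (got - ref + 180.0) % 360.0 - 180.0
            assert abs(diff) < 1e-3

    def test_collinear_rejected(self):
        frame = make_frame(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], ["REF"] * 4
        )
        with pytest.raises(ValueError, match="collinear"):
            pk.dihedral(frame, 0, 1, 2, 3)

    def test_distinct_ids_required(self):
        frame = make_frame(np.eye(4, 3) * 2, ["REF"] * 4)
        with pytest.raises(ValueError, match="distinct"):
            pk.dihedral(frame, 0, 1, 1, 2)


class TestDensityMap:
    def test_single_static_atom_one_cell(self):
        frame = make_frame([[1.03, 2.07, -0.51]], ["HOH"])
        traj = pk.Trajectory([frame, frame, frame])
        dmap = pk.density_map(traj, "HOH", spacing=0.4)
        assert np.sum(dmap.values > 0) == 1
        assert np.max(dmap.values) == pytest.approx(1.0)

    def test_counting_identity(self):
        """Sum of occupancies x frames = total distinct-cell placements."""
        rng = np.random.default_rng(5)
        frames = []
        roles = np.array(["HOH"] * 3)
        elements = np.array(["O"] * 3)
        ids = np.arange(3)
        base = np.array([[0.0, 0, 0], [5.0, 0, 0], [0, 5.0, 0]])
        n_frames = 10
        for _ in range(n_frames):
            frames.append(Frame(ids, roles, elements, base + rng.normal(0, 0.05, (3, 3))))
        dmap = pk.density_map(pk.Trajectory(frames), "HOH", spacing=1.0)
        assert np.sum(dmap.values) * n_frames == pytest.approx(3 * n_frames)

    def test_gaussian_jitter_matches_analytic_mass(self):
        """Occupancy summed near the mean equals the analytic per-cell
        Gaussian masses (product of 1-D normal CDF differences)."""
        from scipy.stats import norm

        rng = np.random.default_rng(6)
        mu = np.array([0.11, -0.23, 0.05])
        sigma = 0.8
        n_frames = 4000
        roles, elements, ids = np.array(["HOH"]), np.array(["O"]), np.arange(1)
        frames = [
            Frame(ids, roles, elements, (mu + rng.normal(0, sigma, 3))[None, :])
            for _ in range(n_frames)
        ]
        dmap = pk.density_map(pk.Trajectory(frames), "HOH", spacing=0.3)
        nx, ny, nz = dmap.values.shape
        centers = [dmap.origin[d] + np.arange(dmap.values.shape[d]) * dmap.spacing
                   for d in range(3)]
        sel_mass = 0.0
        ana_mass = 0.0
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    c = np.array([centers[0][i], centers[1][j], centers[2][k]])
                    if np.linalg.norm(c - mu) > 1.0:
                        continue
                    sel_mass += dmap.values[i, j, k]
                    p = 1.0
                    for d in range(3):
                        lo = c[d] - dmap.spacing / 2
                        p *= norm.cdf((lo + dmap.spacing - mu[d]) / sigma) - norm.cdf(
                            (lo - mu[d]) / sigma
                        )
                    ana_mass += p
        assert sel_mass == pytest.approx(ana_mass, rel=0.05)

    def test_empty_trajectory_rejected(self):
        frame = make_frame([[0, 0, 0]], ["REF"])
        with pytest.raises(ValueError, match="HOH"):
            pk.density_map(pk.Trajectory([frame]), "HOH")
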