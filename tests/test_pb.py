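"""LPB solver: surface construction, closed-form oracles, and solver properties.

Heavier grid-convergence and far-field benchmarks live in the acceptance
suite; here the solver runs on coarse grids to keep the unit tests fast.
"""

import numpy as np
import pytest

from protonpath import pb, synth
from protonpath.structures import Atom, Structure


def ion(q=1.0, r=2.0, pos=(0.0, 0.0, 0.0)):
    return Structure([Atom(0, "ION", "ION", np.array(pos, dtype=float), q, r)])


def coarse_cfg(**kw):
    kw.setdefault("spacing", 0.8)
    kw.setdefault("ionic_strength", 0.0)
    return pb.PBConfig(**kw)


class TestGridSpec:
    def test_auto_grid_pads_and_encloses(self, small_structure):
        grid = pb.auto_grid(small_structure, spacing=0.8)
        assert np.all(grid.contains(small_structure.positions))
        lo = small_structure.positions.min(axis=0)
        hi = small_structure.positions.max(axis=0)
        assert np.all(grid.origin <= lo - 9.9)
        top = grid.origin + grid.spacing * (np.array(grid.dims) - 1)
        assert np.all(top >= hi + 9.9)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="8 nodes"):
            pb.GridSpec(origin=np.zeros(3), spacing=0.5, dims=(4, 10, 10))

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            pb.GridSpec(origin=np.zeros(3), spacing=0.0, dims=(10, 10, 10))


class TestSurfaceAndMaps:
    def test_empty_structure_all_solvent(self):
        grid = pb.GridSpec(origin=np.full(3, -4.0), spacing=1.0, dims=(9, 9, 9))
        diel, kap = pb.build_maps(Structure(atoms=[]), grid)
        assert np.all(diel.eps_x == 80.0)
        assert np.all(kap.kappa2 > 0)

    def test_single_sphere_interior_fraction(self):
        # node fraction with eps_in ~ sphere volume / grid volume
        grid = pb.GridSpec(origin=np.full(3, -6.0), spacing=0.4, dims=(31, 31, 31))
        mask = pb.molecular_surface_mask(ion(r=2.0), grid, probe_radius=1.4)
        cell = grid.spacing**3
        vol_grid = mask.size * cell
        vol_sphere = 4 / 3 * np.pi * 2.0**3
        assert mask.sum() * cell == pytest.approx(vol_sphere, rel=0.10)
        # and the interior nodes are exactly the |x| < 2 nodes (isolated sphere)
        X, Y, Z = grid.node_coordinates()
        d = np.sqrt(X**2 + Y**2 + Z**2)
        assert np.array_equal(mask, d < 2.0)

    def test_probe_excluded_neck_is_interior(self):
        """A 1.4 Å probe cannot enter the neck between two nearby spheres.

        Brute-force oracle: a point is solvent-exterior iff some probe centre
        position within 1.4 Å of it clears every atom by (radius + 1.4).
        """
        sep = 3.5
        atoms = [
            Atom(0, "A", "A", np.array([-sep / 2, 0.0, 0.0]), 0.0, 2.0),
            Atom(1, "B", "B", np.array([sep / 2, 0.0, 0.0]), 0.0, 2.0),
        ]
        s = Structure(atoms)
        grid = pb.GridSpec(origin=np.full(3, -8.0), spacing=0.4, dims=(41, 41, 41))
        mask = pb.molecular_surface_mask(s, grid, probe_radius=1.4)

        rng = np.random.default_rng(0)
        probes = rng.normal(size=(4000, 3))
        probes /= np.linalg.norm(probes, axis=1)[:, None]
        radii = rng.uniform(0, 1.4, size=4000)[:, None]
        centers = s.positions

        def exterior_oracle(p):
            cand = p + probes * radii
            clear = np.ones(len(cand), dtype=bool)
            for k in range(2):
                clear &= np.linalg.norm(cand - centers[k], axis=1) >= 2.0 + 1.4
            return clear.any()

        # Neck points outside both vdW spheres (|x−c| > 2) but probe-excluded:
        # the probe-centre circle sits at radius ~2.92 in the x=0 plane, so
        # anything closer than 1.52 to the axis is unreachable.
        for p in ([0.0, 1.2, 0.0], [0.0, 0.0, 1.2], [0.0, 1.2, 0.4]):
            p = np.array(p)
            assert not exterior_oracle(p), "oracle disagrees with test construction"
            idx = tuple(np.round((p - grid.origin) / grid.spacing).astype(int))
            assert mask[idx], f"neck point {p} should be eps_in"
        far = np.array([0.0, 6.0, 0.0])
        idx = tuple(np.round((far - grid.origin) / grid.spacing).astype(int))
        assert not mask[idx]

    def test_face_eps_bounds(self, small_structure):
        grid = pb.auto_grid(small_structure, spacing=0.8)
        diel, _ = pb.build_maps(small_structure, grid)
        for arr in (diel.eps_x, diel.eps_y, diel.eps_z):
            assert arr.min() >= 2.0 - 1e-12
            assert arr.max() <= 80.0 + 1e-12

    def test_kappa_zero_in_stern_region(self, small_structure):
        grid = pb.auto_grid(small_structure, spacing=0.8)
        _, kap = pb.build_maps(small_structure, grid, ion_exclusion=2.0)
        X, Y, Z = grid.node_coordinates()
        pts = np.stack([X, Y, Z], axis=-1)
        dmin = np.full(grid.dims, np.inf)
        for a in small_structure.atoms:
            d = np.linalg.norm(pts - a.position, axis=-1) - a.radius
            dmin = np.minimum(dmin, d)
        assert np.all(kap.kappa2[dmin < 2.0] == 0.0)
        assert np.all(kap.kappa2[dmin > 2.0 + 1e-9] > 0.0)

    def test_atom_outside_grid_rejected(self):
        grid = pb.GridSpec(origin=np.zeros(3), spacing=1.0, dims=(9, 9, 9))
        with pytest.raises(ValueError, match="outside"):
            pb.build_maps(ion(pos=(30.0, 0, 0)), grid)

    def test_negative_probe_rejected(self, small_structure):
        grid = pb.auto_grid(small_structure, spacing=0.8)
        with pytest.raises(ValueError):
            pb.build_maps(small_structure, grid, probe_radius=-1.0)


class TestSolver:
    def test_zero_charge_gives_zero_potential(self):
        grid = pb.GridSpec(origin=np.full(3, -4.0), spacing=0.8, dims=(11, 11, 11))
        diel, kap = pb.uniform_maps(grid, 80.0)
        field = pb.solve_lpb(diel, kap, ion(q=0.0), tol=1e-8)
        assert np.allclose(field.phi, 0.0, atol=1e-8)

    def test_coulomb_closed_form_coarse(self):
        # uniform eps=80, single charge: phi ~ 332.0636/(80 r)
        grid = pb.GridSpec(origin=np.full(3, -12.0), spacing=0.8, dims=(31, 31, 31))
        diel, kap = pb.uniform_maps(grid, 80.0)
        field = pb.solve_lpb(diel, kap, ion(q=1.0, r=0.0), tol=1e-6)
        for r in (4.0, 6.0):
            probe = ion(q=0.0, pos=(r, 0, 0))
            phi = pb.potential_at_atoms(field, probe)[0]
            assert phi == pytest.approx(pb.COULOMB_KCAL / (80 * r), rel=0.03)

    def test_linearity_superposition(self, small_structure):
        grid = pb.auto_grid(small_structure, spacing=0.8)
        diel, kap = pb.build_maps(small_structure, grid)
        phi1 = pb.solve_lpb(diel, kap, small_structure, tol=1e-8).phi
        doubled = small_structure.with_positions(small_structure.positions)
        doubled = Structure(
            [a.with_charge(2 * a.charge) for a in doubled.atoms]
        )
        phi2 = pb.solve_lpb(diel, kap, doubled, tol=1e-8).phi
        assert np.allclose(phi2, 2 * phi1, atol=5e-5)

    def test_screening_monotonicity(self):
        grid = pb.GridSpec(origin=np.full(3, -10.0), spacing=0.8, dims=(26, 26, 26))
        phis = []
        for I in (0.0, 0.05, 0.15, 0.5):
            diel, kap = pb.uniform_maps(grid, 80.0, ionic_strength=I)
            field = pb.solve_lpb(diel, kap, ion(q=1.0, r=0.0), tol=1e-7)
            probe = ion(q=0.0, pos=(6.0, 0, 0))
            phis.append(pb.potential_at_atoms(field, probe)[0])
        assert all(a >= b for a, b in zip(phis, phis[1:]))

    def test_nonconvergence_reports_residual(self):
        grid = pb.GridSpec(origin=np.full(3, -8.0), spacing=0.8, dims=(21, 21, 21))
        diel, kap = pb.uniform_maps(grid, 80.0)
        with pytest.raises(pb.ConvergenceError, match="residual"):
            pb.solve_lpb(diel, kap, ion(), tol=1e-14, max_iter=3)

    def test_mismatched_grids_rejected(self):
        g1 = pb.GridSpec(origin=np.zeros(3), spacing=1.0, dims=(9, 9, 9))
        g2 = pb.GridSpec(origin=np.zeros(3), spacing=1.0, dims=(11, 11, 11))
        diel, _ = pb.uniform_maps(g1, 80.0)
        _, kap = pb.uniform_maps(g2, 80.0)
        with pytest.raises(ValueError, match="grid"):
            pb.solve_lpb(diel, kap, ion())


class TestPotentialInterpolation:
    def test_constant_field(self, small_structure):
        grid = pb.auto_grid(small_structure, spacing=1.0)
        field = pb.PotentialField(grid=grid, phi=np.full(grid.dims, 3.25))
        vals = pb.potential_at_atoms(field, small_structure)
        assert np.allclose(vals, 3.25)

    def test_atom_on_node_reads_node_value(self):
        grid = pb.GridSpec(origin=np.full(3, -4.0), spacing=1.0, dims=(9, 9, 9))
        phi = np.zeros(grid.dims)
        phi[4, 4, 4] = 7.5
        field = pb.PotentialField(grid=grid, phi=phi)
        assert pb.potential_at_atoms(field, ion(pos=(0, 0, 0)))[0] == pytest.approx(7.5)

    def test_linear_field_exact(self):
        # trilinear interpolation reproduces phi = a·x exactly
        grid = pb.GridSpec(origin=np.full(3, -4.0), spacing=1.0, dims=(9, 9, 9))
        X, _, _ = grid.node_coordinates()
        field = pb.PotentialField(grid=grid, phi=2.5 * X)
        probe = ion(q=0.0, pos=(0.37, -1.2, 2.9))
        assert pb.potential_at_atoms(field, probe)[0] == pytest.approx(2.5 * 0.37, abs=1e-12)

    def test_atom_outside_grid_rejected(self):
        grid = pb.GridSpec(origin=np.zeros(3), spacing=1.0, dims=(9, 9, 9))
        field = pb.PotentialField(grid=grid, phi=np.zeros(grid.dims))
        with pytest.raises(ValueError):
            pb.potential_at_atoms(field, ion(pos=(-3.0, 0, 0)))


class TestReactionFieldEnergy:
    def test_born_closed_form_coarse(self):
        # 3% band is checked at the production 0.4 Å spacing in the acceptance
        # suite; at 0.8 Å the solver should still be within ~4%
        e = pb.reaction_field_energy(ion(), coarse_cfg())
        exact = -pb.COULOMB_KCAL * (1 / 2 - 1 / 80) / (2 * 2.0)
        assert e == pytest.approx(exact, rel=0.04)

    def test_zero_charge_zero_energy(self):
        e = pb.reaction_field_energy(ion(q=0.0), coarse_cfg())
        assert e == pytest.approx(0.0, abs=1e-6)

    def test_quadratic_charge_scaling(self):
        e1 = pb.reaction_field_energy(ion(q=1.0), coarse_cfg())
        e2 = pb.reaction_field_energy(ion(q=2.0), coarse_cfg())
        assert e2 == pytest.approx(4 * e1, rel=1e-3)

    def test_charge_sign_symmetry(self):
        ep = pb.reaction_field_energy(ion(q=1.0), coarse_cfg())
        em = pb.reaction_field_energy(ion(q=-1.0), coarse_cfg())
        assert ep == pytest.approx(em, rel=1e-9)

    def test_translation_invariance(self):
        # moving the solute 0.2 Å relative to the grid changes the energy < 1%
        cfg = coarse_cfg()
        grid = pb.auto_grid(ion(), spacing=cfg.spacing)
        e0 = pb.reaction_field_energy(ion(), cfg, grid=grid)
        e1 = pb.reaction_field_energy(ion(pos=(0.2, 0.0, 0.0)), cfg, grid=grid)
        assert abs(e1 - e0) / abs(e0) < 0.01


class TestDxRoundTrip:
    def test_write_read_identity(self, tmp_path):
        from protonpath.dx import read_dx, write_dx

        grid = pb.GridSpec(origin=np.array([-1.0, 0.0, 2.0]), spacing=0.5,
                           dims=(8, 9, 10))
        rng = np.random.default_rng(1)
        field = pb.PotentialField(grid=grid, phi=rng.normal(size=grid.dims))
        f = tmp_path / "phi.dx"
        write_dx(field, f)
        back = read_dx(f)
        assert back.grid.dims == grid.dims
        assert np.allclose(back.grid.origin, grid.origin)
        assert np.allclose(back.phi, field.phi, atol=1e-5)
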