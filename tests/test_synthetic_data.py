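import numpy as np
import pytest

from stiffmap.field_model import (
    DisplacementField,
    DomainError,
    ElasticityField,
    Grid2D,
    ShapeError,
    stress_from_strain,
)
from stiffmap.findiff_ops import equilibrium_residual_fd, strain_from_displacement_fd
from stiffmap.synthetic_data import (
    BoundaryLoad,
    NoiseSpec,
    Phantom,
    add_gaussian_noise,
    add_structured_noise,
    forward_solve,
    load_dataset,
    make_phantom,
    mean_displacement,
    psf_kernel,
    save_dataset,
)


class TestBoundaryLoad:
    def test_valid_profiles(self):
        for p in ("uniform_strain", "uniform_load", "normal_load",
                  "central_uniform_load"):
            BoundaryLoad(profile=p, F=1.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            BoundaryLoad(profile="torsion", F=1.0)
        with pytest.raises(DomainError):
            BoundaryLoad(profile="uniform_load", F=0.0)
        with pytest.raises(ValueError):
            BoundaryLoad(profile="uniform_load", F=1.0, side="left")


class TestPhantoms:
    def test_inclusion_two_levels(self, square_grid_24):
        ph = make_phantom("inclusion", square_grid_24, E_bg=1.0, E_inc=5.0,
                          radius_frac=0.2)
        assert set(np.unique(ph.elast.E)) == {1.0, 5.0}

    def test_determinism(self, square_grid_24):
        a = make_phantom("multi_inclusion", square_grid_24, seed=3)
        b = make_phantom("multi_inclusion", square_grid_24, seed=3)
        np.testing.assert_array_equal(a.elast.E, b.elast.E)
        np.testing.assert_array_equal(a.elast.nu, b.elast.nu)

    def test_gradient_monotone(self, square_grid_24):
        ph = make_phantom("gradient", square_grid_24, E_range=(1.0, 3.0))
        E = ph.elast.E
        assert np.all(np.diff(E, axis=1) >= 0)  # non-decreasing left->right
        assert E.min() >= 1.0 and E.max() <= 3.0

    def test_bitmap_mask(self, square_grid_24):
        mask = np.zeros(square_grid_24.cell_shape, dtype=bool)
        mask[5:10, 5:10] = True
        ph = make_phantom("bitmap_mask", square_grid_24, mask=mask,
                          E_bg=1.0, E_inc=4.0)
        assert np.all(ph.elast.E[mask] == 4.0)
        assert np.all(ph.elast.E[~mask] == 1.0)

    def test_bitmap_mask_shape_mismatch(self, square_grid_24):
        with pytest.raises(ShapeError):
            make_phantom("bitmap_mask", square_grid_24, mask=np.zeros((3, 3), bool))

    def test_unknown_descriptor(self, square_grid_24):
        with pytest.raises(ValueError):
            make_phantom("fractal", square_grid_24)


class TestForwardSolve:
    def test_uniaxial_closed_form(self, homogeneous_uniaxial):
        grid, phantom, load, u, E0, F = homogeneous_uniaxial
        L = grid.height
        X, Y = grid.node_xy()
        np.testing.assert_allclose(u.ux, F / (L * E0) * X, atol=1e-9)
        np.testing.assert_allclose(u.uy, 0.0, atol=1e-9)

    def test_uniaxial_stress_recovery(self, homogeneous_uniaxial):
        grid, phantom, load, u, E0, F = homogeneous_uniaxial
        st_ = strain_from_displacement_fd(u)
        sigma = stress_from_strain(st_, phantom.elast)
        np.testing.assert_allclose(sigma.sxx, F / grid.height, rtol=1e-8)

    def test_uniaxial_with_poisson_roller(self):
        # roller support keeps the closed form exact for nu != 0
        n = 10
        g = Grid2D(nx=n, ny=n, t=1.0 / (n - 1), h=1.0 / (n - 1))
        E0, nu0, F = 1.5, 0.3, 0.6
        ph = Phantom(
            elast=ElasticityField(E=np.full(g.cell_shape, E0),
                                  nu=np.full(g.cell_shape, nu0)),
            descriptor="homogeneous",
        )
        u = forward_solve(ph, BoundaryLoad(profile="uniform_load", F=F), g)
        X, Y = g.node_xy()
        q = F / g.height
        np.testing.assert_allclose(u.ux, q / E0 * X, atol=1e-9)
        np.testing.assert_allclose(u.uy, -nu0 * q / E0 * Y, atol=1e-9)

    def test_patch_test_constant_strain(self):
        # clamped-style patch: prescribe linear ux via uniform_strain profile
        n = 8
        g = Grid2D(nx=n, ny=n, t=1.0 / (n - 1), h=1.0 / (n - 1))
        ph = Phantom(
            elast=ElasticityField(E=np.full(g.cell_shape, 2.0),
                                  nu=np.full(g.cell_shape, 0.25)),
            descriptor="homogeneous",
        )
        u = forward_solve(ph, BoundaryLoad(profile="uniform_strain", F=1.0), g)
        st_ = strain_from_displacement_fd(u)
        assert np.ptp(st_.exx) < 1e-10 * max(1.0, np.abs(st_.exx).max())

    def test_solver_residual_reported(self, homogeneous_uniaxial):
        grid, phantom, load, u, E0, F = homogeneous_uniaxial
        _, info = forward_solve(phantom, load, grid, full_output=True)
        assert info["relative_residual"] < 1e-8
        assert info["F_applied"] == pytest.approx(F)

    def test_scale_family_identical_displacements(self, square_grid_24):
        from tests.conftest import gaussian_blob_phantom

        ph = gaussian_blob_phantom(square_grid_24)
        c = 7.3
        ph_scaled = Phantom(
            elast=ElasticityField(E=c * ph.elast.E, nu=ph.elast.nu),
            descriptor="blob",
        )
        u1 = forward_solve(ph, BoundaryLoad(profile="uniform_load", F=0.1),
                           square_grid_24)
        u2 = forward_solve(ph_scaled,
                           BoundaryLoad(profile="uniform_load", F=0.1 * c),
                           square_grid_24)
        np.testing.assert_allclose(u1.ux, u2.ux, rtol=1e-9, atol=1e-13)
        np.testing.assert_allclose(u1.uy, u2.uy, rtol=1e-9, atol=1e-13)

    @pytest.mark.parametrize("profile", ["uniform_load", "normal_load",
                                         "central_uniform_load"])
    def test_reaction_balances_applied_force(self, square_grid_24, profile):
        from tests.conftest import gaussian_blob_phantom

        ph = gaussian_blob_phantom(square_grid_24)
        F = 0.25
        _, info = forward_solve(ph, BoundaryLoad(profile=profile, F=F),
                                square_grid_24, full_output=True)
        assert info["F_applied"] == pytest.approx(F, rel=1e-9)
        assert info["reaction_left_x"] == pytest.approx(F, rel=1e-8)

    def test_uniform_strain_reaction_equals_F(self, square_grid_24):
        from tests.conftest import gaussian_blob_phantom

        ph = gaussian_blob_phantom(square_grid_24)
        u, info = forward_solve(ph, BoundaryLoad(profile="uniform_strain", F=0.4),
                                square_grid_24, full_output=True)
        # right edge displacement is uniform in x
        assert np.ptp(u.ux[:, -1]) < 1e-12

    def test_discrete_equilibrium_residual_refines(self):
        # FD residual of the FEM solution decreases under grid refinement
        from tests.conftest import gaussian_blob_phantom

        norms = []
        for n in (17, 33):
            g = Grid2D(nx=n, ny=n, t=1.0 / (n - 1), h=1.0 / (n - 1))
            ph = gaussian_blob_phantom(g)
            u = forward_solve(ph, BoundaryLoad(profile="uniform_load", F=0.1), g)
            st_ = strain_from_displacement_fd(u)
            sigma = stress_from_strain(st_, ph.elast)
            res, _ = equilibrium_residual_fd(sigma, g)
            norms.append(np.mean(np.abs(res.rx) + np.abs(res.ry)))
        assert norms[1] < norms[0]

    def test_phantom_grid_mismatch(self, square_grid_24, unit_grid):
        ph = make_phantom("inclusion", square_grid_24)
        with pytest.raises(ShapeError):
            forward_solve(ph, BoundaryLoad(profile="uniform_load", F=1.0), unit_grid)


class TestGaussianNoise:
    def _field(self, grid, mean_x, mean_y):
        return DisplacementField(
            ux=np.full(grid.node_shape, mean_x),
            uy=np.full(grid.node_shape, mean_y),
            grid=grid,
        )

    def test_sigma_from_snr_worked_example(self, unit_grid):
        # mean 1.27 at SNR 100 -> sigma 0.0127; mean 0.242 -> 0.00242
        u = self._field(unit_grid, 1.27, 0.242)
        spec = NoiseSpec(kind="gaussian", snr=100, seed=0)
        noisy = add_gaussian_noise(u, spec)
        from stiffmap.synthetic_data import _component_sigma

        assert _component_sigma(u.ux, spec) == pytest.approx(0.0127)
        assert _component_sigma(u.uy, spec) == pytest.approx(0.00242)

    def test_snr_infinity_limit(self, unit_grid):
        u = self._field(unit_grid, 1.0, 0.5)
        noisy = add_gaussian_noise(u, NoiseSpec(kind="gaussian", snr=1e15, seed=1))
        np.testing.assert_allclose(noisy.ux, u.ux, atol=1e-12)

    def test_determinism(self, unit_grid):
        u = self._field(unit_grid, 1.0, 0.5)
        spec = NoiseSpec(kind="gaussian", snr=50, seed=9)
        n1 = add_gaussian_noise(u, spec)
        n2 = add_gaussian_noise(u, spec)
        np.testing.assert_array_equal(n1.ux, n2.ux)

    def test_invalid_snr(self):
        with pytest.raises(DomainError):
            NoiseSpec(kind="gaussian", snr=0.0)

    def test_empirical_std_matches_large_grid(self):
        g = Grid2D(nx=80, ny=80, t=1.0, h=1.0)
        u = DisplacementField(
            ux=np.full(g.node_shape, 2.0), uy=np.full(g.node_shape, 1.0), grid=g
        )
        snr = 20.0
        noisy = add_gaussian_noise(u, NoiseSpec(kind="gaussian", snr=snr, seed=2))
        emp = np.std(noisy.ux - u.ux)
        assert abs(emp - 2.0 / snr) / (2.0 / snr) < 0.05

    def test_wrong_kind(self, unit_grid):
        u = self._field(unit_grid, 1.0, 1.0)
        with pytest.raises(ValueError):
            add_gaussian_noise(u, NoiseSpec(kind="structured", snr=10))


class TestStructuredNoise:
    def test_psf_unit_sum(self):
        k = psf_kernel(6.0, 0.5, 0.05)
        assert k.sum() == pytest.approx(1.0)

    def test_constant_field_passthrough(self, unit_grid):
        u = DisplacementField(
            ux=np.full(unit_grid.node_shape, 3.0),
            uy=np.full(unit_grid.node_shape, -1.0),
            grid=unit_grid,
        )
        spec = NoiseSpec(kind="structured", snr=1e15, seed=0)
        out = add_structured_noise(u, spec)
        np.testing.assert_allclose(out.ux, 3.0, atol=1e-9)
        np.testing.assert_allclose(out.uy, -1.0, atol=1e-9)

    def test_delta_limit_large_spread(self, unit_grid):
        # huge decay rates shrink the PSF to a single sample
        rng = np.random.default_rng(0)
        u = DisplacementField(
            ux=rng.normal(size=unit_grid.node_shape),
            uy=rng.normal(size=unit_grid.node_shape),
            grid=unit_grid,
        )
        spec = NoiseSpec(kind="structured", snr=1e15, seed=0,
                         psf_params=(6.0, 1e6, 1e6))
        out = add_structured_noise(u, spec)
        np.testing.assert_allclose(out.ux, u.ux, atol=1e-9)

    def test_determinism(self, unit_grid):
        rng = np.random.default_rng(1)
        u = DisplacementField(
            ux=rng.normal(size=unit_grid.node_shape),
            uy=rng.normal(size=unit_grid.node_shape),
            grid=unit_grid,
        )
        spec = NoiseSpec(kind="structured", snr=30, seed=4)
        np.testing.assert_array_equal(
            add_structured_noise(u, spec).ux, add_structured_noise(u, spec).ux
        )

    def test_blurs_nonconstant_field(self, unit_grid):
        X, Y = unit_grid.node_xy()
        u = DisplacementField(ux=np.sin(3 * X), uy=0 * X, grid=unit_grid)
        spec = NoiseSpec(kind="structured", snr=1e15, seed=0)
        out = add_structured_noise(u, spec)
        assert not np.allclose(out.ux, u.ux)


class TestMeanDisplacement:
    def test_constant(self, unit_grid):
        u = DisplacementField(
            ux=np.full(unit_grid.node_shape, 2.5),
            uy=np.full(unit_grid.node_shape, -0.5),
            grid=unit_grid,
        )
        assert mean_displacement(u) == (2.5, -0.5)

    def test_two_values(self, unit_grid):
        ux = np.full(unit_grid.node_shape, 1.0)
        ux[: unit_grid.ny // 2] = 3.0
        u = DisplacementField(ux=ux, uy=np.zeros(unit_grid.node_shape),
                              grid=unit_grid)
        assert mean_displacement(u)[0] == pytest.approx(2.0)

    def test_forward_solution_mean_positive(self, homogeneous_uniaxial):
        grid, phantom, load, u, E0, F = homogeneous_uniaxial
        ux_bar, _ = mean_displacement(u)
        assert ux_bar > 0


class TestDatasetBundle:
    def test_roundtrip(self, tmp_path, square_grid_24):
        from tests.conftest import gaussian_blob_phantom

        ph = gaussian_blob_phantom(square_grid_24)
        load = BoundaryLoad(profile="uniform_load", F=0.1)
        clean = forward_solve(ph, load, square_grid_24)
        spec = NoiseSpec(kind="gaussian", snr=100, seed=0)
        noisy = add_gaussian_noise(clean, spec)
        path = tmp_path / "ds.npz"
        save_dataset(path, square_grid_24, clean, noisy, ph, load, spec)
        g2, c2, n2, ph2, load2 = load_dataset(path)
        assert g2 == square_grid_24
        np.testing.assert_array_equal(c2.ux, clean.ux)
        np.testing.assert_array_equal(n2.uy, noisy.uy)
        np.testing.assert_array_equal(ph2.elast.E, ph.elast.E)
        assert load2.profile == "uniform_load" and load2.F == 0.1
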