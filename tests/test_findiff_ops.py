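import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stiffmap.field_model import (
    DisplacementField,
    ElasticityField,
    Grid2D,
    ShapeError,
    StressField,
)
from stiffmap.findiff_ops import (
    KERNELS,
    equilibrium_residual_fd,
    strain_from_displacement_fd,
    valid_convolve,
)


class TestKernelTable:
    def test_strain_kernels_exact(self):
        assert np.array_equal(KERNELS["wx"], [[-0.5, 0.5], [-0.5, 0.5]])
        assert np.array_equal(KERNELS["wy"], [[0.5, 0.5], [-0.5, -0.5]])

    def test_rx_kernels_exact(self):
        assert np.array_equal(
            KERNELS["wxx_x"], [[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]]
        )
        assert np.array_equal(KERNELS["wyy_x"], np.zeros((3, 3)))
        assert np.array_equal(
            KERNELS["wxy_x"], [[1, 1, 1], [0, 0, 0], [-1, -1, -1]]
        )

    def test_ry_kernels_exact(self):
        assert np.array_equal(KERNELS["wxx_y"], np.zeros((3, 3)))
        assert np.array_equal(
            KERNELS["wyy_y"], [[1, 1, 1], [0, 0, 0], [-1, -1, -1]]
        )
        assert np.array_equal(
            KERNELS["wxy_y"], [[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]]
        )

    @pytest.mark.parametrize("name", sorted(KERNELS))
    def test_kernels_annihilate_constants(self, name):
        out = valid_convolve(np.full((6, 6), 3.7), KERNELS[name])
        assert np.allclose(out, 0.0)


class TestValidConvolve:
    def test_identity_kernel(self):
        f = np.random.default_rng(0).normal(size=(4, 5))
        np.testing.assert_array_equal(valid_convolve(f, [[1.0]]), f)

    def test_hand_evaluation_with_wx(self):
        out = valid_convolve(np.array([[1.0, 2.0], [3.0, 4.0]]), KERNELS["wx"])
        assert out.shape == (1, 1)
        assert out[0, 0] == pytest.approx(1.0)  # 0.5*(2-1) + 0.5*(4-3)

    def test_output_shape(self):
        out = valid_convolve(np.zeros((7, 9)), np.zeros((3, 2)))
        assert out.shape == (5, 8)

    def test_field_smaller_than_kernel(self):
        with pytest.raises(ShapeError):
            valid_convolve(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_no_kernel_flip(self):
        # correlation-style: asymmetric kernel picks the (i, j+1) sample
        f = np.array([[0.0, 1.0]])
        out = valid_convolve(f, np.array([[0.0, 1.0]]))
        assert out[0, 0] == 1.0


class TestStrainOperator:
    def _disp(self, grid, fx, fy):
        X, Y = grid.node_xy()
        return DisplacementField(ux=fx(X, Y), uy=fy(X, Y), grid=grid)

    def test_linear_ux_gives_unit_exx(self, unit_grid):
        u = self._disp(unit_grid, lambda X, Y: X, lambda X, Y: 0 * X)
        st_ = strain_from_displacement_fd(u)
        assert np.allclose(st_.exx, 1.0)
        assert np.allclose(st_.eyy, 0.0)
        assert np.allclose(st_.gxy, 0.0)

    def test_pure_shear(self, unit_grid):
        u = self._disp(unit_grid, lambda X, Y: 0 * X, lambda X, Y: X)
        st_ = strain_from_displacement_fd(u)
        assert np.allclose(st_.gxy, 1.0)
        assert np.allclose(st_.exx, 0.0)

    def test_linear_uy_gives_unit_eyy(self, unit_grid):
        u = self._disp(unit_grid, lambda X, Y: 0 * X, lambda X, Y: Y)
        st_ = strain_from_displacement_fd(u)
        assert np.allclose(st_.eyy, 1.0)

    def test_quadratic_profile_hand_value(self):
        # ux = x^2, t = 0.1: cell between x=0.1 and 0.2 -> (0.04-0.01)/0.1 = 0.3
        g = Grid2D(nx=5, ny=4, t=0.1, h=1.0)
        X, Y = g.node_xy()
        u = DisplacementField(ux=X**2, uy=0 * X, grid=g)
        st_ = strain_from_displacement_fd(u)
        assert st_.exx[0, 1] == pytest.approx(0.3)

    def test_unit_spacing_mode_skips_division(self):
        g = Grid2D(nx=5, ny=5, t=0.5, h=0.25)
        X, Y = g.node_xy()
        u = DisplacementField(ux=X, uy=0 * X, grid=g)
        phys = strain_from_displacement_fd(u, "physical")
        unit = strain_from_displacement_fd(u, "unit")
        assert np.allclose(phys.exx, 1.0)
        assert np.allclose(unit.exx, 0.5)  # raw difference over one cell

    @given(
        a=st.floats(-2, 2), b=st.floats(-2, 2), c=st.floats(-2, 2),
        d=st.floats(-2, 2), e=st.floats(-2, 2), f=st.floats(-2, 2),
    )
    @settings(max_examples=25, deadline=None)
    def test_exact_on_affine_fields(self, a, b, c, d, e, f):
        g = Grid2D(nx=6, ny=5, t=0.3, h=0.7)
        X, Y = g.node_xy()
        u = DisplacementField(ux=a + b * X + c * Y, uy=d + e * X + f * Y, grid=g)
        st_ = strain_from_displacement_fd(u)
        assert np.allclose(st_.exx, b, atol=1e-12)
        assert np.allclose(st_.eyy, f, atol=1e-12)
        assert np.allclose(st_.gxy, c + e, atol=1e-12)

    def test_first_order_convergence_on_smooth_field(self):
        # error halves (within tolerance) when spacing halves
        def err_at(n):
            g = Grid2D(nx=n, ny=n, t=1.0 / (n - 1), h=1.0 / (n - 1))
            X, Y = g.node_xy()
            u = DisplacementField(
                ux=np.sin(2 * X) * np.cos(Y), uy=X * Y**2, grid=g
            )
            st_ = strain_from_displacement_fd(u)
            Xc, Yc = g.cell_xy()
            true_exx = 2 * np.cos(2 * Xc) * np.cos(Yc)
            return np.mean(np.abs(st_.exx - true_exx))

    # cell-centered differencing is 2nd order; halving spacing must cut the
    # error by at least ~2x (spec bound), in practice ~4x
        e1, e2 = err_at(17), err_at(33)
        assert e2 < e1 / 2 * 1.3


class TestResidualOperator:
    def test_uniform_stress_zero_residual(self, unit_grid):
        sigma = StressField(
            sxx=np.full((6, 6), 2.0), syy=np.full((6, 6), -1.0),
            txy=np.full((6, 6), 0.5),
        )
        res, _ = equilibrium_residual_fd(sigma, unit_grid)
        assert np.allclose(res.rx, 0.0)
        assert np.allclose(res.ry, 0.0)

    def test_linear_sxx_gives_unit_rx(self):
        # sxx = x, unit spacing -> rx = d(sxx)/dx = 1 after /6t
        g = Grid2D(nx=8, ny=8, t=1.0, h=1.0)
        Xc, Yc = g.cell_xy()
        sigma = StressField(sxx=Xc, syy=0 * Xc, txy=0 * Xc)
        res, _ = equilibrium_residual_fd(sigma, g)
        assert np.allclose(res.rx, 1.0)
        assert np.allclose(res.ry, 0.0)

    def test_literal_mode_divides_by_product(self):
        g = Grid2D(nx=8, ny=8, t=0.5, h=0.25)
        Xc, Yc = g.cell_xy()
        sigma = StressField(sxx=Xc, syy=0 * Xc, txy=0 * Xc)
        res, _ = equilibrium_residual_fd(sigma, g, spacing_mode="literal")
        # raw kernel sum per window is 6*t*dsxx/dx = 3.0; /(h*t) = 24.0
        assert np.allclose(res.rx, 6 * g.t / (g.h * g.t))

    def test_linearity_in_stress(self):
        g = Grid2D(nx=7, ny=6, t=0.3, h=0.8)
        rng = np.random.default_rng(5)
        comps = [rng.normal(size=g.cell_shape) for _ in range(3)]
        s1 = StressField(*comps)
        s2 = StressField(*(3.5 * c for c in comps))
        r1, _ = equilibrium_residual_fd(s1, g)
        r2, _ = equilibrium_residual_fd(s2, g)
        assert np.allclose(r2.rx, 3.5 * r1.rx)
        assert np.allclose(r2.ry, 3.5 * r1.ry)

    @given(
        ax=st.floats(-2, 2), bx=st.floats(-2, 2), cx=st.floats(-2, 2),
        ay=st.floats(-2, 2), by=st.floats(-2, 2), cy=st.floats(-2, 2),
        at_=st.floats(-2, 2), bt=st.floats(-2, 2), ct=st.floats(-2, 2),
    )
    @settings(max_examples=25, deadline=None)
    def test_exact_on_affine_stress(self, ax, bx, cx, ay, by, cy, at_, bt, ct):
        g = Grid2D(nx=7, ny=7, t=0.4, h=0.6)
        Xc, Yc = g.cell_xy()
        sigma = StressField(
            sxx=ax + bx * Xc + cx * Yc,
            syy=ay + by * Xc + cy * Yc,
            txy=at_ + bt * Xc + ct * Yc,
        )
        res, _ = equilibrium_residual_fd(sigma, g)
        assert np.allclose(res.rx, bx + ct, atol=1e-10)
        assert np.allclose(res.ry, bt + cy, atol=1e-10)

    def test_too_small_stress_field(self, unit_grid):
        sigma = StressField(sxx=np.zeros((2, 5)), syy=np.zeros((2, 5)),
                            txy=np.zeros((2, 5)))
        with pytest.raises(ShapeError):
            equilibrium_residual_fd(sigma, unit_grid)

    def test_normalized_residual_and_e_tilde(self, unit_grid):
        shape = (6, 6)
        sigma = StressField(sxx=np.ones(shape), syy=np.ones(shape),
                            txy=np.ones(shape))
        elast = ElasticityField(E=np.full(shape, 2.0), nu=np.full(shape, 0.3))
        res, normalized = equilibrium_residual_fd(sigma, unit_grid, elast=elast)
        assert normalized.shape == res.rx.shape
        assert np.allclose(normalized, 0.0)  # zero residual / (9*2)

    def test_shape_chain(self):
        # node -> cell -> residual: N -> N-1 -> N-3
        g = Grid2D(nx=10, ny=9, t=1.0, h=1.0)
        X, Y = g.node_xy()
        u = DisplacementField(ux=X * Y, uy=X + Y, grid=g)
        st_ = strain_from_displacement_fd(u)
        assert st_.shape == (8, 9)
        elast = ElasticityField(E=np.ones(st_.shape), nu=np.zeros(st_.shape))
        from stiffmap.field_model import stress_from_strain

        sigma = stress_from_strain(st_, elast)
        res, _ = equilibrium_residual_fd(sigma, g)
        assert res.shape == (6, 7)
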