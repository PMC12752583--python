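"""Convolutional finite-difference operators.

Strain is obtained from displacement with 2x2 kernels and the equilibrium
residual from stress with 3x3 kernels, all evaluated as correlation-style
sliding sums (no kernel flip, no padding):

    (f * w)(i, j) = sum_a sum_b w(a, b) * f(i+a-1, j+b-1)

With fields in image orientation (row 0 = top, see
:mod:`stiffmap.field_model`) the kernel column index runs along increasing
``x`` and the kernel row index along *decreasing* ``y``, so the kernels below
compute ``+d/dx`` along columns and ``+d/dy`` along rows.

Spacing modes
-------------
``physical`` (default)
    Derivative estimates are divided by the grid spacing so operators are
    unit-consistent and exact on affine fields: strain kernels by ``t`` or
    ``h``; residual x-derivative kernels by ``6t`` and y-derivative kernels
    by ``6h`` (each 3x3 kernel is the sum of three central differences that
    span two cells).
``unit`` / ``literal``
    The raw sliding sums; the residual is divided by the product ``h*t``.
    Reproduces the bare kernel arithmetic.  On a uniform grid the two modes
    differ only by global positive factors per component, which the
    normalized PDE loss absorbs.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from scipy.signal import convolve2d, correlate2d

from .field_model import (
    DisplacementField,
    DomainError,
    ElasticityField,
    Grid2D,
    ResidualField,
    ShapeError,
    StrainField,
    StressField,
)

__all__ = [
    "KERNELS",
    "valid_convolve",
    "strain_from_displacement_fd",
    "equilibrium_residual_fd",
    "local_modulus_aggregate",
]

# 2x2 first-derivative kernels (strain from displacement)
W_X = np.array([[-0.5, 0.5], [-0.5, 0.5]])
W_Y = np.array([[0.5, 0.5], [-0.5, -0.5]])

# 3x3 kernels for the x-equilibrium residual rx
W_XX_RX = np.array([[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]])
W_YY_RX = np.zeros((3, 3))
W_XY_RX = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -1.0, -1.0]])

# 3x3 kernels for the y-equilibrium residual ry
W_XX_RY = np.zeros((3, 3))
W_YY_RY = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -1.0, -1.0]])
W_XY_RY = np.array([[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]])

#: Documented constant table of every finite-difference kernel.
KERNELS: Dict[str, np.ndarray] = {
    "wx": W_X,
    "wy": W_Y,
    "wxx_x": W_XX_RX,
    "wyy_x": W_YY_RX,
    "wxy_x": W_XY_RX,
    "wxx_y": W_XX_RY,
    "wyy_y": W_YY_RY,
    "wxy_y": W_XY_RY,
}


def valid_convolve(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlation-style sliding sum with no padding.

    Output shape is ``(M-A+1, N-B+1)`` for an ``MxN`` field and ``AxB``
    kernel.  Raises :class:`~stiffmap.field_model.ShapeError` if the field is
    smaller than the kernel.
    """
    field = np.asarray(field, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if field.ndim != 2 or kernel.ndim != 2:
        raise ShapeError("valid_convolve expects 2-D field and kernel")
    if field.shape[0] < kernel.shape[0] or field.shape[1] < kernel.shape[1]:
        raise ShapeError(
            f"field {field.shape} smaller than kernel {kernel.shape}"
        )
    return correlate2d(field, kernel, mode="valid")


def _strain_scales(grid_or_spacing, spacing_mode: str) -> Tuple[float, float]:
    if spacing_mode == "physical":
        return grid_or_spacing  # (t, h)
    if spacing_mode in ("unit", "literal"):
        return (1.0, 1.0)
    raise ValueError(f"unknown spacing_mode {spacing_mode!r}")


def strain_from_displacement_fd(
    u: DisplacementField, spacing_mode: str = "physical"
) -> StrainField:
    """Finite-difference strain on the (ny-1, nx-1) cell grid.

    exx = conv(ux, wx)/sx, eyy = conv(uy, wy)/sy,
    gxy = conv(ux, wy)/sy + conv(uy, wx)/sx,
    with (sx, sy) = (t, h) in ``physical`` mode and (1, 1) otherwise.
    """
    sx, sy = _strain_scales((u.grid.t, u.grid.h), spacing_mode)
    exx = valid_convolve(u.ux, W_X) / sx
    eyy = valid_convolve(u.uy, W_Y) / sy
    gxy = valid_convolve(u.ux, W_Y) / sy + valid_convolve(u.uy, W_X) / sx
    return StrainField(exx=exx, eyy=eyy, gxy=gxy)


def local_modulus_aggregate(E_hat: np.ndarray) -> np.ndarray:
    """3x3 box sum of the modulus field, aligned with the residual windows."""
    return correlate2d(np.asarray(E_hat, dtype=float), np.ones((3, 3)), mode="valid")


def equilibrium_residual_fd(
    sigma: StressField,
    grid: Grid2D,
    elast: ElasticityField | None = None,
    spacing_mode: str = "physical",
) -> Tuple[ResidualField, np.ndarray | None]:
    """Equilibrium residuals (rx, ry) on the (ny-3, nx-3) grid.

    In ``physical`` mode each 3x3 kernel sum is divided by ``6t`` (x
    derivatives) or ``6h`` (y derivatives); in ``literal`` mode the combined
    sum is divided by the product ``h*t`` as a single factor.

    If ``elast`` is given, also returns the normalized residual magnitude
    ``(|rx| + |ry|) / E_tilde`` where ``E_tilde`` is the 3x3 neighborhood sum
    of the modulus field over the same windows; raises
    :class:`~stiffmap.field_model.DomainError` if ``E_tilde <= 0`` anywhere.
    """
    if sigma.shape[0] < 3 or sigma.shape[1] < 3:
        raise ShapeError(f"stress field {sigma.shape} smaller than 3x3 kernels")
    if spacing_mode == "physical":
        rx = (
            valid_convolve(sigma.sxx, W_XX_RX) / (6.0 * grid.t)
            + valid_convolve(sigma.txy, W_XY_RX) / (6.0 * grid.h)
        )
        ry = (
            valid_convolve(sigma.txy, W_XY_RY) / (6.0 * grid.t)
            + valid_convolve(sigma.syy, W_YY_RY) / (6.0 * grid.h)
        )
    elif spacing_mode in ("unit", "literal"):
        scale = grid.h * grid.t
        rx = (
            valid_convolve(sigma.sxx, W_XX_RX) + valid_convolve(sigma.txy, W_XY_RX)
        ) / scale
        ry = (
            valid_convolve(sigma.txy, W_XY_RY) + valid_convolve(sigma.syy, W_YY_RY)
        ) / scale
    else:
        raise ValueError(f"unknown spacing_mode {spacing_mode!r}")

    residual = ResidualField(rx=rx, ry=ry)
    if elast is None:
        return residual, None
    if elast.shape != sigma.shape:
        raise ShapeError(
            f"elasticity shape {elast.shape} != stress shape {sigma.shape}"
        )
    e_tilde = local_modulus_aggregate(elast.E)
    if np.any(e_tilde <= 0):
        raise DomainError("local modulus aggregate E_tilde <= 0")
    normalized = (np.abs(rx) + np.abs(ry)) / e_tilde
    return residual, normalized


def correlate_valid_grad(gout: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`valid_convolve` w.r.t. the field (full convolution)."""
    return convolve2d(gout, kernel, mode="full")
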