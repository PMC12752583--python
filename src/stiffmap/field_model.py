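"""Domain types, the plane-stress constitutive relation, and error metrics.

Array convention
----------------
All scalar fields are 2-D :class:`numpy.ndarray` in *image orientation*:

* axis 0 (rows) runs from the **top** of the domain downwards, i.e. row ``0``
  sits at the largest ``y`` and row ``ny-1`` at ``y = y0``;
* axis 1 (columns) runs left to right with increasing ``x``.

This orientation makes the finite-difference kernels in
:mod:`stiffmap.findiff_ops` compute ``+d/dx`` along columns and ``+d/dy``
along (upward) rows exactly as written.  Documentation below uses 1-based
grid indices ``(i, j)`` with ``i`` along ``x`` and ``j`` along ``y``; the
mapping to array storage is ``array[ny - j, i - 1]``.

Poisson's ratio is restricted to the open interval ``(-1, 0.5)`` (with a
``1e-6`` margin at the top) so that the plane-stress constitutive matrix is
positive definite and ``1 - nu**2`` stays well conditioned.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

NU_MAX = 0.5 - 1e-6
NU_MIN = -1.0 + 1e-6

__all__ = [
    "Grid2D",
    "DisplacementField",
    "StrainField",
    "StressField",
    "ElasticityField",
    "ResidualField",
    "FieldSet",
    "stress_from_strain",
    "mae",
    "mre",
    "constitutive_matrix",
]


class ShapeError(ValueError):
    """Raised when field shapes violate a structural contract."""


class DomainError(ValueError):
    """Raised when field values violate a physical-domain contract."""


@dataclass(frozen=True)
class Grid2D:
    """Equispaced rectangular measurement grid.

    Parameters
    ----------
    nx, ny : int
        Number of grid lines along x and y.  Both must be >= 4 so the
        equilibrium-residual grid ``(nx-3) x (ny-3)`` is non-empty.
    t, h : float
        Horizontal (x) and vertical (y) node spacing, in length units.
    origin : (float, float)
        Physical coordinates ``(x0, y0)`` of the bottom-left node.
    """

    nx: int
    ny: int
    t: float
    h: float
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ShapeError(
                f"grid must be at least 4x4 (got {self.nx}x{self.ny}); the "
                "residual grid (nx-3)x(ny-3) would be empty"
            )
        if not (self.t > 0 and self.h > 0):
            raise DomainError(f"spacings must be positive (t={self.t}, h={self.h})")

    # -- shapes ---------------------------------------------------------
    @property
    def node_shape(self) -> Tuple[int, int]:
        """(rows, cols) = (ny, nx) of nodal fields."""
        return (self.ny, self.nx)

    @property
    def cell_shape(self) -> Tuple[int, int]:
        return (self.ny - 1, self.nx - 1)

    @property
    def residual_shape(self) -> Tuple[int, int]:
        return (self.ny - 3, self.nx - 3)

    @property
    def width(self) -> float:
        return (self.nx - 1) * self.t

    @property
    def height(self) -> float:
        return (self.ny - 1) * self.h

    # -- coordinates ----------------------------------------------------
    def node_xy(self) -> Tuple[np.ndarray, np.ndarray]:
        """Physical node coordinates as (X, Y) arrays of shape (ny, nx)."""
        x0, y0 = self.origin
        x = x0 + self.t * np.arange(self.nx)
        y = y0 + self.h * np.arange(self.ny)[::-1]  # row 0 = top
        return np.meshgrid(x, y)

    def cell_xy(self) -> Tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates as (X, Y) arrays of shape (ny-1, nx-1)."""
        X, Y = self.node_xy()
        Xc = 0.25 * (X[:-1, :-1] + X[:-1, 1:] + X[1:, :-1] + X[1:, 1:])
        Yc = 0.25 * (Y[:-1, :-1] + Y[:-1, 1:] + Y[1:, :-1] + Y[1:, 1:])
        return Xc, Yc


def _check_field(name: str, arr: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != tuple(shape):
        raise ShapeError(f"{name} has shape {arr.shape}, expected {tuple(shape)}")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


@dataclass
class DisplacementField:
    """Nodal displacement components (ux, uy) on an (ny, nx) grid."""

    ux: np.ndarray
    uy: np.ndarray
    grid: Grid2D

    def __post_init__(self) -> None:
        self.ux = _check_field("ux", self.ux, self.grid.node_shape)
        self.uy = _check_field("uy", self.uy, self.grid.node_shape)


@dataclass
class StrainField:
    """Strain components on the (ny-1, nx-1) cell-center grid."""

    exx: np.ndarray
    eyy: np.ndarray
    gxy: np.ndarray

    def __post_init__(self) -> None:
        self.exx = np.asarray(self.exx, dtype=float)
        shape = self.exx.shape
        if self.exx.ndim != 2:
            raise ShapeError("strain components must be 2-D")
        self.eyy = _check_field("eyy", self.eyy, shape)
        self.gxy = _check_field("gxy", self.gxy, shape)
        self.exx = _check_field("exx", self.exx, shape)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.exx.shape


@dataclass
class StressField:
    """Stress components on the (ny-1, nx-1) cell-center grid."""

    sxx: np.ndarray
    syy: np.ndarray
    txy: np.ndarray

    def __post_init__(self) -> None:
        self.sxx = np.asarray(self.sxx, dtype=float)
        if self.sxx.ndim != 2:
            raise ShapeError("stress components must be 2-D")
        shape = self.sxx.shape
        self.syy = _check_field("syy", self.syy, shape)
        self.txy = _check_field("txy", self.txy, shape)
        self.sxx = _check_field("sxx", self.sxx, shape)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.sxx.shape


@dataclass
class ElasticityField:
    """Young's modulus E and Poisson's ratio nu on the cell-center grid.

    Invariants: ``E > 0`` everywhere; ``-1 < nu < 0.5`` everywhere (strict,
    with a 1e-6 safety margin below 0.5).
    """

    E: np.ndarray
    nu: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 2:
            raise ShapeError("elasticity components must be 2-D")
        self.nu = _check_field("nu", self.nu, self.E.shape)
        self.E = _check_field("E", self.E, self.E.shape)
        if np.any(self.E <= 0):
            raise DomainError("Young's modulus must be strictly positive")
        if np.any(self.nu <= -1.0) or np.any(self.nu > NU_MAX):
            raise DomainError(
                f"Poisson's ratio must lie in (-1, {NU_MAX}); "
                f"got range [{self.nu.min()}, {self.nu.max()}]"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.E.shape


@dataclass
class ResidualField:
    """Equilibrium residual components on the (ny-3, nx-3) grid."""

    rx: np.ndarray
    ry: np.ndarray

    def __post_init__(self) -> None:
        self.rx = np.asarray(self.rx, dtype=float)
        if self.rx.ndim != 2:
            raise ShapeError("residual components must be 2-D")
        self.ry = _check_field("ry", self.ry, self.rx.shape)
        self.rx = _check_field("rx", self.rx, self.rx.shape)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.rx.shape


# ---------------------------------------------------------------------------
# Constitutive relation
# ---------------------------------------------------------------------------

def constitutive_matrix(E: float, nu: float) -> np.ndarray:
    """3x3 plane-stress constitutive matrix for scalar (E, nu)."""
    return (E / (1.0 - nu**2)) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )


def stress_from_strain(strain: StrainField, elast: ElasticityField) -> StressField:
    """Pointwise plane-stress constitutive map (strain, E, nu) -> stress.

    sigma_xx = E/(1-nu^2) * (exx + nu*eyy)
    sigma_yy = E/(1-nu^2) * (nu*exx + eyy)
    tau_xy   = E/(1-nu^2) * (1-nu)/2 * gxy
    """
    if strain.shape != elast.shape:
        raise ShapeError(
            f"strain shape {strain.shape} != elasticity shape {elast.shape}"
        )
    E, nu = elast.E, elast.nu
    k = E / (1.0 - nu**2)
    sxx = k * (strain.exx + nu * strain.eyy)
    syy = k * (nu * strain.exx + strain.eyy)
    txy = k * ((1.0 - nu) / 2.0) * strain.gxy
    return StressField(sxx=sxx, syy=syy, txy=txy)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mae(est: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error between two equally shaped scalar fields."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ShapeError(f"shape mismatch: {est.shape} vs {truth.shape}")
    return float(np.mean(np.abs(est - truth)))


def mre(est: np.ndarray, truth: np.ndarray) -> float:
    """Mean relative error in percent: 100 * mean(|est - truth| / truth)."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ShapeError(f"shape mismatch: {est.shape} vs {truth.shape}")
    if np.any(truth == 0):
        raise DomainError("mre undefined: truth contains zeros")
    return float(100.0 * np.mean(np.abs(est - truth) / truth))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_COMPONENTS = ("ux", "uy", "exx", "eyy", "gxy", "sxx", "syy", "txy", "E", "nu")


@dataclass
class FieldSet:
    """A bag of named scalar fields attached to one grid.

    Components (all optional): ``ux, uy`` on the node grid; ``exx, eyy, gxy,
    sxx, syy, txy, E, nu`` on the cell grid.  Serializable to NPZ, HDF5
    (group ``/fields``) and per-component CSV (``x,y,value``).
    """

    grid: Grid2D
    fields: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.fields.items():
            if name not in _COMPONENTS:
                raise KeyError(f"unknown field component {name!r}")
            expected = (
                self.grid.node_shape if name in ("ux", "uy") else self.grid.cell_shape
            )
            self.fields[name] = _check_field(name, arr, expected)

    # -- NPZ ------------------------------------------------------------
    def save_npz(self, path: str | os.PathLike) -> None:
        x0, y0 = self.grid.origin
        meta = dict(
            nx=self.grid.nx, ny=self.grid.ny, t=self.grid.t, h=self.grid.h, x0=x0, y0=y0
        )
        np.savez(path, **meta, **self.fields)

    @classmethod
    def load_npz(cls, path: str | os.PathLike) -> "FieldSet":
        with np.load(path) as z:
            grid = Grid2D(
                nx=int(z["nx"]),
                ny=int(z["ny"]),
                t=float(z["t"]),
                h=float(z["h"]),
                origin=(float(z["x0"]), float(z["y0"])),
            )
            fields = {k: z[k] for k in _COMPONENTS if k in z.files}
        return cls(grid=grid, fields=fields)

    # -- HDF5 -----------------------------------------------------------
    def save_hdf5(self, path: str | os.PathLike) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("fields")
            for k, v in self.fields.items():
                g.create_dataset(k, data=v)
            x0, y0 = self.grid.origin
            for k, v in dict(
                nx=self.grid.nx, ny=self.grid.ny, t=self.grid.t, h=self.grid.h,
                x0=x0, y0=y0,
            ).items():
                f.attrs[k] = v

    @classmethod
    def load_hdf5(cls, path: str | os.PathLike) -> "FieldSet":
        import h5py

        with h5py.File(path, "r") as f:
            grid = Grid2D(
                nx=int(f.attrs["nx"]),
                ny=int(f.attrs["ny"]),
                t=float(f.attrs["t"]),
                h=float(f.attrs["h"]),
                origin=(float(f.attrs["x0"]), float(f.attrs["y0"])),
            )
            fields = {k: f["fields"][k][()] for k in f["fields"]}
        return cls(grid=grid, fields=fields)

    # -- CSV ------------------------------------------------------------
    def to_csv(self, directory: str | os.PathLike) -> None:
        """One file per component with header ``x,y,value``."""
        os.makedirs(directory, exist_ok=True)
        Xn, Yn = self.grid.node_xy()
        Xc, Yc = self.grid.cell_xy()
        for name, arr in self.fields.items():
            X, Y = (Xn, Yn) if name in ("ux", "uy") else (Xc, Yc)
            with open(os.path.join(directory, f"{name}.csv"), "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["x", "y", "value"])
                for x, y, v in zip(X.ravel(), Y.ravel(), arr.ravel()):
                    w.writerow([repr(x), repr(y), repr(v)])
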