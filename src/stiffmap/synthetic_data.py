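"""Forward plane-stress simulator, elasticity phantoms, and noise models.

The forward solver uses bilinear quadrilateral (Q4) elements on the
structured grid, with element-wise constant ``(E, nu)`` taken from the
phantom's cell grid.  The left edge is fully clamped in every loading
scenario (a statics problem needs a rigid-body constraint); the right edge
carries one of four load profiles; top and bottom edges are traction free.
Thickness is fixed at 1, so all forces are per unit thickness.

Noise models: additive i.i.d. Gaussian noise with per-component standard
deviation ``sigma = mean(u_component) / SNR``, and structured noise formed by
convolving the displacement with a cosine-modulated Gaussian point-spread
function before adding Gaussian noise at the same SNR rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.ndimage
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .field_model import (
    DisplacementField,
    DomainError,
    ElasticityField,
    Grid2D,
    ShapeError,
    constitutive_matrix,
)

__all__ = [
    "BoundaryLoad",
    "NoiseSpec",
    "Phantom",
    "forward_solve",
    "make_phantom",
    "add_gaussian_noise",
    "add_structured_noise",
    "mean_displacement",
    "psf_kernel",
    "save_dataset",
    "load_dataset",
]

LOAD_PROFILES = ("uniform_strain", "uniform_load", "normal_load", "central_uniform_load")


@dataclass(frozen=True)
class BoundaryLoad:
    """Applied load on the right edge: profile shape and total force F."""

    profile: str
    F: float
    side: str = "right"
    profile_params: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side != "right":
            raise ValueError("only right-side loading is supported")
        if self.profile not in LOAD_PROFILES:
            raise ValueError(f"profile must be one of {LOAD_PROFILES}")
        if not self.F > 0:
            raise DomainError("total force F must be positive")

    @property
    def std_fraction(self) -> float:
        return float(self.profile_params.get("std_fraction", 0.2))

    @property
    def covered_fraction(self) -> float:
        return float(self.profile_params.get("covered_fraction", 0.5))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: 'gaussian' or 'structured', target SNR, and RNG seed.

    ``psf_params = (fc, sx2, sy2)``: modulation frequency in cycles per
    sample and the axial/lateral Gaussian decay rates of the point-spread
    function (exp(-i^2*sx2 - j^2*sy2) * cos(2*pi*fc*j)).  The frequency
    default keeps the literature's numeral 6 although the sampling rate that
    would give it physical units is unstated; at integer lags it reduces the
    modulation to unity.
    """

    kind: str
    snr: float
    seed: int = 0
    psf_params: Tuple[float, float, float] = (6.0, 0.5, 0.05)
    mean_mode: str = "signed"

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "structured"):
            raise ValueError("kind must be 'gaussian' or 'structured'")
        if not self.snr > 0:
            raise DomainError("snr must be positive")
        if self.mean_mode not in ("signed", "absolute"):
            raise ValueError("mean_mode must be 'signed' or 'absolute'")


@dataclass
class Phantom:
    """Ground-truth elasticity field plus the descriptor that generated it."""

    elast: ElasticityField
    descriptor: str
    params: Dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def make_phantom(
    descriptor: str,
    grid: Grid2D,
    seed: int = 0,
    *,
    E_bg: float = 1.0,
    E_inc: float = 5.0,
    nu_bg: float = 0.3,
    nu_inc: float = 0.45,
    radius_frac: float = 0.2,
    n_inclusions: int = 3,
    E_range: Tuple[float, float] = (1.0, 3.0),
    nu_range: Tuple[float, float] = (0.2, 0.4),
    mask: Optional[np.ndarray] = None,
) -> Phantom:
    """Deterministic elasticity phantom on the cell grid of ``grid``.

    Descriptors: ``inclusion`` (one centered circle), ``multi_inclusion``
    (seeded random circles), ``gradient`` (left-to-right E ramp, bottom-to-top
    nu ramp), ``bitmap_mask`` (binary mask rasterized to a two-level map,
    emulating shape-structured ground truths).
    """
    rng = np.random.default_rng(seed)
    Xc, Yc = grid.cell_xy()
    shape = grid.cell_shape
    x0, y0 = grid.origin
    W, H = grid.width, grid.height

    if descriptor == "inclusion":
        cx, cy = x0 + W / 2, y0 + H / 2
        r = radius_frac * min(W, H)
        inside = (Xc - cx) ** 2 + (Yc - cy) ** 2 <= r**2
        E = np.where(inside, E_inc, E_bg)
        nu = np.where(inside, nu_inc, nu_bg)
    elif descriptor == "multi_inclusion":
        E = np.full(shape, E_bg)
        nu = np.full(shape, nu_bg)
        for _ in range(n_inclusions):
            cx = x0 + rng.uniform(0.2, 0.8) * W
            cy = y0 + rng.uniform(0.2, 0.8) * H
            r = rng.uniform(0.08, 0.18) * min(W, H)
            inside = (Xc - cx) ** 2 + (Yc - cy) ** 2 <= r**2
            E = np.where(inside, rng.uniform(*sorted((E_bg, E_inc))), E)
            nu = np.where(inside, rng.uniform(*sorted((nu_bg, nu_inc))), nu)
    elif descriptor == "gradient":
        fx = (Xc - x0) / W
        fy = (Yc - y0) / H
        E = E_range[0] + (E_range[1] - E_range[0]) * fx
        nu = nu_range[0] + (nu_range[1] - nu_range[0]) * fy
    elif descriptor == "bitmap_mask":
        if mask is None:
            raise ValueError("bitmap_mask descriptor requires a boolean mask")
        mask = np.asarray(mask).astype(bool)
        if mask.shape != shape:
            raise ShapeError(f"mask shape {mask.shape} != cell grid {shape}")
        E = np.where(mask, E_inc, E_bg)
        nu = np.where(mask, nu_inc, nu_bg)
    else:
        raise ValueError(f"unknown phantom descriptor {descriptor!r}")

    return Phantom(
        elast=ElasticityField(E=E, nu=nu),
        descriptor=descriptor,
        params=dict(seed=seed, E_bg=E_bg, E_inc=E_inc, nu_bg=nu_bg, nu_inc=nu_inc),
    )


# ---------------------------------------------------------------------------
# Q4 plane-stress finite elements
# ---------------------------------------------------------------------------

_GAUSS = (-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0))


def _q4_stiffness(t: float, h: float, D: np.ndarray) -> np.ndarray:
    """8x8 stiffness of a t-by-h rectangular Q4 element (unit thickness)."""
    K = np.zeros((8, 8))
    # node order: (0,0), (t,0), (t,h), (0,h) counterclockwise
    for xi in _GAUSS:
        for eta in _GAUSS:
            dN_dxi = 0.25 * np.array(
                [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)]
            )
            dN_deta = 0.25 * np.array(
                [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]
            )
            dN_dx = dN_dxi * 2.0 / t
            dN_dy = dN_deta * 2.0 / h
            B = np.zeros((3, 8))
            B[0, 0::2] = dN_dx
            B[1, 1::2] = dN_dy
            B[2, 0::2] = dN_dy
            B[2, 1::2] = dN_dx
            K += (B.T @ D @ B) * (t * h / 4.0)
    return K


def _assemble(grid: Grid2D, E_cells: np.ndarray, nu_cells: np.ndarray) -> sp.csr_matrix:
    """Global stiffness; nodes numbered iy*nx + ix with y ascending."""
    nx, ny = grid.nx, grid.ny
    # unique (E, nu) pairs share one element matrix
    rows, cols, vals = [], [], []
    cache: Dict[Tuple[float, float], np.ndarray] = {}
    for cy in range(ny - 1):
        for cx in range(nx - 1):
            key = (float(E_cells[cy, cx]), float(nu_cells[cy, cx]))
            Ke = cache.get(key)
            if Ke is None:
                Ke = _q4_stiffness(grid.t, grid.h, constitutive_matrix(*key))
                cache[key] = Ke
            n0 = cy * nx + cx
            nodes = (n0, n0 + 1, n0 + 1 + nx, n0 + nx)
            dofs = np.empty(8, dtype=int)
            dofs[0::2] = [2 * n for n in nodes]
            dofs[1::2] = [2 * n + 1 for n in nodes]
            rows.append(np.repeat(dofs, 8))
            cols.append(np.tile(dofs, 8))
            vals.append(Ke.ravel())
    n_dof = 2 * nx * ny
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof),
    )
    return K.tocsr()


def _edge_traction_forces(grid: Grid2D, load: BoundaryLoad) -> np.ndarray:
    """Consistent nodal x-forces on the right edge, summing exactly to F."""
    ny, h = grid.ny, grid.h
    L = grid.height
    y = h * np.arange(ny)  # edge coordinate measured from the bottom node

    if load.profile == "uniform_load":
        q = np.ones(ny)
    elif load.profile == "normal_load":
        s = load.std_fraction * L
        q = np.exp(-((y - L / 2.0) ** 2) / (2.0 * s**2))
    elif load.profile == "central_uniform_load":
        half = load.covered_fraction / 2.0
        q = ((y >= (0.5 - half) * L) & (y <= (0.5 + half) * L)).astype(float)
    else:  # pragma: no cover
        raise ValueError(load.profile)

    # consistent load vector: per-segment 2-point Gauss over linear N_i
    f = np.zeros(ny)
    for k in range(ny - 1):
        for gp in _GAUSS:
            yy = y[k] + (gp + 1.0) / 2.0 * h
            if load.profile == "uniform_load":
                qv = 1.0
            elif load.profile == "normal_load":
                s = load.std_fraction * L
                qv = np.exp(-((yy - L / 2.0) ** 2) / (2.0 * s**2))
            else:
                half = load.covered_fraction / 2.0
                qv = float((0.5 - half) * L <= yy <= (0.5 + half) * L)
            w = h / 2.0
            N1 = (1.0 - gp) / 2.0
            N2 = (1.0 + gp) / 2.0
            f[k] += w * N1 * qv
            f[k + 1] += w * N2 * qv
    total = f.sum()
    if total <= 0:
        raise DomainError("load profile integrates to a non-positive force")
    return f * (load.F / total)


def forward_solve(
    phantom: Phantom,
    load: BoundaryLoad,
    grid: Grid2D,
    full_output: bool = False,
    fixity: str = "roller",
):
    """Static plane-stress solution on the structured grid.

    The left edge restrains rigid-body motion, the right edge is loaded per
    ``load``, top/bottom edges are traction free.  ``fixity`` selects the
    left-edge support: ``roller`` (default) fixes ``ux`` on the edge and
    ``uy`` at the bottom-left node only, leaving transverse contraction
    free — this avoids the corner stress singularities a full clamp induces
    for nu != 0; ``clamp`` fixes both components on the whole edge.

    Returns nodal displacements in image orientation; with
    ``full_output=True`` also returns a dict with the applied/reaction force
    and the relative solver residual.
    """
    if phantom.elast.shape != grid.cell_shape:
        raise ShapeError(
            f"phantom cells {phantom.elast.shape} != grid cells {grid.cell_shape}"
        )
    nx, ny = grid.nx, grid.ny
    # phantom arrays are image-oriented (row 0 = top); FEM uses y ascending
    E_cells = np.flipud(phantom.elast.E)
    nu_cells = np.flipud(phantom.elast.nu)
    K = _assemble(grid, E_cells, nu_cells)
    n_dof = 2 * nx * ny

    left_nodes = np.arange(ny) * nx
    right_nodes = np.arange(ny) * nx + (nx - 1)
    if fixity == "clamp":
        fixed = np.concatenate([2 * left_nodes, 2 * left_nodes + 1])
    elif fixity == "roller":
        fixed = np.concatenate([2 * left_nodes, [2 * left_nodes[0] + 1]])
    else:
        raise ValueError(f"unknown fixity {fixity!r}")

    f = np.zeros(n_dof)
    prescribed_vals = np.zeros(n_dof)
    if load.profile == "uniform_strain":
        # unit prescribed x-displacement on the right edge, then scale so the
        # total reaction equals F (linear problem)
        fixed = np.concatenate([fixed, 2 * right_nodes])
        prescribed_vals[2 * right_nodes] = 1.0
    else:
        f[2 * right_nodes] = _edge_traction_forces(grid, load)

    free = np.setdiff1d(np.arange(n_dof), fixed)
    u = prescribed_vals.copy()
    rhs = f[free] - K[np.ix_(free, fixed)] @ u[fixed]
    K_ff = K[np.ix_(free, free)].tocsc()
    try:
        u_free = spla.spsolve(K_ff, rhs)
    except Exception as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            f"singular stiffness system (insufficient constraints?): {exc}"
        ) from exc
    if not np.all(np.isfinite(u_free)):
        raise np.linalg.LinAlgError("forward solve produced non-finite displacements")
    u[free] = u_free

    res = np.linalg.norm(K_ff @ u_free - rhs)
    rel_res = res / max(np.linalg.norm(rhs), 1e-300)

    reaction = K @ u - f
    if load.profile == "uniform_strain":
        F_reaction = reaction[2 * right_nodes].sum()
        if F_reaction <= 0:
            raise np.linalg.LinAlgError("non-positive reaction under uniform strain")
        scale = load.F / F_reaction
        u *= scale
        F_applied = load.F
    else:
        F_applied = f[2 * right_nodes].sum()

    ux = np.flipud(u[0::2].reshape(ny, nx))
    uy = np.flipud(u[1::2].reshape(ny, nx))
    disp = DisplacementField(ux=ux, uy=uy, grid=grid)
    if not full_output:
        return disp
    info = dict(
        F_applied=float(F_applied),
        relative_residual=float(rel_res),
        reaction_left_x=float(-reaction[2 * left_nodes].sum()),
    )
    return disp, info


# ---------------------------------------------------------------------------
# Noise models
# ---------------------------------------------------------------------------

def mean_displacement(u: DisplacementField) -> Tuple[float, float]:
    """Arithmetic mean of each displacement component (signed)."""
    return float(np.mean(u.ux)), float(np.mean(u.uy))


def _component_sigma(arr: np.ndarray, spec: NoiseSpec) -> float:
    m = np.mean(np.abs(arr)) if spec.mean_mode == "absolute" else np.mean(arr)
    return abs(float(m)) / spec.snr


def add_gaussian_noise(u: DisplacementField, spec: NoiseSpec) -> DisplacementField:
    """Additive zero-mean Gaussian noise with sigma = mean(u)/SNR per component."""
    if spec.kind != "gaussian":
        raise ValueError("spec.kind must be 'gaussian'")
    rng = np.random.default_rng(spec.seed)
    sx = _component_sigma(u.ux, spec)
    sy = _component_sigma(u.uy, spec)
    ux = u.ux + rng.normal(0.0, 1.0, u.ux.shape) * sx
    uy = u.uy + rng.normal(0.0, 1.0, u.uy.shape) * sy
    return DisplacementField(ux=ux, uy=uy, grid=u.grid)


def psf_kernel(fc: float, sx2: float, sy2: float) -> np.ndarray:
    """Cosine-modulated Gaussian PSF, truncated at three standard deviations
    per axis and normalized to unit sum (so constants pass unchanged)."""
    if sx2 <= 0 or sy2 <= 0:
        raise DomainError("PSF spreading parameters must be positive")
    wi = max(1, int(np.ceil(3.0 / np.sqrt(2.0 * sx2))))
    wj = max(1, int(np.ceil(3.0 / np.sqrt(2.0 * sy2))))
    i = np.arange(-wi, wi + 1)[:, None]
    j = np.arange(-wj, wj + 1)[None, :]
    k = np.exp(-(i**2) * sx2 - (j**2) * sy2) * np.cos(2.0 * np.pi * fc * j)
    total = k.sum()
    if abs(total) < 1e-12:
        raise DomainError("PSF sums to ~0; cannot normalize to unit gain")
    return k / total


def add_structured_noise(u: DisplacementField, spec: NoiseSpec) -> DisplacementField:
    """PSF-convolved displacement plus additive Gaussian noise at the SNR."""
    if spec.kind != "structured":
        raise ValueError("spec.kind must be 'structured'")
    fc, sx2, sy2 = spec.psf_params
    k = psf_kernel(fc, sx2, sy2)
    rng = np.random.default_rng(spec.seed)
    out = {}
    for name, arr in (("ux", u.ux), ("uy", u.uy)):
        blurred = scipy.ndimage.convolve(arr, k, mode="nearest")
        sigma = _component_sigma(arr, spec)
        out[name] = blurred + rng.normal(0.0, 1.0, arr.shape) * sigma
    return DisplacementField(ux=out["ux"], uy=out["uy"], grid=u.grid)


# ---------------------------------------------------------------------------
# Dataset bundles
# ---------------------------------------------------------------------------

def save_dataset(path, grid: Grid2D, clean: DisplacementField,
                 noisy: DisplacementField, phantom: Phantom, load: BoundaryLoad,
                 spec: Optional[NoiseSpec] = None) -> None:
    x0, y0 = grid.origin
    meta = dict(
        nx=grid.nx, ny=grid.ny, t=grid.t, h=grid.h, x0=x0, y0=y0,
        load_profile=load.profile, F=load.F,
        descriptor=phantom.descriptor,
    )
    noise = {}
    if spec is not None:
        noise = dict(
            noise_kind=spec.kind, snr=spec.snr, noise_seed=spec.seed,
            psf_params=np.asarray(spec.psf_params),
        )
    np.savez(
        path,
        ux_clean=clean.ux, uy_clean=clean.uy,
        ux=noisy.ux, uy=noisy.uy,
        E=phantom.elast.E, nu=phantom.elast.nu,
        **meta, **noise,
    )


def load_dataset(path):
    with np.load(path) as z:
        grid = Grid2D(
            nx=int(z["nx"]), ny=int(z["ny"]), t=float(z["t"]), h=float(z["h"]),
            origin=(float(z["x0"]), float(z["y0"])),
        )
        clean = DisplacementField(ux=z["ux_clean"], uy=z["uy_clean"], grid=grid)
        noisy = DisplacementField(ux=z["ux"], uy=z["uy"], grid=grid)
        phantom = Phantom(
            elast=ElasticityField(E=z["E"], nu=z["nu"]),
            descriptor=str(z["descriptor"]),
        )
        load = BoundaryLoad(profile=str(z["load_profile"]), F=float(z["F"]))
    return grid, clean, noisy, phantom, load
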