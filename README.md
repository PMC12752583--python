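# stiffmap

Recovery of spatially heterogeneous **Young's modulus** and **Poisson's
ratio** maps from noisy 2-D displacement measurements under plane-stress
linear elasticity.

The method has two phases:

1. **Phase 1** trains three sine-activated coordinate networks — a
   displacement network (denoises the measurements), a strain network
   (decouples differentiation from the noisy data), and an elasticity
   network (predicts `E` and `nu`) — against a four-term L1 loss:
   displacement misfit, strain discrepancy (network strain vs.
   finite-difference strain of the displacement network), a
   modulus-normalized equilibrium-residual loss, and an anchor pinning the
   modulus to an arbitrary reference `Ec`. Derivatives are evaluated by
   convolutional finite-difference kernels, never autodiff-through-space.
   The result is a *relative*-scale modulus map (equilibrium determines `E`
   only up to a multiplicative constant).
2. **Phase 2** recovers the absolute scale by integrating the predicted
   boundary stress along the loaded edge and aligning it with the known
   applied force: `c_hat = F / sum(sigma_xx * h)`, `E_abs = c_hat * E_rel`.

The package is self-contained and testable end-to-end: it includes a
bilinear-quadrilateral (Q4) plane-stress FEM forward solver, elasticity
phantom generators, and Gaussian / structured (PSF) noise models, so no
external datasets are required. Networks and training run on a small
bundled numpy reverse-mode autodiff engine — no deep-learning framework is
needed.

## Layout

| module | contents |
|---|---|
| `stiffmap.field_model` | grids, field types, constitutive relation, MAE/MRE |
| `stiffmap.findiff_ops` | finite-difference kernels, strain & equilibrium-residual operators |
| `stiffmap.synthetic_data` | Q4 FEM forward solver, phantoms, noise models |
| `stiffmap.coordinate_networks` | positional encoding, SIREN MLPs, ablations |
| `stiffmap.phase1_training` | loss terms, pretraining, joint training, presets |
| `stiffmap.phase2_calibration` | boundary-stress profile, scale calibration |
| `stiffmap.evaluation_reporting` | study harness (noise sweeps, ablations), error maps |
| `stiffmap.autodiff` | minimal reverse-mode autodiff on numpy arrays |

## CLI

```bash
# generate a synthetic dataset (phantom -> FEM -> noise)
stiffmap simulate --descriptor inclusion --n 24 --snr 1000 --seed 0 -o ds.npz

# Phase 1 (relative-scale fields); presets: micro | desk | reduced | paper_scale
stiffmap train --data ds.npz --preset desk --ec 1.0 -o fields.npz

# Phase 2 (absolute modulus from the applied force)
stiffmap calibrate --fields fields.npz -F 0.1 -o calibrated.npz

# errors against the bundled ground truth + error maps
stiffmap evaluate --fields calibrated.npz --truth ds.npz --maps maps/

# reduced-scale studies (noise_sweep, pretrain_ablation, ...)
stiffmap study --kind noise_sweep --preset micro --grid-n 16 -o study/
```

## Conventions and caveats

- Scalar fields are arrays in image orientation: row 0 is the top of the
  domain (largest `y`), columns run with `x`. Nodal fields are
  `(ny, nx)`; strain/stress/elasticity live on the `(ny-1, nx-1)`
  cell-center grid; equilibrium residuals on `(ny-3, nx-3)`.
- The finite-difference operators expose a `spacing_mode`: `physical`
  (default; unit-consistent, exact on affine fields) and `literal`
  (raw kernel sums, residual divided by `h*t`). On uniform grids the two
  differ only by global factors that the normalized PDE loss absorbs.
- The positional-encoding frequency parameter defaults to `f = 1e-4` with
  `omega = 64` frequencies (`f**(2i/omega)`, a descending ladder below 1).
  The desk presets use `f = 4.0`, which spreads frequencies above 1 and
  fits markedly better at small scale.
- Training cost: `micro` ≈ 30 s (16×16), `desk` ≈ 90 s (24×24),
  `reduced` ≈ 15 min (32×32) on one CPU core. `paper_scale` mirrors the
  published architecture (depth 16, width 128, 250k iterations) and is not
  meant for CPU runs.
- Forces are per unit thickness (thickness fixed at 1). Only right-edge
  loading is implemented; the left edge restrains rigid-body motion
  (`roller` default, `clamp` optional).
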