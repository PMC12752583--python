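"""Positional encoding and sine-activated coordinate MLPs.

Three networks share one architecture family: an input encoding maps each
normalized coordinate to ``2*omega`` sinusoidal features (``omega`` sine +
``omega`` cosine, interleaved), and a fully connected MLP with sine (SIREN)
hidden activations maps the encoded ``(x, y)`` pair to its output heads
(2 for displacement, 3 for strain, 2 for elasticity).  Only the elasticity
network constrains its outputs: the modulus head through softplus (strictly
positive) and the Poisson head through a bounded sigmoid (see
:class:`NetworkSpec.nu_activation`).

Input coordinates are normalized to [-1, 1] per axis before encoding; the
encoding and SIREN initialization are scale sensitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .autodiff import Tensor
from .field_model import NU_MAX

__all__ = [
    "EncodingSpec",
    "NetworkSpec",
    "positional_encode",
    "encode_xy",
    "MLP",
    "build_network",
    "ablation_activations",
    "save_checkpoint",
    "load_checkpoint",
]

ACTIVATIONS = ("siren", "swish", "tanh", "relu")


@dataclass(frozen=True)
class EncodingSpec:
    """Sinusoidal positional encoding parameters.

    ``f`` is the minimum frequency (default 1e-4) and ``omega`` the number of
    frequencies (default 64).  Frequency ``i`` (1-based) is ``f**(2*i/omega)``
    and each contributes one sine and one cosine feature, giving ``2*omega``
    features per scalar coordinate and ``4*omega`` for an (x, y) pair.
    """

    f: float = 1e-4
    omega: int = 64

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ValueError("minimum frequency f must be positive")
        if not (isinstance(self.omega, (int, np.integer)) and self.omega >= 1):
            raise ValueError("omega must be an integer >= 1")

    @property
    def frequencies(self) -> np.ndarray:
        i = np.arange(1, self.omega + 1)
        return self.f ** (2.0 * i / self.omega)

    @property
    def width(self) -> int:
        return 2 * self.omega


def positional_encode(coord: np.ndarray, spec: EncodingSpec) -> np.ndarray:
    """Encode scalar coordinates to ``(..., 2*omega)`` interleaved features."""
    coord = np.asarray(coord, dtype=float)
    freqs = spec.frequencies
    phase = coord[..., None] * freqs  # (..., omega)
    out = np.empty(coord.shape + (2 * spec.omega,), dtype=float)
    out[..., 0::2] = np.sin(phase)
    out[..., 1::2] = np.cos(phase)
    return out


def encode_xy(x: np.ndarray, y: np.ndarray, spec: EncodingSpec) -> np.ndarray:
    """Encode coordinate pairs into ``(n, 4*omega)`` feature rows."""
    return np.concatenate(
        [positional_encode(np.ravel(x), spec), positional_encode(np.ravel(y), spec)],
        axis=-1,
    )


def normalize_coords(v: np.ndarray) -> np.ndarray:
    """Affine map of a coordinate array onto [-1, 1]."""
    v = np.asarray(v, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return 2.0 * (v - lo) / (hi - lo) - 1.0


@dataclass(frozen=True)
class NetworkSpec:
    """MLP architecture: hidden depth/width, activation, and output heads."""

    depth: int = 16
    width: int = 128
    activation: str = "siren"
    out_heads: int = 2
    final_activation: str = "identity"  # 'identity' | 'elasticity'
    nu_activation: str = "bounded"  # 'bounded' (0.5*sigmoid) | 'softplus'
    w0_first: float = 30.0
    w0_hidden: float = 1.0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.width < 1:
            raise ValueError("depth and width must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")


def ablation_activations(kind: str, base: Optional[NetworkSpec] = None) -> NetworkSpec:
    """Architecture-identical spec with the hidden activation swapped."""
    if kind not in ACTIVATIONS:
        raise ValueError(f"unknown activation kind {kind!r}")
    base = base or NetworkSpec()
    return replace(base, activation=kind)


class MLP:
    """Coordinate MLP over precomputed encoded features.

    Calling the network with an ``(n, d_in)`` feature matrix returns an
    autodiff :class:`~stiffmap.autodiff.Tensor` of shape ``(n, out_heads)``.
    Evaluation is pure and deterministic for fixed parameters.
    """

    def __init__(self, spec: NetworkSpec, d_in: int, seed: int = 0,
                 output_scale: float = 1.0):
        self.spec = spec
        self.d_in = d_in
        self.seed = seed
        self.output_scale = output_scale
        rng = np.random.default_rng(seed)
        dims = [d_in] + [spec.width] * spec.depth + [spec.out_heads]
        self.weights: List[Tensor] = []
        self.biases: List[Tensor] = []
        for layer, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
            if spec.activation == "siren" and layer < spec.depth:
                w0 = spec.w0_first if layer == 0 else spec.w0_hidden
                bound = np.sqrt(6.0 / fan_in) / w0
            else:
                bound = np.sqrt(6.0 / fan_in)  # Xavier-uniform elsewhere
            W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
            b = np.zeros(fan_out)
            self.weights.append(Tensor(W, requires_grad=True))
            self.biases.append(Tensor(b, requires_grad=True))

    @property
    def params(self) -> List[Tensor]:
        out: List[Tensor] = []
        for W, b in zip(self.weights, self.biases):
            out.extend([W, b])
        return out

    def _hidden(self, z: Tensor, layer: int) -> Tensor:
        act = self.spec.activation
        if act == "siren":
            w0 = self.spec.w0_first if layer == 0 else self.spec.w0_hidden
            return (z * w0).sin() if w0 != 1.0 else z.sin()
        if act == "swish":
            return z.swish()
        if act == "tanh":
            return z.tanh()
        return z.relu()

    def __call__(self, features: np.ndarray | Tensor) -> Tensor:
        a = features if isinstance(features, Tensor) else Tensor(features)
        n_layers = len(self.weights)
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            a = a.matmul(W) + b
            if layer < n_layers - 1:
                a = self._hidden(a, layer)
        if self.spec.final_activation == "elasticity":
            E = a[:, 0:1].softplus() * self.output_scale
            if self.spec.nu_activation == "bounded":
                nu = a[:, 1:2].sigmoid() * NU_MAX
            else:
                nu = a[:, 1:2].softplus()
            from .autodiff import concat

            return concat([E, nu], axis=1)
        if self.output_scale != 1.0:
            a = a * self.output_scale
        return a


def build_network(
    spec: NetworkSpec,
    enc: EncodingSpec,
    seed: int = 0,
    output_scale: float = 1.0,
) -> MLP:
    """Deterministically initialized MLP taking ``encode_xy`` features."""
    return MLP(spec, d_in=2 * enc.width, seed=seed, output_scale=output_scale)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, net: MLP, enc: EncodingSpec, extra: Optional[dict] = None):
    meta = dict(
        spec=dataclass_dict(net.spec), enc=dataclass_dict(enc), seed=net.seed,
        d_in=net.d_in, output_scale=net.output_scale, extra=extra or {},
    )
    arrays = {}
    for k, W in enumerate(net.weights):
        arrays[f"W{k}"] = W.data
    for k, b in enumerate(net.biases):
        arrays[f"b{k}"] = b.data
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> Tuple[MLP, EncodingSpec, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        spec = NetworkSpec(**meta["spec"])
        enc = EncodingSpec(**meta["enc"])
        net = MLP(spec, d_in=int(meta["d_in"]), seed=int(meta["seed"]),
                  output_scale=float(meta["output_scale"]))
        for k in range(len(net.weights)):
            net.weights[k].data = z[f"W{k}"]
            net.biases[k].data = z[f"b{k}"]
    return net, enc, meta.get("extra", {})


def dataclass_dict(obj) -> dict:
    import dataclasses

    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
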