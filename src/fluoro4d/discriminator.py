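"""The 4D-consistency discriminator.

The discriminator sees the input channel and a candidate target channel
flattened into XY(ZxT) view — a stack of Z*T 2D slices ordered z-fastest —
as two channels of one 3D block, and emits a map of patch-wise realness
logits (PatchGAN style, no global pooling).

Because the convolutions extend along the flattened Z*T axis with kernel
``zt_kernel`` and the slices are ordered z-fastest, each logit's receptive
field straddles consecutive z-slices within one time point and, once the
receptive field exceeds Z, consecutive time points as well.  That is the
mechanism by which a single discriminator can judge localization, volumetric
consistency and temporal consistency at once, conditioned on the input
protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fluoro4d.io5d import View, ViewError, Volume4D
from fluoro4d.nn import AvgPool, Chain, Conv3d, InstanceNorm, LeakyReLU
from fluoro4d.reslicing import flatten_xy_zt

__all__ = ["DiscriminatorSpec", "Discriminator", "discriminate"]

_MAX_CH_MULT = 8


@dataclass
class DiscriminatorSpec:
    """Patch-discriminator hyperparameters.

    ``zt_kernel`` is the convolution extent along the flattened Z*T axis;
    with the z-fastest slice order, any value > 1 makes patches span
    consecutive z (and, deeper in the network, consecutive t).  Each of the
    ``n_layers`` blocks halves all three extents, so X, Y and Z*T must be
    divisible by ``2**n_layers``.
    """

    base_channels: int = 64
    n_layers: int = 3
    zt_kernel: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


class Discriminator:
    def __init__(self, spec: DiscriminatorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        b, k = spec.base_channels, spec.zt_kernel
        layers = []
        c_in = 2
        for i in range(spec.n_layers):
            c_out = b * min(2**i, _MAX_CH_MULT)
            block = [Conv3d(c_in, c_out, (4, 4, k), rng)]
            if i > 0:
                block.append(InstanceNorm(c_out))
            block += [LeakyReLU(), AvgPool((2, 2, 2))]
            layers.append(Chain(block))
            c_in = c_out
        layers.append(Chain([Conv3d(c_in, 1, (4, 4, k), rng)]))
        self.chain = Chain(layers)

    def params(self):
        return self.chain.params()

    def grads(self):
        return self.chain.grads()

    def zero_grads(self):
        for g in self.grads():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    def patch_shape(self, volume_shape) -> tuple:
        """Closed-form logit-map extents for an (X, Y, Z, T) input."""
        X, Y, Z, T = volume_shape
        f = 2**self.spec.n_layers
        if X % f or Y % f or (Z * T) % f:
            raise ValueError(f"extents (X={X}, Y={Y}, Z*T={Z*T}) must be divisible by {f}")
        return (X // f, Y // f, (Z * T) // f)

    def receptive_field_zt(self) -> int:
        """Receptive field of one logit along the flattened Z*T axis."""
        rf, jump = 1, 1
        for _ in range(self.spec.n_layers):
            rf += (self.spec.zt_kernel - 1) * jump  # conv, stride 1
            rf += (2 - 1) * jump  # pool, kernel 2
            jump *= 2  # pool stride
        rf += (self.spec.zt_kernel - 1) * jump  # final conv
        return rf

    def forward_array(self, x_flat: np.ndarray, cand_flat: np.ndarray):
        """Logits for two pre-flattened (X, Y, Z*T) blocks; returns (y, cache)."""
        stacked = np.stack([x_flat, cand_flat], axis=0).astype(np.float32)
        y, cache = self.chain.forward(stacked)
        return y[0], cache

    def backward_array(self, gy: np.ndarray, cache):
        """Accumulate parameter grads; return grads w.r.t. (input, candidate)."""
        g = self.chain.backward(gy[None], cache)
        return g[0], g[1]

    def discriminate(self, input_v: Volume4D, candidate_v: Volume4D) -> np.ndarray:
        """Patch logit map for an (input, candidate) pair of XYZ-T volumes."""
        if input_v.data.shape != candidate_v.data.shape:
            raise ValueError(
                f"shape mismatch: input {input_v.data.shape} vs candidate {candidate_v.data.shape}"
            )
        if input_v.view is not View.XYZ_T or candidate_v.view is not View.XYZ_T:
            raise ViewError("discriminate expects XYZ_T volumes")
        self.patch_shape(input_v.data.shape)  # validates divisibility
        y, _ = self.forward_array(flatten_xy_zt(input_v), flatten_xy_zt(candidate_v))
        return y


def discriminate(input_v: Volume4D, candidate_v: Volume4D, spec: DiscriminatorSpec) -> np.ndarray:
    """Functional wrapper: build a seeded discriminator and score the pair."""
    return Discriminator(spec).discriminate(input_v, candidate_v)
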