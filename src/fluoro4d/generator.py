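"""The 4D-reslicing generator.

The generator maps one protein's normalized (X, Y, Z, T) block onto a
prediction of another protein's block of identical shape.  It encodes the
input twice: the XYZ path runs a 3D convolutional encoder over the z-stack of
every time point, the XYT path runs a second, independent encoder over the
2D+time movie of every z-slice.  Per-frame encodings are assembled into 5D
feature stacks; the XYT-path stack is resliced into XYZ-T view so that the
two stacks coincide voxel-for-voxel in space and time; and a shared decoder
consumes the concatenated pair for every time point, reconstructing the
output z-stack by z-stack.

Encoders downsample only X and Y (by 2 per level); the third axis (Z for the
XYZ path, T for the XYT path) is convolved with stride 1 and same padding.
This is the only simple scheme under which the two feature stacks come out
shape-identical after reslicing, which is what makes the pairing exact.  It
also makes the network fully convolutional in Z and T, so the parameter
count is independent of those extents.

Single-path ablations are first-class: mode "xyz" feeds the XYZ-path stack
to the decoder twice (no XYT encoder exists), mode "xyt" the converse.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from fluoro4d.io5d import View, ViewError, Volume4D
from fluoro4d.nn import AvgPool, Chain, Conv3d, InstanceNorm, LeakyReLU, NearestUpsample, Tanh, n_parameters

__all__ = ["GeneratorSpec", "Generator"]

_MODES = ("dual", "xyz", "xyt")


@dataclass
class GeneratorSpec:
    """Architecture hyperparameters of the generator.

    ``depth`` is the number of XY halvings; input X and Y extents must be
    divisible by ``2**depth``.  ``base_channels`` is the channel count after
    the stem convolution; it doubles at each level, so the bottleneck carries
    ``base_channels * 2**depth`` feature channels.  Defaults (64, 4) give a
    Pix2Pix-scale network; tests use much smaller values.
    """

    base_channels: int = 64
    depth: int = 4
    use_skip: bool = True
    mode: str = "dual"  # dual | xyz | xyt
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    @property
    def feature_channels(self) -> int:
        return self.base_channels * 2**self.depth


class _Encoder:
    """Stem conv + ``depth`` [pool, conv, norm, act] levels; XY-only pooling."""

    def __init__(self, spec: GeneratorSpec, rng):
        b, d = spec.base_channels, spec.depth
        self.depth = d
        # no normalization on the stem: the outermost layers must carry
        # absolute intensity (instance norm discards per-frame brightness,
        # which the skip path is there to preserve)
        self.blocks = [Chain([Conv3d(1, b, (3, 3, 3), rng), LeakyReLU()])]
        for i in range(d):
            c_in, c_out = b * 2**i, b * 2 ** (i + 1)
            self.blocks.append(
                Chain([AvgPool((2, 2, 1)), Conv3d(c_in, c_out, (3, 3, 3), rng), InstanceNorm(c_out), LeakyReLU()])
            )

    def params(self):
        return [p for blk in self.blocks for p in blk.params()]

    def grads(self):
        return [g for blk in self.blocks for g in blk.grads()]

    def forward(self, x):
        feats, caches = [], []
        h = x
        for j, blk in enumerate(self.blocks):
            h, c = blk.forward(h)
            caches.append(c)
            if j < self.depth:
                feats.append(h)
        return h, feats, caches

    def backward(self, gh, gfeats, caches):
        g = gh
        for j in reversed(range(len(self.blocks))):
            if gfeats is not None and j < self.depth and gfeats[j] is not None:
                g = g + gfeats[j]
            g = self.blocks[j].backward(g, caches[j])
        return g


class _Decoder:
    """Upsample back to input XY extent; optional XYZ-encoder skips; tanh out."""

    def __init__(self, spec: GeneratorSpec, rng):
        b, d = spec.base_channels, spec.depth
        self.depth = d
        # skips come from the XYZ encoder, which only exists in dual/xyz modes
        self.use_skip = spec.use_skip and spec.mode != "xyt"
        in_ch = 2 * spec.feature_channels
        self.ups = []
        self.convs = []
        for i in range(d, 0, -1):
            out_ch = b * 2 ** (i - 1)
            skip_ch = out_ch if self.use_skip else 0
            self.ups.append(NearestUpsample((2, 2, 1)))
            layers = [Conv3d(in_ch + skip_ch, out_ch, (3, 3, 3), rng)]
            if i > 1:  # outermost level un-normalized (see encoder stem note)
                layers.append(InstanceNorm(out_ch))
            layers.append(LeakyReLU())
            self.convs.append(Chain(layers))
            in_ch = out_ch
        self.final = Chain([Conv3d(b, 1, (3, 3, 3), rng), Tanh()])

    def params(self):
        return [p for c in self.convs for p in c.params()] + self.final.params()

    def grads(self):
        return [g for c in self.convs for g in c.grads()] + self.final.grads()

    def forward(self, f1, f2, skips):
        h = np.concatenate([f1, f2], axis=0)
        caches = []
        for lvl in range(self.depth):
            h, cu = self.ups[lvl].forward(h)
            pre_ch = h.shape[0]
            if self.use_skip:
                h = np.concatenate([h, skips[self.depth - 1 - lvl]], axis=0)
            h, cc = self.convs[lvl].forward(h)
            caches.append((cu, pre_ch, cc))
        y, cf = self.final.forward(h)
        caches.append(cf)
        return y[0], caches  # drop the singleton channel axis

    def backward(self, gy, caches):
        g = self.final.backward(gy[None], caches[-1])
        gskips = [None] * self.depth
        for lvl in reversed(range(self.depth)):
            cu, pre_ch, cc = caches[lvl]
            g = self.convs[lvl].backward(g, cc)
            if self.use_skip:
                gskips[self.depth - 1 - lvl] = g[pre_ch:]
                g = g[:pre_ch]
            g = self.ups[lvl].backward(g, cu)
        half = g.shape[0] // 2
        return g[:half], g[half:], gskips


class Generator:
    """Dual-path 4D-reslicing generator (see module docstring)."""

    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.enc_xyz = _Encoder(spec, rng) if spec.mode != "xyt" else None
        self.enc_xyt = _Encoder(spec, rng) if spec.mode != "xyz" else None
        self.dec = _Decoder(spec, rng)

    # -- parameter plumbing --------------------------------------------------

    def params(self):
        out = []
        if self.enc_xyz is not None:
            out += self.enc_xyz.params()
        if self.enc_xyt is not None:
            out += self.enc_xyt.params()
        out += self.dec.params()
        return out

    def grads(self):
        out = []
        if self.enc_xyz is not None:
            out += self.enc_xyz.grads()
        if self.enc_xyt is not None:
            out += self.enc_xyt.grads()
        out += self.dec.grads()
        return out

    def zero_grads(self):
        for g in self.grads():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    # -- forward / backward --------------------------------------------------

    def _check(self, shape):
        X, Y = shape[:2]
        div = 2**self.spec.depth
        if X % div or Y % div:
            raise ValueError(f"X,Y extents {X},{Y} must be divisible by 2**depth = {div}")

    def encode_xyz(self, frame: np.ndarray) -> np.ndarray:
        """Encode one (X, Y, Z) frame to a (C_f, X', Y', Z) feature map."""
        self._check(frame.shape)
        h, _, _ = self.enc_xyz.forward(frame[None].astype(np.float32))
        return h

    def encode_xyt(self, movie: np.ndarray) -> np.ndarray:
        """Encode one (X, Y, T) slice-movie to a (C_f, X', Y', T) feature map."""
        self._check(movie.shape)
        h, _, _ = self.enc_xyt.forward(movie[None].astype(np.float32))
        return h

    def decode_pair(self, f1: np.ndarray, f2: np.ndarray, skips=None) -> np.ndarray:
        """Decode one shape-identical feature pair back to an (X, Y, Z) frame."""
        if f1.shape != f2.shape:
            raise ViewError(
                f"feature pair shapes differ ({f1.shape} vs {f2.shape}); reslicing contract violated"
            )
        if self.dec.use_skip and skips is None:
            raise ValueError("decoder built with skips; pass the XYZ-encoder skip features")
        y, _ = self.dec.forward(f1, f2, skips)
        return y

    def forward_array(self, x: np.ndarray, keep_cache: bool = False):
        """Run the full pipeline on an (X, Y, Z, T) array in XYZ-T view.

        Returns ``(y, cache)``; the cache is None unless ``keep_cache`` and is
        consumed by :meth:`backward_array` during training.
        """
        self._check(x.shape)
        x = np.ascontiguousarray(x, dtype=np.float32)
        X, Y, Z, T = x.shape
        mode = self.spec.mode

        f1s, skips_t, caches_xyz = [], [], []
        if mode != "xyt":
            for t in range(T):
                h, feats, c = self.enc_xyz.forward(x[:, :, :, t][None])
                f1s.append(h)
                skips_t.append(feats)
                caches_xyz.append(c if keep_cache else None)

        f2s, caches_xyt, gzs = [], [], []
        if mode != "xyz":
            for z in range(Z):
                h, _, c = self.enc_xyt.forward(np.ascontiguousarray(x[:, :, z, :])[None])
                gzs.append(h)  # (C_f, X', Y', T)
                caches_xyt.append(c if keep_cache else None)
            # assemble (C_f, X', Y', T, Z) then reslice to XYZ-T: per-t slices
            F2 = np.stack(gzs, axis=-1)  # view XYT_Z
            f2s = [np.ascontiguousarray(F2[:, :, :, t, :]) for t in range(T)]

        ys, caches_dec = [], []
        for t in range(T):
            if mode == "dual":
                f1, f2, sk = f1s[t], f2s[t], skips_t[t]
            elif mode == "xyz":
                f1 = f2 = f1s[t]
                sk = skips_t[t]
            else:  # xyt
                f1 = f2 = f2s[t]
                sk = None
            y, c = self.dec.forward(f1, f2, sk)
            ys.append(y)
            caches_dec.append(c if keep_cache else None)
        out = np.stack(ys, axis=-1)
        cache = (x.shape, caches_xyz, caches_xyt, caches_dec) if keep_cache else None
        return out, cache

    def backward_array(self, gy: np.ndarray, cache) -> None:
        """Accumulate parameter gradients for a forward pass (keep_cache=True)."""
        if cache is None:
            raise ValueError("forward_array must be called with keep_cache=True before backward")
        (X, Y, Z, T), caches_xyz, caches_xyt, caches_dec = cache
        mode = self.spec.mode

        gf1s = [None] * T
        gF2 = None
        for t in range(T):
            g1, g2, gsk = self.dec.backward(np.ascontiguousarray(gy[:, :, :, t]), caches_dec[t])
            if mode == "dual":
                gf1s[t] = (g1, gsk)
                if gF2 is None:
                    gF2 = np.zeros(g2.shape + (T,), dtype=g2.dtype)
                gF2[..., t] = g2
            elif mode == "xyz":
                gf1s[t] = (g1 + g2, gsk)
            else:  # xyt
                if gF2 is None:
                    gF2 = np.zeros(g1.shape + (T,), dtype=g1.dtype)
                gF2[..., t] = g1 + g2

        if mode != "xyt":
            for t in range(T):
                gh, gsk = gf1s[t]
                self.enc_xyz.backward(gh, gsk, caches_xyz[t])
        if mode != "xyz":
            # gF2 axes: (C_f, X', Y', Z, T); XYT-encoder frame z sees (C_f, X', Y', T)
            for z in range(Z):
                self.enc_xyt.backward(np.ascontiguousarray(gF2[:, :, :, z, :]), None, caches_xyt[z])

    def generate(self, v: Volume4D) -> Volume4D:
        """Predict the target channel for a normalized XYZ-T volume."""
        if v.view is not View.XYZ_T:
            raise ViewError(f"generate expects an XYZ_T volume, got {v.view}")
        y, _ = self.forward_array(v.data)
        return v.with_data(y)

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params())}
        np.savez(path, __spec__=np.frombuffer(json.dumps(asdict(self.spec)).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Generator":
        with np.load(path) as npz:
            spec = GeneratorSpec(**json.loads(bytes(npz["__spec__"]).decode()))
            g = cls(spec)
            for i, p in enumerate(g.params()):
                p[...] = npz[f"p{i}"]
        return g

    def single_path_variant(self, mode: str) -> "Generator":
        """Construct the ablation variant sharing this spec (fresh weights)."""
        return Generator(replace(self.spec, mode=mode))
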