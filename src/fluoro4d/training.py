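"""Conditional-adversarial training of the reslicing generator.

Standard Pix2Pix-family objective: the discriminator is trained to tell real
(input, target) pairs from (input, prediction) pairs; the generator minimizes
the adversarial term plus an L1 reconstruction term weighted by
``lambda_l1``.  Defaults (lambda 100, lr 2e-4, Adam betas (0.5, 0.999),
vanilla GAN loss, batch 1) are the published Pix2Pix values; they are starting
points, not tuned constants.

Training alternates one discriminator update and one generator update per
step, each on a single randomly drawn pair, and is bit-reproducible from the
config seed.  A non-finite loss aborts immediately with a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fluoro4d.discriminator import Discriminator, DiscriminatorSpec
from fluoro4d.generator import Generator, GeneratorSpec
from fluoro4d.io5d import Volume4D
from fluoro4d.nn import Adam
from fluoro4d.reslicing import flatten_xy_zt, unflatten_xy_zt

__all__ = [
    "TrainConfig",
    "TrainingDivergedError",
    "loss_discriminator",
    "loss_generator",
    "train",
    "validation_l1",
]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    lambda_l1: float = 100.0
    gan_mode: str = "vanilla"  # vanilla | least_squares
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    adam_betas: tuple = (0.5, 0.999)
    steps: int = 1000
    batch: int = 1
    seed: int = 0
    val_every: int = 25
    #: optional early stopping: end training once validation L1 falls to the
    #: absolute level ``early_stop_l1`` or to ``early_stop_frac`` of its
    #: initial value (whichever is set); ``steps`` stays the hard cap
    early_stop_l1: float = None
    early_stop_frac: float = None

    def __post_init__(self):
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.gan_mode not in ("vanilla", "least_squares"):
            raise ValueError(f"unknown gan_mode {self.gan_mode!r}")


def _softplus(x):
    return np.logaddexp(0.0, x)


def _bce_logits(logits: np.ndarray, target: float):
    """Mean binary cross-entropy with logits; returns (loss, dloss/dlogits)."""
    n = logits.size
    loss = float(np.mean(_softplus(logits) - target * logits))
    sig = 1.0 / (1.0 + np.exp(-logits))
    return loss, (sig - target) / n


def _lsgan(logits: np.ndarray, target: float):
    n = logits.size
    diff = logits - target
    return float(np.mean(diff * diff)), 2.0 * diff / n


def _gan_terms(mode):
    return _bce_logits if mode == "vanilla" else _lsgan


def loss_discriminator(d_real: np.ndarray, d_fake: np.ndarray, mode: str = "vanilla") -> float:
    """D objective: real pairs toward 1, fake pairs toward 0 (mean of both)."""
    term = _gan_terms(mode)
    lr, _ = term(np.asarray(d_real, dtype=np.float64), 1.0)
    lf, _ = term(np.asarray(d_fake, dtype=np.float64), 0.0)
    return 0.5 * (lr + lf)


def loss_generator(d_fake: np.ndarray, pred: Volume4D, target: Volume4D, cfg: TrainConfig) -> float:
    """G objective: adversarial term (fake toward 1) + lambda_l1 * mean |err|."""
    p = pred.data if isinstance(pred, Volume4D) else np.asarray(pred)
    t = target.data if isinstance(target, Volume4D) else np.asarray(target)
    if p.shape != t.shape:
        raise ValueError(f"pred/target shape mismatch: {p.shape} vs {t.shape}")
    adv, _ = _gan_terms(cfg.gan_mode)(np.asarray(d_fake, dtype=np.float64), 1.0)
    return adv + cfg.lambda_l1 * float(np.mean(np.abs(p - t)))


def validation_l1(g: Generator, pairs) -> float:
    """Mean absolute error of the generator over a list of (input, target)."""
    total, n = 0.0, 0
    for x, y in pairs:
        xd = x.data if isinstance(x, Volume4D) else x
        yd = y.data if isinstance(y, Volume4D) else y
        pred, _ = g.forward_array(xd)
        total += float(np.abs(pred - yd).sum())
        n += yd.size
    return total / n


def _as_array_pairs(pairs):
    out = []
    for x, y in pairs:
        xd = x.data if isinstance(x, Volume4D) else np.asarray(x)
        yd = y.data if isinstance(y, Volume4D) else np.asarray(y)
        if xd.shape != yd.shape:
            raise ValueError("input/target shapes must be uniform")
        out.append((np.ascontiguousarray(xd, np.float32), np.ascontiguousarray(yd, np.float32)))
    return out


def _flat(a: np.ndarray) -> np.ndarray:
    # (X,Y,Z,T) -> (X,Y,T*Z), z-fastest; mirrors reslicing.flatten_xy_zt
    X, Y, Z, T = a.shape
    return np.ascontiguousarray(a.transpose(0, 1, 3, 2)).reshape(X, Y, T * Z)


def _unflat(a: np.ndarray, Z: int) -> np.ndarray:
    X, Y, K = a.shape
    return np.ascontiguousarray(a.reshape(X, Y, K // Z, Z).transpose(0, 1, 3, 2))


def train(pairs, g_spec: GeneratorSpec, d_spec: DiscriminatorSpec, cfg: TrainConfig, val_pairs=None):
    """Alternating D/G training; returns ``(checkpoint, history)``.

    ``pairs`` is a non-empty list of (input, target) XYZ-T volumes or arrays
    on the [-1, 1] scale with one common shape.  ``checkpoint`` is a dict with
    the generator, discriminator, specs and config; ``history`` a DataFrame
    of per-step losses plus periodic validation L1 on ``val_pairs`` (defaults
    to the training pairs).
    """
    data = _as_array_pairs(pairs)
    if not data:
        raise ValueError("dataset is empty")
    val = _as_array_pairs(val_pairs) if val_pairs is not None else data

    rng = np.random.default_rng(cfg.seed)
    g = Generator(g_spec)
    d = Discriminator(d_spec)
    opt_g = Adam(g.params(), g.grads(), lr=cfg.lr_g, betas=tuple(cfg.adam_betas))
    opt_d = Adam(d.params(), d.grads(), lr=cfg.lr_d, betas=tuple(cfg.adam_betas))
    term = _gan_terms(cfg.gan_mode)
    Z = data[0][0].shape[2]

    rows = []
    val0 = validation_l1(g, val)
    for step in range(cfg.steps):
        d_loss_acc = adv_acc = l1_acc = 0.0
        for _ in range(cfg.batch):
            x, y = data[rng.integers(len(data))]
            fake, gcache = g.forward_array(x, keep_cache=True)

            xf, yf, ff = _flat(x), _flat(y), _flat(fake)

            # --- discriminator update -----------------------------------
            d.zero_grads()
            lr_logits, cr = d.forward_array(xf, yf)
            lf_logits, cf = d.forward_array(xf, ff)
            loss_r, g_r = term(lr_logits, 1.0)
            loss_f, g_f = term(lf_logits, 0.0)
            d.backward_array(0.5 * g_r, cr)
            d.backward_array(0.5 * g_f, cf)
            opt_d.step()
            d_loss = 0.5 * (loss_r + loss_f)

            # --- generator update (through the updated D) ---------------
            lf2, cf2 = d.forward_array(xf, ff)
            adv, g_adv_logits = term(lf2, 1.0)
            d.zero_grads()  # discard D param grads from this pass
            _, g_cand_flat = d.backward_array(g_adv_logits, cf2)
            g_fake = _unflat(g_cand_flat, Z)
            l1 = float(np.mean(np.abs(fake - y)))
            g_fake += cfg.lambda_l1 * np.sign(fake - y) / fake.size
            g.zero_grads()
            g.backward_array(g_fake.astype(np.float32), gcache)
            opt_g.step()

            if not (np.isfinite(d_loss) and np.isfinite(adv) and np.isfinite(l1)):
                raise TrainingDivergedError(
                    f"non-finite loss at step {step}: d={d_loss}, adv={adv}, l1={l1}"
                )
            d_loss_acc += d_loss
            adv_acc += adv
            l1_acc += l1

        row = {
            "step": step,
            "d_loss": d_loss_acc / cfg.batch,
            "g_adv": adv_acc / cfg.batch,
            "g_l1": l1_acc / cfg.batch,
            "val_l1": np.nan,
        }
        stop = False
        if (step + 1) % cfg.val_every == 0 or step == cfg.steps - 1:
            vl1 = validation_l1(g, val)
            row["val_l1"] = vl1
            if cfg.early_stop_l1 is not None and vl1 <= cfg.early_stop_l1:
                stop = True
            if cfg.early_stop_frac is not None and vl1 <= cfg.early_stop_frac * val0:
                stop = True
        rows.append(row)
        if stop:
            break

    history = pd.DataFrame(rows)
    history.attrs["val_l1_initial"] = val0
    checkpoint = {
        "generator": g,
        "discriminator": d,
        "g_spec": g_spec,
        "d_spec": d_spec,
        "config": cfg,
        "val_l1_initial": val0,
        "val_l1_final": float(history["val_l1"].dropna().iloc[-1]),
    }
    return checkpoint, history
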