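"""Digital activation (DA) and digital inactivation (DI) of protein channels.

These tools edit the *input* channel of a trained predictor — erasing signal
to the diffuse inactive-pool level, boosting contrast above background,
freezing a region in time, or drawing new membrane boundaries — and the
response of the re-predicted output channel is read out with
:func:`response_map`.  Compared with genetic perturbations, the edits have
exact spatial and temporal control, which is the whole point: the response
localizes the modeled relationship between the two proteins.

Erase replaces in-region voxels with the per-(z, t)-slice median *outside*
the mask, not with zero: the inactive pool of a protein is a uniform
low-intensity background, and a predictor trained on real channels has never
seen true zeros.  (Pass ``background=0.0`` to compare.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.draw import line as draw_line

from fluoro4d.io5d import Volume4D

__all__ = [
    "RegionSpec",
    "digital_inactivate",
    "digital_activate",
    "freeze_region",
    "draw_boundary",
    "response_map",
]

_MODES = ("erase", "gain", "freeze", "draw")


@dataclass
class RegionSpec:
    """One DA/DI edit: a spatial mask, a frame range, a mode and parameters.

    ``mask`` is boolean, shaped (X, Y) or (X, Y, Z), broadcast over the
    remaining axes.  ``t_range`` is a half-open (start, stop) frame interval;
    None means the full extent.  ``gain`` scales in-region contrast above
    background for mode "gain"; ``draw_polyline`` / ``draw_intensity`` /
    ``draw_sigma`` configure mode "draw".
    """

    mode: str
    mask: np.ndarray = None
    t_range: tuple = None
    gain: float = 1.0
    draw_polyline: np.ndarray = None
    draw_intensity: float = 1.0
    draw_sigma: float = 1.5

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode in ("erase", "gain", "freeze"):
            if self.mask is None or not np.asarray(self.mask).any():
                raise ValueError(f"mode {self.mode!r} requires a non-empty mask")
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mode == "gain" and self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.mode == "draw":
            self.draw_polyline = np.asarray(self.draw_polyline, dtype=float).reshape(-1, 2)

    def frames(self, T: int) -> range:
        t0, t1 = self.t_range if self.t_range is not None else (0, T)
        if not (0 <= t0 <= t1 <= T):
            raise ValueError(f"t_range {self.t_range} outside [0, {T}]")
        return range(t0, t1)

    def mask3d(self, shape_xyz) -> np.ndarray:
        """Broadcast the stored mask to (X, Y, Z)."""
        m = self.mask
        if m.ndim == 2:
            m = m[:, :, None]
        return np.broadcast_to(m, shape_xyz)


def _check_mask(m2d: np.ndarray):
    if m2d.all():
        raise ValueError("mask covers the entire slice; background is inestimable")


def digital_inactivate(v: Volume4D, r: RegionSpec, background: float | None = None) -> Volume4D:
    """DI: replace in-region voxels with the inactive-pool level.

    The replacement level is the median intensity outside the mask of each
    (z, t) slice (or the fixed ``background`` override).  Voxels outside the
    mask and frame range are bit-identical; the edit is idempotent.
    """
    if r.mode != "erase":
        raise ValueError(f"digital_inactivate requires mode 'erase', got {r.mode!r}")
    out = v.data.copy()
    X, Y, Z, T = out.shape
    m3 = r.mask3d((X, Y, Z))
    for t in r.frames(T):
        for z in range(Z):
            m = m3[:, :, z]
            if not m.any():
                continue
            _check_mask(m)
            level = background if background is not None else np.median(out[:, :, z, t][~m])
            out[:, :, z, t][m] = level
    return v.with_data(out)


def digital_activate(v: Volume4D, r: RegionSpec, clip: tuple | None = None) -> Volume4D:
    """DA: scale in-region contrast above the local background by ``gain``.

    In-region voxels map to ``background + gain * (value - background)`` with
    the per-(z, t)-slice outside-median as background; ``gain=1`` is the
    identity.  Pass ``clip=(-1, 1)`` when operating on normalized inputs to
    keep the edit inside the predictor's training range.
    """
    if r.mode != "gain":
        raise ValueError(f"digital_activate requires mode 'gain', got {r.mode!r}")
    out = v.data.copy()
    X, Y, Z, T = out.shape
    m3 = r.mask3d((X, Y, Z))
    for t in r.frames(T):
        for z in range(Z):
            m = m3[:, :, z]
            if not m.any():
                continue
            _check_mask(m)
            bg = np.median(out[:, :, z, t][~m])
            # ordered so gain == 1 reproduces the input bit-exactly
            vals = r.gain * out[:, :, z, t][m] + (1.0 - r.gain) * bg
            if clip is not None:
                vals = np.clip(vals, *clip)
            out[:, :, z, t][m] = vals
    return v.with_data(out)


def freeze_region(v: Volume4D, r: RegionSpec, t0: int) -> Volume4D:
    """Hold in-region voxels at their frame-``t0`` values for later frames.

    For every frame ``t > t0`` inside ``t_range``, masked voxels are copied
    from frame ``t0``; everything else is untouched.  This is the "keep the
    cell area from shrinking" manipulation.
    """
    if r.mode != "freeze":
        raise ValueError(f"freeze_region requires mode 'freeze', got {r.mode!r}")
    out = v.data.copy()
    X, Y, Z, T = out.shape
    if not 0 <= t0 < T:
        raise ValueError(f"t0={t0} outside [0, {T})")
    m3 = r.mask3d((X, Y, Z))
    ref = out[:, :, :, t0].copy()
    for t in r.frames(T):
        if t > t0:
            out[:, :, :, t][m3] = ref[m3]
    return v.with_data(out)


def draw_boundary(v: Volume4D, r: RegionSpec) -> Volume4D:
    """Render a polyline into a membrane channel (cell-splitting edit).

    The polyline is rasterized, given a Gaussian cross-profile of width
    ``draw_sigma`` (matching the phantom's membrane renderer) at
    ``draw_intensity``, and max-composited onto the stated frames, so drawn
    pixels are never darker than the original.
    """
    if r.mode != "draw":
        raise ValueError(f"draw_boundary requires mode 'draw', got {r.mode!r}")
    pts = r.draw_polyline
    if len(pts) < 2:
        return v.with_data(v.data.copy())
    out = v.data.copy()
    X, Y, Z, T = out.shape
    if (pts < 0).any() or (pts[:, 0] > X - 1).any() or (pts[:, 1] > Y - 1).any():
        raise ValueError("polyline extends outside the image domain")
    mask = np.zeros((X, Y), dtype=bool)
    for a, b in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(*np.round(a).astype(int), *np.round(b).astype(int))
        mask[rr, cc] = True
    d = distance_transform_edt(~mask)
    prof = r.draw_intensity * np.exp(-(d * d) / (2.0 * r.draw_sigma**2))
    for t in r.frames(T):
        for z in range(Z):
            out[:, :, z, t] = np.maximum(out[:, :, z, t], prof)
    return v.with_data(out)


def response_map(pred_before: Volume4D, pred_after: Volume4D, mask: np.ndarray | None = None):
    """Signed difference (after - before) plus in/out-of-mask summaries.

    Returns ``(diff_volume, summary)`` where the summary holds mean and mean
    absolute response inside and outside the given (X, Y) or (X, Y, Z) mask
    (NaN when no mask is given).  Antisymmetric in its arguments.
    """
    if pred_before.data.shape != pred_after.data.shape:
        raise ValueError(
            f"shape mismatch: {pred_before.data.shape} vs {pred_after.data.shape}"
        )
    diff = pred_after.data.astype(np.float64) - pred_before.data.astype(np.float64)
    summary = {
        "mean_inside": np.nan,
        "mean_outside": np.nan,
        "mean_abs_inside": np.nan,
        "mean_abs_outside": np.nan,
    }
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.ndim == 2:
            m = m[:, :, None, None]
        elif m.ndim == 3:
            m = m[:, :, :, None]
        m = np.broadcast_to(m, diff.shape)

        def _mean(sel):
            return float(sel.mean()) if sel.size else float("nan")

        summary = {
            "mean_inside": _mean(diff[m]),
            "mean_outside": _mean(diff[~m]),
            "mean_abs_inside": _mean(np.abs(diff[m])),
            "mean_abs_outside": _mean(np.abs(diff[~m])),
        }
    return pred_before.with_data(diff), summary
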