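"""View-change (reslicing) operators for 4D volumes and 5D feature stacks.

Reslicing means reinterpreting a 4D single-channel block either as a time
series of z-stacks (XYZ-T view) or as a z-series of 2D+time movies (XYT-Z
view).  Every operator here is a pure, invertible index permutation or
reshape: no resampling, no interpolation, and the multiset of voxel values is
conserved exactly.

View tags are mandatory and checked at every operator boundary — the two
views are shape-compatible for square-ish blocks, so silent axis confusion is
the single biggest implementation hazard of the whole method.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from fluoro4d.io5d import View, ViewError, Volume4D

__all__ = [
    "FeatureStack5D",
    "reslice_volume",
    "split_frames",
    "assemble_stack",
    "reslice_features",
    "flatten_xy_zt",
    "unflatten_xy_zt",
]


@dataclass
class FeatureStack5D:
    """Assembled per-frame encoder outputs with an explicit view tag.

    ``data`` has axes ``(channels_f, X', Y', A, B)``.  For view XYZ_T,
    (A, B) = (Z, T); for XYT_Z, (A, B) = (T, Z).  The tag flips whenever the
    trailing axes are swapped; stacks of mismatched views must never be
    combined silently.
    """

    data: np.ndarray
    view: View

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"FeatureStack5D requires 5 axes, got {self.data.ndim}")
        self.view = View(self.view)

    @property
    def shape(self):
        return self.data.shape


def _flip(view: View) -> View:
    return View.XYT_Z if view is View.XYZ_T else View.XYZ_T


def reslice_volume(v: Volume4D) -> Volume4D:
    """Swap the trailing axes (Z <-> T) and flip the view tag.

    ``out[x, y, b, a] == in[x, y, a, b]`` voxel-exactly; applying the operator
    twice is the identity.
    """
    return replace(v, data=np.ascontiguousarray(np.swapaxes(v.data, 2, 3)), view=_flip(v.view))


def split_frames(v: Volume4D) -> list:
    """Split a 4D volume into its 3D blocks along the last axis.

    Element ``k`` of the result equals ``v.data[:, :, :, k]``; for an XYZ-T
    view volume these are the per-timepoint z-stacks.
    """
    return [np.ascontiguousarray(v.data[:, :, :, k]) for k in range(v.data.shape[3])]


def assemble_stack(frames, view) -> FeatureStack5D:
    """Stack per-frame 4D feature maps ``(C_f, X', Y', A)`` along a new axis B.

    Frames are stacked in list order; the given view tag is attached.

    Raises
    ------
    ValueError
        If the frames do not all share one shape.
    """
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("cannot assemble an empty frame list")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"ragged frame shapes: {sorted(shapes)}")
    if frames[0].ndim != 4:
        raise ValueError(f"frames must be 4-axis feature maps, got {frames[0].ndim} axes")
    return FeatureStack5D(np.stack(frames, axis=-1), View(view))


def reslice_features(f: FeatureStack5D) -> FeatureStack5D:
    """Reslice an XYT-Z feature stack into XYZ-T view (swap axes A and B).

    ``out[c, x, y, z, t] == in[c, x, y, t, z]``.  Only defined for XYT_Z
    input: the generator uses this exactly once, to bring the XYT-path stack
    into spatial/temporal registration with the XYZ-path stack.

    Raises
    ------
    ViewError
        If called on an XYZ_T stack (double application is a contract bug).
    """
    if f.view is not View.XYT_Z:
        raise ViewError(f"reslice_features requires an XYT_Z stack, got {f.view}")
    return FeatureStack5D(np.ascontiguousarray(np.swapaxes(f.data, 3, 4)), View.XYZ_T)


def flatten_xy_zt(v: Volume4D) -> np.ndarray:
    """Flatten an XYZ-T volume into a stack of Z*T 2D slices, z-fastest.

    Output slice index ``k = t * Z + z``, so each time point's z-stack is a
    contiguous run of slices.  This is the XY(ZxT) view consumed by the
    discriminator.  Inverse: :func:`unflatten_xy_zt`.
    """
    if v.view is not View.XYZ_T:
        raise ViewError(f"flatten_xy_zt requires an XYZ_T volume, got {v.view}")
    X, Y, Z, T = v.data.shape
    # (X,Y,Z,T) -> (X,Y,T,Z) -> (X,Y,T*Z) gives k = t*Z + z
    return np.ascontiguousarray(v.data.transpose(0, 1, 3, 2)).reshape(X, Y, T * Z)


def unflatten_xy_zt(flat: np.ndarray, z_len: int, template: Volume4D | None = None) -> Volume4D:
    """Invert :func:`flatten_xy_zt` given the Z extent."""
    X, Y, K = flat.shape
    if K % z_len:
        raise ValueError(f"flat slice count {K} not divisible by Z={z_len}")
    data = flat.reshape(X, Y, K // z_len, z_len).transpose(0, 1, 3, 2)
    data = np.ascontiguousarray(data)
    if template is not None:
        return replace(template, data=data, view=View.XYZ_T)
    return Volume4D(data, View.XYZ_T)
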