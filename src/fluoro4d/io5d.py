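"""5D fluorescence stack data model, OME-TIFF I/O, normalization and cropping.

The canonical in-memory axis order is ``(X, Y, Z, T, C)`` — the order in which
the domain usually speaks about a two-protein live-imaging stack.  On disk the
OME convention ``TZCYX`` is used, with an explicit declared mapping between the
two so that a write/read cycle is bit-exact for float32 data.

Calibration defaults correspond to a typical laser-scanning confocal setup for
live epithelial imaging: 0.124 um pixels, 0.5 um z-steps, 10 s between stacks.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: default physical calibration (um, um, s)
DEFAULT_PIXEL_SIZE_UM = 0.124
DEFAULT_Z_STEP_UM = 0.5
DEFAULT_T_INTERVAL_S = 10.0

_CANONICAL = "XYZTC"
#: on-disk OME axis order and its mapping to the canonical in-memory order
_DISK_AXES = "TZCYX"


class DegenerateInputError(ValueError):
    """Raised when an operation receives input with no usable dynamic range."""


class View(str, Enum):
    """Semantic tag for the trailing two axes of a 4D volume or feature stack.

    ``XYZ_T``: the block is a time series of z-stacks (axis 2 = Z, axis 3 = T).
    ``XYT_Z``: the block is a z-series of 2D+time movies (axis 2 = T, axis 3 = Z).
    """

    XYZ_T = "XYZ_T"
    XYT_Z = "XYT_Z"


class ViewError(ValueError):
    """Raised when an operator receives a volume in the wrong view."""


@dataclass
class Image5D:
    """A two-or-more channel spatiotemporal stack with physical calibration.

    ``data`` is ordered ``(X, Y, Z, T, C)`` with non-negative finite
    intensities; ``channel_names`` matches the C axis.
    """

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    t_interval_s: float = DEFAULT_T_INTERVAL_S
    channel_names: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"Image5D requires a 5-axis array, got {self.data.ndim} axes")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all axis lengths must be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[4])]
        if len(self.channel_names) != self.data.shape[4]:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries but C axis is {self.data.shape[4]}"
            )

    @property
    def shape(self):
        return self.data.shape

    def channel(self, c) -> "Volume4D":
        """Extract one channel as an XYZ-T view 4D volume."""
        if isinstance(c, str):
            c = self.channel_names.index(c)
        return Volume4D(
            data=self.data[..., c],
            view=View.XYZ_T,
            pixel_size_um=self.pixel_size_um,
            z_step_um=self.z_step_um,
            t_interval_s=self.t_interval_s,
        )


@dataclass
class Volume4D:
    """One channel's 4D block with an explicit view tag.

    For ``view == XYZ_T`` the axes are (X, Y, Z, T); for ``XYT_Z`` they are
    (X, Y, T, Z).  The tag is the ground truth for what the trailing axes mean
    and every reslicing operator checks it.
    """

    data: np.ndarray
    view: View = View.XYZ_T
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    t_interval_s: float = DEFAULT_T_INTERVAL_S

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D requires a 4-axis array, got {self.data.ndim} axes")
        self.view = View(self.view)

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data) -> "Volume4D":
        return replace(self, data=np.asarray(data))


@dataclass
class NormParams:
    """Affine normalization parameters; needed to invert :func:`normalize`."""

    lo_val: float
    hi_val: float
    lo_pct: float
    hi_pct: float


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _canonicalize(data: np.ndarray, axis_order: str) -> np.ndarray:
    """Permute/expand ``data`` from ``axis_order`` into canonical (X,Y,Z,T,C)."""
    axis_order = axis_order.upper()
    if len(axis_order) != data.ndim:
        raise ValueError(f"axis_order '{axis_order}' inconsistent with array rank {data.ndim}")
    if len(set(axis_order)) != len(axis_order) or not set(axis_order) <= set(_CANONICAL):
        raise ValueError(f"axis_order must be a permutation of a subset of {_CANONICAL!r}")
    # expand missing axes to length 1, then permute
    for ax in _CANONICAL:
        if ax not in axis_order:
            data = data[..., np.newaxis]
            axis_order += ax
    perm = [axis_order.index(ax) for ax in _CANONICAL]
    return np.transpose(data, perm)


def _parse_ome_calibration(ome_xml: str) -> dict:
    out = {}
    m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', ome_xml or "")
    if m:
        out["pixel_size_um"] = float(m.group(1))
    m = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', ome_xml or "")
    if m:
        out["z_step_um"] = float(m.group(1))
    m = re.search(r'TimeIncrement="([\d.eE+-]+)"', ome_xml or "")
    if m:
        out["t_interval_s"] = float(m.group(1))
    names = re.findall(r'<Channel[^>]*\bName="([^"]*)"', ome_xml or "")
    if names:
        out["channel_names"] = names
    return out


def read_stack(path, axis_order: str | None = None) -> Image5D:
    """Read a TIFF/OME-TIFF stack into canonical (X, Y, Z, T, C) order.

    Parameters
    ----------
    path : path-like
        TIFF or OME-TIFF file.  A sidecar ``<path>.yaml`` with calibration
        keys is honoured for plain TIFFs.
    axis_order : str, optional
        Names the axes of the stored array, e.g. ``"XYZ"`` for a 3-axis TIFF.
        When omitted, the axis metadata recorded in the file is used.

    Missing axes become length 1.  Calibration is read from OME metadata when
    present, otherwise defaults (0.124 um, 0.5 um, 10 s) are used with a
    logged warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes  # e.g. 'TZCYX'
        ome_xml = tf.ome_metadata

    if axis_order is None:
        # tifffile uses Q/S for unknown/sample axes; those cannot be mapped
        axis_order = file_axes.replace("S", "C").replace("Q", "")
        if len(axis_order) != data.ndim:
            raise ValueError(
                f"cannot infer axis order from file axes {file_axes!r}; pass axis_order explicitly"
            )

    data = _canonicalize(data, axis_order)

    cal = {}
    if ome_xml:
        cal = _parse_ome_calibration(ome_xml)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            cal.update(yaml.safe_load(fh) or {})
    if not cal:
        logger.warning(
            "%s: no calibration metadata found; using defaults (%.3f um, %.1f um, %.1f s)",
            path.name,
            DEFAULT_PIXEL_SIZE_UM,
            DEFAULT_Z_STEP_UM,
            DEFAULT_T_INTERVAL_S,
        )
    names = cal.pop("channel_names", None)
    img = Image5D(data=data, channel_names=list(names) if names else [], **cal)
    return img


def write_stack(img: Image5D, path) -> None:
    """Write an :class:`Image5D` as OME-TIFF (axes TZCYX) with calibration.

    ``read_stack`` inverts the write bit-exactly for float32 payloads.
    """
    path = Path(path)
    # canonical (X,Y,Z,T,C) -> disk TZCYX
    disk = np.transpose(img.data, (3, 2, 4, 1, 0))
    metadata = {
        "axes": _DISK_AXES,
        "PhysicalSizeX": img.pixel_size_um,
        "PhysicalSizeY": img.pixel_size_um,
        "PhysicalSizeZ": img.z_step_um,
        "TimeIncrement": img.t_interval_s,
        "Channel": {"Name": list(img.channel_names)},
    }
    tifffile.imwrite(path, disk, ome=True, metadata=metadata)


def write_volume(v: Volume4D, path, name: str = "ch0") -> None:
    """Write a single 4D volume (XYZ-T view) as a one-channel OME-TIFF."""
    if v.view is not View.XYZ_T:
        raise ViewError("write_volume expects an XYZ_T-view volume")
    img = Image5D(
        data=v.data[..., np.newaxis],
        pixel_size_um=v.pixel_size_um,
        z_step_um=v.z_step_um,
        t_interval_s=v.t_interval_s,
        channel_names=[name],
    )
    write_stack(img, path)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize(v: Volume4D, lo_pct: float = 0.5, hi_pct: float = 99.5):
    """Percentile-normalize a volume into [-1, 1].

    The ``lo_pct`` percentile maps to -1 and the ``hi_pct`` percentile to +1;
    values beyond are clipped.  Returns ``(normalized volume, NormParams)``
    where the parameters invert the affine map (see :func:`denormalize`).

    Raises
    ------
    DegenerateInputError
        If the two percentiles coincide (zero dynamic range).
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError(f"require 0 <= lo_pct < hi_pct <= 100, got ({lo_pct}, {hi_pct})")
    lo_val, hi_val = np.percentile(v.data, [lo_pct, hi_pct])
    if hi_val <= lo_val:
        raise DegenerateInputError(
            f"percentiles {lo_pct} and {hi_pct} coincide at {lo_val}; constant input?"
        )
    scaled = -1.0 + 2.0 * (v.data.astype(np.float64) - lo_val) / (hi_val - lo_val)
    out = np.clip(scaled, -1.0, 1.0).astype(np.float32)
    return v.with_data(out), NormParams(float(lo_val), float(hi_val), lo_pct, hi_pct)


def denormalize(v: Volume4D, params: NormParams) -> Volume4D:
    """Invert :func:`normalize` (exact for interior, un-clipped voxels)."""
    data = (v.data.astype(np.float64) + 1.0) / 2.0 * (params.hi_val - params.lo_val) + params.lo_val
    return v.with_data(data.astype(np.float32))


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------


def resize_xy(img: Image5D, xy_shape: tuple) -> Image5D:
    """Optional bilinear XY resize applied before cropping (off by default)."""
    from skimage.transform import resize as _resize

    X2, Y2 = xy_shape
    out = _resize(
        img.data,
        (X2, Y2) + img.data.shape[2:],
        order=1,
        preserve_range=True,
        anti_aliasing=True,
    ).astype(img.data.dtype)
    return replace(img, data=out)


def crop_samples(
    img: Image5D,
    patch_shape: tuple,
    stride: tuple,
    input_ch: int = 0,
    target_ch: int = 1,
):
    """Tile an image into (input, target) training pairs.

    Deterministic raster-order tiling over (x, y, z, t), x slowest.  Each pair
    is the input-channel patch and the target-channel patch at the same
    location, both tagged XYZ-T.

    Raises
    ------
    ValueError
        If the patch does not fit inside the image.
    """
    shape = img.data.shape[:4]
    if any(p > s for p, s in zip(patch_shape, shape)):
        raise ValueError(f"patch {patch_shape} larger than image extent {shape}")
    if any(s < 1 for s in stride):
        raise ValueError("stride entries must be >= 1")
    starts = [range(0, shape[i] - patch_shape[i] + 1, stride[i]) for i in range(4)]
    pairs = []
    for x0, y0, z0, t0 in itertools.product(*starts):
        sl = (
            slice(x0, x0 + patch_shape[0]),
            slice(y0, y0 + patch_shape[1]),
            slice(z0, z0 + patch_shape[2]),
            slice(t0, t0 + patch_shape[3]),
        )
        kw = dict(
            pixel_size_um=img.pixel_size_um,
            z_step_um=img.z_step_um,
            t_interval_s=img.t_interval_s,
        )
        pairs.append(
            (
                Volume4D(img.data[sl + (input_ch,)], View.XYZ_T, **kw),
                Volume4D(img.data[sl + (target_ch,)], View.XYZ_T, **kw),
            )
        )
    return pairs


def n_crops(shape: tuple, patch_shape: tuple, stride: tuple) -> int:
    """Closed-form count of tiles produced by :func:`crop_samples`."""
    return int(
        np.prod([(shape[i] - patch_shape[i]) // stride[i] + 1 for i in range(4)])
    )
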