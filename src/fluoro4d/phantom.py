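"""Synthetic epithelial-tissue phantoms with known latent geometry.

The phantom emulates the statistical structure of live confocal imaging of a
contracting epithelial sheet: a jittered-grid Voronoi tessellation of cells,
a randomly chosen fraction of which "activate" (rising logistic activation
a_c(t)) and contract their apical area; a membrane channel (E-Cad-like:
uniform low-intensity cell outlines plus high-intensity junctional clusters);
a contractility channel (Myo-like: diffuse cytoplasmic floor, bright medial
network scaling with activation, weak junctional lining); and a puncta
channel (Jub-like: spots on a subset of the membrane clusters, scaled by
local activation).  Signal decays exponentially toward deeper z-slices
(apical concentration), and Poisson shot noise plus Gaussian read noise are
applied last.  Everything is deterministic given the seed, and the latent
geometry (polygons, activations, areas, cluster points) is returned so that
segmentation, tracking and quantification have brute-force oracles.

The geometry engine is a Voronoi-with-contraction model, not a physical
vertex model: cell polygons share vertices, activated cells pull their
vertices toward their centroid, and shared vertices keep the tessellation
gap-free at every frame.  This preserves the correlations the downstream
analyses exploit (activation <-> shrinkage <-> medial intensity <->
junctional clusters) with simple, inspectable code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter, maximum_filter
from scipy.spatial import Voronoi
from skimage.draw import polygon as draw_polygon

from fluoro4d.io5d import View, Volume4D

__all__ = ["PhantomConfig", "TissueGeometry", "sample_geometry", "render_channel", "make_dataset", "noise_floor"]

_KINDS = ("ecad", "myo", "jub")

# per-channel rendering gains (arbitrary fluorescence units); membrane floor
# deliberately low relative to clusters, mirroring inactive vs active pools
_ECAD_BASE = 0.02
_ECAD_MEMBRANE = 0.18
_ECAD_CLUSTER = 1.0
_MYO_FLOOR = 0.06
_MYO_MEDIAL = 0.9
_MYO_JUNCTIONAL = 0.25
_JUB_BASE = 0.03
_JUB_PUNCTA = 1.0


@dataclass
class PhantomConfig:
    """Study conditions for one phantom movie.

    Defaults model a small desk-scale field of view: 64x64 px, 8 z-slices,
    6 frames at 10 s spacing, 25 cells of which 40% activate and contract by
    ~6% of the vertex-to-centroid distance per frame at full activation.
    ``noise`` is (poisson_scale, read_sigma); poisson_scale is the expected
    photon count at unit intensity (0 disables shot noise).
    """

    grid: tuple = (64, 64, 8, 6)  # (X, Y, Z, T)
    n_cells: int = 25
    activation_fraction: float = 0.4
    shrink_rate: float = 0.06
    membrane_width_px: float = 1.5
    cluster_rate: float = 0.25  # expected clusters per px of edge length
    jub_subset_fraction: float = 0.5
    z_decay: float = 0.25  # per z-slice
    noise: tuple = (50.0, 0.01)
    seed: int = 0

    def __post_init__(self):
        for name in ("activation_fraction", "jub_subset_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.shrink_rate < 0:
            raise ValueError("shrink_rate must be >= 0")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")


@dataclass
class TissueGeometry:
    """Latent phantom state: the ground truth for all quantification oracles."""

    grid: tuple
    polygons: list  # per-cell vertex index loop (topology fixed over time)
    vertices_t: np.ndarray  # (T, n_vertices, 2) float coordinates
    activations: np.ndarray  # (n_cells, T) in [0, 1]
    activated: np.ndarray  # (n_cells,) bool
    areas: np.ndarray = field(default=None)  # (n_cells, T), filled in __post_init__
    cluster_edges: np.ndarray = field(default=None)  # (n_pts, 2) vertex index pairs
    cluster_frac: np.ndarray = field(default=None)  # (n_pts,) position along edge
    cluster_gain: np.ndarray = field(default=None)  # (n_pts,) intensity factors
    cluster_cells: list = field(default=None)  # per point: incident cell ids
    jub_idx: np.ndarray = field(default=None)  # indices into the cluster arrays

    @property
    def n_cells(self) -> int:
        return len(self.polygons)

    @property
    def n_frames(self) -> int:
        return self.vertices_t.shape[0]

    def polygon_coords(self, c: int, t: int) -> np.ndarray:
        return self.vertices_t[t][self.polygons[c]]

    def centroid(self, c: int, t: int) -> np.ndarray:
        return self.polygon_coords(c, t).mean(axis=0)

    def cluster_points(self, t: int) -> np.ndarray:
        """Cluster point coordinates at frame t (they ride on their edge)."""
        if self.cluster_edges is None or len(self.cluster_edges) == 0:
            return np.zeros((0, 2))
        V = self.vertices_t[t]
        a = V[self.cluster_edges[:, 0]]
        b = V[self.cluster_edges[:, 1]]
        s = self.cluster_frac[:, None]
        return (1 - s) * a + s * b

    def label_image(self, t: int) -> np.ndarray:
        """Rasterized ground-truth cell labels (1..n_cells; full tessellation)."""
        X, Y = self.grid[:2]
        lab = np.zeros((X, Y), dtype=np.int32)
        for c in range(self.n_cells):
            poly = self.polygon_coords(c, t)
            rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=(X, Y))
            lab[rr, cc] = c + 1
        if (lab == 0).any():
            # assign leftover boundary pixels to the nearest labelled pixel
            _, (ir, ic) = distance_transform_edt(lab == 0, return_indices=True)
            lab = lab[ir, ic]
        return lab

    def activation_map(self, t: int) -> np.ndarray:
        """Per-pixel activation of the owning cell at frame t."""
        lab = self.label_image(t)
        return self.activations[:, t][lab - 1]


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _jittered_seeds(rng, X, Y, n_cells):
    m = int(np.ceil(np.sqrt(n_cells)))
    sx, sy = X / m, Y / m
    cells = rng.permutation(m * m)[:n_cells]
    pts = []
    for k in cells:
        i, j = divmod(int(k), m)
        pts.append(
            [
                (i + 0.5) * sx + rng.uniform(-0.35, 0.35) * sx,
                (j + 0.5) * sy + rng.uniform(-0.35, 0.35) * sy,
            ]
        )
    return np.array(pts)


def _bounded_voronoi(points, X, Y):
    """Voronoi regions of ``points`` clipped to [0,X]x[0,Y] via mirroring.

    Reflecting the seeds across all four box edges makes every inner region
    finite with edges lying exactly on the box boundary, and neighbouring
    inner regions share vertex indices, which is what lets the contraction
    step preserve the tessellation.
    """
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, X), (1, 0.0), (1, Y)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    n = len(points)
    polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("degenerate tessellation")
        poly = list(region)
        # enforce counter-clockwise orientation
        coords = vor.vertices[poly]
        x, y = coords[:, 0], coords[:, 1]
        if np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)) < 0:
            poly = poly[::-1]
        polys.append(poly)
    used = sorted({v for p in polys for v in p})
    remap = {v: k for k, v in enumerate(used)}
    V = vor.vertices[used].copy()
    V[:, 0] = np.clip(V[:, 0], 0.0, X)
    V[:, 1] = np.clip(V[:, 1], 0.0, Y)
    polys = [[remap[v] for v in p] for p in polys]
    return V, polys


def sample_geometry(cfg: PhantomConfig) -> TissueGeometry:
    """Draw a seeded tissue geometry: tessellation, activations, trajectories.

    A fraction ``activation_fraction`` of cells receives a rising logistic
    activation; their polygon vertices move toward the cell centroid by
    ``shrink_rate * a_c(t)`` per frame (shared vertices average the pull of
    all incident activated cells, so the tiling is preserved).  Vertices on
    the domain boundary stay pinned.  Degenerate tessellations (collinear
    seeds) are re-seeded internally.
    """
    X, Y, Z, T = cfg.grid
    rng = np.random.default_rng(cfg.seed)

    for attempt in range(10):
        try:
            seeds = _jittered_seeds(rng, X, Y, cfg.n_cells)
            V0, polys = _bounded_voronoi(seeds, X, Y)
            break
        except (RuntimeError, Exception) as exc:  # qhull failures included
            if attempt == 9:
                raise RuntimeError(f"could not build a valid tessellation: {exc}")
            continue

    n = cfg.n_cells
    n_act = int(round(cfg.activation_fraction * n))
    activated = np.zeros(n, dtype=bool)
    activated[rng.permutation(n)[:n_act]] = True

    # rising logistic activation with onset before the movie starts: cells
    # are already largely activated when imaging begins and keep rising,
    # mirroring a movie taken during (not before) apical constriction
    t_axis = np.arange(T, dtype=float)
    tau = max(T / 5.0, 0.8)
    a = 1.0 / (1.0 + np.exp(-(t_axis + 0.75 * T) / tau))
    activations = np.where(activated[:, None], a[None, :], 0.0)

    # shift by half a pixel so the domain [-0.5, X-0.5] coincides with the
    # coverage of pixel centers 0..X-1: rasterized cell areas then agree
    # with the continuous (shoelace) areas without a boundary half-pixel band
    V0 = V0 - 0.5

    # boundary vertices may slide along their border but not leave it
    eps = 1e-9
    on_x = (V0[:, 0] < -0.5 + eps) | (V0[:, 0] > X - 0.5 - eps)
    on_y = (V0[:, 1] < -0.5 + eps) | (V0[:, 1] > Y - 0.5 - eps)

    vertices_t = np.empty((T, len(V0), 2))
    vertices_t[0] = V0
    for t in range(1, T):
        V = vertices_t[t - 1].copy()
        disp = np.zeros_like(V)
        count = np.zeros(len(V))
        for c in np.nonzero(activated)[0]:
            idx = polys[c]
            cen = V[idx].mean(axis=0)
            pull = cfg.shrink_rate * activations[c, t]
            disp[idx] += pull * (cen - V[idx])
            count[idx] += 1
        move = np.divide(disp, np.maximum(count, 1)[:, None])
        move[on_x, 0] = 0.0
        move[on_y, 1] = 0.0
        vertices_t[t] = V + move

    areas = np.empty((n, T))
    for t in range(T):
        for c in range(n):
            areas[c, t] = _shoelace(vertices_t[t][polys[c]])

    # junctional clusters: Poisson count per shared edge, positions uniform
    edge_map = {}
    for c, p in enumerate(polys):
        for k in range(len(p)):
            e = tuple(sorted((p[k], p[(k + 1) % len(p)])))
            edge_map.setdefault(e, []).append(c)
    c_edges, c_frac, c_gain, c_cells = [], [], [], []
    for e, cells in sorted(edge_map.items()):
        length = np.linalg.norm(V0[e[0]] - V0[e[1]])
        k = rng.poisson(cfg.cluster_rate * length)
        for _ in range(k):
            c_edges.append(e)
            c_frac.append(rng.uniform(0.1, 0.9))
            c_gain.append(rng.uniform(0.7, 1.3))
            c_cells.append(list(cells))
    c_edges = np.array(c_edges, dtype=int).reshape(-1, 2)
    n_pts = len(c_edges)
    n_jub = int(round(cfg.jub_subset_fraction * n_pts))
    jub_idx = np.sort(rng.permutation(n_pts)[:n_jub])

    return TissueGeometry(
        grid=cfg.grid,
        polygons=polys,
        vertices_t=vertices_t,
        activations=activations,
        activated=activated,
        areas=areas,
        cluster_edges=c_edges,
        cluster_frac=np.array(c_frac),
        cluster_gain=np.array(c_gain),
        cluster_cells=c_cells,
        jub_idx=jub_idx,
    )


def _membrane_profile(geom: TissueGeometry, t: int, sigma: float) -> np.ndarray:
    """Gaussian-profile membrane image: exp(-d^2 / 2 sigma^2) to nearest edge.

    Distances are exact point-to-segment distances (subpixel), so the
    membrane ridge crest lies on the true polygon edge rather than on a
    rasterized approximation of it.
    """
    X, Y = geom.grid[:2]
    V = geom.vertices_t[t]
    edges = []
    drawn = set()
    for p in geom.polygons:
        for k in range(len(p)):
            e = tuple(sorted((p[k], p[(k + 1) % len(p)])))
            if e not in drawn:
                drawn.add(e)
                edges.append(e)
    a = V[[e[0] for e in edges]]  # (E, 2)
    b = V[[e[1] for e in edges]]
    gx, gy = np.meshgrid(np.arange(X, dtype=float), np.arange(Y, dtype=float), indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)  # (N, 2)
    ab = b - a
    denom = np.maximum((ab * ab).sum(axis=1), 1e-12)
    d2_min = np.full(len(pts), np.inf)
    for k in range(len(edges)):  # edge count is small; pixels vectorized
        ap = pts - a[k]
        s = np.clip(ap @ ab[k] / denom[k], 0.0, 1.0)
        closest = a[k] + s[:, None] * ab[k]
        d2 = ((pts - closest) ** 2).sum(axis=1)
        np.minimum(d2_min, d2, out=d2_min)
    return np.exp(-d2_min / (2.0 * sigma * sigma)).reshape(X, Y)


def _puncta_image(shape, points, gains, sigma=1.0) -> np.ndarray:
    img = np.zeros(shape)
    if len(points):
        ix = np.clip(np.round(points[:, 0]).astype(int), 0, shape[0] - 1)
        iy = np.clip(np.round(points[:, 1]).astype(int), 0, shape[1] - 1)
        np.add.at(img, (ix, iy), gains)
        img = gaussian_filter(img, sigma) * (2.0 * np.pi * sigma * sigma)
    return img


def render_channel(geom: TissueGeometry, kind: str, cfg: PhantomConfig, noise_seed: int | None = None) -> Volume4D:
    """Render one fluorescence channel of the phantom as an XYZ-T volume.

    All structural signal is modulated by ``exp(-z_decay * z)`` (apical
    concentration); Poisson shot noise and Gaussian read noise are applied
    last.  Structure and noise seeds both derive from ``cfg.seed`` and the
    channel kind, so repeated renders are identical; pass ``noise_seed`` to
    draw a second noise realization of the same structure (noise-floor
    estimation).
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    X, Y, Z, T = cfg.grid
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _KINDS.index(kind), 7]))
    noise_rng = (
        rng if noise_seed is None else np.random.default_rng(np.random.SeedSequence([noise_seed, _KINDS.index(kind), 11]))
    )
    vol = np.empty((X, Y, Z, T), dtype=np.float32)

    # static medial texture (per-sample, not per-frame: structures persist)
    texture = gaussian_filter(rng.random((X, Y)), 3.0)
    lo, hi = texture.min(), texture.max()
    texture = 0.4 + 0.7 * (texture - lo) / max(hi - lo, 1e-12)

    z_gain = np.exp(-cfg.z_decay * np.arange(Z))
    for t in range(T):
        prof = _membrane_profile(geom, t, cfg.membrane_width_px)
        a_map = geom.activation_map(t)
        a_mem = maximum_filter(a_map, size=3)
        if kind == "ecad":
            pts = geom.cluster_points(t)
            img = (
                _ECAD_BASE
                + _ECAD_MEMBRANE * prof
                + _ECAD_CLUSTER * _puncta_image((X, Y), pts, geom.cluster_gain)
            )
        elif kind == "myo":
            medial_w = 1.0 - np.exp(
                -(distance_transform_edt(prof < 0.5) ** 2) / (2.0 * (2 * cfg.membrane_width_px) ** 2)
            )
            # medial brightness rises with contraction: the same contractile
            # material concentrates as the apical area shrinks (quadratic in
            # the concentration, capped to avoid rasterization blow-ups)
            lab = geom.label_image(t)
            conc = np.clip(geom.areas[:, 0] / np.maximum(geom.areas[:, t], 1e-9), 0.0, 2.0) ** 2
            conc_map = np.where(geom.activated[lab - 1], conc[lab - 1], 1.0)
            img = (
                _MYO_FLOOR
                + _MYO_MEDIAL * a_map * conc_map * medial_w * texture
                + _MYO_JUNCTIONAL * prof * a_mem
            )
        else:  # jub
            pts = geom.cluster_points(t)[geom.jub_idx]
            act = np.array(
                [geom.activations[cells, t].mean() for cells in (geom.cluster_cells[j] for j in geom.jub_idx)]
            )
            gains = geom.cluster_gain[geom.jub_idx] * (0.3 + 0.7 * act) if len(pts) else np.zeros(0)
            img = _JUB_BASE + _JUB_PUNCTA * _puncta_image((X, Y), pts, gains)
        vol[:, :, :, t] = img[:, :, None] * z_gain[None, None, :]

    poisson_scale, read_sigma = cfg.noise
    if poisson_scale and poisson_scale > 0:
        vol = noise_rng.poisson(np.clip(vol, 0, None) * poisson_scale).astype(np.float32) / poisson_scale
    if read_sigma and read_sigma > 0:
        vol = vol + noise_rng.normal(0.0, read_sigma, size=vol.shape).astype(np.float32)
    return Volume4D(np.clip(vol, 0, None), View.XYZ_T)


def make_dataset(cfg: PhantomConfig, n_samples: int, input_kind: str, target_kind: str):
    """Render ``n_samples`` independent phantoms as (input, target) pairs.

    Per-sample seeds are derived from ``cfg.seed`` so the dataset is
    reproducible and samples are mutually independent.  Returns
    ``(pairs, geometries)``; the geometries are the oracles for tests.
    """
    if input_kind == target_kind:
        raise ValueError("input and target kinds must differ")
    pairs, geoms = [], []
    for i in range(n_samples):
        sub = int(np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31 - 1))
        c = replace(cfg, seed=sub)
        geom = sample_geometry(c)
        pairs.append((render_channel(geom, input_kind, c), render_channel(geom, target_kind, c)))
        geoms.append(geom)
    return pairs, geoms


def noise_floor(cfg: PhantomConfig, kind: str = "ecad") -> float:
    """Mean |difference| between two noise realizations of one geometry.

    The input->target map is deterministic given the geometry, so this is a
    lower bound on the L1 a learned predictor can reach on raw intensities.
    """
    geom = sample_geometry(cfg)
    a = render_channel(geom, kind, cfg).data
    b = render_channel(geom, kind, cfg, noise_seed=cfg.seed + 1).data
    return float(np.mean(np.abs(a - b)))
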