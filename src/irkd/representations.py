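"""Time-series windows -> image representations (GAF and PI).

Two image encodings feed the 2-D teachers:

*Gramian angular field* (GAF): the window is min-max rescaled to [-1, 1],
each value mapped to a polar angle ``phi_t = arccos(x_t)``, and the image
is ``cos(phi_i + phi_j)`` (GASF, symmetric, diagonal ``2 x_i^2 - 1``) or
``sin(phi_i - phi_j)`` (GADF, anti-symmetric, zero diagonal).  The series
is linearly resampled to the target resolution before forming the matrix,
so a length-500 window becomes e.g. a 64 x 64 image directly.

*Persistence image* (PI): the window is delay-embedded into a point cloud,
its Rips persistence diagram computed, each (birth, death) point moved to
(birth, persistence) coordinates, and a persistence-weighted Gaussian
surface rasterized on a fixed grid, normalized by its maximum.

Both paths operate per input channel and stack channels, so a 3-channel
window yields a 3 x H x W image.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .homology import PersistenceDiagram, rips_persistence

__all__ = [
    "PIConfig",
    "GafMatrix",
    "IRImage",
    "rescale_unit",
    "gaf",
    "downsample_series",
    "sliding_window_embed",
    "farthest_point_subsample",
    "compute_pd",
    "pd_to_pi",
    "window_to_image",
    "windows_to_images",
]


@dataclass(frozen=True)
class PIConfig:
    """Persistence-image rasterization parameters.

    ``grid_range`` bounds both the birth and the persistence axis;
    ``sigma`` is the Gaussian bandwidth in the same units as the filtration
    scale; ``weight`` is 'persistence' (linear ramp, zero at zero
    persistence) or 'constant'.
    """

    grid_range: tuple = (-10.0, 10.0)
    sigma: float = 0.25
    resolution: int = 64
    weight: str = "persistence"
    homology_dim: int = 1
    embed_dim: int = 3
    embed_delay: int = 2
    max_points: int = 64

    def __post_init__(self):
        lo, hi = self.grid_range
        if not lo < hi:
            raise ValueError("grid_range must satisfy low < high")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if self.weight not in ("persistence", "constant"):
            raise ValueError("weight must be 'persistence' or 'constant'")


@dataclass
class GafMatrix:
    values: np.ndarray
    variant: str  # "gasf" | "gadf"


@dataclass
class IRImage:
    """C x H x W image stack; ``channel_map[i]`` is the source channel of
    image channel i."""

    pixels: np.ndarray
    kind: str  # "gaf" | "pi"
    channel_map: tuple


def rescale_unit(series: np.ndarray) -> np.ndarray:
    """Affine map sending min -> -1 and max -> +1; a constant series maps
    to all zeros (angle pi/2)."""
    series = np.asarray(series, dtype=float)
    lo, hi = series.min(), series.max()
    if hi == lo:
        return np.zeros_like(series)
    return 2.0 * (series - lo) / (hi - lo) - 1.0


def gaf(series: np.ndarray, variant: str = "gasf", tol: float = 1e-9) -> GafMatrix:
    """Gramian angular field of a series already in [-1, 1].

    GASF[i, j] = cos(phi_i + phi_j), GADF[i, j] = sin(phi_i - phi_j) with
    phi = arccos(x).  Values outside [-1-tol, 1+tol] raise; values within
    tolerance are clipped.
    """
    x = np.asarray(series, dtype=float)
    if np.abs(x).max(initial=0.0) > 1.0 + tol:
        raise ValueError("series must lie in [-1, 1] (after rescale_unit)")
    phi = np.arccos(np.clip(x, -1.0, 1.0))
    variant = variant.lower()
    if variant == "gasf":
        values = np.cos(phi[:, None] + phi[None, :])
    elif variant == "gadf":
        values = np.sin(phi[:, None] - phi[None, :])
    else:
        raise ValueError("variant must be 'gasf' or 'gadf'")
    return GafMatrix(values, variant)


def downsample_series(series: np.ndarray, n_target: int) -> np.ndarray:
    """Linear interpolation onto ``n_target`` uniform points spanning the
    original index range."""
    series = np.asarray(series, dtype=float)
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    n = len(series)
    if n_target == n:
        return series.copy()
    return np.interp(np.linspace(0, n - 1, n_target), np.arange(n), series)


def sliding_window_embed(series: np.ndarray, dim: int = 3, delay: int = 2) -> np.ndarray:
    """Delay embedding: point p = (x_p, x_{p+d}, ..., x_{p+(m-1)d}),
    yielding T - (m-1)d points in R^m."""
    series = np.asarray(series, dtype=float)
    T = len(series)
    span = (dim - 1) * delay
    if T < span + 1:
        raise ValueError(
            f"series length {T} too short for dim={dim}, delay={delay}; "
            f"need at least {span + 1}"
        )
    P = T - span
    idx = np.arange(P)[:, None] + delay * np.arange(dim)[None, :]
    return series[idx]


def farthest_point_subsample(cloud: np.ndarray, n_max: int) -> np.ndarray:
    """Greedy max-min (farthest-point) subsampling, seeded at point 0;
    deterministic, preserves the cloud's coarse geometry."""
    cloud = np.asarray(cloud, dtype=float)
    if len(cloud) <= n_max:
        return cloud
    chosen = [0]
    dist = np.linalg.norm(cloud - cloud[0], axis=1)
    for _ in range(n_max - 1):
        nxt = int(dist.argmax())
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(cloud - cloud[nxt], axis=1))
    return cloud[np.sort(chosen)]


def compute_pd(cloud: np.ndarray, max_dim: int = 1) -> PersistenceDiagram:
    """Rips persistence of a point cloud via the built-in backend."""
    cloud = np.atleast_2d(np.asarray(cloud, dtype=float))
    if len(cloud) < 1:
        raise ValueError("point cloud must contain at least one point")
    try:
        return rips_persistence(cloud, max_dim=max_dim)
    except Exception as exc:  # surface input summary with backend failures
        raise RuntimeError(
            f"persistence computation failed on cloud of shape {cloud.shape} "
            f"(range [{cloud.min():.3g}, {cloud.max():.3g}])"
        ) from exc


def pd_to_pi(pd: PersistenceDiagram, cfg: PIConfig) -> IRImage:
    """Rasterize one homology dimension of a diagram into a persistence
    image.

    Finite points are moved to (birth, persistence) coordinates; essential
    (infinite-death) classes carry no finite persistence and are dropped.
    Pixel (i, j) holds the weighted Gaussian sum evaluated at the cell
    center, with row i indexing the persistence axis bottom-up and column j
    the birth axis left-right; the image is normalized by its maximum
    (an empty diagram stays all zero).
    """
    pts = pd.finite(cfg.homology_dim)
    res = cfg.resolution
    img = np.zeros((res, res))
    if len(pts):
        birth = pts[:, 0]
        pers = pts[:, 1] - pts[:, 0]
        if cfg.weight == "persistence":
            wmax = pers.max()
            w = pers / wmax if wmax > 0 else np.zeros_like(pers)
        else:
            w = np.ones_like(pers)
        lo, hi = cfg.grid_range
        centers = lo + (np.arange(res) + 0.5) * (hi - lo) / res
        gb = np.exp(-((centers[None, :] - birth[:, None]) ** 2) / (2 * cfg.sigma**2))
        gp = np.exp(-((centers[None, :] - pers[:, None]) ** 2) / (2 * cfg.sigma**2))
        norm = 1.0 / (2 * np.pi * cfg.sigma**2)
        # sum_p w_p * gp_p(row) * gb_p(col)
        img = norm * np.einsum("p,pi,pj->ij", w, gp, gb)
        m = img.max()
        if m > 0:
            img = img / m
    # kept in float64: the raster is an analysis artifact first (the
    # training stack casts whole batches to float32 downstream)
    return IRImage(img[None, :, :], "pi", (0,))


def _gaf_channel(channel: np.ndarray, resolution: int, variant: str,
                 resize_mode: str) -> np.ndarray:
    if resize_mode == "series":
        x = rescale_unit(downsample_series(channel, resolution))
        return gaf(x, variant).values
    # image-resize mode: full-length GAF then bilinear resize
    x = rescale_unit(channel)
    full = gaf(x, variant).values
    return _bilinear_resize(full, resolution)


def _bilinear_resize(img: np.ndarray, res: int) -> np.ndarray:
    n = img.shape[0]
    grid = np.linspace(0, n - 1, res)
    i0 = np.clip(np.floor(grid).astype(int), 0, n - 2)
    f = grid - i0
    rows = img[i0] * (1 - f)[:, None] + img[i0 + 1] * f[:, None]
    cols = rows[:, i0] * (1 - f)[None, :] + rows[:, i0 + 1] * f[None, :]
    return cols


def window_to_image(
    window: np.ndarray,
    kind: str = "gaf",
    cfg: PIConfig | None = None,
    *,
    variant: str = "gasf",
    resolution: int | None = None,
    gaf_resize: str = "series",
) -> IRImage:
    """Convert one [channels x length] window to a [channels x H x W]
    image representation.

    GAF path per channel: rescale to [-1, 1], resample to the target
    resolution, form the Gramian matrix.  PI path per channel: delay-embed,
    farthest-point subsample, Rips persistence, rasterize.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    kind = kind.lower()
    cfg = cfg if cfg is not None else PIConfig()
    res = resolution if resolution is not None else cfg.resolution
    channels = []
    if kind == "gaf":
        for ch in window:
            channels.append(_gaf_channel(ch, res, variant, gaf_resize))
    elif kind == "pi":
        cfg_r = replace(cfg, resolution=res)
        for ch in window:
            cloud = sliding_window_embed(ch, cfg.embed_dim, cfg.embed_delay)
            cloud = farthest_point_subsample(cloud, cfg.max_points)
            pd = compute_pd(cloud, max_dim=cfg.homology_dim)
            channels.append(pd_to_pi(pd, cfg_r).pixels[0])
    else:
        raise ValueError("kind must be 'gaf' or 'pi'")
    pixels = np.stack(channels).astype(np.float32)
    return IRImage(pixels, kind, tuple(range(window.shape[0])))


def windows_to_images(
    windows: np.ndarray,
    kind: str = "gaf",
    cfg: PIConfig | None = None,
    *,
    variant: str = "gasf",
    resolution: int | None = None,
    cache: dict | None = None,
) -> np.ndarray:
    """Batch conversion of [N x channels x length] -> [N x channels x H x W],
    preserving order.  ``cache`` (window bytes -> pixels) avoids recomputing
    PIs for repeated windows."""
    out = []
    for w in windows:
        if cache is not None:
            key = (kind, w.tobytes())
            if key in cache:
                out.append(cache[key])
                continue
        img = window_to_image(w, kind, cfg, variant=variant, resolution=resolution)
        if cache is not None:
            cache[key] = img.pixels
        out.append(img.pixels)
    return np.stack(out)
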