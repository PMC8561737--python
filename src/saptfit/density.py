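"""Density simulation and map/model density descriptors.

A model's density is simulated as a sum of isotropic atomic Gaussians with
a resolution-dependent width ``sigma = resolution / (pi * sqrt(2))`` and
mass proportional to atomic number, so the integrated density of a map is
proportional to the total atomic number of the model. Radial profiles are
spherical averages over Fibonacci-sphere sample points, the rotation-
invariant fingerprint used by the spherically averaged translation search.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .structures_io import AtomicModel, DensityMap

__all__ = [
    "RadialProfile",
    "simulate_density",
    "radial_profile",
    "real_space_cc",
    "compute_d99",
    "lowpass_filter",
    "atom_sigma",
    "fibonacci_sphere",
    "local_mask",
    "resample_onto",
]


def atom_sigma(resolution: float) -> float:
    """Gaussian width (Å) used for an atom at the given resolution."""
    return resolution / (math.pi * math.sqrt(2.0))


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclasses.dataclass
class RadialProfile:
    shell_radii: np.ndarray  # Å, strictly increasing midpoints
    values: np.ndarray  # mean density per shell
    center: np.ndarray  # Å
    radius: float  # Å, outermost extent

    def __post_init__(self) -> None:
        self.shell_radii = np.asarray(self.shell_radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.shell_radii) != len(self.values):
            raise ValueError("shell_radii and values length mismatch")
        if np.any(np.diff(self.shell_radii) <= 0):
            raise ValueError("shell radii must be strictly increasing")
        self.center = np.asarray(self.center, dtype=float).reshape(3)


def simulate_density(
    model: AtomicModel,
    resolution: float,
    grid: DensityMap | None = None,
    voxel_size: float | None = None,
    pad: float | None = None,
) -> DensityMap:
    """Simulate a density map from a model at the given nominal resolution.

    Each atom contributes a normalized 3D Gaussian of integral equal to its
    atomic number. With ``grid=None`` an axis-aligned grid is built around
    the model (voxel ``resolution / 3`` unless given, padding ``pad`` Å,
    default one resolution unit plus the Gaussian support).

    Raises a bounds error when the model falls outside an explicit grid.
    """
    sigma = atom_sigma(resolution)
    xyz = model.coordinates()
    if xyz.shape[0] == 0:
        raise ValueError("model has no atoms")
    weights = model.atomic_numbers()
    if grid is not None:
        out = np.zeros(grid.shape, dtype=np.float64)
        voxel = grid.voxel_size
        origin = grid.origin
        lo, hi = grid.world_extent()
        if np.any(xyz < lo - 2 * sigma - 1e-6) or np.any(xyz > hi + 2 * sigma + 1e-6):
            raise ValueError("model extends outside the requested grid")
    else:
        v = float(voxel_size) if voxel_size is not None else resolution / 3.0
        if resolution < 2.0 * v:
            raise ValueError(
                f"resolution {resolution} below Nyquist for voxel {v}"
            )
        margin = (pad if pad is not None else resolution) + 4.0 * sigma
        lo = xyz.min(axis=0) - margin
        hi = xyz.max(axis=0) + margin
        shape = np.maximum(np.ceil((hi - lo) / v).astype(int) + 1, 2)
        out = np.zeros(tuple(shape), dtype=np.float64)
        voxel = np.full(3, v)
        origin = lo
    _splat_gaussians(out, xyz, weights, sigma, voxel, origin)
    return DensityMap(out, voxel, origin, nominal_resolution=resolution)


def _splat_gaussians(
    out: np.ndarray,
    xyz: np.ndarray,
    weights: np.ndarray,
    sigma: float,
    voxel: np.ndarray,
    origin: np.ndarray,
    cutoff_sigmas: float = 4.0,
) -> None:
    """Accumulate normalized Gaussians onto ``out`` in place."""
    frac = (xyz - origin) / voxel  # fractional voxel coords, (n, 3)
    hw = np.ceil(cutoff_sigmas * sigma / voxel).astype(int)  # half-window (3,)
    offs = np.stack(
        np.meshgrid(
            *(np.arange(-h, h + 1) for h in hw), indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma**3)
    shape = np.array(out.shape)
    flat = out.ravel()
    # chunk atoms to bound the (n_atoms, n_window, 3) intermediate
    chunk = max(1, int(2e7 // max(offs.shape[0], 1)))
    for s in range(0, frac.shape[0], chunk):
        f = frac[s : s + chunk]
        w = weights[s : s + chunk]
        base = np.round(f).astype(int)
        idx = base[:, None, :] + offs[None, :, :]  # (n, m, 3)
        delta = (idx - f[:, None, :]) * voxel
        vals = (
            w[:, None]
            * norm
            * np.exp(-0.5 * (delta**2).sum(axis=-1) / sigma**2)
        )
        ok = np.all((idx >= 0) & (idx < shape), axis=-1)
        lin = (
            idx[..., 0] * shape[1] * shape[2]
            + idx[..., 1] * shape[2]
            + idx[..., 2]
        )
        np.add.at(flat, lin[ok], vals[ok])


def radial_profile(
    density_map: DensityMap,
    center: np.ndarray,
    radius: float,
    n_shells: int | None = None,
    points_per_shell: int | None = None,
) -> RadialProfile:
    """Spherically averaged density about a point.

    Shell ``k`` is the mean of trilinearly interpolated density over
    Fibonacci-sphere sample points at the shell's mid-radius; sample points
    outside the grid are excluded from the mean. ``n_shells`` defaults to
    ``ceil(radius / voxel)``.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    vmean = float(density_map.voxel_size.mean())
    if n_shells is None:
        n_shells = max(2, int(math.ceil(radius / vmean)))
    if n_shells < 2:
        raise ValueError("n_shells must be >= 2")
    ci = density_map.world_to_index(center)
    if np.any(ci < -0.5) or np.any(ci > np.array(density_map.shape) - 0.5):
        raise ValueError("profile center lies outside the grid")
    radii = shell_radii(radius, n_shells)
    values = np.empty(n_shells)
    arr = density_map.data.astype(float)
    for k, r in enumerate(radii):
        pts = center + r * fibonacci_sphere(
            points_per_shell or _shell_points(r, vmean)
        )
        idx = density_map.world_to_index(pts).T
        sampled = map_coordinates(
            arr, idx, order=1, mode="constant", cval=np.nan
        )
        good = np.isfinite(sampled)
        if not good.any():
            raise ValueError(f"shell {k} (r={r:.2f} Å) lies entirely off-grid")
        values[k] = sampled[good].mean()
    return RadialProfile(radii, values, center, radius)


def shell_radii(radius: float, n_shells: int) -> np.ndarray:
    """Mid-radii of ``n_shells`` equal-width shells spanning (0, radius]."""
    return (np.arange(n_shells) + 0.5) * radius / n_shells


def _shell_points(r: float, voxel: float) -> int:
    return max(32, int(math.ceil(4.0 * np.pi * r * r / voxel**2)))


def resample_onto(source: DensityMap, target: DensityMap) -> np.ndarray:
    """Trilinearly resample ``source`` values onto ``target``'s grid."""
    ix, iy, iz = np.meshgrid(
        *(np.arange(n) for n in target.shape), indexing="ij"
    )
    world = target.origin + np.stack([ix, iy, iz], axis=-1) * target.voxel_size
    idx = (world - source.origin) / source.voxel_size
    return map_coordinates(
        source.data.astype(float),
        [idx[..., 0], idx[..., 1], idx[..., 2]],
        order=1,
        mode="constant",
        cval=0.0,
    )


def local_mask(
    density_map: DensityMap, coords: np.ndarray, r_mask: float = 3.0
) -> np.ndarray:
    """Boolean grid: voxels within ``r_mask`` Å of any of ``coords``."""
    coords = np.atleast_2d(coords)
    lo = density_map.world_to_index(coords.min(axis=0) - r_mask)
    hi = density_map.world_to_index(coords.max(axis=0) + r_mask)
    lo = np.maximum(np.floor(lo).astype(int), 0)
    hi = np.minimum(np.ceil(hi).astype(int) + 1, density_map.shape)
    mask = np.zeros(density_map.shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    pts = density_map.index_to_world(np.stack(grids, axis=-1).reshape(-1, 3))
    d, _ = cKDTree(coords).query(pts, k=1)
    sub = (d <= r_mask).reshape(tuple(hi - lo))
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return mask


def real_space_cc(
    density_map: DensityMap,
    model_map: DensityMap,
    mask: str | np.ndarray = "global",
    model: AtomicModel | np.ndarray | None = None,
    r_mask: float = 3.0,
) -> float:
    """Pearson correlation between two maps over a voxel mask.

    ``model_map`` is resampled onto ``density_map``'s grid first.
    ``mask="global"`` uses all voxels; ``mask="local"`` uses voxels within
    ``r_mask`` Å of any atom of ``model`` (coordinates accepted directly);
    a boolean array on the map grid is used as-is.
    """
    a = density_map.data.astype(float)
    if model_map.shape == density_map.shape and np.allclose(
        model_map.voxel_size, density_map.voxel_size
    ) and np.allclose(model_map.origin, density_map.origin):
        b = model_map.data.astype(float)
    else:
        b = resample_onto(model_map, density_map)
    if isinstance(mask, str):
        if mask == "global":
            sel = np.ones(a.shape, dtype=bool)
        elif mask == "local":
            if model is None:
                raise ValueError("local mask requires model atoms")
            coords = (
                model.coordinates() if isinstance(model, AtomicModel) else np.asarray(model)
            )
            sel = local_mask(density_map, coords, r_mask)
        else:
            raise ValueError(f"unknown mask {mask!r}")
    else:
        sel = np.asarray(mask, dtype=bool)
    n = int(sel.sum())
    if n < 10:
        raise ValueError(f"degenerate mask: only {n} voxels selected")
    x = a[sel]
    y = b[sel]
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValueError("zero variance inside mask")
    return float(xc @ yc) / denom


def compute_d99(density_map: DensityMap) -> float:
    """Resolution d such that Fourier shells beyond 1/d hold 1% of power.

    Power is |F|^2 excluding the DC term; the cumulative-99% spatial
    frequency is interpolated between sorted frequency samples and
    inverted to Å. Scale-invariant by construction.
    """
    data = density_map.data.astype(float)
    if np.allclose(data, data.flat[0]):
        raise ValueError("constant map has no spectral content")
    f = sp_fft.rfftn(data)
    power = np.abs(f) ** 2
    # physical spatial frequencies (1/Å) per axis
    freqs = [
        sp_fft.fftfreq(n, d=v)
        for n, v in zip(data.shape[:2], density_map.voxel_size[:2])
    ]
    freqs.append(
        sp_fft.rfftfreq(data.shape[2], d=density_map.voxel_size[2])
    )
    sx, sy, sz = np.meshgrid(*freqs, indexing="ij")
    s = np.sqrt(sx**2 + sy**2 + sz**2)
    # rfft stores half the spectrum: double the weight of non-self-conjugate
    # planes so shell power matches the full transform
    w = np.full(power.shape, 2.0)
    w[..., 0] = 1.0
    if data.shape[2] % 2 == 0:
        w[..., -1] = 1.0
    power = power * w
    flat_s = s.ravel()
    flat_p = power.ravel()
    # spherical shells only: drop DC and the corner frequencies beyond the
    # Nyquist sphere of the coarsest axis
    s_nyq = 0.5 / float(density_map.voxel_size.max())
    keep = (flat_s > 0) & (flat_s <= s_nyq + 1e-12)
    flat_s = flat_s[keep]
    flat_p = flat_p[keep]
    order = np.argsort(flat_s)
    cum = np.cumsum(flat_p[order])
    total = cum[-1]
    if total == 0:
        raise ValueError("map has no non-DC power")
    k = int(np.searchsorted(cum, 0.99 * total))
    s99 = flat_s[order][min(k, len(cum) - 1)]
    return float(1.0 / s99)


def lowpass_filter(
    density_map: DensityMap, resolution: float, edge_fraction: float = 0.1
) -> DensityMap:
    """Low-pass filter with a raised-cosine edge at 1/resolution.

    The amplitude response is 1 below the edge, 0 above it, and passes
    through 1/2 exactly at spatial frequency 1/resolution.
    """
    data = density_map.data.astype(float)
    f = sp_fft.fftn(data)
    freqs = [
        sp_fft.fftfreq(n, d=v)
        for n, v in zip(data.shape, density_map.voxel_size)
    ]
    sx, sy, sz = np.meshgrid(*freqs, indexing="ij")
    s = np.sqrt(sx**2 + sy**2 + sz**2)
    sc = 1.0 / resolution
    half_width = edge_fraction * sc
    t = np.clip((s - (sc - half_width)) / (2.0 * half_width), 0.0, 1.0)
    response = 0.5 * (1.0 + np.cos(np.pi * t))
    out = np.real(sp_fft.ifftn(f * response))
    return DensityMap(
        out, density_map.voxel_size.copy(), density_map.origin.copy(), resolution
    )
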