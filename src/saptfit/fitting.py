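"""Dock search models into density maps.

The translation search is a spherically averaged phased translation
function (SAPTF): the rotation-invariant radial density profile of the
search model (about its centre of mass, out to its bounding-sphere radius)
is correlated with the map's radial profile about every searched grid
point. Because each shell mean is a convolution of the map with a fixed
spherical-shell kernel, all shell means are computed with FFTs and the
per-voxel Pearson correlation across shells follows vectorized, which
makes the "every grid point" search tractable on desk-scale maps. A peak's
significance is its translation-function Z-score, TFZ = (score - mean)/sd
over the searched points.

The SAPTF peak carries no orientation, so a subsequent rotation search
scans a quasi-uniform SO(3) grid (default 10°), scoring each orientation
by the overlap of the map with the model's Gaussian density — evaluated as
the sum over atoms of the atom-smoothed map at the rotated atom positions,
which ranks orientations identically to the density cross-correlation at a
fraction of the cost — followed by a 2° fine pass and local-CC reporting.
Rigid-body refinement then polishes the six placement parameters against
the local real-space correlation.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import gaussian_filter, map_coordinates, maximum_filter
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .density import (
    atom_sigma,
    fibonacci_sphere,
    local_mask,
    radial_profile,
    real_space_cc,
    shell_radii,
    simulate_density,
)
from .model_prep import SearchModel
from .structures_io import AtomicModel, DensityMap

__all__ = [
    "Placement",
    "TranslationFunctionGrid",
    "TranslationPeak",
    "saptf_translation_search",
    "local_rotation_search",
    "rigid_body_refine",
    "place_n_copies",
    "apply_placement",
    "so3_grid",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Placement:
    """A rigid placement of a search model with its fit scores.

    Model coordinates map to the map frame as
    ``rotation @ (x - com) + translation`` where ``com`` is the model's
    centre of mass and ``translation`` is the placed centre of mass (Å).
    """

    rotation: np.ndarray
    translation: np.ndarray
    saptf_score: float = float("nan")
    tfz: float = float("nan")
    cc_global: float = float("nan")
    cc_local: float = float("nan")
    packing_score: float = 1.0
    copy_index: int = 0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if not math.isclose(float(np.linalg.det(self.rotation)), 1.0, abs_tol=1e-6):
            raise ValueError("rotation is not proper (det != 1)")
        if not 0.0 <= self.packing_score <= 1.0:
            raise ValueError("packing_score out of [0, 1]")


@dataclasses.dataclass
class TranslationPeak:
    index: tuple[int, int, int]
    position: np.ndarray  # Å
    score: float
    tfz: float


@dataclasses.dataclass
class TranslationFunctionGrid:
    scores: np.ndarray
    mean: float
    sd: float
    searched: np.ndarray  # boolean grid of searched points
    degenerate: bool = False


def _as_model(sm: SearchModel | AtomicModel) -> AtomicModel:
    return sm.model if isinstance(sm, SearchModel) else sm


def saptf_translation_search(
    density_map: DensityMap,
    sm: SearchModel | AtomicModel,
    resolution: float | None = None,
    stride: int | None = None,
    max_peaks: int = 20,
    n_shells: int | None = None,
) -> tuple[TranslationFunctionGrid, list[TranslationPeak]]:
    """Score the model's radial profile against the map at grid points.

    Returns the score grid (with its mean and sd over searched points) and
    local-maximum peaks ranked by score, each carrying a TFZ. ``stride``
    defaults to 1 for maps up to 96^3 and 2 above, with a stride-1 re-scan
    in the neighbourhood of each retained peak.
    """
    model = _as_model(sm)
    resolution = resolution or density_map.nominal_resolution
    if resolution is None:
        raise ValueError("a nominal resolution is required")
    com = model.center_of_mass()
    r_b = model.bounding_radius(com)
    half_extent = (np.array(density_map.shape) - 1) * density_map.voxel_size / 2.0
    if r_b > float(half_extent.max()):
        raise ValueError(
            f"model bounding sphere ({r_b:.1f} Å) exceeds the map half-extent"
        )
    if stride is None:
        stride = 1 if max(density_map.shape) <= 96 else 2

    # reference profile of the model's own simulated density about its com
    model_map = simulate_density(model, resolution, voxel_size=float(density_map.voxel_size.min()))
    vmean = float(density_map.voxel_size.mean())
    if n_shells is None:
        n_shells = max(4, int(math.ceil(r_b / vmean)))
    radii = shell_radii(r_b, n_shells)
    ref = radial_profile(model_map, com, r_b, n_shells).values

    shell_means = _shell_mean_stack(density_map, radii)
    scores, valid = _profile_correlation(shell_means, ref, radii)

    # search only where the model sphere fits inside the grid: shell means
    # beyond the boundary average in zero padding and are not comparable
    shape = np.array(density_map.shape)
    margin = np.minimum(
        np.ceil(r_b / density_map.voxel_size).astype(int),
        np.maximum((shape - 3) // 2, 0),
    )
    interior = np.zeros(density_map.shape, dtype=bool)
    interior[
        margin[0] : shape[0] - margin[0],
        margin[1] : shape[1] - margin[1],
        margin[2] : shape[2] - margin[2],
    ] = True
    valid &= interior

    searched = np.zeros(density_map.shape, dtype=bool)
    searched[::stride, ::stride, ::stride] = True
    searched &= valid
    n_searched = int(searched.sum())
    if n_searched < 2:
        grid = TranslationFunctionGrid(scores, 0.0, 0.0, searched, degenerate=True)
        return grid, []
    vals = scores[searched]
    mean = float(vals.mean())
    sd = float(vals.std())
    if sd < 1e-12:
        grid = TranslationFunctionGrid(scores, mean, sd, searched, degenerate=True)
        return grid, []
    grid = TranslationFunctionGrid(scores, mean, sd, searched)

    peaks = _find_peaks(scores, valid, density_map, mean, sd, r_b, max_peaks)
    return grid, peaks


def _shell_mean_stack(density_map: DensityMap, radii: np.ndarray) -> np.ndarray:
    """Per-voxel shell means via FFT convolution with shell kernels."""
    voxel = density_map.voxel_size
    r_max = float(radii[-1])
    half = np.ceil(r_max / voxel).astype(int) + 1
    kshape = 2 * half + 1
    data = density_map.data.astype(float)
    full = np.array(data.shape) + kshape - 1
    fshape = [sp_fft.next_fast_len(int(n)) for n in full]
    f_map = sp_fft.rfftn(data, fshape)
    out = np.empty((len(radii),) + data.shape)
    for k, r in enumerate(radii):
        kern = _shell_kernel(r, voxel, kshape, half)
        f_k = sp_fft.rfftn(kern, fshape)
        conv = sp_fft.irfftn(f_map * f_k, fshape)
        # centred "same" slice of the full convolution
        start = half
        out[k] = conv[
            start[0] : start[0] + data.shape[0],
            start[1] : start[1] + data.shape[1],
            start[2] : start[2] + data.shape[2],
        ]
    return out


def _shell_kernel(
    r: float, voxel: np.ndarray, kshape: np.ndarray, half: np.ndarray
) -> np.ndarray:
    """Trilinear splat of Fibonacci shell points, normalized to sum 1."""
    n_pts = max(32, int(math.ceil(4.0 * np.pi * r * r / float(voxel.mean()) ** 2)))
    pts = r * fibonacci_sphere(n_pts) / voxel  # voxel units, centred
    # reversed offsets so that convolution equals correlation with +offsets
    pts = -pts + half
    kern = np.zeros(tuple(kshape))
    base = np.floor(pts).astype(int)
    frac = pts - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                np.add.at(kern, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz), w)
    return kern / kern.sum()


def _profile_correlation(
    shell_means: np.ndarray, ref: np.ndarray, radii: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Shell-volume-weighted Pearson correlation at every voxel.

    Weighting each shell by its volume (∝ r²) makes the score an overlap
    of spherically averaged densities rather than a flat profile-shape
    match; an unweighted Pearson scores near 1 anywhere inside a smooth
    blob and its peak drifts off the true centre of mass. Mean
    subtraction keeps the score invariant to adding a constant to the map.
    """
    w = radii**2
    w = w / w.sum()
    ref_c = ref - float(w @ ref)
    ref_norm = float(np.sqrt(w @ ref_c**2))
    if ref_norm < 1e-12:
        raise ValueError("model radial profile is constant; SAPTF undefined")
    sm_mean = np.tensordot(w, shell_means, axes=(0, 0))
    sm_c = shell_means - sm_mean
    num = np.tensordot(w * ref_c, sm_c, axes=(0, 0))
    sd = np.sqrt(np.tensordot(w, sm_c**2, axes=(0, 0)))
    valid = sd > 1e-10 * ref_norm
    scores = np.zeros(shell_means.shape[1:])
    scores[valid] = num[valid] / (sd[valid] * ref_norm)
    return scores, valid


def _find_peaks(
    scores: np.ndarray,
    valid: np.ndarray,
    density_map: DensityMap,
    mean: float,
    sd: float,
    r_b: float,
    max_peaks: int,
) -> list[TranslationPeak]:
    work = np.where(valid, scores, -np.inf)
    is_max = (maximum_filter(work, size=3, mode="constant", cval=-np.inf) == work) & valid
    idx = np.argwhere(is_max)
    if idx.size == 0:
        return []
    vals = scores[tuple(idx.T)]
    order = np.argsort(-vals)
    min_sep = r_b / 2.0
    accepted: list[TranslationPeak] = []
    positions: list[np.ndarray] = []
    for o in order:
        pos = density_map.index_to_world(idx[o])
        if positions and np.min(
            np.linalg.norm(np.array(positions) - pos, axis=1)
        ) < min_sep:
            continue
        accepted.append(
            TranslationPeak(
                tuple(int(i) for i in idx[o]),
                pos,
                float(vals[o]),
                (float(vals[o]) - mean) / sd,
            )
        )
        positions.append(pos)
        if len(accepted) >= max_peaks:
            break
    return accepted


# ---------------------------------------------------------------------------
# rotation search


_SO3_CACHE: dict[float, np.ndarray] = {}


def so3_grid(step_deg: float) -> np.ndarray:
    """Quasi-uniform rotation set with the given angular step (degrees).

    Built as Fibonacci-sphere directions for the image of +z crossed with
    uniformly spaced in-plane roll angles; returns an (n, 3, 3) array.
    Grids are cached per step.
    """
    cached = _SO3_CACHE.get(step_deg)
    if cached is not None:
        return cached
    step = math.radians(step_deg)
    n_dir = max(1, int(math.ceil(4.0 * np.pi / step**2)))
    n_roll = max(1, int(math.ceil(2.0 * np.pi / step)))
    dirs = fibonacci_sphere(n_dir)
    z = np.array([0.0, 0.0, 1.0])
    # minimal rotations taking z to each direction, batched as rotvecs
    v = np.cross(np.broadcast_to(z, dirs.shape), dirs)
    s = np.linalg.norm(v, axis=1)
    c = dirs @ z
    angle = np.arctan2(s, c)
    axis = np.where(s[:, None] > 1e-12, v / np.where(s[:, None] > 1e-12, s[:, None], 1.0),
                    np.array([1.0, 0.0, 0.0]))
    align = Rotation.from_rotvec(axis * angle[:, None]).as_matrix()
    rolls = Rotation.from_rotvec(
        z[None, :] * (np.arange(n_roll) * 2.0 * np.pi / n_roll)[:, None]
    ).as_matrix()
    mats = np.einsum("dij,rjk->drik", align, rolls).reshape(-1, 3, 3)
    _SO3_CACHE[step_deg] = mats
    return mats


def _overlap_scores(
    smooth_vals_fn,
    coords_centered: np.ndarray,
    weights: np.ndarray,
    rotations: np.ndarray,
    center: np.ndarray,
) -> np.ndarray:
    """Sum of atom-smoothed map values at rotated atom positions."""
    out = np.empty(len(rotations))
    for s in range(0, len(rotations), 2000):
        rr = rotations[s : s + 2000]
        pts = np.einsum("rij,aj->rai", rr, coords_centered) + center
        vals = smooth_vals_fn(pts.reshape(-1, 3)).reshape(len(rr), -1)
        out[s : s + 2000] = vals @ weights
    return out


def local_rotation_search(
    density_map: DensityMap,
    sm: SearchModel | AtomicModel,
    center: np.ndarray,
    resolution: float | None = None,
    coarse_step_deg: float = 10.0,
    fine_step_deg: float = 2.0,
    r_mask: float = 3.0,
    n_candidates: int = 6,
    return_center: bool = False,
) -> tuple[np.ndarray, float] | tuple[np.ndarray, np.ndarray, float]:
    """Find the model orientation at a translation-peak centre.

    Exhaustive coarse scan over an SO(3) grid; the ``n_candidates`` best
    coarse orientations are each polished by a fine rotation pass at
    ``fine_step_deg`` with a small translation adjustment (the spherically
    averaged peak is only voxel-accurate), and the winner's rotation and
    local real-space correlation are returned. With ``return_center`` the
    jointly optimized centre is returned as well.
    """
    model = _as_model(sm)
    resolution = resolution or density_map.nominal_resolution
    center = np.asarray(center, dtype=float).reshape(3)
    com = model.center_of_mass()
    coords = model.coordinates() - com
    weights = model.atomic_numbers()

    sigma = atom_sigma(resolution)
    smooth = gaussian_filter(
        density_map.data.astype(float),
        sigma=sigma / density_map.voxel_size,
        mode="constant",
    )

    def smooth_vals(pts: np.ndarray) -> np.ndarray:
        idx = ((pts - density_map.origin) / density_map.voxel_size).T
        return map_coordinates(smooth, idx, order=1, mode="constant", cval=0.0)

    def smooth_vals_nn(pts: np.ndarray) -> np.ndarray:
        idx = np.rint((pts - density_map.origin) / density_map.voxel_size).astype(int)
        np.clip(idx, 0, np.array(density_map.shape) - 1, out=idx)
        return smooth[idx[:, 0], idx[:, 1], idx[:, 2]]

    # coarse stage: Cα trace only, nearest-voxel lookups, and a small grid
    # of centre shifts — the spherically averaged peak is voxel-accurate at
    # best and can sit a few Å off the true centre of mass
    ca = np.array(
        [r.atom("CA").position for c in model.chains for r in c.residues
         if r.atom("CA") is not None]
    )
    ca_coords = (ca - com) if len(ca) >= 5 else coords
    ca_weights = np.full(len(ca_coords), 6.0)
    rotations = so3_grid(coarse_step_deg)
    shift_axes = np.array([-3.0, 0.0, 3.0])
    sx, sy, sz = np.meshgrid(shift_axes, shift_axes, shift_axes, indexing="ij")
    shifts = np.column_stack([sx.ravel(), sy.ravel(), sz.ravel()])
    coarse = np.full(len(rotations), -np.inf)
    best_shift = np.zeros((len(rotations), 3))
    # rotate the trace once; shifts only move the lookup points
    for s_lo in range(0, len(rotations), 2000):
        rr = rotations[s_lo : s_lo + 2000]
        pts0 = np.einsum("rij,aj->rai", rr, ca_coords)
        for dt in shifts:
            vals = smooth_vals_nn((pts0 + center + dt).reshape(-1, 3))
            sc = vals.reshape(len(rr), -1) @ ca_weights
            better = sc > coarse[s_lo : s_lo + 2000]
            coarse[s_lo : s_lo + 2000][better] = sc[better]
            best_shift[s_lo : s_lo + 2000][better] = dt
    top = np.argsort(-coarse)[: max(1, n_candidates)]

    # polish each candidate over all six placement parameters (surrogate)
    best_rot, best_center, best_score = None, center, -np.inf
    for t in top:
        r_t = rotations[t]
        c_t = center + best_shift[t]

        def objective(p: np.ndarray) -> float:
            rot = Rotation.from_rotvec(np.radians(p[3:])).as_matrix() @ r_t
            pts = coords @ rot.T + c_t + p[:3]
            return -float(smooth_vals(pts) @ weights)

        res = minimize(
            objective, np.zeros(6), method="Powell",
            options={"maxiter": 8, "xtol": 0.1, "ftol": 1e-8},
        )
        if -res.fun > best_score:
            best_score = -float(res.fun)
            best_rot = Rotation.from_rotvec(np.radians(res.x[3:])).as_matrix() @ r_t
            best_center = c_t + res.x[:3]

    # declared fine pass: exhaustive 2° rotation-vector scan around the best
    steps = np.radians(np.arange(-2 * fine_step_deg, 2 * fine_step_deg + 1e-9, fine_step_deg))
    gx, gy, gz = np.meshgrid(steps, steps, steps, indexing="ij")
    offs = Rotation.from_rotvec(
        np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    ).as_matrix()
    fine = offs @ best_rot
    s = _overlap_scores(smooth_vals, coords, weights, fine, best_center)
    best_rot = fine[int(np.argmax(s))]

    cc = _placement_cc_local(
        density_map, model, best_rot, best_center, resolution, r_mask
    )
    if return_center:
        return best_rot, best_center, cc
    return best_rot, cc


def apply_placement(model: AtomicModel, placement: Placement) -> AtomicModel:
    """Transform model coordinates into the map frame of a placement."""
    com = model.center_of_mass()
    return model.transformed(
        placement.rotation, placement.translation - placement.rotation @ com
    )


def _placement_cc_local(
    density_map: DensityMap,
    model: AtomicModel,
    rotation: np.ndarray,
    translation: np.ndarray,
    resolution: float,
    r_mask: float = 3.0,
) -> float:
    """Local CC evaluated on a lattice-aligned crop around the placed model."""
    com = model.center_of_mass()
    placed = model.transformed(rotation, translation - rotation @ com)
    coords = placed.coordinates()
    pad = r_mask + 4.0 * atom_sigma(resolution)
    lo = np.floor(density_map.world_to_index(coords.min(axis=0) - pad)).astype(int)
    hi = np.ceil(density_map.world_to_index(coords.max(axis=0) + pad)).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, density_map.shape)
    if np.any(hi - lo < 2):
        return float("-inf")
    crop = DensityMap(
        density_map.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]],
        density_map.voxel_size,
        density_map.origin + lo * density_map.voxel_size,
        density_map.nominal_resolution,
    )
    sim_grid = DensityMap(
        np.zeros(crop.shape, dtype=np.float32), crop.voxel_size, crop.origin
    )
    try:
        sim = simulate_density(placed, resolution, grid=sim_grid)
        sel = local_mask(crop, coords, r_mask)
        return real_space_cc(crop, sim, mask=sel)
    except ValueError:
        return float("-inf")


def rigid_body_refine(
    density_map: DensityMap,
    sm: SearchModel | AtomicModel,
    placement: Placement,
    n_cycles: int = 20,
    resolution: float | None = None,
    r_mask: float = 3.0,
) -> Placement:
    """Locally optimize the six rigid-body parameters against cc_local.

    Runs up to ``n_cycles`` iterations of derivative-free optimization
    (Powell) starting from the given placement; the returned placement's
    cc_local never falls below the input's. Convergence is declared when
    the parameter step drops below 0.1 Å / 0.5°.
    """
    model = _as_model(sm)
    resolution = resolution or density_map.nominal_resolution
    r0 = placement.rotation
    t0 = placement.translation
    com = model.center_of_mass()
    coords = model.coordinates() - com
    weights = model.atomic_numbers()

    # the map-model density overlap shares its optimum with cc_local (the
    # model density's norm is rigid-motion invariant) and is far cheaper:
    # smooth the map once with the atom Gaussian, then sum at atom points
    sigma = atom_sigma(resolution)
    smooth = gaussian_filter(
        density_map.data.astype(float),
        sigma=sigma / density_map.voxel_size,
        mode="constant",
    )

    def unpack(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rot = Rotation.from_rotvec(np.radians(p[3:])).as_matrix() @ r0
        return rot, t0 + p[:3]

    def objective(p: np.ndarray) -> float:
        rot, t = unpack(p)
        pts = coords @ rot.T + t
        idx = ((pts - density_map.origin) / density_map.voxel_size).T
        vals = map_coordinates(smooth, idx, order=1, mode="constant", cval=0.0)
        return -float(vals @ weights)

    res = minimize(
        objective,
        np.zeros(6),
        method="Powell",
        options={
            "maxiter": n_cycles,
            "xtol": 0.05,  # parameter units: Å and degrees (below 0.1 Å/0.5°)
            "ftol": 1e-8,
        },
    )
    start_cc = placement.cc_local
    if not np.isfinite(start_cc):
        start_cc = _placement_cc_local(density_map, model, r0, t0, resolution, r_mask)
    rot, t = unpack(res.x)
    end_cc = _placement_cc_local(density_map, model, rot, t, resolution, r_mask)
    if end_cc < start_cc:  # never let refinement make the fit worse
        rot, t, end_cc = r0, t0, start_cc
    return dataclasses.replace(
        placement, rotation=rot, translation=t, cc_local=end_cc
    )


# ---------------------------------------------------------------------------
# multi-copy placement


def _packing_score(
    coords: np.ndarray, placed_coords: list[np.ndarray], clash_dist: float
) -> float:
    """Fraction of atoms farther than ``clash_dist`` from any placed atom."""
    if not placed_coords:
        return 1.0
    tree = cKDTree(np.vstack(placed_coords))
    d, _ = tree.query(coords, k=1)
    return float((d >= clash_dist).mean())


def _mask_claimed(
    density_map: DensityMap, coords: np.ndarray, radius: float
) -> DensityMap:
    masked = density_map.copy()
    sel = local_mask(density_map, coords, radius)
    masked.data[sel] = 0.0
    return masked


def place_n_copies(
    density_map: DensityMap,
    sm: SearchModel | AtomicModel,
    n: int,
    resolution: float | None = None,
    stride: int | None = None,
    packing_threshold: float = 0.7,
    clash_dist: float = 2.0,
    mask_radius_factor: float = 0.5,
    refine_cycles: int = 20,
    max_peaks_per_round: int = 6,
    early_accept_cc: float = 0.9,
) -> list[Placement]:
    """Sequentially place up to ``n`` copies of a search model.

    Each round runs the SAPTF search on the current (masked) map and works
    down the ranked peaks: each peak goes through rotation search and
    rigid-body refinement and must pass the packing check against the
    already-placed copies (``packing_score >= packing_threshold``, where an
    atom clashes when within ``clash_dist`` Å of an accepted copy). SAPTF
    peaks are broad and near-degenerate in score, so among passing peaks
    the one with the best refined local CC wins; a peak reaching
    ``early_accept_cc`` is taken without trying lower-ranked ones. Claimed
    density is zeroed within ``mask_radius_factor * resolution`` Å of the
    accepted atoms before the next round. Returns placements in acceptance
    order; an empty list when nothing is placeable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = _as_model(sm)
    resolution = resolution or density_map.nominal_resolution
    if resolution is None:
        raise ValueError("a nominal resolution is required")
    work = density_map.copy()
    placements: list[Placement] = []
    placed_coords: list[np.ndarray] = []
    for copy_index in range(n):
        grid, peaks = saptf_translation_search(work, model, resolution, stride)
        if grid.degenerate or not peaks:
            logger.info("copy %d: translation search degenerate; stopping", copy_index)
            break
        accepted = None
        for peak in peaks[:max_peaks_per_round]:
            rot, opt_center, cc = local_rotation_search(
                work, model, peak.position, resolution, return_center=True
            )
            cand = Placement(
                rot,
                opt_center,
                saptf_score=peak.score,
                tfz=peak.tfz,
                cc_local=cc,
                copy_index=copy_index,
            )
            cand = rigid_body_refine(
                work, model, cand, n_cycles=refine_cycles, resolution=resolution
            )
            coords = apply_placement(model, cand).coordinates()
            packing = _packing_score(coords, placed_coords, clash_dist)
            cand = dataclasses.replace(cand, packing_score=packing)
            if packing < packing_threshold:
                logger.info(
                    "copy %d: peak at %s rejected (packing %.2f < %.2f)",
                    copy_index,
                    np.round(peak.position, 1),
                    packing,
                    packing_threshold,
                )
                continue
            if accepted is None or cand.cc_local > accepted[0].cc_local:
                accepted = (cand, coords)
            if cand.cc_local >= early_accept_cc:
                break
        if accepted is None:
            logger.info("copy %d: no peak passed the packing check; stopping", copy_index)
            break
        cand, coords = accepted
        # score against the original, unmasked map
        cand = dataclasses.replace(
            cand,
            cc_local=_placement_cc_local(
                density_map, model, cand.rotation, cand.translation, resolution
            ),
            cc_global=_cc_global(density_map, model, cand, resolution),
        )
        placements.append(cand)
        placed_coords.append(coords)
        if copy_index < n - 1:
            work = _mask_claimed(work, coords, mask_radius_factor * resolution)
    return placements


def _cc_global(
    density_map: DensityMap,
    model: AtomicModel,
    placement: Placement,
    resolution: float,
) -> float:
    placed = apply_placement(model, placement)
    sim = simulate_density(
        placed, resolution, voxel_size=float(density_map.voxel_size.min())
    )
    try:
        return real_space_cc(density_map, sim, mask="global")
    except ValueError:
        return float("nan")
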