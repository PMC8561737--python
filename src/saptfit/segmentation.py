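"""Scale-space watershed segmentation of density maps.

The map is thresholded, an initial watershed on the inverted density
(26-connectivity, seeded at local maxima) partitions the above-threshold
voxels, and then repeated rounds of Gaussian smoothing regroup the regions:
each round smooths the map a little more, re-finds the local maxima, and
merges every old region into the new region that claims its maximum.
Rounds continue until the segment count drops to the requested target (or
the smoothing scale hits its ceiling), emulating the iterative
smoothing-and-grouping protocol used to cut an assembly map into its
molecular segments.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .structures_io import DensityMap

__all__ = ["SegmentationResult", "segment_map", "extract_segment"]

_CONN = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclasses.dataclass
class SegmentationResult:
    labels: np.ndarray  # 0 = background, k >= 1 = segment id
    n_segments: int
    centroids: np.ndarray  # (n, 3) Å, density-weighted
    volumes: np.ndarray  # voxels per segment
    sigma_final: float  # Å smoothing scale at termination
    reached_target: bool = True

    def segment_ids(self) -> np.ndarray:
        return np.arange(1, self.n_segments + 1)


def _threshold(data: np.ndarray, policy: str | float, quantile: float = 0.9) -> float:
    """Density threshold; moment-based policies ignore the zero padding."""
    if isinstance(policy, (int, float)) and not isinstance(policy, bool):
        return float(policy)
    nz = data[data != 0]
    if nz.size == 0:
        raise ValueError("map is identically zero")
    if policy == "mean_plus_sd":
        return float(nz.mean() + nz.std())
    if policy == "quantile":
        return float(np.quantile(nz, quantile))
    raise ValueError(f"unknown threshold policy {policy!r}")


def _local_maxima(smoothed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mx = ndimage.maximum_filter(smoothed, footprint=_CONN, mode="constant", cval=-np.inf)
    return (smoothed >= mx) & mask


def segment_map(
    density_map: DensityMap,
    target_n: int,
    threshold_policy: str | float = "mean_plus_sd",
    sigma_max_voxels: float = 10.0,
) -> SegmentationResult:
    """Segment above-threshold density into at most ``target_n`` regions.

    Smoothing σ grows by one voxel per round. If the count cannot be
    brought down to ``target_n`` before ``sigma_max_voxels``, the best
    (last) grouping is returned with ``reached_target=False``.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    data = density_map.data.astype(float)
    if np.allclose(data, data.flat[0]):
        raise ValueError("cannot segment a constant map")
    thr = _threshold(data, threshold_policy)
    mask = data > thr
    if not mask.any():
        raise ValueError(f"no voxels above threshold {thr:.4g}")

    seeds = _local_maxima(data, mask)
    markers, _ = ndimage.label(seeds, structure=_CONN)
    labels = watershed(-data, markers, mask=mask, connectivity=_CONN)
    vmean = float(density_map.voxel_size.mean())
    sigma_vox = 0.0
    while _count(labels) > target_n and sigma_vox < sigma_max_voxels:
        sigma_vox += 1.0
        smoothed = ndimage.gaussian_filter(data, sigma=sigma_vox)
        new_seeds = _local_maxima(smoothed, mask)
        new_markers, n_new = ndimage.label(new_seeds, structure=_CONN)
        if n_new == 0:
            break
        basins = watershed(-smoothed, new_markers, mask=mask, connectivity=_CONN)
        labels = _regroup(labels, basins, data)

    labels = _relabel_consecutive(labels)
    n = _count(labels)
    centroids, volumes = _centroids(labels, data, density_map, n)
    return SegmentationResult(
        labels,
        n,
        centroids,
        volumes,
        sigma_final=sigma_vox * vmean,
        reached_target=n <= target_n,
    )


def _count(labels: np.ndarray) -> int:
    return int(len(np.unique(labels[labels > 0])))


def _regroup(labels: np.ndarray, basins: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Merge old regions whose density maxima fall in the same new basin."""
    out = np.zeros_like(labels)
    for lab in np.unique(labels[labels > 0]):
        sel = labels == lab
        flat = np.where(sel.ravel())[0]
        peak = flat[np.argmax(data.ravel()[flat])]
        target = basins.ravel()[peak]
        if target == 0:  # maximum fell outside the new basins; keep identity
            target = lab + basins.max()
        out[sel] = target
    return out


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    uniq = np.unique(labels[labels > 0])
    out = np.zeros_like(labels)
    for new, old in enumerate(uniq, start=1):
        out[labels == old] = new
    return out


def _centroids(
    labels: np.ndarray, data: np.ndarray, density_map: DensityMap, n: int
) -> tuple[np.ndarray, np.ndarray]:
    centroids = np.zeros((n, 3))
    volumes = np.zeros(n, dtype=int)
    for k in range(1, n + 1):
        sel = labels == k
        volumes[k - 1] = int(sel.sum())
        idx = np.argwhere(sel)
        w = data[sel]
        w = np.clip(w, 0, None)
        if w.sum() <= 0:
            w = np.ones(len(idx))
        ci = (idx * w[:, None]).sum(axis=0) / w.sum()
        centroids[k - 1] = density_map.index_to_world(ci)
    return centroids, volumes


def extract_segment(
    density_map: DensityMap,
    seg: SegmentationResult,
    k: int,
    pad: float = 0.0,
) -> DensityMap:
    """Crop a single segment into its own map.

    Density outside segment ``k`` is zeroed; the crop covers the segment's
    voxel bounding box plus ``pad`` Å, and the origin is adjusted so
    model-space coordinates are preserved exactly.
    """
    if k < 1 or k > seg.n_segments:
        raise KeyError(f"segment id {k} not in 1..{seg.n_segments}")
    sel = seg.labels == k
    idx = np.argwhere(sel)
    pad_vox = np.ceil(pad / density_map.voxel_size).astype(int)
    lo = np.maximum(idx.min(axis=0) - pad_vox, 0)
    hi = np.minimum(idx.max(axis=0) + pad_vox + 1, density_map.shape)
    hi = np.maximum(hi, lo + 2)  # keep >= 2 voxels per axis
    data = np.where(sel, density_map.data, 0.0)[
        lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]
    ]
    return DensityMap(
        data,
        density_map.voxel_size.copy(),
        density_map.origin + lo * density_map.voxel_size,
        density_map.nominal_resolution,
    )
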