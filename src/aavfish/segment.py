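"""3D cell and nucleus segmentation from membrane and nuclear channels.

Cells are reconstructed by marker-controlled watershed on the (smoothed,
optionally plate-enhanced) membrane channel, seeded by segmented nuclei
or by h-minima when no nuclear channel exists. Cells touching any face
of the volume, or mostly outside the tissue mask, are flagged and
excluded from downstream puncta statistics so that only whole cells in
tissue are counted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals, peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from aavfish.volumes import ImageVolume, LabelVolume

log = logging.getLogger(__name__)


def _sigma_vox(sigma_um: float, voxel_size) -> np.ndarray:
    return sigma_um / np.asarray(voxel_size, dtype=float)


def enhance_membranes(
    vol: ImageVolume,
    channel: str = "membrane",
    sigma_smooth: float = 0.3,
    plateness: bool = False,
) -> np.ndarray:
    """Smooth the membrane channel; optionally add plate-likeness.

    Anisotropy-aware Gaussian smoothing (``sigma_smooth`` in microns,
    scaled per axis by voxel size). With ``plateness`` the most negative
    Hessian eigenvalue of the smoothed image is rectified, accentuating
    bright sheet-like structures such as labeled membranes.
    """
    if sigma_smooth < 0:
        raise ValueError("sigma_smooth must be >= 0")
    img = vol.channel(channel).astype(float)
    sig = _sigma_vox(sigma_smooth, vol.voxel_size)
    smoothed = ndimage.gaussian_filter(img, sig) if sigma_smooth > 0 else img
    if not plateness:
        return smoothed
    if np.ptp(smoothed) == 0:
        return np.zeros_like(smoothed)
    elems = hessian_matrix(smoothed, sigma=1.0, use_gaussian_derivatives=False)
    eigs = hessian_matrix_eigvals(elems)  # descending; last = most negative
    return np.clip(-eigs[-1], 0.0, None)


def segment_cells(
    enhanced: np.ndarray,
    voxel_size,
    seeds: LabelVolume | None = None,
    tissue_mask: np.ndarray | None = None,
    h_minima_depth: float | None = None,
) -> LabelVolume:
    """Marker-controlled watershed of membrane ridges into cells.

    ``seeds`` (typically segmented nuclei) provide one marker per cell;
    alternatively ``h_minima_depth`` derives markers from regional
    minima of depth h in the enhanced image. Every in-mask voxel is
    assigned to exactly one cell.
    """
    enhanced = np.asarray(enhanced, dtype=float)
    if tissue_mask is None:
        tissue_mask = np.ones(enhanced.shape, dtype=bool)
    if tissue_mask.shape != enhanced.shape:
        raise ValueError("tissue mask shape disagrees with image shape")
    if seeds is not None:
        markers = seeds.data
    elif h_minima_depth is not None:
        minima = h_minima(enhanced, h_minima_depth)
        markers, _ = ndimage.label(minima & tissue_mask)
    else:
        raise ValueError("provide nuclei seeds or an h_minima depth")
    if int((np.unique(markers) > 0).sum()) == 0:
        raise ValueError("no watershed seeds: zero markers supplied")
    labels = watershed(enhanced, markers=markers, mask=tissue_mask)
    return LabelVolume(labels.astype(np.int32), tuple(voxel_size))


def segment_nuclei(
    vol: ImageVolume,
    channel: str = "nuclei",
    min_volume: float = 1.0,
    sigma_smooth: float = 0.3,
    split_touching: bool = True,
    min_seed_distance: float = 1.5,
) -> LabelVolume:
    """Threshold-and-split nucleus segmentation of the DAPI-like channel.

    Automatic (Otsu) threshold on the smoothed channel, 3D connected
    components, components below ``min_volume`` (um^3) discarded,
    touching nuclei split by a distance-transform watershed with peaks
    at least ``min_seed_distance`` um apart.
    """
    if min_volume < 0:
        raise ValueError("min_volume must be >= 0")
    img = vol.channel(channel).astype(float)
    sig = _sigma_vox(sigma_smooth, vol.voxel_size)
    smoothed = ndimage.gaussian_filter(img, sig) if sigma_smooth > 0 else img
    if np.ptp(smoothed) == 0:
        log.info("blank nuclear channel: no nuclei found")
        return LabelVolume(np.zeros(img.shape, dtype=np.int32), tuple(vol.voxel_size))
    mask = smoothed > threshold_otsu(smoothed)
    voxel_vol = float(np.prod(vol.voxel_size))
    if split_touching:
        dist = ndimage.distance_transform_edt(mask, sampling=vol.voxel_size)
        # light smoothing regularizes EDT plateaus before peak finding
        dist = ndimage.gaussian_filter(dist, _sigma_vox(0.3, vol.voxel_size))
        # anisotropy-aware peak exclusion zone (microns per axis)
        radii = np.maximum(
            np.round(min_seed_distance / np.asarray(vol.voxel_size)).astype(int), 1
        )
        footprint = np.ones(2 * radii + 1, dtype=bool)
        peaks = peak_local_max(
            dist, footprint=footprint, labels=mask, exclude_border=False
        )
        peak_mask = np.zeros(img.shape, dtype=bool)
        peak_mask[tuple(peaks.T)] = True
        # adjacent plateau peaks collapse into one marker
        markers, _ = ndimage.label(peak_mask, structure=np.ones((3, 3, 3)))
        labels = watershed(-dist, markers=markers, mask=mask)
    else:
        labels, _ = ndimage.label(mask)
    # drop components below the size floor, then relabel consecutively
    counts = np.bincount(labels.ravel())
    too_small = np.flatnonzero(counts * voxel_vol < min_volume)
    labels[np.isin(labels, too_small[too_small > 0])] = 0
    uniq = np.unique(labels)
    remap = np.zeros(uniq.max() + 1 if uniq.size else 1, dtype=np.int32)
    remap[uniq[uniq > 0]] = np.arange(1, (uniq > 0).sum() + 1)
    return LabelVolume(remap[labels], tuple(vol.voxel_size))


def build_cell_table(
    labels: LabelVolume, tissue_mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-cell geometry and inclusion flags.

    ``touches_border`` is true iff any voxel of the cell lies on one of
    the six volume faces; ``in_tissue`` iff at least half the cell's
    voxels fall inside the mask; ``included = in_tissue and not
    touches_border``.
    """
    data = labels.data
    if tissue_mask is not None and tissue_mask.shape != data.shape:
        raise ValueError("tissue mask shape disagrees with label shape")
    ids = labels.labels()
    cols = ["cell_id", "centroid_z", "centroid_y", "centroid_x",
            "volume_um3", "n_voxels", "touches_border", "in_tissue", "included"]
    if ids.size == 0:
        return pd.DataFrame(columns=cols)
    nmax = int(ids.max())
    counts = np.bincount(data.ravel(), minlength=nmax + 1)
    centroids = ndimage.center_of_mass(np.ones_like(data, dtype=float), data, ids)
    centroids = (np.asarray(centroids) + 0.5) * np.asarray(labels.voxel_size)
    border = np.zeros(nmax + 1, dtype=bool)
    for face in (data[0], data[-1], data[:, 0], data[:, -1],
                 data[:, :, 0], data[:, :, -1]):
        border[np.unique(face)] = True
    if tissue_mask is not None:
        in_counts = np.bincount(data[tissue_mask].ravel(), minlength=nmax + 1)
        in_tissue = in_counts >= 0.5 * np.maximum(counts, 1)
    else:
        in_tissue = np.ones(nmax + 1, dtype=bool)
    voxel_vol = labels.voxel_volume
    return pd.DataFrame({
        "cell_id": ids.astype(int),
        "centroid_z": centroids[:, 0],
        "centroid_y": centroids[:, 1],
        "centroid_x": centroids[:, 2],
        "volume_um3": counts[ids] * voxel_vol,
        "n_voxels": counts[ids].astype(int),
        "touches_border": border[ids],
        "in_tissue": in_tissue[ids],
        "included": in_tissue[ids] & ~border[ids],
    })


def estimate_tissue_mask(
    vol: ImageVolume,
    channels: tuple[str, ...] = ("membrane", "nuclei"),
    sigma_smooth: float = 2.0,
) -> np.ndarray:
    """Coarse tissue mask from heavily smoothed structural channels.

    Sums the named channels, smooths at a supra-cellular scale, Otsu
    thresholds, and keeps the largest connected component with holes
    filled. A fallback when no curated mask is supplied.
    """
    total = sum(vol.channel(c).astype(float) for c in channels)
    sig = _sigma_vox(sigma_smooth, vol.voxel_size)
    smoothed = ndimage.gaussian_filter(total, sig)
    if np.ptp(smoothed) == 0:
        return np.ones(smoothed.shape, dtype=bool)
    mask = smoothed > threshold_otsu(smoothed)
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = lab == sizes.argmax()
    return ndimage.binary_fill_holes(mask)


def match_labels_iou(
    truth: LabelVolume, pred: LabelVolume, iou_threshold: float = 0.7
) -> pd.DataFrame:
    """One-to-one greedy IoU matching of two label volumes.

    For each truth label, candidate predicted labels are those it
    overlaps; pairs are accepted best-IoU-first, one match per label on
    each side. Used to score segmentation recovery against simulator
    truth.
    """
    t = truth.data.ravel()
    p = pred.data.ravel()
    both = (t > 0) | (p > 0)
    t, p = t[both], p[both]
    pair_ids = t.astype(np.int64) * (p.max(initial=0) + 1) + p
    uniq, inter = np.unique(pair_ids, return_counts=True)
    tmax = int(truth.data.max(initial=0))
    pmax = int(pred.data.max(initial=0))
    t_sizes = np.bincount(truth.data.ravel(), minlength=tmax + 1)
    p_sizes = np.bincount(pred.data.ravel(), minlength=pmax + 1)
    rows = []
    for pid, ov in zip(uniq, inter):
        ti, pi = divmod(int(pid), pmax + 1)
        if ti == 0 or pi == 0:
            continue
        union = t_sizes[ti] + p_sizes[pi] - ov
        rows.append((ti, pi, ov / union))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    used_t, used_p = set(), set()
    matched = []
    for ti, pi, iou in rows:
        if ti in used_t or pi in used_p or iou < iou_threshold:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matched.append({"truth_id": ti, "pred_id": pi, "iou": iou})
    return pd.DataFrame(matched, columns=["truth_id", "pred_id", "iou"])
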