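"""Synthetic 3D FISH volumes with known ground truth.

The generator emulates a confocal z stack of a tissue slab: contiguous
cells delineated by bright membranes (a WGA-like channel), one nucleus
per cell (a DAPI-like channel), and one or two puncta channels in which
each diffraction-limited spot is a single vector genome. Per-cell genome
counts are Poisson with mean proportional to vector titer; genomes sit in
the nucleus with a configurable probability; a two-channel mode renders
either truly co-located spot pairs (the 5' and 3' halves of one genome,
read out by two probe sets) or two independent populations (two different
co-injected vectors). A per-cell expression readout increases with
genome count and saturates.

Cell geometry is a nearest-seed (Voronoi) partition of the slab under
the anisotropy-aware micron metric: simple, contiguous, and exactly
truth-checkable. Genome positions are continuous micron coordinates;
rasterization happens only at render time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from aavfish.coloc import match_positions
from aavfish.volumes import ImageVolume, LabelVolume

log = logging.getLogger(__name__)

CHANNEL_A = "punctaA"
CHANNEL_B = "punctaB"


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TissueParams:
    """Geometry of the simulated tissue slab."""

    shape: tuple[int, int, int] = (40, 192, 192)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.4, 0.2, 0.2)  # um
    n_cells: int = 200
    nucleus_radius: float = 1.2  # um
    membrane_thickness: int = 1  # voxels
    slab_fraction: float = 0.8  # central fraction of y occupied by tissue
    #: optional (z, y, x) micron margins bounding the tissue away from every
    #: volume face (a section smaller than the field of view); overrides
    #: slab_fraction when set, and makes every cell a whole cell
    margin_um: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("shape and voxel_size must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0 < self.slab_fraction <= 1:
            raise ValueError("slab_fraction must be in (0, 1]")
        if self.nucleus_radius <= 0 or self.membrane_thickness < 1:
            raise ValueError("nucleus_radius and membrane_thickness must be positive")

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.voxel_size)


@dataclass(frozen=True)
class InfectionModel:
    """Statistical model of vector genomes per cell.

    ``lam`` is the mean genome count per cell (per channel in
    ``independent`` mode); the effective mean is ``lam * titer_scale``,
    so a titer series is expressed through ``titer_scale`` alone and the
    expected count scales exactly with titer by construction.
    ``nuclear_fraction`` is the probability a genome resides in the
    nucleus. ``detection_efficiency`` models probe-level dropout: the
    probability that a genome present in a cell actually produces a
    punctum in a given channel.
    """

    lam: float = 2.1
    titer_scale: float = 1.0
    nuclear_fraction: float = 0.8
    coloc_mode: str = "single"  # single | co_located | independent
    detection_efficiency: dict = field(
        default_factory=lambda: {CHANNEL_A: 1.0, CHANNEL_B: 1.0}
    )
    coloc_offset_sigma: float = 0.05  # um between paired channel positions

    def __post_init__(self) -> None:
        if self.lam < 0 or self.titer_scale < 0:
            raise ValueError("lam and titer_scale must be >= 0")
        if not 0 <= self.nuclear_fraction <= 1:
            raise ValueError("nuclear_fraction must be in [0, 1]")
        if self.coloc_mode not in ("single", "co_located", "independent"):
            raise ValueError(f"unknown coloc_mode {self.coloc_mode!r}")
        for ch, e in self.detection_efficiency.items():
            if not 0 < e <= 1:
                raise ValueError(f"detection_efficiency[{ch!r}] must be in (0, 1]")
        if self.coloc_offset_sigma < 0:
            raise ValueError("coloc_offset_sigma must be >= 0")

    @property
    def channels(self) -> tuple[str, ...]:
        if self.coloc_mode == "single":
            return (CHANNEL_A,)
        return (CHANNEL_A, CHANNEL_B)


#: Cell-type presets: measured mean genome counts per expressing cell and
#: predominantly nuclear localization shortly after infection.
INFECTION_PRESETS = {
    "rod": InfectionModel(lam=2.1, nuclear_fraction=0.8),
    "cone": InfectionModel(lam=2.5, nuclear_fraction=0.8),
    "rpe": InfectionModel(lam=29.9, nuclear_fraction=0.95),
}


@dataclass(frozen=True)
class RenderParams:
    """Optics and noise for rasterizing a simulated volume."""

    psf_sigma: tuple[float, float, float] = (0.4, 0.15, 0.15)  # um (z, y, x)
    punctum_amplitude: float = 800.0
    membrane_amplitude: float = 400.0
    nuclear_amplitude: float = 300.0
    background: float = 10.0
    noise: str = "poisson"  # poisson | gaussian | none
    gaussian_sigma: float = 5.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be positive")
        if min(self.punctum_amplitude, self.membrane_amplitude,
               self.nuclear_amplitude, self.background) < 0:
            raise ValueError("amplitudes and background must be >= 0")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass(frozen=True)
class ExpressionModel:
    """Saturating map from genome count to a fluorescence readout.

    Mean intensity for count ``k`` is ``baseline + increment * k /
    (1 + k / saturation)``: linear at low copy number, approaching
    ``baseline + increment * saturation`` at high copy number.
    """

    baseline: float = 50.0
    increment: float = 100.0
    saturation: float = 8.0
    noise_sigma: float = 20.0
    threshold: float = 120.0  # expression-positive call

    def __post_init__(self) -> None:
        if self.increment < 0 or self.saturation <= 0 or self.noise_sigma < 0:
            raise ValueError("invalid expression model parameters")

    def mean(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        return self.baseline + self.increment * k / (1.0 + k / self.saturation)


@dataclass
class GroundTruth:
    """Simulator truth: one row per genome-channel observation.

    ``puncta`` columns: genome_id, pair_id, cell_id, channel, z/y/x (um,
    the rendered position), compartment (nuclear/cytoplasmic), present
    (bool: survived channel detection efficiency). ``cell_counts`` holds
    the true per-cell genome count per channel for every cell, including
    zeros. For co-located pairs the channel-B position carries the small
    probe-set offset; its compartment and cell are those of the genome.
    """

    puncta: pd.DataFrame
    cell_counts: pd.DataFrame
    model: InfectionModel
    expression: pd.DataFrame | None = None

    def rendered(self, channel: str) -> pd.DataFrame:
        """Truth rows actually rendered in ``channel``."""
        p = self.puncta
        return p[(p["channel"] == channel) & p["present"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# tissue geometry


def _place_seeds(
    params: TissueParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing placement of cell seed points in the slab (um).

    Returns (seeds_um, y-bounds of the slab in um). Seeds keep a minimum
    pairwise distance so each nucleus fits strictly inside its Voronoi
    cell, and a margin from the slab faces in y.
    """
    extent = params.extent_um
    if params.margin_um is not None:
        m = np.asarray(params.margin_um, dtype=float)
        lo, hi = m, extent - m
    else:
        y_margin = 0.5 * (1.0 - params.slab_fraction) * extent[1]
        lo = np.array([0.0, y_margin, 0.0])
        hi = np.array([extent[0], extent[1] - y_margin, extent[2]])
    slab_vol = float(np.prod(hi - lo))
    if params.n_cells == 0:
        return np.empty((0, 3)), (lo, hi)
    # min separation: nuclei must fit (2r plus slack), but never so large
    # that n_cells cannot pack into the slab.
    sep_pack = 0.7 * (slab_vol / params.n_cells) ** (1.0 / 3.0)
    min_sep = max(2.0 * params.nucleus_radius * 1.15, sep_pack)
    # dart throwing with a uniform-grid neighbor index (bin edge = min_sep,
    # so conflicts are confined to the 27 surrounding bins)
    seeds: list[np.ndarray] = []
    grid: dict[tuple[int, int, int], list[int]] = {}
    max_tries = 2000 * params.n_cells
    tries = 0
    while len(seeds) < params.n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {params.n_cells} cell seeds with minimum "
                f"separation {min_sep:.2f} um in a "
                f"{slab_vol:.0f} um^3 slab after {max_tries} tries"
            )
        tries += 1
        cand = lo + rng.random(3) * (hi - lo)
        key = tuple((cand // min_sep).astype(int))
        ok = True
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for idx in grid.get((key[0] + dz, key[1] + dy, key[2] + dx), ()):
                        if np.linalg.norm(cand - seeds[idx]) < min_sep:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault(key, []).append(len(seeds))
            seeds.append(cand)
    return np.asarray(seeds), (lo, hi)


def tissue_mask_for(params: TissueParams) -> np.ndarray:
    """Boolean slab mask (True = tissue) for the given geometry."""
    extent = params.extent_um
    if params.margin_um is not None:
        lo = np.asarray(params.margin_um, dtype=float)
        hi = extent - lo
    else:
        y_margin = 0.5 * (1.0 - params.slab_fraction) * extent[1]
        lo = np.array([0.0, y_margin, 0.0])
        hi = np.array([extent[0], extent[1] - y_margin, extent[2]])
    mask = np.ones(params.shape, dtype=bool)
    for axis in range(3):
        centers = (np.arange(params.shape[axis]) + 0.5) * params.voxel_size[axis]
        inside = (centers >= lo[axis]) & (centers <= hi[axis])
        sl = [None, None, None]
        sl[axis] = slice(None)
        mask &= inside[tuple(sl)]
    return mask


def simulate_tissue(
    params: TissueParams, seed
) -> tuple[LabelVolume, LabelVolume, pd.DataFrame]:
    """Generate cell and nucleus label volumes plus the cell table.

    Cells are the nearest-seed partition of the slab in the micron
    metric; each cell's nucleus is the ball of ``nucleus_radius`` around
    its seed (inside its own cell by construction). Identical seeds give
    bit-identical outputs.
    """
    from aavfish.segment import build_cell_table  # local: avoid cycle

    rng = as_rng(seed)
    mask = tissue_mask_for(params)
    labels = np.zeros(params.shape, dtype=np.int32)
    nuclei = np.zeros(params.shape, dtype=np.int32)
    if params.n_cells > 0:
        seeds_um, _ = _place_seeds(params, rng)
        vs = np.asarray(params.voxel_size)
        idx = np.argwhere(mask)
        coords_um = (idx + 0.5) * vs
        tree = cKDTree(seeds_um)
        dist, nearest = tree.query(coords_um, k=1, workers=1)
        labels[tuple(idx.T)] = nearest.astype(np.int32) + 1
        inside = dist <= params.nucleus_radius
        nuclei[tuple(idx[inside].T)] = nearest[inside].astype(np.int32) + 1
    cells = build_cell_table(
        LabelVolume(labels, params.voxel_size), tissue_mask=mask
    )
    return (
        LabelVolume(labels, params.voxel_size),
        LabelVolume(nuclei, params.voxel_size),
        cells,
    )


# ---------------------------------------------------------------------------
# genomes


def _compartment_voxels(
    labels: LabelVolume, nuclei: LabelVolume
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per cell, the (nuclear, cytoplasmic) voxel index arrays (N, 3)."""
    flat = labels.data.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    uniq, starts = np.unique(sorted_labels, return_index=True)
    ends = np.append(starts[1:], flat.size)
    nuc_flat = nuclei.data.ravel() > 0
    shape = labels.shape
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for lab, s, e in zip(uniq, starts, ends):
        if lab == 0:
            continue
        vox = np.column_stack(np.unravel_index(order[s:e], shape))
        is_nuc = nuc_flat[order[s:e]]
        out[int(lab)] = (vox[is_nuc], vox[~is_nuc])
    return out


def simulate_genomes(
    labels: LabelVolume,
    nuclei: LabelVolume,
    model: InfectionModel,
    seed,
    cell_table: pd.DataFrame | None = None,
) -> GroundTruth:
    """Draw per-cell genome counts and continuous genome positions.

    Per cell the count is Poisson(lam * titer_scale). Each genome lands
    uniformly in the nucleus with probability ``nuclear_fraction``, else
    uniformly in the cytoplasm. In ``co_located`` mode every genome is
    read out in both channels (subject to per-channel detection
    efficiency) with a Gaussian(coloc_offset_sigma) displacement between
    the two channel positions, truncated at 5 sigma. In ``independent``
    mode the two channels are drawn as independent populations.
    """
    rng = as_rng(seed)
    vs = np.asarray(labels.voxel_size)
    comp_vox = _compartment_voxels(labels, nuclei)
    cell_ids = sorted(comp_vox)
    if not cell_ids:
        raise ValueError("label volume contains no cells")
    mean = model.lam * model.titer_scale

    def draw_positions(n: int, cell: int) -> tuple[np.ndarray, np.ndarray]:
        """(positions_um, compartment flags) for n genomes in one cell."""
        nuc_vox, cyt_vox = comp_vox[cell]
        want_nuc = rng.random(n) < model.nuclear_fraction
        # degenerate compartments fall back to whatever voxels exist
        if len(nuc_vox) == 0:
            want_nuc[:] = False
        if len(cyt_vox) == 0:
            want_nuc[:] = True
        pos = np.empty((n, 3))
        for flag, vox in ((True, nuc_vox), (False, cyt_vox)):
            sel = np.flatnonzero(want_nuc == flag)
            if sel.size == 0:
                continue
            pick = vox[rng.integers(0, len(vox), size=sel.size)]
            pos[sel] = (pick + rng.random((sel.size, 3))) * vs
        return pos, want_nuc

    extent = np.asarray(labels.shape) * vs
    eps = 1e-6

    rows: list[dict] = []
    counts: dict[str, dict[int, int]] = {ch: {} for ch in model.channels}
    gid = 0
    for cell in cell_ids:
        if model.coloc_mode in ("single", "co_located"):
            k = int(rng.poisson(mean))
            counts[CHANNEL_A][cell] = k
            if model.coloc_mode == "co_located":
                counts[CHANNEL_B][cell] = k
            pos, is_nuc = draw_positions(k, cell)
            for i in range(k):
                comp = "nuclear" if is_nuc[i] else "cytoplasmic"
                present_a = rng.random() < model.detection_efficiency.get(CHANNEL_A, 1.0)
                rows.append(dict(
                    genome_id=gid, pair_id=gid, cell_id=cell, channel=CHANNEL_A,
                    z=pos[i, 0], y=pos[i, 1], x=pos[i, 2],
                    compartment=comp, present=present_a,
                ))
                if model.coloc_mode == "co_located":
                    off = rng.normal(0.0, model.coloc_offset_sigma, size=3)
                    nrm = np.linalg.norm(off)
                    cap = 5.0 * model.coloc_offset_sigma
                    if nrm > cap > 0:
                        off *= cap / nrm
                    pb = np.clip(pos[i] + off, eps, extent - eps)
                    present_b = rng.random() < model.detection_efficiency.get(CHANNEL_B, 1.0)
                    rows.append(dict(
                        genome_id=gid, pair_id=gid, cell_id=cell,
                        channel=CHANNEL_B, z=pb[0], y=pb[1], x=pb[2],
                        compartment=comp, present=present_b,
                    ))
                gid += 1
        else:  # independent populations in each channel
            for ch in model.channels:
                k = int(rng.poisson(mean))
                counts[ch][cell] = k
                pos, is_nuc = draw_positions(k, cell)
                for i in range(k):
                    rows.append(dict(
                        genome_id=gid, pair_id=-1, cell_id=cell, channel=ch,
                        z=pos[i, 0], y=pos[i, 1], x=pos[i, 2],
                        compartment="nuclear" if is_nuc[i] else "cytoplasmic",
                        present=rng.random() < model.detection_efficiency.get(ch, 1.0),
                    ))
                    gid += 1

    puncta = pd.DataFrame(
        rows,
        columns=["genome_id", "pair_id", "cell_id", "channel",
                 "z", "y", "x", "compartment", "present"],
    )
    count_rows = [
        {"cell_id": cell, "channel": ch, "true_count": counts[ch].get(cell, 0)}
        for ch in model.channels for cell in cell_ids
    ]
    cell_counts = pd.DataFrame(count_rows)
    return GroundTruth(puncta=puncta, cell_counts=cell_counts, model=model)


# ---------------------------------------------------------------------------
# rendering


def _add_spots(
    canvas: np.ndarray,
    positions_um: np.ndarray,
    amplitude: float,
    sigma_vox: np.ndarray,
    voxel_size: np.ndarray,
) -> None:
    """Accumulate anisotropic Gaussian spots at continuous positions."""
    if len(positions_um) == 0:
        return
    centers = positions_um / voxel_size - 0.5  # voxel-center coordinates
    half = np.ceil(4.0 * sigma_vox).astype(int)
    shape = np.asarray(canvas.shape)
    for c in centers:
        lo = np.maximum(np.round(c).astype(int) - half, 0)
        hi = np.minimum(np.round(c).astype(int) + half + 1, shape)
        if np.any(lo >= hi):
            continue
        axes = [
            np.exp(-0.5 * ((np.arange(lo[a], hi[a]) - c[a]) / sigma_vox[a]) ** 2)
            for a in range(3)
        ]
        canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * (
            axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        )


def render_volume(
    labels: LabelVolume,
    nuclei: LabelVolume,
    truth: GroundTruth,
    rp: RenderParams,
    seed,
    membrane_thickness: int = 1,
) -> ImageVolume:
    """Rasterize membrane, nuclei and puncta channels with noise.

    The membrane channel marks boundary voxels between different cell
    labels (blurred by the PSF); the nuclei channel is the nucleus mask;
    each puncta channel is a sum of anisotropic Gaussian spots at the
    true positions plus a constant background, then the configured noise.
    """
    rng = as_rng(seed)
    vs = np.asarray(labels.voxel_size)
    sigma_vox = np.asarray(rp.psf_sigma) / vs
    if np.any(sigma_vox < 0.25):
        raise ValueError(
            f"PSF sigma {rp.psf_sigma} um is < 0.25 voxel on some axis at "
            f"voxel size {tuple(vs)} um: spots would be unresolvable"
        )
    membrane = find_boundaries(labels.data, mode="thick").astype(float)
    if membrane_thickness > 1:
        membrane = ndimage.binary_dilation(
            membrane > 0, iterations=membrane_thickness - 1
        ).astype(float)
    membrane = ndimage.gaussian_filter(membrane * rp.membrane_amplitude, sigma_vox)
    dapi = ndimage.gaussian_filter(
        (nuclei.data > 0).astype(float) * rp.nuclear_amplitude, sigma_vox
    )

    channels = [membrane, dapi]
    names = ["membrane", "nuclei"]
    for ch in truth.model.channels:
        canvas = np.zeros(labels.shape, dtype=float)
        pts = truth.rendered(ch)
        _add_spots(canvas, pts[["z", "y", "x"]].to_numpy(), rp.punctum_amplitude,
                   sigma_vox, vs)
        channels.append(canvas)
        names.append(ch)

    data = np.stack(channels) + rp.background
    if rp.noise == "poisson":
        data = rng.poisson(data).astype(np.float32)
    elif rp.noise == "gaussian":
        data = np.clip(data + rng.normal(0.0, rp.gaussian_sigma, data.shape), 0, None)
    return ImageVolume(data.astype(np.float32), tuple(vs), tuple(names))


# ---------------------------------------------------------------------------
# expression readout and truth matching


def simulate_expression(
    truth: GroundTruth, em: ExpressionModel, seed, channel: str = CHANNEL_A
) -> pd.DataFrame:
    """Per-cell fluorescence readout increasing with true genome count.

    Returns a frame with cell_id, true_count, expression and the
    expression-positive flag; also stored on ``truth.expression``.
    """
    rng = as_rng(seed)
    cc = truth.cell_counts
    sub = cc[cc["channel"] == channel][["cell_id", "true_count"]].reset_index(drop=True)
    mean = em.mean(sub["true_count"].to_numpy())
    intensity = mean + rng.normal(0.0, em.noise_sigma, size=len(sub))
    out = sub.assign(
        expression=intensity, expression_positive=intensity > em.threshold
    )
    truth.expression = out
    return out


def match_detections_to_truth(
    detected: pd.DataFrame,
    truth: GroundTruth,
    radius: float,
    channel: str = CHANNEL_A,
) -> dict:
    """Score detections against rendered truth by one-to-one matching.

    Returns recall, precision and the mean localization error (um) over
    matched pairs. Precision is None when nothing was detected.
    """
    if radius <= 0:
        raise ValueError("match radius must be > 0")
    truth_pos = truth.rendered(channel)[["z", "y", "x"]].to_numpy()
    if "channel" in detected.columns:
        detected = detected[detected["channel"] == channel]
    det_pos = detected[["z", "y", "x"]].to_numpy()
    pairs = match_positions(det_pos, truth_pos, radius)
    n_match = len(pairs)
    recall = n_match / len(truth_pos) if len(truth_pos) else None
    precision = n_match / len(det_pos) if len(det_pos) else None
    if n_match:
        d = np.linalg.norm(
            det_pos[[i for i, _ in pairs]] - truth_pos[[j for _, j in pairs]],
            axis=1,
        )
        mean_err = float(d.mean())
    else:
        mean_err = None
    return {
        "n_truth": int(len(truth_pos)),
        "n_detected": int(len(det_pos)),
        "n_matched": int(n_match),
        "recall": recall,
        "precision": precision,
        "mean_localization_error": mean_err,
    }
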