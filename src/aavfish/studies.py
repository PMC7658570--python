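"""Canned study designs at the scale of the original experiments.

These functions wire the simulator and the analysis pipeline into the
quantitative study designs the package reproduces end to end:

* a limiting-dilution series: five vector titers equally log-spaced
  across one decade, per-cell genome counts Poisson with mean
  proportional to titer, fully rendered and re-quantified through
  segmentation, spot calling and per-cell counting, then fit by the
  linear dilution regression;

* a dual-vector chance-colocalization experiment: two genome
  populations drawn independently (two co-injected vectors) at the
  measured per-cell scale of ~2.5 genomes per channel in ~500 um^3
  cells, matched across channels at a 0.5 um radius;

* a per-cell count recovery check: rendered volumes at a known mean
  genome count, re-quantified blind, estimated mean vs generating mean.

Geometry emulates photoreceptor-dense tissue: cells of ~120 um^3 whose
nuclei (1.8 um radius) occupy a large fraction of the soma, as in the
outer nuclear layer. Slabs are bounded 1 um away from every volume face
so all simulated cells are whole cells, and problem sizes are chosen so
sampling error stays well below the quantities checked. Detection in
these large volumes runs at threshold k = 7 robust SDs: with tens of
millions of resolution elements per volume, the family-wise false-call
rate at the package-default k = 5 is no longer negligible, so the
studies raise the threshold to keep expected false calls near zero
(spot peaks sit far above either threshold).
"""

from __future__ import annotations

import tempfile

import numpy as np

from aavfish.coloc import ColocResult, coloc_probability, match_positions
from aavfish.pipeline import RunConfig, run_pipeline
from aavfish.simulate import (
    CHANNEL_A,
    CHANNEL_B,
    InfectionModel,
    TissueParams,
    simulate_genomes,
    simulate_tissue,
)
from aavfish.stats import DilutionFit

#: five dilutions equally log-spaced across one decade of titer
#: (relative units; 1.0 is the undiluted top titer)
DILUTION_TITERS = tuple(float(t) for t in np.geomspace(0.1, 1.0, 5).round(6))

#: top-titer mean genomes per cell: the measured per-cell scale in
#: expressing cones
DILUTION_LAM_TOP = 2.5

#: detection threshold for the large-volume studies (see module docstring)
STUDY_DETECTION_K = 7.0


def enclosed_tissue(
    n_cells: int,
    cell_volume_um3: float = 120.0,
    voxel_size: tuple[float, float, float] = (0.4, 0.2, 0.2),
    nucleus_radius: float = 1.8,
    margin: float = 1.0,
) -> dict:
    """Tissue block for a cube-ish slab of whole cells.

    The slab edge length is set so that ``n_cells`` cells of roughly
    ``cell_volume_um3`` tile it, with ``margin`` microns of empty space
    to every volume face.
    """
    edge = (n_cells * cell_volume_um3) ** (1.0 / 3.0)
    shape = tuple(
        int(np.ceil((edge + 2.0 * margin + 1.0) / v)) for v in voxel_size
    )
    return dict(
        shape=shape, voxel_size=voxel_size, n_cells=n_cells,
        nucleus_radius=nucleus_radius, margin_um=(margin,) * 3,
        slab_fraction=1.0,
    )


def dilution_study(
    seed: int,
    out_dir: str | None = None,
    n_cells: int = 550,
    lam_top: float = DILUTION_LAM_TOP,
    titers: tuple[float, ...] = DILUTION_TITERS,
) -> DilutionFit:
    """Run the full limiting-dilution experiment and regression.

    Each titer group is simulated (``n_cells`` whole cells, default
    550 so that well over 500 cells enter every group's count), rendered
    with default optics and shot noise, segmented and spot-called from
    the images alone; per-cell counts feed the ordinary least-squares
    fit of group mean count on relative titer.
    """
    cfg = {
        "seed": int(seed),
        "titer_groups": list(titers),
        "tissue": enclosed_tissue(n_cells),
        "infection": dict(lam=lam_top),
        "detection": dict(k=STUDY_DETECTION_K),
    }
    if out_dir is None:
        with tempfile.TemporaryDirectory() as td:
            res = run_pipeline(RunConfig.model_validate({**cfg, "out": td}))
    else:
        res = run_pipeline(RunConfig.model_validate({**cfg, "out": str(out_dir)}))
    return res["dilution_fit"]


def chance_colocalization_study(
    seed: int,
    n_cells: int = 1000,
    cell_volume_um3: float = 500.0,
    lam: float = 2.5,
    radius: float = 0.5,
) -> ColocResult:
    """Dual-vector control: two independent genome populations.

    ``n_cells`` cells of roughly ``cell_volume_um3`` each receive two
    independent Poisson(``lam``) genome populations placed uniformly
    within the cell; the two channels are matched one-to-one at
    ``radius`` microns and the averaged colocalization probability is
    returned. With no true pairing this measures the chance rate.
    """
    tp = TissueParams(**enclosed_tissue(
        n_cells, cell_volume_um3, voxel_size=(0.5, 0.5, 0.5),
        nucleus_radius=2.5,
    ))
    labels, nuclei, _ = simulate_tissue(tp, int(seed))
    # uniform placement within cells: nuclear draw probability equals the
    # nuclear volume fraction
    f_nuc = float((nuclei.data > 0).sum()) / float((labels.data > 0).sum())
    model = InfectionModel(lam=lam, coloc_mode="independent",
                           nuclear_fraction=f_nuc)
    truth = simulate_genomes(labels, nuclei, model, int(seed) + 1)
    a = truth.rendered(CHANNEL_A)[["z", "y", "x"]].to_numpy()
    b = truth.rendered(CHANNEL_B)[["z", "y", "x"]].to_numpy()
    pairs = match_positions(a, b, radius)
    return coloc_probability(len(pairs), len(a), len(b), radius)


def count_recovery_study(
    seed: int,
    lam: float,
    n_cells: int | None = None,
) -> dict:
    """Render-and-requantify check of per-cell count recovery.

    Simulates whole cells at per-cell mean ``lam``, runs the image-based
    pipeline, and reports the estimated mean puncta per cell next to the
    generating mean. ``n_cells`` defaults to a size that keeps at least
    ~1000 expected genomes in the volume, so the sampling error of the
    mean stays well below 10% of ``lam``. Sparse conditions
    (``lam < 1``) use a coarser voxel grid: they need many cells, and
    nothing about isolated spots requires the finest sampling.
    """
    if n_cells is None:
        n_cells = max(600, int(np.ceil(1000.0 / max(lam, 1e-9))))
    voxel = (0.4, 0.2, 0.2) if lam >= 1 else (0.5, 0.25, 0.25)
    cfg = RunConfig.model_validate({
        "seed": int(seed),
        "out": "unused",
        "tissue": enclosed_tissue(n_cells, voxel_size=voxel),
        "infection": dict(lam=lam),
        "detection": dict(k=STUDY_DETECTION_K),
    })
    with tempfile.TemporaryDirectory() as td:
        cfg = cfg.model_copy(update={"out": td})
        res = run_pipeline(cfg)
    counts = res["run"]["counts"][CHANNEL_A]["count"]
    return {
        "lam": lam,
        "n_cells_simulated": int(n_cells),
        "n_cells_analyzed": int(len(counts)),
        "estimated_mean": float(counts.mean()),
        "relative_error": float(abs(counts.mean() - lam) / lam) if lam else None,
    }
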