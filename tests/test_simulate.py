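"""Simulator ground truth: determinism, conservation, Poisson statistics,
compartment consistency and the rendered-PSF mass oracle."""

import numpy as np
import pandas as pd
import pytest

from aavfish import (
    ExpressionModel,
    InfectionModel,
    RenderParams,
    TissueParams,
    match_detections_to_truth,
    render_volume,
    simulate_expression,
    simulate_genomes,
    simulate_tissue,
)
from aavfish.simulate import CHANNEL_A, CHANNEL_B
from aavfish.volumes import LabelVolume


SMALL = TissueParams(shape=(24, 96, 96), n_cells=40)


class TestTissue:
    def test_zero_cells_gives_empty_world(self):
        labels, nuclei, cells = simulate_tissue(
            TissueParams(shape=(8, 16, 16), n_cells=0), 1
        )
        assert labels.data.max() == 0 and nuclei.data.max() == 0
        assert len(cells) == 0

    def test_deterministic_and_correct_label_count(self):
        a = simulate_tissue(SMALL, 1)
        b = simulate_tissue(SMALL, 1)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        assert len(a[0].labels()) == SMALL.n_cells

    def test_cell_volumes_equal_direct_recount(self):
        labels, _, cells = simulate_tissue(SMALL, 1)
        recount = np.bincount(labels.data.ravel())
        for _, row in cells.iterrows():
            assert row["n_voxels"] == recount[int(row["cell_id"])]
            assert row["volume_um3"] == pytest.approx(
                recount[int(row["cell_id"])] * labels.voxel_volume
            )

    def test_nuclei_sit_inside_their_own_cells(self):
        labels, nuclei, _ = simulate_tissue(SMALL, 2)
        nz = nuclei.data > 0
        assert np.all(labels.data[nz] == nuclei.data[nz])

    def test_unplaceable_cell_count_raises(self):
        with pytest.raises(RuntimeError, match="could not place"):
            simulate_tissue(TissueParams(shape=(8, 24, 24), n_cells=500), 1)


class TestGenomes:
    def test_lambda_zero_yields_no_puncta(self):
        labels, nuclei, _ = simulate_tissue(SMALL, 1)
        truth = simulate_genomes(labels, nuclei, InfectionModel(lam=0.0), 3)
        assert len(truth.puncta) == 0
        assert (truth.cell_counts["true_count"] == 0).all()

    def test_nuclear_fraction_one_puts_everything_in_nuclei(self):
        labels, nuclei, _ = simulate_tissue(SMALL, 1)
        truth = simulate_genomes(
            labels, nuclei, InfectionModel(lam=2.0, nuclear_fraction=1.0), 3
        )
        assert (truth.puncta["compartment"] == "nuclear").all()

    def test_poisson_mean_within_standard_error(self):
        # many cells, coarse voxels: CLT check of the count model
        tp = TissueParams(shape=(60, 120, 120), voxel_size=(0.8, 0.8, 0.8),
                          n_cells=2000, nucleus_radius=2.0, slab_fraction=1.0)
        labels, nuclei, _ = simulate_tissue(tp, 1)
        lam = 2.0
        truth = simulate_genomes(labels, nuclei, InfectionModel(lam=lam), 3)
        mean = truth.cell_counts["true_count"].mean()
        se = np.sqrt(lam / tp.n_cells)
        assert abs(mean - lam) < 3 * se

    def test_compartment_flags_agree_with_nucleus_mask(self, scene):
        truth, nuclei = scene["truth"], scene["nuclei"]
        vox = np.floor(
            truth.puncta[["z", "y", "x"]].to_numpy()
            / np.asarray(nuclei.voxel_size)
        ).astype(int)
        in_nuc = nuclei.data[tuple(vox.T)] > 0
        assert np.array_equal(in_nuc, truth.puncta["compartment"] == "nuclear")

    def test_puncta_lie_inside_their_assigned_cells(self, scene):
        truth, labels = scene["truth"], scene["labels"]
        vox = np.floor(
            truth.puncta[["z", "y", "x"]].to_numpy()
            / np.asarray(labels.voxel_size)
        ).astype(int)
        assert np.array_equal(
            labels.data[tuple(vox.T)], truth.puncta["cell_id"].to_numpy()
        )

    def test_titer_scale_multiplies_expected_count(self):
        labels, nuclei, _ = simulate_tissue(SMALL, 1)
        base = InfectionModel(lam=1.0, titer_scale=4.0)
        truth = simulate_genomes(labels, nuclei, base, 5)
        # 40 cells at mean 4: SE = sqrt(4/40) ~ 0.32
        assert truth.cell_counts["true_count"].mean() == pytest.approx(4.0, abs=1.0)

    def test_co_located_pairs_share_pair_id_and_stay_close(self):
        labels, nuclei, _ = simulate_tissue(SMALL, 1)
        model = InfectionModel(lam=2.0, coloc_mode="co_located",
                               coloc_offset_sigma=0.05)
        truth = simulate_genomes(labels, nuclei, model, 7)
        a = truth.puncta[truth.puncta["channel"] == CHANNEL_A]
        b = truth.puncta[truth.puncta["channel"] == CHANNEL_B]
        assert len(a) == len(b) and len(a) > 0
        merged = a.merge(b, on="pair_id", suffixes=("_a", "_b"))
        d = np.linalg.norm(
            merged[["z_a", "y_a", "x_a"]].to_numpy()
            - merged[["z_b", "y_b", "x_b"]].to_numpy(), axis=1)
        assert np.all(d <= 5 * 0.05 + 1e-9)

    def test_independent_mode_draws_unpaired_channels(self):
        labels, nuclei, _ = simulate_tissue(SMALL, 1)
        truth = simulate_genomes(
            labels, nuclei, InfectionModel(lam=2.0, coloc_mode="independent"), 7
        )
        assert set(truth.puncta["channel"]) == {CHANNEL_A, CHANNEL_B}
        assert (truth.puncta["pair_id"] == -1).all()


class TestRender:
    def test_no_puncta_no_background_is_zero(self, scene):
        labels, nuclei = scene["labels"], scene["nuclei"]
        empty = simulate_genomes(labels, nuclei, InfectionModel(lam=0.0), 1)
        rp = RenderParams(background=0.0, noise="none")
        vol = render_volume(labels, nuclei, empty, rp, 1)
        assert np.all(vol.channel(CHANNEL_A) == 0)

    def test_single_spot_mass_matches_separable_gaussian_sum(self):
        labels = LabelVolume(np.ones((24, 48, 48), dtype=np.int32), (0.4, 0.2, 0.2))
        nuclei = LabelVolume(np.zeros((24, 48, 48), dtype=np.int32), (0.4, 0.2, 0.2))
        pos = np.array([4.83, 4.61, 4.37])  # um, off-grid
        puncta = pd.DataFrame([{
            "genome_id": 0, "pair_id": 0, "cell_id": 1, "channel": CHANNEL_A,
            "z": pos[0], "y": pos[1], "x": pos[2],
            "compartment": "cytoplasmic", "present": True,
        }])
        counts = pd.DataFrame([{"cell_id": 1, "channel": CHANNEL_A, "true_count": 1}])
        from aavfish.simulate import GroundTruth
        truth = GroundTruth(puncta, counts, InfectionModel(lam=1.0))
        rp = RenderParams(background=0.0, noise="none", membrane_amplitude=0.0)
        vol = render_volume(labels, nuclei, truth, rp, 1)
        sigma_vox = np.asarray(rp.psf_sigma) / np.asarray(labels.voxel_size)
        center = pos / np.asarray(labels.voxel_size) - 0.5
        expected = rp.punctum_amplitude * np.prod([
            np.exp(-0.5 * ((np.arange(n) - c) / s) ** 2).sum()
            for n, c, s in zip(labels.shape, center, sigma_vox)
        ])
        assert vol.channel(CHANNEL_A).sum() == pytest.approx(expected, rel=1e-3)

    def test_same_seed_bit_identical(self, scene):
        rp = RenderParams()
        v1 = render_volume(scene["labels"], scene["nuclei"], scene["truth"], rp, 9)
        v2 = render_volume(scene["labels"], scene["nuclei"], scene["truth"], rp, 9)
        assert np.array_equal(v1.data, v2.data)

    def test_unresolvable_psf_rejected(self, scene):
        rp = RenderParams(psf_sigma=(0.05, 0.15, 0.15))
        with pytest.raises(ValueError, match="0.25 voxel"):
            render_volume(scene["labels"], scene["nuclei"], scene["truth"], rp, 1)

    def test_spot_conservation_per_channel(self, scene):
        """Rendered spot count equals truth rows with the presence flag."""
        truth = scene["truth"]
        n_present = int(truth.rendered(CHANNEL_A).shape[0])
        assert n_present == int(
            (truth.puncta["present"] & (truth.puncta["channel"] == CHANNEL_A)).sum()
        )


class TestExpression:
    def test_zero_baseline_zero_count_zero_noise(self):
        em = ExpressionModel(baseline=0.0, noise_sigma=0.0)
        assert em.mean(0) == 0.0

    def test_monotone_in_count_below_saturation(self):
        em = ExpressionModel(noise_sigma=0.0)
        means = em.mean(np.arange(0, 8))
        assert np.all(np.diff(means) > 0)

    def test_empirical_mean_matches_model_clt(self):
        em = ExpressionModel(noise_sigma=20.0)
        n = 5000
        counts = pd.DataFrame({
            "cell_id": np.arange(n), "channel": CHANNEL_A,
            "true_count": np.full(n, 3),
        })
        from aavfish.simulate import GroundTruth
        truth = GroundTruth(pd.DataFrame(columns=["channel", "present"]),
                            counts, InfectionModel(lam=1.0))
        out = simulate_expression(truth, em, 9)
        se = em.noise_sigma / np.sqrt(n)
        assert abs(out["expression"].mean() - em.mean(3)) < 3 * se


class TestTruthMatching:
    def test_identity_detection_scores_perfectly(self, scene):
        det = scene["truth"].rendered(CHANNEL_A)[["z", "y", "x"]].copy()
        det["channel"] = CHANNEL_A
        m = match_detections_to_truth(det, scene["truth"], radius=0.2)
        assert m["recall"] == 1.0 and m["precision"] == 1.0
        assert m["mean_localization_error"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_detection_gives_zero_recall_null_precision(self, scene):
        det = pd.DataFrame(columns=["channel", "z", "y", "x"])
        m = match_detections_to_truth(det, scene["truth"], radius=0.2)
        assert m["recall"] == 0.0 and m["precision"] is None

    def test_jitter_below_half_radius_all_matched_with_oracle_error(self, scene):
        rng = np.random.default_rng(0)
        truth_pos = scene["truth"].rendered(CHANNEL_A)[["z", "y", "x"]].to_numpy()
        radius = 0.4
        jitter = rng.uniform(-radius / (2 * np.sqrt(3)), radius / (2 * np.sqrt(3)),
                             truth_pos.shape)
        det = pd.DataFrame(truth_pos + jitter, columns=["z", "y", "x"])
        det["channel"] = CHANNEL_A
        m = match_detections_to_truth(det, scene["truth"], radius=radius)
        assert m["recall"] == 1.0
        # oracle: per-point displacement magnitudes (pairing is unambiguous
        # because jitter is far below inter-punctum distances in most cases)
        expected = np.linalg.norm(jitter, axis=1).mean()
        assert m["mean_localization_error"] == pytest.approx(expected, rel=0.05)
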