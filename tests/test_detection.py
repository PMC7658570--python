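"""LoG spot calling: response properties, thresholding, separation rule,
cell/compartment assignment and count conservation."""

import numpy as np
import pandas as pd
import pytest

from aavfish import (
    DetectionParams,
    InfectionModel,
    RenderParams,
    TissueParams,
    assign_puncta,
    call_puncta,
    log_response,
    match_detections_to_truth,
    per_cell_counts,
    render_volume,
    simulate_genomes,
    simulate_tissue,
)
from aavfish.detect import detect_puncta
from aavfish.simulate import CHANNEL_A, GroundTruth, tissue_mask_for
from aavfish.volumes import LabelVolume

VS = (0.4, 0.2, 0.2)


def _spot_volume(positions_um, amplitude=800.0, shape=(24, 64, 64),
                 sigma=(0.4, 0.15, 0.15), background=0.0):
    from aavfish.simulate import _add_spots
    canvas = np.zeros(shape)
    _add_spots(canvas, np.atleast_2d(positions_um), amplitude,
               np.asarray(sigma) / np.asarray(VS), np.asarray(VS))
    return canvas + background


class TestLogResponse:
    def test_constant_volume_has_zero_response(self):
        resp, _ = log_response(np.full((16, 32, 32), 5.0), VS, [0.15])
        # zero up to the truncated-kernel float residue
        assert np.allclose(resp, 0.0, atol=1e-3 * 5.0)

    def test_linearity_in_intensity(self):
        img = _spot_volume([4.8, 6.4, 6.4])
        r1, _ = log_response(img, VS, [0.15])
        r2, _ = log_response(2.0 * img, VS, [0.15])
        assert np.allclose(r2, 2.0 * r1, rtol=1e-9)

    def test_peak_at_spot_center_and_matched_scale(self):
        """A spot of PSF size sigma peaks at its center at the list scale
        nearest sigma (scales +/-50% around it)."""
        vs = (0.2, 0.1, 0.1)  # fine grid so the scale space is well sampled
        pos = np.array([3.2, 3.2, 3.2])
        sigma_spot = 0.2
        from aavfish.simulate import _add_spots
        img = np.zeros((32, 64, 64))
        _add_spots(img, pos[None], 800.0,
                   np.array([sigma_spot * 0.4 / 0.15, sigma_spot, sigma_spot])
                   / np.asarray(vs), np.asarray(vs))
        scales = [0.1, 0.2, 0.3]
        resp, arg = log_response(img, vs, scales)
        peak = np.unravel_index(resp.argmax(), resp.shape)
        center_vox = pos / np.asarray(vs) - 0.5
        assert np.all(np.abs(np.asarray(peak) - center_vox) <= 1.0)
        assert arg[peak] == 1

    def test_unresolvable_scale_rejected(self):
        with pytest.raises(ValueError, match="0.25 voxel"):
            log_response(np.zeros((8, 16, 16)), VS, [0.01])


class TestCallPuncta:
    def test_blank_volume_empty_table(self):
        img = np.zeros((16, 32, 32))
        resp, _ = log_response(img, VS, [0.15])
        out = call_puncta(resp, img, VS)
        assert len(out) == 0

    def test_separation_rule_merges_close_pairs(self):
        params = DetectionParams(min_separation=0.5)
        far = _spot_volume([[4.8, 4.0, 4.0], [4.8, 4.0, 5.6]])  # 1.6 um apart
        resp, _ = log_response(far, VS, params.scales)
        assert len(call_puncta(resp, far, VS, params)) == 2
        near = _spot_volume([[4.8, 4.0, 4.0], [4.8, 4.0, 4.2]])  # 0.2 um apart
        resp, _ = log_response(near, VS, params.scales)
        assert len(call_puncta(resp, near, VS, params)) == 1

    def test_raising_k_never_increases_detections(self, scene):
        vol, mask = scene["volume"], scene["mask"]
        img = vol.channel(CHANNEL_A)
        resp, _ = log_response(img, vol.voxel_size, DetectionParams().scales)
        n_prev = np.inf
        for k in (2.0, 5.0, 10.0, 25.0):
            n = len(call_puncta(resp, img, vol.voxel_size,
                                DetectionParams(k=k), tissue_mask=mask))
            assert n <= n_prev
            n_prev = n

    def test_sparse_spots_at_snr10_recovered(self):
        """20 rendered spots at amplitude/noise-SD 10: recall and precision
        >= 0.95 within a 2-voxel matching radius."""
        rng = np.random.default_rng(5)
        shape = (32, 96, 96)
        extent = np.asarray(shape) * np.asarray(VS)
        pos = rng.uniform([2, 2, 2], extent - 2, size=(20, 3))
        background = 100.0
        amplitude = 10.0 * np.sqrt(background)  # SNR 10 vs shot noise
        img = _spot_volume(pos, amplitude=amplitude, shape=shape,
                           background=background)
        img = rng.poisson(img).astype(float)
        det = detect_puncta_like(img)
        truth = _truth_from_positions(pos)
        m = match_detections_to_truth(det, truth, radius=0.8)  # 2 voxels (z)
        assert m["recall"] >= 0.95
        assert m["precision"] >= 0.95


def detect_puncta_like(img):
    params = DetectionParams()
    resp, _ = log_response(img, VS, params.scales, params.axial_ratio)
    out = call_puncta(resp, img, VS, params)
    out["channel"] = CHANNEL_A
    return out


def _truth_from_positions(pos):
    puncta = pd.DataFrame({
        "genome_id": np.arange(len(pos)), "pair_id": -1, "cell_id": 1,
        "channel": CHANNEL_A, "z": pos[:, 0], "y": pos[:, 1], "x": pos[:, 2],
        "compartment": "cytoplasmic", "present": True,
    })
    counts = pd.DataFrame([{"cell_id": 1, "channel": CHANNEL_A,
                            "true_count": len(pos)}])
    return GroundTruth(puncta, counts, InfectionModel(lam=1.0))


class TestAssignment:
    @pytest.fixture()
    def world(self):
        labels = np.zeros((12, 24, 24), dtype=np.int32)
        labels[2:10, 2:12, 2:22] = 1
        labels[2:10, 12:22, 2:22] = 2
        nuclei = np.zeros_like(labels)
        nuclei[4:8, 4:8, 4:8] = 1
        lv = LabelVolume(labels, VS)
        nv = LabelVolume(nuclei, VS)
        from aavfish import build_cell_table
        return lv, nv, build_cell_table(lv)

    def test_background_punctum_is_extracellular(self, world):
        lv, nv, table = world
        p = pd.DataFrame([{"punctum_id": 0, "channel": CHANNEL_A,
                           "z": 0.1, "y": 0.1, "x": 0.1}])
        out = assign_puncta(p, lv, nv, table)
        assert pd.isna(out.loc[0, "cell_id"])
        assert out.loc[0, "compartment"] == "extracellular"
        assert not out.loc[0, "retained"]

    def test_nuclear_punctum_flagged_nuclear(self, world):
        lv, nv, table = world
        p = pd.DataFrame([{"punctum_id": 0, "channel": CHANNEL_A,
                           "z": 2.2, "y": 1.2, "x": 1.2}])  # voxel (5,6,6)
        out = assign_puncta(p, lv, nv, table)
        assert out.loc[0, "cell_id"] == 1
        assert out.loc[0, "compartment"] == "nuclear"

    def test_random_puncta_match_array_lookup_oracle(self, world):
        lv, nv, table = world
        rng = np.random.default_rng(1)
        extent = np.asarray(lv.shape) * np.asarray(VS)
        pos = rng.uniform(0, extent - 1e-6, size=(1000, 3))
        p = pd.DataFrame(pos, columns=["z", "y", "x"])
        p.insert(0, "punctum_id", np.arange(len(p)))
        p["channel"] = CHANNEL_A
        out = assign_puncta(p, lv, nv, table)
        vox = np.floor(pos / np.asarray(VS)).astype(int)
        cells_oracle = lv.data[tuple(vox.T)]
        nuc_oracle = nv.data[tuple(vox.T)] > 0
        got = out["cell_id"].fillna(0).to_numpy(dtype=int)
        assert np.array_equal(got, cells_oracle)
        assert np.array_equal(out["compartment"] == "nuclear", nuc_oracle)

    def test_grid_mismatch_rejected(self, world):
        lv, _, table = world
        bad = LabelVolume(np.zeros((2, 2, 2), dtype=np.int32), VS)
        p = pd.DataFrame([{"punctum_id": 0, "channel": CHANNEL_A,
                           "z": 1, "y": 1, "x": 1}])
        with pytest.raises(ValueError, match="grid"):
            assign_puncta(p, lv, bad, table)


class TestNucleusAssignment:
    def test_nearest_nucleus_within_radius_else_unassigned(self):
        from aavfish.detect import assign_puncta_to_nuclei

        nuclei = np.zeros((12, 24, 24), dtype=np.int32)
        nuclei[5:7, 4:8, 4:8] = 1    # centroid near (2.4, 1.1, 1.1) um
        nuclei[5:7, 16:20, 16:20] = 2
        nv = LabelVolume(nuclei, VS)
        p = pd.DataFrame({
            "punctum_id": [0, 1, 2],
            "z": [2.4, 2.4, 0.2],
            "y": [1.5, 3.4, 0.2],   # near n1, near n2, far from both
            "x": [1.5, 3.4, 0.2],
        })
        out = assign_puncta_to_nuclei(p, nv, max_radius=1.5)
        assert out.loc[0, "nucleus_id"] == 1
        assert out.loc[1, "nucleus_id"] == 2
        assert pd.isna(out.loc[2, "nucleus_id"])


class TestPerCellCounts:
    def test_no_puncta_zero_fill_over_included_cells(self, scene):
        from aavfish import build_cell_table
        table = scene["cells"]
        empty = pd.DataFrame(columns=["punctum_id", "channel", "cell_id",
                                      "retained"])
        out = per_cell_counts(empty, table, channel=None)
        assert len(out) == int(table["included"].sum())
        assert (out["count"] == 0).all()

    def test_counts_conserve_retained_puncta(self, scene):
        vol, mask, table = scene["volume"], scene["mask"], scene["cells"]
        det = detect_puncta(vol, CHANNEL_A, tissue_mask=mask)
        asg = assign_puncta(det, scene["labels"], scene["nuclei"], table)
        out = per_cell_counts(asg, table, channel=CHANNEL_A)
        assert out["count"].sum() == int(asg["retained"].sum())
        assert set(out["cell_id"]) == set(table.loc[table["included"], "cell_id"])

    def test_matches_groupby_oracle(self, scene):
        rng = np.random.default_rng(2)
        table = scene["cells"]
        included = table.loc[table["included"], "cell_id"].to_numpy()
        cells = rng.choice(included, size=200)
        asg = pd.DataFrame({
            "punctum_id": np.arange(200), "channel": CHANNEL_A,
            "cell_id": cells, "retained": True,
        })
        out = per_cell_counts(asg, table, channel=CHANNEL_A).set_index("cell_id")
        oracle = pd.Series(cells).value_counts()
        for cid in included:
            assert out.loc[cid, "count"] == int(oracle.get(cid, 0))
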