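"""Classical segmentation backend, features and the localization score."""

import numpy as np
import pytest

from eventscope import (CameraConfig, ChannelSettings, Frame, count_cells,
                        extract_features, nuclear_localization_score,
                        segment_cells, top_quartile_nucleus_mask)
from eventscope.sample import _relax

from conftest import BF, bf_frame, make_colony, make_scope


def frame_from(pixels, channel=BF):
    from eventscope import StagePose
    return Frame(pixels=np.asarray(pixels, np.uint16),
                 channel_settings=channel, stage=StagePose(), t_sim=0.0)


class TestSegmentCells:
    def test_wrong_channel_rejected(self):
        fr = frame_from(np.zeros((32, 32)),
                        ChannelSettings("GFP", 150.0, 100.0))
        with pytest.raises(ValueError):
            segment_cells(fr)

    def test_blank_frame_yields_zero_regions(self):
        fr = frame_from(np.full((64, 64), 1000))
        assert count_cells(segment_cells(fr)) == 0

    def test_exact_count_and_centroids_on_noise_free_scene(self, scatter_scene):
        state, mic = scatter_scene
        labels = segment_cells(bf_frame(mic))
        assert count_cells(labels) == state.count() == 12
        feats = extract_features(labels, {})
        gt = [mic._to_px(c.centroid) for c in state.cells]
        for f in feats:
            d = min(np.hypot(f.centroid[0] - g[0], f.centroid[1] - g[1])
                    for g in gt)
            assert d <= 2.0

    def test_touching_pair_is_split_by_watershed(self, quiet_camera):
        state = make_colony(2, seed=1, half_um=16.0, cycle_randomized=False)
        state.cells[0].centroid = np.array([-1.5, 0.0])
        state.cells[1].centroid = np.array([1.5, 0.0])
        state.cells[0].radius = state.cells[1].radius = 2.0  # 1.5 radii apart
        mic = make_scope(state, quiet_camera)
        assert count_cells(segment_cells(bf_frame(mic))) == 2

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_count_error_within_5pct_at_snr_5(self, seed):
        cam = CameraConfig(width=256, height=256, read_noise_sd=90.0)
        half = cam.width * cam.pixel_size_um / 2 - 4
        state = make_colony(24, seed=seed, half_um=half,
                            cycle_randomized=False)
        for _ in range(30):
            _relax(state)
        mic = make_scope(state, cam, seed=seed)
        fr = bf_frame(mic, noise=True)
        err = abs(count_cells(segment_cells(fr)) - state.count())
        assert err / state.count() <= 0.05


class TestFeatures:
    def test_count_cells_on_label_values(self):
        assert count_cells(np.zeros((8, 8), int)) == 0
        lab = np.zeros((8, 8), int)
        lab[0, 0], lab[2, 2], lab[5, 5] = 1, 2, 3
        assert count_cells(lab) == 3

    def test_mean_intensity_is_arithmetic_mean(self):
        lab = np.zeros((4, 10), int)
        lab[0, :] = 1
        px = np.zeros((4, 10))
        px[0, :] = np.arange(10)
        feats = extract_features(lab, {"GFP": frame_from(px)})
        assert feats[0].mean_intensity["GFP"] == pytest.approx(4.5)

    def test_shape_mismatch_rejected(self):
        lab = np.ones((8, 8), int)
        with pytest.raises(ValueError):
            extract_features(lab, {"GFP": frame_from(np.zeros((4, 4)))})

    def test_relabeling_permutes_but_preserves_measurements(self):
        rng = np.random.default_rng(0)
        lab = np.zeros((32, 32), int)
        lab[2:8, 2:8], lab[12:20, 12:22], lab[24:30, 2:12] = 1, 2, 3
        px = frame_from(rng.integers(0, 1000, (32, 32)))
        perm = {1: 3, 2: 1, 3: 2}
        lab2 = np.zeros_like(lab)
        for a, b in perm.items():
            lab2[lab == a] = b
        f1 = extract_features(lab, {"x": px})
        f2 = extract_features(lab2, {"x": px})
        key = lambda f: (f.area_px, f.centroid, f.mean_intensity["x"])
        assert sorted(map(key, f1)) == sorted(map(key, f2))

    def test_tagged_cells_stand_out_in_rfp(self, quiet_camera):
        state = make_colony(8, seed=9, half_um=12.0, cycle_randomized=False)
        for c in state.cells[:4]:
            c.rfp_tagged = True
        for _ in range(30):
            _relax(state)
        mic = make_scope(state, quiet_camera)
        labels = mic.render_labels()
        rfp = mic.acquire(ChannelSettings("RFP", 150.0, 100.0))
        feats = extract_features(labels, {"RFP": rfp})
        tagged = {c.id for c in state.cells if c.rfp_tagged}
        hi = [f.mean_intensity["RFP"] for f in feats if f.label in tagged]
        lo = [f.mean_intensity["RFP"] for f in feats if f.label not in tagged]
        # contrast far exceeds 5x the read-noise SD
        assert min(hi) - max(lo) > 5 * quiet_camera.read_noise_sd + 20


class TestNuclearLocalizationScore:
    def test_uniform_signal_scores_one(self):
        cell = np.zeros((16, 16), bool)
        cell[4:12, 4:12] = True
        nuc = np.zeros_like(cell)
        nuc[6:10, 6:10] = True
        gfp = np.full((16, 16), 123.0)
        assert nuclear_localization_score(cell, nuc, gfp) == pytest.approx(1.0)

    def test_concentrated_signal_scores_area_ratio(self):
        cell = np.zeros((16, 16), bool)
        cell[4:12, 4:12] = True          # 64 px
        nuc = np.zeros_like(cell)
        nuc[6:10, 6:10] = True           # 16 px = 1/4 of the cell
        gfp = np.zeros((16, 16))
        gfp[nuc] = 40.0
        assert nuclear_localization_score(cell, nuc, gfp) == pytest.approx(4.0)

    def test_invariant_to_zero_offset_rescaling(self):
        rng = np.random.default_rng(1)
        cell = np.zeros((16, 16), bool)
        cell[2:14, 2:14] = True
        nuc = np.zeros_like(cell)
        nuc[5:9, 5:9] = True
        gfp = rng.uniform(1, 100, (16, 16))
        s1 = nuclear_localization_score(cell, nuc, gfp)
        s2 = nuclear_localization_score(cell, nuc, 7.3 * gfp)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_empty_and_escaping_masks_rejected(self):
        cell = np.zeros((8, 8), bool)
        cell[2:6, 2:6] = True
        with pytest.raises(ValueError):
            nuclear_localization_score(cell, np.zeros_like(cell), np.ones((8, 8)))
        outside = np.zeros_like(cell)
        outside[0, 0] = True
        with pytest.raises(ValueError):
            nuclear_localization_score(cell, outside, np.ones((8, 8)))

    def test_top_quartile_mask_tracks_bright_nucleus(self):
        cell = np.zeros((20, 20), bool)
        cell[2:18, 2:18] = True
        gfp = np.full((20, 20), 10.0)
        gfp[8:12, 8:12] = 100.0
        nuc = top_quartile_nucleus_mask(cell, gfp)
        assert nuc[9, 9] and not nuc[3, 3]
        assert nuc.sum() <= 0.30 * cell.sum()
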