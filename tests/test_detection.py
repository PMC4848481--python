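"""Detection, exclusion masks, linking and drift estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from mechcomp import SceneGeometry
from mechcomp import detection as det
from mechcomp import synthetic as syn


def _match(detections, scene, radius_px):
    """Greedy nearest matching of detections to ground-truth positions."""
    gt = scene.positions / scene.geometry.pixel_size
    found = detections[["x_px", "y_px"]].to_numpy(float)
    if not len(found):
        return 0, np.array([])
    d, idx = cKDTree(gt).query(found)
    ok = d <= radius_px
    matched = len(np.unique(idx[ok]))
    return matched, d[ok]


class TestDetectNuclei:
    def test_single_noiseless_spot_within_half_pixel(self, rect_geometry):
        from mechcomp import PointScene

        scene = PointScene(
            cell_id=[0],
            x=[50.0],
            y=[30.0],
            population=np.array(["cell"], dtype=object),
            geometry=rect_geometry,
        )
        stack = syn.render_images(scene, psf_sigma_px=2.0)
        d = det.detect_nuclei(stack.data[0], sigma_px=2.0)
        assert len(d) == 1
        assert d["x_px"].iloc[0] == pytest.approx(50.0, abs=0.5)
        assert d["y_px"].iloc[0] == pytest.approx(30.0, abs=0.5)

    def test_blank_frame_zero_detections(self):
        assert len(det.detect_nuclei(np.zeros((64, 64)), sigma_px=2.0)) == 0

    def test_hundred_cell_render_perfect_precision_recall(self, rendered_hundred):
        stack, scene = rendered_hundred
        d = det.detect_nuclei(stack.data[0], sigma_px=2.0, threshold_rel=0.2)
        assert len(d) == 100
        matched, errs = _match(d, scene, radius_px=2.0)
        assert matched == 100  # precision = recall = 1
        assert np.sqrt(np.mean(errs**2)) < 0.5

    def test_translation_equivariance(self, rendered_hundred):
        stack, _ = rendered_hundred
        img = stack.data[0]
        shifted = np.roll(img, (5, 3), axis=(0, 1))
        a = det.detect_nuclei(img[:-8, :-8], sigma_px=2.0, threshold_rel=0.2)
        b = det.detect_nuclei(shifted[5:-3, 3:-5], sigma_px=2.0, threshold_rel=0.2)
        # same crop content, so identical detections
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True), atol=1e-9
        )

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            det.detect_nuclei(np.zeros((8, 8)), sigma_px=0.0)
        with pytest.raises(ValueError):
            det.detect_nuclei(np.zeros((8, 8)), sigma_px=1.0, threshold_rel=1.5)


class TestExclusion:
    def test_empty_mask_is_identity(self, rendered_hundred):
        stack, _ = rendered_hundred
        d = det.detect_nuclei(stack.data[0], sigma_px=2.0, threshold_rel=0.2)
        mask = np.zeros(stack.data[0].shape, dtype=bool)
        filtered, area = det.apply_exclusion(d, mask, pixel_size=1.0)
        assert len(filtered) == len(d)
        assert area[0] == pytest.approx(300.0 * 300.0)

    def test_full_mask_removes_everything(self, rendered_hundred):
        stack, _ = rendered_hundred
        d = det.detect_nuclei(stack.data[0], sigma_px=2.0, threshold_rel=0.2)
        mask = np.ones(stack.data[0].shape, dtype=bool)
        filtered, area = det.apply_exclusion(d, mask, pixel_size=1.0)
        assert len(filtered) == 0
        assert area[0] == 0.0

    def test_half_mask_halves_count_density_preserved(self):
        geom = SceneGeometry(shape="rectangle", width=400.0, height=400.0)
        scene = syn.make_monolayer(geom, 30.0, min_spacing=0.0, seed=4)
        d = pd.DataFrame(
            {"frame": 0, "x_px": scene.x, "y_px": scene.y, "peak_intensity": 1.0}
        )
        mask = np.zeros((400, 400), dtype=bool)
        mask[:, 200:] = True
        filtered, area = det.apply_exclusion(d, mask, pixel_size=1.0)
        n = scene.n_cells
        assert abs(len(filtered) - n / 2) < 3 * np.sqrt(n * 0.25)
        dens_full = n / (400 * 400 / 1e4)
        dens_half = len(filtered) / (area[0] / 1e4)
        assert dens_half == pytest.approx(dens_full, rel=0.15)


class TestLinking:
    def test_two_drifting_cells_two_clean_tracks(self):
        rows = []
        for f in range(10):
            rows.append((f, 10.0 + f, 50.0))
            rows.append((f, 110.0 + f, 50.0))
        d = pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
        ts = det.link_tracks(d, max_disp_um=5.0)
        assert ts.n_tracks == 2
        for _, tr in ts.iter_tracks():
            assert len(tr) == 10
            assert np.ptp(tr["y_um"]) == 0  # no identity swaps across the gap

    def test_single_cell_full_track(self):
        d = pd.DataFrame({"frame": range(10), "x_px": 5.0, "y_px": 5.0})
        ts = det.link_tracks(d, max_disp_um=1.0)
        assert ts.n_tracks == 1
        assert len(ts.df) == 10

    def test_row_order_permutation_invariant(self):
        rng = np.random.default_rng(0)
        rows = []
        for f in range(5):
            for i, x in enumerate([10.0, 60.0, 110.0]):
                rows.append((f, x + f, 20.0 * i))
        d = pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
        shuffled = d.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = det.link_tracks(d, max_disp_um=5.0).df
        b = det.link_tracks(shuffled, max_disp_um=5.0).df

        def signatures(df):
            return sorted(
                tuple(zip(tr["frame"], tr["x_um"], tr["y_um"]))
                for _, tr in df.groupby("cell_id")
            )

        # same partition into tracks, up to relabelling of track ids
        assert signatures(a) == signatures(b)

    def test_links_correct_against_generator_ground_truth(self):
        cfg = syn.load_preset("contact_migration")
        cfg.update(duration_h=4.0, t_contact_h=1.0, onset_lag_h=1.0)
        ts = syn.make_trajectories(cfg, seed=6)
        d = ts.df.rename(columns={"x_um": "x_px", "y_um": "y_px"})[
            ["frame", "x_px", "y_px"]
        ]
        linked = det.link_tracks(d, max_disp_um=6.0)
        # map linked ids back to true ids via frame-0 positions
        true0 = ts.df[ts.df["frame"] == 0]
        link0 = linked.df[linked.df["frame"] == 0]
        _, idx = cKDTree(true0[["x_um", "y_um"]].to_numpy()).query(
            link0[["x_um", "y_um"]].to_numpy()
        )
        mapping = dict(zip(link0["cell_id"], true0["cell_id"].to_numpy()[idx]))
        merged = linked.df.assign(true_id=linked.df["cell_id"].map(mapping)).merge(
            ts.df, on=["frame", "x_um", "y_um"], suffixes=("", "_gt")
        )
        correct = (merged["true_id"] == merged["cell_id_gt"]).mean()
        assert correct >= 0.99

    def test_every_detection_in_at_most_one_track(self):
        d = pd.DataFrame(
            {"frame": [0, 0, 1, 1], "x_px": [0.0, 50.0, 1.0, 51.0], "y_px": 0.0}
        )
        ts = det.link_tracks(d, max_disp_um=5.0)
        assert len(ts.df) == 4
        assert ts.df.groupby(["frame", "cell_id"]).size().max() == 1


class TestDrift:
    def _drifting_stack(self, step=(2.0, 0.0), n_frames=5):
        from conftest import inset_monolayer

        # generous margin so no spot is clipped at the largest drift
        base = inset_monolayer(200.0, 20.0, 25.0, 8.0, seed=8)
        scenes = []
        for t in range(n_frames):
            s = base.subset(np.ones(base.n_cells, dtype=bool))
            s.x = s.x + step[0] * t
            s.y = s.y + step[1] * t
            s.time = float(t)
            scenes.append(s)
        return scenes

    def test_constant_image_drift_recovered(self):
        scenes = self._drifting_stack()
        stacks = [syn.render_images(s, psf_sigma_px=2.0, seed=0).data[0] for s in scenes]
        drift = det.estimate_drift(np.stack(stacks))
        for t in range(5):
            assert drift[t, 0] == pytest.approx(2.0 * t, abs=0.1 * max(t, 1))
            assert drift[t, 1] == pytest.approx(0.0, abs=0.1 * max(t, 1))

    def test_static_stack_zero_drift(self, rendered_hundred):
        stack, _ = rendered_hundred
        data = np.repeat(stack.data, 3, axis=0)
        drift = det.estimate_drift(data)
        np.testing.assert_allclose(drift, 0.0, atol=1e-6)

    def test_detection_route_and_round_trip_registration(self):
        scenes = self._drifting_stack(step=(1.5, -1.0))
        df = pd.concat([s.to_dataframe() for s in scenes], ignore_index=True)
        drift = det.estimate_drift(df)
        assert drift[-1, 0] == pytest.approx(1.5 * 4, abs=0.2)
        assert drift[-1, 1] == pytest.approx(-1.0 * 4, abs=0.2)
        # subtracting the drift re-registers consecutive frames
        stack = np.stack(
            [syn.render_images(s, psf_sigma_px=2.0, seed=0).data[0] for s in scenes]
        )
        img_drift = det.estimate_drift(stack)
        reg = det.subtract_drift(stack, img_drift)
        residual = det.estimate_drift(reg)
        assert np.abs(np.diff(residual, axis=0)).max() < 0.2

    def test_featureless_frames_warn_zero_drift(self):
        data = np.zeros((3, 32, 32))
        with pytest.warns(UserWarning, match="featureless"):
            drift = det.estimate_drift(data)
        np.testing.assert_array_equal(drift, 0.0)
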