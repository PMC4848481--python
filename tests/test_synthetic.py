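"""Generator correctness: placement, copula, trajectories, deaths, counts."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp, spearmanr

from mechcomp import SceneGeometry
from mechcomp import density as den
from mechcomp import synthetic as syn


class TestMonolayer:
    def test_disc_count_matches_density_area_arithmetic(self, disc_geometry):
        scene = syn.make_monolayer(disc_geometry, 61.0, min_spacing=5.0, seed=0)
        assert scene.n_cells == round(61.0 * math.pi * 400.0**2 / 1e4) == 3066

    def test_zero_density_gives_empty_scene(self, rect_geometry):
        scene = syn.make_monolayer(rect_geometry, 0.0, min_spacing=5.0, seed=0)
        assert scene.n_cells == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hardcore_spacing_and_containment(self, rect_geometry, seed):
        scene = syn.make_monolayer(rect_geometry, 40.0, min_spacing=4.0, seed=seed)
        nn = cKDTree(scene.positions).query(scene.positions, k=2)[0][:, 1]
        assert nn.min() >= 4.0
        assert scene.geometry.contains(scene.x, scene.y).all()

    def test_global_density_recovers_preset(self, disc_geometry):
        scene = syn.make_monolayer(disc_geometry, 61.0, min_spacing=5.0, seed=3)
        g = den.global_density(scene)
        assert g.density == pytest.approx(61.0, abs=0.1)

    def test_deterministic_per_seed(self, rect_geometry):
        a = syn.make_monolayer(rect_geometry, 30.0, 5.0, seed=7)
        b = syn.make_monolayer(rect_geometry, 30.0, 5.0, seed=7)
        c = syn.make_monolayer(rect_geometry, 30.0, 5.0, seed=8)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert not np.array_equal(a.positions, c.positions)

    def test_infeasible_packing_raises_with_achievable_maximum(self, rect_geometry):
        with pytest.raises(ValueError, match="achievable maximum"):
            syn.make_monolayer(rect_geometry, 500.0, min_spacing=10.0, seed=0)


class TestCompetitionScene:
    def test_clone_density_ratio_within_five_percent(self):
        cfg = syn.load_preset("competition_scene")
        scene = syn.make_competition_scene(cfg, seed=1)
        rc = cfg["clone_radius"]
        n_clone = int((scene.population == "loser").sum())
        clone_density = n_clone / (math.pi * rc**2 / 1e4)
        ratio = clone_density / cfg["loser_pure_density"]
        assert ratio == pytest.approx(cfg["density_ratio_clone_vs_pure"], rel=0.05)

    def test_unit_ratio_clone_matches_pure_density(self):
        cfg = syn.load_preset("competition_scene")
        cfg["density_ratio_clone_vs_pure"] = 1.0
        scene = syn.make_competition_scene(cfg, seed=2)
        rc = cfg["clone_radius"]
        n_clone = int((scene.population == "loser").sum())
        clone_density = n_clone / (math.pi * rc**2 / 1e4)
        assert clone_density == pytest.approx(cfg["loser_pure_density"], rel=0.05)

    def test_cross_population_spacing_holds(self):
        scene = syn.make_competition_scene(seed=3)
        nn = cKDTree(scene.positions).query(scene.positions, k=2)[0][:, 1]
        assert nn.min() >= 4.0 - 1e-9

    def test_clone_overflow_raises(self):
        cfg = syn.load_preset("competition_scene")
        cfg["clone_radius"] = 300.0
        with pytest.raises(ValueError, match="does not fit"):
            syn.make_competition_scene(cfg, seed=0)


@pytest.fixture(scope="module")
def dense_scene():
    geom = SceneGeometry(shape="rectangle", width=1200.0, height=1200.0)
    return syn.make_monolayer(geom, 70.0, min_spacing=4.0, seed=5)


class TestMarkerCopula:
    def test_perfect_rank_corr_gives_spearman_one(self, small_scene):
        out = syn.make_marker_intensities(
            small_scene, 1.0, seed=0, sigma_um=50.0, radius_um=200.0
        )
        dens = den.local_density(out, den.LocalDensityParams(sigma=50, radius=200))
        assert spearmanr(dens, out.marker).statistic == pytest.approx(1.0)

    def test_zero_rank_corr_gives_near_zero_spearman(self, dense_scene):
        out = syn.make_marker_intensities(dense_scene, 0.0, seed=1)
        dens = den.local_density(out)
        assert abs(spearmanr(dens, out.marker).statistic) < 0.03

    def test_marginal_invariant_to_rank_corr(self, dense_scene):
        a = syn.make_marker_intensities(dense_scene, 0.0, seed=2).marker
        b = syn.make_marker_intensities(dense_scene, 0.9, seed=3).marker
        assert ks_2samp(a, b).pvalue > 0.01

    def test_intensities_positive_lognormal(self, dense_scene):
        out = syn.make_marker_intensities(dense_scene, 0.5, seed=4)
        assert (out.marker > 0).all()

    def test_degenerate_density_warns(self, rect_geometry):
        # three cells farther apart than the cutoff: all local densities 0
        from mechcomp import PointScene

        scene = PointScene(
            cell_id=[0, 1, 2],
            x=[10.0, 100.0, 190.0],
            y=[75.0, 75.0, 75.0],
            population=np.full(3, "cell", dtype=object),
            geometry=rect_geometry,
        )
        with pytest.warns(UserWarning, match="identical local density"):
            syn.make_marker_intensities(scene, 0.5, seed=0)

    def test_too_few_cells_raises(self, rect_geometry):
        from mechcomp import PointScene

        scene = PointScene(
            cell_id=[0],
            x=[10.0],
            y=[10.0],
            population=np.array(["cell"], dtype=object),
            geometry=rect_geometry,
        )
        with pytest.raises(ValueError):
            syn.make_marker_intensities(scene, 0.5, seed=0)


class TestTrajectories:
    def test_tracks_unbroken_and_conserved(self):
        ts = syn.make_trajectories(seed=1)
        n_frames = ts.df["frame"].nunique()
        lengths = ts.df.groupby("cell_id")["frame"].agg(["count", "min", "max"])
        assert (lengths["count"] == n_frames).all()
        assert (lengths["min"] == 0).all()

    def test_ground_truth_onsets_recorded(self):
        ts = syn.make_trajectories(seed=2)
        assert ts.meta["onset_loser_h"] - ts.meta["onset_winner_h"] == pytest.approx(2.0)

    def test_post_contact_directionality_exceeds_pre(self):
        from mechcomp.kinematics import trajectory_metrics

        ts = syn.make_trajectories(seed=3)
        t_on = ts.meta["onset_loser_h"]
        d_pre, d_post = [], []
        for _, tr in ts.iter_tracks():
            pre = tr[tr["time_h"] <= ts.meta["onset_winner_h"]]
            post = tr[tr["time_h"] >= t_on]
            d_pre.append(trajectory_metrics(pre).directionality)
            d_post.append(trajectory_metrics(post).directionality)
        assert np.mean(d_post) > np.mean(d_pre)

    def test_no_directed_motion_yields_no_change_point(self):
        from mechcomp.kinematics import detect_onset, project_displacement

        cfg = syn.load_preset("contact_migration")
        cfg["directed_fraction"] = 0.0
        cfg["post_contact_speed"] = cfg["pre_contact_speed"]
        ts = syn.make_trajectories(cfg, seed=4)
        fs = project_displacement(ts, np.array([1.0, 0.0]))
        assert detect_onset(fs["winner"]) is None

    def test_zero_duration_raises(self):
        cfg = syn.load_preset("contact_migration")
        cfg["duration_h"] = 0.0
        with pytest.raises(ValueError):
            syn.make_trajectories(cfg, seed=0)

    def test_deterministic_per_seed(self):
        a = syn.make_trajectories(seed=9).df
        b = syn.make_trajectories(seed=9).df
        assert a.equals(b)


class TestRendering:
    def test_single_spot_argmax_at_position(self, rect_geometry):
        from mechcomp import PointScene

        scene = PointScene(
            cell_id=[0],
            x=[50.0],
            y=[30.0],
            population=np.array(["cell"], dtype=object),
            geometry=rect_geometry,
        )
        stack = syn.render_images(scene, psf_sigma_px=2.0)
        y, x = np.unravel_index(np.argmax(stack.data[0]), stack.data[0].shape)
        assert (x, y) == (50, 30)

    def test_out_of_raster_cells_clipped_with_warning(self, rect_geometry):
        from mechcomp import PointScene

        scene = PointScene(
            cell_id=[0, 1],
            x=[50.0, 500.0],
            y=[30.0, 30.0],
            population=np.full(2, "cell", dtype=object),
            geometry=rect_geometry,
        )
        with pytest.warns(UserWarning, match="clipped"):
            stack = syn.render_images(scene, psf_sigma_px=2.0)
        assert stack.data.max() > 0

    def test_noise_model_and_determinism(self, small_scene):
        kw = dict(psf_sigma_px=2.0, noise_model={"poisson": True, "read_sigma": 5.0})
        a = syn.render_images(small_scene, seed=5, **kw)
        b = syn.render_images(small_scene, seed=5, **kw)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.data.dtype == np.uint16


class TestDeathEvents:
    def _series(self, n, seed=0):
        geom = SceneGeometry(shape="rectangle", width=2000.0, height=2000.0)
        base = syn.make_monolayer(geom, n / (geom.area / 1e4), min_spacing=0.0, seed=seed)
        end = base.subset(np.ones(base.n_cells, dtype=bool))
        end.time = 1.0
        return [base, end]

    def test_zero_baseline_rate_no_deaths(self):
        cfg = {"baseline_death_rate": 0.0, "compression_death_multiplier": 3.0}
        out = syn.make_death_events(cfg, self._series(1000), compressed=True, seed=0)
        assert syn.count_death_events(out) == (0, 1000)

    def test_unit_multiplier_matches_baseline(self):
        cfg = {"baseline_death_rate": 0.05, "compression_death_multiplier": 1.0}
        a = syn.make_death_events(cfg, self._series(20000), compressed=False, seed=1)
        b = syn.make_death_events(cfg, self._series(20000), compressed=True, seed=2)
        fa = syn.count_death_events(a)[0] / 20000
        fb = syn.count_death_events(b)[0] / 20000
        assert fb == pytest.approx(fa, rel=0.15)

    def test_excessive_rate_raises(self):
        cfg = {"baseline_death_rate": 0.6, "compression_death_multiplier": 3.0}
        with pytest.raises(ValueError, match="outside"):
            syn.make_death_events(cfg, self._series(100), compressed=True, seed=0)

    def test_multiplier_recovered_on_assay_pair(self):
        pair = syn.compression_assay_pair(seed=3)
        frac = {
            k: syn.count_death_events(v)[0] / syn.count_death_events(v)[1]
            for k, v in pair.items()
        }
        assert frac["compressed"] / frac["uncompressed"] == pytest.approx(3.0, abs=0.3)


class TestCountTimecourse:
    def test_zero_growth_zero_noise_is_constant(self):
        cfg = syn.load_preset("wt_homeostasis")
        cfg["growth_rate"] = 0.0
        cfg["noise_cv"] = 0.0
        cs = syn.make_count_timecourse(cfg, "homeostasis", seed=0)
        assert np.unique(cs.counts["cell"]).size == 1

    def test_counts_are_nonnegative_integers(self):
        for scenario in (
            "homeostasis",
            "loser_collapse",
            "treatment_monoculture",
            "treatment_competition",
        ):
            cs = syn.make_count_timecourse(None, scenario, seed=1)
            for c in cs.counts.values():
                assert np.issubdtype(c.dtype, np.integer)
                assert (c >= 0).all()

    def test_ground_truth_recorded(self):
        cs = syn.make_count_timecourse(None, "treatment_competition", seed=2)
        assert cs.meta["day6_fraction"] == pytest.approx(0.17)

    def test_loser_collapse_ends_below_peak(self):
        cs = syn.make_count_timecourse(None, "loser_collapse", seed=3)
        c = cs.counts["loser"]
        assert c[-1] < c.max()

    def test_unknown_scenario_raises(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            syn.make_count_timecourse(None, "zombie_apocalypse", seed=0)
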