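"""Generator tests: fibril geometry, cluster decoration, background, rendering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import goldpcf as gp
from goldpcf.simulate import LABEL_COLUMNS


def straight_config(**kw):
    base = dict(
        window=gp.Window2D(0, 2000, 0, 2000),
        n_fibrils=1,
        fibril_length_nm=850.0,
        max_turn_per_step=0.0,
        repeat_jitter_sd=0.0,
    )
    base.update(kw)
    return gp.SimulationConfig(**base)


class TestSimulateFibril:
    def test_zero_jitter_straight_fibril_spacing_exact(self):
        """A straight, jitter-free 850 nm fibril carries 10 beads 85 nm apart.

        With the first cluster inset half a repeat (42.5 nm) the arc positions
        are 42.5, 127.5, ..., 807.5: ten clusters, spacings exactly 85 nm.
        """
        # window much larger than the fibril so the walk cannot hit a wall
        rng = np.random.default_rng(0)
        fib = gp.simulate_fibril(
            straight_config(window=gp.Window2D(0, 20000, 0, 20000)), rng
        )
        assert fib.n_clusters == 10
        np.testing.assert_allclose(np.diff(fib.cluster_arc_positions), 85.0)
        # confirm the path really is straight, then chords equal arcs
        p = fib.polyline
        d = np.diff(p, axis=0)
        assert np.abs(d[:, 0] * d[0, 1] - d[:, 1] * d[0, 0]).max() < 1e-6
        centers = fib.cluster_centers()
        np.testing.assert_allclose(
            np.linalg.norm(np.diff(centers, axis=0), axis=1), 85.0, rtol=1e-9
        )

    def test_zero_offset_single_label_sits_on_bead_center(self, rng):
        fib = gp.simulate_fibril(
            straight_config(labels_per_cluster=1, label_offset_radius=0.0), rng
        )
        np.testing.assert_allclose(fib.label_points(), fib.cluster_centers())

    def test_labels_lie_on_offset_shell(self, rng):
        fib = gp.simulate_fibril(straight_config(), rng)
        np.testing.assert_allclose(
            np.linalg.norm(fib.label_offsets, axis=1), 9.0, rtol=1e-12
        )

    def test_arc_positions_strictly_increasing_with_jitter(self, rng):
        fib = gp.simulate_fibril(straight_config(repeat_jitter_sd=4.0), rng)
        assert (np.diff(fib.cluster_arc_positions) > 0).all()

    def test_six_bead_segments_arc_through_at_most_120_degrees(self):
        """Median net turning over a 6-bead (5-repeat) arc stays under 120 deg.

        Matches the observed curvature of collagen VI fibrils: even strongly
        curved segments of 6 beads arc through about 120 degrees, so the
        walk's default turn parameter must keep the median well below that.
        """
        rng = np.random.default_rng(99)
        cfg = gp.SimulationConfig(window=gp.Window2D(0, 4000, 0, 4000))
        turns = []
        for _ in range(500):
            fib = gp.simulate_fibril(cfg, rng)
            arcs = fib.cluster_arc_positions
            if len(arcs) < 6:
                continue
            # heading at the first and last bead of a 6-bead stretch
            p = fib.point_at_arc(
                np.array([arcs[0], arcs[0] + 1, arcs[5], arcs[5] + 1])
            )
            h0 = np.arctan2(p[1, 1] - p[0, 1], p[1, 0] - p[0, 0])
            h1 = np.arctan2(p[3, 1] - p[2, 1], p[3, 0] - p[2, 0])
            d = np.rad2deg(np.abs((h1 - h0 + np.pi) % (2 * np.pi) - np.pi))
            turns.append(d)
        assert len(turns) >= 400
        assert np.median(turns) <= 120.0

    def test_window_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match="repeat"):
            gp.simulate_fibril(
                straight_config(window=gp.Window2D(0, 50, 0, 50)), rng
            )

    def test_non_finite_config_rejected(self, rng):
        with pytest.raises(ValueError):
            gp.simulate_fibril(straight_config(repeat_d=np.nan), rng)

    def test_polyline_stays_inside_window(self):
        rng = np.random.default_rng(3)
        cfg = gp.SimulationConfig(
            window=gp.Window2D(0, 300, 0, 300), fibril_length_nm=2000.0
        )
        fib = gp.simulate_fibril(cfg, rng)
        assert cfg.window.contains(fib.polyline).all()


class TestBackgroundAndScene:
    def test_zero_intensity_empty(self, small_window, rng):
        assert len(gp.simulate_background(small_window, 0.0, rng)) == 0

    def test_negative_intensity_rejected(self, small_window, rng):
        with pytest.raises(ValueError):
            gp.simulate_background(small_window, -1e-6, rng)

    def test_poisson_count_calibration(self, small_window):
        """Mean count over 200 seeds stays within 3 sigma of intensity*area."""
        lam = 1000.0 / small_window.area  # expect 1000 points
        counts = [
            len(gp.simulate_background(small_window, lam, np.random.default_rng(s)))
            for s in range(200)
        ]
        assert abs(np.mean(counts) - 1000) < 3 * np.sqrt(1000) / np.sqrt(200) * 3

    def test_fixed_seed_reproducible(self, small_window):
        a = gp.simulate_background(small_window, 1e-3, np.random.default_rng(5))
        b = gp.simulate_background(small_window, 1e-3, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_scene_background_only_equals_background(self, small_window, rng):
        bg = gp.simulate_background(small_window, 1e-4, rng)
        scene = gp.assemble_scene([], bg, small_window)
        pd.testing.assert_frame_equal(
            scene, bg[LABEL_COLUMNS].reset_index(drop=True)
        )

    def test_scene_label_count_two_fibrils(self, rng):
        """2 interior fibrils x 10 clusters x 3 labels = 60 points, annotated."""
        cfg = straight_config(window=gp.Window2D(0, 4000, 0, 4000))
        fibs = [gp.simulate_fibril(cfg, rng) for _ in range(2)]
        scene = gp.assemble_scene(
            fibs, pd.DataFrame(columns=LABEL_COLUMNS), cfg.window
        )
        assert len(scene) == 60
        assert set(scene["fibril_id"]) == {0, 1}
        assert scene["cluster_id"].between(0, 9).all()

    def test_annotations_roundtrip_csv(self, tmp_path, small_window, rng):
        cfg = straight_config(window=small_window, fibril_length_nm=400.0)
        scene = gp.assemble_scene(
            [gp.simulate_fibril(cfg, rng)],
            gp.simulate_background(small_window, 1e-5, rng),
            small_window,
        )
        p = tmp_path / "labels.csv"
        from goldpcf.simulate import write_labels_csv, read_labels_csv

        write_labels_csv(scene, p)
        back = read_labels_csv(p)
        pd.testing.assert_frame_equal(scene, back, check_dtype=False)

    def test_scene_reproducible_bit_for_bit(self):
        cfg = gp.SimulationConfig(n_fibrils=5)
        a = gp.simulate_scene(cfg, seed=11).labels
        b = gp.simulate_scene(cfg, seed=11).labels
        pd.testing.assert_frame_equal(a, b)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=10, deadline=None)
    def test_all_scene_points_inside_window(self, seed):
        cfg = gp.SimulationConfig(n_fibrils=3, window=gp.Window2D(0, 600, 0, 600))
        scene = gp.simulate_scene(cfg, seed=seed)
        assert cfg.window.contains(scene.labels[["x_nm", "y_nm"]].to_numpy()).all()


class TestIntraClusterGeometry:
    def test_pair_distance_mode_near_twice_shell_radius(self):
        """Pairwise label distances within clusters peak at 2 rho ~ 18 nm.

        Chords between points at fixed radius rho with uniform angles have a
        density singular at 2 rho, so the empirical histogram mode over >1e4
        pairs must land in [16, 20] nm for rho = 9 nm.
        """
        rng = np.random.default_rng(42)
        cfg = gp.SimulationConfig(window=gp.Window2D(0, 4000, 0, 4000))
        dists = []
        while len(dists) < 3 * 10**4:
            fib = gp.simulate_fibril(cfg, rng)
            pts = fib.label_points()
            for c in range(fib.n_clusters):
                sub = pts[fib.label_cluster_index == c]
                for i in range(len(sub)):
                    for j in range(i + 1, len(sub)):
                        dists.append(np.linalg.norm(sub[i] - sub[j]))
        hist, edges = np.histogram(dists, bins=np.arange(0.0, 19.0, 1.0))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert 16.0 <= mode <= 20.0


class TestRenderVolume:
    def test_single_label_peak_at_center(self, rng):
        rc = gp.RenderConfig(volume_shape=(32, 32, 32), noise_sd=0.0)
        c = (16 + 0.5) * rc.voxel_size  # physical center of voxel index 16
        df = pd.DataFrame({"x_nm": [c], "y_nm": [c], "z_nm": [c]})
        vol, truth = gp.render_volume(df, rc, rng)
        assert vol.grid.argmax() == np.ravel_multi_index((16, 16, 16), vol.shape)
        np.testing.assert_allclose(truth.iloc[0], [16.0, 16.0, 16.0])

    def test_isotropic_blob_when_no_elongation(self, rng):
        rc = gp.RenderConfig(
            volume_shape=(33, 33, 33), elongation_factor=1.0, noise_sd=0.0
        )
        c = (16 + 0.5) * rc.voxel_size
        df = pd.DataFrame({"x_nm": [c], "y_nm": [c], "z_nm": [c]})
        vol, _ = gp.render_volume(df, rc, rng)
        gz = vol.grid[:, 16, 16]
        gy = vol.grid[16, :, 16]
        gx = vol.grid[16, 16, :]
        np.testing.assert_allclose(gz, gy, rtol=1e-6)
        np.testing.assert_allclose(gz, gx, rtol=1e-6)

    def test_elongation_doubles_fwhm_along_wedge(self, rng):
        """FWHM along the wedge axis is elongation_factor x the in-plane FWHM."""
        rc = gp.RenderConfig(
            volume_shape=(65, 65, 65), elongation_factor=2.0, noise_sd=0.0
        )
        c = (32 + 0.5) * rc.voxel_size
        df = pd.DataFrame({"x_nm": [c], "y_nm": [c], "z_nm": [c]})
        vol, _ = gp.render_volume(df, rc, rng)

        def fwhm(profile):
            x = np.arange(len(profile))
            half = profile.max() / 2
            above = x[profile >= half]
            return above[-1] - above[0]

        ratio = fwhm(vol.grid[:, 32, 32]) / fwhm(vol.grid[32, 32, :])
        assert ratio == pytest.approx(2.0, rel=0.15)  # voxel quantization

    def test_dark_polarity_minimum_at_label(self, rng):
        rc = gp.RenderConfig(volume_shape=(32, 32, 32), noise_sd=0.0, polarity="dark")
        c = (16 + 0.5) * rc.voxel_size
        df = pd.DataFrame({"x_nm": [c], "y_nm": [c], "z_nm": [c]})
        vol, _ = gp.render_volume(df, rc, rng)
        assert vol.grid.argmin() == np.ravel_multi_index((16, 16, 16), vol.shape)

    def test_point_outside_volume_rejected_by_name(self, rng):
        rc = gp.RenderConfig(volume_shape=(16, 16, 16))
        df = pd.DataFrame({"x_nm": [10.0, 9999.0], "y_nm": [10.0, 10.0],
                           "z_nm": [10.0, 10.0]})
        with pytest.raises(ValueError, match="index 1"):
            gp.render_volume(df, rc, rng)


class TestMrcIO:
    def test_volume_roundtrip_preserves_grid_and_voxel_size(self, tmp_path, rng):
        grid = rng.normal(size=(8, 12, 10)).astype(np.float32)
        vol = gp.TomogramVolume(grid=grid, voxel_size=2.4)
        p = tmp_path / "t.mrc"
        gp.write_mrc(vol, p)
        back = gp.read_mrc(p)
        np.testing.assert_allclose(back.grid, grid, rtol=1e-6)
        assert back.voxel_size == pytest.approx(2.4)
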