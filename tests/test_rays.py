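"""Cross-section frames, ray casting, series sampling, label stripping."""

import numpy as np
import pytest

from mhmmseg.rays import (
    ADVENTITIA,
    INTIMA,
    LUMEN,
    PATHOLOGY,
    N_SAMPLES,
    Ray,
    RayBoundsError,
    VesselAxis,
    build_series_table,
    cast_rays,
    cross_section_frame,
    label_series,
    ray_grid,
    sample_points,
    sample_series,
    strip_labels,
    wall_thickness_for_radius,
)
from mhmmseg.volume import Volume


def helix_axis(n=120, radius=5.0, pitch=12.0):
    t = np.linspace(0, 4 * np.pi, n)
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                           pitch * t / (2 * np.pi)])
    return VesselAxis(pts)


class TestAxis:
    def test_tangents_unit_norm(self):
        ax = helix_axis()
        np.testing.assert_allclose(np.linalg.norm(ax.tangents, axis=1), 1.0,
                                   atol=1e-9)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            VesselAxis(np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1.0]]))

    def test_nonunit_tangents_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError):
            VesselAxis(pts, tangents=np.array([[0, 0, 2.0], [0, 0, 2.0]]))


class TestFrames:
    def test_straight_axis_frame_spans_xy(self):
        ax = VesselAxis(np.column_stack([np.zeros(10), np.zeros(10),
                                         np.arange(10.0)]))
        u, v = cross_section_frame(ax, 3)
        assert abs(u[2]) < 1e-12 and abs(v[2]) < 1e-12
        assert abs(np.dot(u, v)) < 1e-12

    def test_frames_orthogonal_to_helix_tangent(self):
        ax = helix_axis()
        for i in range(len(ax)):
            u, v = cross_section_frame(ax, i)
            assert abs(np.dot(u, ax.tangents[i])) < 1e-9
            assert abs(np.dot(v, ax.tangents[i])) < 1e-9
            assert np.linalg.norm(np.cross(u, v) - ax.tangents[i]) < 1e-9

    def test_parallel_transport_is_smooth(self):
        ax = helix_axis()
        frames = ax.frames
        for i in range(1, len(ax)):
            cosang = np.clip(np.dot(frames[i - 1, 0], frames[i, 0]), -1, 1)
            assert np.degrees(np.arccos(cosang)) < 10.0

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            cross_section_frame(helix_axis(), 999)


class TestCastRays:
    def test_five_degrees_gives_72_rays(self):
        rays = cast_rays((np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
                         np.zeros(3), 5.0)
        assert len(rays) == 72

    def test_ninety_degrees_gives_axis_aligned_rays(self):
        u, v = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        rays = cast_rays((u, v), np.zeros(3), 90.0)
        dirs = np.array([r.direction for r in rays])
        np.testing.assert_allclose(dirs, [u, v, -u, -v], atol=1e-12)

    def test_first_sample_is_axis_point(self):
        origin = np.array([3.0, 4.0, 5.0])
        for ray in cast_rays((np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
                             origin, 45.0, step_mm=0.7):
            np.testing.assert_allclose(ray.points[0], origin)

    def test_nondivisor_step_rejected(self):
        with pytest.raises(ValueError):
            cast_rays((np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
                      np.zeros(3), 7.0)


class TestSampling:
    def test_constant_volume(self):
        vol = Volume(np.full((20, 20, 20), 7.0), (1, 1, 1))
        ray = Ray(np.array([10.0, 10.0, 2.0]), np.array([0, 0, 1.0]),
                  n_samples=10, step_mm=1.0)
        series = sample_series(vol, ray)
        np.testing.assert_allclose(series.intensities, 7.0)

    def test_linear_ramp_is_linear_in_sample_index(self):
        data = np.broadcast_to(np.arange(30.0)[:, None, None], (30, 8, 8)).copy()
        vol = Volume(data, (0.5, 0.5, 0.5))
        ray = Ray(np.array([1.0, 2.0, 2.0]), np.array([1.0, 0, 0]),
                  n_samples=12, step_mm=0.25)
        vals = sample_series(vol, ray).intensities
        np.testing.assert_allclose(np.diff(vals), vals[1] - vals[0], atol=1e-9)

    def test_voxel_centers_reproduce_stored_values(self, rng):
        vol = Volume(rng.normal(size=(10, 10, 10)), (0.7, 0.7, 0.7))
        ray = Ray(np.array([0.0, 1.4, 2.1]), np.array([1.0, 0, 0]),
                  n_samples=8, step_mm=0.7)
        vals = sample_series(vol, ray).intensities
        np.testing.assert_allclose(vals, vol.data[:8, 2, 3], atol=1e-12)

    def test_out_of_bounds_names_ray(self):
        vol = Volume(np.zeros((5, 5, 5)), (1, 1, 1))
        ray = Ray(np.zeros(3), np.array([1.0, 0, 0]), n_samples=18,
                  step_mm=1.0, axis_index=4, angle_deg=35.0)
        with pytest.raises(RayBoundsError, match="axis 4, angle 35"):
            sample_series(vol, ray)

    def test_batch_grid_matches_per_ray(self, rng):
        vol = Volume(rng.normal(size=(30, 30, 30)), (1, 1, 1))
        ax = VesselAxis(np.column_stack([np.full(6, 15.0), np.full(6, 15.0),
                                         np.arange(10.0, 16.0)]))
        pos, _, _ = ray_grid(ax, None, 45.0, 8, 1.0)
        vals, inside = sample_points(vol, pos)
        rays = cast_rays(cross_section_frame(ax, 2), ax.points[2], 45.0, 8, 1.0)
        for r_i, ray in enumerate(rays):
            series = sample_series(vol, ray)
            np.testing.assert_allclose(vals[2, r_i], series.intensities,
                                       atol=1e-12)


class TestLabelStripping:
    def make_label_volume(self, sequence):
        """A volume whose x-axis carries the given label codes."""
        data = np.zeros((len(sequence), 3, 3), dtype=np.int8)
        data[:, :, :] = np.array(sequence)[:, None, None]
        return Volume(data, (1, 1, 1))

    def ray_along_x(self, n):
        return Ray(np.array([0.0, 1.0, 1.0]), np.array([1.0, 0, 0]),
                   n_samples=n, step_mm=1.0)

    def test_stripping_rule_oracle(self):
        # 6 lumen voxels then 12 background, thickness 2
        vol = self.make_label_volume([1] * 6 + [0] * 12)
        states, valid = label_series(vol, self.ray_along_x(18), 2)
        assert valid
        assert states.tolist() == [LUMEN] * 4 + [INTIMA] * 2 + [ADVENTITIA] * 12

    def test_all_lumen_ray_has_no_boundary(self):
        vol = self.make_label_volume([1] * 18)
        states, valid = label_series(vol, self.ray_along_x(18), 2)
        assert valid
        assert np.all(states == LUMEN)

    def test_pathology_only_after_intima_block(self):
        vol = self.make_label_volume([1] * 5 + [3] * 4 + [0] * 9)
        states, valid = label_series(vol, self.ray_along_x(18), 3)
        assert valid
        assert states.tolist() == [LUMEN] * 2 + [INTIMA] * 3 + [PATHOLOGY] * 4 \
            + [ADVENTITIA] * 9

    def test_short_vessel_caps_intima_thickness(self):
        vol = self.make_label_volume([1] * 2 + [0] * 16)
        states, valid = label_series(vol, self.ray_along_x(18), 4)
        assert valid
        assert states.tolist() == [INTIMA] * 2 + [ADVENTITIA] * 16

    def test_nonlumen_start_flagged_invalid(self):
        vol = self.make_label_volume([0] * 18)
        _, valid = label_series(vol, self.ray_along_x(18), 2)
        assert not valid

    def test_vessel_reappearance_flagged_invalid(self):
        vol = self.make_label_volume([1] * 4 + [0] * 4 + [1] * 10)
        states, valid = label_series(vol, self.ray_along_x(18), 2)
        assert not valid
        assert not np.any(states[4:] == LUMEN)

    def test_invalid_wall_thickness_rejected(self):
        vol = self.make_label_volume([1] * 18)
        with pytest.raises(ValueError):
            label_series(vol, self.ray_along_x(18), 5)

    def test_batch_strip_matches_single(self, rng):
        raw = rng.choice([0, 1, 2, 3], size=(40, 18),
                         p=[0.4, 0.3, 0.2, 0.1])
        raw[:, 0] = 1
        batch_states, batch_valid = strip_labels(raw, 3)
        for i in range(40):
            vol = self.make_label_volume(raw[i])
            s, v = label_series(vol, self.ray_along_x(18), 3)
            assert np.array_equal(batch_states[i], s)
            assert batch_valid[i] == v

    def test_state_sequence_is_forward_path(self, straight_phantom):
        """Valid training series never return to lumen after leaving it."""
        ph = straight_phantom
        from mhmmseg.rays import ray_grid, sample_points

        pos, _, _ = ray_grid(ph.axes[0], None, 15.0, 18, 0.7)
        raw, _ = sample_points(ph.labels, pos, order=0)
        for s in range(raw.shape[0]):
            states, valid = strip_labels(raw[s], 2)
            for row, ok in zip(states, valid):
                if not ok:
                    continue
                left = np.flatnonzero(row != LUMEN)
                if len(left):
                    assert not np.any(row[left[0]:] == LUMEN)


class TestWallRule:
    @pytest.mark.parametrize("radius,expect", [(1.0, 2), (1.5, 3), (2.0, 3),
                                               (2.5, 4), (3.0, 4)])
    def test_thickness_from_radius(self, radius, expect):
        assert wall_thickness_for_radius(radius) == expect


class TestSeriesTable:
    def test_table_shape_and_columns(self, straight_phantom, feature_volumes):
        ph = straight_phantom
        table = build_series_table(ph.volume, ph.axes[0], feature_volumes,
                                   labels=ph.labels, wall_thickness_vox=2,
                                   angular_step_deg=30.0,
                                   on_bounds_error="skip")
        n_axis = len(ph.axes[0])
        assert len(table) + table.attrs["skipped_rays"] * N_SAMPLES \
            == n_axis * 12 * N_SAMPLES
        for col in ("phantom_id", "axis_index", "angle_deg", "sample_index",
                    "x", "y", "z", "intensity", "state", "valid", "sato"):
            assert col in table.columns

    def test_series_count_per_cross_section(self, straight_phantom,
                                            feature_volumes):
        ph = straight_phantom
        table = build_series_table(ph.volume, ph.axes[0], feature_volumes,
                                   on_bounds_error="skip")
        per_section = table.groupby("axis_index").size() / N_SAMPLES
        assert (per_section == 72).all()
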