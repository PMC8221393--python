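"""Phantom geometry, closed-form volume oracles, and rendering."""

import math

import numpy as np
import pytest
from scipy import ndimage

from cardiomorph import phantom
from cardiomorph.phantom import ChamberGeom, analytic_chamber_volume


def brute_force_ellipsoid_volume(geom, t, period, n=400):
    """Independent oracle: Monte-Carlo-free midpoint voxelization at fine pitch."""
    az = geom.axial_semi_axis(t, period)
    ay, ax = geom.semi_axes[1], geom.semi_axes[2]
    # integrate cross-section areas over z by midpoint rule
    zs = np.linspace(-az, az, n, endpoint=False) + az / n
    frac = 1.0 - (zs / az) ** 2
    frac[frac < 0] = 0
    return float(np.sum(math.pi * ay * ax * frac) * (2 * az / n))


class TestAnalyticVolume:
    def test_no_modulation_gives_static_ellipsoid(self):
        g = ChamberGeom(center=(0, 0, 0), semi_axes=(30.0, 40.0, 50.0), alpha=0.0)
        expect = 4.0 / 3.0 * math.pi * 30 * 40 * 50
        for t in (0.0, 123.4, 400.0):
            assert analytic_chamber_volume(g, t, 400.0) == pytest.approx(expect)

    def test_default_ventricle_mean_phase_value(self):
        # (4/3)π · 63 · 55 · 36.5 ≈ 5.298e5 μm³ at the mean phase (sin = 0)
        g = ChamberGeom(
            center=(0, 0, 0), semi_axes=(36.5, 55.0, 63.0), alpha=0.25, phase_offset=0.0
        )
        assert analytic_chamber_volume(g, 0.0, 400.0) == pytest.approx(5.298e5, rel=1e-3)

    def test_peak_is_mean_times_one_plus_alpha(self):
        g = ChamberGeom(
            center=(0, 0, 0),
            semi_axes=(30.0, 40.0, 50.0),
            alpha=0.25,
            phase_offset=0.0,
        )
        t_peak = 100.0  # sin(2π·100/400) = 1
        assert analytic_chamber_volume(g, t_peak, 400.0) == pytest.approx(
            1.25 * g.mean_volume
        )

    def test_matches_independent_integration_oracle(self):
        g = ChamberGeom(
            center=(0, 0, 0), semi_axes=(36.5, 55.0, 63.0), alpha=0.25, phase_offset=1.0
        )
        for t in (0.0, 77.0, 200.0):
            assert analytic_chamber_volume(g, t, 400.0) == pytest.approx(
                brute_force_ellipsoid_volume(g, t, 400.0), rel=1e-4
            )

    def test_cycle_average_equals_mean_volume(self):
        g = ChamberGeom(
            center=(0, 0, 0), semi_axes=(30.0, 40.0, 50.0), alpha=0.3, phase_offset=0.7
        )
        n = 20
        vols = [analytic_chamber_volume(g, k * 400.0 / n, 400.0) for k in range(n)]
        assert np.mean(vols) == pytest.approx(g.mean_volume, rel=1e-12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ChamberGeom(center=(0, 0, 0), semi_axes=(0, 1, 1))
        with pytest.raises(ValueError):
            ChamberGeom(center=(0, 0, 0), semi_axes=(10, 10, 10), alpha=1.0)
        with pytest.raises(ValueError):
            ChamberGeom(
                center=(0, 0, 0), semi_axes=(10, 10, 10), trabeculation_amplitude=6.0
            )


class TestMakeTruth:
    def test_static_geometry_gives_identical_frames(self):
        params = phantom.preset(2, pitch=4.0)  # 2 dpf: no trabeculation
        from dataclasses import replace

        static = replace(
            params,
            atrium=replace(params.atrium, alpha=0.0),
            ventricle=replace(params.ventricle, alpha=0.0),
        )
        m0 = phantom.make_truth(static, 0)
        m7 = phantom.make_truth(static, 7)
        assert np.array_equal(m0.labels, m7.labels)

    def test_determinism(self, fast_params):
        a = phantom.make_truth(fast_params, 3)
        b = phantom.make_truth(fast_params, 3)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("dpf", [2, 3, 4, 5])
    def test_voxel_volume_within_2pct_of_closed_form(self, dpf):
        params = phantom.preset(dpf, pitch=2.0)
        k = 3
        t = params.frame_time(k)
        cm = phantom.make_truth(params, k)
        vv = cm.voxel_volume
        for label, geom in ((1, params.atrium), (2, params.ventricle)):
            measured = float((cm.labels == label).sum()) * vv
            expect = analytic_chamber_volume(
                geom, t, params.period, include_trabeculation=True
            )
            # canal voxels outside the ellipsoids inflate each chamber slightly
            assert measured == pytest.approx(expect, rel=0.02)

    def test_voxel_error_shrinks_when_pitch_halves(self):
        # convergence of the voxelization toward the closed form
        errs = {}
        for pitch in (2.0, 1.0):
            params = phantom.preset(2, pitch=pitch)  # smooth chambers only
            cm = phantom.make_truth(params, 5)
            t = params.frame_time(5)
            expect = analytic_chamber_volume(params.ventricle, t, params.period)
            measured = float((cm.labels == 2).sum()) * cm.voxel_volume
            # exclude the canal's contribution from the comparison
            errs[pitch] = abs(measured - expect) / expect
        assert errs[1.0] < errs[2.0]

    def test_lumen_is_single_26_connected_component(self, fast_truth_cine):
        s = np.ones((3, 3, 3))
        for cm in fast_truth_cine:
            _, n = ndimage.label(cm.labels > 0, structure=s)
            assert n == 1

    def test_labels_disjoint_and_both_present(self, fast_truth_cine):
        for cm in fast_truth_cine:
            assert (cm.labels == 1).any() and (cm.labels == 2).any()

    def test_geometry_exceeding_grid_rejected(self):
        with pytest.raises(ValueError):
            phantom.PhantomParams(
                atrium=ChamberGeom(center=(10, 20, 20), semi_axes=(30, 30, 30)),
                ventricle=ChamberGeom(center=(10, 60, 20), semi_axes=(30, 30, 30)),
                grid_shape=(16, 32, 32),
                voxel_spacing=(2.0, 2.0, 2.0),
            )


class TestRenderFrame:
    def test_lumen_darker_than_shell(self, fast_params):
        truth = phantom.make_truth(fast_params, 0)
        img = phantom.render_frame(fast_params, 0, seed=0)
        lumen = truth.labels > 0
        t = fast_params.frame_time(0)
        from cardiomorph.phantom import _inside_chamber, _inside_canal, _voxel_centers

        Z, Y, X = _voxel_centers(fast_params.grid_shape, fast_params.voxel_spacing)
        w = fast_params.wall_thickness
        outer = (
            _inside_chamber(fast_params.ventricle, t, fast_params.period, Z, Y, X, grow=w)
            | _inside_chamber(fast_params.atrium, t, fast_params.period, Z, Y, X, grow=w)
            | _inside_canal(fast_params, Z, Y, X, grow=w)
        )
        shell = outer & ~lumen
        assert img.data[lumen].mean() < img.data[shell].mean()

    def test_noise_seed_changes_noise_not_structure(self, fast_params):
        from dataclasses import replace

        clean = replace(fast_params, noise_sigma=0.0)
        a = phantom.render_frame(clean, 0, seed=1)
        b = phantom.render_frame(clean, 0, seed=2)
        assert np.array_equal(a.data, b.data)
        noisy = phantom.render_frame(fast_params, 0, seed=1)
        noisy2 = phantom.render_frame(fast_params, 0, seed=2)
        assert not np.array_equal(noisy.data, noisy2.data)

    def test_output_is_8bit(self, fast_params):
        img = phantom.render_frame(fast_params, 0, seed=0)
        assert img.data.dtype == np.uint8


class TestMakeCine:
    def test_frame_count_and_pairing(self, fast_params):
        images, truths = phantom.make_cine(fast_params, seed=0)
        assert len(images) == 20 and len(truths) == 20

    def test_designed_atrial_extreme_ratio(self, fast_params):
        # α_A = 3/7 → max/min analytic volumes in ratio (10/7)/(4/7)
        g = fast_params.atrium
        vols = [
            analytic_chamber_volume(g, fast_params.frame_time(k), fast_params.period)
            for k in range(20)
        ]
        assert max(vols) / min(vols) == pytest.approx((10 / 7) / (4 / 7), rel=1e-9)

    def test_single_frame_cycle_rejected(self):
        with pytest.raises(ValueError):
            phantom.preset(4, pitch=4.0, frames=1)

    def test_same_seed_reproduces_bit_identical_frames(self, fast_params):
        im1, tr1 = phantom.make_cine(fast_params, seed=5)
        im2, tr2 = phantom.make_cine(fast_params, seed=5)
        for a, b in zip(im1, im2):
            assert np.array_equal(a.data, b.data)
        for a, b in zip(tr1, tr2):
            assert np.array_equal(a.labels, b.labels)


class TestTrainingSlices:
    def test_deterministic_per_seed(self):
        i1, m1 = phantom.training_slice(11)
        i2, m2 = phantom.training_slice(11)
        assert np.array_equal(i1, i2) and np.array_equal(m1, m2)

    def test_different_seeds_differ(self):
        i1, _ = phantom.training_slice(0)
        i2, _ = phantom.training_slice(1)
        assert not np.array_equal(i1, i2)

    def test_shapes_and_mostly_nonempty_masks(self):
        imgs, masks = phantom.training_slices(range(16))
        assert imgs.shape == (16, 128, 128) and masks.shape == (16, 128, 128)
        # z spans the whole heart, so pole slices with an empty lumen occur,
        # but most slices cut through the chamber bodies
        nonempty = sum(m.sum() > 50 for m in masks)
        assert nonempty >= 10
        assert imgs.min() >= 0.0 and imgs.max() <= 1.0
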