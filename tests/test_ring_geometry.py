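"""Focus detection, plane fitting, profiles and diameter recovery."""

import math

import numpy as np
import pytest

import nucleoring as nr
from nucleoring import ring_geometry as rg
from nucleoring import synthetic_data as sd

from conftest import CANVAS, CENTER, VOXEL_SIZE, make_planar_ring_stack

PSF = (50.0, 150.0)


def tilted_normal(tilt_deg, azimuth_rad=0.0):
    a = math.radians(tilt_deg)
    return (
        math.cos(a),
        math.sin(a) * math.cos(azimuth_rad),
        math.sin(a) * math.sin(azimuth_rad),
    )


class TestDetectFoci:
    def test_all_zero_stack_gives_empty_list(self, full_mask):
        stack = nr.ImageStack(np.zeros(CANVAS), VOXEL_SIZE)
        assert rg.detect_foci(stack, full_mask) == []

    def test_empty_mask_errors(self, planar_ring):
        _, stack = planar_ring
        with pytest.raises(ValueError, match="empty mask"):
            rg.detect_foci(stack, np.zeros(CANVAS, bool))

    def test_well_separated_rings_counted_exactly(self, full_mask):
        # 12 rings on a wide grid: separation ~1.9 um, far beyond the blur
        specs = []
        rng = np.random.default_rng(0)
        for i in range(3):
            for j in range(4):
                specs.append(
                    sd.RingSpec(
                        center=(CENTER[0], 1400.0 + i * 2400.0, 1000.0 + j * 1900.0),
                        diameter=240.0,
                        normal=tuple(sd.sample_unit_vectors(1, rng)[0]),
                    )
                )
        stack = sd.apply_blur(sd.render_rings(specs, CANVAS, VOXEL_SIZE), *PSF)
        foci = rg.detect_foci(stack, full_mask)
        assert len(foci) == 12

    def test_sorted_by_total_intensity(self, full_mask):
        bright = sd.RingSpec(center=(CENTER[0], 2000.0, 2000.0), diameter=240.0,
                             normal=(1.0, 0.0, 0.0), amplitude=200.0)
        dim = sd.RingSpec(center=(CENTER[0], 5500.0, 5500.0), diameter=240.0,
                          normal=(1.0, 0.0, 0.0), amplitude=100.0)
        stack = sd.render_rings([dim, bright], CANVAS, VOXEL_SIZE)
        foci = rg.detect_foci(stack, full_mask)
        assert len(foci) == 2
        assert foci[0].total_intensity > foci[1].total_intensity


class TestPlaneFit:
    def test_planar_ring_normal_recovered(self, planar_ring, full_mask):
        _, stack = planar_ring
        focus = rg.detect_foci(stack, full_mask)[0]
        fit = rg.fit_ring_plane(focus, stack)
        angle = math.degrees(math.acos(min(1.0, abs(fit.normal[0]))))
        assert angle < 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_normal_recovered_blur_free(self, seed, full_mask):
        """Normal recovery to ~ the 125 nm axial-sampling quantization limit."""
        rng = np.random.default_rng(seed)
        normal = sd.sample_unit_vectors(1, rng)[0]
        spec = sd.RingSpec(center=CENTER, diameter=240.0, normal=tuple(normal))
        stack = sd.render_rings([spec], CANVAS, VOXEL_SIZE)
        focus = rg.detect_foci(stack, full_mask)[0]
        fit = rg.fit_ring_plane(focus, stack)
        angle = math.degrees(math.acos(min(1.0, abs(float(np.dot(fit.normal, normal))))))
        assert angle < 3.0

    def test_isotropic_blob_rejected(self, full_mask):
        data = np.zeros(CANVAS)
        data[16, 96, 96] = 1000.0
        stack = sd.apply_blur(nr.ImageStack(data, VOXEL_SIZE), 120.0, 120.0)
        focus = rg.detect_foci(stack, full_mask)[0]
        with pytest.raises(rg.RingQCError, match="not ring-like"):
            rg.fit_ring_plane(focus, stack)

    def test_rotation_is_orthonormal(self, planar_ring, full_mask):
        _, stack = planar_ring
        focus = rg.detect_foci(stack, full_mask)[0]
        fit = rg.fit_ring_plane(focus, stack)
        assert np.allclose(fit.rotation @ fit.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)


class TestRotateToPlane:
    def test_identity_rotation_matches_central_slice(self, planar_ring, full_mask):
        _, stack = planar_ring
        focus = rg.detect_foci(stack, full_mask)[0]
        view = rg.rotate_to_plane(
            focus, stack, np.eye(3), half_size_nm=400.0, projection="max"
        )
        # resample the central plane directly for comparison
        flat = rg.rotate_to_plane(
            focus, stack, np.eye(3), half_size_nm=400.0,
            slab_halfwidth_px=0, projection="max",
        )
        rms = np.sqrt(np.mean((view.image2d - flat.image2d) ** 2))
        assert rms < 0.01 * stack.data.max() + 1e-9

    def test_round_trip_rotation(self, full_mask):
        spec = sd.RingSpec(
            center=CENTER, diameter=240.0, normal=tilted_normal(30.0)
        )
        stack = sd.apply_blur(sd.render_rings([spec], CANVAS, VOXEL_SIZE), *PSF)
        focus = rg.detect_foci(stack, full_mask)[0]
        rot = rg._rotation_to_z(np.asarray(spec.normal))
        v1 = rg.rotate_to_plane(focus, stack, rot, half_size_nm=400.0)
        v2 = rg.rotate_to_plane(focus, stack, rot @ rot.T @ rot, half_size_nm=400.0)
        rms = np.sqrt(np.mean((v1.image2d - v2.image2d) ** 2))
        assert rms < 0.02 * stack.data.max()

    def test_tilted_ring_becomes_round(self, full_mask):
        spec = sd.RingSpec(center=CENTER, diameter=240.0, normal=tilted_normal(35.0))
        stack = sd.render_rings([spec], CANVAS, VOXEL_SIZE)
        focus = rg.detect_foci(stack, full_mask)[0]
        rot = rg._rotation_to_z(np.asarray(spec.normal))
        view = rg.rotate_to_plane(focus, stack, rot, half_size_nm=300.0)
        img = view.image2d - view.image2d.min()
        rows, cols = np.indices(img.shape)
        dy, dx = rows - view.center2d[0], cols - view.center2d[1]
        w = img.sum()
        cyy = (img * dy * dy).sum() / w
        cxx = (img * dx * dx).sum() / w
        cxy = (img * dy * dx).sum() / w
        evals = np.linalg.eigvalsh([[cyy, cxy], [cxy, cxx]])
        assert math.sqrt(evals[1] / evals[0]) < 1.1

    def test_focus_near_border_flagged_clipped(self, full_mask):
        spec = sd.RingSpec(
            center=(250.0, 500.0, 500.0), diameter=240.0, normal=(1.0, 0.0, 0.0)
        )
        stack = sd.render_rings([spec], CANVAS, VOXEL_SIZE)
        focus = rg.detect_foci(stack, full_mask)[0]
        with pytest.raises(rg.RingQCError, match="clipped"):
            rg.rotate_to_plane(focus, stack, np.eye(3), half_size_nm=700.0)


class TestLineProfile:
    def _view(self):
        img = np.zeros((21, 21))
        return rg.PlanarView(img, 40.0, np.eye(3), (10.0, 10.0))

    def test_constant_image_constant_profile(self):
        view = self._view()
        view.image2d += 3.5
        prof = rg.line_profile(view, 25.0, 600.0)
        assert np.allclose(prof, 3.5)

    def test_reversal_symmetry(self, planar_ring, full_mask):
        _, stack = planar_ring
        focus = rg.detect_foci(stack, full_mask)[0]
        view = rg.rotate_to_plane(focus, stack, np.eye(3), half_size_nm=500.0)
        p0 = rg.line_profile(view, 33.0, 800.0)
        p180 = rg.line_profile(view, 213.0, 800.0)
        assert np.allclose(p0, p180[::-1], atol=1e-9)

    def test_exiting_line_errors_with_padding_hint(self):
        view = self._view()
        with pytest.raises(ValueError, match="pad"):
            rg.line_profile(view, 0.0, 5000.0)


class TestPeakPairDistance:
    def test_two_gaussians_recovered(self):
        x = np.arange(23, dtype=float)
        prof = np.exp(-((x - 5.0) ** 2) / 2.0) + np.exp(-((x - 17.0) ** 2) / 2.0)
        d = rg.peak_pair_distance(prof, pixel_size=20.0)
        assert abs(d - 240.0) < 2.0

    def test_single_central_peak_rejected(self):
        x = np.arange(23, dtype=float)
        prof = np.exp(-((x - 11.0) ** 2) / 8.0)
        with pytest.raises(rg.RingQCError, match="no ring signature"):
            rg.peak_pair_distance(prof, pixel_size=20.0)

    def test_offset_invariance(self):
        x = np.arange(23, dtype=float)
        prof = np.exp(-((x - 5.0) ** 2) / 2.0) + np.exp(-((x - 17.0) ** 2) / 2.0)
        d0 = rg.peak_pair_distance(prof, 20.0)
        d1 = rg.peak_pair_distance(prof + 100.0, 20.0)
        assert d0 == pytest.approx(d1, abs=1e-9)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError, match="7 samples"):
            rg.peak_pair_distance(np.ones(5), 20.0)


class TestAnnulusModel:
    def test_peak_radius_matches_numeric_maximum(self):
        from scipy.special import i0e

        radius, sigma = 120.0, 64.0
        r = np.linspace(0.0, 250.0, 25001)
        profile = np.exp(-((r - radius) ** 2) / (2 * sigma**2)) * i0e(
            r * radius / sigma**2
        ) * np.exp(-(2 * r * radius - 2 * r * radius) )
        # full expression exp(-(r^2+R^2)/2s^2) I0(rR/s^2), via i0e for stability
        profile = np.exp(-((r**2 + radius**2) - 2 * r * radius) / (2 * sigma**2)) * i0e(
            r * radius / sigma**2
        )
        numeric = r[np.argmax(profile)]
        assert rg.annulus_peak_radius(radius, sigma) == pytest.approx(numeric, abs=0.05)

    def test_unresolvable_ring_has_no_peak(self):
        assert rg.annulus_peak_radius(80.0, 64.0) == 0.0

    def test_correction_round_trip(self):
        for radius in (120.0, 150.0, 200.0):
            peak = rg.annulus_peak_radius(radius, 64.0)
            assert rg.correct_peak_distance(2 * peak, 64.0) == pytest.approx(
                2 * radius, abs=0.1
            )

    def test_below_resolution_limit_rejected(self):
        with pytest.raises(rg.RingQCError, match="resolution"):
            rg.correct_peak_distance(50.0, 64.0)


class TestRingDiameter:
    def test_blur_free_planar_ring_within_half_voxel(self, planar_ring, full_mask):
        _, stack = planar_ring
        focus = rg.detect_foci(stack, full_mask)[0]
        m = rg.ring_diameter(focus, stack)
        assert m.accepted
        assert abs(m.diameter - 240.0) <= 20.0
        assert m.diameter == pytest.approx(np.mean(m.distances))

    def test_ellipse_diameter_between_axes(self, full_mask):
        spec = sd.RingSpec(
            center=CENTER,
            diameter=math.sqrt(260.0 * 220.0),
            normal=(1.0, 0.0, 0.0),
            ellipticity=260.0 / 220.0,
        )
        stack = sd.render_rings([spec], CANVAS, VOXEL_SIZE)
        focus = rg.detect_foci(stack, full_mask)[0]
        m = rg.ring_diameter(focus, stack)
        assert m.accepted
        assert 220.0 <= m.diameter <= 260.0

    def test_blob_rejected_with_flag(self, full_mask):
        data = np.zeros(CANVAS)
        data[16, 96, 96] = 1000.0
        stack = sd.apply_blur(nr.ImageStack(data, VOXEL_SIZE), 120.0, 120.0)
        focus = rg.detect_foci(stack, full_mask)[0]
        m = rg.ring_diameter(focus, stack)
        assert not m.accepted
        assert m.distances is None
        assert "rejected" in m.qc_flag

    def test_recovery_within_measurable_cone(self, full_mask):
        """Accurate diameters for rings inside the orientation cone the
        axial-to-lateral PSF ratio permits, under the study blur and noise."""
        rng = np.random.default_rng(21)
        errors = []
        for k in range(8):
            tilt = rng.uniform(0.0, 20.0)
            spec = sd.RingSpec(
                center=(
                    CENTER[0] + rng.uniform(-60, 60),
                    CENTER[1] + rng.uniform(-20, 20),
                    CENTER[2] + rng.uniform(-20, 20),
                ),
                diameter=240.0,
                normal=tilted_normal(tilt, rng.uniform(0, 2 * math.pi)),
                amplitude=1000.0,
            )
            stack = sd.apply_blur(sd.render_rings([spec], CANVAS, VOXEL_SIZE), *PSF)
            stack = sd.add_noise(stack, sd.NoiseModel(1.0, 2.0, 5.0, 1000 + k))
            focus = rg.detect_foci(stack, full_mask)[0]
            m = rg.ring_diameter(focus, stack, psf_sigma=PSF)
            if m.accepted:
                errors.append(m.diameter - 240.0)
        assert len(errors) >= 5
        assert abs(np.mean(errors)) < 0.05 * 240.0

    def test_orientation_change_within_cone_small_effect(self, full_mask):
        diams = []
        for tilt in (0.0, 15.0):
            spec = sd.RingSpec(
                center=CENTER, diameter=240.0, normal=tilted_normal(tilt),
                amplitude=1000.0,
            )
            stack = sd.apply_blur(sd.render_rings([spec], CANVAS, VOXEL_SIZE), *PSF)
            focus = rg.detect_foci(stack, full_mask)[0]
            m = rg.ring_diameter(focus, stack, psf_sigma=PSF)
            assert m.accepted
            diams.append(m.diameter)
        assert abs(diams[1] - diams[0]) / diams[0] < 0.05

    def test_too_tilted_rejected_under_anisotropic_blur(self, full_mask):
        spec = sd.RingSpec(
            center=CENTER, diameter=240.0, normal=tilted_normal(70.0),
            amplitude=1000.0,
        )
        stack = sd.apply_blur(sd.render_rings([spec], CANVAS, VOXEL_SIZE), *PSF)
        focus = rg.detect_foci(stack, full_mask)[0]
        m = rg.ring_diameter(focus, stack, psf_sigma=PSF)
        assert not m.accepted


class TestSummaries:
    def _accepted(self, label, diameter):
        return rg.DiameterMeasurement(
            focus_label=label,
            distances=(diameter, diameter, diameter),
            diameter=diameter,
            planarity=0.1,
            qc_flag="ok",
        )

    def test_twelve_rings_give_36_profiles(self):
        ms = [self._accepted(i, 240.0 + i) for i in range(12)]
        s = rg.summarize_diameters(ms)
        assert s.n_rings == 12
        assert s.n_profiles == 36

    def test_single_ring_sd_zero(self):
        s = rg.summarize_diameters([self._accepted(1, 240.0)])
        assert s.sd == 0.0
        assert s.n_rings == 1

    def test_rejected_excluded_and_all_rejected_errors(self):
        rejected = rg.DiameterMeasurement(2, None, float("nan"), 0.9, "rejected(x)")
        s = rg.summarize_diameters([self._accepted(1, 240.0), rejected])
        assert s.n_rings == 1
        with pytest.raises(ValueError, match="no accepted"):
            rg.summarize_diameters([rejected])

    def test_frame_columns(self):
        ms = [self._accepted(1, 240.0)]
        frame = rg.measurements_to_frame(ms)
        assert list(frame.columns) == [
            "focus_label", "d0_nm", "d60_nm", "d120_nm",
            "diameter_nm", "planarity", "qc_flag",
        ]
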