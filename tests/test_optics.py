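"""Ray tracer: refraction, tracing, focus search and system metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketscope import optics
from pocketscope.optics import (
    OpticalTrain,
    Ray,
    SensorModel,
    SourceModel,
    SphericalSurface,
    ball_lens_efl,
    build_iphone2g_microscope,
    find_best_focus,
    rayleigh_resolution_um,
    refract_ray,
    spot_metrics,
    trace,
    usaf_frequency,
)


def _ray(origin, direction):
    return Ray(np.asarray(origin, float), np.asarray(direction, float))


class TestRefraction:
    def test_normal_incidence_planar_unchanged(self):
        s = SphericalSurface(1.0, 0.0, 5.0, 1.0, 1.7)
        out = refract_ray(_ray([0, 0, 0], [0, 0, 1]), s)
        assert out.alive
        np.testing.assert_allclose(out.direction, [0, 0, 1], atol=1e-12)

    def test_snell_30deg_into_glass(self):
        # asin(sin 30 / 1.5) = 19.47 degrees
        s = SphericalSurface(1.0, 0.0, 50.0, 1.0, 1.5)
        th = math.radians(30)
        out = refract_ray(_ray([0, 0, 0], [math.sin(th), 0, math.cos(th)]), s)
        angle = math.degrees(math.asin(out.direction[0]))
        assert angle == pytest.approx(19.47, abs=0.01)

    def test_vignetting_kills_ray(self):
        s = SphericalSurface(1.0, 0.0, 0.4, 1.0, 1.0)
        out = refract_ray(_ray([0.5, 0, 0], [0, 0, 1]), s)
        assert not out.alive and out.reason == "vignetted"

    def test_miss_flags_reason(self):
        s = SphericalSurface(1.0, 0.5, 0.5, 1.0, 1.5)
        out = refract_ray(_ray([5.0, 0, 0], [0, 0, 1]), s)
        assert not out.alive and out.reason == "no intersection"

    def test_total_internal_reflection(self):
        s = SphericalSurface(1.0, 0.0, 50.0, 1.5, 1.0)
        th = math.radians(60)  # beyond the ~41.8 deg critical angle
        out = refract_ray(_ray([0, 0, 0], [math.sin(th), 0, math.cos(th)]), s)
        assert not out.alive and out.reason == "total internal reflection"

    @settings(deadline=None, max_examples=50)
    @given(
        theta=st.floats(0.0, 0.55),
        n2=st.floats(1.1, 1.9),
    )
    def test_reversibility(self, theta, n2):
        """Reversing a refracted ray and re-refracting recovers the input."""
        s_in = SphericalSurface(1.0, 0.0, 50.0, 1.0, n2)
        r = _ray([0, 0, 0], [math.sin(theta), 0, math.cos(theta)])
        out = refract_ray(r, s_in)
        assert out.alive
        s_back = SphericalSurface(2.0, 0.0, 50.0, n2, 1.0)
        back = refract_ray(
            Ray(out.origin, out.direction, out.wavelength_nm), s_back
        )
        assert back.alive
        np.testing.assert_allclose(back.direction, r.direction, atol=1e-9)


class TestTrace:
    def _lone_ball(self, n=1.5168, d=1.0):
        R = d / 2
        return OpticalTrain(
            [
                SphericalSurface(-R, R, R, 1.0, n),
                SphericalSurface(R, -R, R, n, 1.0),
            ],
            SensorModel(),
            sensor_z=10.0,
            object_z=-5.0,
        )

    def test_axial_ray_hits_origin(self, stock_train):
        res = trace(stock_train, _ray([0, 0, stock_train.object_z], [0, 0, 1]))
        np.testing.assert_allclose(res.sensor_hit, [0, 0], atol=1e-12)

    def test_paraxial_ball_bfl(self):
        """Parallel paraxial ray crosses the axis at BFL = EFL - R behind a
        lone ball: nD/4(n-1) - D/2 = 0.2337 mm for BK7-like glass."""
        train = self._lone_ball()
        res = trace(train, _ray([0.01, 0, -5.0], [0, 0, 1]))
        hit, d = res.path[2], res.ray.direction
        z_cross = hit[2] - hit[0] / d[0] * d[2]
        assert z_cross - 0.5 == pytest.approx(0.2337, abs=0.002)

    def test_path_bookkeeping(self, stock_train):
        res = trace(stock_train, _ray([0, 0, stock_train.object_z], [0.05, 0, 1]))
        # start + one point per surface + sensor
        assert len(res.path) == len(stock_train.surfaces) + 2

    def test_dead_ray_partial_path(self, stock_train):
        th = math.radians(60)
        res = trace(
            stock_train,
            _ray([0, 0, stock_train.object_z], [math.sin(th), 0, math.cos(th)]),
        )
        assert res.sensor_hit is None
        assert len(res.path) <= len(stock_train.surfaces) + 2

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            OpticalTrain([], SensorModel(), 1.0, -1.0)

    def test_paraxial_efl_matches_thick_lens_formula(self):
        """Traced EFL of a lone ball agrees with nD/4(n-1) to < 0.1%."""
        for n in (1.4, 1.5168, 1.7):
            train = self._lone_ball(n=n)
            res = trace(train, _ray([1e-4, 0, -5.0], [0, 0, 1]))
            hit, d = res.path[2], res.ray.direction
            z_cross = hit[2] - hit[0] / d[0] * d[2]
            efl_traced = z_cross  # from ball centre (z=0)
            assert efl_traced == pytest.approx(ball_lens_efl(1.0, n), rel=1e-3)


class TestSpotMetrics:
    def test_ideal_thin_lens_point_image(self):
        f = 10.0
        train = OpticalTrain(
            [SphericalSurface(0.0, 0.0, 5.0, focal_length=f)],
            SensorModel(),
            sensor_z=2 * f,
            object_z=-2 * f,
        )
        sp = spot_metrics(train, SourceModel(0.0, 5.0, 200))
        assert sp.rms_radius_mm < 1e-6

    def test_stock_best_focus_spot_within_pixel(self, stock_train, stock_metrics):
        z = -stock_metrics.best_focus_object_distance_mm
        t = optics.replace_object_z(stock_train, z)
        sp = spot_metrics(t, SourceModel(0.0, 5.0, 200))
        assert sp.rms_radius_mm <= stock_train.sensor.pixel_pitch_um * 1e-3

    def test_sampler_convergence(self, stock_train):
        sp1 = spot_metrics(stock_train, SourceModel(0.0, 5.0, 200))
        sp2 = spot_metrics(stock_train, SourceModel(0.0, 5.0, 400))
        assert sp2.rms_radius_mm == pytest.approx(sp1.rms_radius_mm, rel=0.01)

    def test_energy_bookkeeping(self, stock_train):
        sp = spot_metrics(stock_train, SourceModel(0.0, 30.0, 300))
        assert len(sp.hit_points) + sp.n_vignetted == sp.n_launched

    def test_no_throughput_raises(self, stock_train):
        t = optics.replace_object_z(stock_train, -50.0)
        blocked = OpticalTrain(
            [SphericalSurface(-10.0, 0.0, 1e-6, 1.0, 1.0)] ,
            t.sensor, t.sensor_z, t.object_z,
        )
        with pytest.raises(RuntimeError):
            spot_metrics(blocked, SourceModel(0.5, 5.0, 100))


class TestBestFocus:
    def test_gaussian_lens_law(self):
        """Ideal thin lens, sensor at v: best focus at 1/u + 1/v = 1/f."""
        f, v = 10.0, 30.0
        train = OpticalTrain(
            [SphericalSurface(0.0, 0.0, 5.0, focal_length=f)],
            SensorModel(),
            sensor_z=v,
            object_z=-20.0,
        )
        z = find_best_focus(train, (-25.0, -10.0), divergence_half_angle_deg=5.0)
        assert -z == pytest.approx(1.0 / (1 / f - 1 / v), abs=1e-3)

    def test_no_interior_minimum_raises(self):
        f, v = 10.0, 30.0
        train = OpticalTrain(
            [SphericalSurface(0.0, 0.0, 5.0, focal_length=f)],
            SensorModel(),
            sensor_z=v,
            object_z=-20.0,
        )
        with pytest.raises(ValueError):
            find_best_focus(train, (-60.0, -40.0))

    def test_sensor_shift_moves_focus_longitudinally(self):
        """A 10 µm sensor shift moves best focus by ~(u/v)² · shift."""
        f, v = 10.0, 30.0

        def focus(sensor_z):
            train = OpticalTrain(
                [SphericalSurface(0.0, 0.0, 5.0, focal_length=f)],
                SensorModel(),
                sensor_z=sensor_z,
                object_z=-20.0,
            )
            return find_best_focus(train, (-25.0, -10.0))

        z0, z1 = focus(v), focus(v + 0.01)
        u = 1.0 / (1 / f - 1 / v)
        expected = 0.01 * (u / v) ** 2
        assert abs(z1 - z0) == pytest.approx(expected, rel=0.15)


class TestSystemMetrics:
    def test_stock_magnification(self, stock_metrics):
        assert stock_metrics.magnification == pytest.approx(4.8, rel=0.10)

    def test_stock_fov(self, stock_metrics):
        assert stock_metrics.field_of_view_diameter_mm == pytest.approx(0.55, rel=0.10)

    def test_stock_best_focus_from_ball_centre(self, stock_metrics):
        assert stock_metrics.best_focus_object_distance_mm == pytest.approx(
            0.722, rel=0.05
        )

    def test_stock_numerical_aperture(self, stock_metrics):
        assert stock_metrics.numerical_aperture == pytest.approx(0.44, rel=0.10)

    def test_stock_depth_of_field(self, stock_metrics):
        assert stock_metrics.depth_of_field_um == pytest.approx(3.0, rel=0.50)
        # diffraction estimate lambda/NA^2 lands in the same band
        assert stock_metrics.depth_of_field_diffraction_um == pytest.approx(
            3.0, rel=0.50
        )

    def test_rayleigh_identity(self, stock_metrics):
        m = stock_metrics
        assert m.rayleigh_resolution_um * m.numerical_aperture / (
            m.wavelength_nm * 1e-3
        ) == pytest.approx(0.61, abs=1e-12)

    def test_rayleigh_at_printed_na(self):
        assert rayleigh_resolution_um(488.0, 0.44) == pytest.approx(0.68, abs=0.005)

    def test_magnification_decreases_with_ball_efl(self):
        mags = []
        for d in (1.0, 2.0, 3.0):
            train = build_iphone2g_microscope(ball_diameter_mm=d)
            mags.append(optics.system_metrics(train).magnification)
        assert mags[0] > mags[1] > mags[2]


class TestBuilder:
    def test_structure(self, stock_train):
        zs = [s.vertex_z for s in stock_train.surfaces]
        assert zs == sorted(zs)
        assert stock_train.sensor_z > zs[-1]
        assert stock_train.object_z < zs[0]

    def test_high_index_ball_focuses_on_rear_surface(self):
        assert ball_lens_efl(1.0, 2.0) == pytest.approx(0.5)

    def test_larger_ball_longer_efl(self):
        assert ball_lens_efl(3.0, 1.5168) == pytest.approx(3 * ball_lens_efl(1.0, 1.5168))


class TestUsaf:
    @pytest.mark.parametrize(
        "group, element, expected",
        [(9, 2, 574.7), (0, 1, 1.0), (7, 6, 228.1)],
    )
    def test_chart_frequencies(self, group, element, expected):
        assert usaf_frequency(group, element) == pytest.approx(expected, abs=0.05)

    def test_element_out_of_range(self):
        with pytest.raises(ValueError):
            usaf_frequency(9, 7)
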