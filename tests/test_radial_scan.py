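import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fundusvessel as fv
from fundusvessel.errors import (
    ConfigError,
    GeometryError,
    MeasurementError,
    NoBackgroundError,
)
from fundusvessel.radial_scan import Polarity, RingProfile, VesselChain

from helpers import brute_force_min_distances, match_measurements_to_truth

TWO_PI = 2 * math.pi


# ---------------------------------------------------------------------------
# ring_radii
# ---------------------------------------------------------------------------

class TestRingRadii:
    def test_defaults_span_annulus_evenly(self):
        disc = fv.DiscGeometry(center=(300.0, 300.0), disc_radius=50.0)
        radii = fv.ring_radii(disc, fv.ScanConfig())
        assert len(radii) == 30
        assert radii[0] == 100
        assert radii[-1] == 200
        np.testing.assert_allclose(np.diff(radii), 100 / 29)

    def test_two_rings_are_the_endpoints(self):
        disc = fv.DiscGeometry(center=(300.0, 300.0), disc_radius=50.0)
        radii = fv.ring_radii(disc, fv.ScanConfig(n_rings=2))
        np.testing.assert_allclose(radii, [100, 200])

    def test_inverted_annulus_is_config_error(self):
        with pytest.raises(ConfigError):
            fv.ScanConfig(inner_factor=4.0, outer_factor=2.0)

    def test_outer_ring_must_fit_in_image(self):
        disc = fv.DiscGeometry(center=(160.0, 160.0), disc_radius=50.0)
        with pytest.raises(GeometryError):
            fv.ring_radii(disc, fv.ScanConfig(), image_shape=(320, 320))


# ---------------------------------------------------------------------------
# sample_ring
# ---------------------------------------------------------------------------

class TestSampleRing:
    def test_constant_image_gives_constant_profile(self, uniform_image):
        prof = fv.sample_ring(uniform_image, (160, 160), 100)
        assert len(prof.angles) == math.ceil(TWO_PI * 100)
        np.testing.assert_allclose(prof.intensities, 50.0)

    def test_half_plane_has_two_monotone_transitions(self):
        px = np.zeros((321, 321))
        px[:, :160] = 255.0  # left half bright, boundary through the centre
        img = fv.FundusImage(px)
        prof = fv.sample_ring(img, (160.0, 160.0), 100)
        # away from the vertical boundary the profile is saturated/zero;
        # sign changes of (I - 127.5) count the transitions per turn
        signs = np.sign(prof.intensities - 127.5)
        nonzero = signs[signs != 0]
        flips = np.count_nonzero(np.diff(nonzero)) + (nonzero[0] != nonzero[-1])
        assert flips == 2

    def test_rotating_image_shifts_profile_by_quarter_turn(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 256, (321, 321)).astype(float)
        img = fv.FundusImage(px)
        # rot90(k=-1) on a square grid is a clockwise quarter turn about
        # the exact centre (160, 160)
        rot = fv.FundusImage(np.rot90(px, k=-1))
        center = (160.0, 160.0)
        # radius chosen so the sample count (ceil(2*pi*r) = 628) is a
        # multiple of 4: sampling points then map onto each other exactly
        # and bilinear interpolation commutes with the rotation
        prof = fv.sample_ring(img, center, 99.9)
        prof_rot = fv.sample_ring(rot, center, 99.9)
        n = len(prof.angles)
        assert n % 4 == 0
        np.testing.assert_allclose(prof_rot.intensities,
                                   np.roll(prof.intensities, n // 4),
                                   atol=1.0)

    def test_ring_outside_bounds_is_geometry_error(self, uniform_image):
        with pytest.raises(GeometryError):
            fv.sample_ring(uniform_image, (160, 160), 200)


# ---------------------------------------------------------------------------
# detect_crossings
# ---------------------------------------------------------------------------

def make_profile(intensities, radius=100.0):
    vals = np.asarray(intensities, dtype=float)
    n = vals.size
    return RingProfile(ring_index=0, radius=radius, center=(160.0, 160.0),
                       angles=np.arange(n) * (TWO_PI / n), intensities=vals)


class TestDetectCrossings:
    def test_all_below_threshold_no_crossings(self):
        assert fv.detect_crossings(make_profile(np.full(100, 10.0)), 204) == []

    def test_all_above_threshold_errors(self):
        with pytest.raises(NoBackgroundError):
            fv.detect_crossings(make_profile(np.full(100, 250.0)), 204)

    def test_single_pulse_one_start_one_end(self):
        vals = np.full(360, 10.0)
        vals[40:80] = 250.0
        crossings = fv.detect_crossings(make_profile(vals), 204)
        assert [c.polarity for c in crossings] == [Polarity.START, Polarity.END]
        start, end = crossings
        assert start.angle < end.angle
        assert math.radians(39) < start.angle < math.radians(40)
        assert math.radians(79) < end.angle < math.radians(80)

    def test_pulse_straddling_the_seam_is_one_vessel(self):
        vals = np.full(360, 10.0)
        vals[:30] = 250.0
        vals[340:] = 250.0  # single arc through angle 0
        crossings = fv.detect_crossings(make_profile(vals), 204)
        assert len(crossings) == 2

    def test_crossing_angle_interpolated_subsample(self):
        vals = np.full(360, 100.0)
        vals[90] = 300.0  # ramp 100 -> 300 crosses 204 at fraction 0.52
        crossings = fv.detect_crossings(make_profile(vals), 204.0)
        step = TWO_PI / 360
        assert crossings[0].angle == pytest.approx(89 * step + 0.52 * step)

    def test_six_simulated_vessels_on_every_ring(self, disc):
        spec = fv.SimSpec(vessels=fv.alternating_layout(6, 8, 13, phase=0.2))
        image, mask, _ = fv.generate(spec)
        enhanced = fv.enhance_with_mask(image, mask)
        cfg = fv.ScanConfig()
        for i, r in enumerate(fv.ring_radii(disc, cfg)):
            prof = fv.sample_ring(enhanced, disc.center, float(r), i)
            crossings = fv.detect_crossings(prof, cfg.resolve_threshold(enhanced))
            starts = [c for c in crossings if c.polarity is Polarity.START]
            assert len(starts) == 6
            assert len(crossings) == 12

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=255,
                              allow_nan=False), min_size=4, max_size=200),
           st.floats(min_value=1, max_value=254))
    def test_starts_and_ends_alternate_and_balance(self, vals, threshold):
        profile = make_profile(np.asarray(vals))
        try:
            crossings = fv.detect_crossings(profile, threshold)
        except NoBackgroundError:
            assert np.all(np.asarray(vals) >= threshold)
            return
        polarities = [c.polarity for c in crossings]
        assert polarities.count(Polarity.START) == polarities.count(Polarity.END)
        for a, b in zip(polarities, polarities[1:]):
            assert a is not b

    @pytest.mark.parametrize("scale", [1.0, 0.5, 0.125])
    def test_threshold_scale_invariance(self, scale):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 255, 400)
        base = fv.detect_crossings(make_profile(vals), 204.0)
        scaled = fv.detect_crossings(make_profile(vals * scale), 204.0 * scale)
        assert [c.angle for c in scaled] == [c.angle for c in base]
        assert [c.polarity for c in scaled] == [c.polarity for c in base]


# ---------------------------------------------------------------------------
# chain_vessels
# ---------------------------------------------------------------------------

def pulse(ring, start_angle, end_angle, radius=100.0):
    prof = RingProfile(ring_index=ring, radius=radius, center=(160.0, 160.0),
                       angles=np.array([0.0]), intensities=np.array([0.0]))
    s = fv.Crossing(ring_index=ring, angle=start_angle,
                    point=prof.point_at(start_angle), polarity=Polarity.START)
    e = fv.Crossing(ring_index=ring, angle=end_angle,
                    point=prof.point_at(end_angle), polarity=Polarity.END)
    return [s, e]


class TestChainVessels:
    def test_zero_drift_four_pulses_four_chains(self):
        angles = [0.5, 2.0, 3.5, 5.0]
        per_ring = [[c for a in angles for c in pulse(r, a, a + 0.2)]
                    for r in range(30)]
        chains = fv.chain_vessels(per_ring, fv.ScanConfig(), inner_radius=100)
        assert len(chains) == 4
        assert all(ch.n_rings == 30 for ch in chains)
        anchors = [ch.anchor_angle for ch in chains]
        np.testing.assert_allclose(anchors, angles, atol=1e-9)

    def test_low_support_chain_dropped(self):
        per_ring = [pulse(r, 1.0, 1.2) if r < 3 else [] for r in range(30)]
        chains = fv.chain_vessels(per_ring, fv.ScanConfig(), inner_radius=100)
        assert chains == []

    def test_empty_input_empty_output(self):
        assert fv.chain_vessels([], fv.ScanConfig()) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_six_vessels_recovered_under_noise(self, seed, disc):
        rng = np.random.default_rng(seed)
        vessels = fv.random_layout(rng, 6, artery_width_mean=8,
                                   vein_width_mean=13, width_sd=0.5)
        spec = fv.SimSpec(vessels=vessels, noise_sd=5.0, seed=seed)
        image, mask, truth = fv.generate(spec)
        measurements = fv.analyze_image(image, mask, disc)
        assert len(measurements) == 6


# ---------------------------------------------------------------------------
# measure_vessel
# ---------------------------------------------------------------------------

def chain_from_points(pairs):
    """Build a VesselChain from {ring: ((srow, scol), (erow, ecol))}."""
    crossings = {}
    for ring, (s, e) in pairs.items():
        crossings[ring] = (
            fv.Crossing(ring_index=ring, angle=0.0, point=s,
                        polarity=Polarity.START),
            fv.Crossing(ring_index=ring, angle=0.1, point=e,
                        polarity=Polarity.END))
    return VesselChain(vessel_id=0, crossings=crossings)


class TestMeasureVessel:
    def test_min_distance_across_all_rings(self):
        chain = chain_from_points({0: ((0.0, 0.0), (3.0, 4.0)),
                                   1: ((50.0, 50.0), (6.0, 8.0))})
        m = fv.measure_vessel(chain)
        # ring-0 start at origin: min over ends (3,4) and (6,8) is 5
        assert m.diameters[0] == pytest.approx(5.0)

    def test_constant_diameters_degenerate_stats(self):
        chain = chain_from_points(
            {r: ((0.0, float(r)), (10.0, float(r))) for r in range(3)})
        m = fv.measure_vessel(chain)
        assert m.mean == pytest.approx(10)
        assert m.median == pytest.approx(10)
        assert m.sd == 0.0

    def test_empty_chain_errors(self):
        with pytest.raises(MeasurementError):
            fv.measure_vessel(VesselChain(vessel_id=0, crossings={}))

    def test_oblique_ribbon_perpendicular_width(self, disc):
        # a 7 px ribbon crossing the annulus 30 degrees off-radial: the
        # shortest start-to-end distance is the perpendicular width
        spec = fv.SimSpec(vessels=(fv.VesselSpec(angle=0.9, width=7.0,
                                                 obliquity_deg=30.0),))
        image, mask, _ = fv.generate(spec)
        (m,) = fv.analyze_image(image, mask, disc)
        assert m.mean == pytest.approx(7.0, abs=1.5)

    @pytest.mark.parametrize("seed", [3, 14])
    def test_matches_brute_force_oracle(self, seed, disc):
        rng = np.random.default_rng(seed)
        vessels = fv.random_layout(rng, 5, 8, 13)
        spec = fv.SimSpec(vessels=vessels, noise_sd=2.0, seed=seed)
        image, mask, _ = fv.generate(spec)
        _, chains, _ = fv.analyze_image_detailed(image, mask, disc)
        for chain in chains:
            m = fv.measure_vessel(chain)
            expected = brute_force_min_distances(
                [p for _, p in chain.start_points()], chain.end_points())
            np.testing.assert_allclose(m.diameters, expected, rtol=1e-12)


# ---------------------------------------------------------------------------
# analyze_image (end to end)
# ---------------------------------------------------------------------------

class TestAnalyzeImage:
    def test_zero_noise_known_widths(self, disc):
        spec = fv.SimSpec(vessels=fv.alternating_layout(
            4, artery_width=6, vein_width=10, phase=0.4))
        image, mask, truth = fv.generate(spec)
        measurements = fv.analyze_image(image, mask, disc)
        assert len(measurements) == 4
        for m, t in match_measurements_to_truth(measurements, truth.vessels):
            assert m.mean == pytest.approx(t.width, abs=1.5)

    def test_empty_scene_gives_no_vessels(self, disc):
        image = fv.FundusImage(np.full((320, 320), 40.0))
        mask = fv.VesselMask(np.zeros((320, 320), dtype=bool))
        assert fv.analyze_image(image, mask, disc) == []

    def test_repeat_run_bit_identical(self, disc):
        spec = fv.SimSpec(vessels=fv.alternating_layout(6, 8, 13, phase=0.2),
                          noise_sd=4.0, seed=21)
        image, mask, _ = fv.generate(spec)
        a = fv.analyze_image(image, mask, disc)
        b = fv.analyze_image(image, mask, disc)
        assert len(a) == len(b)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.diameters, mb.diameters)
            assert (ma.mean, ma.median, ma.sd) == (mb.mean, mb.median, mb.sd)

    def test_drop_first_ring_yields_29_values(self, disc):
        spec = fv.SimSpec(vessels=fv.alternating_layout(4, 8, 12, phase=0.3))
        image, mask, _ = fv.generate(spec)
        measurements = fv.analyze_image(image, mask, disc,
                                        fv.ScanConfig(drop_first_ring=True))
        assert all(m.n_rings == 29 for m in measurements)
        assert all(0 not in m.ring_indices for m in measurements)

    def test_inner_radius_override_trims_rings(self, disc):
        spec = fv.SimSpec(vessels=fv.alternating_layout(4, 8, 12, phase=0.3))
        image, mask, _ = fv.generate(spec)
        cfg = fv.ScanConfig(inner_radius_overrides={0: 100.0},
                            min_ring_support=0.5)
        measurements = fv.analyze_image(image, mask, disc, cfg)
        radii = fv.ring_radii(disc, cfg)
        v0 = next(m for m in measurements if m.vessel_id == 0)
        assert all(radii[r] >= 100.0 for r in v0.ring_indices)

    @pytest.mark.parametrize("k", range(1, 7))
    def test_rotation_equivariance_of_diameters(self, k, disc):
        # rotating the layout by multiples of 15 degrees moves each vessel's
        # recovered mean by less than half a pixel
        base_phase = 0.12
        widths = dict(artery_width=8, vein_width=13)
        spec0 = fv.SimSpec(vessels=fv.alternating_layout(
            4, phase=base_phase, **widths))
        speck = fv.SimSpec(vessels=fv.alternating_layout(
            4, phase=base_phase + k * math.radians(15), **widths))
        m0 = fv.analyze_image(*fv.generate(spec0)[:2], disc)
        mk = fv.analyze_image(*fv.generate(speck)[:2], disc)
        for a, b in zip(sorted(m.mean for m in m0), sorted(m.mean for m in mk)):
            assert abs(a - b) < 0.5
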