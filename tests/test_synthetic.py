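import numpy as np
import pytest

from panoct.protocol import ScanProtocol
from panoct.scan_geometry import ScanGeometry, bscan_depth_profile
from panoct.synthetic import (
    Lesion,
    SyntheticScene,
    autofocus_hill_climb,
    en_face_projection,
    generate_cornea_volume,
    generate_phantom_volume,
    generate_retina_volume,
    reference_arm_for_surface_depth,
)


def _subpixel_peak_um(bscan, pitch_um):
    """Centroid-refined brightest-peak depth per A-scan (test-side helper,
    independent of the package's detectors)."""
    idx = np.argmax(bscan, axis=-1)
    win = np.clip(idx[:, None] + np.arange(-2, 3), 0, bscan.shape[-1] - 1)
    vals = np.take_along_axis(bscan, win, axis=-1)
    return (vals * win).sum(axis=-1) / vals.sum(axis=-1) * pitch_um


class TestRetinaGenerator:
    def test_center_pivot_renders_flat_surface(self, newborn_eye, small_protocol):
        geom = ScanGeometry(8.725, 0.0, 15.0, 1.357)
        scene = SyntheticScene(eye=newborn_eye, geom=geom, speckle_mode="none",
                               rolloff_db_per_mm=0.0, noise_floor=0.0, seed=0)
        vol = generate_retina_volume(scene, small_protocol,
                                     reference_arm_for_surface_depth(scene, 1.0))
        rpe = np.argmax(vol.intensity, axis=2)
        assert rpe.max() - rpe.min() <= 1

    def test_surface_follows_bscan_depth_profile(self, quiet_scene, small_protocol):
        vol = generate_retina_volume(
            quiet_scene, small_protocol,
            reference_arm_for_surface_depth(quiet_scene, 2.0))
        mid = vol.intensity.shape[0] // 2
        rpe_um = _subpixel_peak_um(np.asarray(vol.intensity[mid], float),
                                   vol.depth_pixel_pitch_um)
        prof_um = bscan_depth_profile(quiet_scene.geom, vol.alpha_fast_deg) * 1000
        # depth decreases toward the periphery by exactly the profile
        rel = rpe_um[len(rpe_um) // 2] - rpe_um
        assert np.all(np.abs(rel - prof_um) <= vol.depth_pixel_pitch_um)

    def test_same_seed_is_bit_identical(self, newborn_eye, small_protocol):
        geom = ScanGeometry.for_eye(newborn_eye, fov_deg=30.0)
        mk = lambda: generate_retina_volume(
            SyntheticScene(eye=newborn_eye, geom=geom, seed=42),
            small_protocol, 22.0)
        a, b = mk(), mk()
        assert np.array_equal(a.intensity, b.intensity)
        assert a.intensity.dtype == np.float32

    def test_different_seed_differs(self, newborn_eye, small_protocol):
        geom = ScanGeometry.for_eye(newborn_eye, fov_deg=30.0)
        mk = lambda s: generate_retina_volume(
            SyntheticScene(eye=newborn_eye, geom=geom, seed=s),
            small_protocol, 22.0)
        assert not np.array_equal(mk(1).intensity, mk(2).intensity)

    def test_aliasing_warning_recorded(self, newborn_eye):
        # full 140 deg fan cannot fit into a 1.28 mm window
        geom = ScanGeometry.for_eye(newborn_eye)
        scene = SyntheticScene(eye=newborn_eye, geom=geom, speckle_mode="none",
                               noise_floor=0.0, rolloff_db_per_mm=0.0, seed=0)
        p = ScanProtocol(n_ascans_per_bscan=17, n_bscans=3, samples_per_ascan=256,
                         sampling_rate_hz=None)
        vol = generate_retina_volume(scene, p,
                                     reference_arm_for_surface_depth(scene, 1.0))
        assert vol.meta["warnings"]

    def test_speckle_preserves_expected_intensity(self, newborn_eye):
        """Multiplicative exponential speckle is unit mean: the ratio of
        speckled to clean total intensity converges to 1."""
        geom = ScanGeometry.for_eye(newborn_eye, fov_deg=30.0)
        p = ScanProtocol(n_ascans_per_bscan=144, n_bscans=144,
                         samples_per_ascan=256, sampling_rate_hz=None)
        base = dict(eye=newborn_eye, geom=geom, rolloff_db_per_mm=0.0,
                    noise_floor=0.0, seed=77)
        stage = reference_arm_for_surface_depth(
            SyntheticScene(speckle_mode="none", **base), 0.6)
        clean = generate_retina_volume(
            SyntheticScene(speckle_mode="none", **base), p, stage).intensity
        speckled = generate_retina_volume(
            SyntheticScene(speckle_mode="multiplicative-exponential", **base),
            p, stage).intensity
        sel = clean > 0
        n = sel.sum()
        assert n > 1e5
        ratios = speckled[sel] / clean[sel]
        # exponential: mean 1, sd 1 -> 3 standard errors of the mean
        assert abs(ratios.mean() - 1.0) < 3.0 / np.sqrt(n)


class TestCorneaGenerator:
    def test_apex_at_configured_depth(self, quiet_scene, small_protocol):
        vol = generate_cornea_volume(quiet_scene, small_protocol, 0.3)
        mid = vol.intensity.shape[0] // 2
        apex_px = np.argmax(vol.intensity[mid, small_protocol.n_ascans_per_bscan // 2])
        assert apex_px * vol.depth_pixel_pitch_um / 1000 == pytest.approx(
            vol.meta["apex_depth_mm"], abs=vol.depth_pixel_pitch_um / 1000)

    def test_stage_shift_moves_apex_by_opl_factor(self, quiet_scene, small_protocol):
        v1 = generate_cornea_volume(quiet_scene, small_protocol, 0.3)
        v2 = generate_cornea_volume(quiet_scene, small_protocol, 0.5)
        d = (v1.meta["apex_depth_mm"] - v2.meta["apex_depth_mm"])
        assert d == pytest.approx(quiet_scene.opl_factor * 0.2)
        mid = v1.intensity.shape[0] // 2
        jc = small_protocol.n_ascans_per_bscan // 2
        shift_px = (np.argmax(v1.intensity[mid, jc]) - np.argmax(v2.intensity[mid, jc]))
        assert shift_px * v1.depth_pixel_pitch_um == pytest.approx(200.0, abs=5.0)

    def test_seed_determinism(self, quiet_scene, small_protocol):
        a = generate_cornea_volume(quiet_scene, small_protocol, 0.3)
        b = generate_cornea_volume(quiet_scene, small_protocol, 0.3)
        assert np.array_equal(a.intensity, b.intensity)


@pytest.fixture(scope="module")
def phantom():
    geom = ScanGeometry(12.0, 12.0, 70.0, 1.0)
    p = ScanProtocol(n_ascans_per_bscan=161, n_bscans=41,
                     samples_per_ascan=1024, sampling_rate_hz=None)
    return generate_phantom_volume(12.0, 40.0, 0.3, geom, p,
                                   depth_pixel_pitch_um=18.0, ring_boost=2.0)


class TestPhantomGenerator:
    def test_all_seven_rings_within_reach(self, phantom):
        rings = phantom.meta["rings"]
        assert [r[0] for r in rings] == list(range(8))
        assert not phantom.meta["rings_omitted"]

    def test_en_face_shows_rings_at_predicted_pivot_angles(self, phantom):
        ef = en_face_projection(phantom, "max")
        row = ef[ef.shape[0] // 2]
        af = phantom.alpha_fast_deg
        for k, beta, alpha in phantom.meta["rings"]:
            if k in (0, 7):  # centre mark and the FOV-edge ring
                continue
            i = int(np.argmin(np.abs(af - alpha)))
            j = int(np.argmin(np.abs(af - (alpha - 5.0))))  # off-ring baseline
            assert row[i - 3:i + 4].max() > 1.4 * row[j - 2:j + 3].max()

    def test_narrow_scan_misses_far_rings(self):
        geom = ScanGeometry(12.0, 0.0, 15.0, 1.0)  # reach = 15 deg central
        p = ScanProtocol(n_ascans_per_bscan=33, n_bscans=5, samples_per_ascan=256,
                         sampling_rate_hz=None)
        vol = generate_phantom_volume(12.0, 40.0, 0.3, geom, p,
                                      depth_pixel_pitch_um=18.0)
        assert [r[0] for r in vol.meta["rings"]] == [0]
        assert len(vol.meta["rings_omitted"]) == 7


class TestEnFaceProjection:
    def test_constant_volume_projects_to_constant(self, quiet_scene, small_protocol):
        vol = generate_cornea_volume(quiet_scene, small_protocol, 0.3)
        vol.intensity[:] = 2.5
        assert en_face_projection(vol, "mean") == pytest.approx(2.5)
        assert en_face_projection(vol, "max") == pytest.approx(2.5)

    def test_max_dominates_mean_pointwise(self, quiet_scene, small_protocol):
        vol = generate_retina_volume(
            quiet_scene, small_protocol,
            reference_arm_for_surface_depth(quiet_scene, 1.5))
        assert np.all(en_face_projection(vol, "max")
                      >= en_face_projection(vol, "mean"))

    def test_unknown_method_rejected(self, quiet_scene, small_protocol):
        vol = generate_cornea_volume(quiet_scene, small_protocol, 0.3)
        with pytest.raises(ValueError):
            en_face_projection(vol, "median")


class TestAutofocus:
    def test_quadratic_metric_converges_to_peak(self):
        best = autofocus_hill_climb(lambda x: -(x - 3.2) ** 2, start=0.0,
                                    step=1.0, tol=1e-4)
        assert best == pytest.approx(3.2, abs=1e-3)

    def test_monotone_metric_runs_to_boundary(self):
        best = autofocus_hill_climb(lambda x: x, start=1.0, step=0.5,
                                    tol=1e-4, bounds=(0.0, 5.0))
        assert best == pytest.approx(5.0)

    def test_matches_exhaustive_search_on_defocus_stack(self):
        """Brightness of a blurred scene peaks at the in-focus setting;
        hill climbing finds the same optimum as a dense grid."""
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(7)
        sharp = (rng.random((48, 48)) > 0.9).astype(float)

        def metric(f):
            img = gaussian_filter(sharp, sigma=0.4 + 2.0 * abs(f - 1.7))
            return float((img ** 2).mean())

        grid = np.linspace(0.0, 4.0, 401)
        best_grid = grid[int(np.argmax([metric(f) for f in grid]))]
        best_hc = autofocus_hill_climb(metric, start=0.0, step=0.8, tol=1e-3,
                                       bounds=(0.0, 4.0))
        assert best_hc == pytest.approx(best_grid, abs=0.02)

    def test_non_finite_metric_raises(self):
        with pytest.raises(ValueError):
            autofocus_hill_climb(lambda x: float("nan"), 0.0, 1.0)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            autofocus_hill_climb(lambda x: x, 0.0, 0.0)


class TestLesionValidation:
    def test_extent_ordering_enforced(self):
        with pytest.raises(ValueError):
            Lesion(0.0, 0.0, 2.0, 3.0, 1.0)

    def test_positive_height_required(self):
        with pytest.raises(ValueError):
            Lesion(0.0, 0.0, 3.0, 2.0, 0.0)

    def test_shape_mismatch_rejected(self, quiet_scene, small_protocol):
        vol = generate_cornea_volume(quiet_scene, small_protocol, 0.3)
        from panoct.synthetic import FanVolume

        with pytest.raises(ValueError, match="shape"):
            FanVolume(vol.intensity[:, :, :-1], vol.alpha_fast_deg,
                      vol.alpha_slow_deg, 5.0, 0.3, small_protocol,
                      quiet_scene.geom, 0)
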