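import numpy as np
import pytest

from panoct.morphometry import (
    SegmentationError,
    cartesian_to_fan,
    cell_areas_mm2,
    detect_lesions,
    elevation_map,
    fit_sphere,
    measure_lesion,
    run_morphometry,
    scan_convert,
    segment_surface,
)
from panoct.protocol import ScanProtocol
from panoct.scan_geometry import ScanGeometry
from panoct.synthetic import (
    Lesion,
    SyntheticScene,
    generate_retina_volume,
    reference_arm_for_surface_depth,
)


def _scene(eye, geom, lesions=(), seed=5):
    return SyntheticScene(eye=eye, geom=geom, lesions=tuple(lesions),
                          speckle_mode="none", rolloff_db_per_mm=0.0,
                          noise_floor=1e-3, seed=seed)


def _volume(scene, nf=96, ns=96, nz=768, pitch=18.0, depth=11.5):
    p = ScanProtocol(n_ascans_per_bscan=nf, n_bscans=ns, samples_per_ascan=nz,
                     sampling_rate_hz=None)
    stage = reference_arm_for_surface_depth(scene, depth)
    return generate_retina_volume(scene, p, stage, depth_pixel_pitch_um=pitch)


@pytest.fixture(scope="module")
def wide_volume(newborn_eye, default_geom):
    # angular sampling fine enough that the 5x5 median's curvature bias
    # stays below one depth pixel
    return _volume(_scene(newborn_eye, default_geom), nf=144, ns=144)


class TestSegmentSurface:
    def test_flat_scene_yields_constant_map(self, newborn_eye, small_protocol):
        geom = ScanGeometry(8.725, 0.0, 15.0, 1.357)
        scene = _scene(newborn_eye, geom)
        vol = _volume(scene, nf=33, ns=7, nz=512, pitch=5.0, depth=1.3)
        surface = segment_surface(vol)
        assert surface.valid.all()
        assert surface.depth_um.max() - surface.depth_um.min() <= (
            vol.depth_pixel_pitch_um)

    def test_noiseless_surface_tracks_generator(self, wide_volume):
        surface = segment_surface(wide_volume)
        # RPE (brightest) layer: reconstruct truth from the rendering metadata
        truth_center = (wide_volume.meta["surface_depth_center_mm"]
                        + max(wide_volume.meta["layer_offsets_um"]) / 1000) * 1000
        mid = surface.depth_um.shape[0] // 2
        jc = surface.depth_um.shape[1] // 2
        assert surface.depth_um[mid, jc] == pytest.approx(
            truth_center, abs=wide_volume.depth_pixel_pitch_um)

    def test_mostly_empty_volume_raises(self, wide_volume):
        import copy

        vol = copy.copy(wide_volume)
        vol.intensity = wide_volume.intensity.copy()
        vol.intensity[:, : int(0.8 * vol.intensity.shape[1])] = 0.0
        with pytest.raises(SegmentationError):
            segment_surface(vol)


class TestScanConversion:
    def test_center_pivot_surface_lies_on_sphere(self, newborn_eye):
        geom = ScanGeometry(8.725, 0.0, 30.0, 1.357)
        vol = _volume(_scene(newborn_eye, geom), nf=49, ns=49, nz=512,
                      pitch=10.0, depth=2.5)
        surface = segment_surface(vol)
        pts = scan_convert(surface, vol.geom)
        radii = np.linalg.norm(pts, axis=-1)
        rpe_radius = geom.radius_mm + max(vol.meta["layer_offsets_um"]) / 1000 / 1.357
        assert np.nanmax(np.abs(radii - rpe_radius)) < (
            vol.depth_pixel_pitch_um / 1000)

    def test_default_geometry_surface_on_sphere(self, wide_volume):
        surface = segment_surface(wide_volume)
        pts = scan_convert(surface, wide_volume.geom)
        rpe_radius = (wide_volume.geom.radius_mm
                      + max(wide_volume.meta["layer_offsets_um"]) / 1000 / 1.357)
        radii = np.linalg.norm(pts, axis=-1)
        # evaluate inside the designed FOV cone: the square angle grid
        # overscans its corners beyond alpha_max
        af = np.deg2rad(wide_volume.alpha_fast_deg)[None, :]
        al = np.deg2rad(wide_volume.alpha_slow_deg)[:, None]
        cone = np.degrees(np.arccos(np.cos(af) * np.cos(al))) <= (
            wide_volume.geom.pivot_half_angle_max_deg)
        assert np.nanmax(np.abs(radii - rpe_radius)[cone]) < (
            wide_volume.depth_pixel_pitch_um / 1000)

    def test_roundtrip_identity(self, wide_volume):
        surface = segment_surface(wide_volume)
        pts = scan_convert(surface, wide_volume.geom)
        O0 = surface.meta["pivot_opl_at_zero_depth_mm"]
        af, al, depth = cartesian_to_fan(pts, wide_volume.geom, O0)
        sel = surface.valid
        assert np.allclose(af[sel],
                           np.broadcast_to(wide_volume.alpha_fast_deg,
                                           af.shape)[sel], atol=1e-9)
        assert np.allclose(al[sel],
                           np.broadcast_to(wide_volume.alpha_slow_deg[:, None],
                                           al.shape)[sel], atol=1e-9)
        assert np.allclose(depth[sel], surface.depth_um[sel], atol=1e-3)

    def test_missing_metadata_rejected(self, wide_volume):
        surface = segment_surface(wide_volume)
        surface.meta.pop("pivot_opl_at_zero_depth_mm")
        with pytest.raises(ValueError, match="pivot_opl"):
            scan_convert(surface, wide_volume.geom)


class TestFitSphere:
    @staticmethod
    def _sphere_points(n, radius, center=(0.0, 0.0, 0.0), seed=0, sigma=0.0):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = np.asarray(center) + radius * u
        if sigma:
            pts = pts + rng.normal(0.0, sigma, size=pts.shape)
        return pts

    def test_exact_sphere_recovered(self):
        pts = self._sphere_points(500, 8.725, center=(1.0, -2.0, 0.5))
        fit = fit_sphere(pts)
        assert fit.radius_mm == pytest.approx(8.725, abs=1e-9)
        assert fit.center_mm == pytest.approx([1.0, -2.0, 0.5], abs=1e-9)
        assert fit.rms_mm < 1e-9

    def test_robust_to_lesion_elevated_points(self):
        pts = self._sphere_points(2000, 8.725, seed=3)
        lesion = slice(0, 200)  # 10 % of points pushed inward
        pts[lesion] *= 1.0 - 1.5 / 8.725
        fit = fit_sphere(pts)
        assert fit.radius_mm == pytest.approx(8.725, abs=0.05)

    def test_noise_monte_carlo(self):
        devs = [abs(fit_sphere(self._sphere_points(2000, 8.725, seed=s,
                                                   sigma=0.020),
                               robust=False).radius_mm - 8.725)
                for s in range(50)]
        assert max(devs) < 0.02

    def test_coplanar_points_rejected(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.random(100), rng.random(100),
                               np.zeros(100)])
        with pytest.raises(ValueError, match="coplanar"):
            fit_sphere(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sphere(np.zeros((5, 3)))


class TestElevation:
    def test_pure_sphere_has_zero_elevation(self):
        pts = TestFitSphere._sphere_points(800, 8.725)
        fit = fit_sphere(pts)
        assert elevation_map(pts, fit) == pytest.approx(0.0, abs=1e-9)

    def test_inward_points_are_positive(self):
        pts = TestFitSphere._sphere_points(800, 8.725)
        fit = fit_sphere(pts, robust=False)
        inner = pts * (1.0 - 0.5 / 8.725)
        assert np.all(elevation_map(inner, fit) > 0.4)


class TestDetectAndMeasure:
    def test_four_disjoint_lesions_found(self, newborn_eye, default_geom):
        # footprints separated by more than the 5x5 median support
        lesions = [Lesion(45.0, 0.0, 6.37, 3.05, 1.41),
                   Lesion(0.0, 0.0, 5.2, 4.04, 1.08),
                   Lesion(70.0, 120.0, 5.48, 4.71, 1.56),
                   Lesion(100.0, -100.0, 3.0, 2.0, 1.0)]
        vol = _volume(_scene(newborn_eye, default_geom, lesions), nf=160, ns=160)
        table, extras = run_morphometry(vol, min_height_mm=0.15, min_area_mm2=1.0)
        assert len(table) == 4

    def test_empty_scene_finds_nothing(self, wide_volume):
        table, _ = run_morphometry(wide_volume, 0.15, 1.0)
        assert table.empty

    def test_overlapping_pair_merges_to_one_label(self, newborn_eye, default_geom):
        lesions = [Lesion(20.0, 0.0, 4.0, 3.0, 1.0),
                   Lesion(30.0, 0.0, 4.0, 3.0, 1.0)]
        vol = _volume(_scene(newborn_eye, default_geom, lesions), nf=128, ns=128)
        table, _ = run_morphometry(vol, 0.15, 1.0)
        assert len(table) == 1

    def test_circular_cap_has_equal_axes(self, newborn_eye, default_geom):
        vol = _volume(_scene(newborn_eye, default_geom,
                             [Lesion(30.0, 0.0, 4.0, 4.0, 1.2)]), nf=160, ns=160)
        table, _ = run_morphometry(vol, 0.15, 1.0)
        row = table.iloc[0]
        assert row.Length_mm == pytest.approx(row.Width_mm, rel=0.02)
        assert row.Height_mm == pytest.approx(1.2, abs=0.02)

    def test_chord_extent_shorter_than_arc(self, newborn_eye, default_geom):
        vol = _volume(_scene(newborn_eye, default_geom,
                             [Lesion(40.0, 0.0, 6.37, 3.05, 1.41)]),
                      nf=160, ns=160)
        arc, _ = run_morphometry(vol, 0.15, 1.0, mode="arc")
        chord, _ = run_morphometry(vol, 0.15, 1.0, mode="chord")
        assert chord.iloc[0].Length_mm < arc.iloc[0].Length_mm
        assert chord.iloc[0].Length_mm == pytest.approx(arc.iloc[0].Length_mm,
                                                        rel=0.05)

    def test_azimuthal_rotation_invariance(self, newborn_eye, default_geom):
        """Rotating the scene 90 deg about the visual axis changes the
        measurements by less than 1 %."""
        rows = []
        for az in (10.0, 100.0):
            vol = _volume(_scene(newborn_eye, default_geom,
                                 [Lesion(45.0, az, 5.48, 4.71, 1.56)]),
                          nf=160, ns=160)
            table, _ = run_morphometry(vol, 0.15, 1.0)
            rows.append(table.iloc[0])
        for field in ("Length_mm", "Width_mm", "Height_mm"):
            assert rows[1][field] == pytest.approx(rows[0][field], rel=0.01)

    def test_min_area_filters_specks(self, newborn_eye, default_geom):
        vol = _volume(_scene(newborn_eye, default_geom,
                             [Lesion(30.0, 0.0, 2.0, 1.6, 0.8)]), nf=160, ns=160)
        small, _ = run_morphometry(vol, 0.15, min_area_mm2=5.0)
        kept, _ = run_morphometry(vol, 0.15, min_area_mm2=0.5)
        assert small.empty and len(kept) == 1

    def test_measure_empty_footprint_rejected(self):
        pts = TestFitSphere._sphere_points(400, 8.725).reshape(20, 20, 3)
        fit = fit_sphere(pts)
        elev = elevation_map(pts, fit)
        areas = np.ones((20, 20))
        with pytest.raises(ValueError, match="empty"):
            measure_lesion(np.zeros((20, 20), int), elev, pts, fit, areas,
                           label=1)
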