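import math

import numpy as np
import pytest

import corneaheal as ch
from corneaheal.geometry import OutsideValidDomain, ValidationError
from corneaheal.octpipe import (
    EnFaceImage,
    NoSurfaceFound,
    SurfaceMap,
    WoundMask,
    curvature_corrected_area,
    detect_anterior_surface,
    measure_oct_wound,
    project_enface,
    segment_wound_enface,
)
from corneaheal.synthetic import OCTVolume

from .oracles import cap_area_quadrature


def flat_phantom(z_index=100, samples=(48, 48, 256), extent=(5.0, 5.0, 1.0)):
    scan = ch.ScanSpec(extent=extent, samples=samples)
    vol = np.zeros(samples, dtype=np.float32)
    vol[:, :, z_index] = 1.0
    return OCTVolume(intensity=vol, scan=scan)


def disc_mask(n, radius_px, pitch):
    ii, jj = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    mask = (ii - c) ** 2 + (jj - c) ** 2 < radius_px**2
    return WoundMask(mask=mask, pitch=pitch)


def centered_disc_mask(scan, model, chord_radius_mm):
    """Disc of pixel centres within chord_radius of the apex."""
    X, Y = scan.lateral_grid()
    rho = model.rho(X, Y)
    return WoundMask(mask=rho < chord_radius_mm, pitch=scan.pitch[:2])


class TestDetectAnteriorSurface:
    def test_flat_phantom_constant_depth(self):
        """A planar interface at z-index 100 is detected at (100 + 0.5) dz everywhere."""
        vol = flat_phantom()
        s = detect_anterior_surface(vol)
        dz = vol.scan.pitch[2]
        assert np.allclose(s.depth, (100 + 0.5) * dz, atol=1e-9)
        assert s.valid.all()

    def test_spherical_phantom_tracks_analytic_surface(self, noisefree_vol96, model, scan96):
        s = detect_anterior_surface(noisefree_vol96)
        X, Y = scan96.lateral_grid()
        ztrue = model.surface_depth(X, Y)
        dz = scan96.pitch[2]
        err = np.abs(s.depth - ztrue)[s.valid]
        assert err.max() <= 2 * dz

    def test_speckled_phantom_tracks_analytic_surface(self, speckled_vol96, model, scan96):
        s = detect_anterior_surface(speckled_vol96)
        X, Y = scan96.lateral_grid()
        ztrue = model.surface_depth(X, Y)
        err = np.abs(s.depth - ztrue)[s.valid]
        assert np.quantile(err, 0.99) <= 2 * scan96.pitch[2]

    def test_all_zero_volume_raises(self):
        vol = OCTVolume(
            intensity=np.zeros((48, 48, 64), np.float32),
            scan=ch.ScanSpec(extent=(5, 5, 1), samples=(48, 48, 64)),
        )
        with pytest.raises(NoSurfaceFound):
            detect_anterior_surface(vol)

    def test_quantile_out_of_range_raises(self, noisefree_vol96):
        with pytest.raises(ValidationError):
            detect_anterior_surface(noisefree_vol96, threshold_quantile=0.4)

    def test_fitted_radius_close_to_model(self, noisefree_vol96, model):
        s = detect_anterior_surface(noisefree_vol96)
        assert s.meta["fitted_radius_mm"] == pytest.approx(model.radius_of_curvature, rel=0.15)


class TestProjectEnface:
    def test_uniform_volume_gives_uniform_image(self):
        scan = ch.ScanSpec(extent=(5, 5, 1), samples=(48, 48, 128))
        vol = OCTVolume(intensity=np.full((48, 48, 128), 0.7, np.float32), scan=scan)
        surf = SurfaceMap(
            depth=np.full((48, 48), 0.2),
            fit=np.full((48, 48), 0.2),
            valid=np.ones((48, 48), bool),
            outlier=np.zeros((48, 48), bool),
            scan=scan,
        )
        img = project_enface(vol, surf, (10, 40))
        assert np.allclose(img.intensity, 0.7)

    def test_wound_contrast_reaches_configured_minimum(self, noisefree_vol96, wound, scan96):
        """Mean en face intensity inside the true footprint >= 1.5x outside."""
        s = detect_anterior_surface(noisefree_vol96)
        img = project_enface(noisefree_vol96, s)
        inside = wound.footprint(scan96)
        ok = s.valid
        contrast = img.intensity[inside & ok].mean() / img.intensity[~inside & ok].mean()
        assert contrast >= 1.5

    def test_empty_window_raises(self, noisefree_vol96):
        s = detect_anterior_surface(noisefree_vol96)
        with pytest.raises(ValidationError):
            project_enface(noisefree_vol96, s, (10, 10))

    def test_inverted_window_raises(self, noisefree_vol96):
        s = detect_anterior_surface(noisefree_vol96)
        with pytest.raises(ValidationError):
            project_enface(noisefree_vol96, s, (40, 10))


class TestSegmentWoundEnface:
    def test_binary_disc_recovered_exactly(self):
        """An already-binary disc image segments to the disc itself."""
        n, r = 128, 40
        disc = disc_mask(n, r, (0.03, 0.03)).mask
        img = EnFaceImage(intensity=np.where(disc, 1.0, 0.0), pitch=(0.03, 0.03))
        m = segment_wound_enface(img, min_area_mm2=0.2)
        assert not m.empty_wound
        assert m.n_foreground == pytest.approx(disc.sum(), rel=0.01)
        assert (m.mask & ~disc).sum() <= 0.01 * disc.sum()

    def test_uniform_image_flags_closed_wound(self):
        img = EnFaceImage(intensity=np.full((64, 64), 0.3), pitch=(0.05, 0.05))
        m = segment_wound_enface(img)
        assert m.empty_wound and m.n_foreground == 0

    def test_speckled_phantom_area_close_to_footprint(self, speckled_vol96, scan96):
        s = detect_anterior_surface(speckled_vol96)
        img = project_enface(speckled_vol96, s)
        m = segment_wound_enface(img, roi=s.valid)
        assert m.n_foreground == pytest.approx(speckled_vol96.metadata["footprint_pixels"], rel=0.05)

    def test_nonfinite_pixels_raise(self):
        img = EnFaceImage(intensity=np.full((32, 32), np.nan), pitch=(0.05, 0.05))
        with pytest.raises(ValidationError):
            segment_wound_enface(img)

    def test_subminimal_area_flagged_closed(self):
        img = EnFaceImage(intensity=np.zeros((64, 64)), pitch=(0.05, 0.05))
        img.intensity[30:33, 30:33] = 1.0  # 9 px = 0.0225 mm2 < 0.2 mm2
        m = segment_wound_enface(img, min_area_mm2=0.2)
        assert m.empty_wound


class TestCurvatureCorrectedArea:
    def test_disc_matches_spherical_cap(self, model):
        """Centred 3-mm disc at R = 7.5: corrected ~ 29.51 mm^2, projected ~ 28.27 mm^2."""
        scan = ch.ScanSpec(extent=(7.5, 7.5, 1.0), samples=(512, 512, 32))
        mask = centered_disc_mask(scan, model, 3.0)
        res = curvature_corrected_area(mask, scan, model)
        truth = cap_area_quadrature(7.5, 3.0)  # = 2 pi R^2 (1 - sqrt(1 - (3/7.5)^2)) = 29.506
        assert truth == pytest.approx(29.506, abs=5e-3)
        assert res.corrected_area_mm2 == pytest.approx(truth, rel=0.01)
        assert res.projected_area_mm2 == pytest.approx(math.pi * 9, rel=0.01)

    def test_flat_limit_equality(self):
        flat = ch.CorneaModel(radius_of_curvature=1e6)
        scan = ch.ScanSpec(extent=(7.5, 7.5, 1.0), samples=(256, 256, 32))
        mask = centered_disc_mask(scan, flat, 3.0)
        res = curvature_corrected_area(mask, scan, flat)
        assert abs(res.corrected_area_mm2 / res.projected_area_mm2 - 1) < 1e-5

    def test_single_apex_pixel(self, model):
        scan = ch.ScanSpec(extent=(7.5, 7.5, 1.0), samples=(64, 64, 32))
        mask = np.zeros((64, 64), bool)
        mask[32, 32] = True  # pixel centre at (+dx/2, +dy/2): essentially the apex
        res = curvature_corrected_area(WoundMask(mask, scan.pitch[:2]), scan, model)
        assert res.projected_area_mm2 == pytest.approx(scan.pixel_area_mm2)
        assert res.corrected_area_mm2 == pytest.approx(scan.pixel_area_mm2, rel=1e-4)

    def test_monotone_in_curvature(self, model):
        """Corrected area grows as the cornea gets more curved (1/R increases)."""
        scan = ch.ScanSpec(extent=(7.5, 7.5, 1.0), samples=(128, 128, 32))
        mask = centered_disc_mask(scan, model, 3.0)
        areas = [
            curvature_corrected_area(mask, scan, ch.CorneaModel(radius_of_curvature=R)).corrected_area_mm2
            for R in (1e6, 20.0, 10.0, 7.5, 5.0)
        ]
        assert np.all(np.diff(areas) > 0)

    def test_outside_domain_raises(self):
        small = ch.CorneaModel(radius_of_curvature=2.0)
        scan = ch.ScanSpec(extent=(7.5, 7.5, 1.0), samples=(64, 64, 32))
        mask = centered_disc_mask(scan, small, 1.0).mask
        mask[0, 0] = True  # corner pixel at rho ~ 5.2 mm > R = 2 mm
        with pytest.raises(OutsideValidDomain):
            curvature_corrected_area(WoundMask(mask, scan.pitch[:2]), scan, small)

    def test_empty_mask_zero_area(self, model):
        scan = ch.ScanSpec(extent=(7.5, 7.5, 1.0), samples=(64, 64, 32))
        res = curvature_corrected_area(WoundMask(np.zeros((64, 64), bool), scan.pitch[:2]), scan, model)
        assert res.projected_area_mm2 == 0.0 and res.corrected_area_mm2 == 0.0


class TestMeasureOctWound:
    def test_noise_free_recovers_trephine_diameter(self, noisefree_vol96, model):
        m = measure_oct_wound(noisefree_vol96, model)
        assert m.equivalent_diameter_mm == pytest.approx(6.0, abs=0.1)
        assert m.corrected_area_mm2 >= m.projected_area_mm2

    def test_speckled_corrected_area_close_to_cap_truth(self, speckled_vol96, model, wound):
        m = measure_oct_wound(speckled_vol96, model)
        assert m.corrected_area_mm2 == pytest.approx(wound.cap_area(7.5), rel=0.05)

    def test_healed_phantom_reports_closed(self, healed_vol96, model):
        m = measure_oct_wound(healed_vol96, model)
        assert m.empty_wound and m.area_mm2 == 0.0

    def test_translation_robustness(self, model):
        """Shifting the wound centre by 1 mm changes the projected area by < 2%.

        Uses a 1.6-mm-deep scan: at the standard 1-mm depth the anterior
        surface leaves the volume at rho ~ 3.6 mm, so a decentred 6-mm wound
        would be genuinely clipped out of the field rather than mismeasured.
        """
        scan = ch.ScanSpec(extent=(7.5, 7.5, 1.6), samples=(96, 96, 128))
        noise = ch.NoiseSpec(speckle_contrast=0.0)
        a = measure_oct_wound(
            ch.generate_oct_volume(model, ch.WoundSpec(), scan, noise, seed=0), model
        )
        b = measure_oct_wound(
            ch.generate_oct_volume(model, ch.WoundSpec(center=(0.7, -0.7)), scan, noise, seed=0),
            model,
        )
        assert abs(b.projected_area_mm2 / a.projected_area_mm2 - 1) < 0.02

    def test_resolution_convergence(self, model, wound):
        """Measured area error shrinks from coarse to fine lateral sampling."""
        noise = ch.NoiseSpec(speckle_contrast=0.0)
        errs = []
        for n in (64, 128, 256):
            vol = ch.generate_oct_volume(model, wound, ch.ScanSpec.reduced(n), noise, seed=0)
            m = measure_oct_wound(vol, model)
            errs.append(abs(m.projected_area_mm2 / wound.planar_area - 1))
        assert errs[2] <= errs[0]
        assert errs[2] < 0.005

    def test_fit_radius_mode_reports_both_radii(self, noisefree_vol96, model):
        m = measure_oct_wound(noisefree_vol96, model, ch.OCTConfig(fit_radius=True))
        d = m.diagnostics["area"]
        assert d["radius_used_mm"] == pytest.approx(d["fitted_radius_mm"])
        assert d["configured_radius_mm"] == 7.5
        assert m.corrected_area_mm2 == pytest.approx(ch.WoundSpec().cap_area(7.5), rel=0.05)

    def test_stage_error_identifies_stage(self):
        vol = OCTVolume(
            intensity=np.zeros((48, 48, 64), np.float32),
            scan=ch.ScanSpec(extent=(5, 5, 1), samples=(48, 48, 64)),
        )
        with pytest.raises(ch.PipelineStageError) as exc:
            measure_oct_wound(vol, ch.CorneaModel())
        assert exc.value.stage == "detect_anterior_surface"
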