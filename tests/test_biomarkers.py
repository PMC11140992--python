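"""ROI arithmetic, thicknesses, flattening, profiles, band region, ellipse."""

import numpy as np
import pandas as pd
import pytest

from octenergy.biomarkers import (
    BandNotFoundError,
    BandRegion,
    ReflectivityProfile,
    RoiSpec,
    ez_band_region,
    fit_ellipse_moments,
    flatten_to_brm,
    layer_thickness,
    mean_profile,
    measure_eye,
    roi_columns,
)
from octenergy.segmentation import BoundaryTrace, SegmentationResult, detect_elm_rpe, segment

from conftest import small_config
from octenergy.phantom import synth_bscan_stack


class TestRoiColumns:
    def test_worked_example(self):
        cols = roi_columns(RoiSpec(500, 1.4, "superior"), 1000)
        assert cols.min() == 750 and cols.max() == 945
        cols = roi_columns(RoiSpec(500, 1.4, "inferior"), 1000)
        assert cols.min() == 55 and cols.max() == 250

    def test_unit_scale(self):
        cols = roi_columns(RoiSpec(0, 1.0, "superior"), 2000)
        assert cols.min() == 350 and cols.max() == 624

    def test_truncation_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            cols = roi_columns(RoiSpec(500, 1.4, "superior"), 900)
        assert cols.max() == 899

    def test_empty_roi_errors(self):
        with pytest.raises(ValueError):
            roi_columns(RoiSpec(990, 1.4, "superior"), 1000)


def _flat_seg(cols, **depths):
    return SegmentationResult(traces={
        k: BoundaryTrace(k, np.full(cols, float(v))) for k, v in depths.items()
    })


class TestLayerThickness:
    def test_flat_example(self):
        seg = _flat_seg(100, ELM=300.0, BrM=330.0)
        roi = np.arange(20, 80)
        assert layer_thickness(seg, roi, "ELM", "BrM", 1.6) == pytest.approx(48.0)

    def test_identical_traces_zero(self):
        seg = _flat_seg(50, ELM=200.0, BrM=200.0)
        assert layer_thickness(seg, np.arange(50), "ELM", "BrM", 1.6) == 0.0

    def test_undefined_fraction_errors(self):
        d = np.full(100, 300.0)
        d[:20] = np.nan
        seg = SegmentationResult(traces={
            "ELM": BoundaryTrace("ELM", d),
            "BrM": BoundaryTrace("BrM", np.full(100, 330.0)),
        })
        with pytest.raises(ValueError, match="undefined"):
            layer_thickness(seg, np.arange(100), "ELM", "BrM", 1.6)


class TestFlatten:
    def test_flat_brm_global_shift_only(self, nf_flat):
        stack, truth = nf_flat
        img = stack.frames[0].astype(float)
        flat = flatten_to_brm(img, truth.boundaries["BrM"])
        assert np.ptp(flat.shifts) == 0
        s = flat.shifts[0]
        inner = slice(max(0, s), min(img.shape[0], img.shape[0] + s))
        assert np.array_equal(flat.data[inner], img[inner.start - s : inner.stop - s])

    def test_curved_brm_constant_after_flattening(self, nf_curved):
        stack, truth = nf_curved
        img = stack.frames[0].astype(float)
        seg = segment(img)
        flat = flatten_to_brm(img, seg["BrM"].depth)
        # re-detect the bands in the flattened image
        shifted = SegmentationResult(traces={
            k: BoundaryTrace(k, v.depth + flat.shifts) for k, v in seg.traces.items()
        })
        _, _, brm2 = detect_elm_rpe(flat.data, shifted)
        inner = slice(5, -5)
        # integer (non-stretching) shifts leave at most +-0.5 px of the
        # original curvature around the fixed target row
        dev = brm2.depth[inner] - np.median(brm2.depth[inner])
        assert np.abs(dev).max() <= 0.5

    def test_thickness_preserved(self, nf_curved):
        stack, truth = nf_curved
        img = stack.frames[0].astype(float)
        seg = segment(img)
        flat = flatten_to_brm(img, seg["BrM"].depth)
        before = seg["BrM"].depth - seg["ELM"].depth
        after = (seg["BrM"].depth + flat.shifts) - (seg["ELM"].depth + flat.shifts)
        assert np.array_equal(before, after)


class TestMeanProfile:
    def test_identical_columns_equal_single_column(self, nf_flat):
        stack, truth = nf_flat
        cfg = small_config(curvature_um=0.0, n_vessels=0, seed=1)
        stack, truth = synth_bscan_stack(cfg)
        img = stack.frames[0].astype(float)
        flat = flatten_to_brm(img, truth.boundaries["BrM"])
        prof = mean_profile(flat, np.arange(100, 130))
        col = flat.data[flat.mask[:, 100], 100]
        assert np.allclose(prof.intensity, col)

    def test_disjoint_identical_rois_match(self):
        cfg = small_config(curvature_um=0.0, n_vessels=0, seed=1)
        stack, truth = synth_bscan_stack(cfg)
        flat = flatten_to_brm(stack.frames[0].astype(float), truth.boundaries["BrM"])
        p1 = mean_profile(flat, np.arange(50, 80))
        p2 = mean_profile(flat, np.arange(300, 330))
        assert np.allclose(p1.intensity, p2.intensity)
        assert np.array_equal(p1.depth, p2.depth)


def gaussian_pair_profile(amp_elm=20000.0, amp_ez=30000.0, elm=-30.0, ez=-20.0,
                          s_elm=1.5, s_ez=2.5, bg=13000.0, offset=0.0):
    depth = np.arange(-60.0, 10.0)
    y = (bg + offset
         + amp_elm * np.exp(-0.5 * ((depth - elm) / s_elm) ** 2)
         + amp_ez * np.exp(-0.5 * ((depth - ez) / s_ez) ** 2))
    return ReflectivityProfile(depth, y)


class TestEzBandRegion:
    def test_left_edge_at_trough(self):
        prof = gaussian_pair_profile()
        region = ez_band_region(prof, elm_depth=-30.0)
        # trough between the two Gaussians
        trough = prof.depth[np.argmin(prof.intensity[(prof.depth > -30) & (prof.depth < -20)]) + int(np.sum(prof.depth <= -30))]
        assert region.x_left == pytest.approx(trough, abs=1.0)
        assert region.x_left > -30.0 and region.x_right > -20.0

    def test_monotone_posterior_profile_errors(self):
        depth = np.arange(-40.0, 0.0)
        y = 20000.0 * np.exp(-0.5 * ((depth + 30) / 2.0) ** 2) + np.linspace(3000, 0, 40)
        prof = ReflectivityProfile(depth, y)
        with pytest.raises(BandNotFoundError):
            ez_band_region(prof, elm_depth=-30.0)

    def test_additive_offset_invariance(self):
        r1 = ez_band_region(gaussian_pair_profile(), -30.0)
        r2 = ez_band_region(gaussian_pair_profile(offset=500.0), -30.0)
        assert r1.x_left == r2.x_left and r1.x_right == r2.x_right
        assert np.allclose(r2.curve - r2.baseline, r1.curve - r1.baseline)


class TestEllipseFit:
    def test_circle(self):
        r = 5.0
        x = np.linspace(-r, r, 20001)
        half = np.sqrt(np.maximum(r * r - x * x, 0.0))
        fit = fit_ellipse_moments(BandRegion(-r, r, x, half, -half),
                                  intensity_scale=1.0, oversample=2000)
        assert fit.aspect_ratio == pytest.approx(1.0, abs=1e-6)
        assert fit.area == pytest.approx(np.pi * r * r, rel=1e-4)

    @pytest.mark.parametrize("w,h", [(8.0, 3.0), (4.0, 9.0), (5.0, 5.0)])
    def test_rectangle_aspect_equals_side_ratio(self, w, h):
        x = np.linspace(0.0, w, 201)
        fit = fit_ellipse_moments(
            BandRegion(0.0, w, x, np.full_like(x, h), np.zeros_like(x)),
            intensity_scale=1.0,
        )
        assert fit.aspect_ratio == pytest.approx(min(w, h) / max(w, h), abs=1e-3)
        assert fit.area == pytest.approx(w * h, rel=1e-9)

    def test_intensity_scale_rescales_rectangle(self):
        # doubling s halves the intensity-axis extent: for a w x h/s
        # rectangle the aspect ratio follows min/max of the new sides
        w, h = 6.0, 8000.0
        x = np.linspace(0.0, w, 201)
        region = BandRegion(0.0, w, x, np.full_like(x, h), np.zeros_like(x))
        s1, s2 = 1000.0, 2000.0
        ar1 = fit_ellipse_moments(region, s1).aspect_ratio
        ar2 = fit_ellipse_moments(region, s2).aspect_ratio
        assert ar1 == pytest.approx(min(w, h / s1) / max(w, h / s1), abs=1e-3)
        assert ar2 == pytest.approx(min(w, h / s2) / max(w, h / s2), abs=1e-3)

    def test_matches_rasterization_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 25
            x = np.linspace(0.0, 12.0, n)
            base = np.linspace(rng.uniform(0, 2), rng.uniform(1, 3), n)
            curve = base + np.sin(np.linspace(0, np.pi, n)) ** rng.uniform(0.8, 1.6) \
                * rng.uniform(3, 7)
            region = BandRegion(0.0, 12.0, x, curve, base)
            fit = fit_ellipse_moments(region, 1.0)
            # pixel-moment oracle on a dense rasterization
            N = 1200
            gx = np.linspace(0, 12, N)
            gy = np.linspace(base.min() - 0.5, curve.max() + 0.5, N)
            gb = np.interp(gx, x, base)
            gc = np.interp(gx, x, curve)
            M = (gy[:, None] >= gb[None, :]) & (gy[:, None] <= gc[None, :])
            ys, xs = np.nonzero(M)
            px, py = gx[xs], gy[ys]
            cov = np.cov(np.stack([px, py]))
            ev = np.linalg.eigvalsh(cov)
            oracle = np.sqrt(max(ev[0], 0) / ev[1])
            assert fit.aspect_ratio == pytest.approx(oracle, rel=0.01)


class TestMeasureEye:
    def test_noise_free_recovery_and_determinism(self, nf_curved):
        stack, truth = nf_curved
        meta = {"mouse": "m0", "group": "WT", "condition": "light", "cs": 15.0}
        recs1 = measure_eye(stack, meta, registration_kwargs={"rot_max_deg": 0.5})
        recs2 = measure_eye(stack, meta, registration_kwargs={"rot_max_deg": 0.5})
        for r in recs1:
            assert abs(r.elm_rpe_um - truth.elm_rpe_um) <= 1.6
            assert 0 < r.mcp_ar <= 1.0
            assert abs(r.ipl_um - 55.0) <= 1.6
            assert abs(r.inl_opl_um - 50.0) <= 1.6
        df1 = pd.DataFrame([r.as_dict() for r in recs1])
        df2 = pd.DataFrame([r.as_dict() for r in recs2])
        assert df1.equals(df2)

    def test_stage_error_carries_eye_id(self):
        from octenergy.phantom import BScanStack

        bad = BScanStack(frames=np.zeros((1, 128, 128), dtype=np.uint16),
                         axial_px_um=1.6, lateral_px_um=2.8, onh_col=64)
        with pytest.raises(RuntimeError, match=r"\[register\] eye m9"):
            measure_eye(bad, {"mouse": "m9"})
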