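"""Phantom generator: profile construction, stack rendering, cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octenergy.phantom import (
    LAYER_ORDER,
    CohortSpec,
    GroupSpec,
    LayerSpec,
    PhantomConfig,
    PhantomSizingError,
    make_retina_layers,
    simulate_cohort,
    synth_bscan_stack,
    synth_profile,
)

from conftest import small_config


def fwhm(profile, px_um):
    """Full width at half maximum of the dominant peak, by linear
    interpolation of the half-maximum crossings."""
    p = profile - profile.min()
    half = p.max() / 2.0
    above = np.where(p >= half)[0]
    i0, i1 = above[0], above[-1]
    left = i0 - 1 + (half - p[i0 - 1]) / (p[i0] - p[i0 - 1])
    right = i1 + (half - p[i1]) / (p[i1 + 1] - p[i1])
    return (right - left) * px_um


class TestSynthProfile:
    def test_two_slab_step(self):
        layers = [
            LayerSpec("ILM", 50.0, 100.0),
            LayerSpec("GCL/IPL", 50.0, 200.0),
        ]
        profile, bounds = synth_profile(
            layers, axial_px_um=1.0, n_px=256, offset_um=0.0,
            vitreous_reflectivity=100.0, edge_sigma_um=0.5,
        )
        assert bounds["ILM"] == 0.0
        assert bounds["GCL/IPL"] == 50.0
        # plateaus at the slab reflectivities, transition midpoint at 50 px
        assert np.allclose(profile[10:40], 100.0, atol=0.5)
        assert np.allclose(profile[60:90], 200.0, atol=0.5)
        assert abs(profile[50] - 150.0) < 1.0

    def test_band_peak_value_on_zero_background(self):
        layers = [LayerSpec("ELM", 20.0, 0.0, amplitude=30000.0, width_sigma_um=2.0)]
        profile, bounds = synth_profile(
            layers, axial_px_um=1.0, n_px=128, offset_um=0.0,
            vitreous_reflectivity=0.0,
        )
        centre = bounds["ELM"]
        assert centre == 10.0
        assert profile[int(centre)] == pytest.approx(30000.0, abs=1.0)
        assert profile.argmax() == int(centre)

    def test_ez_fwhm_doubles_with_sigma(self):
        def prof(sigma):
            layers = [LayerSpec("EZ", 60.0, 0.0, amplitude=20000.0, width_sigma_um=sigma)]
            p, _ = synth_profile(layers, 0.5, n_px=256, offset_um=0.0,
                                 vitreous_reflectivity=0.0)
            return p

        w1 = fwhm(prof(3.0), 0.5)
        w2 = fwhm(prof(6.0), 0.5)
        assert w1 == pytest.approx(2.355 * 3.0, rel=0.02)
        assert w2 / w1 == pytest.approx(2.0, rel=0.02)

    def test_band_maxima_and_plateaus_default_stack(self):
        layers = make_retina_layers(elm_rpe_um=50.0)
        profile, bounds = synth_profile(layers, 1.6, n_px=400)
        for band in ("ELM", "EZ", "RPE"):
            c = int(round(bounds[band]))
            assert profile[c] >= profile[c - 2]
            assert profile[c] >= profile[c + 2]
        # ONL plateau at its base reflectivity
        onl_mid = int((bounds["OPL/ONL"] + bounds["ELM"]) / 2)
        assert profile[onl_mid] == pytest.approx(11000.0, rel=0.02)

    def test_field_of_view_error(self):
        layers = make_retina_layers()
        with pytest.raises(PhantomSizingError):
            synth_profile(layers, 1.6, n_px=128)

    def test_layer_order_enforced(self):
        layers = [LayerSpec("GCL/IPL", 50, 100.0), LayerSpec("ILM", 50, 200.0)]
        with pytest.raises(ValueError, match="order"):
            synth_profile(layers, 1.0, 512)


class TestSynthStack:
    def test_no_noise_no_jitter_frames_identical(self):
        cfg = small_config(n_frames=3, seed=5)
        stack, _ = synth_bscan_stack(cfg)
        assert np.array_equal(stack.frames[0], stack.frames[1])
        assert np.array_equal(stack.frames[0], stack.frames[2])

    def test_zero_curvature_traces_constant(self, nf_flat):
        _, truth = nf_flat
        for name, depth in truth.boundaries.items():
            assert np.ptp(depth) == 0.0, name

    def test_fixed_seed_bit_identical(self):
        cfg = small_config(speckle_sigma=0.05, max_jitter_rot_deg=1.0,
                           max_jitter_shift_px=3.0, n_frames=3, seed=77)
        s1, t1 = synth_bscan_stack(cfg)
        s2, t2 = synth_bscan_stack(cfg)
        assert np.array_equal(s1.frames, s2.frames)
        assert t1.frame_transforms == t2.frame_transforms

    def test_noise_free_column_reproduces_profile(self):
        """A zero-curvature, vessel-free rendering is the 1-D profile
        extruded laterally (up to 16-bit quantization)."""
        cfg = small_config(curvature_um=0.0, n_vessels=0, seed=9)
        stack, _ = synth_bscan_stack(cfg)
        layers = make_retina_layers()
        profile, _ = synth_profile(
            layers, cfg.axial_px_um, cfg.rows,
            offset_um=cfg.ilm_offset_um,
            vitreous_reflectivity=cfg.vitreous_reflectivity,
            edge_sigma_um=cfg.edge_sigma_um,
        )
        for c in (0, 100, 300):
            assert np.max(np.abs(stack.frames[0][:, c].astype(float) - profile)) <= 0.5

    def test_first_frame_is_identity(self):
        cfg = small_config(max_jitter_rot_deg=1.0, max_jitter_shift_px=3.0,
                           n_frames=4, seed=6)
        stack, truth = synth_bscan_stack(cfg)
        assert truth.frame_transforms[0] == (0.0, 0.0, 0.0)
        assert len(truth.frame_transforms) == 4

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), elm_rpe=st.floats(44.0, 58.0))
    def test_boundary_ordering_monotone(self, seed, elm_rpe):
        cfg = small_config(seed=seed)
        _, truth = synth_bscan_stack(cfg, elm_rpe_um=elm_rpe)
        truth.check_ordering()
        order = [n for n in LAYER_ORDER if n in truth.boundaries]
        d = np.stack([truth.boundaries[n] for n in order])
        assert np.all(np.diff(d, axis=0) > 0)

    def test_truth_elm_rpe_matches_request(self):
        _, truth = synth_bscan_stack(small_config(seed=4), elm_rpe_um=47.5)
        assert truth.elm_rpe_um == pytest.approx(47.5, abs=1e-9)


def tiny_cohort_phantom():
    # geometry is irrelevant for truth-table tests; keep rendering cheap
    return PhantomConfig(rows=96, cols=64, axial_px_um=6.0, lateral_px_um=2.8,
                         curvature_um=0.0, ilm_offset_um=60.0, n_vessels=0)


class TestSimulateCohort:
    def test_group_mean_difference(self):
        spec = CohortSpec(
            groups=(
                GroupSpec("A", "light", 50, elm_rpe_um=50.0, elm_rpe_sd=0.5),
                GroupSpec("B", "dark", 50, elm_rpe_um=46.0, elm_rpe_sd=0.5),
            ),
            phantom=tiny_cohort_phantom(),
            seed=11,
        )
        _, table = simulate_cohort(spec)
        means = table.groupby("group")["elm_rpe_um"].mean()
        # sample means differ by 4 um up to between-mouse noise (sd 0.5, n 50)
        assert means["A"] - means["B"] == pytest.approx(4.0, abs=3 * 0.5 / np.sqrt(25))

    def test_cs_fold_design_point(self):
        spec = CohortSpec(
            groups=(
                GroupSpec("WT", "light", 200, cs_mean=15.0, cs_shape=30.0),
                GroupSpec("5xFAD", "light", 200, cs_mean=9.0, cs_shape=30.0),
            ),
            phantom=tiny_cohort_phantom(),
            seed=13,
        )
        _, table = simulate_cohort(spec)
        m = table.groupby("group")["cs"].mean()
        assert m["5xFAD"] / m["WT"] == pytest.approx(0.6, abs=0.04)

    def test_degenerate_noise_identical_mice(self):
        spec = CohortSpec(
            groups=(GroupSpec("A", "light", 4, elm_rpe_um=50.0, elm_rpe_sd=0.0),),
            phantom=tiny_cohort_phantom(),
            seed=3,
        )
        _, table = simulate_cohort(spec)
        assert table["elm_rpe_um"].nunique() == 1

    def test_reproducible(self):
        spec = CohortSpec(
            groups=(GroupSpec("A", "dark", 3),),
            phantom=tiny_cohort_phantom(),
            seed=21,
        )
        mice1, t1 = simulate_cohort(spec)
        mice2, t2 = simulate_cohort(spec)
        assert t1.equals(t2)
        assert np.array_equal(mice1[0].stack.frames, mice2[0].stack.frames)

    def test_validation(self):
        with pytest.raises(ValueError):
            GroupSpec("A", "light", 1)
        with pytest.raises(ValueError):
            GroupSpec("A", "twilight", 3)
        with pytest.raises(ValueError):
            GroupSpec("A", "light", 3, cs_mean=-1.0)
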