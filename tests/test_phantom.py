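import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hkemidif.phantom import (PhantomConfig, TissueTACTable, make_frame_scheme,
                              make_phantom, sample_activity_image, tissue_tac,
                              true_curve)


class TestFrameScheme:
    def test_default_scheme_expands_to_45_contiguous_frames(self, default_scheme):
        assert len(default_scheme) == 45
        assert default_scheme[0] == (0.0, 6.0)
        # contiguity: every frame starts where the previous one ended
        ends = [s + d for s, d in default_scheme]
        starts = [s for s, _ in default_scheme]
        assert starts[1:] == ends[:-1]

    def test_default_scheme_total_duration(self, default_scheme):
        expected = 17 * 6 + 4 * 15 + 4 * 30 + 4 * 60 + 4 * 180 + 12 * 300
        assert default_scheme.total_duration == expected == 4842

    def test_singleton_spec(self):
        scheme = make_frame_scheme([(1, 10)])
        assert tuple(scheme) == ((0.0, 10.0),)

    @pytest.mark.parametrize("bad", [[], [(0, 6)], [(3, 0)], [(2, -1)]])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            make_frame_scheme(bad)

    @given(st.lists(st.tuples(st.integers(1, 6),
                              st.floats(0.5, 400.0)), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_expansion_conserves_total_duration(self, spec):
        scheme = make_frame_scheme(spec)
        assert len(scheme) == sum(c for c, _ in spec)
        assert np.isclose(scheme.total_duration,
                          sum(c * d for c, d in spec), rtol=1e-12)


class TestMakePhantom:
    def test_default_contains_aorta_with_at_least_four_voxels(self):
        labels, mu, guidance = make_phantom()
        assert labels.labels.shape == (64, 64)
        assert labels.mask("aorta").sum() >= 4
        assert set(labels.label_names.values()) >= {"aorta"}

    def test_noiseless_guidance_is_piecewise_constant(self, small_phantom):
        labels, _, guidance = small_phantom
        for lbl in np.unique(labels.labels):
            if lbl == 0:
                continue
            assert len(np.unique(guidance[labels.labels == lbl])) == 1

    def test_aorta_in_plane_width_matches_brute_force_circle(self):
        # 5 mm diameter at 1.56 mm spacing: voxel centres within the circle
        cfg = PhantomConfig(grid_size=64, guidance_noise_sigma=0.0)
        labels, _, _ = make_phantom(cfg)
        aorta = labels.mask("aorta")
        ys, xs = np.where(aorta)
        assert xs.max() - xs.min() + 1 == 3  # round(5 / 1.56)
        assert ys.max() - ys.min() + 1 == 3
        # brute-force oracle: centre of the aorta circle, count voxel centres
        cy = (ys.min() + ys.max() + 1) / 2 * 1.56
        cx = (xs.min() + xs.max() + 1) / 2 * 1.56
        count = 0
        for iy in range(64):
            for ix in range(64):
                y, x = (iy + 0.5) * 1.56, (ix + 0.5) * 1.56
                if (y - cy) ** 2 + (x - cx) ** 2 <= 2.5**2:
                    count += 1
        assert aorta.sum() == count

    def test_mu_map_air_zero_soft_tissue_waterlike(self, small_phantom):
        labels, mu, _ = small_phantom
        assert np.all(mu.values[labels.labels == 0] == 0.0)
        assert np.allclose(mu.values[labels.labels > 0], 0.0096)

    def test_slab_mode_replicates_slices(self):
        cfg = PhantomConfig(grid_size=48, n_slices=3, guidance_noise_sigma=0.0)
        labels, mu, guidance = make_phantom(cfg)
        assert labels.labels.shape == (3, 48, 48)
        assert labels.voxel_size == (2.031, 1.56, 1.56)
        assert np.array_equal(labels.labels[0], labels.labels[2])

    def test_degenerate_aorta_rejected(self):
        with pytest.raises(ValueError, match="aorta"):
            make_phantom(PhantomConfig(aorta_diameter_mm=2.0))

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            make_phantom(PhantomConfig(voxel_size_mm=0.0))


class TestTissueTAC:
    @pytest.mark.parametrize("model", ["blood", "uptake"])
    def test_zero_at_injection_time(self, model):
        assert tissue_tac(model, None, 0.0) == 0.0

    def test_blood_peaks_before_sixty_seconds(self):
        t = np.arange(0.0, 600.0, 0.5)
        curve = tissue_tac("blood", None, t)
        assert t[np.argmax(curve)] < 60.0

    def test_uptake_approaches_plateau(self):
        plateau, tau = 12.5, 300.0
        val = tissue_tac("uptake", {"plateau": plateau, "tau_s": tau}, 10 * tau)
        assert val == pytest.approx(plateau, rel=0.01)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            tissue_tac("blood", None, -1.0)

    @given(st.floats(0.0, 5000.0))
    @settings(max_examples=100, deadline=None)
    def test_curves_nonnegative(self, t):
        assert tissue_tac("blood", None, t) >= 0.0
        assert tissue_tac("uptake", None, t) >= 0.0


class _LinearTAC(TissueTACTable):
    """Test helper: a(t) = t for every tissue."""

    def value(self, tissue, t):
        return np.asarray(t, dtype=float)


class TestSampleActivityImage:
    def test_identical_curves_give_uniform_image(self, small_phantom,
                                                 default_scheme):
        labels, _, _ = small_phantom
        # near-instant saturation: a(t) ~ plateau over the whole frame
        curves = {name: ("uptake", {"plateau": 7.0, "tau_s": 1e-9})
                  for name in labels.label_names.values()}
        img = sample_activity_image(labels, TissueTACTable(curves), (100.0, 50.0))
        assert np.allclose(img[labels.labels > 0], 7.0)
        assert np.all(img[labels.labels == 0] == 0.0)

    def test_linear_curve_frame_average_is_exact_midpoint(self, small_phantom):
        labels, _, _ = small_phantom
        table = _LinearTAC({n: ("blood", {}) for n in labels.label_names.values()})
        img = sample_activity_image(labels, table, (0.0, 10.0))
        assert np.allclose(img[labels.labels > 0], 5.0)

    def test_blood_frame_average_matches_fine_quadrature(self, tac_table):
        frame = (24.0, 6.0)
        got = tac_table.frame_average("aorta", frame, dt=0.1)
        t = np.linspace(frame[0], frame[0] + frame[1], 60001)
        oracle = np.trapezoid(tac_table.value("aorta", t), t) / frame[1]
        assert got == pytest.approx(oracle, rel=1e-3)

    def test_missing_label_error_names_the_tissue(self, small_phantom):
        labels, _, _ = small_phantom
        table = TissueTACTable({"aorta": ("blood", {})})
        with pytest.raises(KeyError, match="kidney|stomach|background"):
            sample_activity_image(labels, table, (0.0, 6.0))

    def test_pointwise_ordering_of_curves_orders_voxel_values(self, small_phantom):
        labels, _, _ = small_phantom
        hi = {"plateau": 20.0, "tau_s": 100.0}
        lo = {"plateau": 5.0, "tau_s": 100.0}
        curves = {n: ("uptake", hi if n == "aorta" else lo)
                  for n in labels.label_names.values()}
        img = sample_activity_image(labels, TissueTACTable(curves), (30.0, 60.0))
        assert img[labels.mask("aorta")].min() > img[labels.mask("kidney")].max()

    def test_true_curve_equals_aorta_roi_mean_of_sampled_image(
            self, small_phantom, tac_table, default_scheme):
        labels, _, _ = small_phantom
        truth = true_curve(tac_table, default_scheme)
        for k in (0, 3, 20, 44):
            img = sample_activity_image(labels, tac_table, default_scheme[k])
            assert img[labels.mask("aorta")].mean() == pytest.approx(truth[k],
                                                                     rel=1e-12)
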