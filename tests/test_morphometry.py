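"""Foveal/macular curvature, centre-point thickness, tertile validation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foveapit import morphometry as mm
from foveapit import synthetic as syn
from foveapit.segmentation import VolumeTraces


def quad_rows(a, x0, c0, width=512):
    """ILM-style rows with pit-positive leading coefficient a at column x0."""
    x = np.arange(width, dtype=float)
    return c0 - a * (x - x0) ** 2


def closed_form_quadratic(x, y):
    """Independent least-squares oracle via the normal equations."""
    X = np.column_stack([x**2, x, np.ones_like(x)])
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFoveaCenter:
    def make_traces(self, thick):
        S, W = thick.shape
        ilm = np.full((S, W), 100.0)
        return ilm, ilm + thick

    def test_unique_minimum(self):
        thick = np.full((128, 512), 120.0)
        thick[64, 256] = 80.0
        c = mm.locate_fovea_center(*self.make_traces(thick))
        assert (c.slice, c.column) == (64, 256)

    def test_plateau_centroid(self):
        """Three equal minimal cells -> centroid column (brute-force rule)."""
        thick = np.full((128, 512), 120.0)
        thick[64, 255:258] = 80.0
        c = mm.locate_fovea_center(*self.make_traces(thick))
        assert (c.slice, c.column) == (64, 256)

    def test_border_minimum_fails_qc(self):
        thick = np.full((128, 512), 120.0)
        thick[0, 256] = 60.0
        with pytest.raises(mm.QCError, match="border"):
            mm.locate_fovea_center(*self.make_traces(thick))

    def test_edge_column_fails_qc(self):
        thick = np.full((128, 512), 120.0)
        thick[64, 3] = 60.0
        with pytest.raises(mm.QCError, match="lateral edge"):
            mm.locate_fovea_center(*self.make_traces(thick))

    def test_synthetic_volume_center_recovered(self, noiseless_record):
        rec, truth = noiseless_record
        assert abs(rec.center.slice - truth.pit_center[0]) <= 1
        assert abs(rec.center.column - truth.pit_center[1]) <= 2


class TestCprt:
    def test_reporting_scale_arithmetic(self):
        ilm = np.full(512, 100.0)
        rpe = np.full(512, 187.0)
        px, um = mm.compute_cprt(ilm, rpe, mm.FoveaCenter(64, 256), 2.6)
        assert px == 87.0
        assert um == pytest.approx(226.2)

    def test_unit_scale(self):
        px, um = mm.compute_cprt(np.full(8, 100.0), np.full(8, 190.0),
                                 mm.FoveaCenter(0, 4), 1.0)
        assert (px, um) == (90.0, 90.0)

    def test_degenerate_thickness_rejected(self):
        with pytest.raises(mm.QCError):
            mm.compute_cprt(np.full(8, 100.0), np.full(8, 100.0),
                            mm.FoveaCenter(0, 4), 1.0)


class TestFovealCurvature:
    def test_exact_quadratic_recovery_reporting_scale(self):
        rows = quad_rows(0.0725, 256.0, 300.0)
        fc = mm.fit_foveal_curvature(rows, 256)
        assert fc == pytest.approx(0.0725, abs=1e-12)
        assert 100 * fc == pytest.approx(7.25, abs=1e-9)

    def test_straight_line_zero(self):
        rows = 200.0 + 0.3 * np.arange(512)
        assert mm.fit_foveal_curvature(rows, 256) == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(0)
        rows = quad_rows(0.05, 256.0, 280.0) + rng.normal(0, 0.5, 512)
        fc = mm.fit_foveal_curvature(rows, 256)
        u = np.arange(-12.0, 13.0)
        oracle = closed_form_quadratic(u, rows[244:269])
        assert fc == pytest.approx(-oracle[0], abs=1e-10)

    def test_noisy_mean_unbiased(self):
        """1,000 noisy replicates: mean fitted FC within 1% of truth."""
        rng = np.random.default_rng(1)
        truth = 0.0725
        base = quad_rows(truth, 256.0, 300.0)
        fits = [mm.fit_foveal_curvature(base + rng.normal(0, 0.5, 512), 256)
                for _ in range(1000)]
        assert np.mean(fits) == pytest.approx(truth, rel=0.01)

    def test_window_clipped_fails_qc(self):
        with pytest.raises(mm.QCError, match="window"):
            mm.fit_foveal_curvature(np.full(512, 100.0), 5)

    def test_invalid_columns_fail_qc(self):
        valid = np.ones(512, bool)
        valid[250] = False
        with pytest.raises(mm.QCError, match="invalid"):
            mm.fit_foveal_curvature(np.full(512, 100.0), 256, valid)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(shift=st.integers(-200, 200), offset=st.floats(-50, 50))
    def test_translation_and_vertical_shift_invariance(self, shift, offset):
        x0 = 256 + shift
        rows = quad_rows(0.0725, float(x0), 300.0) + offset
        assert mm.fit_foveal_curvature(rows, x0) == pytest.approx(0.0725, abs=1e-8)


class TestMacularCurvature:
    def rpe_stack(self, a=0.0021):
        return np.stack([quad_rows(a, 256.0, 420.0) for _ in range(128)])

    def test_exact_recovery_reporting_scale(self):
        mc = mm.fit_macular_curvature(self.rpe_stack())
        assert mc == pytest.approx(0.0021, abs=1e-12)
        assert 100 * mc == pytest.approx(0.21, abs=1e-9)

    def test_flat_rpe_zero(self):
        assert mm.fit_macular_curvature(np.full((128, 512), 400.0)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_single_outlier_slice_ignored(self):
        rpe = self.rpe_stack()
        rpe[60] = quad_rows(0.5, 256.0, 420.0)
        assert mm.fit_macular_curvature(rpe) == pytest.approx(0.0021, abs=1e-12)

    def test_median_robust_to_15_of_32_corruptions(self):
        """One-sided corruption of up to 15 central slices leaves MC fixed."""
        rng = np.random.default_rng(2)
        rpe = self.rpe_stack()
        corrupt = rng.choice(list(mm.CENTRAL_SLICES), size=15, replace=False)
        for s in corrupt:
            rpe[s] = quad_rows(0.0021 + abs(rng.normal(1.0)), 256.0, 420.0)
        assert mm.fit_macular_curvature(rpe) == pytest.approx(0.0021, abs=1e-12)

    def test_vertical_shift_invariance(self):
        mc0 = mm.fit_macular_curvature(self.rpe_stack())
        mc1 = mm.fit_macular_curvature(self.rpe_stack() + 37.0)
        assert mc1 == pytest.approx(mc0, abs=1e-8)

    def test_too_many_bad_slices_fail_qc(self):
        valid = np.ones((128, 512), bool)
        for s in list(mm.CENTRAL_SLICES)[:4]:
            valid[s, ::2] = False  # 50% valid < 90% threshold
        with pytest.raises(mm.QCError, match="central slices"):
            mm.fit_macular_curvature(self.rpe_stack(), valid)


class TestQuantifyVolume:
    def test_noiseless_end_to_end(self, noiseless_record, noiseless_params):
        rec, truth = noiseless_record
        assert rec.qc.startswith("ok")
        assert abs(rec.fc - truth.a_fovea_true) / truth.a_fovea_true < 1e-3
        assert rec.mc == pytest.approx(truth.a_macula_true, rel=0.01)
        assert rec.cprt_px == pytest.approx(truth.cprt_true_px, abs=0.1)
        assert rec.cprt_um == pytest.approx(
            truth.cprt_true_px * noiseless_params.axial_scale_um, abs=0.3)
        assert rec.fc_x100 == 100 * rec.fc

    def test_truncated_volume_rejected(self, noiseless_volume):
        vol, _ = noiseless_volume
        bad = dataclasses.replace(vol, frames=vol.frames[:100])
        with pytest.raises(ValueError, match="128"):
            mm.quantify_volume(bad)

    def test_qc_failure_yields_null_record(self):
        """A volume whose thickness minimum sits on the border is reported
        with null measures and a reason, not an exception."""
        ilm = np.full((128, 512), 100.0)
        rpe = ilm + 120.0
        rpe[0, 256] = ilm[0, 256] + 30.0
        traces = VolumeTraces(ilm=ilm, rpe=rpe, valid=np.ones((128, 512), bool),
                              qc=["ok"] * 128)
        rec = mm.quantify_traces(traces, 2.6)
        assert rec.fc is None and rec.mc is None
        assert "border" in rec.qc


class TestTertileValidation:
    def test_well_separated_all_correct(self):
        truth = np.concatenate([np.linspace(0.04, 0.05, 10),
                                np.linspace(0.07, 0.08, 10),
                                np.linspace(0.10, 0.11, 10)])
        res = mm.tertile_ordering_validation(truth, truth.copy(), n_sets=10)
        assert res.sets_correct == 10
        assert res.tie_flagged == []

    def test_identical_pipeline_values_all_tied(self):
        truth = np.linspace(0.04, 0.11, 30)
        res = mm.tertile_ordering_validation(truth, np.full(30, 0.07), n_sets=10)
        assert res.sets_correct == 0
        assert res.tie_flagged == list(range(10))

    def test_separation_below_noise_floor_fails_sometimes(self):
        """When measurement noise dwarfs the tertile spread, sets misorder."""
        rng = np.random.default_rng(3)
        truth = np.linspace(0.0720, 0.0730, 30)  # tiny spread
        pipeline = truth + rng.normal(0, 0.002, 30)  # noise >> spread
        res = mm.tertile_ordering_validation(truth, pipeline, n_sets=10)
        assert res.sets_correct < 10

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            mm.tertile_ordering_validation(np.arange(10.0), np.arange(10.0), 10)
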