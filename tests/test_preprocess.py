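"""Filter/detrend/smoothing contracts and the drift-outlier exclusion rule."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lffconn import BoldRun, ParameterError
from lffconn.preprocess import (
    FilterSpec,
    PreprocessSpec,
    detrend_linear,
    drift_statistic,
    drop_dummies,
    exclude_drift_runs,
    lowpass,
    preprocess_run,
    smooth,
)
from lffconn.synthetic import simulate_run


def _run_from(data, tr=2.0, n_dummy=0, voxel=(0.52, 0.52, 1.0)):
    return BoldRun(
        data=np.asarray(data, dtype=np.float64),
        voxel_size_mm=voxel,
        origin_mm=(0.0, 0.0, 0.0),
        tr_s=tr,
        n_dummy=n_dummy,
    )


class TestDropDummies:
    def test_125_volumes_with_5_dummies_leaves_120(self):
        run = _run_from(np.zeros((2, 2, 2, 125)), n_dummy=5)
        out = drop_dummies(run)
        assert out.data.shape[3] == 120
        assert out.n_dummy == 0

    def test_zero_dummies_is_identity(self):
        run = _run_from(np.random.default_rng(0).standard_normal((2, 2, 2, 10)))
        assert drop_dummies(run) is run

    def test_all_frames_dummy_rejected(self):
        run = _run_from(np.zeros((2, 2, 2, 6)), n_dummy=4)
        run.n_dummy = 6  # corrupt metadata after construction
        with pytest.raises(ParameterError):
            drop_dummies(run)


class TestSmooth:
    def test_zero_fwhm_is_identity(self):
        run = _run_from(np.random.default_rng(0).standard_normal((4, 4, 3, 5)))
        assert smooth(run, 0.0) is run

    def test_constant_volume_unchanged(self):
        run = _run_from(np.full((6, 6, 4, 3), 7.5))
        out = smooth(run, 7.8, voxel_scale=10.0)
        assert np.allclose(out.data, 7.5, atol=1e-10)

    def test_interior_impulse_mass_conserved(self):
        data = np.zeros((31, 31, 11, 2))
        data[15, 15, 5, 0] = 3.0
        run = _run_from(data, voxel=(0.52, 0.52, 1.0))
        out = smooth(run, 7.8, voxel_scale=10.0)
        assert out.data[..., 0].sum() == pytest.approx(3.0, rel=1e-6)
        assert out.data[..., 1].sum() == pytest.approx(0.0, abs=1e-12)

    def test_impulse_response_variance_matches_kernel_sigma(self):
        """Second moment of the impulse response ~ sigma^2 per axis (mm^2)."""
        data = np.zeros((41, 41, 1, 2))
        data[20, 20, 0, 0] = 1.0
        run = _run_from(data, voxel=(0.5, 0.5, 1.0))
        fwhm = 3.0
        sigma_mm = fwhm / (2 * np.sqrt(2 * np.log(2)))
        out = smooth(run, fwhm).data[:, :, 0, 0]
        x_mm = (np.arange(41) - 20) * 0.5
        w = out.sum(axis=1)
        var = float((w * x_mm**2).sum() / w.sum())
        assert var == pytest.approx(sigma_mm**2, rel=0.02)

    def test_per_volume_mean_preserved_for_interior_support(self):
        data = np.zeros((21, 21, 9, 2))
        data[8:13, 8:13, 3:6, :] = np.random.default_rng(1).standard_normal((5, 5, 3, 2))
        run = _run_from(data, voxel=(1.0, 1.0, 1.0))
        out = smooth(run, 2.0)
        for t in range(2):
            assert out.data[..., t].mean() == pytest.approx(
                data[..., t].mean(), rel=1e-6, abs=1e-12
            )


class TestDetrend:
    def test_pure_ramp_removed_exactly(self):
        t = np.arange(50, dtype=float)
        out = detrend_linear(2.0 * t + 5.0)
        assert np.all(np.abs(out) < 1e-10)

    def test_sinusoid_survives_except_projection(self):
        """A bin-aligned 0.05 Hz sinusoid equals its explicit LS residual."""
        n, tr = 100, 2.0
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * 0.05 * t)
        design = np.vstack([np.ones(n), np.arange(n)]).T
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        oracle = x - design @ beta
        assert detrend_linear(x) == pytest.approx(oracle, abs=1e-10)
        assert np.corrcoef(detrend_linear(x), x)[0, 1] > 0.99

    def test_idempotent(self):
        x = np.random.default_rng(2).standard_normal(64)
        once = detrend_linear(x)
        assert detrend_linear(once) == pytest.approx(once, abs=1e-10)

    def test_output_mean_zero_for_nd_input(self):
        x = np.random.default_rng(3).standard_normal((3, 4, 2, 30))
        out = detrend_linear(x)
        assert np.allclose(out.mean(axis=-1), 0.0, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            detrend_linear(np.array([1.0, 2.0]))


class TestLowpass:
    def test_above_cutoff_sinusoid_annihilated(self):
        t = np.arange(120) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)
        out = lowpass(x, 2.0, FilterSpec(0.08))
        assert (out**2).sum() < 1e-10 * (x**2).sum()

    def test_below_cutoff_bin_aligned_sinusoid_preserved(self):
        n, tr = 100, 2.0
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * 0.04 * t)  # bin 8 of 1/200 Hz spacing
        assert lowpass(x, tr, FilterSpec(0.08)) == pytest.approx(x, abs=1e-8)

    def test_white_noise_energy_matches_parseval_over_kept_bins(self):
        n, tr, fc = 120, 2.0, 0.08
        x = np.random.default_rng(4).standard_normal(n)
        out = lowpass(x, tr, FilterSpec(fc))
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(n, tr)
        w = np.full(spec.size, 2.0)
        w[0] = 1.0
        if n % 2 == 0:
            w[-1] = 1.0
        kept = freqs <= fc + 1e-15
        oracle = (w[kept] * np.abs(spec[kept]) ** 2).sum() / n
        assert (out**2).sum() == pytest.approx(oracle, rel=1e-10)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            lowpass(np.zeros(16), 2.0, FilterSpec(0.25))

    @given(
        arrays(
            np.float64,
            st.integers(8, 64),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_idempotent_and_linear(self, x):
        spec = FilterSpec(0.08)
        once = lowpass(x, 2.0, spec)
        twice = lowpass(once, 2.0, spec)
        scale = max(1.0, np.abs(once).max())
        assert np.allclose(twice, once, atol=1e-10 * scale)
        doubled = lowpass(2.0 * x, 2.0, spec)
        assert np.allclose(doubled, 2.0 * once, atol=1e-9 * scale)

    def test_commutes_with_detrend_on_band_limited_trend_free_input(self):
        """Both operators are projections; on the intersection of their fixed
        subspaces (band-limited, zero least-squares line) the order is
        immaterial.  Construct such an input explicitly."""
        from lffconn.synthetic import simulate_lff

        n, tr = 120, 2.0
        spec = FilterSpec(0.08)
        y0 = simulate_lff(n, tr, (0.01, 0.08), np.random.default_rng(5))
        design = np.vstack([np.ones(n), np.arange(n, dtype=float)]).T
        pinv = np.linalg.pinv(design)
        filtered_design = np.stack(
            [lowpass(design[:, j], tr, spec) for j in range(2)], axis=1
        )
        coef = np.linalg.solve(pinv @ filtered_design, pinv @ y0)
        y = y0 - filtered_design @ coef  # band-limited AND zero line fit
        a = lowpass(detrend_linear(y), tr, spec)
        b = detrend_linear(lowpass(y, tr, spec))
        assert a == pytest.approx(b, abs=1e-8)
        assert a == pytest.approx(y, abs=1e-8)


@pytest.fixture(scope="module")
def cohort_runs(tiny_config):
    cfg = dataclasses.replace(tiny_config, n_volumes=60)
    runs = []
    for i in range(5):
        rng = np.random.default_rng(100 + i)
        run, _ = simulate_run(cfg, "preop", rng, rat_id=f"rat{i:02d}", outlier=(i == 2))
        runs.append(run)
    return runs


class TestDriftExclusion:
    def test_planted_outlier_detected_without_false_positives(self, cohort_runs):
        kept, excluded = exclude_drift_runs(cohort_runs, quad_threshold=1.0)
        assert [r.rat_id for r, _ in excluded] == ["rat02"]
        assert len(kept) == 4
        assert "drift" in excluded[0][1]

    def test_no_outlier_cohort_keeps_everything(self, cohort_runs):
        clean = [r for r in cohort_runs if r.rat_id != "rat02"]
        kept, excluded = exclude_drift_runs(clean, quad_threshold=1.0)
        assert excluded == []
        assert len(kept) == len(clean)

    def test_infinite_threshold_excludes_nothing(self, cohort_runs):
        kept, excluded = exclude_drift_runs(cohort_runs, quad_threshold=np.inf)
        assert excluded == []

    def test_statistic_targets_quadratic_not_linear_drift(self):
        t = np.arange(80, dtype=float)
        linear = _run_from(np.broadcast_to(5.0 * t, (2, 2, 2, 80)).copy())
        u = (t - t.mean()) / (t.max() - t.mean())
        quad = _run_from(np.broadcast_to(10.0 * u**2 + np.random.default_rng(0).standard_normal(80) * 0.1, (2, 2, 2, 80)).copy())
        assert drift_statistic(linear) < 0.1
        assert drift_statistic(quad) > 1.0


class TestChain:
    def test_full_chain_output_is_band_limited_and_mean_free(self, preop_run):
        run, _ = preop_run
        out = preprocess_run(run, PreprocessSpec())
        assert out.data.shape[3] == run.data.shape[3] - run.n_dummy
        tc = out.data[0, 0, 0, :]
        freqs = np.fft.rfftfreq(tc.size, out.tr_s)
        amp = np.abs(np.fft.rfft(tc))
        assert np.all(amp[freqs > 0.08 + 1e-12] < 1e-6 * max(amp.max(), 1))
        assert abs(tc.mean()) < 1e-8
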