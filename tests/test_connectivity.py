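"""Correlation-map statistics: Pearson oracle equivalence, effective-df
threshold inversion, counting, normalization, and the group map."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lffconn import (
    BoldRun,
    CorrelationMap,
    DegenerateSeedError,
    ParameterError,
    SampleSizeError,
    correlation_map,
    count_significant,
    effective_df,
    group_tmap,
    normalize_counts,
    r_critical,
    seed_reference,
)
from lffconn.io import RoiSpec, default_seeds
from lffconn.preprocess import FilterSpec, lowpass


def _toy_run(data, tr=2.0):
    return BoldRun(
        data=np.asarray(data, dtype=np.float64),
        voxel_size_mm=(1.0, 1.0, 1.0),
        origin_mm=(0.0, 0.0, 0.0),
        tr_s=tr,
    )


class TestSeedReference:
    def test_mean_of_identical_voxels_is_the_series(self):
        s = np.sin(np.linspace(0, 4 * np.pi, 40))
        data = np.tile(s, (2, 2, 1, 1))
        run = _toy_run(data)
        roi = RoiSpec("blk", (0.5, 0.5, 0.5), (2, 2, 1), "L")
        ref = seed_reference(run, roi)
        assert ref == pytest.approx(s, abs=1e-12)

    def test_cancelling_voxels_raise_degenerate_seed(self):
        s = np.sin(np.linspace(0, 4 * np.pi, 40))
        data = np.stack([s, -s])[:, None, None, :]
        run = _toy_run(data)
        roi = RoiSpec("blk", (0.5, 0.5, 0.5), (2, 1, 1), "L")
        with pytest.raises(DegenerateSeedError):
            seed_reference(run, roi)

    def test_reference_tracks_generating_latent(self, preop_preprocessed, preop_run):
        _, truth = preop_run
        ref = seed_reference(preop_preprocessed, default_seeds()["SI_L"])
        latent = truth.latents["SI"][5:]
        latent = lowpass(latent - latent.mean(), 2.0, FilterSpec(0.08))
        r = np.corrcoef(ref, latent)[0, 1]
        assert r > 0.9


class TestCorrelationMap:
    def test_perfect_and_anti_correlated_voxels(self):
        rng = np.random.default_rng(0)
        ref = lowpass(rng.standard_normal(120), 2.0, FilterSpec(0.08))
        data = np.stack([ref, -ref, 2.5 * ref + 7.0])[:, None, None, :]
        cmap = correlation_map(_toy_run(data), ref)
        assert cmap.r[0, 0, 0] == pytest.approx(1.0, abs=1e-12)
        assert cmap.r[1, 0, 0] == pytest.approx(-1.0, abs=1e-12)
        assert cmap.r[2, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_pearson_formula(self):
        """Map equals the direct per-voxel formula on a 5x5x2x20 toy run."""
        rng = np.random.default_rng(1)
        data = rng.standard_normal((5, 5, 2, 20))
        ref = rng.standard_normal(20)
        cmap = correlation_map(_toy_run(data), ref, cutoff_hz=0.1)
        for i in range(5):
            for j in range(5):
                for k in range(2):
                    x = data[i, j, k]
                    xd, rd = x - x.mean(), ref - ref.mean()
                    oracle = (xd @ rd) / np.sqrt((xd @ xd) * (rd @ rd))
                    assert cmap.r[i, j, k] == pytest.approx(oracle, abs=1e-12)

    def test_five_point_hand_series(self):
        """Hand Pearson arithmetic, including an outlier-dominated series."""
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.corrcoef([2.0, 4.0, 6.0, 8.0, 10.0], ref)[0, 1] == pytest.approx(1.0)
        # deviations (-21,-20,-19,-18,78)·(-2,-1,0,1,2) = 200; 200/sqrt(7610*10)
        hand = 200.0 / np.sqrt(76100.0)
        assert np.corrcoef([1.0, 2.0, 3.0, 4.0, 100.0], ref)[0, 1] == pytest.approx(
            hand, abs=1e-12
        )

    def test_zero_variance_voxel_flagged_undefined_not_zero(self):
        ref = lowpass(np.random.default_rng(2).standard_normal(120), 2.0, FilterSpec(0.08))
        data = np.stack([ref, np.full(120, 3.0)])[:, None, None, :]
        cmap = correlation_map(_toy_run(data), ref)
        assert np.isnan(cmap.r[1, 0, 0])
        assert not cmap.significant[1, 0, 0]

    def test_zero_variance_reference_rejected(self):
        run = _toy_run(np.random.default_rng(3).standard_normal((2, 2, 2, 120)))
        with pytest.raises(DegenerateSeedError):
            correlation_map(run, np.full(120, 2.0))

    def test_length_mismatch_rejected(self):
        run = _toy_run(np.zeros((2, 2, 2, 120)))
        with pytest.raises(ParameterError):
            correlation_map(run, np.zeros(60))

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_scale_invariance(self, a, b):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((3, 2, 2, 120))
        ref = lowpass(rng.standard_normal(120), 2.0, FilterSpec(0.08))
        base = correlation_map(_toy_run(data), ref)
        scaled = correlation_map(_toy_run(a * data + b), ref)
        assert np.allclose(scaled.r, base.r, atol=1e-9)


class TestEffectiveDf:
    def test_study_settings_give_36p4(self):
        assert effective_df(120, 2.0, 0.08) == pytest.approx(36.4)

    def test_full_band_limit_approaches_n_minus_2(self):
        df = effective_df(120, 2.0, 0.2499999)
        assert df == pytest.approx(118.0, abs=0.01)

    def test_too_narrow_band_rejected(self):
        with pytest.raises(ParameterError):
            effective_df(10, 2.0, 0.01)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            effective_df(120, 2.0, 0.25)


class TestRCritical:
    def test_median_of_null_is_zero(self):
        assert r_critical(0.5, 36.4) == 0.0

    def test_monotone_in_p(self):
        assert r_critical(1e-5, 36.4) > r_critical(1e-3, 36.4)

    def test_two_sided_equals_half_p_one_sided(self):
        assert r_critical(0.01, 20.0, "two") == pytest.approx(r_critical(0.005, 20.0, "one"))

    def test_inverts_the_t_transform(self):
        from scipy import stats

        df = 36.4
        rc = r_critical(2.5e-5, df)
        t = rc * np.sqrt(df / (1 - rc**2))
        assert stats.t.sf(t, df) == pytest.approx(2.5e-5, rel=1e-9)

    def test_quick_null_calibration_at_p_0p01(self):
        """Filtered-noise exceedance of r_critical(0.01) within 3 binomial SEs."""
        n, tr, fc, reps = 120, 2.0, 0.08, 20_000
        rng = np.random.default_rng(77)
        spec = FilterSpec(fc)
        x = lowpass(rng.standard_normal((reps, n)), tr, spec)
        y = lowpass(rng.standard_normal((reps, n)), tr, spec)
        x -= x.mean(1, keepdims=True)
        y -= y.mean(1, keepdims=True)
        r = np.einsum("ij,ij->i", x, y) / np.sqrt(
            np.einsum("ij,ij->i", x, x) * np.einsum("ij,ij->i", y, y)
        )
        rc = r_critical(0.01, effective_df(n, tr, fc))
        rate = (r >= rc).mean()
        assert rate == pytest.approx(0.01, abs=3 * np.sqrt(0.01 * 0.99 / reps))


class TestCounting:
    def _map(self, r_values, rc=0.75):
        r = np.asarray(r_values, dtype=float)
        return CorrelationMap(r=r, effective_df=36.4, p_threshold=0.01, r_critical=rc)

    def test_all_ones_counts_whole_mask(self):
        cmap = self._map(np.ones((3, 3, 1)))
        mask = np.ones((3, 3, 1), bool)
        assert count_significant(cmap, mask) == 9

    def test_empty_mask_counts_zero(self):
        cmap = self._map(np.ones((3, 3, 1)))
        assert count_significant(cmap, np.zeros((3, 3, 1), bool)) == 0

    def test_toy_enumeration(self):
        vals = np.array([0.9, 0.8, 0.2, 0.75, -0.9, np.nan, 0.76, 0.0, 1.0]).reshape(3, 3, 1)
        cmap = self._map(vals, rc=0.75)
        mask = np.ones((3, 3, 1), bool)
        oracle = sum(1 for v in vals.ravel() if not np.isnan(v) and v >= 0.75)
        assert count_significant(cmap, mask) == oracle == 5

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(-1, 1, size=(6, 6, 2))
        mask = np.ones_like(vals, bool)
        counts = [
            count_significant(self._map(vals, rc=rc), mask)
            for rc in np.linspace(0.0, 1.0, 11)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestNormalize:
    def test_table_style_fraction(self):
        out = normalize_counts({"SI_R": 2}, {"SI_R": 100})
        assert out["SI_R"] == pytest.approx(0.02)

    def test_identity_for_equal_counts(self):
        assert normalize_counts({"SI_R": 37}, {"SI_R": 37})["SI_R"] == 1.0

    def test_zero_preop_flagged_nan(self):
        assert np.isnan(normalize_counts({"SI_R": 5}, {"SI_R": 0})["SI_R"])


class TestGroupTmap:
    def _maps(self, rs):
        return [
            CorrelationMap(r=np.asarray(r, float), effective_df=36.4,
                           p_threshold=0.01, r_critical=0.6)
            for r in rs
        ]

    def test_all_zero_rats_give_t0_p1(self):
        maps = self._maps([np.zeros((2, 2, 1))] * 5)
        t, p, sig = group_tmap(maps)
        assert np.all(t == 0.0)
        assert np.all(p == 1.0)
        assert not sig.any()

    def test_fewer_than_three_rats_rejected(self):
        with pytest.raises(SampleSizeError):
            group_tmap(self._maps([np.zeros((2, 2, 1))] * 2))

    def test_identical_positive_maps_flagged_undefined(self):
        maps = self._maps([np.full((2, 2, 1), 0.5)] * 4)
        t, p, sig = group_tmap(maps)
        assert np.all(np.isnan(t))
        assert not sig.any()

    def test_power_on_synthetic_rat_maps(self, tiny_atlas):
        """Coupled-region z-scores light up > 50% of both SI masks; background stays dark."""
        rng = np.random.default_rng(8)
        shape = tiny_atlas.labels.shape
        si = tiny_atlas.mask("SI_L") | tiny_atlas.mask("SI_R")
        maps = []
        for _ in range(17):
            z = rng.normal(0.0, 1.0 / np.sqrt(36.4), size=shape)
            z[si] = rng.normal(np.arctanh(0.9), 0.15, size=int(si.sum()))
            maps.append(
                CorrelationMap(r=np.tanh(z), effective_df=36.4,
                               p_threshold=2.5e-5, r_critical=0.6)
            )
        t, p, sig = group_tmap(maps, p_threshold=0.001)
        assert sig[tiny_atlas.mask("SI_L")].mean() > 0.5
        assert sig[tiny_atlas.mask("SI_R")].mean() > 0.5
        assert sig[tiny_atlas.labels == 0].mean() < 0.01
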