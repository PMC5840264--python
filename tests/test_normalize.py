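"""Intra/inter-sample normalization: factor definitions, robustness, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msistream import normalize
from msistream.normalize import (
    apply_inter,
    apply_intra,
    fold_change_diagnostics,
    inter_factors,
    intra_factors,
    sample_profile,
)
from msistream.store import SampleDataset
from msistream.synthetic import mfc_recovery_study

from conftest import make_sample


def one_pixel(values, sample_id="s"):
    v = np.asarray(values, dtype=float)
    return SampleDataset(sample_id, np.arange(1, v.size + 1, dtype=float), v[None, :], np.array([[0, 0]]))


class TestIntraFactors:
    def test_mean_factor_is_spectrum_mean(self):
        s = one_pixel([2, 4, 6])
        f = intra_factors(s, "mean")
        assert f.factors[0] == pytest.approx(4.0)
        np.testing.assert_allclose(apply_intra(s, f).intensities, [[0.5, 1.0, 1.5]])

    def test_median_factor_uses_positive_entries(self):
        f = intra_factors(one_pixel([1, 2, 9]), "median")
        assert f.factors[0] == pytest.approx(2.0)
        # zeros excluded: median of positives {5, 7}
        f = intra_factors(one_pixel([0, 5, 7, 0]), "median")
        assert f.factors[0] == pytest.approx(6.0)

    def test_mfc_factor_is_median_of_ratios(self):
        s = one_pixel([2, 4, 8])
        f = intra_factors(s, "mfc", reference=np.array([1.0, 2.0, 2.0]), min_shared=1)
        assert f.factors[0] == pytest.approx(2.0)  # ratios [2, 2, 4]
        np.testing.assert_allclose(apply_intra(s, f).intensities, [[1.0, 2.0, 4.0]])

    def test_all_zero_spectrum_flagged_not_scaled(self):
        s = SampleDataset("s", np.array([1.0, 2.0]), np.array([[0.0, 0.0], [1.0, 3.0]]),
                          np.array([[0, 0], [1, 0]]))
        for method in ("mean", "median"):
            f = intra_factors(s, method)
            assert f.degenerate[0] and not f.degenerate[1]
            assert f.factors[0] == 1.0
        out = apply_intra(s, intra_factors(s, "mean"))
        np.testing.assert_array_equal(out.intensities[0], [0.0, 0.0])

    def test_mfc_too_few_shared_features_flagged(self):
        s = one_pixel([1, 0, 0, 0])
        f = intra_factors(s, "mfc", reference=np.array([1.0, 1.0, 1.0, 1.0]), min_shared=2)
        assert f.degenerate[0]
        assert f.factors[0] == 1.0

    def test_negative_intensities_rejected(self):
        s = one_pixel([1, 2, 3])
        s.intensities[0, 0] = -1
        with pytest.raises(ValueError, match="non-negative"):
            intra_factors(s, "mean")

    def test_after_mean_normalization_every_spectrum_mean_is_one(self):
        s = make_sample("s", n_pixels=8, n_features=5, rng=np.random.default_rng(0))
        out = apply_intra(s, intra_factors(s, "mean"))
        np.testing.assert_allclose(out.intensities.mean(axis=1), 1.0)

    def test_mfc_self_consistency(self):
        """Re-deriving mfc factors after mfc normalization gives 1."""
        rng = np.random.default_rng(1)
        s = make_sample("s", n_pixels=12, n_features=30, rng=rng)
        ref = np.median(s.intensities, axis=0)
        out = apply_intra(s, intra_factors(s, "mfc", reference=ref))
        f2 = intra_factors(out, "mfc", reference=ref)
        np.testing.assert_allclose(f2.factors[~f2.degenerate], 1.0, atol=1e-9)


class TestInterFactors:
    def test_mfc_factors_against_median_reference(self):
        f = inter_factors({"a": np.array([1.0, 1.0]), "b": np.array([3.0, 3.0])},
                          "mfc", min_shared=1)
        lookup = dict(zip(f.unit_ids, f.factors))
        assert lookup["a"] == pytest.approx(0.5)  # ref = [2, 2]
        assert lookup["b"] == pytest.approx(1.5)

    def test_single_sample_mean(self):
        f = inter_factors({"a": np.array([2.0, 4.0])}, "mean")
        assert f.factors[0] == pytest.approx(3.0)

    def test_identical_profiles_give_unit_mfc_factors(self):
        prof = np.array([1.0, 5.0, 2.0])
        f = inter_factors({k: prof.copy() for k in "abc"}, "mfc", min_shared=1)
        np.testing.assert_allclose(f.factors, 1.0)

    def test_zero_profile_names_sample(self):
        with pytest.raises(ValueError, match="bad"):
            inter_factors({"ok": np.array([1.0]), "bad": np.array([0.0])}, "mean")

    def test_apply_inter_uniform_scaling(self):
        s = make_sample("s")
        out = apply_inter(s, 2.0)
        np.testing.assert_allclose(out.intensities, s.intensities / 2.0)
        np.testing.assert_array_equal(apply_inter(s, 1.0).intensities, s.intensities)
        with pytest.raises(ValueError):
            apply_inter(s, 0.0)

    def test_mean_intra_and_inter_commute(self):
        rng = np.random.default_rng(5)
        s = make_sample("s", n_pixels=9, n_features=6, rng=rng)
        factor = 1.7
        a = apply_inter(apply_intra(s, intra_factors(s, "mean")), factor)
        b = apply_intra(apply_inter(s, factor), intra_factors(apply_inter(s, factor), "mean"))
        # mean factors are equivariant, so the final matrices differ only by
        # the uniform factor applied once on each path
        np.testing.assert_allclose(a.intensities * factor, b.intensities, rtol=1e-12)


class TestSampleProfile:
    def test_profile_is_columnwise_mean(self):
        s = SampleDataset("s", np.array([1.0, 2.0]), np.array([[1.0, 3.0], [3.0, 5.0]]),
                          np.array([[0, 0], [1, 0]]))
        np.testing.assert_allclose(sample_profile(s, use_mask=False), [2.0, 4.0])

    def test_mask_restricts_to_selected_pixels(self):
        s = SampleDataset("s", np.array([1.0, 2.0]), np.array([[1.0, 3.0], [3.0, 5.0]]),
                          np.array([[0, 0], [1, 0]]), tissue_mask=np.array([False, True]))
        np.testing.assert_allclose(sample_profile(s), [3.0, 5.0])

    def test_empty_mask_rejected(self):
        s = make_sample("s")
        s.tissue_mask = np.zeros(s.n_pixels, dtype=bool)
        with pytest.raises(ValueError, match="zero pixels"):
            sample_profile(s)

    def test_streaming_matches_direct_column_means(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, size=(100, 7))
        s = SampleDataset("s", np.sort(rng.uniform(100, 900, 7)), x,
                          np.column_stack([np.arange(100) % 10, np.arange(100) // 10]))
        np.testing.assert_allclose(sample_profile(s, use_mask=False), x.mean(axis=0), rtol=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(c=st.floats(min_value=0.01, max_value=100.0), seed=st.integers(0, 2**16))
def test_scale_equivariance_of_all_methods(c, seed):
    """Scaling a spectrum by c scales every factor estimator by c exactly."""
    rng = np.random.default_rng(seed)
    s = make_sample("s", n_pixels=3, n_features=12, rng=rng)
    ref = np.median(s.intensities, axis=0) + 0.1
    scaled = s.copy()
    scaled.intensities = s.intensities * c
    for method in ("mean", "median", "mfc"):
        f0 = intra_factors(s, method, reference=ref, min_shared=1)
        f1 = intra_factors(scaled, method, reference=ref, min_shared=1)
        np.testing.assert_allclose(f1.factors, c * f0.factors, rtol=1e-9)


class TestRobustness:
    def test_mfc_tolerates_asymmetric_perturbation_mean_does_not(self):
        """MFC factor recovery stays exact up to (but excluding) half of the
        features perturbed upward; the exact-half point is the median's
        breakdown boundary.  Mean (TIC-style) normalization is already off by
        >5% at a 30% perturbed fraction."""
        df = mfc_recovery_study(n_spectra=30, n_features=400, n_seeds=3,
                                fractions=[0.1, 0.3, 0.45], seed=0)
        mfc = df[df.method == "mfc"].set_index("fraction")["median_rel_error"]
        mean = df[df.method == "mean"].set_index("fraction")["median_rel_error"]
        assert (mfc <= 0.05).all()
        assert mean[0.3] > 0.05

    def test_mixed_direction_perturbation_robust_through_half(self):
        """With asymmetric increases *and* decreases (unbiased directions),
        the median-of-ratios estimator stays exact at and beyond 50%."""
        rng = np.random.default_rng(0)
        base = 10.0 ** rng.normal(0, 1, 400)
        scales = rng.uniform(0.5, 2.0, 30)
        for frac in (0.5, 0.6):
            k = int(round(frac * 400))
            mult = np.ones((30, 400))
            for i in range(30):
                idx = rng.choice(400, k, replace=False)
                mult[i, idx] = np.where(rng.random(k) < 0.5, 3.0, 1 / 3.0)
            est = np.median(scales[:, None] * base[None, :] * mult / base[None, :], axis=1)
            err = np.median(np.abs(est - scales) / scales)
            assert err <= 0.05


class TestDiagnostics:
    def test_normalized_workspace_centres_on_zero(self, tmp_path):
        from msistream.store import create_workspace

        ws = create_workspace(str(tmp_path / "w.h5"))
        rng = np.random.default_rng(3)
        mz = np.sort(rng.uniform(100, 900, 20))
        base = rng.uniform(1, 10, 20)
        for i in range(2):
            n_pix = 6
            intens = np.tile(base, (n_pix, 1))
            coords = np.column_stack([np.arange(n_pix), np.zeros(n_pix, dtype=int)])
            ws.add_sample(SampleDataset(f"s{i}", mz.copy(), intens, coords))
        table = fold_change_diagnostics(ws, scope="intra")
        np.testing.assert_allclose(table["median"], 0.0, atol=1e-12)

    def test_uniformly_scaled_spectrum_shows_log_shift(self, tmp_path):
        from msistream.store import create_workspace

        ws = create_workspace(str(tmp_path / "w.h5"))
        rng = np.random.default_rng(4)
        base = rng.uniform(1, 10, 20)
        intens = np.tile(base, (3, 1))
        intens[1] *= 10.0
        coords = np.column_stack([np.arange(3), np.zeros(3, dtype=int)])
        ws.add_sample(SampleDataset("s", np.sort(rng.uniform(100, 900, 20)), intens, coords))
        table = fold_change_diagnostics(ws, scope="intra")
        assert table.loc[1, "median"] == pytest.approx(np.log(10.0))

    def test_mfc_normalization_shrinks_dispersion_of_medians(self, tmp_path):
        """Planted per-pixel scale drift: the spread of per-spectrum log-fold
        medians strictly decreases after intra-sample mfc normalization."""
        from msistream.store import create_workspace
        from msistream.synthetic import SyntheticParams, generate

        ws, truth = generate(SyntheticParams(n_samples=2, shape=(10, 10), n_features=60,
                                             n_background=0, pixel_scale_sigma=0.6, seed=6),
                             path=str(tmp_path / "w.h5"))
        before = fold_change_diagnostics(ws, scope="intra")["median"].std()
        normalize.normalize_workspace(ws, scope="intra", method="mfc")
        after = fold_change_diagnostics(ws, scope="intra")["median"].std()
        assert after < before


class TestWorkspaceNormalization:
    def test_inter_mfc_recovers_planted_sample_scales(self, tmp_path):
        from msistream.synthetic import SyntheticParams, generate

        ws, truth = generate(SyntheticParams(n_samples=5, shape=(12, 12), n_features=50,
                                             n_background=0, sigma_add=0.0, sigma_mult=0.05,
                                             pixel_scale_sigma=0.0, seed=2),
                             path=str(tmp_path / "w.h5"))
        profiles = {s.sample_id: sample_profile(s) for s in ws.iter_samples()}
        f = inter_factors(profiles, "mfc")
        true = np.array([truth.sample_scale[k] for k in f.unit_ids])
        est = f.factors
        # factors are identifiable up to a common constant; compare shapes
        ratio = est / true
        assert np.std(ratio) / np.mean(ratio) < 0.05

    def test_ledger_records_both_scopes(self, filled_workspace):
        normalize.normalize_workspace(filled_workspace, scope="intra", method="mean")
        normalize.normalize_workspace(filled_workspace, scope="inter", method="median")
        names = [m.step_name for m in filled_workspace.metadata]
        assert names[-2:] == ["normalize-intra", "normalize-inter"]
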