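import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aoquant.preprocess import (
    ChainSpec,
    DegenerateSpectrumError,
    PreprocessingChain,
    airpls,
    apply_chain,
    msc,
    parse_chain,
    sg_smooth,
    snv,
)

W = np.linspace(400, 1800, 701)


def _sg_oracle(y, window, order):
    """Per-point truncated-window polynomial least squares."""
    n = len(y)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        idx = np.arange(lo, hi) - i
        coef = np.polyfit(idx, y[lo:hi], order)
        out[i] = np.polyval(coef, 0.0)
    return out


class TestSG:
    def test_constant_unchanged(self):
        y = np.full(50, 3.7)
        assert np.allclose(sg_smooth(y, 9, 3), y)

    def test_reproduces_squared_index_exactly(self):
        y = np.arange(701, dtype=float) ** 2
        out = sg_smooth(y, 7, 2)
        assert np.abs(out - y).max() <= 1e-9
        # interior agrees with the direct per-window least-squares oracle
        oracle = _sg_oracle(y, 7, 2)
        assert np.abs(out[3:-3] - oracle[3:-3]).max() <= 1e-7

    def test_linear_ramp_unchanged(self):
        y = 3.0 * np.arange(200) + 2.0
        assert np.abs(sg_smooth(y, 5, 1) - y).max() < 1e-9

    def test_matches_oracle_on_noisy_interior(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=101)
        out = sg_smooth(y, 9, 3)
        oracle = _sg_oracle(y, 9, 3)
        assert np.allclose(out[4:-4], oracle[4:-4], atol=1e-10)

    @pytest.mark.parametrize("window,order", [(6, 2), (2, 1), (5, 5), (5, 7)])
    def test_invalid_parameters_rejected(self, window, order):
        with pytest.raises(ValueError):
            sg_smooth(np.arange(50.0), window, order)


class TestAirPLS:
    def test_zero_spectrum_gives_zero_baseline(self):
        base, corr = airpls(np.zeros(100))
        assert np.allclose(base, 0.0)
        assert np.allclose(corr, 0.0)

    def test_recovers_linear_baseline(self):
        base_true = 5.0 + 0.01 * (W - 400)
        baseline, corrected = airpls(base_true, lam=1e5)
        assert np.abs(corrected).max() < 1e-3 * base_true.max()

    def test_planted_peak_height_preserved(self):
        h = 10.0
        base_true = 5.0 + 0.01 * (W - 400)
        peak = h * np.exp(-4 * np.log(2) * ((W - 1000) / 20.0) ** 2)
        _, corrected = airpls(base_true + peak, lam=1e5)
        rec = corrected[np.argmin(np.abs(W - 1000))]
        assert abs(rec - h) / h < 0.05

    def test_baseline_never_exceeds_spectrum_maximum(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300).cumsum() + 50
        baseline, _ = airpls(x, lam=1e4)
        assert baseline.max() <= x.max() + 1e-6

    def test_first_order_penalty_variant_runs(self):
        x = np.ones(50) * 4.0
        baseline, _ = airpls(x, lam=10.0, diff_order=1)
        assert np.allclose(baseline, 4.0, atol=1e-6)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            airpls(np.arange(10.0), lam=0.0)


class TestSNV:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        out = snv(rng.normal(2.0, 3.0, 500))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1.0) < 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        assert np.allclose(snv(3.0 + 2.0 * x), snv(x), atol=1e-10)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            snv(np.full(50, 1.0))

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_idempotence(self, seed):
        x = np.random.default_rng(seed).normal(size=64)
        once = snv(x)
        assert np.allclose(snv(once), once, atol=1e-10)


class TestMSC:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.ref = np.abs(rng.normal(size=300)).cumsum()

    def test_sample_equal_to_reference_unchanged(self):
        out, _ = msc(self.ref[None, :].repeat(2, axis=0), reference=self.ref)
        assert np.allclose(out[0], self.ref, atol=1e-9)

    def test_inverts_known_slope_and_offset(self):
        sample = 2.0 * self.ref + 3.0
        out, _ = msc(sample[None, :], reference=self.ref)
        assert np.abs(out[0] - self.ref).max() <= 1e-9

    def test_identical_set_with_mean_reference_unchanged(self):
        X = self.ref[None, :].repeat(4, axis=0)
        out, ref = msc(X)
        assert np.allclose(out, X, atol=1e-9)
        assert np.allclose(ref, self.ref)

    def test_uncorrelated_sample_rejected(self):
        flat = np.zeros(300)
        with pytest.raises(DegenerateSpectrumError):
            msc(flat[None, :], reference=self.ref)


class TestChains:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.X = 10 + np.abs(rng.normal(size=(6, 200))).cumsum(axis=1)

    def test_empty_chain_is_identity(self):
        out, _ = apply_chain(self.X, "")
        assert np.array_equal(out, self.X)

    def test_snv_chain_centers_every_row(self):
        out, _ = apply_chain(self.X, "SNV")
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)

    def test_chain_equals_manual_composition(self):
        out, _ = apply_chain(self.X, "airPLS+SG+MSC", lam=1e4, window=7, order=2)
        step1 = airpls(self.X, lam=1e4)[1]
        step2 = sg_smooth(step1, 7, 2)
        step3, _ = msc(step2)
        assert np.allclose(out, step3, atol=1e-9)

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            apply_chain(self.X, "airPLS+WAVELET")

    def test_duplicate_transform_rejected(self):
        with pytest.raises(ValueError):
            ChainSpec(("SNV", "SNV"))

    def test_parse_chain_label_roundtrip(self):
        spec = parse_chain("airPLS + SG + MSC")
        assert spec.steps == ("airPLS", "SG", "MSC")
        assert spec.label == "airPLS + SG + MSC"

    def test_fitted_context_reused_on_test_set(self):
        """Test spectra are corrected with the calibration MSC reference, not
        their own mean, so the transform is leak-free and deterministic."""
        cal, test = self.X[:4], self.X[4:]
        z_cal, ctx = apply_chain(cal, "SG+MSC")
        z_test, _ = apply_chain(test, "SG+MSC", fitted_context=ctx)
        ref = ctx.msc_reference
        assert ref is not None
        expected, _ = msc(sg_smooth(test, 7, 2), reference=ref)
        assert np.allclose(z_test, expected, atol=1e-10)
        # refitting on the test set instead gives a different answer
        z_refit, _ = apply_chain(test, "SG+MSC")
        assert not np.allclose(z_test, z_refit)

    def test_unfitted_msc_transform_rejected(self):
        chain = PreprocessingChain(spec=parse_chain("MSC"))
        with pytest.raises(RuntimeError):
            chain.transform(self.X)

    def test_length_and_grid_preserved(self):
        for chain in ("airPLS", "SG", "SNV", "airPLS+SG+MSC"):
            out, _ = apply_chain(self.X, chain)
            assert out.shape == self.X.shape
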