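import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirstew.preprocessing import (
    DegenerateSpectrumError,
    PreprocSpec,
    apply_preprocessing,
    detrend,
    savgol_derivative,
    snv,
    snvd,
)
from nirstew.spectra_io import GridMismatchError, SpectraValidationError

from conftest import make_spectra


class TestSNV:
    def test_hand_example(self):
        out = snv(make_spectra([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out.values, [[-1.0, 0.0, 1.0]], atol=1e-12)

    def test_rows_normalised_to_mean0_sd1(self, rng):
        out = snv(make_spectra(rng.standard_normal((5, 40)) * 3 + 7))
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0, atol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
        seed=st.integers(0, 10_000),
    )
    def test_affine_invariance(self, scale, offset, seed):
        # SNV removes exactly the multiplicative-scatter-plus-offset model
        x = np.random.default_rng(seed).standard_normal((1, 30))
        base = snv(make_spectra(x))
        transformed = snv(make_spectra(scale * x + offset))
        np.testing.assert_allclose(transformed.values, base.values, atol=1e-9)

    def test_zero_variance_row_names_sample(self):
        s = make_spectra([[1.0, 2.0], [3.0, 3.0]], ids=["ok", "flat"])
        with pytest.raises(DegenerateSpectrumError, match="flat"):
            snv(s)


class TestDetrend:
    def test_annihilates_quadratic(self):
        lam = np.linspace(650, 950, 60)
        row = 2.0 + 0.3 * lam - 0.001 * lam**2
        out = detrend(make_spectra([row], lam), degree=2)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_constant_row_gives_zeros(self):
        out = detrend(make_spectra([np.full(20, 5.0)]), degree=2)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_residual_orthogonal_to_polynomial_basis(self, rng):
        lam = np.linspace(960, 1660, 80)
        row = rng.standard_normal(80)
        resid = detrend(make_spectra([row], lam), degree=2).values[0]
        for basis in (np.ones_like(lam), lam, lam**2):
            dot = abs(resid @ basis)
            assert dot < 1e-8 * np.linalg.norm(resid) * np.linalg.norm(basis)

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(SpectraValidationError):
            detrend(make_spectra([[1.0, 2.0, 3.0]]), degree=2)


class TestSNVD:
    def test_equally_spaced_line_annihilated(self):
        # SNV of [2,4,6] is a straight line in lambda; degree-2 detrend kills it
        out = snvd(make_spectra([[2.0, 4.0, 6.0, 8.0]]))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_equals_manual_composition(self, rng):
        s = make_spectra(rng.standard_normal((3, 25)) + 5, 650 + np.arange(25) * 2.0)
        np.testing.assert_allclose(
            snvd(s).values, detrend(snv(s), 2).values, rtol=1e-12
        )

    def test_degree2_polynomial_row_maps_to_zero(self):
        lam = np.linspace(0, 10, 30)
        row = 1.0 + 2.0 * lam + 3.0 * lam**2
        out = snvd(make_spectra([row], lam))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)


class TestSavgolDerivative:
    spec = PreprocSpec(name="der1")

    def test_exact_on_linear_first_derivative(self):
        lam = 960.0 + 3.6 * np.arange(40)
        out = savgol_derivative(make_spectra([3 * lam + 1], lam), self.spec, 1)
        np.testing.assert_allclose(out.values, 3.0, atol=1e-9)
        assert out.n_wavelengths == 40 - 14  # half-window dropped at each edge

    def test_exact_on_quadratic_second_derivative(self):
        lam = np.linspace(0, 40, 50)
        out = savgol_derivative(make_spectra([lam**2], lam), self.spec, 2)
        np.testing.assert_allclose(out.values, 2.0, atol=1e-8)

    def test_matches_finite_difference_of_smoothed_row(self, rng):
        # derivative of the local fit ~ central differences of the SG smooth
        pitch = 0.0001
        lam = pitch * np.arange(300)
        coefs = rng.uniform(-1, 1, 6)
        row = np.polyval(coefs, lam)
        d1 = savgol_derivative(make_spectra([row], lam), self.spec, 1).values[0]
        from scipy.signal import savgol_filter

        smooth = savgol_filter(row, 15, 2)
        fd = (smooth[2:] - smooth[:-2]) / (2 * pitch)
        # d1 covers original points 7..292; fd (central diff of the smooth)
        # covers 1..298, so fd[7:-7] aligns with d1[1:-1] on points 8..291
        np.testing.assert_allclose(d1[1:-1], fd[7:-7], atol=1e-6)

    @settings(derandomize=True, max_examples=20)
    @given(a=st.floats(-5, 5), seed=st.integers(0, 10_000))
    def test_linearity(self, a, seed):
        g = np.random.default_rng(seed)
        lam = np.arange(30, dtype=float)
        s1, s2 = g.standard_normal(30), g.standard_normal(30)
        lhs = savgol_derivative(make_spectra([a * s1 + s2], lam), self.spec, 1).values
        r1 = savgol_derivative(make_spectra([s1], lam), self.spec, 1).values
        r2 = savgol_derivative(make_spectra([s2], lam), self.spec, 1).values
        np.testing.assert_allclose(lhs, a * r1 + r2, atol=1e-8)

    def test_first_derivative_twice_approximates_second(self):
        lam = np.linspace(0, 2 * np.pi, 500)
        row = np.sin(lam)
        s = make_spectra([row], lam)
        der1 = savgol_derivative(s, self.spec, 1)
        der11 = savgol_derivative(der1, self.spec, 1).values[0]
        der2 = savgol_derivative(s, self.spec, 2).values[0][7:-7]
        np.testing.assert_allclose(der11, der2, atol=5e-3 * np.abs(der2).max() + 1e-6)

    def test_non_uniform_grid_rejected(self, rng):
        lam = np.sort(rng.uniform(960, 1660, 40))
        with pytest.raises(GridMismatchError):
            savgol_derivative(make_spectra(rng.standard_normal((1, 40)), lam), self.spec, 1)

    def test_window_longer_than_spectrum_rejected(self):
        with pytest.raises(SpectraValidationError):
            savgol_derivative(make_spectra([[1.0] * 10]), self.spec, 1)


def test_dispatch_by_name(rng):
    s = make_spectra(rng.standard_normal((2, 40)) + 3)
    assert apply_preprocessing(s, PreprocSpec(name="none")) is s
    np.testing.assert_array_equal(
        apply_preprocessing(s, PreprocSpec(name="snv")).values, snv(s).values
    )
    np.testing.assert_array_equal(
        apply_preprocessing(s, PreprocSpec(name="der2")).values,
        savgol_derivative(s, PreprocSpec(name="der2"), 2).values,
    )


def test_spec_validation():
    with pytest.raises(ValueError):
        PreprocSpec(name="msc")
    with pytest.raises(ValueError):
        PreprocSpec(name="der1", sg_window=14)
    with pytest.raises(ValueError):
        PreprocSpec(name="der1", sg_window=3, sg_polyorder=3)
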