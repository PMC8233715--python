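"""Pretreatment operators: exact identities, model inversion, chain parsing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import nirspec_fa as nf
from nirspec_fa import preprocess as pp
from nirspec_fa.errors import (
    ChainParseError,
    ConfigurationError,
    DegenerateInputError,
    NotFittedError,
)

GRID21 = nf.WavelengthGrid(1000.0, 0.5, 21)

spectrum_strategy = arrays(
    np.float64, 21,
    elements=st.floats(-2.0, 2.0, allow_nan=False, allow_infinity=False),
).filter(lambda x: np.std(x, ddof=1) > 1e-3 and np.abs(x).sum() > 1e-3)


class TestSimpleOperators:
    def test_offset_subtracts_minimum(self):
        np.testing.assert_allclose(
            pp.offset_baseline(np.array([0.4, 0.6, 1.4])), [0.0, 0.2, 1.0]
        )

    def test_offset_constant_to_zero_and_idempotent(self):
        const = np.full(5, 3.2)
        np.testing.assert_allclose(pp.offset_baseline(const), 0.0)
        x = np.array([0.0, 0.5, 1.0])
        np.testing.assert_array_equal(pp.offset_baseline(x), x)

    def test_area_example(self):
        np.testing.assert_allclose(
            pp.area_normalize(np.array([1.0, 1.0, 2.0])), [0.25, 0.25, 0.5]
        )

    def test_area_zero_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            pp.area_normalize(np.zeros(5))

    def test_snv_example(self):
        np.testing.assert_allclose(pp.snv(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_snv_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            pp.snv(np.full(8, 1.5))

    @settings(max_examples=50, derandomize=True)
    @given(spectrum_strategy)
    def test_area_and_snv_identities(self, x):
        assert abs(np.abs(pp.area_normalize(x)).sum() - 1.0) < 1e-12
        z = pp.snv(x)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1.0) < 1e-10

    @settings(max_examples=25, derandomize=True)
    @given(spectrum_strategy,
           st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    def test_snv_affine_invariance(self, x, a, b):
        np.testing.assert_allclose(pp.snv(a * x + b), pp.snv(x), atol=1e-8)


class TestDetrend:
    def test_annihilates_quadratic(self):
        lam = GRID21.normalized()
        x = 1.3 - 0.7 * lam + 0.4 * lam**2
        np.testing.assert_allclose(pp.detrend(x, GRID21), 0.0, atol=1e-9)

    def test_residual_orthogonality(self, rng):
        x = rng.standard_normal(21)
        r = pp.detrend(x, GRID21)
        lam = GRID21.normalized()
        for basis in (np.ones(21), lam, lam**2):
            assert abs(r @ basis) < 1e-8

    def test_matches_polyfit_oracle_and_reduces_variance(self, rng):
        x = rng.standard_normal(21)
        lam = GRID21.normalized()
        oracle = x - np.polyval(np.polyfit(lam, x, 2), lam)
        np.testing.assert_allclose(pp.detrend(x, GRID21), oracle, atol=1e-9)
        assert pp.detrend(x, GRID21).var() <= x.var() + 1e-12


class TestScatterCorrection:
    def test_msc_inverts_affine_model(self, rng):
        ref = rng.uniform(0.2, 1.2, 21)
        x = 2.0 * ref + 0.3
        np.testing.assert_allclose(pp.msc(x, ref), ref, atol=1e-10)

    def test_msc_identity_and_idempotence(self, rng):
        ref = rng.uniform(0.2, 1.2, 21)
        np.testing.assert_allclose(pp.msc(ref, ref), ref, atol=1e-10)
        x = ref * 1.4 + 0.1 + 0.01 * rng.standard_normal(21)
        once = pp.msc(x, ref)
        np.testing.assert_allclose(pp.msc(once, ref), once, atol=1e-10)

    def test_emsc_inverts_extended_model(self, rng):
        ref = rng.uniform(0.2, 1.2, 21)
        lam = GRID21.normalized()
        x = 1.5 * ref + 0.2 + 0.1 * lam
        np.testing.assert_allclose(pp.emsc(x, ref, GRID21), ref, atol=1e-9)
        np.testing.assert_allclose(pp.emsc(ref, ref, GRID21), ref, atol=1e-9)

    def test_emsc_reduces_to_msc_without_polynomial_distortion(self, rng):
        # On data generated from the pure affine model the two corrections
        # must agree: the EMSC polynomial coefficients are estimated as ~0.
        ref = np.sin(np.linspace(0, 3, 21)) + 2.0
        x = 1.7 * ref + 0.25
        np.testing.assert_allclose(
            pp.emsc(x, ref, GRID21), pp.msc(x, ref), atol=1e-8
        )


class TestDerivatives:
    def test_sg_linear_ramp_exact(self):
        lam = GRID21.wavelengths()
        s = 0.003
        d = pp.savgol_derivative(s * lam, 1, 2, 5, GRID21)
        np.testing.assert_allclose(d, s, atol=1e-12)

    def test_sg_constant_zero(self):
        d = pp.savgol_derivative(np.full(21, 0.8), 1, 2, 5, GRID21)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_sg_quadratic_matches_analytic_derivative(self):
        lam = GRID21.wavelengths()
        a, b, c = 2e-6, -0.004, 3.0
        x = a * lam**2 + b * lam + c
        d = pp.savgol_derivative(x, 1, 2, 5, GRID21)
        np.testing.assert_allclose(d, 2 * a * lam + b, atol=1e-9)

    def test_sg_contract_violations(self):
        x = np.zeros(21)
        with pytest.raises(ConfigurationError):
            pp.savgol_derivative(x, 1, 2, 4, GRID21)  # even window
        with pytest.raises(ConfigurationError):
            pp.savgol_derivative(x, 3, 2, 5, GRID21)  # deriv > poly

    def test_norris_linear_ramp_exact(self):
        lam = GRID21.wavelengths()
        for gap in (1, 3, 7):
            d = pp.norris_gap_derivative(0.01 * lam, 1, gap, GRID21)
            np.testing.assert_allclose(d, 0.01, atol=1e-12)

    def test_norris_gap1_equals_central_difference(self, rng):
        x = rng.standard_normal(21)
        d = pp.norris_gap_derivative(x, 1, 1, GRID21)
        oracle = (x[2:] - x[:-2]) / (2 * GRID21.step_nm)
        np.testing.assert_allclose(d[1:-1], oracle, atol=1e-12)

    def test_norris_gap_too_large(self):
        with pytest.raises(ConfigurationError):
            pp.norris_gap_derivative(np.zeros(21), 1, 11, GRID21)


class TestChainParsing:
    def test_expansion_of_compound_tokens(self):
        chain = nf.parse_chain("Offset|Area|SNV+D|SG-1-2-3")
        kinds = [type(s).__name__ for s in chain.steps]
        assert kinds == ["OffsetBaseline", "AreaNormalize", "SNV", "Detrend",
                         "SGDerivative"]
        sg = chain.steps[-1]
        assert (sg.deriv_order, sg.poly_order, sg.window_points) == (1, 2, 3)

    def test_none_is_identity(self, rng):
        chain = nf.parse_chain("None")
        assert chain.steps == []
        x = rng.uniform(size=(3, 21))
        np.testing.assert_array_equal(chain.fit_transform(x, GRID21), x)

    def test_norris_token(self):
        chain = nf.parse_chain("NG-1-13")
        assert type(chain.steps[0]).__name__ == "NorrisGap"
        assert chain.steps[0].gap_points == 13

    def test_smoothing_shorthand_is_zeroth_derivative(self):
        chain = nf.parse_chain("SG1-2-2")
        sg = chain.steps[0]
        assert sg.deriv_order == 0
        assert sg.window_points % 2 == 1 and sg.window_points > sg.poly_order

    @pytest.mark.parametrize("bad", ["Offfset", "SG-1-2", "NG-2-5", "SG-1-3-2"])
    def test_malformed_tokens_rejected(self, bad):
        with pytest.raises(ChainParseError):
            nf.parse_chain(bad)

    def test_round_trip_spec_string(self):
        spec = "Offset|Area|SNV|D|SG-1-2-3"
        assert nf.parse_chain(spec).spec() == spec


class TestChainApplication:
    def test_unfitted_chain_refuses_new_data(self, rng):
        chain = nf.parse_chain("MSC")
        with pytest.raises(NotFittedError):
            chain.transform(rng.uniform(size=(2, 21)), GRID21)

    def test_msc_reference_is_calibration_mean(self, rng):
        cal = rng.uniform(0.2, 1.2, size=(10, 21))
        chain = nf.parse_chain("MSC")
        chain.fit_transform(cal, GRID21)
        mean = cal.mean(axis=0)
        np.testing.assert_allclose(
            chain.transform(mean[None, :], GRID21)[0], mean, atol=1e-10
        )

    def test_no_leakage_batch_equals_one_at_a_time(self, rng):
        cal = rng.uniform(0.2, 1.2, size=(12, 21))
        val = rng.uniform(0.2, 1.2, size=(5, 21))
        chain = nf.parse_chain("Offset|SNV|MSC|SG-1-2-5")
        chain.fit_transform(cal, GRID21)
        batch = chain.transform(val, GRID21)
        singles = np.vstack([
            chain.transform(v[None, :], GRID21) for v in val
        ])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_deterministic(self, rng):
        cal = rng.uniform(0.2, 1.2, size=(8, 21))
        chain = nf.parse_chain("SNV+D")
        a = chain.fit_transform(cal, GRID21)
        b = chain.transform(cal, GRID21)
        np.testing.assert_array_equal(a, b)
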