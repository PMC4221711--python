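"""Unit and property tests for the MID core: correction, enrichment, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import tracefate as tf
from tracefate.errors import (
    DegenerateInputError,
    InvalidMeasurementError,
    InvalidParameterError,
)

from conftest import binomial_convolve, random_mid


def _raw(name, n, intensities, sample="s1"):
    return tf.RawIntensityVector(
        compound=tf.CompoundSpec(name, n), sample_id=sample,
        intensities=np.asarray(intensities, dtype=float),
    )


class TestCorrectionMatrix:
    def test_n1_closed_form(self):
        cm = tf.build_correction_matrix(1, 0.01)
        np.testing.assert_allclose(cm.entries, [[0.99, 0.0], [0.01, 1.0]])

    def test_zero_abundance_is_identity(self):
        cm = tf.build_correction_matrix(4, 0.0)
        np.testing.assert_array_equal(cm.entries, np.eye(5))

    def test_columns_stochastic_and_diagonal(self):
        cm = tf.build_correction_matrix(6, 0.0107)
        np.testing.assert_allclose(cm.entries.sum(axis=0), 1.0, atol=1e-12)
        for j in range(7):
            assert cm.entries[j, j] == pytest.approx((1 - 0.0107) ** (6 - j))
        assert np.allclose(np.triu(cm.entries, k=1), 0.0)

    @pytest.mark.parametrize("n_carbons,p13", [(0, 0.01), (-3, 0.01), (5, 0.5), (5, -0.1)])
    def test_invalid_parameters(self, n_carbons, p13):
        with pytest.raises(InvalidParameterError):
            tf.build_correction_matrix(n_carbons, p13)

    @given(
        n=st.integers(min_value=1, max_value=30),
        p13=st.floats(min_value=0.0, max_value=0.1),
    )
    @settings(deadline=None, max_examples=60)
    def test_column_stochastic_property(self, n, p13):
        cm = tf.build_correction_matrix(n, p13)
        np.testing.assert_allclose(cm.entries.sum(axis=0), 1.0, atol=1e-12)

    def test_matches_independent_convolution_oracle(self):
        # C @ e_j must equal the polynomial-convolution forward model
        p13 = 0.0107
        cm = tf.build_correction_matrix(5, p13)
        for j in range(6):
            e = np.zeros(6)
            e[j] = 1.0
            np.testing.assert_allclose(
                cm.entries @ e, binomial_convolve(e, p13), atol=1e-14
            )


class TestCorrection:
    def test_unlabeled_compound_corrects_to_pure_m0(self):
        p = 0.0107
        raw = _raw("lactate", 3, [(1 - p) ** 3, 3 * p * (1 - p) ** 2,
                                  3 * p**2 * (1 - p), p**3])
        mid = tf.correct_natural_abundance(raw, p13=p)
        np.testing.assert_allclose(mid.fractions, [1, 0, 0, 0], atol=1e-9)

    def test_p13_zero_is_identity(self):
        raw = _raw("malate", 4, [5, 1, 2, 0, 2])
        mid = tf.correct_natural_abundance(raw, p13=0.0)
        np.testing.assert_allclose(mid.fractions, np.array([5, 1, 2, 0, 2]) / 10)

    @pytest.mark.parametrize("method", ["nnls", "solve_clip"])
    def test_round_trip_recovers_true_mid(self, method):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            x = random_mid(rng, n)
            raw = _raw("c", n, binomial_convolve(x, 0.0107))
            mid = tf.correct_natural_abundance(raw, p13=0.0107, method=method)
            np.testing.assert_allclose(mid.fractions, x, atol=1e-8)

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidParameterError):
            tf.correct_natural_abundance(_raw("c", 2, [1, 0, 0]), method="magic")

    def test_all_zero_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            _raw("c", 2, [0, 0, 0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            _raw("c", 2, [1, -1, 0])


class TestMidStatistics:
    def test_normalize(self):
        mid = tf.normalize_mid(_raw("c", 2, [6, 1, 3]))
        np.testing.assert_allclose(mid.fractions, [0.6, 0.1, 0.3])

    def test_point_mass_preserved(self):
        mid = tf.normalize_mid(_raw("c", 3, [0, 0, 0, 1]))
        np.testing.assert_allclose(mid.fractions, [0, 0, 0, 1])

    def test_zero_carbon_compound_forbidden(self):
        with pytest.raises(InvalidParameterError):
            tf.CompoundSpec("x", 0)

    def test_fractional_enrichment_reads_mid(self):
        mid = tf.MID(tf.CompoundSpec("c", 2), np.array([0.6, 0.1, 0.3]))
        assert tf.fractional_enrichment(mid, 2) == pytest.approx(0.3)
        with pytest.raises(IndexError):
            tf.fractional_enrichment(mid, 3)

    def test_enrichment_invariant_to_rescaling(self):
        rng = np.random.default_rng(0)
        v = rng.random(5) + 0.1
        m1 = tf.normalize_mid(_raw("c", 4, v))
        m2 = tf.normalize_mid(_raw("c", 4, v * 137.0))
        for k in range(5):
            assert tf.fractional_enrichment(m1, k) == pytest.approx(
                tf.fractional_enrichment(m2, k)
            )

    def test_contribution_ratio(self):
        num = tf.MID(tf.CompoundSpec("glutamate", 5), np.array([0.8, 0, 0.2, 0, 0, 0]))
        den = tf.MID(tf.CompoundSpec("pyruvate", 3), np.array([0.2, 0, 0, 0.8]))
        assert tf.contribution_ratio(num, 2, den, 3) == pytest.approx(0.25)
        assert tf.contribution_ratio(num, 2, num, 2) == pytest.approx(1.0)

    def test_contribution_ratio_zero_denominator(self):
        num = tf.MID(tf.CompoundSpec("a", 2), np.array([0.5, 0.25, 0.25]))
        den = tf.MID(tf.CompoundSpec("b", 2), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(DegenerateInputError):
            tf.contribution_ratio(num, 1, den, 2)


class TestStudentT:
    def test_identical_groups(self):
        r = tf.student_t_compare([1, 2, 3], [1, 2, 3])
        assert r.t_stat == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_closed_form_example(self):
        # pooled t, df=4: t = -1.2247, p = 0.2879
        r = tf.student_t_compare([1, 2, 3], [2, 3, 4])
        assert r.t_stat == pytest.approx(-1.224745, abs=1e-5)
        assert r.p_value == pytest.approx(0.287900, abs=1e-4)
        assert r.fold_change == pytest.approx(1.5)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        r = tf.student_t_compare(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert r.t_stat == pytest.approx(float(t_ref))
        assert r.p_value == pytest.approx(float(p_ref))

    def test_zero_variance_unequal_means_flagged(self):
        r = tf.student_t_compare([1, 1], [2, 2])
        assert r.degenerate
        assert r.p_value == 0.0

    def test_single_observation_rejected(self):
        with pytest.raises(InvalidParameterError):
            tf.student_t_compare([1], [2, 3])


class TestSeahorse:
    def _wells(self, ppr, ocr, condition):
        return [
            tf.SeahorseMeasurement(f"{condition}{i}", condition, p, o)
            for i, (p, o) in enumerate(zip(ppr, ocr))
        ]

    def test_constant_wells(self):
        res = tf.glycolysis_oxphos_ratio(
            self._wells([10, 10], [5, 5], "parental")
            + self._wells([10, 10], [5, 5], "mesenchymal")
        )
        mean, sem, n = res["per_condition"]["parental"]
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(0.0)
        # identical groups -> t=0, p=1
        assert res["comparison"].t_stat == pytest.approx(0.0)
        assert res["comparison"].p_value == pytest.approx(1.0)

    def test_nonpositive_ocr_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            tf.SeahorseMeasurement("w", "parental", 10.0, 0.0)

    def test_simulated_shift_detected(self):
        from tracefate.simulate import PRESETS, simulate_seahorse_wells

        wells = simulate_seahorse_wells(PRESETS["parental"], "parental", 6, seed=3)
        wells += simulate_seahorse_wells(PRESETS["mesenchymal"], "mesenchymal", 6, seed=4)
        res = tf.glycolysis_oxphos_ratio(wells)
        mes = res["per_condition"]["mesenchymal"][0]
        par = res["per_condition"]["parental"][0]
        assert mes < par
        assert res["comparison"].p_value < 0.05


class TestFluxRecovery:
    def _noise_free_mids(self, params):
        from tracefate.simulate import true_mids

        glc = true_mids(params, "glucose")
        gln = true_mids(params, "glutamine")
        mk = lambda name, v: tf.MID(tf.COMPOUNDS[name], v)
        return (
            mk("pyruvate", glc["pyruvate"]),
            mk("glutamate", glc["glutamate"]),
            mk("glutamate", gln["glutamate"]),
        )

    def test_noise_free_exact_inversion(self):
        params = tf.FluxParams(f_pyr=0.8, g_pdh=0.6, q_gln=0.5)
        rec = tf.recover_flux_params(*self._noise_free_mids(params))
        assert rec.g_pdh == pytest.approx(0.6, abs=1e-10)
        assert rec.f_pyr == pytest.approx(0.8, abs=1e-10)
        assert rec.q_gln == pytest.approx(0.5, abs=1e-10)

    def test_glutamate_m2_forward_value(self):
        # glutamate M+2 = g_pdh * f_pyr * (1 - q_gln) = 0.5*0.8*0.5
        params = tf.FluxParams(f_pyr=0.8, g_pdh=0.5, q_gln=0.5)
        _, glu, _ = self._noise_free_mids(params)
        assert tf.fractional_enrichment(glu, 2) == pytest.approx(0.20)

    def test_contribution_ratio_is_pdh_proxy(self):
        # glutamate-M+2 over pyruvate-M+3 = g_pdh * (1 - q_gln)
        params = tf.FluxParams(f_pyr=0.8, g_pdh=0.6, q_gln=0.5)
        pyr, glu, _ = self._noise_free_mids(params)
        assert tf.contribution_ratio(glu, 2, pyr, 3) == pytest.approx(0.30)

    def test_proxy_strictly_increasing_in_g_pdh(self):
        ratios = []
        for g in np.linspace(0.05, 0.95, 7):
            pyr, glu, _ = self._noise_free_mids(
                tf.FluxParams(f_pyr=0.8, g_pdh=float(g), q_gln=0.5)
            )
            ratios.append(tf.contribution_ratio(glu, 2, pyr, 3))
        assert np.all(np.diff(ratios) > 0)

    def test_unlabeled_arms_degenerate(self):
        params = tf.FluxParams(f_pyr=0.0, g_pdh=0.5, q_gln=0.5)
        with pytest.raises(DegenerateInputError):
            tf.recover_flux_params(*self._noise_free_mids(params))
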