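import json

import numpy as np
import pytest

from nirfish.labels import SampleLabel, SpectrumSet
from nirfish.preprocess import (
    AutoscaleParams,
    apply_pretreatment,
    autoscale_apply,
    autoscale_fit,
    pair_center,
    sg_coefficients,
    sg_derivative,
    snv,
)

from conftest import make_spectrum_set


def _single_row(values):
    wl = np.linspace(1000, 1000 + 10 * (len(values) - 1), len(values))
    return SpectrumSet(wl, np.array([values], dtype=float), [SampleLabel("E", 1, "C", 3, 1)], np.array([1]))


class TestSNV:
    def test_symmetric_three_point_row(self):
        out = snv(_single_row([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.intensities[0], [-1.0, 0.0, 1.0])

    def test_rows_become_zero_mean_unit_sd(self):
        ss = make_spectrum_set(p=30)
        out = snv(ss).intensities
        assert np.all(np.abs(out.mean(axis=1)) < 1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="row"):
            snv(_single_row([5.0, 5.0, 5.0]))

    def test_idempotent(self):
        ss = make_spectrum_set(p=30)
        once = snv(ss)
        twice = snv(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    def test_removes_multiplicative_and_additive_scatter(self):
        ss = make_spectrum_set(p=30)
        rng = np.random.default_rng(3)
        scale = rng.uniform(0.5, 2.0, size=(ss.n_rows, 1))
        offset = rng.normal(size=(ss.n_rows, 1))
        distorted = ss.replace_intensities(scale * ss.intensities + offset)
        np.testing.assert_allclose(snv(distorted).intensities, snv(ss).intensities, atol=1e-10)


class TestSavitzkyGolay:
    def test_first_derivative_weights_match_quadratic_lsq_oracle(self):
        # independent oracle: differentiate the 5-point quadratic LSQ fit at
        # the window centre, one basis vector at a time
        oracle1 = np.empty(5)
        oracle2 = np.empty(5)
        x = np.arange(-2.0, 3.0)
        for j in range(5):
            e = np.zeros(5)
            e[j] = 1.0
            c2, c1, _ = np.polyfit(x, e, 2)
            oracle1[j] = c1           # d/dx at x=0
            oracle2[j] = 2 * c2       # d2/dx2 at x=0
        np.testing.assert_allclose(oracle1, np.array([-2, -1, 0, 1, 2]) / 10, atol=1e-12)
        np.testing.assert_allclose(oracle2, np.array([2, -1, -2, -1, 2]) / 7, atol=1e-12)
        np.testing.assert_allclose(sg_coefficients(1), oracle1, atol=1e-12)
        np.testing.assert_allclose(sg_coefficients(2), oracle2, atol=1e-12)

    def test_polynomial_reproduction(self):
        p = 20
        i = np.arange(p, dtype=float)
        a, b, c = 0.7, -1.3, 0.25
        row = a + b * i + c * i**2
        ss = _single_row(list(row))
        d1 = sg_derivative(ss, 1)
        np.testing.assert_allclose(d1.intensities[0], b + 2 * c * i[2:-2], atol=1e-10)
        d2 = sg_derivative(ss, 2)
        np.testing.assert_allclose(d2.intensities[0], np.full(p - 4, 2 * c), atol=1e-10)

    def test_edges_trimmed(self):
        ss = make_spectrum_set(p=12)
        out = sg_derivative(ss, 1)
        assert out.n_wavelengths == 8
        np.testing.assert_array_equal(out.wavelengths, ss.wavelengths[2:-2])

    def test_linearity(self):
        a_set = make_spectrum_set(p=15, rng=np.random.default_rng(1))
        b_set = make_spectrum_set(p=15, rng=np.random.default_rng(2))
        combo = a_set.replace_intensities(2.0 * a_set.intensities - 0.5 * b_set.intensities)
        lhs = sg_derivative(combo, 1).intensities
        rhs = 2.0 * sg_derivative(a_set, 1).intensities - 0.5 * sg_derivative(b_set, 1).intensities
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_too_few_wavelengths(self):
        with pytest.raises(ValueError, match="5"):
            sg_derivative(_single_row([1.0, 2.0, 3.0, 4.0]), 1)

    def test_non_uniform_grid_rejected(self):
        wl = np.array([1000.0, 1010.0, 1020.0, 1100.0, 1110.0, 1120.0])
        ss = SpectrumSet(wl, np.random.default_rng(0).normal(size=(1, 6)),
                         [SampleLabel("E", 1, "C", 3, 1)], np.array([1]))
        with pytest.raises(ValueError, match="non-uniform"):
            sg_derivative(ss, 1)


class TestPairCenter:
    def test_two_row_day_centres_to_half_difference(self):
        ss = make_spectrum_set(n_days=1, replicates=1, p=4)
        c, t = ss.intensities
        out = pair_center(ss).intensities
        np.testing.assert_allclose(out[0], (c - t) / 2)
        np.testing.assert_allclose(out[1], (t - c) / 2)

    def test_per_day_column_sums_vanish(self):
        ss = make_spectrum_set(n_days=4, replicates=3, p=8)
        out = pair_center(ss)
        for d in np.unique(ss.day):
            sums = out.intensities[out.day == d].sum(axis=0)
            assert np.all(np.abs(sums) < 1e-10)

    def test_removes_any_additive_day_offset(self):
        ss = make_spectrum_set(n_days=3, replicates=2, p=6)
        v = np.linspace(-2, 5, 6)
        shifted = ss.intensities.copy()
        shifted[ss.day == 2] += v
        out_shifted = pair_center(ss.replace_intensities(shifted))
        out_plain = pair_center(ss)
        np.testing.assert_allclose(out_shifted.intensities, out_plain.intensities, atol=1e-12)

    def test_metadata_untouched(self):
        ss = make_spectrum_set()
        out = pair_center(ss)
        assert out.labels == ss.labels
        np.testing.assert_array_equal(out.day, ss.day)

    def test_unpaired_day_rejected(self):
        ss = make_spectrum_set(n_days=2, replicates=1)
        keep = [i for i, l in enumerate(ss.labels) if not (ss.day[i] == 2 and l.group == "T")]
        with pytest.raises(ValueError, match="2"):
            pair_center(ss.subset_rows(keep))


class TestAutoscale:
    def test_fit_apply_same_set_gives_zero_mean_unit_sd(self):
        ss = make_spectrum_set(p=7)
        params = autoscale_fit(ss)
        out = autoscale_apply(ss, params).intensities
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_held_out_uses_training_parameters(self):
        train = make_spectrum_set(p=5, rng=np.random.default_rng(10))
        test = make_spectrum_set(p=5, rng=np.random.default_rng(11))
        params = autoscale_fit(train)
        out = autoscale_apply(test, params).intensities
        expected = (test.intensities - train.intensities.mean(axis=0)) / train.intensities.std(axis=0, ddof=1)
        np.testing.assert_allclose(out, expected)
        assert np.abs(out.mean(axis=0)).max() > 1e-6  # held-out columns need not centre

    def test_constant_column_names_wavelength(self):
        ss = make_spectrum_set(p=5)
        X = ss.intensities.copy()
        X[:, 2] = 4.2
        with pytest.raises(ValueError, match=str(int(ss.wavelengths[2]))):
            autoscale_fit(ss.replace_intensities(X))

    def test_params_serialization_roundtrip(self):
        ss = make_spectrum_set(p=5)
        params = autoscale_fit(ss)
        back = AutoscaleParams.from_json(params.to_json())
        np.testing.assert_array_equal(back.means, params.means)
        np.testing.assert_array_equal(back.sds, params.sds)


def test_apply_pretreatment_alternatives_and_chain():
    ss = make_spectrum_set(p=20)
    alt = apply_pretreatment(ss, "der1", day_center=False)
    np.testing.assert_allclose(alt.intensities, sg_derivative(ss, 1).intensities)
    chained = apply_pretreatment(ss, "der1", day_center=False, snv_first=True)
    np.testing.assert_allclose(chained.intensities, sg_derivative(snv(ss), 1).intensities)
    with pytest.raises(ValueError, match="unknown pretreatment"):
        apply_pretreatment(ss, "msc")
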