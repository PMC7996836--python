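import numpy as np
import pytest

from cemarker._errors import EstimatorError
from cemarker.infotheory import (
    LN2,
    CEProfile,
    EstimatorConfig,
    PairwiseCE,
    conditional_entropy,
    entropy,
    expected_ce_profile,
    mutual_information,
    profiles_to_frame,
    read_profiles_csv,
    surrogate_pvalue,
    write_profiles_csv,
)
from cemarker.io import EEGRecording

KNN = EstimatorConfig(n_surrogates=0)
GAUSS = EstimatorConfig(method="gaussian", n_surrogates=0)

GAUSS_H = lambda var: 0.5 * np.log(2 * np.pi * np.e * var)


def gaussian_pair(rng, rho, sigma=1.0, n=5000):
    x = sigma * rng.standard_normal(n)
    y = rho * x + sigma * np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return x, y


class TestEntropy:
    def test_gaussian_method_matches_closed_form(self, rng):
        x = rng.standard_normal(5000)
        expected = GAUSS_H(np.var(x, ddof=1))
        assert entropy(x, GAUSS) == pytest.approx(expected, abs=1e-12)

    def test_knn_close_to_gaussian_truth(self):
        vals = [
            entropy(np.random.default_rng(s).standard_normal(5000), KNN)
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(GAUSS_H(1.0), abs=0.05)

    def test_scaling_shifts_entropy_by_log_factor(self, rng):
        x = rng.standard_normal(5000)
        assert entropy(2 * x, KNN) - entropy(x, KNN) == pytest.approx(np.log(2), abs=0.05)

    def test_units_conversion_is_exact(self, rng):
        x = rng.standard_normal(1000)
        nats = entropy(x, KNN)
        bits = entropy(x, EstimatorConfig(units="bits", n_surrogates=0))
        assert bits == pytest.approx(nats / LN2, rel=1e-12)

    def test_constant_input_fails(self):
        with pytest.raises(EstimatorError, match="constant"):
            entropy(np.full(500, 2.0), KNN)

    def test_short_input_fails(self, rng):
        with pytest.raises(EstimatorError, match=">= 100"):
            entropy(rng.standard_normal(50), KNN)


class TestMutualInformation:
    def test_gaussian_method_matches_closed_form(self, rng):
        x, y = gaussian_pair(rng, 0.6)
        rho = np.corrcoef(x, y)[0, 1]
        expected = -0.5 * np.log(1 - rho**2)
        assert mutual_information(x, y, GAUSS) == pytest.approx(expected, abs=1e-12)

    def test_knn_close_to_gaussian_truth(self):
        vals = []
        for s in range(5):
            x, y = gaussian_pair(np.random.default_rng(s), 0.6)
            vals.append(mutual_information(x, y, KNN))
        assert np.mean(vals) == pytest.approx(-0.5 * np.log(1 - 0.36), abs=0.05)

    def test_independent_samples_near_zero(self, rng):
        x, y = rng.standard_normal(5000), rng.standard_normal(5000)
        assert abs(mutual_information(x, y, KNN)) < 0.05

    def test_exactly_symmetric(self, rng):
        x, y = gaussian_pair(rng, 0.4, n=800)
        assert mutual_information(x, y, KNN) == mutual_information(y, x, KNN)

    def test_length_mismatch_fails(self, rng):
        with pytest.raises(EstimatorError, match="length mismatch"):
            mutual_information(rng.standard_normal(500), rng.standard_normal(400), KNN)

    def test_added_noise_cannot_raise_mi(self, rng):
        x, y = gaussian_pair(rng, 0.6, n=4000)
        mi_clean = mutual_information(x, y, KNN)
        mi_noisy = mutual_information(x, y + rng.standard_normal(4000), KNN)
        assert mi_noisy <= mi_clean + 0.05

    def test_agrees_with_sklearn_ksg(self, rng):
        from sklearn.feature_selection import mutual_info_regression

        x, y = gaussian_pair(rng, 0.6, n=2000)
        ours = mutual_information(x, y, KNN)
        theirs = mutual_info_regression(x[:, None], y, n_neighbors=4, random_state=0)[0]
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_estimator_consistency_error_shrinks_with_n(self):
        true = -0.5 * np.log(1 - 0.36)
        errs = []
        for n in (500, 2000, 8000):
            per_seed = []
            for s in range(8):
                x, y = gaussian_pair(np.random.default_rng(100 + s), 0.6, n=n)
                per_seed.append(abs(mutual_information(x, y, KNN) - true))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]


class TestConditionalEntropy:
    def test_matches_closed_form_rho_08(self):
        true = GAUSS_H(1.0 * (1 - 0.64))
        vals = []
        for s in range(10):
            x, y = gaussian_pair(np.random.default_rng(s), 0.8)
            vals.append(conditional_entropy(x, y, KNN).value)
        assert np.mean(vals) == pytest.approx(true, abs=0.07)

    def test_independent_conditioner_leaves_entropy(self, rng):
        x = rng.standard_normal(5000)
        y = rng.standard_normal(5000)
        ce = conditional_entropy(x, y, KNN)
        assert ce.value == pytest.approx(ce.h_x, abs=0.05)

    def test_identity_enforced_exactly(self, rng):
        x, y = gaussian_pair(rng, 0.5, n=600)
        ce = conditional_entropy(x, y, KNN)
        assert ce.value - (ce.h_x - ce.mi_xy) == 0.0

    def test_identity_violation_rejected(self):
        with pytest.raises(EstimatorError, match="identity"):
            PairwiseCE(value=1.0, h_x=2.0, mi_xy=0.5)

    def test_no_surrogates_means_no_pvalue(self, rng):
        x, y = gaussian_pair(rng, 0.5, n=600)
        assert conditional_entropy(x, y, KNN).p_value is None

    def test_pvalue_attached_when_configured(self, rng):
        cfg = EstimatorConfig(n_surrogates=19, seed=3)
        x, y = gaussian_pair(rng, 0.9, n=400)
        ce = conditional_entropy(x, y, cfg)
        assert ce.p_value == pytest.approx(1 / 20)


class TestSurrogates:
    def test_strong_coupling_gives_minimal_pvalue(self, rng):
        cfg = EstimatorConfig(n_surrogates=100, seed=5)
        x, y = gaussian_pair(rng, 0.9, n=2000)
        mi = mutual_information(x, y, cfg)
        assert surrogate_pvalue(x, y, mi, cfg) == pytest.approx(1 / 101)

    def test_pvalue_never_zero_and_at_most_one(self, rng):
        cfg = EstimatorConfig(n_surrogates=9, seed=5)
        x, y = rng.standard_normal(300), rng.standard_normal(300)
        mi = mutual_information(x, y, cfg)
        p = surrogate_pvalue(x, y, mi, cfg)
        assert 0.0 < p <= 1.0

    def test_requires_surrogates(self, rng):
        with pytest.raises(EstimatorError, match="n_surrogates"):
            surrogate_pvalue(rng.standard_normal(300), rng.standard_normal(300), 0.1, KNN)

    def test_seeded_determinism(self, rng):
        cfg = EstimatorConfig(n_surrogates=25, seed=8)
        x, y = gaussian_pair(rng, 0.3, n=500)
        mi = mutual_information(x, y, cfg)
        assert surrogate_pvalue(x, y, mi, cfg) == surrogate_pvalue(x, y, mi, cfg)


class TestExpectedCEProfile:
    def recording(self, data, names=None):
        names = names or tuple(f"C{i + 1}" for i in range(data.shape[0]))
        return EEGRecording("sub-01", names, 250.0, data)

    def test_two_channels_single_term_average(self, rng):
        data = rng.standard_normal((2, 1500))
        prof = expected_ce_profile(self.recording(data), KNN)
        pair = conditional_entropy(data[0], data[1], KNN)
        assert prof.ce_values[0] == pytest.approx(pair.value, rel=1e-9)

    def test_independent_channels_ce_near_marginal_entropy(self, rng):
        data = rng.standard_normal((4, 4000))
        prof = expected_ce_profile(self.recording(data), KNN)
        for i in range(4):
            h = entropy(data[i], KNN)
            assert prof.ce_values[i] == pytest.approx(h, abs=0.07)

    def test_common_source_drives_ce_far_below_entropy(self, rng):
        source = rng.standard_normal(3000)
        data = np.vstack([source + 0.01 * rng.standard_normal(3000) for _ in range(3)])
        prof = expected_ce_profile(self.recording(data), KNN)
        for i in range(3):
            assert prof.ce_values[i] < entropy(data[i], KNN) - 1.0

    def test_single_channel_rejected(self, rng):
        with pytest.raises(EstimatorError, match=">= 2 channels"):
            expected_ce_profile(self.recording(rng.standard_normal((1, 1000))), KNN)

    def test_channel_pvalues_are_medians_of_pairwise(self, rng):
        cfg = EstimatorConfig(n_surrogates=9, seed=2, max_samples=300)
        data = rng.standard_normal((3, 300))
        prof = expected_ce_profile(self.recording(data), cfg)
        assert prof.p_values is not None
        assert np.all((prof.p_values > 0) & (prof.p_values <= 1))

    def test_subsampling_is_deterministic(self, rng):
        cfg = EstimatorConfig(n_surrogates=0, max_samples=1000, seed=4)
        data = rng.standard_normal((2, 5000))
        p1 = expected_ce_profile(self.recording(data), cfg)
        p2 = expected_ce_profile(self.recording(data), cfg)
        np.testing.assert_array_equal(p1.ce_values, p2.ce_values)


class TestProfileIO:
    def make_profiles(self, rng, n=3, c=4):
        return [
            CEProfile(f"s{i}", tuple(f"C{j}" for j in range(c)), rng.standard_normal(c) + 2)
            for i in range(n)
        ]

    def test_frame_shape_and_order(self, rng):
        frame = profiles_to_frame(self.make_profiles(rng))
        assert frame.shape == (3, 4)
        assert list(frame.index) == ["s0", "s1", "s2"]

    def test_mismatched_channels_rejected(self, rng):
        profs = self.make_profiles(rng)
        bad = CEProfile("s9", ("X", "Y", "Z", "W"), rng.standard_normal(4))
        with pytest.raises(EstimatorError, match="channel set"):
            profiles_to_frame(profs + [bad])

    def test_csv_round_trip(self, rng, tmp_path):
        profs = self.make_profiles(rng)
        path = write_profiles_csv(profs, tmp_path / "profiles.csv")
        back = read_profiles_csv(path)
        assert [p.participant_id for p in back] == [p.participant_id for p in profs]
        np.testing.assert_allclose(back[0].ce_values, profs[0].ce_values, rtol=1e-9)
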