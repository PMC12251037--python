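"""Age transform, clock training/prediction and cohort age deltas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import folate_response as fr
from folate_response import clock as clk


class TestAgeTransform:
    @pytest.mark.parametrize(
        "age,expected",
        [(20.0, 0.0), (41.0, 1.0), (0.0, np.log(1 / 21))],
    )
    def test_anchor_values(self, age, expected):
        assert fr.age_transform(age) == pytest.approx(expected, abs=1e-12)

    @given(age=st.floats(0.0, 120.0))
    @settings(deadline=None)
    def test_round_trip(self, age):
        assert fr.inverse_age_transform(fr.age_transform(age)) == pytest.approx(
            age, abs=1e-9
        )

    def test_strictly_increasing(self):
        ages = np.linspace(0, 120, 500)
        assert np.all(np.diff(fr.age_transform(ages)) > 0)

    def test_negative_age_raises(self):
        with pytest.raises(ValueError):
            fr.age_transform(-1.0)


@pytest.fixture(scope="module")
def small_model():
    methylome = fr.random_methylome(10, 10, seed=3)
    ages = np.linspace(5.0, 95.0, 40)
    beta = fr.generate_beta_matrix(ages, methylome, noise_sd=0.0, seed=0)
    return methylome, ages, beta


class TestTraining:
    def test_noiseless_recovery(self, small_model):
        _, ages, beta = small_model
        model = fr.train_filtered_clock(beta, ages, list(beta.index), seed=0)
        pred = fr.predict_age(model, beta)
        assert np.mean(np.abs(pred.to_numpy() - ages)) < 0.1

    def test_nonzero_count_bounded_by_whitelist(self, trained_clock):
        assert 0 < trained_clock.nonzero_count <= len(trained_clock.whitelist)

    def test_duplicated_samples_fixed_penalty_identical(self, small_model):
        _, ages, beta = small_model
        dup = pd.concat(
            [beta, beta.set_axis([f"{c}_dup" for c in beta.columns], axis=1)], axis=1
        )
        a = fr.train_filtered_clock(beta, ages, list(beta.index), alpha=1e-4)
        b = fr.train_filtered_clock(
            dup, np.concatenate([ages, ages]), list(beta.index), alpha=1e-4
        )
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-8)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-8)

    def test_missing_whitelist_cpg_raises(self, small_model):
        _, ages, beta = small_model
        with pytest.raises(KeyError, match="missing"):
            fr.train_filtered_clock(beta, ages, ["cgABSENT"], seed=0)

    def test_constant_ages_raise(self, small_model):
        methylome, _, _ = small_model
        ages = np.full(20, 50.0)
        beta = fr.generate_beta_matrix(ages, methylome, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="constant"):
            fr.train_filtered_clock(beta, ages, list(beta.index), seed=0)

    def test_noisy_recovery_within_three_years(self, dataset, trained_clock):
        pred = fr.predict_age(trained_clock, dataset.beta_train)
        truth = dataset.train_ages.loc[pred.index]
        mae = float(np.mean(np.abs(pred.to_numpy() - truth.to_numpy())))
        assert mae < 3.0

    def test_training_correlation(self, dataset, trained_clock):
        pred = fr.predict_age(trained_clock, dataset.beta_train)
        truth = dataset.train_ages.loc[pred.index]
        r, _ = fr.correlate(pred.to_numpy(), truth.to_numpy())
        assert r >= 0.95


class TestPrediction:
    def test_zero_coefficients_return_intercept_age(self):
        model = fr.ClockModel(["cg1"], fr.age_transform(50.0), np.zeros(1))
        beta = pd.Series({"cg1": 0.73})
        assert fr.predict_age(model, beta) == pytest.approx(50.0)

    def test_non_whitelist_rows_ignored(self, dataset, trained_clock):
        perturbed = dataset.beta_before.copy()
        noise_rows = [r for r in perturbed.index if r.startswith("noise")]
        assert noise_rows
        perturbed.loc[noise_rows] = 0.123
        a = fr.predict_age(trained_clock, dataset.beta_before)
        b = fr.predict_age(trained_clock, perturbed)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_missing_cpg_raises_unless_imputed(self, dataset, trained_clock):
        incomplete = dataset.beta_before.drop(index=trained_clock.whitelist[0])
        with pytest.raises(KeyError, match="missing whitelist"):
            fr.predict_age(trained_clock, incomplete)
        imputed = fr.predict_age(trained_clock, incomplete, impute_mean=True)
        assert np.isfinite(imputed.to_numpy()).all()


class TestSerialization:
    def test_bit_exact_round_trip(self, trained_clock, tmp_path):
        path = tmp_path / "model.tsv"
        fr.write_model(trained_clock, path)
        loaded = fr.read_model(path)
        assert loaded.whitelist == trained_clock.whitelist
        assert loaded.intercept == trained_clock.intercept
        assert loaded.adult_age == trained_clock.adult_age
        assert np.array_equal(loaded.coefficients, trained_clock.coefficients)


class TestCohortDeltas:
    def test_identical_timepoints_zero_deltas(self, dataset, trained_clock):
        deltas, summary = fr.cohort_age_deltas(
            trained_clock, dataset.beta_before, dataset.beta_before
        )
        assert all(d.delta == 0.0 for d in deltas)
        assert float(summary["fraction_decreasing"].iloc[0]) == 0.0

    def test_single_patient_delta_sign(self):
        d = clk.AgeDelta("p", 60.0, 57.0)
        assert d.delta == pytest.approx(-3.0)

    def test_mismatched_columns_raise(self, dataset, trained_clock):
        shuffled = dataset.beta_after[list(dataset.beta_after.columns[::-1])]
        with pytest.raises(ValueError, match="matching sample columns"):
            fr.cohort_age_deltas(trained_clock, dataset.beta_before, shuffled)

    def test_planted_group_deltas_recovered(self, dataset, trained_clock, labels):
        cfg = fr.SimConfig()
        _, summary = fr.cohort_age_deltas(
            trained_clock, dataset.beta_before, dataset.beta_after, labels
        )
        summary = summary.set_index("group")
        for group, mean, sd in (
            (fr.RESPONDER, cfg.age_delta_responder_mean, cfg.age_delta_responder_sd),
            (
                fr.NON_RESPONDER,
                cfg.age_delta_nonresponder_mean,
                np.hypot(cfg.assoc_slope * cfg.assoc_burden_sd, cfg.assoc_noise_sd),
            ),
        ):
            n = summary.loc[group, "n"]
            tol = 3 * sd / np.sqrt(n)
            assert abs(summary.loc[group, "mean_delta_years"] - mean) < tol
        # most non-responders got biologically younger, most responders not
        assert summary.loc[fr.NON_RESPONDER, "fraction_decreasing"] > 0.6
        assert summary.loc[fr.NON_RESPONDER, "p_value"] < 0.05
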