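import numpy as np
import pandas as pd
import pytest

from cfrl import build_schedule, draw_outcomes, resolve_parameters, simulate_agent
from cfrl.behaviour import (
    CurveComparison,
    behavioural_summary,
    correct_choice_rate,
    curve_squared_distance,
    median_split,
    model_estimate_curves,
    normalized_bias,
    preferred_choice_rate,
)
from cfrl.fitting import FitOptions, fit_map, fit_mle
from cfrl.models import MODELS
from conftest import make_manual_dataset


def _symmetric_dataset(counts_a):
    """One Symmetric instance per (session, count) with given #A out of 24."""
    frames = []
    for session, n_a in enumerate(counts_a, start=1):
        choices = [0] * n_a + [1] * (24 - n_a)
        df = make_manual_dataset(choices, [1] * 24, [1] * 24)
        df["session"] = session
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestPreferredChoiceRate:
    def test_counting_example_28_of_48(self):
        rate, tie = preferred_choice_rate(_symmetric_dataset([14, 14]))
        assert rate == pytest.approx(28 / 48)
        assert not tie

    def test_all_one_option(self):
        rate, _ = preferred_choice_rate(_symmetric_dataset([24, 24]))
        assert rate == 1.0

    def test_exact_tie_flagged_at_half(self):
        rate, tie = preferred_choice_rate(_symmetric_dataset([12, 12]))
        assert rate == 0.5
        assert tie

    def test_minority_option_counts_toward_modal(self):
        rate, _ = preferred_choice_rate(_symmetric_dataset([4, 4]))  # modal is option 1
        assert rate == pytest.approx(20 / 24)

    def test_at_least_half_for_simulated_agents(self, sim_dataset):
        rate, _ = preferred_choice_rate(sim_dataset)
        assert 0.5 <= rate <= 1.0

    def test_requires_symmetric_trials(self):
        df = make_manual_dataset([0, 1], [1, -1], label="Asymmetric")
        with pytest.raises(ValueError):
            preferred_choice_rate(df)


class TestCorrectChoiceRate:
    def test_always_correct_in_asymmetric(self, design_complete):
        df = make_manual_dataset([0] * 24, [1] * 24, [1] * 24,
                                 instance=1, label="Asymmetric")
        assert correct_choice_rate(df, "Asymmetric", design=design_complete) == 1.0

    def test_reversal_phases_flip_the_correct_option(self, design_complete):
        # option 0 all 24 trials: perfect before reversal, wrong after
        df = make_manual_dataset([0] * 24, [1] * 24, [1] * 24,
                                 instance=3, label="Reversal")
        assert correct_choice_rate(df, "Reversal", "first_half", design_complete) == 1.0
        assert correct_choice_rate(df, "Reversal", "second_half", design_complete) == 0.0
        assert correct_choice_rate(df, "Reversal", "all", design_complete) == 0.5

    def test_random_agent_near_chance(self, design_complete, one_model):
        params = resolve_parameters(one_model, [0.0, 0.3])
        rng = np.random.default_rng(6)
        rates = []
        for sub_rng in rng.spawn(10):
            data = simulate_agent(
                one_model, params, design_complete, draw_outcomes(design_complete, sub_rng),
                sub_rng,
            )
            rates.append(correct_choice_rate(data, "Asymmetric", design=design_complete))
        assert np.mean(rates) == pytest.approx(0.5, abs=0.05)

    def test_symmetric_rejected(self, sim_dataset, design_complete):
        with pytest.raises(ValueError):
            correct_choice_rate(sim_dataset, "Symmetric", design=design_complete)


class TestNormalizedBias:
    def test_symmetric_rates_give_zero(self):
        p = resolve_parameters(MODELS["Full"], [1.0, 0.4, 0.4, 0.2, 0.2])
        assert normalized_bias(p, 1) == 0.0

    def test_experiment1_direct_value(self):
        p = resolve_parameters(MODELS["Full"], [1.0, 0.6, 0.2, 0.0, 0.0])
        assert normalized_bias(p, 1) == pytest.approx(0.5)

    def test_pure_confirmation_pattern_is_one(self):
        p = resolve_parameters(MODELS["Confirmation"], [1.0, 0.3, 0.0])
        assert normalized_bias(p, 2) == pytest.approx(1.0)

    def test_result_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = resolve_parameters(MODELS["Full"], [1.0, *rng.uniform(0.01, 1, 4)])
            assert -1.0 <= normalized_bias(p, 2) <= 1.0

    def test_zero_denominator_flagged(self):
        p = resolve_parameters(MODELS["Full"], [1.0, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ZeroDivisionError):
            normalized_bias(p, 1)

    def test_printed_form_differs_when_counterfactual_rates_tied(self):
        p = resolve_parameters(MODELS["Full"], [1.0, 0.6, 0.2, 0.3, 0.3])
        assert normalized_bias(p, 2) != normalized_bias(p, 2, printed_form=True)

    def test_invalid_experiment(self):
        p = resolve_parameters(MODELS["One"], [1.0, 0.3])
        with pytest.raises(ValueError):
            normalized_bias(p, 3)


class TestMedianSplit:
    def test_twenty_subjects_split_evenly(self):
        labels = median_split(np.arange(20, dtype=float))
        assert (labels == "high").sum() == 10
        assert (labels == "low").sum() == 10

    def test_degenerate_split_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = median_split(np.ones(6))
        assert (labels == "low").all()

    def test_monotone_transformation_invariance(self):
        x = np.random.default_rng(1).normal(size=15)
        assert (median_split(x) == median_split(np.exp(3 * x))).all()

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            median_split([1.0])


class TestModelEstimateCurves:
    def test_probabilities_in_open_interval(self, sim_dataset, confirmation, design_complete):
        params = resolve_parameters(confirmation, [5.0, 0.4, 0.1])
        comp = model_estimate_curves(sim_dataset, confirmation, params, design_complete)
        assert ((comp.curves["p_designated"] > 0) & (comp.curves["p_designated"] < 1)).all()
        assert len(comp.curves) == 192

    def test_deterministic(self, sim_dataset, confirmation, design_complete):
        params = resolve_parameters(confirmation, [5.0, 0.4, 0.1])
        a = model_estimate_curves(sim_dataset, confirmation, params, design_complete)
        b = model_estimate_curves(sim_dataset, confirmation, params, design_complete)
        pd.testing.assert_frame_equal(a.curves, b.curves)

    def test_tying_rates_at_mean_changes_trajectory(self, sim_dataset, confirmation,
                                                    design_complete):
        biased = resolve_parameters(confirmation, [5.0, 0.4, 0.1])
        tied = resolve_parameters(confirmation, [5.0, 0.25, 0.25])
        a = model_estimate_curves(sim_dataset, confirmation, biased, design_complete)
        b = model_estimate_curves(sim_dataset, confirmation, tied, design_complete)
        assert not np.allclose(a.curves["p_designated"], b.curves["p_designated"])

    def test_curves_aligned_on_context_trials(self, sim_dataset, confirmation, design_complete):
        params = resolve_parameters(confirmation, [5.0, 0.4, 0.1])
        comp = model_estimate_curves(sim_dataset, confirmation, params, design_complete)
        for _, grp in comp.curves.groupby(["session", "context_instance"]):
            assert sorted(grp["context_trial"]) == list(range(1, 25))


class TestCurveSquaredDistance:
    def test_perfect_prediction_gives_zero(self):
        curves = pd.DataFrame(
            {
                "condition": ["Symmetric"] * 4,
                "session": 1,
                "context_instance": 0,
                "context_trial": range(1, 5),
                "chose_designated": [1.0, 0.0, 1.0, 1.0],
                "p_designated": [1.0, 0.0, 1.0, 1.0],
            }
        )
        assert curve_squared_distance(CurveComparison(curves)) == 0.0

    def test_constant_half_prediction_gives_quarter(self):
        curves = pd.DataFrame(
            {
                "condition": ["Symmetric"] * 6 + ["Reversal"] * 6,
                "session": 1,
                "context_instance": 0,
                "context_trial": list(range(1, 7)) * 2,
                "chose_designated": [1.0, 0.0] * 6,
                "p_designated": 0.5,
            }
        )
        assert curve_squared_distance(CurveComparison(curves)) == pytest.approx(0.25)


@pytest.fixture(scope="module")
def bias_cohorts(design_complete, confirmation):
    """Matched high-bias and low-bias Confirmation cohorts (same seeds)."""
    high = resolve_parameters(confirmation, [5.0, 0.55, 0.05])
    low = resolve_parameters(confirmation, [5.0, 0.30, 0.30])
    cohorts = {}
    for name, params in [("high", high), ("low", low)]:
        rng = np.random.default_rng(101)
        cohorts[name] = [
            simulate_agent(
                confirmation, params, design_complete, draw_outcomes(design_complete, sub_rng),
                sub_rng,
            )
            for sub_rng in rng.spawn(30)
        ]
    return cohorts


class TestBehaviouralSignatures:
    def test_high_bias_cohort_has_higher_preferred_rate(self, bias_cohorts):
        rates = {
            k: np.mean([preferred_choice_rate(d)[0] for d in v])
            for k, v in bias_cohorts.items()
        }
        assert rates["high"] > rates["low"]

    def test_high_bias_cohort_worse_after_reversal(self, bias_cohorts, design_complete):
        rates = {
            k: np.mean(
                [correct_choice_rate(d, "Reversal", "second_half", design_complete) for d in v]
            )
            for k, v in bias_cohorts.items()
        }
        assert rates["high"] < rates["low"]

    def test_behavioural_summary_shape(self, bias_cohorts, design_complete):
        summary = behavioural_summary(bias_cohorts["high"][:5], design_complete)
        assert len(summary) == 5
        assert summary["preferred_choice_rate"].between(0.5, 1).all()
        for col in ("correct_rate_asymmetric", "correct_rate_reversal_first",
                    "correct_rate_reversal_second"):
            assert summary[col].between(0, 1).all()

    def test_complete_feedback_beats_partial_in_asymmetric(self, confirmation):
        params = resolve_parameters(confirmation, [5.0, 0.35, 0.25])
        rates = {}
        for feedback in ("partial", "complete"):
            design = build_schedule(feedback=feedback, seed=77)
            rng = np.random.default_rng(202)
            rates[feedback] = np.mean(
                [
                    correct_choice_rate(
                        simulate_agent(
                            confirmation, params, design, draw_outcomes(design, sub_rng), sub_rng
                        ),
                        "Asymmetric",
                        design=design,
                    )
                    for sub_rng in rng.spawn(25)
                ]
            )
        assert rates["complete"] > rates["partial"]

    @pytest.mark.slow
    def test_map_bias_sign_recovered_for_most_biased_subjects(
        self, bias_cohorts, confirmation
    ):
        opts = FitOptions(n_restarts=4, seed=9)
        signs = [
            normalized_bias(fit_map(d, confirmation, opts).params, 2) > 0
            for d in bias_cohorts["high"][:20]
        ]
        assert np.mean(signs) >= 0.9

    @pytest.mark.slow
    def test_median_split_of_mixed_cohort_reproduces_signatures(
        self, bias_cohorts, confirmation, design_complete
    ):
        opts = FitOptions(n_restarts=4, seed=9)
        datasets = bias_cohorts["high"][:10] + bias_cohorts["low"][:10]
        biases = np.array(
            [normalized_bias(fit_map(d, confirmation, opts).params, 2) for d in datasets]
        )
        groups = median_split(biases)
        pref = np.array([preferred_choice_rate(d)[0] for d in datasets])
        rev2 = np.array(
            [correct_choice_rate(d, "Reversal", "second_half", design_complete)
             for d in datasets]
        )
        assert pref[groups == "high"].mean() > pref[groups == "low"].mean()
        assert rev2[groups == "high"].mean() < rev2[groups == "low"].mean()

    @pytest.mark.slow
    def test_biased_model_curves_closer_on_biased_cohort(
        self, bias_cohorts, confirmation, one_model, design_complete
    ):
        opts = FitOptions(n_restarts=4, seed=13)
        d_biased, d_unbiased = [], []
        for data in bias_cohorts["high"][:12]:
            fit_b = fit_mle(data, confirmation, opts)
            fit_u = fit_mle(data, one_model, opts)
            d_biased.append(
                curve_squared_distance(
                    model_estimate_curves(data, confirmation, fit_b.params, design_complete)
                )
            )
            d_unbiased.append(
                curve_squared_distance(
                    model_estimate_curves(data, one_model, fit_u.params, design_complete)
                )
            )
        assert np.mean(d_biased) < np.mean(d_unbiased)
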