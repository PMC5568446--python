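"""Behavioural dependent variables, bias indices and model-estimate curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import replay_choice_probabilities
from .models import ModelSpec, ParameterSet
from .task import ASYMMETRIC, REVERSAL, SYMMETRIC, TaskDesign, default_design

__all__ = [
    "preferred_choice_rate",
    "correct_choice_rate",
    "normalized_bias",
    "median_split",
    "model_estimate_curves",
    "curve_squared_distance",
    "CurveComparison",
    "behavioural_summary",
]


def preferred_choice_rate(data: pd.DataFrame) -> tuple[float, bool]:
    """Fraction of Symmetric trials on which the subject chose their modal
    option, computed per context instance (each has its own stimuli) and
    averaged.  Returns (rate, tie_flag); an exact 50/50 instance contributes
    0.5 and sets the flag.  The rate is >= 0.5 by construction.
    """
    sym = data[data["context_label"] == SYMMETRIC]
    if len(sym) == 0:
        raise ValueError("no Symmetric trials in dataset")
    rates, tie = [], False
    for _, grp in sym.groupby(["session", "context_instance"]):
        frac0 = (grp["choice"] == 0).mean()
        if frac0 == 0.5:
            tie = True
        rates.append(max(frac0, 1.0 - frac0))
    return float(np.mean(rates)), tie


def _correct_mask(data: pd.DataFrame, design: TaskDesign) -> np.ndarray:
    """Per-trial indicator that the currently more rewarding option was
    chosen, derived from the design's context specs."""
    specs = design.contexts
    instances = data["context_instance"].to_numpy(dtype=np.int64)
    trials = data["context_trial"].to_numpy(dtype=np.int64)
    choices = data["choice"].to_numpy(dtype=np.int64)
    correct = np.empty(len(data), dtype=bool)
    for i in range(len(data)):
        best = specs[instances[i]].correct_option(trials[i])
        if best is None:
            raise ValueError("correct option undefined for a tied-probability context")
        correct[i] = choices[i] == best
    return correct


def correct_choice_rate(
    data: pd.DataFrame,
    condition: str,
    phase: str = "all",
    design: TaskDesign | None = None,
) -> float:
    """Fraction of trials on which the currently more rewarding option was
    chosen, for the Asymmetric or Reversal condition.

    ``phase`` selects ``all``, ``first_half`` or ``second_half``; halves are
    defined by the reversal point, so in the second half the correct option
    is the initially worse one.  The Symmetric condition has no correct
    option and is rejected.
    """
    if condition == SYMMETRIC:
        raise ValueError("Symmetric condition has no correct option")
    if condition not in (ASYMMETRIC, REVERSAL):
        raise ValueError(f"unknown condition {condition!r}")
    if phase not in ("all", "first_half", "second_half"):
        raise ValueError(f"unknown phase {phase!r}")
    design = design if design is not None else default_design()
    sub = data[data["context_label"] == condition]
    if len(sub) == 0:
        raise ValueError(f"no {condition} trials in dataset")
    if phase != "all":
        # the halfway point: the reversal trial where defined, else T/2
        cut = np.array(
            [
                design.contexts[i].reversal_trial or design.trials_per_context // 2
                for i in sub["context_instance"].to_numpy(dtype=np.int64)
            ]
        )
        trials = sub["context_trial"].to_numpy(dtype=np.int64)
        sub = sub[trials <= cut] if phase == "first_half" else sub[trials > cut]
        if len(sub) == 0:
            raise ValueError(f"no {condition} trials in phase {phase!r}")
    return float(_correct_mask(sub, design).mean())


def normalized_bias(
    params: ParameterSet, experiment: int, printed_form: bool = False
) -> float:
    """Normalised learning-rate asymmetry in [-1, 1].

    Experiment 1 (factual only): ``(αc+ − αc−) / (αc+ + αc−)``.
    Experiment 2 (factual + counterfactual):
    ``[(αc+ − αc−) − (αu+ − αu−)] / (αc+ + αc− + αu+ + αu−)``, positive for
    a confirmation pattern.  ``printed_form=True`` substitutes ``(αu+ + αu−)``
    for the second numerator term (an alternative published reading).
    """
    acp, acm = params.alpha_c_plus, params.alpha_c_minus
    aup, aum = params.alpha_u_plus, params.alpha_u_minus
    if experiment == 1:
        denom = acp + acm
        if denom == 0:
            raise ZeroDivisionError("undefined bias: both factual rates are 0")
        return (acp - acm) / denom
    if experiment == 2:
        denom = acp + acm + aup + aum
        if denom == 0:
            raise ZeroDivisionError("undefined bias: all learning rates are 0")
        second = (aup + aum) if printed_form else (aup - aum)
        return ((acp - acm) - second) / denom
    raise ValueError(f"experiment must be 1 or 2, got {experiment}")


def median_split(indices) -> np.ndarray:
    """Label each subject 'high' (strictly above the median) or 'low'
    (at or below); equal group sizes for even N with distinct values."""
    values = np.asarray(indices, dtype=float)
    if values.size < 2:
        raise ValueError("median split needs >= 2 subjects")
    if np.all(values == values[0]):
        import warnings

        warnings.warn("degenerate median split: all indices equal", stacklevel=2)
    med = np.median(values)
    return np.where(values > med, "high", "low")


@dataclass(frozen=True)
class CurveComparison:
    """Aligned per-trial trajectories: observed choice indicator of the
    designated option and a model's predicted probability for it."""

    curves: pd.DataFrame  # condition, session, context_instance, context_trial,
    #                       chose_designated, p_designated


def model_estimate_curves(
    data: pd.DataFrame,
    model: ModelSpec,
    params: ParameterSet,
    design: TaskDesign | None = None,
) -> CurveComparison:
    """Replay the fitted model over the subject's actual choice/outcome
    sequence and record the predicted probability of the designated option
    per trial.

    Designated options: Symmetric -> the subject's preferred (modal) option
    in that context instance; Asymmetric -> the correct option; Reversal ->
    the initially more advantageous option.
    """
    design = design if design is not None else default_design()
    p0 = replay_choice_probabilities(data, params, model.has_perseveration)
    df = data.copy()
    df["p_option0"] = p0
    rows = []
    for (session, inst), grp in df.groupby(["session", "context_instance"], sort=True):
        spec = design.contexts[int(inst)]
        if spec.label == SYMMETRIC:
            designated = 0 if (grp["choice"] == 0).mean() >= 0.5 else 1
        else:
            designated = spec.correct_option(1)  # initially better option
        p_designated = grp["p_option0"] if designated == 0 else 1.0 - grp["p_option0"]
        rows.append(
            pd.DataFrame(
                {
                    "condition": spec.label,
                    "session": session,
                    "context_instance": inst,
                    "context_trial": grp["context_trial"].to_numpy(),
                    "chose_designated": (grp["choice"] == designated).astype(float).to_numpy(),
                    "p_designated": np.asarray(p_designated, dtype=float),
                }
            )
        )
    return CurveComparison(curves=pd.concat(rows, ignore_index=True))


def curve_squared_distance(comparison: CurveComparison) -> float:
    """Mean squared distance between the predicted probability and the
    observed choice indicator of the designated option, averaged within and
    then across conditions."""
    curves = comparison.curves
    per_condition = (
        curves.assign(sq=(curves["p_designated"] - curves["chose_designated"]) ** 2)
        .groupby("condition")["sq"]
        .mean()
    )
    return float(per_condition.mean())


def behavioural_summary(
    datasets: dict[str, pd.DataFrame] | list[pd.DataFrame],
    design: TaskDesign | None = None,
) -> pd.DataFrame:
    """Per-subject table of the behavioural dependent variables."""
    design = design if design is not None else default_design()
    if isinstance(datasets, dict):
        items = datasets.items()
    else:
        items = [(df["subject"].iloc[0], df) for df in datasets]
    rows = []
    for subject, df in items:
        rate, tie = preferred_choice_rate(df)
        rows.append(
            {
                "subject": subject,
                "preferred_choice_rate": rate,
                "preferred_tie": tie,
                "correct_rate_asymmetric": correct_choice_rate(df, ASYMMETRIC, design=design),
                "correct_rate_reversal_first": correct_choice_rate(
                    df, REVERSAL, "first_half", design=design
                ),
                "correct_rate_reversal_second": correct_choice_rate(
                    df, REVERSAL, "second_half", design=design
                ),
            }
        )
    return pd.DataFrame(rows)
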