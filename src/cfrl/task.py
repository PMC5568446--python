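"""Task schedules, outcome draws and agent simulation.

The default design mirrors a two-session probabilistic instrumental-learning
experiment: each session interleaves four two-armed contexts (one Symmetric
.50/.50, two Asymmetric .75/.25, one Reversal .83/.17 whose contingencies
swap after 12 context-trials) for 24 trials each, 96 trials per session and
192 in total.  Outcomes are +1/-1 points drawn independently per option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    ModelSpec,
    ParameterSet,
    choice_probability,
    counterfactual_update,
    factual_update,
)

__all__ = [
    "ContextSpec",
    "TaskDesign",
    "OutcomeTable",
    "default_design",
    "build_schedule",
    "expected_concordance",
    "draw_outcomes",
    "simulate_agent",
    "make_virtual_cohort",
    "BIAS_PROFILES",
]

SYMMETRIC = "Symmetric"
ASYMMETRIC = "Asymmetric"
REVERSAL = "Reversal"

DATASET_COLUMNS = [
    "subject",
    "session",
    "context_label",
    "context_instance",
    "context_trial",
    "choice",
    "outcome_chosen",
    "outcome_unchosen",
]


class DesignError(ValueError):
    """Raised for invalid task-design configurations."""


@dataclass(frozen=True)
class ContextSpec:
    """One fixed pair of cues: label, per-option reward probabilities and an
    optional contingency-reversal point (context-trial index after which the
    probabilities swap)."""

    label: str
    p_a: float
    p_b: float
    reversal_trial: int | None = None

    def __post_init__(self) -> None:
        for p in (self.p_a, self.p_b):
            if not 0.0 <= p <= 1.0:
                raise DesignError(f"reward probability {p} outside [0, 1]")
        if self.reversal_trial is not None and self.reversal_trial < 1:
            raise DesignError("reversal_trial must be >= 1")

    def probabilities(self, context_trial: int) -> tuple[float, float]:
        """Reward probabilities (option A, option B) in force at a 1-based
        context-trial index, honouring the reversal point."""
        if self.reversal_trial is not None and context_trial > self.reversal_trial:
            return self.p_b, self.p_a
        return self.p_a, self.p_b

    def correct_option(self, context_trial: int) -> int | None:
        """0/1 index of the currently more rewarding option, None if tied."""
        pa, pb = self.probabilities(context_trial)
        if pa == pb:
            return None
        return 0 if pa > pb else 1


def _default_contexts() -> tuple[ContextSpec, ...]:
    return (
        ContextSpec(SYMMETRIC, 0.50, 0.50),
        ContextSpec(ASYMMETRIC, 0.75, 0.25),
        ContextSpec(ASYMMETRIC, 0.75, 0.25),
        ContextSpec(REVERSAL, 0.83, 0.17, reversal_trial=12),
    )


@dataclass(frozen=True)
class TaskDesign:
    """A fully materialised schedule.

    ``order`` holds, per session, the sequence of context indices (into
    ``contexts``) in presentation order; every context index appears exactly
    ``trials_per_context`` times per session.  A context's *instance* is
    identified by (session, context index): the second session re-uses the
    same contingencies with fresh stimuli, so values re-initialise there.
    """

    contexts: tuple[ContextSpec, ...]
    n_sessions: int = 2
    trials_per_context: int = 24
    feedback: str = "complete"  # {"partial", "complete"}
    order: tuple[tuple[int, ...], ...] = field(default=(), hash=False)

    def __post_init__(self) -> None:
        if self.trials_per_context < 1:
            raise DesignError("trials_per_context must be >= 1")
        if self.n_sessions < 1:
            raise DesignError("n_sessions must be >= 1")
        if self.feedback not in ("partial", "complete"):
            raise DesignError(f"feedback must be 'partial' or 'complete', got {self.feedback!r}")
        if len(self.order) != self.n_sessions:
            raise DesignError("order must contain one sequence per session")
        expected = {i: self.trials_per_context for i in range(len(self.contexts))}
        for seq in self.order:
            counts: dict[int, int] = {}
            for c in seq:
                counts[c] = counts.get(c, 0) + 1
            if counts != expected:
                raise DesignError(
                    "each context must appear exactly trials_per_context times per session"
                )

    @property
    def trials_per_session(self) -> int:
        return len(self.contexts) * self.trials_per_context

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session


#: outcome array indexed [session, position-in-session, option] with values +-1
OutcomeTable = np.ndarray


def default_design(feedback: str = "complete", seed: int = 0) -> TaskDesign:
    """The standard 2-session, 192-trial design with a seeded interleaving."""
    return build_schedule(feedback=feedback, seed=seed)


def build_schedule(
    contexts: tuple[ContextSpec, ...] | None = None,
    n_sessions: int = 2,
    trials_per_context: int = 24,
    feedback: str = "complete",
    seed: int | np.random.Generator = 0,
) -> TaskDesign:
    """Materialise a schedule with a uniformly shuffled per-session
    interleaving of contexts.  Identical seed -> identical schedule."""
    if contexts is None:
        contexts = _default_contexts()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = []
    for _ in range(n_sessions):
        seq = np.repeat(np.arange(len(contexts)), trials_per_context)
        rng.shuffle(seq)
        order.append(tuple(int(c) for c in seq))
    return TaskDesign(
        contexts=tuple(contexts),
        n_sessions=n_sessions,
        trials_per_context=trials_per_context,
        feedback=feedback,
        order=tuple(order),
    )


def expected_concordance(p1: float, p2: float) -> float:
    """Probability that two independently drawn binary outcomes coincide:
    ``p1*p2 + (1-p1)*(1-p2)``."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    return p1 * p2 + (1.0 - p1) * (1.0 - p2)


def draw_outcomes(design: TaskDesign, rng: np.random.Generator) -> OutcomeTable:
    """Draw a +-1 outcome for *both* options of every scheduled trial,
    independently per option with the probabilities in force on that trial."""
    out = np.empty((design.n_sessions, design.trials_per_session, 2), dtype=np.int8)
    for s in range(design.n_sessions):
        counters = [0] * len(design.contexts)
        for pos, ctx_idx in enumerate(design.order[s]):
            counters[ctx_idx] += 1
            pa, pb = design.contexts[ctx_idx].probabilities(counters[ctx_idx])
            u = rng.random(2)
            out[s, pos, 0] = 1 if u[0] < pa else -1
            out[s, pos, 1] = 1 if u[1] < pb else -1
    return out


def _iter_schedule(design: TaskDesign):
    """Yield (session, position, context index, context trial 1..T)."""
    for s in range(design.n_sessions):
        counters = [0] * len(design.contexts)
        for pos, ctx_idx in enumerate(design.order[s]):
            counters[ctx_idx] += 1
            yield s, pos, ctx_idx, counters[ctx_idx]


def simulate_agent(
    model: ModelSpec,
    params: ParameterSet,
    design: TaskDesign,
    outcomes: OutcomeTable,
    rng: np.random.Generator,
    subject: int | str = 0,
) -> pd.DataFrame:
    """Simulate one agent on a materialised schedule with pre-drawn outcomes.

    The agent chooses via softmax over the current context's Q-values
    (initialised to 0 per context instance), updates the chosen value from
    its outcome and, under complete feedback, the unchosen value from the
    forgone outcome.  Returns a trial-level DataFrame in the standard
    dataset layout.
    """
    q = {(s, c): [0.0, 0.0] for s in range(design.n_sessions) for c in range(len(design.contexts))}
    last_choice: dict[tuple[int, int], int | None] = {k: None for k in q}
    complete = design.feedback == "complete"
    rows = []
    for s, pos, ctx_idx, ctx_trial in _iter_schedule(design):
        key = (s, ctx_idx)
        qa, qb = q[key]
        bonus_a = bonus_b = 0.0
        if model.has_perseveration and last_choice[key] is not None:
            if last_choice[key] == 0:
                bonus_a = params.pi
            else:
                bonus_b = params.pi
        p_a = choice_probability(qa, qb, params.beta, bonus_a, bonus_b)
        choice = 0 if rng.random() < p_a else 1
        r_c = int(outcomes[s, pos, choice])
        r_u = int(outcomes[s, pos, 1 - choice])
        upd = factual_update(q[key][choice], r_c, params.alpha_c_plus, params.alpha_c_minus)
        q[key][choice] = upd.value
        if complete:
            upd_u = counterfactual_update(
                q[key][1 - choice], r_u, params.alpha_u_plus, params.alpha_u_minus
            )
            q[key][1 - choice] = upd_u.value
        last_choice[key] = choice
        rows.append(
            (
                subject,
                s + 1,
                design.contexts[ctx_idx].label,
                ctx_idx,
                ctx_trial,
                choice,
                r_c,
                r_u if complete else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


#: Discrete generating profiles for recovery designs.  Each maps to
#: (alpha_c_plus, alpha_c_minus, alpha_u_plus, alpha_u_minus) at beta = 5.
BIAS_PROFILES = {
    "unbiased": (0.30, 0.30, 0.30, 0.30),
    "semi-biased": (0.45, 0.15, 0.30, 0.30),
    "biased": (0.45, 0.15, 0.15, 0.45),
}
_PROFILE_BETA = 5.0


def _draw_empirical_like(model: ModelSpec, rng: np.random.Generator) -> list[float]:
    """Generating parameters drawn from the fitting priors: beta ~ gamma(1.2,
    scale 5), each learning rate ~ beta(1.1, 1.1), pi ~ N(0, 1)."""
    free = []
    for name in model.free_names:
        if name == "beta":
            free.append(float(rng.gamma(shape=1.2, scale=5.0)))
        elif name == "pi":
            free.append(float(rng.normal(0.0, 1.0)))
        else:
            free.append(float(rng.beta(1.1, 1.1)))
    return free


def make_virtual_cohort(
    bias_profile: str,
    n_subjects: int,
    design: TaskDesign,
    rng: np.random.Generator,
    model: ModelSpec | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate a cohort of virtual subjects and return their datasets plus
    the generating-parameter table (one row per subject).

    ``bias_profile`` is one of ``unbiased | semi-biased | biased``
    (discrete Full-model learning rates, beta = 5) or ``empirical-like``
    (parameters drawn from the fitting priors).  Each subject gets an
    independent RNG substream, so cohorts are reproducible and subjects
    distinct.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (cohort correlations undefined)")
    from .models import MODELS, free_values, resolve_parameters  # local to avoid cycle noise

    if bias_profile == "empirical-like":
        if model is None:
            model = MODELS["Confirmation"]
    elif bias_profile in BIAS_PROFILES:
        if model is None:
            model = MODELS["Full"]
        if model.name != "Full":
            raise ValueError("discrete profiles are defined on the Full model's slots")
    else:
        raise ValueError(
            f"unknown bias_profile {bias_profile!r}; choose from "
            f"{sorted(BIAS_PROFILES) + ['empirical-like']}"
        )

    streams = rng.spawn(n_subjects)
    datasets, rows = [], []
    for i, sub_rng in enumerate(streams):
        if bias_profile == "empirical-like":
            free = _draw_empirical_like(model, sub_rng)
            params = resolve_parameters(model, free)
        else:
            acp, acm, aup, aum = BIAS_PROFILES[bias_profile]
            params = ParameterSet(
                beta=_PROFILE_BETA,
                alpha_c_plus=acp,
                alpha_c_minus=acm,
                alpha_u_plus=aup,
                alpha_u_minus=aum,
            )
            free = free_values(model, params)
        outcomes = draw_outcomes(design, sub_rng)
        datasets.append(simulate_agent(model, params, design, outcomes, sub_rng, subject=i))
        rows.append({"subject": i, **dict(zip(model.free_names, free))})
    return datasets, pd.DataFrame(rows)
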