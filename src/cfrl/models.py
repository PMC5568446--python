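"""Model space and elementary computations for asymmetric Q-learning.

The model family shares a single value-update/choice architecture: a
Rescorla-Wagner delta rule with separate learning rates for positive and
negative prediction errors of the chosen (factual) and unchosen
(counterfactual) option, and a softmax decision rule.  Variants differ only
in how the four learning-rate slots are tied together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ParameterSet",
    "ModelSpec",
    "UpdateResult",
    "MODELS",
    "get_model",
    "factual_update",
    "counterfactual_update",
    "choice_probability",
    "resolve_parameters",
]

ALPHA_SLOTS = ("alpha_c_plus", "alpha_c_minus", "alpha_u_plus", "alpha_u_minus")


@dataclass(frozen=True)
class ParameterSet:
    """Concrete parameter values for one agent/fit.

    ``beta`` is the softmax scaling factor (larger -> more deterministic
    choice); the four ``alpha_*`` slots are learning rates for positive /
    negative prediction errors of the chosen / unchosen option; ``pi`` is an
    additive perseveration bonus on the previously chosen option's decision
    variable (0 disables it).
    """

    beta: float
    alpha_c_plus: float
    alpha_c_minus: float
    alpha_u_plus: float
    alpha_u_minus: float
    pi: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        for slot in ALPHA_SLOTS:
            a = getattr(self, slot)
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"{slot} must be in [0, 1], got {a}")

    def as_dict(self) -> dict[str, float]:
        return {
            "beta": self.beta,
            **{s: getattr(self, s) for s in ALPHA_SLOTS},
            "pi": self.pi,
        }

    def replace(self, **kwargs: float) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class UpdateResult:
    """Outcome of a single delta-rule update: new value and prediction error."""

    value: float
    pe: float


@dataclass(frozen=True)
class ModelSpec:
    """A named model variant: which free parameters it has and how they map
    onto the four learning-rate slots."""

    name: str
    free_names: tuple[str, ...]
    #: map alpha slot -> free-parameter name
    tying: dict[str, str] = field(hash=False)
    has_perseveration: bool = False

    @property
    def df(self) -> int:
        return len(self.free_names)

    def resolve(self, free_params) -> ParameterSet:
        return resolve_parameters(self, free_params)


def _spec(name, free_names, tying, persev=False):
    return ModelSpec(
        name=name, free_names=tuple(free_names), tying=tying, has_perseveration=persev
    )


#: The model space.  Free-parameter orderings are part of the public file
#: format (fits CSV / params YAML) and must not change.
MODELS: dict[str, ModelSpec] = {
    "Full": _spec(
        "Full",
        ("beta", "alpha_c_plus", "alpha_c_minus", "alpha_u_plus", "alpha_u_minus"),
        {s: s for s in ALPHA_SLOTS},
    ),
    "Information": _spec(
        "Information",
        ("beta", "alpha_c", "alpha_u"),
        {
            "alpha_c_plus": "alpha_c",
            "alpha_c_minus": "alpha_c",
            "alpha_u_plus": "alpha_u",
            "alpha_u_minus": "alpha_u",
        },
    ),
    "Valence": _spec(
        "Valence",
        ("beta", "alpha_plus", "alpha_minus"),
        {
            "alpha_c_plus": "alpha_plus",
            "alpha_c_minus": "alpha_minus",
            "alpha_u_plus": "alpha_plus",
            "alpha_u_minus": "alpha_minus",
        },
    ),
    "Confirmation": _spec(
        "Confirmation",
        ("beta", "alpha_con", "alpha_dis"),
        {
            "alpha_c_plus": "alpha_con",
            "alpha_c_minus": "alpha_dis",
            "alpha_u_plus": "alpha_dis",
            "alpha_u_minus": "alpha_con",
        },
    ),
    "Perseveration": _spec(
        "Perseveration",
        ("beta", "alpha_c", "alpha_u", "pi"),
        {
            "alpha_c_plus": "alpha_c",
            "alpha_c_minus": "alpha_c",
            "alpha_u_plus": "alpha_u",
            "alpha_u_minus": "alpha_u",
        },
        persev=True,
    ),
    "One": _spec(
        "One",
        ("beta", "alpha"),
        {s: "alpha" for s in ALPHA_SLOTS},
    ),
}


def get_model(name: str) -> ModelSpec:
    """Look up a model by name (case-insensitive)."""
    key = name.strip().lower().capitalize()
    try:
        return MODELS[key]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; choose from {sorted(MODELS)}"
        ) from None


def resolve_parameters(model: ModelSpec, free_params) -> ParameterSet:
    """Expand a model's free-parameter vector (or mapping) into a full
    :class:`ParameterSet` via the model's tying map.

    ``free_params`` may be a sequence ordered as ``model.free_names`` or a
    mapping from free-parameter name to value.
    """
    if isinstance(free_params, dict):
        missing = set(model.free_names) - set(free_params)
        extra = set(free_params) - set(model.free_names)
        if missing or extra:
            raise ValueError(
                f"{model.name} expects parameters {model.free_names}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        values = dict(free_params)
    else:
        free_params = list(free_params)
        if len(free_params) != model.df:
            raise ValueError(
                f"{model.name} has {model.df} free parameters "
                f"{model.free_names}, got {len(free_params)} values"
            )
        values = dict(zip(model.free_names, free_params))

    kwargs = {slot: values[src] for slot, src in model.tying.items()}
    kwargs["beta"] = values["beta"]
    if model.has_perseveration:
        kwargs["pi"] = values["pi"]
    return ParameterSet(**kwargs)


def free_values(model: ModelSpec, params: ParameterSet) -> list[float]:
    """Project a full ParameterSet back onto a model's free-parameter vector."""
    out = []
    inverse: dict[str, float] = {"beta": params.beta, "pi": params.pi}
    for slot, src in model.tying.items():
        inverse[src] = getattr(params, slot)
    for name in model.free_names:
        out.append(inverse[name])
    return out


def _delta_update(q: float, r: float, alpha_plus: float, alpha_minus: float) -> UpdateResult:
    pe = r - q
    if pe > 0:
        q = q + alpha_plus * pe
    elif pe < 0:
        q = q + alpha_minus * pe
    # pe == 0: no-op (the two branches coincide there anyway)
    return UpdateResult(value=q, pe=pe)


def factual_update(
    q_c: float, r_c: float, alpha_c_plus: float, alpha_c_minus: float
) -> UpdateResult:
    """Update the chosen option's value from its obtained outcome.

    The prediction error is ``r_c - q_c``; it is scaled by ``alpha_c_plus``
    when positive and ``alpha_c_minus`` when negative.
    """
    return _delta_update(q_c, r_c, alpha_c_plus, alpha_c_minus)


def counterfactual_update(
    q_u: float, r_u: float, alpha_u_plus: float, alpha_u_minus: float
) -> UpdateResult:
    """Update the unchosen option's value from the displayed forgone outcome."""
    return _delta_update(q_u, r_u, alpha_u_plus, alpha_u_minus)


def choice_probability(
    q_c: float, q_u: float, beta: float, persev_bonus_c: float = 0.0, persev_bonus_u: float = 0.0
) -> float:
    """Softmax probability of picking the option with value ``q_c``.

    Computes ``exp(beta*(q_c+b_c)) / (exp(beta*(q_c+b_c)) + exp(beta*(q_u+b_u)))``
    in a numerically stable form.  The perseveration bonuses default to 0.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    x = beta * ((q_c + persev_bonus_c) - (q_u + persev_bonus_u))
    # logistic(x), stable for large |x|
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def log_choice_probability(
    q_c: float, q_u: float, beta: float, persev_bonus_c: float = 0.0, persev_bonus_u: float = 0.0
) -> float:
    """log of :func:`choice_probability`, stable where the probability underflows."""
    x = beta * ((q_c + persev_bonus_c) - (q_u + persev_bonus_u))
    # log(sigmoid(x)) = -log(1 + exp(-x))
    if x >= 0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))
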