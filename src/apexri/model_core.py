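"""Predicted sequence completion times for the eight model variants.

Every model is the sum of an achieved-skill curve and (except offline V1)
a shared reactive-inhibition (RI) term.  Skill follows a flexible
power-exponential (APEX) practice function

    RT_skill = a + b * exp(-c * u) * u**(-k)

where the practice argument ``u`` is what distinguishes the variants:

- ``online``     u = S, the cumulative modeled sequence number (learning
                 accrues with execution);
- ``offline_v1`` / ``offline_v2``  u = T - 1, the cumulative break count
                 (learning accrues only across breaks); V1 omits RI, V2
                 adds it; the ``_offset`` variants subtract an extra
                 rest-period gain g during the test phase;
- ``hybridJ``    u = S', a mixture allocating j learning units to each
                 break and the remaining units to executed sequences;
- ``hybridE``    exponential factor runs on breaks, power factor on
                 sequences; ``hybridP`` the reverse.

RI adds (ST-1)*y within each trial plus (T-1)*z of residual build-up
across trials, with the trial counter restarting in the test phase
because the 5-min rest is assumed to resolve all residual RI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .trial_design import DesignConstants

__all__ = [
    "EPSILON_BASE", "ModelParams", "ModelSpec", "MODEL_REGISTRY",
    "DEFAULT_COMPARISON_MODELS", "get_model", "epsilon_shift", "ri_rt",
    "skill_rt", "effective_units", "predict_rt",
]

#: Offset used wherever a (T-1)- or (S'-0)-style base would be raised to a
#: negative power at zero: the model substitutes (T - 0.9999999999) for
#: (T - 1), keeping the first-trial skill value finite while perturbing
#: every later trial by a numerically negligible 1e-10.
EPSILON_BASE = 0.9999999999

PARAM_FIELDS = ("a", "b", "c", "k", "y", "z", "g", "j")


def epsilon_shift(t):
    """Shifted practice index ``t - 0.9999999999`` (positive for t >= 1)."""
    return np.asarray(t, dtype=float) - EPSILON_BASE


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector; only the fields a model uses need to be set.

    a : asymptotic skill (ms)
    b : magnitude of practice gain (ms)
    c : exponential rate (per practice unit)
    k : power rate (unitless)
    y : within-trial RI slope (ms per sequence)
    z : residual RI slope (ms per trial)
    g : extra rest-period offline gain (ms; offset variants only)
    j : offline learning units per break (hybridJ only)
    """

    a: float | None = None
    b: float | None = None
    c: float | None = None
    k: float | None = None
    y: float | None = None
    z: float | None = None
    g: float | None = None
    j: float | None = None

    def require(self, names: tuple[str, ...]) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"missing parameters: {', '.join(missing)}")
        nonpos = [n for n in names if n != "j" and getattr(self, n) <= 0]
        if nonpos:
            raise ValueError(
                f"parameters must be > 0: {', '.join(nonpos)}"
            )
        if "j" in names and self.j < 0:
            raise ValueError("j must be >= 0")

    def to_array(self, names: tuple[str, ...]) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    @classmethod
    def from_array(cls, names: tuple[str, ...], values) -> "ModelParams":
        return cls(**dict(zip(names, map(float, values))))

    def asdict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_FIELDS
                if getattr(self, n) is not None}

    def with_values(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry: name, free parameters, and whether RI is included."""

    name: str
    param_names: tuple[str, ...]
    has_ri: bool
    skill: Callable[..., np.ndarray]

    @property
    def h(self) -> int:
        """Number of free parameters (the BIC penalty count)."""
        return len(self.param_names)



def _col(schedule, name: str) -> np.ndarray:
    """Column accessor working on DataFrames and plain dicts of arrays."""
    v = schedule[name]
    if hasattr(v, "to_numpy"):
        return v.to_numpy(dtype=float)
    return np.asarray(v, dtype=float)

def ri_rt(params: ModelParams, schedule: pd.DataFrame) -> np.ndarray:
    """Reactive-inhibition RT increment per schedule row (ms).

    (ST-1)*y + (T-1)*z during training and (ST-1)*y + (T_test-1)*z during
    test: within-trial RI is zero on the first modeled sequence of each
    trial, and residual RI restarts at zero on the first test trial (the
    rest period is assumed to fully resolve it).
    """
    params.require(("y", "z"))
    st = _col(schedule, "st")
    x = _col(schedule, "x")
    t_phase = np.where(x == 0, _col(schedule, "trial"),
                       _col(schedule, "trial_test"))
    return (st - 1.0) * params.y + (t_phase - 1.0) * params.z


def effective_units(schedule: pd.DataFrame, j: float,
                    consts: DesignConstants) -> np.ndarray:
    """Effective cumulative learning units S' of the hybridJ model.

    S' = S * (Stot - Btot*j)/Stot + (T_cum - 1)*j, with the break factor
    (T_cum - 1) epsilon-shifted so S' stays positive on trial one even at
    the all-offline bound j = Stot/Btot.  Units are conserved: at the last
    test sequence S = Stot and T_cum - 1 = Btot, so S' = Stot for any j.
    """
    if not 0 <= j <= consts.j_max + 1e-12:
        raise ValueError(
            f"j={j} out of bounds [0, Stot/Btot = {consts.j_max:.6g}]"
        )
    s = _col(schedule, "s")
    tcum = _col(schedule, "trial_cum")
    online_share = (consts.stot - consts.btot * j) / consts.stot
    return s * online_share + epsilon_shift(tcum) * j


def _apex(u: np.ndarray, a: float, b: float, c: float, k: float) -> np.ndarray:
    return a + b * np.exp(-c * u) * u ** (-k)


def _skill_online(params, schedule, consts):
    s = _col(schedule, "s")
    return _apex(s, params.a, params.b, params.c, params.k)


def _skill_offline(params, schedule, consts):
    tm1 = epsilon_shift(_col(schedule, "trial_cum"))
    return _apex(tm1, params.a, params.b, params.c, params.k)


def _skill_offline_offset(params, schedule, consts):
    x = _col(schedule, "x")
    return _skill_offline(params, schedule, consts) - params.g * x


def _skill_hybridJ(params, schedule, consts):
    sp = effective_units(schedule, params.j, consts)
    return _apex(sp, params.a, params.b, params.c, params.k)


def _skill_hybridE(params, schedule, consts):
    # exponential improvement offline (breaks), power improvement online
    s = _col(schedule, "s")
    tm1 = epsilon_shift(_col(schedule, "trial_cum"))
    return params.a + params.b * np.exp(-params.c * tm1) * s ** (-params.k)


def _skill_hybridP(params, schedule, consts):
    s = _col(schedule, "s")
    tm1 = epsilon_shift(_col(schedule, "trial_cum"))
    return params.a + params.b * np.exp(-params.c * s) * tm1 ** (-params.k)


MODEL_REGISTRY: Mapping[str, ModelSpec] = {
    spec.name: spec for spec in (
        ModelSpec("offline_v1", ("a", "b", "c", "k"), False, _skill_offline),
        ModelSpec("offline_v1_offset", ("a", "b", "c", "k", "g"), False,
                  _skill_offline_offset),
        ModelSpec("offline_v2", ("a", "b", "c", "k", "y", "z"), True,
                  _skill_offline),
        ModelSpec("offline_v2_offset", ("a", "b", "c", "k", "g", "y", "z"),
                  True, _skill_offline_offset),
        ModelSpec("online", ("a", "b", "c", "k", "y", "z"), True,
                  _skill_online),
        ModelSpec("hybridJ", ("a", "b", "c", "k", "j", "y", "z"), True,
                  _skill_hybridJ),
        ModelSpec("hybridE", ("a", "b", "c", "k", "y", "z"), True,
                  _skill_hybridE),
        ModelSpec("hybridP", ("a", "b", "c", "k", "y", "z"), True,
                  _skill_hybridP),
    )
}

#: The six models entering the default BIC comparison; the rest-offset
#: variants exist in the registry but never improved BIC and are excluded
#: from the default set.
DEFAULT_COMPARISON_MODELS = (
    "offline_v1", "offline_v2", "online", "hybridJ", "hybridE", "hybridP",
)


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; registered models: "
            f"{', '.join(MODEL_REGISTRY)}"
        ) from None


def _consts_from_schedule(schedule: pd.DataFrame) -> DesignConstants:
    stot = int(np.max(_col(schedule, "s")))
    btot = int(np.max(_col(schedule, "trial_cum"))) - 1
    return DesignConstants(stot=stot, btot=btot, n_obs=stot)


def skill_rt(model: ModelSpec | str, params: ModelParams,
             schedule: pd.DataFrame,
             consts: DesignConstants | None = None) -> np.ndarray:
    """Latent achieved-skill RT per schedule row (ms)."""
    spec = get_model(model) if isinstance(model, str) else model
    # the RI slopes y and z do not enter the skill curve
    params.require(tuple(n for n in spec.param_names if n not in ("y", "z")))
    if consts is None:
        consts = _consts_from_schedule(schedule)
    if "j" in spec.param_names and params.j > consts.j_max + 1e-12:
        raise ValueError(f"j={params.j} exceeds Stot/Btot = {consts.j_max:.6g}")
    return spec.skill(params, schedule, consts)


def predict_rt(model: ModelSpec | str, params: ModelParams,
               schedule: pd.DataFrame,
               consts: DesignConstants | None = None) -> np.ndarray:
    """Predicted observed RT: achieved skill plus RI where the model has it."""
    spec = get_model(model) if isinstance(model, str) else model
    params.require(spec.param_names)
    rt = skill_rt(spec, params, schedule, consts)
    if spec.has_ri:
        rt = rt + ri_rt(params, schedule)
    return rt
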