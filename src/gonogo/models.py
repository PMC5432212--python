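"""Likelihood machinery for the nested Go/NoGo model family M1–M6.

All models are asymmetric Q-learning ("delta rule") models over three
response options per cue, with a softmax choice rule on action weights:

    w(Go)   = Q(Go)   + pi * V(cue) + b
    w(NoGo) = Q(NoGo)
    p(a)    = softmax(w)(a)

    Q <- Q + eps * (rho * r - Q)

where r in {-1, 0, +1} is the outcome, rho > 0 the feedback sensitivity
(scaling the outcome into value units), eps the learning rate, b a
valence-independent go bias and pi the Pavlovian weight on the fixed cue
values V(Win) = +0.5, V(Avoid) = -0.5.  Initial Q-values equal rho * V,
reflecting the instructed cue valence.

The instrumental learning bias kappa makes the learning rate asymmetric
(higher after rewarded Go, lower after punished NoGo), built symmetrically
in model space:

    eps0            = invlogit(eps_raw)
    eps_punished_nogo = invlogit(eps_raw - kappa)
    eps_rewarded_go = eps0 + (eps0 - eps_punished_nogo)

Drug-session (methylphenidate, "MPH") mechanisms extend the winning base
model: an additive shift of the Pavlovian weight (pi_mph), an additive shift
of kappa in sampling space (kappa_mph_selective), and a diffuse learning
rate (eps_diffuse) that, under MPH, spreads reward credit from a rewarded Go
response to the other (unchosen) Go response.

The model family:

====== ==========================================================
name   active parameters beyond rho, eps0
====== ==========================================================
M1     —
M2     b
M3a    b, pi
M3b    b, kappa
M4     b, pi, kappa
M5a    M4 + pi_mph
M5b    M4 + kappa_mph_selective
M5c    M4 + kappa_mph_diffuse
M6     M4 + pi_mph + kappa_mph_diffuse
====== ==========================================================
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from . import _kernels
from .task import Response, RESPONSE_CODES, RESPONSES_BY_CODE, TrialRecord, Valence

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MODELS",
    "RawParameters",
    "ModelParameters",
    "LatentState",
    "PLACEBO",
    "MPH",
    "transform_parameters",
    "initial_values",
    "action_weights",
    "choice_probabilities",
    "effective_learning_rate",
    "update_values",
    "session_loglik",
]

PLACEBO = "placebo"
MPH = "MPH"

#: sampling-space parameter names, in canonical order
PARAMETER_NAMES = (
    "rho_raw",
    "eps_raw",
    "b",
    "pi",
    "kappa_raw",
    "pi_mph",
    "kappa_mph_sel_raw",
    "kappa_mph_diff_raw",
)


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Which parameters a model activates (rho and eps0 are always active)."""

    name: str
    b: bool = False
    pi: bool = False
    kappa: bool = False
    pi_mph: bool = False
    kappa_mph_sel: bool = False
    kappa_mph_diff: bool = False

    @property
    def active_parameters(self) -> tuple[str, ...]:
        flags = {
            "rho_raw": True,
            "eps_raw": True,
            "b": self.b,
            "pi": self.pi,
            "kappa_raw": self.kappa,
            "pi_mph": self.pi_mph,
            "kappa_mph_sel_raw": self.kappa_mph_sel,
            "kappa_mph_diff_raw": self.kappa_mph_diff,
        }
        return tuple(p for p in PARAMETER_NAMES if flags[p])

    @property
    def uses_drug_effects(self) -> bool:
        return self.pi_mph or self.kappa_mph_sel or self.kappa_mph_diff

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            return MODELS[name]
        except KeyError:
            raise ValueError(f"unknown model {name!r}; choose from {sorted(MODELS)}") from None


MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1"),
    "M2": ModelSpec("M2", b=True),
    "M3a": ModelSpec("M3a", b=True, pi=True),
    "M3b": ModelSpec("M3b", b=True, kappa=True),
    "M4": ModelSpec("M4", b=True, pi=True, kappa=True),
    "M5a": ModelSpec("M5a", b=True, pi=True, kappa=True, pi_mph=True),
    "M5b": ModelSpec("M5b", b=True, pi=True, kappa=True, kappa_mph_sel=True),
    "M5c": ModelSpec("M5c", b=True, pi=True, kappa=True, kappa_mph_diff=True),
    "M6": ModelSpec("M6", b=True, pi=True, kappa=True, pi_mph=True, kappa_mph_diff=True),
}


@dataclasses.dataclass(frozen=True)
class RawParameters:
    """One subject's parameters in (unconstrained) sampling space.

    Inactive parameters are held at 0, where they are inert by construction.
    """

    rho_raw: float = 0.0
    eps_raw: float = 0.0
    b: float = 0.0
    pi: float = 0.0
    kappa_raw: float = 0.0
    pi_mph: float = 0.0
    kappa_mph_sel_raw: float = 0.0
    kappa_mph_diff_raw: float = 0.0

    def to_array(self, names: Sequence[str] = PARAMETER_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float], names: Sequence[str]) -> "RawParameters":
        return cls(**{n: float(v) for n, v in zip(names, values)})


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Session-effective parameters in model space.

    ``pi`` and the learning rates already include any drug-session shift;
    ``eps_diffuse`` is nonzero only when the diffuse mechanism is active in
    this session.
    """

    rho: float
    eps0: float
    eps_rewarded_go: float
    eps_punished_nogo: float
    b: float = 0.0
    pi: float = 0.0
    eps_diffuse: float = 0.0
    diffuse_active: bool = False


def transform_parameters(
    raw: RawParameters, spec: ModelSpec, drug: str = PLACEBO
) -> ModelParameters:
    """Map sampling-space parameters to model space for one session.

    rho is exponentiated (positivity), learning rates are inverse-logit
    transformed ([0, 1]), and the learning-bias asymmetry is built
    symmetrically around eps0 in model space.  Under MPH, pi_mph shifts the
    Pavlovian weight (M5a/M6), kappa_mph_selective shifts kappa in sampling
    space before the sigmoid construction (M5b), and kappa_mph_diffuse
    activates the diffuse reward-credit learning rate (M5c/M6).
    """
    if drug not in (PLACEBO, MPH):
        raise ValueError(f"drug must be {PLACEBO!r} or {MPH!r}, got {drug!r}")
    is_mph = drug == MPH

    kappa_arg = raw.kappa_raw if spec.kappa else 0.0
    if is_mph and spec.kappa_mph_sel:
        kappa_arg += raw.kappa_mph_sel_raw

    eps0 = float(expit(raw.eps_raw))
    eps_pn = float(expit(raw.eps_raw - kappa_arg))
    eps_rg = eps0 + (eps0 - eps_pn)
    if eps_rg > 1.0 or eps_rg < 0.0:
        if eps_rg > 1.0 + 1e-9 or eps_rg < -1e-9:
            logger.warning(
                "symmetric rewarded-Go learning rate %.4f outside [0, 1]; clipping",
                eps_rg,
            )
        eps_rg = min(max(eps_rg, 0.0), 1.0)

    pi_eff = raw.pi if spec.pi else 0.0
    if is_mph and spec.pi_mph:
        pi_eff += raw.pi_mph

    diffuse = bool(is_mph and spec.kappa_mph_diff)
    return ModelParameters(
        rho=float(np.exp(raw.rho_raw)),
        eps0=eps0,
        eps_rewarded_go=eps_rg,
        eps_punished_nogo=eps_pn,
        b=raw.b if spec.b else 0.0,
        pi=pi_eff,
        eps_diffuse=float(expit(raw.kappa_mph_diff_raw)) if diffuse else 0.0,
        diffuse_active=diffuse,
    )


def transform_parameter_draws(
    draws: np.ndarray, spec: ModelSpec, drug: str = PLACEBO
) -> dict[str, np.ndarray]:
    """Vectorized :func:`transform_parameters` over an (n_draws, 8) array of
    full sampling-space vectors (canonical :data:`PARAMETER_NAMES` order).

    Returns model-space arrays; the rewarded-Go rate is clipped to [0, 1]
    silently (draw-wise transforms are applied before summarizing, so the
    clip region is visited routinely in the tails).
    """
    if drug not in (PLACEBO, MPH):
        raise ValueError(f"drug must be {PLACEBO!r} or {MPH!r}, got {drug!r}")
    is_mph = drug == MPH
    draws = np.asarray(draws, dtype=float)
    col = {name: draws[:, i] for i, name in enumerate(PARAMETER_NAMES)}
    kappa_arg = col["kappa_raw"] if spec.kappa else 0.0
    if is_mph and spec.kappa_mph_sel:
        kappa_arg = kappa_arg + col["kappa_mph_sel_raw"]
    eps0 = expit(col["eps_raw"])
    eps_pn = expit(col["eps_raw"] - kappa_arg)
    eps_rg = np.clip(2.0 * eps0 - eps_pn, 0.0, 1.0)
    pi_eff = col["pi"] if spec.pi else np.zeros(len(draws))
    if is_mph and spec.pi_mph:
        pi_eff = pi_eff + col["pi_mph"]
    diffuse = bool(is_mph and spec.kappa_mph_diff)
    return {
        "rho": np.exp(col["rho_raw"]),
        "eps0": eps0,
        "eps_rewarded_go": eps_rg,
        "eps_punished_nogo": eps_pn,
        "b": col["b"] if spec.b else np.zeros(len(draws)),
        "pi": np.asarray(pi_eff, dtype=float) + np.zeros(len(draws)),
        "eps_diffuse": expit(col["kappa_mph_diff_raw"]) if diffuse else np.zeros(len(draws)),
    }


# ---------------------------------------------------------------------------
# latent state and single-trial operations (reference, dict-based path)


@dataclasses.dataclass
class LatentState:
    """Q-values per (cue, response) and fixed Pavlovian cue values V."""

    Q: dict[tuple[int, Response], float]
    V: dict[int, float]


def initial_values(rho: float, cue_valences: Mapping[int, Valence]) -> LatentState:
    """Initial state: Q0 = rho * V with V = +0.5 (Win) / -0.5 (Avoid)."""
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    V = {
        cue: (0.5 if val is Valence.WIN else -0.5) for cue, val in cue_valences.items()
    }
    Q = {
        (cue, a): rho * v
        for cue, v in V.items()
        for a in Response
    }
    return LatentState(Q=Q, V=V)


def action_weights(
    state: LatentState, cue_id: int, params: ModelParameters
) -> dict[Response, float]:
    """Action weights: Go responses get the Pavlovian and go-bias terms."""
    if cue_id not in state.V:
        raise KeyError(f"cue {cue_id} not in latent state")
    v = state.V[cue_id]
    return {
        Response.GO_LEFT: state.Q[(cue_id, Response.GO_LEFT)] + params.pi * v + params.b,
        Response.GO_RIGHT: state.Q[(cue_id, Response.GO_RIGHT)] + params.pi * v + params.b,
        Response.NOGO: state.Q[(cue_id, Response.NOGO)],
    }


def choice_probabilities(weights: Mapping[Response, float]) -> dict[Response, float]:
    """Softmax over the three response weights (max-subtracted for safety)."""
    w = np.array([weights[a] for a in Response], dtype=float)
    w -= w.max()
    e = np.exp(w)
    p = e / e.sum()
    return {a: float(pi) for a, pi in zip(Response, p)}


def effective_learning_rate(
    params: ModelParameters, response: Response, outcome: int
) -> float:
    """Asymmetric learning rate: eps_rewarded_go after (Go, +1),
    eps_punished_nogo after (NoGo, -1), eps0 otherwise."""
    if outcome == 1 and response.is_go:
        return params.eps_rewarded_go
    if outcome == -1 and response is Response.NOGO:
        return params.eps_punished_nogo
    return params.eps0


def update_values(
    state: LatentState,
    cue_id: int,
    response: Response,
    outcome: int,
    params: ModelParameters,
) -> LatentState:
    """Delta-rule update of the chosen action's Q-value; under the active
    diffuse mechanism a rewarded Go additionally updates the unchosen Go
    response with the chosen action's prediction error."""
    Q = dict(state.Q)
    pe = params.rho * outcome - Q[(cue_id, response)]
    rate = effective_learning_rate(params, response, outcome)
    diffuse_fires = params.diffuse_active and outcome == 1 and response.is_go
    if diffuse_fires:
        rate = min(rate + params.eps_diffuse, 1.0)
        other = Response.GO_RIGHT if response is Response.GO_LEFT else Response.GO_LEFT
        Q[(cue_id, other)] += params.eps_diffuse * pe
    Q[(cue_id, response)] += rate * pe
    return LatentState(Q=Q, V=state.V)


# ---------------------------------------------------------------------------
# session likelihood (array path, numba-compiled)


def trials_to_arrays(
    trials: Sequence[TrialRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pack one subject-session into (cue_index, response_code, outcome, V).

    Cue ids are mapped to 0-based indices in sorted order; V holds the
    Pavlovian value (+0.5 / -0.5) per cue index.
    """
    cue_ids = sorted({t.cue_id for t in trials})
    index = {c: i for i, c in enumerate(cue_ids)}
    valence_by_cue: dict[int, Valence] = {}
    for t in trials:
        prev = valence_by_cue.setdefault(t.cue_id, t.valence)
        if prev is not t.valence:
            raise ValueError(f"cue {t.cue_id} has inconsistent valence across trials")
    cue = np.array([index[t.cue_id] for t in trials], dtype=np.int64)
    resp = np.array([RESPONSE_CODES[t.response] for t in trials], dtype=np.int64)
    outcome = np.array([t.outcome for t in trials], dtype=np.int64)
    v = np.array(
        [0.5 if valence_by_cue[c] is Valence.WIN else -0.5 for c in cue_ids], dtype=float
    )
    return cue, resp, outcome, v


def session_loglik(
    params: ModelParameters, trials: Sequence[TrialRecord]
) -> tuple[float, np.ndarray]:
    """Log-likelihood of one subject-session under session-effective
    parameters.

    Trials must be in presentation order (sorted by ``trial_index``).
    Returns the total log-likelihood and the per-trial log-probabilities of
    the observed responses (the pointwise contributions WAIC needs).
    """
    if not trials:
        raise ValueError("empty trial sequence")
    idx = [t.trial_index for t in trials]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("trials must be sorted by trial_index")
    if len({(t.subject_id, t.session) for t in trials}) != 1:
        raise ValueError("session_loglik expects a single subject-session")
    cue, resp, outcome, v = trials_to_arrays(trials)
    pointwise = _kernels.session_loglik_kernel(
        cue,
        resp,
        outcome,
        v,
        params.rho,
        params.eps0,
        params.eps_rewarded_go,
        params.eps_punished_nogo,
        params.b,
        params.pi,
        params.eps_diffuse,
        params.diffuse_active,
    )
    return float(pointwise.sum()), pointwise


def session_probabilities(
    params: ModelParameters, trials: Sequence[TrialRecord]
) -> np.ndarray:
    """Per-trial choice probabilities (n_trials x 3, columns GoLeft, GoRight,
    NoGo) along the observed history — the one-step-ahead quantities."""
    cue, resp, outcome, v = trials_to_arrays(trials)
    return _kernels.session_probs_kernel(
        cue,
        resp,
        outcome,
        v,
        params.rho,
        params.eps0,
        params.eps_rewarded_go,
        params.eps_punished_nogo,
        params.b,
        params.pi,
        params.eps_diffuse,
        params.diffuse_active,
    )
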