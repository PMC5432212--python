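"""WAIC model comparison and absolute-fit checks.

WAIC is computed from the pointwise log-likelihood draws on the deviance
scale, waic = -2 * (lppd - p_waic), with the variance-form penalty
p_waic = sum_t Var_draws[log p(y_t)].  Lower is better; differences of 2-6
are conventionally read as positive evidence, 6-10 as strong and >10 as
very strong.

Two absolute-fit procedures complement the relative comparison:

* one-step-ahead prediction — replay each subject's actual choice/outcome
  history and record the model's choice probabilities at every trial;
* posterior predictive simulation — play the task afresh (choices sampled
  from the model, outcomes from the feedback rule), which discards
  subject-specific history effects.

Both are averaged over posterior draws.  In the no-learning limit the two
coincide; with learning they diverge because simulation generates its own
histories.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import _kernels
from .inference import PosteriorFit, _make_transform, _prepare_sessions
from .models import ModelSpec, RawParameters
from .task import RESPONSE_CODES

RESPONSE_CODES_BY_NAME = {r.value: c for r, c in RESPONSE_CODES.items()}

__all__ = [
    "WaicResult",
    "PredictionResult",
    "waic",
    "compare_models",
    "evidence_label",
    "one_step_ahead",
    "posterior_predictive_simulate",
]


@dataclasses.dataclass(frozen=True)
class WaicResult:
    """WAIC on the deviance scale with its pointwise decomposition."""

    waic: float
    lppd: float
    p_waic: float
    pointwise: np.ndarray  # per-trial deviance-scale contributions
    n_draws: int
    name: str = ""
    fingerprint: str = ""


def waic(pointwise_loglik: np.ndarray, name: str = "", fingerprint: str = "") -> WaicResult:
    """WAIC from an (n_draws, n_trials) matrix of pointwise log-likelihoods.

    lppd_t = log mean_d exp(loglik_dt) (computed with log-sum-exp);
    p_waic_t = Var_d[loglik_dt]; contributions -2*(lppd_t - p_waic_t) sum to
    the total.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihoods must be (n_draws, n_trials)")
    n_draws = ll.shape[0]
    if n_draws < 2:
        raise ValueError("WAIC needs at least 2 draws (variance penalty undefined)")
    lppd_t = logsumexp(ll, axis=0) - np.log(n_draws)
    p_t = ll.var(axis=0, ddof=1)
    pointwise = -2.0 * (lppd_t - p_t)
    return WaicResult(
        waic=float(pointwise.sum()),
        lppd=float(lppd_t.sum()),
        p_waic=float(p_t.sum()),
        pointwise=pointwise,
        n_draws=n_draws,
        name=name,
        fingerprint=fingerprint,
    )


def waic_of_fit(fit: PosteriorFit) -> WaicResult:
    return waic(fit.pointwise_loglik, name=fit.model.name, fingerprint=fit.fingerprint)


def evidence_label(delta: float) -> str:
    """Conventional deviance-scale evidence bands for a WAIC difference."""
    if delta <= 0:
        return "best"
    if delta < 2:
        return "weak"
    if delta <= 6:
        return "positive"
    if delta <= 10:
        return "strong"
    return "very strong"


def compare_models(
    results: Sequence[WaicResult], reference: str | None = None
) -> pd.DataFrame:
    """Rank models by WAIC (ascending = best first).

    Ties keep input order and are flagged.  Results carrying different data
    fingerprints cannot be compared and raise.  ``reference`` names the
    model against which ``delta_vs_reference`` is reported (defaults to the
    first input, conventionally the simplest model).
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    prints = {r.fingerprint for r in results if r.fingerprint}
    if len(prints) > 1:
        raise ValueError(f"results come from different datasets: {sorted(prints)}")
    names = [r.name or f"model{i}" for i, r in enumerate(results)]
    ref = reference if reference is not None else names[0]
    if ref not in names:
        raise ValueError(f"reference {ref!r} not among {names}")
    ref_waic = results[names.index(ref)].waic
    frame = pd.DataFrame(
        {
            "model": names,
            "waic": [r.waic for r in results],
            "lppd": [r.lppd for r in results],
            "p_waic": [r.p_waic for r in results],
        }
    )
    frame = frame.sort_values("waic", kind="stable").reset_index(drop=True)
    best = frame["waic"].iloc[0]
    frame["delta_waic"] = frame["waic"] - best
    frame["delta_vs_reference"] = frame["waic"] - ref_waic
    frame["evidence"] = [
        "best" if i == 0 else evidence_label(d)
        for i, d in enumerate(frame["delta_waic"])
    ]
    frame["tied_with_best"] = (frame["delta_waic"] == 0.0) & (frame.index > 0)
    return frame


# ---------------------------------------------------------------------------
# absolute fit


@dataclasses.dataclass(frozen=True)
class PredictionResult:
    """Per-trial predicted response probabilities, averaged over draws.

    ``frame`` columns: subject_id, session, trial, cue_id, valence,
    required_action, p_go_left, p_go_right, p_nogo.
    """

    frame: pd.DataFrame
    method: str  # "one_step_ahead" | "simulation"
    n_draws: int

    def go_curves(self) -> pd.DataFrame:
        """p(Go) per cue type (required Go/NoGo x valence) and cue
        repetition, averaged over subjects and sessions."""
        f = self.frame.copy()
        f["p_go"] = f["p_go_left"] + f["p_go_right"]
        f["cue_type"] = np.where(
            f["required_action"].eq("NoGo"), "NoGo-to-", "Go-to-"
        ) + f["valence"].map({"Win": "Win", "Avoid": "Avoid"})
        f["repetition"] = f.groupby(
            ["subject_id", "session", "cue_id"]
        ).cumcount() + 1
        return (
            f.groupby(["cue_type", "repetition"])["p_go"].mean().reset_index()
        )


def _select_draws(fit: PosteriorFit, n_draws: int | None) -> np.ndarray:
    total = fit.n_draws
    if n_draws is None or n_draws >= total:
        return np.arange(total)
    return np.linspace(0, total - 1, n_draws).astype(int)


def _fit_subject_draws(fit: PosteriorFit, sid: int, draw_idx: np.ndarray) -> np.ndarray:
    return fit.flat_subject_draws(sid)[draw_idx]


def one_step_ahead(
    fit: PosteriorFit | tuple[RawParameters, ModelSpec],
    trials: pd.DataFrame,
    n_draws: int | None = None,
) -> PredictionResult:
    """Choice probabilities along each subject's actual history.

    ``fit`` is either a posterior fit (probabilities averaged over retained
    draws, optionally subsampled to ``n_draws``) or a (parameters, model)
    pair for fixed-parameter prediction.
    """
    if isinstance(fit, tuple):
        raw, model = fit
        get_draws = lambda sid: raw.to_array()[None, :]  # noqa: E731
        draw_idx = np.array([0])
    else:
        model = fit.model
        draw_idx = _select_draws(fit, n_draws)
        get_draws = lambda sid: _fit_subject_draws(fit, sid, draw_idx)  # noqa: E731
    transform = _make_transform(model)
    subject_ids, sessions, meta = _prepare_sessions(trials, model)
    blocks = []
    for sid in subject_ids:
        draws = get_draws(sid)
        for sd in sessions[sid]:
            acc = np.zeros((sd.n_trials, 3))
            for vec in draws:
                acc += _kernels.session_probs_kernel(
                    sd.cue, sd.resp, sd.outcome, sd.v, *transform(vec, sd.is_mph)
                )
            blocks.append(acc / len(draws))
    probs = np.vstack(blocks)
    frame = meta[
        ["subject_id", "session", "trial", "cue_id", "valence", "required_action"]
    ].reset_index(drop=True)
    frame[["p_go_left", "p_go_right", "p_nogo"]] = probs
    return PredictionResult(frame=frame, method="one_step_ahead", n_draws=len(draw_idx))


def posterior_predictive_simulate(
    fit: PosteriorFit | tuple[RawParameters, ModelSpec],
    trials: pd.DataFrame,
    validity: float = 0.8,
    n_reps_per_draw: int = 1,
    n_draws: int | None = None,
    seed: int = 0,
) -> PredictionResult:
    """Play the task afresh from the fitted parameters.

    Each subject-session's observed cue sequence is replayed as the
    schedule, but choices are sampled from the model and outcomes from the
    feedback rule (desirable outcome with probability ``validity`` after a
    correct response).  Choice probabilities are averaged over draws x
    ``n_reps_per_draw`` repetitions.
    """
    rng = np.random.default_rng(seed)
    if isinstance(fit, tuple):
        raw, model = fit
        get_draws = lambda sid: raw.to_array()[None, :]  # noqa: E731
        n_used = 1
    else:
        model = fit.model
        draw_idx = _select_draws(fit, n_draws)
        get_draws = lambda sid: _fit_subject_draws(fit, sid, draw_idx)  # noqa: E731
        n_used = len(draw_idx)
    transform = _make_transform(model)
    subject_ids, sessions, meta = _prepare_sessions(trials, model)
    # required actions per cue come from the trial table
    req = meta.drop_duplicates(["subject_id", "session", "cue_id"]).set_index(
        ["subject_id", "session", "cue_id"]
    )["required_action"]
    blocks = []
    for sid in subject_ids:
        draws = get_draws(sid)
        for sd in sessions[sid]:
            session_name = "MPH" if sd.is_mph else "placebo"
            sub_meta = meta[
                (meta["subject_id"] == sid) & (meta["session"] == session_name)
            ]
            cue_ids = np.sort(sub_meta["cue_id"].unique())
            required = np.array(
                [RESPONSE_CODES_BY_NAME[req[(sid, session_name, c)]] for c in cue_ids],
                dtype=np.int64,
            )
            acc = np.zeros((sd.n_trials, 3))
            for vec in draws:
                pr = transform(vec, sd.is_mph)
                for _ in range(n_reps_per_draw):
                    _, _, probs = _kernels.simulate_session_kernel(
                        sd.cue,
                        required,
                        sd.v,
                        validity,
                        *pr,
                        rng.random(sd.n_trials),
                        rng.random(sd.n_trials),
                    )
                    acc += probs
            blocks.append(acc / (len(draws) * n_reps_per_draw))
    probs = np.vstack(blocks)
    frame = meta[
        ["subject_id", "session", "trial", "cue_id", "valence", "required_action"]
    ].reset_index(drop=True)
    frame[["p_go_left", "p_go_right", "p_nogo"]] = probs
    return PredictionResult(frame=frame, method="simulation", n_draws=n_used)
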