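"""Hierarchical Bayesian estimation of the Go/NoGo model family.

The generative hierarchy follows the original protocol: each subject's
sampling-space parameter vector x is drawn from group normals,
x_j ~ N(X_j, sigma_j), with weakly informative hyperpriors
X_rho ~ N(2, 3), X_eps/kappa ~ N(0, 2), X_b/pi ~ N(0, 3) and
sigma_j ~ half-Cauchy(2).  The likelihood of a subject's two sessions is the
sequential softmax choice model of :mod:`gonogo.models`.

Sampling is adaptive random-walk Metropolis-within-Gibbs: per sweep, every
subject-level parameter receives a single-site Metropolis update (proposal
scales adapted during warmup toward ~0.44 acceptance, then frozen), group
means are drawn from their conjugate normal conditionals, and group SDs are
slice-sampled on the log scale.  Several sweeps are run per recorded
iteration (internal thinning) so that the retained draws carry low
autocorrelation; convergence is checked with rank-normalized split R-hat at
the protocol threshold of 1.1, with one escalation of the iteration counts
on non-convergence.  Non-convergence after escalation is flagged on the
returned fit, never raised.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import pathlib
from typing import Callable, Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd

from . import _kernels
from .models import (
    MPH,
    PARAMETER_NAMES,
    PLACEBO,
    ModelSpec,
    transform_parameter_draws,
)
from .task import RESPONSE_CODES, Response, Valence

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorFit",
    "default_priors",
    "PAPER_MCMC",
    "REDUCED_MCMC",
    "fit_model",
    "compute_rhat",
    "subject_estimates",
    "subject_raw_medians",
    "data_fingerprint",
]


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Normal hyperpriors on group means and a half-Cauchy scale on group SDs."""

    means: Mapping[str, float]
    sds: Mapping[str, float]
    sd_scale: float = 2.0

    def __post_init__(self):
        if self.sd_scale <= 0:
            raise ValueError("half-Cauchy scale must be positive")
        for name, sd in self.sds.items():
            if sd <= 0:
                raise ValueError(f"prior sd for {name} must be positive")


def default_priors() -> PriorSpec:
    """The protocol hyperpriors: X_rho ~ N(2,3); learning-rate and
    kappa-type means ~ N(0,2); bias/Pavlovian-type means ~ N(0,3);
    all group SDs ~ half-Cauchy(2)."""
    return PriorSpec(
        means={p: (2.0 if p == "rho_raw" else 0.0) for p in PARAMETER_NAMES},
        sds={
            "rho_raw": 3.0,
            "eps_raw": 2.0,
            "b": 3.0,
            "pi": 3.0,
            "kappa_raw": 2.0,
            "pi_mph": 3.0,
            "kappa_mph_sel_raw": 2.0,
            "kappa_mph_diff_raw": 2.0,
        },
        sd_scale=2.0,
    )


@dataclasses.dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration.

    ``n_warmup``/``n_samples`` count recorded iterations; each recorded
    iteration comprises ``n_sweeps`` full Gibbs sweeps (internal thinning).
    On non-convergence both counts are escalated once to 1500, per protocol.
    """

    n_chains: int = 4
    n_warmup: int = 200
    n_samples: int = 1000
    n_sweeps: int = 10
    escalated_warmup: int = 1500
    escalated_samples: int = 1500
    rhat_threshold: float = 1.1
    rhat_method: str = "rank"  # "rank" (rank-normalized split) or "split"
    allow_escalation: bool = True
    seed: int = 0

    def __post_init__(self):
        for field in ("n_chains", "n_warmup", "n_samples", "n_sweeps"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")


#: the original protocol: 4 chains x (200 warmup + 1000 retained)
PAPER_MCMC = McmcConfig(n_chains=4, n_warmup=200, n_samples=1000)
#: desk-scale default for tests and recovery studies
REDUCED_MCMC = McmcConfig(n_chains=2, n_warmup=200, n_samples=300)


@dataclasses.dataclass(frozen=True)
class _SessionData:
    cue: np.ndarray
    resp: np.ndarray
    outcome: np.ndarray
    v: np.ndarray
    is_mph: bool
    n_trials: int


@dataclasses.dataclass
class PosteriorFit:
    """Draws and diagnostics from one hierarchical fit.

    Array layouts: group draws are (chain, draw, param); subject draws are
    (chain, draw, subject, param); pointwise log-likelihoods are
    (chain*draw, trial), rows stacked chain-major, columns aligned with
    ``trial_meta``.
    """

    model: ModelSpec
    param_names: tuple[str, ...]
    subject_ids: list[int]
    group_mean_draws: np.ndarray
    group_sd_draws: np.ndarray
    subject_draws: np.ndarray
    pointwise_loglik: np.ndarray
    trial_meta: pd.DataFrame
    rhat: pd.Series
    converged: bool
    escalated: bool
    config: McmcConfig
    fingerprint: str
    seed: int

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())

    @property
    def n_draws(self) -> int:
        return self.group_mean_draws.shape[0] * self.group_mean_draws.shape[1]

    def flat_subject_draws(self, subject: int) -> np.ndarray:
        """All retained draws for one subject as an (n_draws, 8) full
        sampling-space array (inactive parameters zero)."""
        s = self.subject_ids.index(subject)
        active = self.subject_draws[:, :, s, :].reshape(-1, len(self.param_names))
        full = np.zeros((active.shape[0], len(PARAMETER_NAMES)))
        for j, name in enumerate(self.param_names):
            full[:, PARAMETER_NAMES.index(name)] = active[:, j]
        return full

    def draws_long(self) -> pd.DataFrame:
        """Draws in long format (chain, iteration, parameter, value)."""
        rows = []
        n_chains, n_draws, d = self.group_mean_draws.shape
        for c in range(n_chains):
            for i in range(n_draws):
                for j, name in enumerate(self.param_names):
                    rows.append((c, i, f"mu_{name}", self.group_mean_draws[c, i, j]))
                    rows.append((c, i, f"sigma_{name}", self.group_sd_draws[c, i, j]))
                for s, sid in enumerate(self.subject_ids):
                    for j, name in enumerate(self.param_names):
                        rows.append((c, i, f"{name}[{sid}]", self.subject_draws[c, i, s, j]))
        return pd.DataFrame(rows, columns=["chain", "iteration", "parameter", "value"])

    def save(self, directory: str | pathlib.Path) -> None:
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            directory / "draws.npz",
            group_mean=self.group_mean_draws,
            group_sd=self.group_sd_draws,
            subject=self.subject_draws,
            pointwise=self.pointwise_loglik,
        )
        self.trial_meta.to_csv(directory / "trial_meta.csv", index=False)
        self.rhat.rename("rhat").rename_axis("parameter").reset_index().to_csv(
            directory / "rhat.csv", index=False
        )
        meta = {
            "model": self.model.name,
            "param_names": list(self.param_names),
            "subject_ids": self.subject_ids,
            "converged": self.converged,
            "escalated": self.escalated,
            "config": dataclasses.asdict(self.config),
            "fingerprint": self.fingerprint,
            "seed": self.seed,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | pathlib.Path) -> "PosteriorFit":
        directory = pathlib.Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        arrays = np.load(directory / "draws.npz")
        rhat = pd.read_csv(directory / "rhat.csv").set_index("parameter")["rhat"]
        return cls(
            model=ModelSpec.from_name(meta["model"]),
            param_names=tuple(meta["param_names"]),
            subject_ids=list(meta["subject_ids"]),
            group_mean_draws=arrays["group_mean"],
            group_sd_draws=arrays["group_sd"],
            subject_draws=arrays["subject"],
            pointwise_loglik=arrays["pointwise"],
            trial_meta=pd.read_csv(directory / "trial_meta.csv"),
            rhat=rhat,
            converged=meta["converged"],
            escalated=meta["escalated"],
            config=McmcConfig(**meta["config"]),
            fingerprint=meta["fingerprint"],
            seed=meta["seed"],
        )


# ---------------------------------------------------------------------------
# data preparation


def data_fingerprint(trials: pd.DataFrame) -> str:
    """Stable hash of a trial table (order-insensitive across row order)."""
    canon = trials.sort_values(["subject_id", "session", "trial"]).reset_index(drop=True)
    payload = canon.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _prepare_sessions(
    trials: pd.DataFrame, model: ModelSpec
) -> tuple[list[int], dict[int, list[_SessionData]], pd.DataFrame]:
    required = {"subject_id", "session", "trial", "cue_id", "valence", "response", "outcome"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if trials.empty:
        raise ValueError("empty cohort")
    subject_ids = sorted(trials["subject_id"].unique().tolist())
    sessions: dict[int, list[_SessionData]] = {}
    meta_parts = []
    for sid in subject_ids:
        sub = trials[trials["subject_id"] == sid]
        present = set(sub["session"].unique())
        if model.uses_drug_effects and present != {PLACEBO, MPH}:
            raise ValueError(
                f"model {model.name} needs both sessions; subject {sid} has {sorted(present)}"
            )
        per_subject = []
        for session in (PLACEBO, MPH):
            ses = sub[sub["session"] == session].sort_values("trial")
            if ses.empty:
                continue
            cue_ids = np.sort(ses["cue_id"].unique())
            index = {c: i for i, c in enumerate(cue_ids)}
            val = ses.drop_duplicates("cue_id").set_index("cue_id")["valence"]
            v = np.array(
                [0.5 if Valence(val[c]) is Valence.WIN else -0.5 for c in cue_ids]
            )
            per_subject.append(
                _SessionData(
                    cue=ses["cue_id"].map(index).to_numpy(dtype=np.int64),
                    resp=ses["response"].map(
                        {r.value: c for r, c in RESPONSE_CODES.items()}
                    ).to_numpy(dtype=np.int64),
                    outcome=ses["outcome"].to_numpy(dtype=np.int64),
                    v=v,
                    is_mph=session == MPH,
                    n_trials=len(ses),
                )
            )
            meta_parts.append(ses)
        sessions[sid] = per_subject
    trial_meta = pd.concat(meta_parts, ignore_index=True)
    return subject_ids, sessions, trial_meta


# ---------------------------------------------------------------------------
# scalar transform (hot path)


def _make_transform(model: ModelSpec) -> Callable:
    """Session-effective model-space scalars from a full 8-vector."""
    use_b, use_pi, use_k = model.b, model.pi, model.kappa
    use_pim, use_ksel, use_kdiff = model.pi_mph, model.kappa_mph_sel, model.kappa_mph_diff

    def transform(full: np.ndarray, is_mph: bool):
        rho = math.exp(full[0])
        kappa_arg = full[4] if use_k else 0.0
        if is_mph and use_ksel:
            kappa_arg += full[6]
        eps0 = 1.0 / (1.0 + math.exp(-full[1]))
        eps_pn = 1.0 / (1.0 + math.exp(-(full[1] - kappa_arg)))
        eps_rg = 2.0 * eps0 - eps_pn
        if eps_rg > 1.0:
            eps_rg = 1.0
        elif eps_rg < 0.0:
            eps_rg = 0.0
        b = full[2] if use_b else 0.0
        pi = full[3] if use_pi else 0.0
        if is_mph and use_pim:
            pi += full[5]
        diffuse = is_mph and use_kdiff
        eps_diff = 1.0 / (1.0 + math.exp(-full[7])) if diffuse else 0.0
        return rho, eps0, eps_rg, eps_pn, b, pi, eps_diff, diffuse

    return transform


def _subject_loglik(full: np.ndarray, sessions: list[_SessionData], transform) -> float:
    total = 0.0
    for sd in sessions:
        pr = transform(full, sd.is_mph)
        total += _kernels.session_loglik_sum_kernel(
            sd.cue, sd.resp, sd.outcome, sd.v, *pr
        )
    return total


def _subject_pointwise(full: np.ndarray, sessions: list[_SessionData], transform) -> np.ndarray:
    parts = [
        _kernels.session_loglik_kernel(sd.cue, sd.resp, sd.outcome, sd.v, *transform(full, sd.is_mph))
        for sd in sessions
    ]
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# samplers


def _slice_sample(x0: float, logf: Callable[[float], float], rng, w: float = 1.0,
                  max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping-out procedure)."""
    y = logf(x0) - rng.exponential()
    left = x0 - w * rng.random()
    right = left + w
    steps = 0
    while logf(left) > y and steps < max_steps:
        left -= w
        steps += 1
    steps = 0
    while logf(right) > y and steps < max_steps:
        right += w
        steps += 1
    while True:
        x1 = left + (right - left) * rng.random()
        if logf(x1) > y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _run_chain(
    chain_seed: int,
    subject_ids: list[int],
    sessions: dict[int, list[_SessionData]],
    model: ModelSpec,
    priors: PriorSpec,
    n_warmup: int,
    n_samples: int,
    n_sweeps: int,
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(chain_seed)
    transform = _make_transform(model)
    names = model.active_parameters
    active_idx = np.array([PARAMETER_NAMES.index(n) for n in names])
    d = len(names)
    n_subj = len(subject_ids)
    prior_mean = np.array([priors.means[n] for n in names])
    prior_sd = np.array([priors.sds[n] for n in names])
    hc_scale = priors.sd_scale

    # overdispersed initialization per chain
    mu = prior_mean + 0.5 * rng.standard_normal(d)
    sigma = np.exp(rng.normal(-0.5, 0.3, d))
    full = np.zeros((n_subj, len(PARAMETER_NAMES)))
    for s in range(n_subj):
        full[s, active_idx] = mu + sigma * rng.standard_normal(d)
    subj_sessions = [sessions[sid] for sid in subject_ids]
    cur_ll = np.array(
        [_subject_loglik(full[s], subj_sessions[s], transform) for s in range(n_subj)]
    )

    scales = np.full((n_subj, d), 0.5)
    acc = np.zeros((n_subj, d))
    # extra directional proposal along the anti-correlated (rho_raw, eps_raw)
    # ridge, the known slow direction of this likelihood; once enough warmup
    # history exists it is replaced by a joint proposal with the empirical
    # per-subject posterior covariance (Haario-style adaptive Metropolis)
    dir_scales = np.full(n_subj, 0.5)
    dir_acc = np.zeros(n_subj)
    joint_scale = np.full(n_subj, 2.38 / math.sqrt(d))
    chol: list = [None] * n_subj
    history: list[list[np.ndarray]] = [[] for _ in range(n_subj)]
    adapt_batch = 20
    batch_count = 0

    warm_sweeps = n_warmup * n_sweeps
    total_sweeps = (n_warmup + n_samples) * n_sweeps
    out_mu = np.empty((n_samples, d))
    out_sigma = np.empty((n_samples, d))
    out_x = np.empty((n_samples, n_subj, d))
    n_trials_total = sum(sd.n_trials for per in subj_sessions for sd in per)
    out_pw = np.empty((n_samples, n_trials_total))
    rec = 0

    for sweep in range(total_sweeps):
        warm = sweep < warm_sweeps
        # subject-level single-site Metropolis updates
        normals = rng.standard_normal((n_subj, d))
        unifs = rng.random((n_subj, d))
        for s in range(n_subj):
            fs = full[s]
            for j in range(d):
                pj = active_idx[j]
                old = fs[pj]
                prop = old + scales[s, j] * normals[s, j]
                fs[pj] = prop
                new_ll = _subject_loglik(fs, subj_sessions[s], transform)
                dmu = mu[j]
                dsd2 = sigma[j] * sigma[j]
                dlp = (
                    new_ll
                    - cur_ll[s]
                    - 0.5 * ((prop - dmu) ** 2 - (old - dmu) ** 2) / dsd2
                )
                if math.log(unifs[s, j]) < dlp:
                    cur_ll[s] = new_ll
                    acc[s, j] += 1.0
                else:
                    fs[pj] = old
            if chol[s] is not None:
                # joint update with empirical covariance
                old_active = fs[active_idx].copy()
                step_vec = joint_scale[s] * (chol[s] @ rng.standard_normal(d))
                fs[active_idx] = old_active + step_vec
                new_ll = _subject_loglik(fs, subj_sessions[s], transform)
                new_active = fs[active_idx]
                dlp = (
                    new_ll
                    - cur_ll[s]
                    - 0.5
                    * float(
                        (((new_active - mu) ** 2 - (old_active - mu) ** 2) / sigma**2).sum()
                    )
                )
                if math.log(rng.random()) < dlp:
                    cur_ll[s] = new_ll
                    dir_acc[s] += 1.0
                else:
                    fs[active_idx] = old_active
            else:
                # directional rho/eps update (indices 0 and 1 are always active)
                delta = dir_scales[s] * rng.standard_normal()
                old0, old1 = fs[0], fs[1]
                fs[0] = old0 + delta
                fs[1] = old1 - delta
                new_ll = _subject_loglik(fs, subj_sessions[s], transform)
                dlp = (
                    new_ll
                    - cur_ll[s]
                    - 0.5 * ((fs[0] - mu[0]) ** 2 - (old0 - mu[0]) ** 2) / (sigma[0] ** 2)
                    - 0.5 * ((fs[1] - mu[1]) ** 2 - (old1 - mu[1]) ** 2) / (sigma[1] ** 2)
                )
                if math.log(rng.random()) < dlp:
                    cur_ll[s] = new_ll
                    dir_acc[s] += 1.0
                else:
                    fs[0], fs[1] = old0, old1
            if warm and sweep >= warm_sweeps // 4:
                history[s].append(fs[active_idx].copy())
        # group-level Gibbs updates
        x_active = full[:, active_idx]
        for j in range(d):
            xj = x_active[:, j]
            # conjugate normal for the group mean
            prec = 1.0 / (prior_sd[j] ** 2) + n_subj / (sigma[j] ** 2)
            mean = (prior_mean[j] / prior_sd[j] ** 2 + xj.sum() / sigma[j] ** 2) / prec
            mu[j] = mean + math.sqrt(1.0 / prec) * rng.standard_normal()
            # slice sample log sigma under half-Cauchy prior
            ssq = float(((xj - mu[j]) ** 2).sum())

            def logf(log_s: float, _ssq=ssq) -> float:
                s_ = math.exp(log_s)
                half_cauchy = -math.log(1.0 + (s_ / hc_scale) ** 2)
                return (
                    half_cauchy
                    + log_s  # jacobian
                    - n_subj * log_s
                    - _ssq / (2.0 * s_ * s_)
                )

            sigma[j] = math.exp(_slice_sample(math.log(sigma[j]), logf, rng))
        # proposal-scale adaptation (warmup only, diminishing)
        if warm and (sweep + 1) % adapt_batch == 0:
            batch_count += 1
            rate = acc / adapt_batch
            step = min(0.5, 1.0 / math.sqrt(batch_count))
            scales *= np.exp(step * (rate - 0.44))
            acc[:] = 0.0
            joint_rate = dir_acc / adapt_batch
            for s in range(n_subj):
                if chol[s] is not None:
                    joint_scale[s] *= math.exp(step * (joint_rate[s] - 0.30))
                else:
                    dir_scales[s] *= math.exp(step * (joint_rate[s] - 0.44))
                if len(history[s]) >= 10 * d:
                    cov = np.cov(np.asarray(history[s]).T) + 1e-6 * np.eye(d)
                    try:
                        chol[s] = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
            dir_acc[:] = 0.0
        # record retained iterations
        if not warm and (sweep + 1 - warm_sweeps) % n_sweeps == 0:
            out_mu[rec] = mu
            out_sigma[rec] = sigma
            out_x[rec] = full[:, active_idx]
            out_pw[rec] = np.concatenate(
                [
                    _subject_pointwise(full[s], subj_sessions[s], transform)
                    for s in range(n_subj)
                ]
            )
            rec += 1
    return {"mu": out_mu, "sigma": out_sigma, "x": out_x, "pointwise": out_pw}


def compute_rhat(draws: np.ndarray, method: str = "rank") -> float:
    """Potential scale reduction factor for one parameter.

    ``draws`` has shape (chain, draw).  ``method`` selects the
    rank-normalized split variant (default) or the classic split variant.
    Chains with zero total variance return NaN (documented degenerate case).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("compute_rhat needs an array of shape (n_chains>=2, n_draws)")
    if draws.shape[1] < 2:
        raise ValueError("compute_rhat needs at least 2 draws per chain")
    if np.ptp(draws) == 0.0:
        return float("nan")
    if method not in ("rank", "split"):
        raise ValueError("method must be 'rank' or 'split'")
    return float(az.rhat(draws, method=method))


def _all_rhats(
    mu: np.ndarray, sigma: np.ndarray, x: np.ndarray,
    names: Sequence[str], subject_ids: Sequence[int], method: str
) -> pd.Series:
    values = {}
    for j, name in enumerate(names):
        values[f"mu_{name}"] = compute_rhat(mu[:, :, j], method)
        values[f"sigma_{name}"] = compute_rhat(np.log(sigma[:, :, j]), method)
        for s, sid in enumerate(subject_ids):
            values[f"{name}[{sid}]"] = compute_rhat(x[:, :, s, j], method)
    return pd.Series(values)


def fit_model(
    trials: pd.DataFrame,
    model: ModelSpec | str,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
) -> PosteriorFit:
    """Fit one model to a cohort of trial records.

    Applies the escalation rule once (iteration counts to 1500) if any
    R-hat exceeds the threshold; a fit that still fails the criterion is
    returned with ``converged=False`` rather than raising.
    """
    model = ModelSpec.from_name(model) if isinstance(model, str) else model
    priors = priors or default_priors()
    config = config or REDUCED_MCMC
    subject_ids, sessions, trial_meta = _prepare_sessions(trials, model)
    fingerprint = data_fingerprint(trials)

    def run(n_warmup: int, n_samples: int) -> tuple:
        seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
        chains = [
            _run_chain(
                int(ss.generate_state(1)[0] % (2**31)),
                subject_ids,
                sessions,
                model,
                priors,
                n_warmup,
                n_samples,
                config.n_sweeps,
            )
            for ss in seeds
        ]
        mu = np.stack([c["mu"] for c in chains])
        sigma = np.stack([c["sigma"] for c in chains])
        x = np.stack([c["x"] for c in chains])
        pw = np.concatenate([c["pointwise"] for c in chains], axis=0)
        rhat = _all_rhats(
            mu, sigma, x, model.active_parameters, subject_ids, config.rhat_method
        )
        return mu, sigma, x, pw, rhat

    mu, sigma, x, pw, rhat = run(config.n_warmup, config.n_samples)
    escalated = False
    if rhat.max() > config.rhat_threshold and config.allow_escalation:
        escalated = True
        mu, sigma, x, pw, rhat = run(config.escalated_warmup, config.escalated_samples)
    return PosteriorFit(
        model=model,
        param_names=model.active_parameters,
        subject_ids=subject_ids,
        group_mean_draws=mu,
        group_sd_draws=sigma,
        subject_draws=x,
        pointwise_loglik=pw,
        trial_meta=trial_meta,
        rhat=rhat,
        converged=bool(rhat.max() <= config.rhat_threshold),
        escalated=escalated,
        config=config,
        fingerprint=fingerprint,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# posterior summaries


_MODEL_SPACE_ROWS = (
    ("rho", lambda spec: True),
    ("eps0", lambda spec: True),
    ("b", lambda spec: spec.b),
    ("pi", lambda spec: spec.pi),
    ("eps_rewarded_go", lambda spec: spec.kappa),
    ("eps_punished_nogo", lambda spec: spec.kappa),
)


def subject_estimates(fit: PosteriorFit) -> pd.DataFrame:
    """Per-subject model-space medians and [25, 75] percentiles.

    Transforms are applied draw-wise before summarizing (median of the
    transformed draws, not the transform of the median).  For drug-effect
    models the MPH-session-effective parameters are reported as additional
    "<name> (MPH)" rows.
    """
    rows = []
    for sid in fit.subject_ids:
        full = fit.flat_subject_draws(sid)
        placebo = transform_parameter_draws(full, fit.model, PLACEBO)
        reported: list[tuple[str, np.ndarray]] = [
            (name, placebo[name]) for name, active in _MODEL_SPACE_ROWS if active(fit.model)
        ]
        if fit.model.uses_drug_effects:
            mph = transform_parameter_draws(full, fit.model, MPH)
            if fit.model.pi_mph:
                reported.append(("pi (MPH)", mph["pi"]))
            if fit.model.kappa_mph_sel:
                reported.append(("eps_rewarded_go (MPH)", mph["eps_rewarded_go"]))
                reported.append(("eps_punished_nogo (MPH)", mph["eps_punished_nogo"]))
            if fit.model.kappa_mph_diff:
                reported.append(("eps_diffuse (MPH)", mph["eps_diffuse"]))
        for name, draws in reported:
            q25, med, q75 = np.percentile(draws, [25, 50, 75])
            rows.append(
                {"subject_id": sid, "parameter": name, "median": med, "q25": q25, "q75": q75}
            )
    return pd.DataFrame(rows)


def subject_raw_medians(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior medians of subject-level sampling-space parameters
    (subjects x active parameters); the recovery studies correlate these
    against generative ground truth."""
    med = np.median(
        fit.subject_draws.reshape(-1, len(fit.subject_ids), len(fit.param_names)), axis=0
    )
    frame = pd.DataFrame(med, columns=list(fit.param_names))
    frame.insert(0, "subject_id", fit.subject_ids)
    return frame
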