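"""Synthetic cohorts: simulate subjects performing the task twice.

Each subject completes one placebo and one drug (MPH) session in a
counterbalanced cross-over design, with an independent stimulus set and
pseudorandom cue order per session.  Subject-level parameters are drawn in
sampling space from group normal distributions, and drug-effect parameters
can be coupled to a standard-normal subject covariate (a working-memory-span
stand-in) at a target population correlation.

The default group means are anchored to the fitted group medians of the
winning models on the original study (base parameters from the M4 column of
the base-model table, drug-effect parameters from the M6 column of the
extended-model table), converted to sampling space; group SDs are chosen so
that the model-space inter-quartile ranges approximately match the published
ones (the study reports no sampling-space group SDs).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit

from . import _kernels
from .models import (
    MPH,
    PARAMETER_NAMES,
    PLACEBO,
    ModelSpec,
    RawParameters,
    transform_parameters,
)
from .task import (
    CueSpec,
    DEFAULT_N_REPS,
    DEFAULT_VALIDITY,
    RESPONSES_BY_CODE,
    Response,
    TaskSchedule,
    TrialRecord,
    Valence,
    build_cue_set,
    build_task_schedule,
    trials_to_frame,
)

__all__ = [
    "GroupGenerativeSpec",
    "SyntheticCohort",
    "default_generative_spec",
    "sample_cohort_parameters",
    "simulate_subject_session",
    "simulate_cohort",
]

#: drug-effect parameters that may be coupled to the covariate
COUPLABLE = ("pi_mph", "kappa_mph_sel_raw", "kappa_mph_diff_raw")

# Sampling-space anchors: ln / logit of the published model-space medians.
# rho 32.5, eps0 0.021, b -0.03, pi 0.12 (M4); kappa from
# eps_punished_nogo = invlogit(eps_raw - kappa) = 0.008; pi(MPH) - pi = -0.32
# and eps_diffuse 0.003 (M6).
_DEFAULT_MEANS = {
    "rho_raw": float(np.log(32.5)),
    "eps_raw": float(logit(0.021)),
    "b": -0.03,
    "pi": 0.12,
    "kappa_raw": float(logit(0.021) - logit(0.008)),
    "pi_mph": -0.32,
    "kappa_mph_sel_raw": 0.3,
    "kappa_mph_diff_raw": float(logit(0.003)),
}

# SDs sized so model-space IQRs roughly reproduce the published M4 spreads
# (IQR of a normal = 1.349 sd): rho [14.9, 56.4], eps0 [0.010, 0.063],
# b [-0.29, 0.19], pi [-0.29, 0.70].
_DEFAULT_SDS = {
    "rho_raw": 1.0,
    "eps_raw": 1.35,
    "b": 0.35,
    "pi": 0.7,
    "kappa_raw": 0.5,
    "pi_mph": 0.5,
    "kappa_mph_sel_raw": 0.3,
    "kappa_mph_diff_raw": 0.5,
}


@dataclasses.dataclass(frozen=True)
class GroupGenerativeSpec:
    """Group-level generative distribution for a synthetic cohort.

    ``means``/``sds`` are sampling-space normals per active parameter;
    ``coupling`` maps drug-effect parameter names to the target population
    correlation with the subject covariate.
    """

    means: Mapping[str, float]
    sds: Mapping[str, float]
    coupling: Mapping[str, float] = dataclasses.field(default_factory=dict)
    n_subjects: int = 20
    validity: float = DEFAULT_VALIDITY
    n_reps: int = DEFAULT_N_REPS

    def __post_init__(self):
        for name, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"sd for {name} must be >= 0, got {sd}")
        for name, c in self.coupling.items():
            if name not in COUPLABLE:
                raise ValueError(f"only drug-effect parameters can be coupled, got {name!r}")
            if abs(c) > 1:
                raise ValueError(f"|coupling| must be <= 1, got {c} for {name}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.validity <= 1.0:
            raise ValueError("validity must lie in [0, 1]")


def default_generative_spec(
    model: ModelSpec | str,
    n_subjects: int = 20,
    coupling: Mapping[str, float] | None = None,
    n_reps: int = DEFAULT_N_REPS,
    validity: float = DEFAULT_VALIDITY,
    **overrides: float,
) -> GroupGenerativeSpec:
    """Generative spec with published-median anchors for a model's active
    parameters.  ``overrides`` replace individual means (``pi=0.5``) or SDs
    (``pi_sd=0.0``)."""
    spec = ModelSpec.from_name(model) if isinstance(model, str) else model
    means = {p: _DEFAULT_MEANS[p] for p in spec.active_parameters}
    sds = {p: _DEFAULT_SDS[p] for p in spec.active_parameters}
    for key, value in overrides.items():
        if key.endswith("_sd"):
            name = key[: -len("_sd")]
            target = sds
        else:
            name, target = key, means
        if name not in means:
            raise ValueError(f"{name!r} is not active in model {spec.name}")
        target[name] = float(value)
    return GroupGenerativeSpec(
        means=means,
        sds=sds,
        coupling=dict(coupling or {}),
        n_subjects=n_subjects,
        validity=validity,
        n_reps=n_reps,
    )


def sample_cohort_parameters(
    spec: GroupGenerativeSpec, seed: int | np.random.Generator
) -> tuple[list[RawParameters], np.ndarray]:
    """Draw per-subject sampling-space parameters and the covariate.

    Coupled parameters are built as ``mean + sd * (c*z + sqrt(1-c^2)*e)``
    with covariate ``z`` and independent noise ``e`` both standard normal,
    so the population correlation with the covariate equals ``c``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = spec.n_subjects
    covariate = rng.standard_normal(n)
    columns: dict[str, np.ndarray] = {}
    for name in spec.means:
        noise = rng.standard_normal(n)
        c = spec.coupling.get(name, 0.0)
        unit = c * covariate + np.sqrt(1.0 - c * c) * noise
        columns[name] = spec.means[name] + spec.sds[name] * unit
    params = [
        RawParameters(**{name: float(columns[name][i]) for name in columns})
        for i in range(n)
    ]
    return params, covariate


def simulate_subject_session(
    params: RawParameters,
    model_spec: ModelSpec,
    drug: str,
    schedule: TaskSchedule,
    cues: Sequence[CueSpec],
    rng: np.random.Generator,
    subject_id: int = 0,
) -> list[TrialRecord]:
    """Play one session: sample responses from the model and outcomes from
    the probabilistic feedback rule, learning from the sampled events."""
    p = transform_parameters(params, model_spec, drug)
    by_id = {c.cue_id: c for c in cues}
    cue_ids = sorted(by_id)
    index = {c: i for i, c in enumerate(cue_ids)}
    cue_arr = np.array([index[c] for c in schedule.trials], dtype=np.int64)
    required = np.array(
        [_response_code(by_id[c].required_action) for c in cue_ids], dtype=np.int64
    )
    v = np.array(
        [0.5 if by_id[c].valence is Valence.WIN else -0.5 for c in cue_ids], dtype=float
    )
    n = len(schedule)
    u_resp = rng.random(n)
    u_fb = rng.random(n)
    responses, outcomes, _ = _kernels.simulate_session_kernel(
        cue_arr,
        required,
        v,
        schedule.validity,
        p.rho,
        p.eps0,
        p.eps_rewarded_go,
        p.eps_punished_nogo,
        p.b,
        p.pi,
        p.eps_diffuse,
        p.diffuse_active,
        u_resp,
        u_fb,
    )
    records = []
    for t in range(n):
        cue = by_id[schedule.trials[t]]
        response = RESPONSES_BY_CODE[int(responses[t])]
        records.append(
            TrialRecord(
                subject_id=subject_id,
                session=drug,
                trial_index=t + 1,
                cue_id=cue.cue_id,
                valence=cue.valence,
                required_action=cue.required_action,
                response=response,
                correct=response is cue.required_action,
                outcome=int(outcomes[t]),
            )
        )
    return records


def _response_code(response: Response) -> int:
    return {Response.GO_LEFT: 0, Response.GO_RIGHT: 1, Response.NOGO: 2}[response]


@dataclasses.dataclass(frozen=True)
class SyntheticCohort:
    """A simulated cohort with its ground truth.

    ``trials`` is the long-format trial table over all subjects and both
    sessions; ``true_parameters`` one row per subject (sampling space);
    ``covariate`` the per-subject covariate values.
    """

    trials: pd.DataFrame
    true_parameters: pd.DataFrame
    covariate: pd.Series
    model: str
    seed: int
    validity: float
    n_reps: int

    def save(self, directory: str | pathlib.Path) -> None:
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(directory / "trials.csv", index=False)
        self.true_parameters.to_csv(directory / "true_parameters.csv", index=False)
        self.covariate.rename("covariate").rename_axis("subject_id").reset_index().to_csv(
            directory / "covariate.csv", index=False
        )
        manifest = {
            "model": self.model,
            "seed": self.seed,
            "validity": self.validity,
            "n_reps": self.n_reps,
            "n_subjects": int(self.true_parameters.shape[0]),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | pathlib.Path) -> "SyntheticCohort":
        directory = pathlib.Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        covariate = pd.read_csv(directory / "covariate.csv").set_index("subject_id")[
            "covariate"
        ]
        return cls(
            trials=pd.read_csv(directory / "trials.csv"),
            true_parameters=pd.read_csv(directory / "true_parameters.csv"),
            covariate=covariate,
            model=manifest["model"],
            seed=manifest["seed"],
            validity=manifest["validity"],
            n_reps=manifest["n_reps"],
        )


def simulate_cohort(
    spec: GroupGenerativeSpec,
    model_spec: ModelSpec | str,
    seed: int,
) -> SyntheticCohort:
    """Simulate a full cohort: two sessions per subject, order
    counterbalanced by subject index, independent stimuli per session."""
    model_spec = (
        ModelSpec.from_name(model_spec) if isinstance(model_spec, str) else model_spec
    )
    rng = np.random.default_rng(seed)
    params, covariate = sample_cohort_parameters(spec, rng)
    all_records: list[TrialRecord] = []
    for s, subject_params in enumerate(params):
        order = (PLACEBO, MPH) if s % 2 == 0 else (MPH, PLACEBO)
        for drug in order:
            cues = build_cue_set(rng)
            schedule = build_task_schedule(
                cues, n_reps=spec.n_reps, seed=rng, validity=spec.validity
            )
            all_records.extend(
                simulate_subject_session(
                    subject_params, model_spec, drug, schedule, cues, rng, subject_id=s
                )
            )
    truth = pd.DataFrame(
        [
            {"subject_id": s, **{n: getattr(p, n) for n in PARAMETER_NAMES}}
            for s, p in enumerate(params)
        ]
    )
    return SyntheticCohort(
        trials=trials_to_frame(all_records),
        true_parameters=truth,
        covariate=pd.Series(covariate, index=truth["subject_id"], name="covariate"),
        model=model_spec.name,
        seed=seed,
        validity=spec.validity,
        n_reps=spec.n_reps,
    )
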