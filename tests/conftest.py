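import numpy as np
import pytest

from gonogo import (
    RawParameters,
    Response,
    TrialRecord,
    Valence,
    build_cue_set,
    build_task_schedule,
)
from gonogo.task import RESPONSES_BY_CODE


@pytest.fixture(scope="session")
def cues():
    return build_cue_set(seed=7)


@pytest.fixture(scope="session")
def schedule(cues):
    return build_task_schedule(cues, n_reps=40, seed=7)


@pytest.fixture(scope="session")
def table1_m4_raw():
    """Sampling-space parameters whose model-space transforms match the
    published M4 group medians (rho 32.5, eps0 0.021, eps_punished_nogo
    0.008, b -0.03, pi 0.12)."""
    from scipy.special import logit

    return RawParameters(
        rho_raw=float(np.log(32.5)),
        eps_raw=float(logit(0.021)),
        b=-0.03,
        pi=0.12,
        kappa_raw=float(logit(0.021) - logit(0.008)),
    )


def random_session(rng: np.random.Generator, n_trials: int = 64,
                   subject_id: int = 0, session: str = "placebo") -> list[TrialRecord]:
    """A random but structurally valid single-subject session: 8 cues with
    the crossed design, random responses, outcomes respecting the
    valence-outcome safety rule."""
    cue_valence = {c: (Valence.WIN if c <= 4 else Valence.AVOID) for c in range(1, 9)}
    required = {
        1: Response.GO_LEFT, 2: Response.GO_RIGHT, 3: Response.NOGO, 4: Response.NOGO,
        5: Response.GO_LEFT, 6: Response.GO_RIGHT, 7: Response.NOGO, 8: Response.NOGO,
    }
    records = []
    for t in range(n_trials):
        cue = int(rng.integers(1, 9))
        resp = RESPONSES_BY_CODE[int(rng.integers(0, 3))]
        if cue_valence[cue] is Valence.WIN:
            outcome = int(rng.integers(0, 2))  # {0, +1}
        else:
            outcome = int(rng.integers(-1, 1))  # {-1, 0}
        records.append(
            TrialRecord(
                subject_id=subject_id,
                session=session,
                trial_index=t + 1,
                cue_id=cue,
                valence=cue_valence[cue],
                required_action=required[cue],
                response=resp,
                correct=resp is required[cue],
                outcome=outcome,
            )
        )
    return records


def random_raw(rng: np.random.Generator) -> RawParameters:
    """Random sampling-space parameters over a realistic range."""
    return RawParameters(
        rho_raw=float(rng.normal(2.0, 1.0)),
        eps_raw=float(rng.normal(-2.5, 1.0)),
        b=float(rng.normal(0.0, 0.5)),
        pi=float(rng.normal(0.2, 0.6)),
        kappa_raw=float(rng.normal(0.8, 0.5)),
        pi_mph=float(rng.normal(0.0, 0.5)),
        kappa_mph_sel_raw=float(rng.normal(0.0, 0.4)),
        kappa_mph_diff_raw=float(rng.normal(-3.0, 1.0)),
    )
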