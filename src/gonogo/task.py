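"""Motivational Go/NoGo task construction.

The task presents eight cues, each with an instructed valence (Win cues can
yield reward, Avoid cues can yield punishment) and one correct response out
of three (Go-left, Go-right, NoGo).  Valence is fully crossed with the
required Go/NoGo response (two cues per cell), and among the four Go cues
each valence contributes one Go-left and one Go-right cue, so that no overall
Go tendency is reinforced by the cue set itself.

Feedback is probabilistic: a correct response is followed by the desirable
outcome (reward for Win cues, neutral for Avoid cues) with probability equal
to the feedback validity (0.8 by default), and by the undesirable outcome
otherwise.  Win cues never yield punishment; Avoid cues never yield reward.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Valence",
    "Response",
    "CueSpec",
    "TaskSchedule",
    "TrialRecord",
    "build_cue_set",
    "build_task_schedule",
    "sample_feedback",
    "trials_to_frame",
    "frame_to_trials",
    "DEFAULT_VALIDITY",
    "DEFAULT_N_REPS",
]

DEFAULT_VALIDITY = 0.8
DEFAULT_N_REPS = 40

N_CUES = 8


class Valence(str, enum.Enum):
    WIN = "Win"
    AVOID = "Avoid"


class Response(str, enum.Enum):
    GO_LEFT = "GoLeft"
    GO_RIGHT = "GoRight"
    NOGO = "NoGo"

    @property
    def is_go(self) -> bool:
        return self is not Response.NOGO


#: integer codes used by the array/likelihood layer
RESPONSE_CODES = {Response.GO_LEFT: 0, Response.GO_RIGHT: 1, Response.NOGO: 2}
RESPONSES_BY_CODE = {v: k for k, v in RESPONSE_CODES.items()}


@dataclasses.dataclass(frozen=True)
class CueSpec:
    """One cue: identity, instructed valence, and the correct response."""

    cue_id: int  # 1..8
    valence: Valence
    required_action: Response

    @property
    def is_go_cue(self) -> bool:
        return self.required_action.is_go


@dataclasses.dataclass(frozen=True)
class TaskSchedule:
    """Ordered cue sequence with feedback validity.

    ``trials`` holds cue ids; each cue appears exactly ``n_reps`` times and
    no cue appears three times in a row.
    """

    trials: tuple[int, ...]
    validity: float
    n_reps: int

    def __len__(self) -> int:
        return len(self.trials)


@dataclasses.dataclass(frozen=True)
class TrialRecord:
    """One observed or simulated trial."""

    subject_id: int
    session: str  # "placebo" | "MPH"
    trial_index: int  # 1-based
    cue_id: int
    valence: Valence
    required_action: Response
    response: Response
    correct: bool
    outcome: int  # -1, 0, +1


def build_cue_set(seed: int | np.random.Generator) -> list[CueSpec]:
    """Construct the eight task cues.

    Valence and required Go/NoGo are fully crossed (2 cues per cell); the
    assignment of left vs. right to the two Go cues of each valence is
    randomized by ``seed``.  Cue ids 1..8 index presentation identity only.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cues: list[CueSpec] = []
    cue_id = 1
    for valence in (Valence.WIN, Valence.AVOID):
        go_actions = [Response.GO_LEFT, Response.GO_RIGHT]
        rng.shuffle(go_actions)
        for action in (*go_actions, Response.NOGO, Response.NOGO):
            cues.append(CueSpec(cue_id=cue_id, valence=valence, required_action=action))
            cue_id += 1
    perm = rng.permutation(N_CUES)
    return [
        dataclasses.replace(cues[p], cue_id=i + 1)
        for i, p in enumerate(perm)
    ]


def build_task_schedule(
    cues: Sequence[CueSpec],
    n_reps: int = DEFAULT_N_REPS,
    seed: int | np.random.Generator = 0,
    validity: float = DEFAULT_VALIDITY,
    max_attempts: int = 1000,
) -> TaskSchedule:
    """Pseudorandom cue order: uniform counts, at most one immediate repeat.

    Shuffles the full sequence and repairs triple-runs by rejection, retrying
    up to ``max_attempts`` full shuffles before raising.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0.0 <= validity <= 1.0:
        raise ValueError(f"validity must lie in [0, 1], got {validity}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids = np.repeat([c.cue_id for c in cues], n_reps)
    for _ in range(max_attempts):
        order = rng.permutation(ids)
        if _max_run_length(order) <= 2:
            return TaskSchedule(trials=tuple(int(i) for i in order), validity=validity, n_reps=n_reps)
    raise RuntimeError(
        f"could not build a schedule without triple repeats in {max_attempts} attempts"
    )


def _max_run_length(seq: np.ndarray) -> int:
    if len(seq) == 0:
        return 0
    change = np.flatnonzero(np.diff(seq) != 0)
    bounds = np.concatenate(([-1], change, [len(seq) - 1]))
    return int(np.max(np.diff(bounds)))


def sample_feedback(
    valence: Valence,
    correct: bool,
    validity: float,
    rng: np.random.Generator,
) -> int:
    """Draw one outcome r in {-1, 0, +1}.

    The desirable outcome (+1 for Win, 0 for Avoid) follows a correct
    response with probability ``validity`` and an incorrect response with
    probability ``1 - validity``.
    """
    if not 0.0 <= validity <= 1.0:
        raise ValueError(f"validity must lie in [0, 1], got {validity}")
    p_desirable = validity if correct else 1.0 - validity
    desirable = rng.random() < p_desirable
    if valence is Valence.WIN:
        return 1 if desirable else 0
    return 0 if desirable else -1


# ---------------------------------------------------------------------------
# long-format trial table I/O

TRIAL_COLUMNS = [
    "subject_id",
    "session",
    "trial",
    "cue_id",
    "valence",
    "required_action",
    "response",
    "correct",
    "outcome",
]


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Serialize trial records to the long-format table (one row per trial)."""
    return pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in trials],
            "session": [t.session for t in trials],
            "trial": [t.trial_index for t in trials],
            "cue_id": [t.cue_id for t in trials],
            "valence": [t.valence.value for t in trials],
            "required_action": [t.required_action.value for t in trials],
            "response": [t.response.value for t in trials],
            "correct": [t.correct for t in trials],
            "outcome": [t.outcome for t in trials],
        }
    )


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame`; validates the outcome/valence rules."""
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        valence = Valence(row.valence)
        outcome = int(row.outcome)
        if valence is Valence.WIN and outcome == -1:
            raise ValueError("Win cues cannot yield punishment (r = -1)")
        if valence is Valence.AVOID and outcome == 1:
            raise ValueError("Avoid cues cannot yield reward (r = +1)")
        records.append(
            TrialRecord(
                subject_id=int(row.subject_id),
                session=str(row.session),
                trial_index=int(row.trial),
                cue_id=int(row.cue_id),
                valence=valence,
                required_action=Response(row.required_action),
                response=Response(row.response),
                correct=bool(row.correct),
                outcome=outcome,
            )
        )
    return records
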