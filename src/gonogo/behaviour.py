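"""Descriptive behavioural summaries.

The central quantity is the motivational bias: the excess proportion of Go
responses to Win cues over Avoid cues, p(Go|Win) - p(Go|Avoid).  Summaries
split Go responding into correct and incorrect components (a Go response to
a NoGo cue, or the wrong-sided Go to a Go cue, is incorrect), resolve
p(Go) by cue type and cue repetition, and relate per-subject quantities to
a covariate via Pearson correlation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiasSummary",
    "summarize_pgo",
    "sliding_average",
    "covariate_correlation",
    "drug_effect_summary",
    "plot_go_curves",
]

CUE_TYPES = ("Go-to-Win", "Go-to-Avoid", "NoGo-to-Win", "NoGo-to-Avoid")


@dataclasses.dataclass(frozen=True)
class BiasSummary:
    """Per subject-session aggregates and trial-resolved curves.

    ``aggregate`` columns: subject_id, session, p_go_win, p_go_avoid, bias,
    correct_go_win, incorrect_go_win, correct_go_avoid, incorrect_go_avoid.
    ``curves`` columns: subject_id, session, cue_type, repetition, p_go.
    ``missing_cue_types`` flags any (subject, session) lacking a cue type.
    """

    aggregate: pd.DataFrame
    curves: pd.DataFrame
    missing_cue_types: pd.DataFrame


def _augment(trials: pd.DataFrame) -> pd.DataFrame:
    f = trials.copy()
    f["is_go"] = f["response"].isin(["GoLeft", "GoRight"])
    f["cue_type"] = np.where(f["required_action"].eq("NoGo"), "NoGo-to-", "Go-to-") + f[
        "valence"
    ]
    f["repetition"] = f.groupby(["subject_id", "session", "cue_id"]).cumcount() + 1
    return f


def summarize_pgo(trials: pd.DataFrame) -> BiasSummary:
    """Go-response proportions by valence, their correct/incorrect split,
    and p(Go) curves per cue type and repetition."""
    if trials.empty:
        raise ValueError("empty trial table")
    f = _augment(trials.sort_values(["subject_id", "session", "trial"]))
    grp = f.groupby(["subject_id", "session"])
    rows = []
    for (sid, session), sub in grp:
        win = sub[sub["valence"] == "Win"]
        avoid = sub[sub["valence"] == "Avoid"]
        p_go_win = win["is_go"].mean() if len(win) else np.nan
        p_go_avoid = avoid["is_go"].mean() if len(avoid) else np.nan
        rows.append(
            {
                "subject_id": sid,
                "session": session,
                "p_go_win": p_go_win,
                "p_go_avoid": p_go_avoid,
                "bias": p_go_win - p_go_avoid,
                "correct_go_win": (win["is_go"] & win["correct"]).mean(),
                "incorrect_go_win": (win["is_go"] & ~win["correct"]).mean(),
                "correct_go_avoid": (avoid["is_go"] & avoid["correct"]).mean(),
                "incorrect_go_avoid": (avoid["is_go"] & ~avoid["correct"]).mean(),
            }
        )
    aggregate = pd.DataFrame(rows)
    curves = (
        f.groupby(["subject_id", "session", "cue_type", "repetition"])["is_go"]
        .mean()
        .rename("p_go")
        .reset_index()
    )
    present = f.groupby(["subject_id", "session"])["cue_type"].agg(set)
    missing = [
        {"subject_id": sid, "session": session, "missing": sorted(set(CUE_TYPES) - got)}
        for (sid, session), got in present.items()
        if set(CUE_TYPES) - got
    ]
    return BiasSummary(
        aggregate=aggregate,
        curves=curves,
        missing_cue_types=pd.DataFrame(missing, columns=["subject_id", "session", "missing"]),
    )


def sliding_average(series: Sequence[float], window: int = 5) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges (the first
    and last points average over fewer than ``window`` trials)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    if s.empty:
        raise ValueError("empty series")
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def covariate_correlation(values: Sequence[float], covariate: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided t-distributed p-value."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if len(x) != len(y):
        raise ValueError("values and covariate must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def drug_effect_summary(summary: BiasSummary) -> pd.DataFrame:
    """Per-subject MPH-minus-placebo deltas of the motivational bias and of
    its correct/incorrect Go decomposition, plus cohort means with the
    within-subject standard error of the difference.

    The last row (subject_id = "mean") carries the cohort mean; the
    accompanying ``*_se`` columns hold sd(deltas)/sqrt(n).
    """
    agg = summary.aggregate
    sessions = set(agg["session"].unique())
    if not {"placebo", "MPH"} <= sessions:
        raise ValueError(f"both sessions required, got {sorted(sessions)}")
    wide = agg.pivot(index="subject_id", columns="session")
    deltas = pd.DataFrame(index=wide.index)
    for col in (
        "bias",
        "p_go_win",
        "p_go_avoid",
        "correct_go_win",
        "incorrect_go_win",
        "correct_go_avoid",
        "incorrect_go_avoid",
    ):
        deltas[f"delta_{col}"] = wide[(col, "MPH")] - wide[(col, "placebo")]
    deltas["delta_bias_correct"] = deltas["delta_correct_go_win"] - deltas["delta_correct_go_avoid"]
    deltas["delta_bias_incorrect"] = (
        deltas["delta_incorrect_go_win"] - deltas["delta_incorrect_go_avoid"]
    )
    out = deltas.reset_index()
    n = len(out)
    mean_row = {"subject_id": "mean", **{c: out[c].mean() for c in deltas.columns}}
    se_row = {
        "subject_id": "sed",
        **{c: out[c].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan for c in deltas.columns},
    }
    return pd.concat([out, pd.DataFrame([mean_row, se_row])], ignore_index=True)


def plot_go_curves(curves: pd.DataFrame, ax=None, window: int = 1):
    """Plot mean p(Go) per cue type over cue repetitions (optionally with a
    sliding average)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    styles = {
        "Go-to-Win": ("tab:green", "-"),
        "Go-to-Avoid": ("tab:red", "-"),
        "NoGo-to-Win": ("tab:green", "--"),
        "NoGo-to-Avoid": ("tab:red", "--"),
    }
    mean = curves.groupby(["cue_type", "repetition"])["p_go"].mean().reset_index()
    for cue_type, (color, ls) in styles.items():
        sub = mean[mean["cue_type"] == cue_type].sort_values("repetition")
        if sub.empty:
            continue
        y = sliding_average(sub["p_go"], window) if window > 1 else sub["p_go"].to_numpy()
        ax.plot(sub["repetition"], y, color=color, linestyle=ls, label=cue_type)
    ax.set_xlabel("cue repetition")
    ax.set_ylabel("p(Go)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax
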