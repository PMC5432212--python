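"""Straight-line reference implementation of the choice model.

A deliberately naive, dict-based transcription of the model equations
(softmax choice over action weights, delta-rule updates with the symmetric
learning-rate asymmetry, the drug-session parameter shifts and the diffuse
reward-credit update).  It shares no code with the package and exists only
as an independent oracle for likelihood tests.
"""

import math

GO_RESPONSES = ("GoLeft", "GoRight")
ALL_RESPONSES = ("GoLeft", "GoRight", "NoGo")

_HAS_B = ("M2", "M3a", "M3b", "M4", "M5a", "M5b", "M5c", "M6")
_HAS_PI = ("M3a", "M4", "M5a", "M5b", "M5c", "M6")
_HAS_KAPPA = ("M3b", "M4", "M5a", "M5b", "M5c", "M6")
_HAS_PI_MPH = ("M5a", "M6")
_HAS_K_SEL = ("M5b",)
_HAS_K_DIFF = ("M5c", "M6")


def _invlogit(x):
    return 1.0 / (1.0 + math.exp(-x))


def literal_session_loglik(trials, raw, model, drug):
    """Total log-likelihood of one session.

    ``trials``: list of (cue_id, valence "Win"/"Avoid", response, outcome).
    ``raw``: dict with the eight sampling-space parameters.
    """
    mph = drug == "MPH"
    rho = math.exp(raw["rho_raw"])
    kappa = raw["kappa_raw"] if model in _HAS_KAPPA else 0.0
    if mph and model in _HAS_K_SEL:
        kappa = kappa + raw["kappa_mph_sel_raw"]
    eps0 = _invlogit(raw["eps_raw"])
    eps_punished_nogo = _invlogit(raw["eps_raw"] - kappa)
    eps_rewarded_go = eps0 + (eps0 - eps_punished_nogo)
    eps_rewarded_go = min(max(eps_rewarded_go, 0.0), 1.0)
    b = raw["b"] if model in _HAS_B else 0.0
    pi = raw["pi"] if model in _HAS_PI else 0.0
    if mph and model in _HAS_PI_MPH:
        pi = pi + raw["pi_mph"]
    diffuse = mph and model in _HAS_K_DIFF
    kappa_diffuse = _invlogit(raw["kappa_mph_diff_raw"]) if diffuse else 0.0

    V = {}
    Q = {}
    for cue, valence, _, _ in trials:
        if cue not in V:
            V[cue] = 0.5 if valence == "Win" else -0.5
            for a in ALL_RESPONSES:
                Q[(cue, a)] = rho * V[cue]

    total = 0.0
    for cue, _, resp, r in trials:
        w = {}
        for a in ALL_RESPONSES:
            w[a] = Q[(cue, a)]
            if a in GO_RESPONSES:
                w[a] += pi * V[cue] + b
        denom = sum(math.exp(w[a]) for a in ALL_RESPONSES)
        total += math.log(math.exp(w[resp]) / denom)

        pe = rho * r - Q[(cue, resp)]
        if r == 1 and resp in GO_RESPONSES:
            rate = eps_rewarded_go
            if diffuse:
                rate = min(eps_rewarded_go + kappa_diffuse, 1.0)
                other = "GoRight" if resp == "GoLeft" else "GoLeft"
                Q[(cue, other)] = Q[(cue, other)] + kappa_diffuse * pe
        elif r == -1 and resp == "NoGo":
            rate = eps_punished_nogo
        else:
            rate = eps0
        Q[(cue, resp)] = Q[(cue, resp)] + rate * pe
    return total
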