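"""Numba-compiled inner loops for session likelihood, prediction and
simulation.

All kernels walk one subject-session trial by trial: softmax choice
probabilities from the current action weights, then a delta-rule update of
the chosen action's Q-value (and, when the diffuse mechanism is active and a
Go response was rewarded, a spill-over update of the unchosen Go response
using the chosen action's prediction error).

Inputs are plain arrays: ``cue`` (0-based cue index per trial), ``resp``
(0=GoLeft, 1=GoRight, 2=NoGo), ``outcome`` (-1/0/+1) and ``v`` (Pavlovian
value +-0.5 per cue index).  Parameters are session-effective model-space
scalars (see :func:`gonogo.models.transform_parameters`).
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_ACTIONS = 3


@njit(cache=True)
def _init_q(v, rho):
    n_cues = v.shape[0]
    Q = np.empty((n_cues, N_ACTIONS))
    for c in range(n_cues):
        q0 = rho * v[c]
        for a in range(N_ACTIONS):
            Q[c, a] = q0
    return Q


@njit(cache=True, inline="always")
def _softmax3(w0, w1, w2):
    m = w0
    if w1 > m:
        m = w1
    if w2 > m:
        m = w2
    e0 = np.exp(w0 - m)
    e1 = np.exp(w1 - m)
    e2 = np.exp(w2 - m)
    z = e0 + e1 + e2
    return e0 / z, e1 / z, e2 / z


@njit(cache=True, inline="always")
def _update(Q, c, a, r, rho, eps0, eps_rg, eps_pn, eps_diffuse, diffuse_active):
    pe = rho * r - Q[c, a]
    if r == 1 and a < 2:
        rate = eps_rg
        if diffuse_active:
            rate = rate + eps_diffuse
            if rate > 1.0:
                rate = 1.0
            Q[c, 1 - a] += eps_diffuse * pe
    elif r == -1 and a == 2:
        rate = eps_pn
    else:
        rate = eps0
    Q[c, a] += rate * pe


@njit(cache=True)
def session_loglik_kernel(
    cue, resp, outcome, v, rho, eps0, eps_rg, eps_pn, b, pi, eps_diffuse, diffuse_active
):
    """Per-trial log-probabilities of the observed responses."""
    n = cue.shape[0]
    Q = _init_q(v, rho)
    out = np.empty(n)
    for t in range(n):
        c = cue[t]
        pav = pi * v[c] + b
        p0, p1, p2 = _softmax3(Q[c, 0] + pav, Q[c, 1] + pav, Q[c, 2])
        a = resp[t]
        if a == 0:
            out[t] = np.log(p0)
        elif a == 1:
            out[t] = np.log(p1)
        else:
            out[t] = np.log(p2)
        _update(Q, c, a, outcome[t], rho, eps0, eps_rg, eps_pn, eps_diffuse, diffuse_active)
    return out


@njit(cache=True)
def session_loglik_sum_kernel(
    cue, resp, outcome, v, rho, eps0, eps_rg, eps_pn, b, pi, eps_diffuse, diffuse_active
):
    """Total session log-likelihood (allocation-free MCMC inner loop)."""
    n = cue.shape[0]
    Q = _init_q(v, rho)
    total = 0.0
    for t in range(n):
        c = cue[t]
        pav = pi * v[c] + b
        p0, p1, p2 = _softmax3(Q[c, 0] + pav, Q[c, 1] + pav, Q[c, 2])
        a = resp[t]
        if a == 0:
            total += np.log(p0)
        elif a == 1:
            total += np.log(p1)
        else:
            total += np.log(p2)
        _update(Q, c, a, outcome[t], rho, eps0, eps_rg, eps_pn, eps_diffuse, diffuse_active)
    return total


@njit(cache=True)
def session_probs_kernel(
    cue, resp, outcome, v, rho, eps0, eps_rg, eps_pn, b, pi, eps_diffuse, diffuse_active
):
    """Choice probabilities per trial (n x 3) along the observed history."""
    n = cue.shape[0]
    Q = _init_q(v, rho)
    out = np.empty((n, N_ACTIONS))
    for t in range(n):
        c = cue[t]
        pav = pi * v[c] + b
        p0, p1, p2 = _softmax3(Q[c, 0] + pav, Q[c, 1] + pav, Q[c, 2])
        out[t, 0] = p0
        out[t, 1] = p1
        out[t, 2] = p2
        _update(Q, c, resp[t], outcome[t], rho, eps0, eps_rg, eps_pn, eps_diffuse, diffuse_active)
    return out


@njit(cache=True)
def simulate_session_kernel(
    cue,
    required,
    v,
    validity,
    rho,
    eps0,
    eps_rg,
    eps_pn,
    b,
    pi,
    eps_diffuse,
    diffuse_active,
    u_resp,
    u_fb,
):
    """Generate responses and outcomes along a schedule.

    ``required`` is the correct response code per cue index; ``u_resp`` and
    ``u_fb`` are pre-drawn uniforms (one pair per trial) so the simulation
    is reproducible from the caller's generator.  Returns (responses,
    outcomes, probabilities) with probabilities the model's choice
    probabilities at each trial before the response was drawn.
    """
    n = cue.shape[0]
    Q = _init_q(v, rho)
    responses = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.int64)
    probs = np.empty((n, N_ACTIONS))
    for t in range(n):
        c = cue[t]
        pav = pi * v[c] + b
        p0, p1, p2 = _softmax3(Q[c, 0] + pav, Q[c, 1] + pav, Q[c, 2])
        probs[t, 0] = p0
        probs[t, 1] = p1
        probs[t, 2] = p2
        u = u_resp[t]
        if u < p0:
            a = 0
        elif u < p0 + p1:
            a = 1
        else:
            a = 2
        correct = a == required[c]
        p_desirable = validity if correct else 1.0 - validity
        desirable = u_fb[t] < p_desirable
        if v[c] > 0.0:  # Win cue
            r = 1 if desirable else 0
        else:  # Avoid cue
            r = 0 if desirable else -1
        responses[t] = a
        outcomes[t] = r
        _update(Q, c, a, r, rho, eps0, eps_rg, eps_pn, eps_diffuse, diffuse_active)
    return responses, outcomes, probs
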