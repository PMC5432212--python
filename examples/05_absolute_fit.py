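"""Absolute model fit: one-step-ahead prediction vs. posterior predictive
simulation.

One-step-ahead conditions each trial's predicted choice probabilities on
the subject's actual history; simulation plays the task afresh, sampling
choices and outcomes from the model.  The two coincide without learning and
diverge once learning makes predictions history-dependent.
"""

from gonogo import (
    MODELS,
    RawParameters,
    default_generative_spec,
    one_step_ahead,
    posterior_predictive_simulate,
    simulate_cohort,
)

spec = default_generative_spec("M4", n_subjects=6)
cohort = simulate_cohort(spec, "M4", seed=9)
params = RawParameters(rho_raw=3.0, eps_raw=-3.5, b=-0.03, pi=0.12, kappa_raw=1.0)

osa = one_step_ahead((params, MODELS["M4"]), cohort.trials)
sim = posterior_predictive_simulate((params, MODELS["M4"]), cohort.trials, seed=0)

for pred in (osa, sim):
    curves = pred.go_curves().set_index(["cue_type", "repetition"])["p_go"]
    print(f"\n{pred.method} predictions, p(Go) by cue type:")
    for cue_type in ("Go-to-Win", "Go-to-Avoid", "NoGo-to-Win", "NoGo-to-Avoid"):
        first, last = curves[(cue_type, 1)], curves[(cue_type, 40)]
        print(f"  {cue_type:14s} repetition 1: {first:.3f} -> 40: {last:.3f}")

gap = (osa.frame["p_nogo"] - sim.frame["p_nogo"]).abs().mean()
print(f"\nMean |difference| in p(NoGo) between methods: {gap:.3f}")
print("Both methods show learning (Go cues up, NoGo cues down) and the")
print("Win > Avoid motivational bias; they differ because the simulation")
print("generates its own choice/outcome histories.")
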