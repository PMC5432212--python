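# Methods

This note documents the generative model, the estimation machinery, the
synthetic-data generator and the numerical choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task model

The task presents 8 cues per session; cue valence (Win/Avoid) is fully
crossed with the required response (Go-left, Go-right, NoGo), two cues per
cell, and among Go cues each valence has one left and one right cue so the
cue set cannot reinforce an overall Go tendency. Each cue appears `n_reps`
times (default 40 → 320 trials); the order is a uniform shuffle rejected
until no cue occurs three times in succession (bounded retries, error on
exhaustion). Feedback is probabilistic with validity 0.8: correct responses
are followed by the desirable outcome (+1 for Win, 0 for Avoid) with
probability 0.8, incorrect responses with probability 0.2; Win cues never
yield −1 and Avoid cues never yield +1.

Left/right assignment to specific Go cues is randomized per cue-set seed
(any 2/2 split per valence is valid); the two sessions of a subject use
independent cue sets, and cue identity never transfers across sessions.
Whether cue counts should additionally be balanced within task halves is
unspecified in the source protocol and is not enforced.

## Choice model family

Per cue `s` the learner tracks one Q-value per response option (three per
cue). Action weights add the Pavlovian term and go bias to Go responses
only:

    w(a,s) = Q(a,s) + pi * V(s) + b   (a Go), w(NoGo,s) = Q(NoGo,s)

with fixed cue values V = +0.5 (Win) / −0.5 (Avoid) and initial
Q0 = rho * V, reflecting that valence is instructed, not learned. Choice
probabilities are a softmax over the three weights (max-subtracted).
Updates follow the delta rule Q ← Q + eps * (rho*r − Q), so |Q| ≤ rho
always.

Constrained parameters live in sampling space: rho = exp(rho_raw),
eps = invlogit(eps_raw). The learning-bias asymmetry is constructed
symmetrically in model space:

    eps0 = invlogit(eps_raw)
    eps_punished_nogo = invlogit(eps_raw − kappa)
    eps_rewarded_go = eps0 + (eps0 − eps_punished_nogo)

`eps_rewarded_go` can leave [0,1] for extreme raw values; it is clipped
(with a logged warning on the scalar path). Whether the original fits
clipped this region is unknowable from the protocol; clipping preserves a
valid learning rate and is exercised only in prior tails.

Drug-session mechanisms (sessions are labelled placebo/MPH; placebo always
uses baseline parameters):

* pi_MPH shifts the Pavlovian weight additively under drug (M5a, M6);
* kappa_MPH-selective shifts kappa additively **in sampling space**, i.e.
  before the sigmoid construction, mirroring how the constraint machinery
  is specified (M5b);
* kappa_MPH-diffuse = invlogit(kappa_mph_diff_raw) is a learning rate that
  fires when a Go response is rewarded under drug: the chosen Go's rate
  becomes eps_rewarded_go + eps_diffuse (clipped at 1) and the unchosen Go
  is updated by eps_diffuse times the *chosen* action's prediction error
  (M5c, M6). With eps_diffuse = 0 the update reduces exactly to M4's.

The additive composition for the chosen-Go rate keeps the symmetric
construction intact in the placebo limit; the alternative (folding the
diffuse term into the sigmoid) would change placebo behaviour and break
nesting. Initial Q0 uses the subject's single rho: no model places a drug
effect on rho, so a session-specific rho does not arise.

The family: M1 {rho, eps0}; M2 +b; M3a +pi; M3b +kappa (no pi); M4 +pi
+kappa; M5a/M5b/M5c = M4 + one drug mechanism; M6 = M4 + pi_MPH +
kappa_MPH-diffuse. The composite with pi_MPH and kappa_MPH-selective is
deliberately not implemented. Inactive parameters are pinned at 0 where
they are inert, which makes the nesting chain exact: with extra parameters
zeroed, all models produce identical likelihoods (tested to 1e−10).

## Hierarchical estimation

Subject-level sampling-space parameters are modelled as x_j ~ N(X_j,
sigma_j) per active parameter j, with hyperpriors X_rho ~ N(2,3),
X_eps ~ N(0,2), X_kappa-type ~ N(0,2), X_b ~ N(0,3), X_pi-type ~ N(0,3)
and sigma_j ~ half-Cauchy(2). Each active parameter has its own group SD,
including the drug-effect parameters.

The sampler is adaptive random-walk **Metropolis-within-Gibbs**:

* subject-level: one single-site Metropolis update per parameter per sweep
  (normal proposals; scales adapted in batches of 20 sweeps toward 0.44
  acceptance with a diminishing step, frozen after warmup), plus one joint
  update per subject. Early in warmup the joint update is a directional
  step along the anti-correlated (rho_raw, eps_raw) ridge — the known slow
  direction of this likelihood, since feedback sensitivity and learning
  rate trade off; once enough warmup history exists (10·d draws, collected
  after the first quarter of warmup) it becomes a Haario-style adaptive
  Metropolis step with the empirical per-subject covariance, scale adapted
  toward 0.3 acceptance.
* group means: conjugate normal Gibbs draws.
* group SDs: univariate slice sampling on log sigma (stepping-out), which
  handles the half-Cauchy tail without tuning.

A *centered* parameterization is used: with conjugate group-mean updates
and slice-sampled SDs this is the natural, well-mixing choice for a
Metropolis-within-Gibbs scheme (non-centered parameterizations address a
funnel pathology specific to gradient-based samplers).

One **recorded iteration** comprises `n_sweeps` full sweeps (default 10),
i.e. the chain is internally thinned so the retained draws carry low
autocorrelation; `n_warmup`/`n_samples` count recorded iterations. The
protocol configuration is 4 chains × (200 + 1000) iterations
(`PAPER_MCMC`); the desk-scale default is 2 chains × (200 + 300)
(`REDUCED_MCMC`). Convergence requires rank-normalized split R-hat < 1.1
for every group- and subject-level parameter (computed via arviz; the
classic split variant is available; constant chains return NaN). On
non-convergence both iteration counts are escalated once to 1500; a fit
that still fails is returned flagged (`converged=False`), never silently
dropped or raised.

Chains are initialized overdispersed (group means jittered around prior
centers, subjects around their chain's group means). Per-trial pointwise
log-likelihoods are recorded at every retained iteration for WAIC. All
seeds are explicit; chain seeds are spawned from the configuration seed.

The likelihood inner loops are numba-compiled; a single subject-session
evaluation (320 trials) costs ~10 µs, which is what makes the recovery
studies feasible on one CPU.

## Model comparison and absolute fit

WAIC is computed on the deviance scale, waic = −2 (lppd − p_waic), with
lppd via log-sum-exp over draws and the variance-form penalty
p_waic = Σ_t Var_draws[log p(y_t)] (sample variance, ddof = 1; the arviz
cross-check in the tests accounts for its ddof = 0 convention). Pointwise
contributions sum exactly to the total. WAIC is summed over all subjects'
trials jointly (the standard choice; noted because per-subject averaging
is also seen in the literature). Rankings annotate ΔWAIC with the
conventional evidence bands (2–6 positive, 6–10 strong, >10 very strong);
ties keep input order and are flagged; results from different data
fingerprints refuse to compare.

One-step-ahead prediction replays each subject's actual choices and
outcomes and records the model's per-trial choice probabilities; posterior
predictive simulation plays the task afresh (choices sampled from the
model, outcomes from the feedback rule at the stated validity), reusing
each session's observed cue sequence as the schedule. Both average
probabilities across posterior draws (all retained draws by default,
subsampled evenly when requested). They coincide exactly in the
no-learning limit and diverge under learning, because simulation generates
its own histories.

## Synthetic cohorts

The generator emulates the study structure: each subject completes one
placebo and one drug session (order counterbalanced by subject index),
each with its own stimulus set and schedule. Subject parameters are drawn
from sampling-space normals; a standard-normal covariate (a
working-memory-span stand-in) can be coupled to drug-effect parameters at
a target correlation c via x = mean + sd·(c·z + √(1−c²)·e).

Default group means are the published fitted group medians converted to
sampling space (base parameters from the winning base model: rho 32.5,
eps0 0.021, b −0.03, pi 0.12, kappa from eps_punished_nogo 0.008;
drug-effect anchors from the winning extended model: pi_MPH −0.32,
eps_diffuse 0.003). Group SDs are not published; defaults are sized so the
model-space inter-quartile ranges approximately reproduce the published
spreads under normality (IQR = 1.349 sd), e.g. sd(rho_raw) = 1.0 for the
rho IQR [14.9, 56.4]. The covariate is continuous rather than mimicking
the discrete half-point span scale — only correlation targets matter for
recovery. Dropout, exclusions and physiological measures are not emulated.

What passing recovery tests therefore show: parameters of this model class
are identifiable from cohorts with this structure and realistic parameter
spread, and the fitting/comparison machinery is correct. What they do not
show: that real subjects follow the model, or that real-data fits would
converge equally fast — real data carry sequential dependencies, lapses
and parameter drift the generator deliberately omits.

## Problem sizes

Recovery studies run at deliberate desk scale: parameter recovery uses 20
subjects × 2 sessions × 320 trials with `REDUCED_MCMC`; model-selection
recovery uses 10 cohorts of 12 subjects with a lighter configuration (2
chains, 100 + 150 iterations, 6 sweeps each); covariate-coupling recovery
uses 10 cohorts of 40 subjects (2 chains, 120 + 160, 6 sweeps) — at 20
subjects the realized generative coupling itself is too noisy for a stable
sign across seeds. These
sizes are the package's test defaults; the full protocol configuration
(`PAPER_MCMC`, 99-subject cohorts) is supported through the same API.

## Known limitations

* The sampler is random-walk based; posterior tails mix more slowly than a
  gradient-based sampler would, which the internal thinning compensates at
  desk scale. Very weakly identified parameters (e.g. a near-zero diffuse
  learning rate) can keep R-hat above threshold in small cohorts — such
  fits are flagged, and the escalation rule is the first remedy.
* `eps_rewarded_go` clipping makes the likelihood flat in a region visited
  only for extreme raw values; proposals into deep clipping are effectively
  rejected by the data.
* Reaction times, session-order effects and mixed-effects analyses of raw
  behaviour are out of scope; behavioural summaries are descriptive
  (proportions, paired deltas with within-subject SED, Pearson
  correlations with t-distributed p-values).
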