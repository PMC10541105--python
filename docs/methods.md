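# Methods

## Generative task model

The agent models the task as a partially observable semi-Markov process.
Each hidden state `s` persists for a dwell time `d` drawn from a per-state
discrete distribution `D(d|s)` on a grid of `dt = 0.1 s` steps up to
`d_max = 15 s`, and emits a single observation on entry, drawn from
`O(o|s)`.  Between entries the observation is empty with certainty, so a
non-empty observation always signals a transition into a new state, while
transitions can also occur silently (the entry emission is the empty symbol
with probability 0.05).  Emission rows place 0.95 on the state's
characteristic event, 0.05 on the empty symbol, and a background 1e-4 on
every other symbol, then normalize; the background keeps every observation
possible in every state, which is essential when the *real* event stream
departs from the agent's map (that mismatch is the entire point of the
lesion experiments).

The observation alphabet is {light-on, left-odor, right-odor, well-entry,
reward, light-off, empty}.  A single side-agnostic well-entry symbol marks
arrival at either well and a single reward symbol marks every bolus: the
wells are externally identical, so side and bolus identity are exactly the
hidden information the map must supply.

### Dwell distributions

Dwell kernels are Gaussians with s.d. `cv_d * mean` (`cv_d = 0.05`),
discretized on the grid and mixed with a uniform floor:
`D = d_b + (1 - n*d_b) * q`, `d_b = 1e-4`.  The mixture form keeps every
grid point at or above the floor *and* sums exactly to one, so the convex
dwell-learning update preserves both properties with no repair step.  The
floor is not a numerical nicety: the surviving tail is what keeps a state
hypothesis alive after its expected dwell has elapsed, allowing, e.g., the
well state to reclaim posterior mass when a delayed reward finally arrives,
which is what lets the dwell-learning rule relearn the new delay.

## Filtering

Filtering is exact for the generative model above.  The exit posterior
`alpha_{s,t} = P(s_t = s, transition at t | o_1..o_t)` sums over entry
times back to the most recent non-empty observation (an entry earlier than
that would put a non-empty observation mid-dwell, probability zero), each
term weighted by the entry emission, the dwell probability of the implied
duration, and the recursively computed entry flux `Σ_{s'} T[s'->s]
alpha_{s',k-1}`.  The occupancy belief uses the same recursion with the
dwell density replaced by its inclusive survival function.  The one-step
observation marginal conditions on whether a transition occurs:

    P(o_{t+1}|o_1..o_t) = Σ_s (Σ_{s'} T_{s,s'} O_{s',o_{t+1}}) alpha_{s,t}
                          + 1[o_{t+1} = empty] (1 - Σ_s alpha_{s,t}).

The no-transition branch is the indicator of the empty symbol because
mid-dwell steps emit nothing by construction — under this semantics a
non-empty observation automatically implies a transition (the transition
posterior sums to one there), with no extra assumption needed.  All
quantities propagate in linear space with per-step renormalization by the
one-step marginal; windows between events span at most ~70 steps, so
log-space bookkeeping is unnecessary (trial likelihoods for block inference
*are* accumulated in log space, since they multiply ~100 marginals).

When the time since the last non-empty observation exceeds the dwell grid,
entry hypotheses beyond `d_max` are dropped (mass treated as zero) and a
warning is issued once per trace.  Expected dwell is undefined for states
with zero exit posterior; the sentinel is NaN, and downstream prediction
errors are unaffected because they are gated by the same posterior.

An independent brute-force oracle enumerates every (state sequence, dwell
sequence) hypothesis on small instances and computes the same posteriors by
direct summation; the test suite pins the recursions to it at 1e-8 on 100
randomized instances, and separately checks the ordinary-HMM limit
(point-mass dwells) against a direct HMM forward pass.

## Learning

Prediction errors are vectorized and gated by the transition posterior:

    delta_{s,t} = beta_{s,t} ( g(E[d_{s,t}]) (r_{t+1} + E[V_succ | s, o_{t+1}])
                               - V_s ),        g(d) = exp(-tau d).

`tau = 0.05` per grid step (0.5 s^-1).  The discount is applied as decay;
a configuration flag restores the growth form `exp(+tau d)` for sensitivity
checks, since the two appear interchangeably in the literature this model
family comes from.  The successor value is the `T*O`-weighted average over
successors consistent with the next observation.

Three updates run per step or per event:

* **Values** — `V_s += eta_r * E_s * Σ_s delta_{s,t}` with `eta_r = 0.5`;
  the eligibility trace `E_s = max(gamma E_s, beta_s)` (`gamma = 0.95`)
  is zeroed at each light onset, so credit spreads backward only within a
  trial.  Because every state's value moves with the *total* error, states
  that co-occur in a belief mixture share credit; this cross-talk is a
  real feature of the rule and shapes the lesioned models' residual
  errors (see Limitations).
* **Dwells (Model 1 only)** — at each non-empty observation,
  `D_s += eta_d * beta_s * (K - D_s)` with `eta_d = 0.3`, where `K` is the
  floored Gaussian kernel centred on the time since the previous non-empty
  observation.  Model 2's dwells are fixed (its blocks carry timing in
  separate states) and the updater refuses Model 2 agents.
* **Block transitions (Model 2 only)** — after each trial, the inter-trial
  -> trial-start row moves toward the Bayesian posterior over blocks,
  `T_n += eta_t (L_n T_n / Σ_i L_i T_i - T_n)`, where `L_n` is the
  likelihood of the trial's observation sequence under block n's subgraph
  (product of one-step marginals, accumulated in log space, starting from
  a point-mass entry into the block's trial-start state at light onset).
  `eta_t` has no canonical published value; the default 0.3 matches the
  dwell rate's order of magnitude and is exposed in the configuration.

Total error maps to firing as `3 + 5*delta` Hz for positive and
`3 - 2*|delta|` Hz for negative errors, floored at 0 Hz.  The negative
branch is implemented as suppression: the conversion exists to mirror
dopamine responses, which pause below baseline on omission; a literal
`+ k2*delta` with `k2 = -2` would instead raise firing on negative errors
and is available behind `printed_k2_form` for comparison.  Rates cannot be
negative, hence the 0 Hz floor.

## Task maps and lesions

**Model 1** (flat): trial start, left/right cue, left/right well, two
reward states per side, inter-trial — ten states.  Transitions follow the
trial's physical course; the two branch points that genuinely vary in the
task (which cue, whether a second bolus follows) carry 0.5/0.5.  Initial
dwell means sit at the nominal event latencies (1 s to odor, 1 s to well,
1 s in well/reward states, 4 s inter-trial); results are insensitive to
this initialization, which is why the analysis protocol discards burn-in
sessions.  Initial values are zero.  The lesion sets cue -> same-side well
to 0.55 and cue -> opposite well to 0.45: the agent can no longer carry
side identity across the response, and must lean on observed timing
instead.

**Model 2** (hierarchical): one trial subgraph per block, each encoding
that block's contingencies exactly (deterministic lower-level transitions,
dwells fixed at the task's mean latencies — the long-well dwell uses the
mean of the titrated delay over a block, ≈6.3 s at defaults), under a
shared inter-trial state.  The four block patterns are (left short/right
long), (left long/right short), (left big/right small), (left small/right
big); which physical side plays which role in a session only permutes the
order in which the patterns are visited.  The inter-trial -> trial-start
row starts uniform (0.25 each; initialization is otherwise unconstrained)
and is the only plastic transition.  The hierarchy is encoded as tags on a
single flat index space, so the same filter serves both models.  The lesion
floors every row entry at 0.15 (renormalizing after each update): the agent
can never become confident about the current block, so contingency changes
are absorbed as inferred block shifts instead of prediction errors.  The
lesion transform is idempotent; the floor travels with the space and is
reapplied after every row update.

## Simulation protocol

A run is one agent experiencing 30 sessions (values, dwells and the upper
row persisting across sessions); the first 10 sessions are excluded from
all summaries and results average over 20 independent runs.  Sessions have
four 65-trial blocks.  Free-choice trials are omitted by default (the
scheduler can generate them, in which case they are relabeled toward the
block's higher-valued side before reaching the agent); with choices clamped
to the rewarded well, every forced-long trial counts as a long-side choice
and the long delay ramps deterministically 1, 2, ..., 7 s within each delay
block.  Sides are randomly designated per session from the seeded stream.
One bolus is one reward unit.

Event-aligned analyses tag: the unexpectedly immediate reward after the
block-2 switch (2sh), the omitted reward at the previously learned 0.5 s
latency (2lo, event step = well entry + 0.5 s), the first and second
boluses of block 3 (3bg), the second bolus of block 4 (4bg), and the
omitted second bolus of block 4 (4sm, event step = first bolus + 0.5 s).
Omission steps use the programmed prior-block latency, which coincides with
the learned dwell mode by construction.  High/low cue labels come from the
programmed contingencies, not learned values, so labels are stable.
Windows are the first trial, first 5 and last 5 occurrences of each event
within its block, averaged over post-burn-in sessions and then runs.

Two execution paths produce the same error streams: a pure-Python reference
loop assembled from the module-level operations, and a compiled (numba)
engine used for the full-scale conditions; an equivalence test pins them to
each other at 1e-9 on a complete session for all four model/lesion
combinations.  The full study conditions take roughly three minutes on one
CPU.

## Synthetic unit recordings

Synthetic dopamine units exist so the unit-analysis chain (waveform
classification, responsiveness, difference scores) can be exercised with
known ground truth.  Each unit is assigned one (run, session) of a source
experiment; its rate is baseline x gain except in 400 ms windows starting
100 ms after each tagged event, where it is the error-to-firing map applied
to that event's simulated error, times the unit's gain (lognormal, 20%
s.d.).  Spikes are homogeneous Poisson within segments.  Non-dopaminergic
units fire at a PE-independent 1–10 Hz.  Waveform features (spike half
duration in ms, amplitude ratio) come from two separable Gaussian clusters,
the dopaminergic cluster having the longer half duration.  Each trial's
timeline includes a 1 s pre-light segment so the inter-trial baseline
window is observable.

What the generator does *not* emulate: bursting or any non-Poisson count
statistics, inter-unit correlations, rate drift within a session, spike
sorting artefacts, or any coupling between waveform and firing.  Passing
tests therefore show that the analysis chain recovers the signatures its
estimators target under clean conditions — not that it is robust to the
full noise structure of in-vivo recordings.

## Unit-level statistics

Classification: seeded k-means (k = 2, 10 restarts, standardized features)
gives provisional memberships; each unit is then assigned by the
leave-one-out rule — recompute every cluster's centre and s.d. without the
unit, assign if within 3 s.d. per feature dimension (a Mahalanobis variant
is available) of exactly one centre, otherwise unclassified.
Reward-responsiveness: paired one-sided t-test of per-trial firing in
[reward + 0.1 s, reward + 0.5 s] against a 400 ms baseline, by default the
inter-trial window ending at light onset (a pre-reward variant is
provided, as both anchors appear in common use); responsive iff the mean
increases and p < 0.05.  Difference scores per unit: delivery and omission
scores are early-minus-late mean firing at the tagged events (first/last 5
per relevant block, averaged over blocks), so a fading delivery response is
positive and a recovering omission suppression negative; the cue score is
the late-minus-early growth of the high-minus-low cue contrast.  Population
tests: Wilcoxon signed-rank against zero within a group, rank-sum between
groups.  Firing is spike count over window length; no smoothing.

## Numerical choices and degenerate inputs

Probabilities propagate in linear space with per-step renormalization;
the engine clamps a vanishing one-step marginal at 1e-300 (the reference
path raises an impossible-observation error naming the symbol; with the
emission backgrounds and dwell floors this cannot occur for streams the
simulator produces).  All-zero emission rows, zero block evidence, zero
cluster variance, and windows with too few trials raise typed errors.
Ties in the eligibility max-rule resolve toward the decayed trace (numpy
`maximum` semantics are symmetric; the operands are equal).  State-space
serialization is JSON with full float round-trip.

## Limitations

* The lesioned models' errors are attenuated, not abolished: a residual
  adaptation transient (a few tenths of a PE unit over the first ~5–10
  trials of a changed block) survives, driven by the floored block prior
  and by value cross-talk through the shared-total update.  On synthetic
  populations of 60 units this residual is at the edge of detectability of
  a signed-rank test, so "lesion scores indistinguishable from zero" holds
  in roughly half of seeded replicates rather than uniformly — the
  qualitative control/lesion separation (rank-sum between groups) is
  robust, the strict null on the lesion group is not.
* No choice policy: the agent always takes the rewarded well, free-choice
  trials are relabeled, and behavioral measures (reaction time, accuracy)
  are out of scope.
* The observation function is fixed and known to the agent; only dwells,
  values and the block row are learned.
* Smoothing (backward inference) is not implemented; all quantities are
  filtering quantities.
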