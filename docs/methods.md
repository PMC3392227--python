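# Methods

## The task and the designs

A trial presents a tone pip and an LED flash separated by a stimulus onset
asynchrony τ (ms, positive = light first); the participant reports which came
first. The package generates four schedule families, each defined by an exact
per-block SOA multiset so that schedule moments are algebraic identities, not
sampling approximations:

1. **Blocked bias.** An 11-point, 40-ms grid carries the counts
   (2, 2, 6, 12, 18, 20, 18, 12, 6, 2, 2) per 100-trial block — a discretised
   Gaussian with nominal SD 80 ms (the realised weighted SD is √6464 ≈ 80.4 ms)
   centred on −80 ms (sound first) or +80 ms (light first, the same grid
   shifted +160 ms). One tone pitch per condition.
2. **Mixed bias.** 50 low- and 50 high-tone trials interleaved per block,
   each pitch on its halved biased table, so the block mean SOA is exactly 0.
3. **Mixed unbiased.** Pitch random (exactly 50/50); SOAs from the symmetric
   element-wise sum of the two halved tables on the 15-point −280…+280 grid.
4. **Adaptation/test.** Before each of 16 test pairs (2 pitches × 8 balanced
   SOAs, each once per block), a run of 6, 8 or 10 adaptation stimuli, half at
   −235 ms carrying one pitch and half at +235 ms carrying the other, in
   random order.

Choices the published design descriptions leave open, resolved here: trial
order within a block is a uniform random permutation from a seed; the
adaptation run length is drawn uniformly from {6, 8, 10} per test trial
(balance across blocks is not enforced); inter-stimulus pacing values
(1.2–1.8 s gaps, 0.4–0.7 s warning delay, 0.6–0.9 s test delay) are recorded
as metadata drawn uniformly from their ranges but have no effect on
simulation; pitch-to-bias counterbalancing alternates with the participant
index and is overridable per call.

## The observer model

Each trial passes through a serial pipeline:

1. **Lag adaptation** subtracts an adaptation state `c` (ms) from τ. `c`
   follows an exponential moving average of the stimulus stream,
   `c ← c + α·(τ − c)` with rate `alpha_lag` (default 0.05) — the simplest
   dynamics whose fixed point is the stream mean, which is all the
   steady-state theory constrains. The channel is shared across pitches or
   pitch-specific (`lag_channels`). Adaptation operates on the physical SOA
   by default; a switch (`lag_input="sensed"`) lets it operate on the noisy
   sensed interval instead, since the data do not distinguish the two. Test
   stimuli drive adaptation like adaptation stimuli (they are physically
   alike); `adapt_during_test=False` disables that.
2. **Sensing** adds zero-mean Gaussian noise with SD `sigma_sensed`
   (default 80 ms, the same order as the fitted temporal resolutions and the
   schedule SD, so prior and likelihood carry comparable weight).
3. **Bayesian calibration** combines the sensed value with a conjugate
   Gaussian prior per prior channel (`none` / `shared` / `per_pitch`):
   `t̂ = (σ_sensed²·µ̂ + σ̂²·t_s)/(σ_sensed² + σ̂²)`.
4. **Judgment** is the sign of `t̂`; an exact tie is a fair, seeded coin.

**Prior modes.** The default `oracle` mode fixes each channel's prior to the
steady-state distribution of *sensed post-adjustment* intervals implied by the
schedule: mean = channel mean of (τ − c∞), variance = channel variance of
(τ − c∞) plus σ_sensed², where c∞ is the adaptation fixed point (the channel
stream mean, or the initial `c` when `alpha_lag = 0`). An `online` mode learns
(µ̂, σ̂²) by exponentially weighted moments at `online_rate` for studying
dynamics; steady-state analyses use the oracle.

**Steady state.** Setting the expected posterior to zero gives

    d_u = c − σ_sensed²/(σ_prior² + σ_sensed²) · (µ_prior − c).

The prior variance is σ_prior² + σ_sensed² — the variance of what the
observer can actually learn from noisy samples — which makes this closed form
*exactly* the fixed point of the simulator; the oracle-equivalence tests
exploit that. Both limiting behaviours hold: `c = µ_prior ⇒ d_u = µ_prior`
(full lag adaptation) and `c = 0 ⇒ d_u = −w·µ_prior` (pure Bayesian shift,
opposite in sign to the exposure mean, growing with sensory noise).
`predict_mixed_shifts` evaluates this per tone for the 2×3 table of
{lag pitch-specific?} × {Bayesian absent / shared / pitch-specific}; only
shared lag with pitch-specific priors yields the reversed tone ordering.

## Psychometric fitting

`P(light first | τ) = Φ((τ − d)/σ)`, fitted by maximising the binomial
log-likelihood over d ∈ [−500, 500] ms and σ ∈ [1, 1000] ms. There is no
lapse parameter, matching the 2-parameter model the shift analysis assumes.
Numerics: predicted probabilities are clipped to [1e−9, 1 − 1e−9]; a coarse
25-ms grid over the bounded box seeds the 5 best starts for Nelder-Mead
refinement (function tolerance 1e−8 nats); all-zero or all-one response sets,
and solutions pinned at a σ bound, are flagged degenerate rather than
returned as converged. Tests verify agreement with an exhaustive 0.5-ms grid
search, exact shift/mirror reparameterisation invariances, and estimator bias
below 2 ms at the pooled design size (3,200 trials, 200 replicates). An
optional seeded nonparametric bootstrap (binomial resampling within SOA bins)
provides percentile confidence intervals.

## Group analysis

Per-participant fits populate a shift table. Because pitch-to-bias assignment
is counterbalanced, the analysis recovers each participant's association from
the data (sign of the per-pitch mean adaptation SOA, else mean scheduled SOA;
means within 40 ms of zero — one grid step — carry no association, which
rejects the unbiased design). Conditions are compared with a classical
two-sided paired *t*-test (df = n−1); identical pairwise differences are
flagged degenerate rather than reported as p = 0. The direction label is a
significance-gated sign rule on the mean PSE difference
Δ = d(sound-first tone) − d(light-first tone): `lag_adaptation` if Δ < 0,
`bayesian` if Δ > 0, `null` if the paired test is not significant at α = 0.05
(or |Δ| is below an optional threshold). No multiple-testing correction is
applied across designs.

## What the simulator does and does not emulate

The generator reproduces the designs' trial counts, count tables,
counterbalancing and phase structure exactly, and produces responses from the
observer model above. It does not emulate lapses or response biases, reaction
times, session/day structure, drifting attention, or individual differences
beyond independent RNG streams (all simulated participants share one
parameter set). Passing tests therefore demonstrate internal consistency of
model, fitting and analysis — e.g. that the analysis pipeline recovers the
mechanism signature the generator encodes — not that human observers obey the
model. Published PSEs are accordingly treated as *parameter-recovery* targets:
responses are simulated from the psychometric curve at the pooled published
fits and refitted, rather than reanalysing unavailable raw data.

## Problem sizes

Simulation-backed checks use the pooled design sizes directly (3,200 trials
for a pooled blocked condition; 576 per tone in the adaptation design) with
50-replicate Monte-Carlo averages, and 6–8 replicates of 3,200 trials for the
oracle-equivalence grid; these sizes put Monte-Carlo standard errors on the
PSE near 0.5–2 ms, small against the 47–100 ms effects under test.

## Known limitations

- The adaptation dynamics (EMA) and the online prior-learning rule are
  modelling choices; only their fixed points are constrained by theory.
- `classify_direction` assumes exactly two conditions per participant.
- The oracle prior uses the whole schedule's steady state; very short
  schedules with evolving `c` mix transient and asymptotic behaviour.
- SOAs are integer milliseconds by construction; the fit accepts any real
  bins but the schedule generators stay on the 40-ms lattice.
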