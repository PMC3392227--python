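"""Generative TOJ observer: sensory noise, lag adaptation, Bayesian calibration.

The serial model has two stages.  A *lag adaptation* stage subtracts a slowly
adapting constant ``c`` (ms) from the physical SOA τ, so the most frequent lag
comes to feel simultaneous.  The adjusted interval is then sensed with
Gaussian noise (SD ``sigma_sensed``) and passed to a *Bayesian calibration*
stage that combines the sensed value with a learned prior over sensed
intervals, pulling estimates toward the most frequent order.  Either stage can
be tone-pitch-specific ("channelled") or shared across pitches; which
combination holds is exactly what the mixed-bias designs discriminate.

At steady state the observed point of subjective simultaneity is

    d_u = c - sigma_sensed**2 / (sigma_prior**2 + sigma_sensed**2) * (mu_prior - c)

where ``mu_prior``/``sigma_prior`` are the mean and SD of the true stimulation
interval feeding the adapted channel.  With full adaptation (c = mu_prior) the
prior over adjusted intervals is centred on zero and d_u = mu_prior (pure lag
adaptation); with no adaptation (c = 0) d_u is the pure Bayesian term, opposite
in sign to mu_prior.  The prior's variance is ``sigma_prior**2 +
sigma_sensed**2`` because the observer can only learn the distribution of
*sensed* intervals, which carry the sensory noise; with that convention the
closed form is exactly the fixed point of the trial-level simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .schedules import PITCHES, Block

__all__ = [
    "ObserverParams",
    "ObserverState",
    "SerialModelParams",
    "MixedPrediction",
    "sense_interval",
    "update_lag",
    "update_prior",
    "posterior_estimate",
    "judge",
    "run_experiment",
    "simulate_experiment",
    "steady_state_pse",
    "predict_mixed_shifts",
]

SHARED = "all"


@dataclass(frozen=True)
class ObserverParams:
    """Configuration of the generative observer.

    sigma_sensed : SD (ms) of the sensed interval around the adjusted interval.
    alpha_lag    : per-trial learning rate of the adaptation state c (EMA).
    lag_channels : "shared" (one c for both pitches) or "per_pitch".
    prior_channels : "none" (judge the raw sensed value), "shared", "per_pitch".
    prior_mode   : "oracle" fixes each prior to the schedule's true
                   steady-state sensed distribution; "online" learns it by an
                   exponentially weighted mean/variance at ``online_rate``.
    lag_input    : adapt on the "physical" SOA (default) or the "sensed" one.
    adapt_during_test : whether test stimuli also drive adaptation.
    """

    sigma_sensed: float = 80.0
    alpha_lag: float = 0.05
    lag_channels: Literal["shared", "per_pitch"] = "shared"
    prior_channels: Literal["none", "shared", "per_pitch"] = "per_pitch"
    prior_mode: Literal["oracle", "online"] = "oracle"
    online_rate: float = 0.05
    lag_input: Literal["physical", "sensed"] = "physical"
    adapt_during_test: bool = True

    def __post_init__(self):
        if not (self.sigma_sensed > 0):
            raise ValueError("sigma_sensed must be positive")
        for name in ("alpha_lag", "online_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lag_channels not in ("shared", "per_pitch"):
            raise ValueError("lag_channels must be 'shared' or 'per_pitch'")
        if self.prior_channels not in ("none", "shared", "per_pitch"):
            raise ValueError("prior_channels must be 'none', 'shared' or 'per_pitch'")

    def lag_channel(self, pitch: str) -> str:
        return pitch if self.lag_channels == "per_pitch" else SHARED

    def prior_channel(self, pitch: str) -> str:
        return pitch if self.prior_channels == "per_pitch" else SHARED


@dataclass
class ObserverState:
    """Mutable per-participant state: adaptation c and learned prior moments."""

    c: dict[str, float] = field(default_factory=dict)
    prior_mu: dict[str, float] = field(default_factory=dict)
    prior_var: dict[str, float] = field(default_factory=dict)


def sense_interval(tau: float, c: float, sigma_sensed: float, rng) -> float:
    """Sensed interval: adjusted interval (τ − c) plus Gaussian noise."""
    if not (math.isfinite(tau) and math.isfinite(c)):
        raise ValueError("tau and c must be finite")
    if not (sigma_sensed > 0):
        raise ValueError("sigma_sensed must be positive")
    return float(tau - c + rng.normal(0.0, sigma_sensed))


def update_lag(
    state: ObserverState, tau: float, pitch: str, params: ObserverParams
) -> ObserverState:
    """EMA step of the adaptation state on the selected channel."""
    if pitch not in PITCHES:
        raise ValueError(f"unknown pitch tag {pitch!r}")
    ch = params.lag_channel(pitch)
    c = state.c.get(ch, 0.0)
    state.c[ch] = c + params.alpha_lag * (tau - c)
    return state


def update_prior(
    state: ObserverState, t_s: float, pitch: str, params: ObserverParams
) -> ObserverState:
    """Exponentially weighted update of the learned prior mean/variance.

    A no-op in oracle mode, where priors are fixed analytically before a run.
    """
    if params.prior_channels == "none":
        raise ValueError("no prior channel to update (prior_channels='none')")
    if params.prior_mode == "oracle":
        return state
    if pitch not in PITCHES:
        raise ValueError(f"unknown pitch tag {pitch!r}")
    ch = params.prior_channel(pitch)
    r = params.online_rate
    mu = state.prior_mu.get(ch, 0.0)
    var = state.prior_var.get(ch, params.sigma_sensed**2)
    delta = t_s - mu
    state.prior_mu[ch] = mu + r * delta
    state.prior_var[ch] = max((1.0 - r) * (var + r * delta * delta), 1e-12)
    return state


def posterior_estimate(
    t_s: float, prior_mu: float, prior_var: float, sigma_sensed: float
) -> float:
    """Conjugate-Gaussian posterior mean of the interval given a sensed value."""
    if not (prior_var > 0 and sigma_sensed > 0):
        raise ValueError("variances must be positive")
    s2 = sigma_sensed**2
    return (s2 * prior_mu + prior_var * t_s) / (s2 + prior_var)


def judge(t_hat: float, rng) -> str:
    """Forced-choice order report; an exact tie is resolved by a fair coin."""
    if not math.isfinite(t_hat):
        raise ValueError("estimate must be finite")
    if t_hat > 0:
        return "light_first"
    if t_hat < 0:
        return "sound_first"
    return "light_first" if rng.random() < 0.5 else "sound_first"


# ---------------------------------------------------------------------------
# schedule-level steady state and oracle priors

def _adapting_trials(blocks: Iterable[Block], params: ObserverParams):
    for block in blocks:
        for t in block.trials:
            if t.phase == "test" and not params.adapt_during_test:
                continue
            yield t


def _steady_state_c(
    blocks: Sequence[Block], params: ObserverParams, initial_c: Mapping[str, float]
) -> dict[str, float]:
    """Asymptotic adaptation state: the channel mean of its stimulus stream.

    With a frozen adaptation rate the state never leaves its initial value.
    """
    channels = list(PITCHES) if params.lag_channels == "per_pitch" else [SHARED]
    if params.alpha_lag == 0.0:
        return {ch: initial_c.get(ch, 0.0) for ch in channels}
    sums: dict[str, list[float]] = {ch: [] for ch in channels}
    for t in _adapting_trials(blocks, params):
        sums[params.lag_channel(t.pitch)].append(t.soa)
    return {
        ch: (float(np.mean(v)) if v else initial_c.get(ch, 0.0))
        for ch, v in sums.items()
    }


def _oracle_priors(
    blocks: Sequence[Block], params: ObserverParams, c_ss: Mapping[str, float]
) -> tuple[dict[str, float], dict[str, float]]:
    """True steady-state distribution of sensed (post-adjustment) intervals.

    Mean: channel mean of (τ − c_ss).  Variance: channel variance of the
    adjusted intervals plus the sensory noise variance, since the observer
    learns from noisy sensed values.
    """
    channels = list(PITCHES) if params.prior_channels == "per_pitch" else [SHARED]
    adjusted: dict[str, list[float]] = {ch: [] for ch in channels}
    for block in blocks:
        for t in block.trials:
            adj = t.soa - c_ss[params.lag_channel(t.pitch)]
            adjusted[params.prior_channel(t.pitch)].append(adj)
    mu, var = {}, {}
    for ch, vals in adjusted.items():
        if not vals:
            continue  # channel unused by this schedule; never consulted
        mu[ch] = float(np.mean(vals))
        var[ch] = float(np.var(vals)) + params.sigma_sensed**2
    return mu, var


def _as_channel_map(value, channels: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {ch: float(value.get(ch, 0.0)) for ch in channels}
    return {ch: float(value) for ch in channels}


# ---------------------------------------------------------------------------
# trial-level simulation

def run_experiment(
    blocks: Sequence[Block],
    params: ObserverParams,
    n_participants: int = 1,
    seed=0,
    initial_c: float | Mapping[str, float] | Literal["steady"] = "steady",
    participant_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate observers over a schedule; one trial table row per stimulus.

    Each participant runs an independent RNG substream over the same blocks.
    Adaptation-phase trials update state but carry no response.  ``initial_c``
    is the starting adaptation state per lag channel; the default "steady"
    starts at the schedule's asymptotic state, which is the right choice for
    steady-state analyses (pass 0.0 to model a cold start).
    """
    blocks = list(blocks)
    if not blocks or all(not b.trials for b in blocks):
        raise ValueError("empty schedule")
    if n_participants < 1:
        raise ValueError("need at least one participant")
    lag_channels = list(PITCHES) if params.lag_channels == "per_pitch" else [SHARED]
    if initial_c == "steady":
        c0 = _steady_state_c(blocks, params, {ch: 0.0 for ch in lag_channels})
    else:
        c0 = _as_channel_map(initial_c, lag_channels)

    use_prior = params.prior_channels != "none"
    if use_prior and params.prior_mode == "oracle":
        c_ss = _steady_state_c(blocks, params, c0)
        oracle_mu, oracle_var = _oracle_priors(blocks, params, c_ss)

    if participant_labels is None:
        participant_labels = [f"p{i}" for i in range(n_participants)]
    elif len(participant_labels) != n_participants:
        raise ValueError("participant_labels length must equal n_participants")

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(n_participants)
    rows = []
    for label, ss in zip(participant_labels, streams):
        rng = np.random.default_rng(ss)
        state = ObserverState(c=dict(c0))
        if use_prior and params.prior_mode == "oracle":
            state.prior_mu = dict(oracle_mu)
            state.prior_var = dict(oracle_var)
        for b_idx, block in enumerate(blocks):
            for trial in block.trials:
                ch = params.lag_channel(trial.pitch)
                t_s = sense_interval(
                    trial.soa, state.c.get(ch, 0.0), params.sigma_sensed, rng
                )
                response = None
                if trial.phase == "test":
                    if use_prior:
                        pch = params.prior_channel(trial.pitch)
                        t_hat = posterior_estimate(
                            t_s, state.prior_mu.get(pch, 0.0),
                            state.prior_var.get(pch, params.sigma_sensed**2),
                            params.sigma_sensed,
                        )
                    else:
                        t_hat = t_s
                    response = judge(t_hat, rng)
                if trial.phase == "adaptation" or params.adapt_during_test:
                    lag_sig = trial.soa if params.lag_input == "physical" else t_s
                    update_lag(state, lag_sig, trial.pitch, params)
                if use_prior and params.prior_mode == "online":
                    update_prior(state, t_s, trial.pitch, params)
                rows.append(
                    (label, b_idx, trial.index, trial.phase, trial.pitch,
                     trial.soa, response)
                )
    return pd.DataFrame(
        rows,
        columns=["participant", "block", "trial", "phase", "pitch", "soa_ms",
                 "response"],
    )


def simulate_experiment(
    experiment: int,
    params: ObserverParams | None = None,
    n_participants: int | None = None,
    n_blocks: int | None = None,
    seed=0,
    initial_c="steady",
    **schedule_kwargs,
) -> pd.DataFrame:
    """Simulate a full multi-participant design with default counterbalancing.

    Each participant gets an individually counterbalanced schedule (pitch-bias
    assignment alternates across participants) and an independent RNG stream.
    """
    from .schedules import EXPERIMENT_DEFAULTS, participant_schedule

    if params is None:
        params = ObserverParams()
    if n_participants is None:
        n_participants = EXPERIMENT_DEFAULTS[experiment][0]
    root = np.random.SeedSequence(seed)
    sched_ss, run_ss = root.spawn(2)
    sched_streams = sched_ss.spawn(n_participants)
    run_streams = run_ss.spawn(n_participants)
    frames = []
    for i in range(n_participants):
        blocks = participant_schedule(
            experiment, i, seed=np.random.default_rng(sched_streams[i]),
            n_blocks=n_blocks, **schedule_kwargs,
        )
        frames.append(
            run_experiment(blocks, params, n_participants=1, seed=run_streams[i],
                           initial_c=initial_c, participant_labels=[f"p{i}"])
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# closed-form steady state

@dataclass(frozen=True)
class SerialModelParams:
    """Parameters of the steady-state serial model for one channel.

    mu_prior / sigma_prior: mean and SD (ms) of the true stimulation interval
    feeding the channel; sigma_sensed: sensory noise SD (ms); c: adaptation
    state (ms).
    """

    mu_prior: float
    sigma_prior: float
    sigma_sensed: float
    c: float = 0.0

    def __post_init__(self):
        if not (self.sigma_prior > 0 and self.sigma_sensed > 0):
            raise ValueError("sigma_prior and sigma_sensed must be positive")


def steady_state_pse(p: SerialModelParams) -> float:
    """Observed PSE of the serial model at steady state.

    Interpolates between full Bayesian calibration (c = 0: the PSE is opposite
    in sign to mu_prior) and full lag adaptation (c = mu_prior: the PSE equals
    mu_prior).
    """
    w = p.sigma_sensed**2 / (p.sigma_prior**2 + p.sigma_sensed**2)
    return p.c - w * (p.mu_prior - p.c)


@dataclass(frozen=True)
class MixedPrediction:
    """Per-tone steady-state PSEs in a mixed-bias design and the sign label."""

    d_u: dict[str, float]
    label: Literal["lag_adaptation", "bayesian", "null"]


def predict_mixed_shifts(
    lag_pitch_specific: bool,
    bayes_mode: Literal["none", "shared", "per_pitch"],
    design: Mapping[str, str],
    p: SerialModelParams,
) -> MixedPrediction:
    """Predicted per-tone PSEs for the 2x3 mechanism table of the mixed design.

    Rows: whether lag adaptation distinguishes the pitches.  Columns: whether
    Bayesian calibration is absent, shared across pitches, or pitch-specific.
    ``design`` maps each pitch to its bias; the tone bound to sound-first
    stimuli has channel mean −|mu_prior|, the other +|mu_prior|.  The label
    reports the sign of d_u(sound-first tone) − d_u(light-first tone):
    negative means the lag-adaptation pattern survives, positive means the
    Bayesian reversal, zero means no shift.
    """
    if bayes_mode not in ("none", "shared", "per_pitch"):
        raise ValueError(f"unknown bayes_mode {bayes_mode!r}")
    if set(design) != set(PITCHES) or set(design.values()) != {
        "sound_first", "light_first"
    }:
        raise ValueError("design must map the two pitches onto the two biases")
    mag = abs(p.mu_prior)
    mu_tone = {
        pitch: (-mag if bias == "sound_first" else mag)
        for pitch, bias in design.items()
    }
    d_u = {}
    for pitch in PITCHES:
        c = mu_tone[pitch] if lag_pitch_specific else 0.0
        if bayes_mode == "per_pitch":
            d = steady_state_pse(replace(p, mu_prior=mu_tone[pitch], c=c))
        elif bayes_mode == "shared":
            # pooled prior is centred on the pooled adjusted mean, which is 0
            d = steady_state_pse(replace(p, mu_prior=c, c=c))
        else:
            d = c
        d_u[pitch] = float(d)

    sf = next(p_ for p_, b in design.items() if b == "sound_first")
    lf = next(p_ for p_, b in design.items() if b == "light_first")
    delta = d_u[sf] - d_u[lf]
    label = "null" if delta == 0 else ("lag_adaptation" if delta < 0 else "bayesian")
    return MixedPrediction(d_u=d_u, label=label)
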