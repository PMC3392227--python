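"""Group-level calibration analysis of fitted PSE shifts.

Per-participant psychometric fits are collected into a shift table, the two
pitch/bias conditions are compared with a paired t-test, and the sign of the
mean PSE difference classifies which calibration mechanism the data favour:
``lag_adaptation`` when the PSE of the sound-first-associated condition lies
below that of the light-first one (shifts toward the exposure peak) and
``bayesian`` when the ordering is reversed (shifts away from the peak).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .psychometric import FitConfig, PsychometricFit, bin_responses, fit_psychometric

__all__ = [
    "PairedComparison",
    "shift_table",
    "infer_tone_bias",
    "shift_table_by_bias",
    "paired_t",
    "classify_direction",
    "pooled_fit",
]


@dataclass(frozen=True)
class PairedComparison:
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def shift_table(
    dataset: pd.DataFrame,
    conditions: Mapping[str, Mapping[str, object]],
    config: FitConfig = FitConfig(),
) -> pd.DataFrame:
    """One psychometric fit per participant x condition.

    ``conditions`` maps a condition name to column filters selecting its test
    trials, e.g. ``{"sound_first": {"pitch": "low"}, "light_first":
    {"pitch": "high"}}``.  Every participant must supply every condition.
    """
    if dataset.empty:
        raise ValueError("empty dataset")
    rows = []
    for participant in sorted(dataset["participant"].unique()):
        for cond, sel in conditions.items():
            try:
                binned = bin_responses(dataset, participant=participant, **sel)
            except ValueError as err:
                raise ValueError(
                    f"participant {participant!r} lacks condition {cond!r}"
                ) from err
            fit = fit_psychometric(binned, config)
            rows.append((participant, cond, fit.d, fit.sigma, fit.n_trials,
                         fit.converged))
    return pd.DataFrame(
        rows, columns=["participant", "condition", "d", "sigma", "n_trials",
                       "converged"],
    )


def infer_tone_bias(dataset: pd.DataFrame) -> pd.DataFrame:
    """Recover each participant's pitch-to-bias association from the trials.

    Pitch assignment is counterbalanced across participants, so the
    association must be read off per participant: from the sign of the
    adaptation SOAs when an adaptation phase exists, otherwise from the sign
    of the pitch's mean scheduled SOA.  Unbiased designs, where both means are
    zero, are rejected as carrying no association.
    """
    rows = []
    for participant, grp in dataset.groupby("participant"):
        for pitch, pg in grp.groupby("pitch"):
            adapt = pg[pg["phase"] == "adaptation"]
            mean = adapt["soa_ms"].mean() if len(adapt) else pg["soa_ms"].mean()
            # biased designs put the per-pitch mean at +-80 or +-235 ms;
            # anything inside one grid step of zero carries no association
            if abs(mean) < 40.0:
                raise ValueError(
                    f"participant {participant!r}, pitch {pitch!r}: mean SOA "
                    f"{mean:.1f} ms carries no bias association"
                )
            bias = "sound_first" if mean < 0 else "light_first"
            rows.append((participant, pitch, bias))
    out = pd.DataFrame(rows, columns=["participant", "pitch", "bias"])
    bad = out.groupby("participant")["bias"].nunique()
    if (bad != 2).any():
        raise ValueError("each participant needs one sound-first and one "
                         "light-first pitch")
    return out


def shift_table_by_bias(
    dataset: pd.DataFrame, config: FitConfig = FitConfig()
) -> pd.DataFrame:
    """Shift table with conditions named by the inferred bias association.

    Handles counterbalanced datasets where e.g. the low tone is sound-first
    for half the participants and light-first for the rest.
    """
    assoc = infer_tone_bias(dataset)
    rows = []
    for _, r in assoc.iterrows():
        binned = bin_responses(
            dataset, participant=r["participant"], pitch=r["pitch"]
        )
        fit = fit_psychometric(binned, config)
        rows.append((r["participant"], r["bias"], fit.d, fit.sigma,
                     fit.n_trials, fit.converged))
    return pd.DataFrame(
        rows, columns=["participant", "condition", "d", "sigma", "n_trials",
                       "converged"],
    )


def paired_t(values_a, values_b) -> PairedComparison:
    """Classical paired t-test (two-sided) with condition means and SEMs.

    Identical pairwise differences leave the t statistic undefined; such
    inputs are flagged degenerate instead of reporting p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length samples of at least 2 pairs")
    diff = a - b
    n = len(diff)
    sd = np.std(diff, ddof=1)
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if sd == 0.0:
        return PairedComparison(mean_a, mean_b, _sem(a), _sem(b),
                                t=float("nan"), df=n - 1, p=float("nan"),
                                degenerate=True)
    t = float(np.mean(diff) / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return PairedComparison(mean_a, mean_b, _sem(a), _sem(b), t=t, df=n - 1, p=p)


def classify_direction(
    shift: pd.DataFrame,
    tone_bias: Mapping[str, str] | None = None,
    threshold: float = 0.0,
    alpha: float = 0.05,
) -> str:
    """Label the calibration direction from a two-condition shift table.

    ``tone_bias`` maps each condition name in the table to its associated bias
    ("sound_first"/"light_first").  The per-participant PSE difference
    Δ = d(sound-first condition) − d(light-first condition) is tested with a
    paired t-test; the sign of the mean Δ gives the label only when |mean Δ|
    exceeds ``threshold`` and the test is significant at ``alpha``.
    """
    if tone_bias is None:
        # condition names already are the biases (e.g. from shift_table_by_bias)
        tone_bias = {"sound_first": "sound_first", "light_first": "light_first"}
    if set(tone_bias.values()) != {"sound_first", "light_first"}:
        raise ValueError("tone_bias must assign both biases exactly once")
    by_bias = {bias: cond for cond, bias in tone_bias.items()}
    wide = shift.pivot(index="participant", columns="condition", values="d")
    missing = {c for c in tone_bias if c not in wide.columns}
    if missing or wide.isna().any().any():
        raise ValueError("every participant needs both conditions")
    a = wide[by_bias["sound_first"]].to_numpy()
    b = wide[by_bias["light_first"]].to_numpy()
    cmp = paired_t(a, b)
    delta = float(np.mean(a - b))
    if cmp.degenerate or cmp.p > alpha or abs(delta) <= threshold:
        return "null"
    return "lag_adaptation" if delta < 0 else "bayesian"


def pooled_fit(
    dataset: pd.DataFrame,
    config: FitConfig = FitConfig(),
    **selectors,
) -> PsychometricFit:
    """Single fit over all participants' pooled responses for one condition."""
    return fit_psychometric(bin_responses(dataset, **selectors), config)
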