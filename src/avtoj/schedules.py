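"""Trial schedules for the four biased-stimulation TOJ designs.

An audiovisual temporal-order-judgment (TOJ) trial presents a tone pip and a
light flash separated by a stimulus onset asynchrony (SOA).  Sign convention:
positive SOA means the light onset came first.  The four designs are

1. *Blocked bias*: every block draws its SOAs from a Gaussian-shaped count
   table centred on -80 ms (sound-first) or +80 ms (light-first), one tone
   pitch per condition.
2. *Mixed bias*: 50 low- and 50 high-tone trials interleaved in one block,
   each pitch tied to one of the two biased tables, so the block mean is 0.
3. *Mixed, unbiased*: pitch is random and SOAs come from the symmetric sum of
   the two biased tables on a 15-point grid.
4. *Adaptation/test*: runs of 6-10 adaptation pairs at -235/+235 ms (one
   pitch each) precede single test pairs drawn from a balanced 8-SOA grid.

All randomness is confined to trial ordering (and the adaptation run lengths
of design 4); the SOA multiset of every block is fixed by the printed count
tables, so schedule moments are exact, not approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PITCHES",
    "PITCH_HZ",
    "SOAGrid",
    "CountTable",
    "Trial",
    "Block",
    "schedule_counts",
    "exp1_schedule",
    "exp2_block",
    "exp3_block",
    "exp4_block",
    "participant_schedule",
    "EXPERIMENT_DEFAULTS",
]

PITCHES = ("low", "high")
PITCH_HZ = {"low": 1046, "high": 1480}

BIASES = ("sound_first", "light_first")

#: Presentations per 100-trial block over an 11-point grid; a discretised
#: Gaussian with SD 80 ms centred on the grid's middle value.
CANONICAL_COUNTS = (2, 2, 6, 12, 18, 20, 18, 12, 6, 2, 2)

ADAPT_SOAS = (-235, 235)
ADAPT_RUN_LENGTHS = (6, 8, 10)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SOAGrid:
    """Ordered SOA values (ms, integers) used by one condition."""

    values: tuple[int, ...]

    def __post_init__(self):
        vals = tuple(int(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        # strictly increasing on the 40 ms lattice (design 4 skips lattice points)
        if any(b - a <= 0 or (b - a) % 40 for a, b in zip(vals, vals[1:])):
            raise ValueError("SOA grid must be strictly increasing in 40 ms steps")

    def shifted(self, delta_ms: int) -> "SOAGrid":
        return SOAGrid(tuple(v + delta_ms for v in self.values))


EXP1_SOUND_FIRST_GRID = SOAGrid(tuple(range(-280, 121, 40)))
EXP1_LIGHT_FIRST_GRID = EXP1_SOUND_FIRST_GRID.shifted(160)
EXP3_GRID = SOAGrid(tuple(range(-280, 281, 40)))
EXP4_TEST_GRID = SOAGrid((-280, -200, -120, -40, 40, 120, 200, 280))


@dataclass(frozen=True)
class CountTable:
    """Mapping SOA (ms) -> presentations per block."""

    counts: Mapping[int, int]

    def __post_init__(self):
        frozen = {int(k): int(v) for k, v in sorted(self.counts.items())}
        if any(v < 0 for v in frozen.values()):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", frozen)

    @property
    def soas(self) -> np.ndarray:
        return np.array(sorted(self.counts), dtype=int)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def mean(self) -> float:
        return sum(s * c for s, c in self.counts.items()) / self.total

    @property
    def sd(self) -> float:
        mu = self.mean
        return float(
            np.sqrt(sum(c * (s - mu) ** 2 for s, c in self.counts.items()) / self.total)
        )

    def expand(self) -> np.ndarray:
        """The SOA multiset as a sorted integer array of length ``total``."""
        return np.repeat(self.soas, [self.counts[s] for s in sorted(self.counts)])

    def halved(self) -> "CountTable":
        if any(v % 2 for v in self.counts.values()):
            raise ValueError("cannot halve odd counts")
        return CountTable({s: c // 2 for s, c in self.counts.items()})


@dataclass(frozen=True)
class Trial:
    """One scheduled stimulus pair.

    ``gap_s``, ``warn_delay_s`` and ``test_delay_s`` are pacing metadata
    (seconds) recorded for design 4; they do not influence simulation.
    """

    index: int
    soa: int
    pitch: str
    phase: str = "test"
    gap_s: float | None = None
    warn_delay_s: float | None = None
    test_delay_s: float | None = None

    def __post_init__(self):
        if self.pitch not in PITCHES:
            raise ValueError(f"unknown pitch tag {self.pitch!r}")
        if self.phase not in ("test", "adaptation"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase == "adaptation" and self.soa not in ADAPT_SOAS:
            raise ValueError("adaptation SOA must be -235 or +235 ms")


@dataclass(frozen=True)
class Block:
    trials: tuple[Trial, ...]
    experiment: int
    condition: str
    tags: Mapping[str, object] = field(default_factory=dict)

    @property
    def test_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.phase == "test")

    def soa_multiset(self, phase: str = "test") -> dict[int, int]:
        out: dict[int, int] = {}
        for t in self.trials:
            if t.phase == phase:
                out[t.soa] = out.get(t.soa, 0) + 1
        return out


def _grid_for(condition: str) -> SOAGrid:
    if condition == "sound_first":
        return EXP1_SOUND_FIRST_GRID
    if condition == "light_first":
        return EXP1_LIGHT_FIRST_GRID
    raise ValueError(f"unknown condition {condition!r}")


def schedule_counts(experiment: int, condition: str | None = None) -> CountTable:
    """Canonical per-block count table for a design.

    ``condition`` is ``sound_first``/``light_first`` for designs 1 and 2 (the
    per-tone half table in design 2) and ignored for designs 3 and 4.
    """
    if experiment == 1:
        grid = _grid_for(condition)
        return CountTable(dict(zip(grid.values, CANONICAL_COUNTS)))
    if experiment == 2:
        return schedule_counts(1, condition).halved()
    if experiment == 3:
        combined: dict[int, int] = {s: 0 for s in EXP3_GRID.values}
        for bias in BIASES:
            for s, c in schedule_counts(2, bias).counts.items():
                combined[s] += c
        return CountTable(combined)
    if experiment == 4:
        return CountTable({s: 1 for s in EXP4_TEST_GRID.values})
    raise ValueError(f"unknown experiment {experiment!r}")


def _shuffled_trials(soas: np.ndarray, pitches: Sequence[str], rng) -> tuple[Trial, ...]:
    order = rng.permutation(len(soas))
    return tuple(
        Trial(index=i, soa=int(soas[j]), pitch=pitches[j]) for i, j in enumerate(order)
    )


def exp1_schedule(
    condition: str, pitch: str, n_blocks: int, seed=0
) -> list[Block]:
    """Blocked-bias design: ``n_blocks`` 100-trial single-pitch blocks."""
    if pitch not in PITCHES:
        raise ValueError(f"unknown pitch tag {pitch!r}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = _rng(seed)
    table = schedule_counts(1, condition)
    soas = table.expand()
    blocks = []
    for _ in range(n_blocks):
        trials = _shuffled_trials(soas, [pitch] * len(soas), rng)
        blocks.append(
            Block(trials=trials, experiment=1, condition=condition,
                  tags={"pitch": pitch})
        )
    return blocks


def _check_bias_map(bias_of_pitch: Mapping[str, str]) -> None:
    if set(bias_of_pitch) != set(PITCHES):
        raise ValueError("bias map must assign both pitches")
    if set(bias_of_pitch.values()) != set(BIASES):
        raise ValueError("the two pitches must carry the two distinct biases")


def exp2_block(bias_of_pitch: Mapping[str, str], seed=0) -> Block:
    """Mixed-bias design: 50 trials per pitch, each pitch on its biased half table."""
    _check_bias_map(bias_of_pitch)
    rng = _rng(seed)
    soas_list: list[int] = []
    pitches: list[str] = []
    for pitch in PITCHES:
        half = schedule_counts(2, bias_of_pitch[pitch])
        soas_list.extend(half.expand().tolist())
        pitches.extend([pitch] * half.total)
    trials = _shuffled_trials(np.array(soas_list), pitches, rng)
    return Block(trials=trials, experiment=2, condition="mixed",
                 tags={"bias_of_pitch": dict(bias_of_pitch)})


def exp3_block(seed=0) -> Block:
    """Mixed unbiased design: symmetric combined table, random 50/50 pitch."""
    rng = _rng(seed)
    soas = schedule_counts(3).expand()
    pitches = ["low"] * 50 + ["high"] * 50
    rng.shuffle(pitches)
    trials = _shuffled_trials(soas, pitches, rng)
    return Block(trials=trials, experiment=3, condition="unbiased", tags={})


def exp4_block(adapt_pitch_map: Mapping[str, int], seed=0) -> Block:
    """Adaptation/test design: 16 test pairs, each preceded by a 6/8/10 run.

    ``adapt_pitch_map`` assigns one pitch to the -235 ms adaptation SOA and the
    other to +235 ms.  Every adaptation run holds equal numbers of both.
    """
    if set(adapt_pitch_map) != set(PITCHES) or set(
        adapt_pitch_map.values()
    ) != set(ADAPT_SOAS):
        raise ValueError("adapt map must pair the two pitches with -235 and +235 ms")
    rng = _rng(seed)
    pitch_of_soa = {v: k for k, v in adapt_pitch_map.items()}
    test_pairs = [(s, p) for s in EXP4_TEST_GRID.values for p in PITCHES]
    order = rng.permutation(len(test_pairs))

    trials: list[Trial] = []
    idx = 0
    for j in order:
        n_adapt = int(rng.choice(ADAPT_RUN_LENGTHS))
        run = [-235] * (n_adapt // 2) + [235] * (n_adapt // 2)
        rng.shuffle(run)
        for soa in run:
            trials.append(
                Trial(index=idx, soa=soa, pitch=pitch_of_soa[soa],
                      phase="adaptation", gap_s=float(rng.uniform(1.2, 1.8)))
            )
            idx += 1
        soa, pitch = test_pairs[j]
        trials.append(
            Trial(index=idx, soa=soa, pitch=pitch, phase="test",
                  warn_delay_s=float(rng.uniform(0.4, 0.7)),
                  test_delay_s=float(rng.uniform(0.6, 0.9)))
        )
        idx += 1
    return Block(trials=tuple(trials), experiment=4, condition="adapt_test",
                 tags={"adapt_pitch_map": dict(adapt_pitch_map)})


#: (participants, blocks) the study ran per design.
EXPERIMENT_DEFAULTS = {1: (8, 8), 2: (8, 24), 3: (8, 24), 4: (6, 12)}


def participant_schedule(
    experiment: int,
    participant: int,
    seed=0,
    n_blocks: int | None = None,
    bias_of_pitch: Mapping[str, str] | None = None,
    adapt_pitch_map: Mapping[str, int] | None = None,
) -> list[Block]:
    """Assemble one participant's block list with default counterbalancing.

    Pitch-to-bias assignment and (in design 1) condition order alternate with
    the participant index, mirroring counterbalancing across participants.
    """
    rng = _rng(seed)
    if n_blocks is None:
        n_blocks = EXPERIMENT_DEFAULTS[experiment][1]
    flip = participant % 2 == 1
    if experiment == 1:
        if n_blocks % 2:
            raise ValueError("design 1 needs an even block count (half per condition)")
        # pitch assignment alternates with participant parity; condition order
        # alternates with the participant pair index
        pitch_of = {"sound_first": "low", "light_first": "high"}
        if flip:
            pitch_of = {"sound_first": "high", "light_first": "low"}
        conditions = ["sound_first", "light_first"]
        if (participant // 2) % 2 == 1:
            conditions.reverse()
        blocks: list[Block] = []
        for cond in conditions:
            blocks.extend(exp1_schedule(cond, pitch_of[cond], n_blocks // 2, rng))
        return blocks
    if experiment == 2:
        if bias_of_pitch is None:
            bias_of_pitch = (
                {"low": "light_first", "high": "sound_first"}
                if flip
                else {"low": "sound_first", "high": "light_first"}
            )
        return [exp2_block(bias_of_pitch, rng) for _ in range(n_blocks)]
    if experiment == 3:
        return [exp3_block(rng) for _ in range(n_blocks)]
    if experiment == 4:
        if adapt_pitch_map is None:
            adapt_pitch_map = (
                {"low": -235, "high": 235} if flip else {"high": -235, "low": 235}
            )
        return [exp4_block(adapt_pitch_map, rng) for _ in range(n_blocks)]
    raise ValueError(f"unknown experiment {experiment!r}")
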