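"""Trial-table CSV and flat key-value configuration files.

The trial CSV is the package's single on-disk data format: one row per
scheduled stimulus, columns ``participant, block, trial, phase, pitch,
soa_ms, response``.  The response cell is empty exactly on adaptation rows.
A leading comment line carries the schema version so that readers can reject
files written under a different layout loudly instead of misparsing them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .observer import ObserverParams

__all__ = ["SCHEMA", "read_trials", "write_trials", "read_config", "write_config",
           "RunConfig"]

SCHEMA = "avtoj.trials.v1"
COLUMNS = ["participant", "block", "trial", "phase", "pitch", "soa_ms", "response"]
_PHASES = {"test", "adaptation"}
_PITCHES = {"low", "high"}
_RESPONSES = {"light_first", "sound_first"}


def write_trials(dataset: pd.DataFrame, path) -> None:
    """Write a trial table deterministically (sorted, LF, UTF-8)."""
    missing = [c for c in COLUMNS if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset lacks columns {missing}")
    df = dataset[COLUMNS].sort_values(["participant", "block", "trial"])
    df = df.copy()
    df["response"] = df["response"].fillna("")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# schema: {SCHEMA}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_trials(path) -> pd.DataFrame:
    """Read and strictly validate a trial CSV; errors name the offending line."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    offset = 0
    if first.startswith("#"):
        offset = 1
        declared = first.split("schema:")[-1].strip() if "schema:" in first else first
        if declared != SCHEMA:
            raise ValueError(f"unknown trial-CSV schema {declared!r}")
    df = pd.read_csv(path, skiprows=offset, dtype=str, keep_default_na=False)
    if list(df.columns) != COLUMNS:
        raise ValueError(
            f"unexpected columns {list(df.columns)}; expected {COLUMNS}"
        )
    # first data row sits after the optional comment line and the header
    for i, row in df.iterrows():
        line = offset + 2 + i
        if row["phase"] not in _PHASES:
            raise ValueError(f"line {line}: bad phase {row['phase']!r}")
        if row["pitch"] not in _PITCHES:
            raise ValueError(f"line {line}: bad pitch {row['pitch']!r}")
        try:
            int(row["soa_ms"]), int(row["block"]), int(row["trial"])
        except ValueError:
            raise ValueError(f"line {line}: non-integer block/trial/soa_ms") from None
        resp = row["response"]
        if row["phase"] == "adaptation" and resp != "":
            raise ValueError(f"line {line}: adaptation row carries a response")
        if row["phase"] == "test" and resp not in _RESPONSES:
            raise ValueError(f"line {line}: bad response {resp!r}")
    out = df.copy()
    for col in ("block", "trial", "soa_ms"):
        out[col] = out[col].astype(int)
    out["response"] = out["response"].replace({"": None})
    return out


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything a simulate run needs; round-trips through a flat text file."""

    experiment: int
    seed: int
    participants: int | None = None
    blocks: int | None = None
    observer: ObserverParams = ObserverParams()

    def as_flat(self) -> dict[str, str]:
        flat = {
            "experiment": str(self.experiment),
            "seed": str(self.seed),
        }
        if self.participants is not None:
            flat["participants"] = str(self.participants)
        if self.blocks is not None:
            flat["blocks"] = str(self.blocks)
        for f in dataclasses.fields(ObserverParams):
            flat[f"observer.{f.name}"] = str(getattr(self.observer, f.name))
        return flat


def write_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in config.as_flat().items():
            fh.write(f"{key} = {val}\n")


def _parse(text: str, typ):
    if typ is bool:
        return text == "True"
    return typ(text)


def read_config(path) -> RunConfig:
    flat: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            flat[key.strip()] = val.strip()
    obs_kwargs = {}
    for f in dataclasses.fields(ObserverParams):
        key = f"observer.{f.name}"
        if key in flat:
            typ = {"sigma_sensed": float, "alpha_lag": float, "online_rate": float,
                   "adapt_during_test": bool}.get(f.name, str)
            obs_kwargs[f.name] = _parse(flat.pop(key), typ)
    known = {"experiment", "seed", "participants", "blocks"}
    unknown = set(flat) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    if "experiment" not in flat or "seed" not in flat:
        raise ValueError("config must set experiment and seed")
    return RunConfig(
        experiment=int(flat["experiment"]),
        seed=int(flat["seed"]),
        participants=int(flat["participants"]) if "participants" in flat else None,
        blocks=int(flat["blocks"]) if "blocks" in flat else None,
        observer=ObserverParams(**obs_kwargs),
    )
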