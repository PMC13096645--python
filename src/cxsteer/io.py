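"""File formats and configuration.

Traces and paths are plain delimited text (CSV) with a header row naming the
columns (``time, omega`` or ``time, x, y``, any order) and ``#`` comment
lines.  Values round-trip at full float precision.  The run configuration is
a single YAML file with one block per module; unknown keys are rejected so
typos fail loudly, and every run echoes its resolved configuration for
provenance.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agent_loop import TrialConfig
from .circuit_core import CircuitConfig
from .experiments import SweepSpec
from .mb_input import FamiliarityConfig
from .path_metrics import OmegaTrace, PathTable
from .synthetic_behaviour import TrackballSpec

_FLOAT_FMT = "%.17g"  # lossless for float64


class FormatError(ValueError):
    """Malformed data file (missing column, bad cell, non-monotone time...)."""


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as delimited text: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    out = {}
    for col in required:
        cells = df[col].tolist()
        values = np.empty(len(cells))
        for row, cell in enumerate(cells):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise FormatError(f"{path}: empty cell in column '{col}', data row {row + 1}")
            try:
                # Python's parser is correctly rounded, so 17-significant-digit
                # text round-trips float64 exactly
                values[row] = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric cell in column '{col}', data row {row + 1} "
                    f"(value {cell!r})"
                ) from exc
        out[col] = values
    return pd.DataFrame(out)


def read_trace(path) -> OmegaTrace:
    """Read a (time, omega) angular-velocity trace from delimited text."""
    df = _read_table(path, ("time", "omega"))
    try:
        return OmegaTrace(time=df["time"].to_numpy(), omega=df["omega"].to_numpy())
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_trace(trace: OmegaTrace, path) -> None:
    pd.DataFrame({"time": trace.time, "omega": trace.omega}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_path(path) -> PathTable:
    """Read a (time, x, y) trajectory from delimited text."""
    df = _read_table(path, ("time", "x", "y"))
    try:
        return PathTable(
            time=df["time"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy()
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_path(table: PathTable, path) -> None:
    pd.DataFrame({"time": table.time, "x": table.x, "y": table.y}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# run configuration

_BLOCKS = {
    "circuit": CircuitConfig,
    "familiarity": FamiliarityConfig,
    "trial": TrialConfig,
    "sweep": SweepSpec,
    "synth": TrackballSpec,
}
_TOP_KEYS = set(_BLOCKS) | {"seed", "outdir", "log_level", "rotation"}

# rotation block feeds sun_rotation_experiment keyword arguments
_ROTATION_KEYS = {
    "n_agents",
    "rotation_deg",
    "rotation_step",
    "segment_stride",
    "n_steps",
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for one run."""

    circuit: CircuitConfig
    familiarity: FamiliarityConfig
    trial: TrialConfig
    sweep: SweepSpec
    synth: TrackballSpec
    rotation: dict
    seed: int = 0
    outdir: str = "runs"
    log_level: str = "INFO"


def _build_block(cls, mapping: dict, block: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - field_names
    if unknown:
        raise FormatError(f"unknown key(s) {sorted(unknown)} in config block '{block}'")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return cls(**coerced)


def load_config(path=None, text: str | None = None) -> RunConfig:
    """Load and validate a YAML run configuration; absent blocks use defaults."""
    if text is None:
        text = Path(path).read_text()
    raw = yaml.safe_load(_io.StringIO(text)) or {}
    if not isinstance(raw, dict):
        raise FormatError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise FormatError(f"unknown top-level config key(s) {sorted(unknown)}")
    blocks = {
        name: _build_block(cls, raw.get(name, {}) or {}, name)
        for name, cls in _BLOCKS.items()
    }
    rotation = raw.get("rotation", {}) or {}
    bad = set(rotation) - _ROTATION_KEYS
    if bad:
        raise FormatError(f"unknown key(s) {sorted(bad)} in config block 'rotation'")
    return RunConfig(
        rotation=rotation,
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "runs")),
        log_level=str(raw.get("log_level", "INFO")),
        **blocks,
    )


def dump_config(cfg: RunConfig, path) -> None:
    """Echo the resolved configuration (for provenance of every run)."""
    payload = {
        name: dataclasses.asdict(getattr(cfg, name)) for name in _BLOCKS
    }
    for block in payload.values():
        for k, v in block.items():
            if isinstance(v, tuple):
                block[k] = list(v)
    payload["rotation"] = dict(cfg.rotation)
    payload.update(seed=cfg.seed, outdir=str(cfg.outdir), log_level=cfg.log_level)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
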