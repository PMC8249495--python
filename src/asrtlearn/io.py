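"""Trial-log CSV schema, validation, run configuration, and stats reports.

The trial log is a tidy UTF-8 CSV with a mandatory header and one row per key
press::

    subject_id,experiment_id,session,block,trial,role,position,correct,rt_ms

``position`` is 1..4 (empty only in unfilled design exports), ``correct`` is
0/1 (empty before simulation), ``rt_ms`` a positive real in milliseconds
(empty before simulation).  Rows are sorted by (subject_id, session, block,
trial).  Labeled logs append ``category`` and ``exclusion_reason`` columns
(plus the stream-audit column ``triplet_high``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import PatternSpec
from .simulate import RTModelParams

__all__ = [
    "SCHEMA_COLUMNS",
    "LABELED_COLUMNS",
    "TrialLogError",
    "read_trial_log",
    "write_trial_log",
    "read_labeled_log",
    "write_labeled_log",
    "RunConfig",
    "load_config",
    "write_stats_report",
]

SCHEMA_COLUMNS = [
    "subject_id", "experiment_id", "session", "block", "trial",
    "role", "position", "correct", "rt_ms",
]
LABELED_COLUMNS = SCHEMA_COLUMNS + ["category", "exclusion_reason", "triplet_high"]

_ROLES = {"pattern", "random_fill", "warmup", "random_block"}


class TrialLogError(ValueError):
    """Format, validation or sequencing error in a trial-log CSV."""

    def __init__(self, message: str, violations: list[str] | None = None):
        self.violations = violations or []
        if self.violations:
            shown = "; ".join(self.violations[:10])
            more = f" (+{len(self.violations) - 10} more)" if len(self.violations) > 10 else ""
            message = f"{message}: {shown}{more}"
        super().__init__(message)


def _validate(df: pd.DataFrame, path: Path) -> list[str]:
    """Row-level violations with CSV line numbers (header is line 1)."""
    line = df.index.to_numpy() + 2
    problems: list[str] = []

    def flag(bad: np.ndarray, message: str) -> None:
        for ln in line[bad][:25]:
            problems.append(f"line {ln}: {message}")

    for col in ("subject_id", "experiment_id", "session", "block", "trial"):
        bad = df[col].isna().to_numpy()
        flag(bad, f"missing {col}")
    flag((~df["role"].isin(_ROLES)).to_numpy(), "unknown role")
    pos = df["position"]
    flag((pos.notna() & ~pos.isin([1.0, 2.0, 3.0, 4.0])).to_numpy(),
         "position outside 1..4")
    rt = df["rt_ms"]
    flag((rt.notna() & (rt <= 0)).to_numpy(), "rt_ms must be > 0")
    corr = df["correct"]
    flag((corr.notna() & ~corr.isin([0.0, 1.0])).to_numpy(), "correct must be 0 or 1")
    return problems


def _check_sorted_rows(df: pd.DataFrame) -> None:
    keys = df[["subject_id", "session", "block", "trial"]].apply(
        pd.to_numeric, errors="coerce"
    )
    if keys.isna().any().any():
        return  # row-level validation already reports these
    arr = keys.to_numpy()
    order = np.lexsort(arr.T[::-1])
    if not np.array_equal(order, np.arange(len(arr))):
        raise TrialLogError(
            "rows are not sorted by (subject_id, session, block, trial)"
        )


def _read(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TrialLogError(f"no such file: {path}")
    df = pd.read_csv(path)
    if list(df.columns) != columns:
        raise TrialLogError(
            f"malformed header in {path}: expected {columns}, got {list(df.columns)}"
        )
    if df.empty:
        return df
    problems = _validate(df, path)
    if problems:
        raise TrialLogError(f"invalid trial log {path}", problems)
    _check_sorted_rows(df)
    for col in ("subject_id", "experiment_id", "session", "block", "trial"):
        df[col] = df[col].astype(np.int64)
    return df


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-log CSV (raises :class:`TrialLogError`)."""
    return _read(path, SCHEMA_COLUMNS)


def read_labeled_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a labeled trial-log CSV."""
    return _read(path, LABELED_COLUMNS)


def _format_for_csv(trials: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = trials[columns].copy()
    for col in ("position", "correct"):
        if col in out:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    return out


def write_trial_log(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial log in the canonical CSV schema (missing values empty)."""
    _format_for_csv(trials, SCHEMA_COLUMNS).to_csv(path, index=False)


def write_labeled_log(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled trial log (schema + category/exclusion columns)."""
    _format_for_csv(trials, LABELED_COLUMNS).to_csv(path, index=False)


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (YAML/JSON); unknown keys rejected."""

    experiment_id: int
    seed: int
    subjects: int = 25
    pattern: str | list[int] = "auto"
    block_filter: str = "all_blocks"
    min_trials: int = 1
    random_gap_policy: str = "exclude"
    rt_model: RTModelParams = dataclasses.field(default_factory=RTModelParams)

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2, 3):
            raise ValueError(f"experiment_id must be 1, 2 or 3, got {self.experiment_id}")
        if self.seed is None:
            raise ValueError("seed is mandatory for any simulation command")
        if self.block_filter not in ("all_blocks", "first_blocks_of_sessions"):
            raise ValueError(f"unknown block_filter {self.block_filter!r}")
        if self.random_gap_policy not in ("exclude", "bridge"):
            raise ValueError(f"unknown random_gap_policy {self.random_gap_policy!r}")

    def pattern_spec(self) -> PatternSpec | None:
        if self.pattern == "auto":
            return None
        return PatternSpec(tuple(int(p) for p in self.pattern))


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration, rejecting unknown keys."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    rt_raw = raw.pop("rt_model", {})
    rt_known = {f.name for f in dataclasses.fields(RTModelParams)}
    rt_unknown = set(rt_raw) - rt_known
    if rt_unknown:
        raise ValueError(f"unknown rt_model keys: {sorted(rt_unknown)}")
    if "seed" not in rt_raw and "seed" in raw:
        rt_raw = {**rt_raw, "seed": raw["seed"]}
    params = RTModelParams(**rt_raw)
    params.validate()
    return RunConfig(rt_model=params, **raw)


def write_stats_report(report: dict, path: str | Path) -> None:
    """Serialize a nested stats report as deterministic JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
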