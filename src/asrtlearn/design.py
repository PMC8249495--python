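"""Deterministic stimulus-stream designs for SRT and ASRT experiments.

The serial reaction time (SRT) task repeats a fixed 12-element sequence of
screen positions; the alternating serial reaction time (ASRT) task interleaves
a fixed 4-element pattern with random elements, so that every second trial is
predetermined.  This module builds the exact block/session layouts of the three
experiments the package analyses, with per-trial role bookkeeping:

* role ``pattern``       -- predetermined cue position (fixed here),
* role ``random_fill``   -- random ASRT element (position drawn later),
* role ``warmup``        -- the five random trials opening each ASRT block,
* role ``random_block``  -- trials of the fully random SRT blocks.

Designs are plain pandas DataFrames in the trial-log schema (see
:mod:`asrtlearn.io`) with ``position`` unset (NaN) for random roles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

__all__ = [
    "PatternSpec",
    "SRT_SEQUENCE",
    "EXPERIMENT_LAYOUTS",
    "EXP1_RANDOM_BLOCKS",
    "ASRT_BLOCK_LENGTH",
    "ASRT_WARMUP_TRIALS",
    "SRT_BLOCK_LENGTH",
    "srt_sequence",
    "enumerate_asrt_patterns",
    "build_design",
    "infer_patterns",
    "DesignError",
]

POSITIONS = (1, 2, 3, 4)

#: The fixed 12-element SRT sequence of cue positions.
SRT_SEQUENCE = (2, 3, 1, 4, 3, 2, 4, 1, 3, 4, 2, 1)

SRT_BLOCK_LENGTH = 60          # 5 repetitions of the 12-element sequence
ASRT_BLOCK_LENGTH = 85         # 5 warm-up + 10 repetitions of 8 elements
ASRT_WARMUP_TRIALS = 5
ASRT_BIN_TRIALS = 16           # two 8-element sequences per bin
SRT_BIN_TRIALS = 12            # one 12-element sequence per bin
N_BINS = 5

#: experiment_id -> (sessions, blocks per session, trials per block)
EXPERIMENT_LAYOUTS = {
    1: (2, 13, SRT_BLOCK_LENGTH),
    2: (1, 45, ASRT_BLOCK_LENGTH),
    3: (8, 25, ASRT_BLOCK_LENGTH),
}

#: Blocks of Experiment 1 whose cues are fully random (per session).
EXP1_RANDOM_BLOCKS = (6, 12)

ROLE_PATTERN = "pattern"
ROLE_RANDOM_FILL = "random_fill"
ROLE_WARMUP = "warmup"
ROLE_RANDOM_BLOCK = "random_block"


class DesignError(ValueError):
    """Raised for invalid design requests (unknown experiment, bad pattern)."""


@dataclass(frozen=True)
class PatternSpec:
    """A 4-element ASRT pattern and its two-trials-apart transition map.

    ``pattern`` is a permutation of {1,2,3,4}.  Because pattern elements occur
    on every second trial, each pattern position predicts the pattern position
    two trials later: ``transition_map[p] = next element of the 4-cycle``.
    A 4-cycle has no fixed point, so no position predicts itself.
    """

    pattern: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if tuple(sorted(self.pattern)) != POSITIONS:
            raise DesignError(
                f"pattern must be a permutation of {POSITIONS}, got {self.pattern}"
            )

    @property
    def transition_map(self) -> dict[int, int]:
        p = self.pattern
        return {p[i]: p[(i + 1) % 4] for i in range(4)}

    def transition_array(self) -> np.ndarray:
        """Transition map as an int array indexed by position (index 0 unused)."""
        arr = np.zeros(5, dtype=np.int64)
        for a, b in self.transition_map.items():
            arr[a] = b
        return arr

    def canonical(self) -> "PatternSpec":
        """Lexicographically smallest rotation (stable class representative)."""
        p = self.pattern
        rotations = [p[i:] + p[:i] for i in range(4)]
        return PatternSpec(min(rotations))


def srt_sequence() -> tuple[int, ...]:
    """Return the fixed 12-element SRT cue-position sequence."""
    return SRT_SEQUENCE


def enumerate_asrt_patterns() -> tuple[PatternSpec, ...]:
    """All rotation-distinct ASRT patterns (canonical representatives, sorted).

    Two patterns that are cyclic rotations of each other generate identical
    stimulus statistics (the same transition map up to phase), so patterns are
    deduplicated under rotation: 4!/4 = 6 classes.
    """
    seen: dict[tuple[int, ...], PatternSpec] = {}
    for perm in permutations(POSITIONS):
        spec = PatternSpec(perm).canonical()
        seen[spec.pattern] = spec
    return tuple(seen[k] for k in sorted(seen))


def _asrt_session_arrays(n_blocks: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(trial, role, pattern_slot) arrays for one ASRT session of n_blocks."""
    trial = np.tile(np.arange(1, ASRT_BLOCK_LENGTH + 1), n_blocks)
    role = np.where(
        trial <= ASRT_WARMUP_TRIALS,
        ROLE_WARMUP,
        np.where((trial - ASRT_WARMUP_TRIALS) % 2 == 1, ROLE_PATTERN, ROLE_RANDOM_FILL),
    )
    # pattern trials are 6, 8, 10, ...; slot cycles 0..3 (10 repetitions/block)
    slot = np.where(role == ROLE_PATTERN, ((trial - 6) // 2) % 4, -1)
    return trial, role, slot


def build_design(
    experiment_id: int,
    pattern_spec: PatternSpec | None = None,
    subject_count: int = 1,
    seed: int = 0,
    first_subject_id: int = 1,
) -> pd.DataFrame:
    """Build the trial-level design for one experiment.

    Parameters
    ----------
    experiment_id
        1 (SRT: 2 sessions x 13 blocks x 60 trials, blocks 6 and 12 random),
        2 (ASRT: 1 session x 45 blocks x 85 trials),
        3 (ASRT: 8 sessions x 25 blocks x 85 trials).
    pattern_spec
        ASRT pattern for every subject; if None (ASRT), patterns are assigned
        per subject by a seeded shuffle cycling through the six rotation
        classes.  Ignored for experiment 1.
    subject_count
        Number of subjects (identical layout, per-subject patterns).
    seed
        Seed for the pattern-assignment shuffle only.

    Returns
    -------
    DataFrame in the trial-log schema; ``position`` is set for pattern-role
    trials and NaN for random roles, ``correct``/``rt_ms`` are NaN.
    """
    if experiment_id not in EXPERIMENT_LAYOUTS:
        raise DesignError(f"unknown experiment_id {experiment_id!r}; expected 1, 2 or 3")
    n_sessions, n_blocks, block_len = EXPERIMENT_LAYOUTS[experiment_id]
    n_per_subject = n_sessions * n_blocks * block_len

    session = np.repeat(np.arange(1, n_sessions + 1), n_blocks * block_len)
    block = np.tile(np.repeat(np.arange(1, n_blocks + 1), block_len), n_sessions)

    if experiment_id == 1:
        trial = np.tile(np.arange(1, block_len + 1), n_sessions * n_blocks)
        is_random = np.isin(block, EXP1_RANDOM_BLOCKS)
        role = np.where(is_random, ROLE_RANDOM_BLOCK, ROLE_PATTERN)
        seq = np.asarray(SRT_SEQUENCE, dtype=float)
        position = np.where(role == ROLE_PATTERN, seq[(trial - 1) % 12], np.nan)
        subject_patterns: list[PatternSpec | None] = [None] * subject_count
        slot = None
    else:
        trial, role_sess, slot_sess = _asrt_session_arrays(n_blocks)
        trial = np.tile(trial, n_sessions)
        role = np.tile(role_sess, n_sessions)
        slot = np.tile(slot_sess, n_sessions)
        if pattern_spec is not None:
            subject_patterns = [pattern_spec] * subject_count
        else:
            classes = enumerate_asrt_patterns()
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(classes))
            subject_patterns = [
                classes[order[i % len(classes)]] for i in range(subject_count)
            ]
        position = None  # filled per subject below

    subject_ids = np.arange(first_subject_id, first_subject_id + subject_count)
    subj_col = np.repeat(subject_ids, n_per_subject)

    if experiment_id == 1:
        pos_col = np.tile(position, subject_count)
    else:
        pattern_values = np.array(
            [spec.pattern for spec in subject_patterns], dtype=np.int64
        )  # (S, 4)
        slot_all = np.tile(slot, subject_count)
        subj_idx = np.repeat(np.arange(subject_count), n_per_subject)
        pos_col = np.full(subject_count * n_per_subject, np.nan)
        mask = slot_all >= 0
        pos_col[mask] = pattern_values[subj_idx[mask], slot_all[mask]]

    df = pd.DataFrame(
        {
            "subject_id": subj_col,
            "experiment_id": np.full(subj_col.shape, experiment_id, dtype=np.int64),
            "session": np.tile(session, subject_count),
            "block": np.tile(block, subject_count),
            "trial": np.tile(trial, subject_count),
            "role": np.tile(role, subject_count),
            "position": pos_col,
            "correct": np.full(subj_col.shape, np.nan),
            "rt_ms": np.full(subj_col.shape, np.nan),
        }
    )
    return df


def infer_patterns(trials: pd.DataFrame) -> dict[int, PatternSpec]:
    """Recover each subject's ASRT pattern from the pattern-role cue positions.

    Reads the first four pattern trials (trials 6, 8, 10, 12 of the first
    block) per subject; raises :class:`DesignError` for SRT-only logs.
    """
    if int(trials["experiment_id"].iloc[0]) == 1:
        raise DesignError("experiment 1 (SRT) has no ASRT pattern to infer")
    pat_rows = trials[
        (trials["role"] == ROLE_PATTERN) & (trials["trial"].isin((6, 8, 10, 12)))
    ]
    out: dict[int, PatternSpec] = {}
    for subject, grp in pat_rows.groupby("subject_id", sort=True):
        first = grp.iloc[:4]
        pattern = tuple(int(p) for p in first["position"])
        out[int(subject)] = PatternSpec(pattern)  # validates permutation
    return out
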