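"""Triplet classification and trial exclusion rules.

In the ASRT stream every trial ends a *triplet* (trials n-2, n-1, n).  A
triplet is **high-probability** when its first and third elements follow the
pattern's two-apart transition map (it can be produced by the deterministic
pattern), otherwise **low-probability** (only producible by a random draw).
Per first element the conforming continuation occurs ~62.5% of the time and
each non-conforming one ~12.5%.

Each trial gets exactly one label:

* ``pattern``      -- predetermined element ending a triplet,
* ``random_high``  -- random element ending a high-probability triplet,
* ``random_low``   -- random element ending a low-probability triplet,
* ``excluded``     -- with a single reason: warm-up, random block, missing
  triplet context, wrong response, repetition (XXX) or trill (XYX).

Repetitions and trills are always low-probability under a permutation-derived
map (a 4-cycle has no fixed point) and are excluded because participants show
pre-existing response tendencies to them.  Triplet context never crosses a
block boundary, but warm-up and error trials do serve as context (the
stimulus stream, not the response, defines the transitional statistics).
SRT trials (experiment 1) carry no triplet labels: included trials get
category ``none`` and support only the general-skill measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import (
    ROLE_PATTERN,
    ROLE_RANDOM_BLOCK,
    ROLE_RANDOM_FILL,
    ROLE_WARMUP,
    PatternSpec,
    infer_patterns,
)

__all__ = [
    "CATEGORIES",
    "EXCLUSION_REASONS",
    "classify_triplet",
    "label_trials",
    "category_frequencies",
    "triplet_continuation_table",
    "LabelingError",
    "AuditError",
]

CATEGORIES = ("pattern", "random_high", "random_low", "excluded", "none")
EXCLUSION_REASONS = (
    "none", "warmup", "error", "trill", "repetition", "no_context", "random_block",
)

SORT_KEYS = ["subject_id", "session", "block", "trial"]


class LabelingError(ValueError):
    """Raised for unordered input or invalid triplet positions."""


class AuditError(ValueError):
    """Raised when a stream has no classifiable trials to audit."""


def classify_triplet(first_position: int, third_position: int,
                     transition_map: dict[int, int]) -> str:
    """Classify the triplet (first, x, third) as ``"high"`` or ``"low"``.

    High iff the transition map sends the first element to the third; the
    middle element is irrelevant.
    """
    for pos in (first_position, third_position):
        if pos not in (1, 2, 3, 4):
            raise LabelingError(f"position {pos!r} outside 1..4")
    return "high" if transition_map[first_position] == third_position else "low"


def _check_sorted(trials: pd.DataFrame) -> None:
    keys = trials[SORT_KEYS].to_numpy()
    if len(keys) > 1:
        diffs = keys[1:] != keys[:-1]
        # lexicographic monotonicity: first differing key must increase
        first_diff = np.argmax(diffs, axis=1)
        rows = diffs.any(axis=1)
        inc = keys[1:, :][np.arange(len(keys) - 1), first_diff] > \
            keys[:-1, :][np.arange(len(keys) - 1), first_diff]
        if not np.all(inc[rows]):
            raise LabelingError(
                "trials must be sorted by (subject_id, session, block, trial)"
            )


def label_trials(
    trials: pd.DataFrame,
    pattern_spec: PatternSpec | dict[int, PatternSpec] | None = None,
) -> pd.DataFrame:
    """Label every trial with its triplet category and exclusion reason.

    Parameters
    ----------
    trials
        Trial log sorted by (subject_id, session, block, trial).
    pattern_spec
        A single :class:`PatternSpec` for all subjects, a mapping
        ``subject_id -> PatternSpec``, or None to infer each subject's pattern
        from its pattern-role cue positions (ASRT only; ignored for SRT).

    Returns a copy with ``category`` and ``exclusion_reason`` columns.
    """
    _check_sorted(trials)
    df = trials.copy()
    experiment_id = int(df["experiment_id"].iloc[0])
    role = df["role"].to_numpy()
    trial = df["trial"].to_numpy()
    correct = df["correct"].to_numpy()
    is_error = correct == 0  # NaN (unsimulated logs) counts as correct

    if experiment_id == 1:
        reason = np.select(
            [role == ROLE_RANDOM_BLOCK, is_error],
            ["random_block", "error"],
            default="none",
        )
        category = np.where(reason == "none", "none", "excluded")
        df["category"] = category
        df["exclusion_reason"] = reason
        df["triplet_high"] = np.nan
        return df

    position = df["position"].to_numpy()
    if np.isnan(position).any():
        raise LabelingError("ASRT log has unset cue positions")
    position = position.astype(np.int64)

    if pattern_spec is None:
        patterns = infer_patterns(df)
    elif isinstance(pattern_spec, PatternSpec):
        patterns = {int(s): pattern_spec for s in df["subject_id"].unique()}
    else:
        patterns = {int(k): v for k, v in pattern_spec.items()}

    subjects, subj_idx = np.unique(df["subject_id"].to_numpy(), return_inverse=True)
    tmap = np.zeros((len(subjects), 5), dtype=np.int64)
    for i, s_id in enumerate(subjects):
        tmap[i] = patterns[int(s_id)].transition_array()

    has_context = trial >= 3  # context never crosses the block boundary
    first = np.where(has_context, np.roll(position, 2), 0)
    middle = np.where(has_context, np.roll(position, 1), 0)
    conforming = has_context & (
        tmap[subj_idx, np.where(has_context, first, 1)] == position
    )
    repetition = has_context & (first == position) & (middle == position)
    trill = has_context & (first == position) & (middle != position)

    reason = np.select(
        [
            role == ROLE_WARMUP,
            role == ROLE_RANDOM_BLOCK,
            ~has_context,
            is_error,
            repetition,
            trill,
        ],
        ["warmup", "random_block", "no_context", "error", "repetition", "trill"],
        default="none",
    )
    included = reason == "none"
    category = np.select(
        [
            included & (role == ROLE_PATTERN),
            included & (role == ROLE_RANDOM_FILL) & conforming,
            included & (role == ROLE_RANDOM_FILL) & ~conforming,
        ],
        ["pattern", "random_high", "random_low"],
        default="excluded",
    )
    df["category"] = category
    df["exclusion_reason"] = reason
    # factual stream-level triplet probability from the cue positions (NaN
    # where no within-block triplet exists or the trial is outside the
    # alternating structure); a block's first pattern trial can end a low
    # triplet through its warm-up context even though its *category* is
    # pattern (categories are role-based, as in the trial taxonomy)
    classifiable = has_context & np.isin(role, (ROLE_PATTERN, ROLE_RANDOM_FILL))
    df["triplet_high"] = np.where(classifiable, conforming.astype(float), np.nan)
    return df


def triplet_continuation_table(trials: pd.DataFrame,
                               min_first_trial: int = 12) -> pd.DataFrame:
    """Conditional triplet-continuation frequencies of an ASRT cue stream.

    For triplets (n-2, n-1, n) lying within a block, tabulates per first
    element the percentage of continuations onto each third element and the
    percentage of triplets ending on a pattern-role trial.  In the stationary
    alternating stream the map-conforming continuation occurs 62.5% of the
    time, each non-conforming one 12.5%, and half of all triplet-ending
    trials are predetermined.

    Because an 85-trial block truncates the alternation, the audit only uses
    triplets whose context starts at ``min_first_trial`` (default 12) or
    later: the pattern firsts of a block then span whole 4-cycles, so every
    pattern element serves as triplet context equally often and the
    theoretical percentages are exact in expectation.

    Returns a DataFrame indexed by first element with columns ``to_1`` ..
    ``to_4`` (percent), ``pattern_ending`` (percent) and ``n_triplets``.
    """
    if trials["position"].isna().any():
        raise AuditError("stream has unset cue positions")
    pos = trials["position"].to_numpy().astype(np.int64)
    trial = trials["trial"].to_numpy()
    role = trials["role"].to_numpy()
    ok = trial >= min_first_trial + 2
    first = np.roll(pos, 2)[ok]
    third = pos[ok]
    ends_pattern = role[ok] == ROLE_PATTERN
    if len(first) == 0:
        raise AuditError("no triplets in stream after the phase restriction")
    rows = []
    for f in (1, 2, 3, 4):
        sel = first == f
        n = int(sel.sum())
        row = {"first": f, "n_triplets": n}
        for t in (1, 2, 3, 4):
            row[f"to_{t}"] = 100.0 * float((third[sel] == t).mean()) if n else np.nan
        row["pattern_ending"] = 100.0 * float(ends_pattern[sel].mean()) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("first")


def category_frequencies(labeled_trials: pd.DataFrame) -> dict[str, float]:
    """Stream-level proportions of pattern / random-high / random-low trials.

    Audits the stimulus stream against its theoretical transitional
    statistics, so the denominator is every trial that ends a within-block
    triplet of the alternating structure (response errors and trill/repetition
    exclusions do not change what the stream presented): pattern approaches
    1/2, random-high 1/8 and random-low 3/8 on a long stream.
    """
    t = labeled_trials
    classifiable = t[t["triplet_high"].notna()]
    if classifiable.empty:
        raise AuditError("no classifiable trials in stream (all excluded)")
    role = classifiable["role"].to_numpy()
    high = classifiable["triplet_high"].to_numpy() == 1.0
    is_pattern = role == ROLE_PATTERN
    n = len(classifiable)
    return {
        "pattern": float(np.sum(is_pattern)) / n,
        "random_high": float(np.sum(~is_pattern & high)) / n,
        "random_low": float(np.sum(~is_pattern & ~high)) / n,
    }
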