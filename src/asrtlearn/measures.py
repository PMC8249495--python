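"""Learning scores per block/bin and their online/offline decomposition.

Three learning measures are computed from labeled trial logs:

* **general skill**: mean RT over included trials (and, in ASRT, over
  random-low trials only, which removes any predictable structure);
* **statistical learning**: RT(random-low) - RT(random-high);
* **high-order rule learning**: RT(random-high) - RT(pattern).

Each block is split into five positional bins (12 trials in SRT, 16 in ASRT;
warm-ups are not binned and exclusions thin bins without shifting their
boundaries).  *Online* learning of a block is the score change from its first
to its last bin; *offline* learning of a rest is the change from the last bin
of one block to the first bin of the next; *long-offline* learning spans
session gaps.  General-skill deltas are negated so that learning is positive
for every measure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import (
    ASRT_BIN_TRIALS,
    ASRT_BLOCK_LENGTH,
    ASRT_WARMUP_TRIALS,
    N_BINS,
    ROLE_RANDOM_BLOCK,
    SRT_BIN_TRIALS,
    SRT_BLOCK_LENGTH,
)

__all__ = [
    "MEASURES",
    "bin_blocks",
    "block_scores",
    "bin_scores",
    "online_offline",
    "long_offline",
    "subject_delta_means",
    "BinningError",
]

logger = logging.getLogger(__name__)

#: measure name -> (ScoreTable column, sign applied to online/offline deltas).
#: General-skill deltas are reversed so that learning appears positive.
MEASURES = {
    "general_skill": ("general_skill_rt", -1.0),
    "general_skill_random_low": ("general_skill_rt_random_low", -1.0),
    "statistical": ("stat_score", 1.0),
    "rule": ("rule_score", 1.0),
}

_BLOCK_KEYS = ["subject_id", "session", "block"]


class BinningError(ValueError):
    """Raised when a block does not have the expected number of trials."""


def bin_blocks(labeled_trials: pd.DataFrame) -> pd.DataFrame:
    """Annotate trials with their within-block bin index (1..5).

    Bins are positional on the stimulus stream: ASRT bin k covers post-warm-up
    trials 16(k-1)+1..16k, SRT bin k covers trials 12(k-1)+1..12k.  Warm-up
    trials get no bin.  Blocks of unexpected length raise
    :class:`BinningError`.
    """
    df = labeled_trials.copy()
    experiment_id = int(df["experiment_id"].iloc[0])
    expected = SRT_BLOCK_LENGTH if experiment_id == 1 else ASRT_BLOCK_LENGTH
    sizes = df.groupby(_BLOCK_KEYS, sort=False).size()
    bad = sizes[sizes != expected]
    if not bad.empty:
        raise BinningError(
            f"blocks with unexpected length (expected {expected}): "
            f"{bad.index.tolist()[:5]}"
        )
    trial = df["trial"].to_numpy()
    if experiment_id == 1:
        df["bin"] = (trial - 1) // SRT_BIN_TRIALS + 1
    else:
        k = (trial - ASRT_WARMUP_TRIALS - 1) // ASRT_BIN_TRIALS + 1
        df["bin"] = np.where(trial <= ASRT_WARMUP_TRIALS, np.nan, k)
    return df


def _scores(labeled: pd.DataFrame, keys: list[str], min_trials: int) -> pd.DataFrame:
    experiment_id = int(labeled["experiment_id"].iloc[0])
    included = labeled[labeled["exclusion_reason"] == "none"]

    gs = included.groupby(keys)["rt_ms"].agg(
        general_skill_rt="mean", n_included="size"
    )

    cat = included[included["category"].isin(("pattern", "random_high", "random_low"))]
    if not cat.empty:
        per_cat = cat.groupby(keys + ["category"], observed=True)["rt_ms"].agg(
            ["mean", "size"]
        ).unstack("category")
    else:
        per_cat = pd.DataFrame(index=gs.index)

    def col(kind: str, category: str) -> pd.Series:
        try:
            return per_cat[(kind, category)]
        except KeyError:
            return pd.Series(np.nan, index=gs.index)

    out = gs.copy()
    for category in ("pattern", "random_high", "random_low"):
        out[f"mean_rt_{category}"] = col("mean", category)
        out[f"n_{category}"] = col("size", category).fillna(0).astype(int)

    def guarded(a: str, b: str) -> pd.Series:
        ok = (out[f"n_{a}"] >= min_trials) & (out[f"n_{b}"] >= min_trials)
        return (out[f"mean_rt_{a}"] - out[f"mean_rt_{b}"]).where(ok)

    out["general_skill_rt_random_low"] = out["mean_rt_random_low"].where(
        out["n_random_low"] >= min_trials
    )
    out["stat_score"] = guarded("random_low", "random_high")
    out["rule_score"] = guarded("random_high", "pattern")

    # flag fully random blocks (excluded from learning analyses)
    random_blocks = (
        labeled.assign(_rb=labeled["role"] == ROLE_RANDOM_BLOCK)
        .groupby(_BLOCK_KEYS)["_rb"].any()
    )
    out = out.reset_index()
    out = out.merge(random_blocks.rename("is_random_block").reset_index(),
                    on=_BLOCK_KEYS, how="left")
    out.insert(0, "experiment_id", experiment_id)
    n_missing = int(out["general_skill_rt"].isna().sum())
    if n_missing:
        logger.info("score table: %d empty cells", n_missing)
    return out


def block_scores(labeled_trials: pd.DataFrame, min_trials: int = 1) -> pd.DataFrame:
    """Per (subject, session, block) learning scores over included trials."""
    return _scores(labeled_trials, _BLOCK_KEYS, min_trials)


def bin_scores(labeled_trials: pd.DataFrame, min_trials: int = 1) -> pd.DataFrame:
    """Per (subject, session, block, bin) learning scores.

    Difference scores are missing (NaN) wherever a constituent category has
    fewer than ``min_trials`` trials in the cell.
    """
    df = labeled_trials if "bin" in labeled_trials.columns else bin_blocks(labeled_trials)
    binned = df[df["bin"].notna()].copy()
    binned["bin"] = binned["bin"].astype(int)
    return _scores(binned, _BLOCK_KEYS + ["bin"], min_trials)


def _first_last(bin_table: pd.DataFrame, column: str) -> pd.DataFrame:
    """Per-block first/last-bin values of ``column`` for analyzable blocks."""
    t = bin_table[~bin_table["is_random_block"].astype(bool)]
    wide = t.pivot_table(index=_BLOCK_KEYS, columns="bin", values=column,
                         aggfunc="first")
    wide = wide.reindex(columns=range(1, N_BINS + 1))
    out = pd.DataFrame(
        {"first": wide[1], "last": wide[N_BINS]}, index=wide.index
    ).reset_index()
    return out.sort_values(_BLOCK_KEYS, kind="stable").reset_index(drop=True)


def online_offline(
    bin_score_table: pd.DataFrame,
    measure: str,
    block_filter: str = "all_blocks",
    random_gap_policy: str = "exclude",
) -> pd.DataFrame:
    """Online and offline gains per subject for one measure.

    Online gain of a block = score(last bin) - score(first bin); offline gain
    of a rest = score(first bin of next block) - score(last bin of the
    previous block); both multiplied by the measure's learning-positive sign.
    Fully random blocks are dropped; in Experiment 1 the rests adjacent to a
    removed random block are excluded under ``random_gap_policy="exclude"``
    (the default) or bridged into a single longer gap under ``"bridge"``.
    ``block_filter="first_blocks_of_sessions"`` restricts to the first block
    of each session and the rest that follows it.

    Returns a tidy table (subject_id, session, block, kind, measure, value)
    containing only available deltas; blocks with a missing first or last bin
    are skipped.
    """
    if measure not in MEASURES:
        raise KeyError(f"unknown measure {measure!r}; expected one of {list(MEASURES)}")
    if block_filter not in ("all_blocks", "first_blocks_of_sessions"):
        raise ValueError(f"unknown block_filter {block_filter!r}")
    if random_gap_policy not in ("exclude", "bridge"):
        raise ValueError(f"unknown random_gap_policy {random_gap_policy!r}")
    column, sign = MEASURES[measure]
    fl = _first_last(bin_score_table, column)

    online = fl.copy()
    online["value"] = sign * (online["last"] - online["first"])
    online["kind"] = "online"

    fl["prev_last"] = fl.groupby(["subject_id", "session"])["last"].shift(1)
    fl["prev_block"] = fl.groupby(["subject_id", "session"])["block"].shift(1)
    offline = fl.dropna(subset=["prev_block"]).copy()
    if random_gap_policy == "exclude":
        offline = offline[offline["block"] - offline["prev_block"] == 1]
    offline["value"] = sign * (offline["first"] - offline["prev_last"])
    offline["kind"] = "offline"
    # an offline gap is keyed by the block it leads out of
    offline["block"] = offline["prev_block"].astype(int)

    if block_filter == "first_blocks_of_sessions":
        first_block = fl.groupby(["subject_id", "session"])["block"].transform("min")
        keep_online = online["block"] == first_block
        online = online[keep_online.reindex(online.index, fill_value=False)]
        offline = offline[offline["block"]
                          == offline.groupby(["subject_id", "session"])["block"]
                          .transform("min")]

    cols = ["subject_id", "session", "block", "kind", "value"]
    out = pd.concat([online[cols], offline[cols]], ignore_index=True)
    n_skipped = int(out["value"].isna().sum())
    if n_skipped:
        logger.info("online_offline(%s): %d deltas missing and skipped",
                    measure, n_skipped)
    out = out.dropna(subset=["value"]).reset_index(drop=True)
    out.insert(3, "measure", measure)
    return out


def long_offline(bin_score_table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Offline gains across session gaps (empty for single-session designs).

    Per session gap: score(first bin of the first analyzable block of the next
    session) - score(last bin of the last analyzable block of the previous
    session), learning-positive sign applied.
    """
    if measure not in MEASURES:
        raise KeyError(f"unknown measure {measure!r}")
    column, sign = MEASURES[measure]
    fl = _first_last(bin_score_table, column)

    firsts = fl.loc[fl.groupby(["subject_id", "session"])["block"].idxmin()]
    lasts = fl.loc[fl.groupby(["subject_id", "session"])["block"].idxmax()]
    rows = []
    for subject, grp in firsts.groupby("subject_id"):
        sessions = sorted(grp["session"])
        for prev_s, next_s in zip(sessions[:-1], sessions[1:]):
            start = lasts[(lasts["subject_id"] == subject)
                          & (lasts["session"] == prev_s)]["last"]
            end = grp[grp["session"] == next_s]["first"]
            value = sign * (float(end.iloc[0]) - float(start.iloc[0]))
            rows.append({"subject_id": subject, "session": prev_s,
                         "block": -1, "kind": "long_offline",
                         "measure": measure, "value": value})
    out = pd.DataFrame(rows, columns=["subject_id", "session", "block",
                                      "kind", "measure", "value"])
    return out.dropna(subset=["value"]).reset_index(drop=True)


def subject_delta_means(delta_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean gain per kind (subjects with no delta of a kind drop).

    Returns a wide table indexed by subject with one column per kind
    ('online', 'offline', 'long_offline' as available).
    """
    if delta_table.empty:
        return pd.DataFrame()
    return delta_table.groupby(["subject_id", "kind"])["value"].mean().unstack("kind")
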