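"""Binning, learning scores, and the online/offline decomposition."""

import numpy as np
import pandas as pd
import pytest

import asrtlearn as al
from asrtlearn.measures import BinningError


def _bin_table(rows):
    """Minimal bin-score table from (subject, session, block, bin, value)."""
    df = pd.DataFrame(rows, columns=["subject_id", "session", "block", "bin",
                                     "general_skill_rt"])
    df["stat_score"] = df["general_skill_rt"]
    df["rule_score"] = df["general_skill_rt"]
    df["general_skill_rt_random_low"] = df["general_skill_rt"]
    df["is_random_block"] = False
    return df


def _one_block(values, subject=1, session=1, block=1):
    return [(subject, session, block, k, v) for k, v in enumerate(values, 1)]


def test_asrt_bins_are_sixteen_stream_trials(labeled_exp2):
    binned = al.bin_blocks(labeled_exp2)
    assert binned.loc[binned["trial"] <= 5, "bin"].isna().all()
    counts = binned.dropna(subset=["bin"]).groupby(
        ["subject_id", "block", "bin"]).size()
    assert (counts == 16).all()
    assert sorted(binned["bin"].dropna().unique()) == [1, 2, 3, 4, 5]


def test_srt_bins_are_twelve_trials(exp1_log):
    binned = al.bin_blocks(al.label_trials(exp1_log))
    counts = binned.groupby(["session", "block", "bin"]).size()
    assert (counts == 12).all()


def test_exclusions_do_not_shift_bin_boundaries(labeled_exp2):
    """Bin membership is positional: dropping trials leaves bins in place."""
    binned = al.bin_blocks(labeled_exp2)
    by_position = ((binned["trial"] - 6) // 16 + 1).where(binned["trial"] > 5)
    assert binned["bin"].equals(by_position)


def test_unexpected_block_length_raises(labeled_exp2):
    truncated = labeled_exp2[~((labeled_exp2["block"] == 3)
                               & (labeled_exp2["trial"] > 80))]
    with pytest.raises(BinningError):
        al.bin_blocks(truncated)


def _make_labeled(cells):
    """Labeled-trial frame from (category, rt) tuples in one block/bin."""
    rows = []
    for i, (category, rt) in enumerate(cells, 1):
        rows.append({
            "subject_id": 1, "experiment_id": 2, "session": 1, "block": 1,
            "trial": i, "role": "random_fill" if category.startswith("random")
            else "pattern", "position": 1, "correct": 1.0, "rt_ms": rt,
            "category": category, "exclusion_reason": "none",
            "triplet_high": np.nan,
        })
    return pd.DataFrame(rows)


def test_score_arithmetic_from_definitions():
    lab = _make_labeled(
        [("random_low", 500.0), ("random_low", 500.0),
         ("random_high", 480.0), ("random_high", 480.0),
         ("pattern", 470.0), ("pattern", 470.0)]
    )
    scores = al.block_scores(lab)
    row = scores.iloc[0]
    assert row["stat_score"] == pytest.approx(20.0)
    assert row["rule_score"] == pytest.approx(10.0)
    assert row["general_skill_rt"] == pytest.approx((500 + 480 + 470) / 3)
    assert row["general_skill_rt_random_low"] == pytest.approx(500.0)


def test_identical_rts_give_zero_difference_scores():
    lab = _make_labeled([("random_low", 450.0), ("random_high", 450.0),
                         ("pattern", 450.0)])
    row = al.block_scores(lab).iloc[0]
    assert row["stat_score"] == 0.0
    assert row["rule_score"] == 0.0


def test_missing_category_gives_missing_score():
    lab = _make_labeled([("random_high", 480.0), ("pattern", 470.0)])
    row = al.block_scores(lab).iloc[0]
    assert np.isnan(row["stat_score"])
    assert row["rule_score"] == pytest.approx(10.0)
    row2 = al.block_scores(lab, min_trials=2).iloc[0]
    assert np.isnan(row2["rule_score"])


def test_monotone_rt_decrease_gives_decreasing_bin_means(labeled_exp2):
    lab = labeled_exp2.copy()
    lab["rt_ms"] = 600.0 - 2.0 * lab["trial"]
    bins = al.bin_scores(al.bin_blocks(lab))
    for _, grp in bins.groupby(["subject_id", "session", "block"]):
        gs = grp.sort_values("bin")["general_skill_rt"].to_numpy()
        assert (np.diff(gs) < 0).all()


def test_general_skill_online_gain_is_reversed_rt_change():
    tbl = _bin_table(_one_block([500, 490, 480, 470, 460]))
    deltas = al.online_offline(tbl, "general_skill")
    online = deltas[deltas["kind"] == "online"]
    assert online["value"].to_list() == [pytest.approx(40.0)]
    stat = al.online_offline(tbl, "statistical")
    assert stat[stat["kind"] == "online"]["value"].to_list() == [pytest.approx(-40.0)]


def test_constant_scores_give_zero_deltas():
    rows = _one_block([400] * 5, block=1) + _one_block([400] * 5, block=2)
    deltas = al.online_offline(_bin_table(rows), "statistical")
    assert (deltas["value"] == 0).all()
    assert sorted(deltas["kind"].unique()) == ["offline", "online"]


def test_online_offline_telescopes_to_end_minus_start():
    rng = np.random.default_rng(7)
    rows = []
    for block in range(1, 9):
        rows += _one_block(rng.normal(450, 30, 5), block=block)
    tbl = _bin_table(rows)
    for measure, sign in [("general_skill", -1), ("statistical", 1)]:
        deltas = al.online_offline(tbl, measure)
        total = deltas["value"].sum()
        expected = sign * (tbl["general_skill_rt"].iloc[-1]
                           - tbl["general_skill_rt"].iloc[0])
        assert total == pytest.approx(expected, abs=1e-9)


def test_srt_gaps_adjacent_to_random_blocks_are_excluded():
    rows = []
    for block in range(1, 14):
        rows += _one_block([500.0 - block] * 5, block=block)
    tbl = _bin_table(rows)
    tbl.loc[tbl["block"].isin((6, 12)), "is_random_block"] = True
    deltas = al.online_offline(tbl, "general_skill")
    online_blocks = set(deltas[deltas["kind"] == "online"]["block"])
    assert online_blocks == set(range(1, 14)) - {6, 12}
    offline_gaps = set(deltas[deltas["kind"] == "offline"]["block"])
    assert offline_gaps == {1, 2, 3, 4, 7, 8, 9, 10}
    bridged = al.online_offline(tbl, "general_skill", random_gap_policy="bridge")
    assert set(bridged[bridged["kind"] == "offline"]["block"]) == \
        offline_gaps | {5, 11}


def test_first_blocks_filter_keeps_one_block_and_gap_per_session():
    rows = []
    for session in (1, 2):
        for block in (1, 2, 3):
            rows += _one_block([400, 398, 396, 394, 392],
                               session=session, block=block)
    deltas = al.online_offline(_bin_table(rows), "general_skill",
                               block_filter="first_blocks_of_sessions")
    online = deltas[deltas["kind"] == "online"]
    offline = deltas[deltas["kind"] == "offline"]
    assert list(online[["session", "block"]].itertuples(index=False)) == \
        [(1, 1), (2, 1)]
    assert list(offline[["session", "block"]].itertuples(index=False)) == \
        [(1, 1), (2, 1)]


def test_missing_bin_skips_only_touching_deltas():
    rows = (_one_block([500, 495, 490, 485, 480], block=1)
            + _one_block([478, 476, 474, 472, 470], block=2)
            + _one_block([468, 466, 464, 462, 460], block=3))
    tbl = _bin_table(rows)
    tbl.loc[(tbl["block"] == 2) & (tbl["bin"] == 5), "stat_score"] = np.nan
    deltas = al.online_offline(tbl, "statistical")
    online_blocks = set(deltas[deltas["kind"] == "online"]["block"])
    offline_gaps = set(deltas[deltas["kind"] == "offline"]["block"])
    assert online_blocks == {1, 3}      # block 2 lost its last bin
    assert offline_gaps == {1}          # gap 2->3 needs block 2 bin 5
    full = al.online_offline(_bin_table(rows), "statistical")
    assert set(full[full["kind"] == "online"]["block"]) == {1, 2, 3}


def test_long_offline_gains():
    # single session -> empty
    tbl = _bin_table(_one_block([400] * 5))
    assert al.long_offline(tbl, "general_skill").empty
    # two sessions, constant -> zero; with a jump J -> J (reversed for RT)
    rows = (_one_block([400] * 5, session=1, block=1)
            + _one_block([400] * 5, session=1, block=2)
            + _one_block([390] * 5, session=2, block=1))
    lo = al.long_offline(_bin_table(rows), "general_skill")
    assert lo["kind"].to_list() == ["long_offline"]
    assert lo["value"].to_list() == [pytest.approx(10.0)]
    lo_stat = al.long_offline(_bin_table(rows), "statistical")
    assert lo_stat["value"].to_list() == [pytest.approx(-10.0)]


def test_subject_delta_means_drop_missing_subjects():
    tbl = pd.DataFrame({
        "subject_id": [1, 1, 2],
        "session": 1, "block": 1,
        "measure": "statistical",
        "kind": ["online", "offline", "online"],
        "value": [4.0, -2.0, 6.0],
    })
    means = al.subject_delta_means(tbl)
    assert means.loc[1, "online"] == 4.0
    assert means.loc[1, "offline"] == -2.0
    assert np.isnan(means.loc[2, "offline"])
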