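"""Group inference: RM-ANOVA vs sums-of-squares oracle, trends, t tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import asrtlearn as al
from asrtlearn.inference import InferenceError, cohens_d_one_sample


def _block_table(values, is_random=None, extra_cols=()):
    """Block ScoreTable from values[subject][block]."""
    rows = []
    for s, blocks in enumerate(values, 1):
        for b, v in enumerate(blocks, 1):
            row = {"subject_id": s, "session": 1, "block": b,
                   "general_skill_rt": v,
                   "is_random_block": bool(is_random and b in is_random)}
            for c in extra_cols:
                row[c] = v
            rows.append(row)
    return pd.DataFrame(rows)


def one_way_rm_f(y):
    """Sums-of-squares oracle for the one-way repeated-measures F."""
    y = np.asarray(y, dtype=float)  # subjects x conditions
    n, a = y.shape
    grand = y.mean()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = a * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = a - 1, (a - 1) * (n - 1)
    return (ss_cond / df1) / (ss_err / df2), df1, df2


def interaction_rm_f(y):
    """Sums-of-squares oracle for the within-subjects B x T interaction F."""
    y = np.asarray(y, dtype=float)  # subjects x blocks x triplet-levels
    n, b, t = y.shape
    grand = y.mean()
    m_bt = y.mean(axis=0)
    m_b = y.mean(axis=(0, 2))
    m_t = y.mean(axis=(0, 1))
    ss_int = n * ((m_bt - m_b[:, None] - m_t[None, :] + grand) ** 2).sum()
    m_sb = y.mean(axis=2)
    m_st = y.mean(axis=1)
    m_s = y.mean(axis=(1, 2))
    resid = (y - m_bt[None] - m_sb[:, :, None] - m_st[:, None, :]
             + m_b[None, :, None] + m_t[None, None, :] + m_s[:, None, None]
             - grand)
    ss_err = (resid ** 2).sum()
    df1 = (b - 1) * (t - 1)
    df2 = (b - 1) * (t - 1) * (n - 1)
    return (ss_int / df1) / (ss_err / df2), df1, df2


def test_one_way_rm_anova_matches_hand_sums_of_squares():
    y = [[430.0, 415.0, 402.0], [455.0, 441.0, 433.0], [470.0, 459.0, 444.0]]
    res = al.rm_anova_block(_block_table(y), "general_skill")
    f, df1, df2 = one_way_rm_f(y)
    assert res.statistic_value == pytest.approx(f, abs=1e-6)
    assert res.df == (df1, df2)
    # GG correction can only raise the p value
    p_unc = stats.f.sf(f, df1, df2)
    assert res.p_value >= p_unc - 1e-12
    assert res.n_subjects == 3


def test_two_way_interaction_matches_hand_sums_of_squares():
    rng = np.random.default_rng(3)
    y = 450 + rng.normal(0, 12, size=(4, 3, 2))  # 4 subjects, 3 blocks, 2 triplets
    rows = []
    for s in range(4):
        for b in range(3):
            rows.append({"subject_id": s + 1, "session": 1, "block": b + 1,
                         "is_random_block": False,
                         "mean_rt_random_low": y[s, b, 0],
                         "mean_rt_random_high": y[s, b, 1]})
    res = al.rm_anova_block(pd.DataFrame(rows), "statistical")
    f, df1, df2 = interaction_rm_f(y)
    assert res.statistic_value == pytest.approx(f, abs=1e-6)
    assert res.df == (df1, df2)


def test_flat_scores_give_small_f_and_large_p():
    rng = np.random.default_rng(1)
    y = 400 + rng.normal(0, 1e-3, size=(5, 4))
    res = al.rm_anova_block(_block_table(y.tolist()), "general_skill")
    assert res.p_value > 0.2


def test_strong_block_trend_is_detected():
    rng = np.random.default_rng(2)
    y = [[450 - 8 * b + rng.normal(0, 4) for b in range(6)] for _ in range(10)]
    res = al.rm_anova_block(_block_table(y), "general_skill")
    assert res.p_value < 0.05
    assert res.statistic_value > 10


def test_rm_anova_needs_three_complete_subjects():
    y = [[430.0, 415.0], [455.0, 441.0]]
    with pytest.raises(InferenceError):
        al.rm_anova_block(_block_table(y), "general_skill")


def test_spearman_trend_perfect_and_tied_ranks():
    assert al.spearman_trend([500, 480, 460, 440]).statistic_value == -1.0
    assert al.spearman_trend([10, 20, 30, 40]).statistic_value == 1.0
    # ranks (1,2,3,4) vs (2,1,4,3): rho = 1 - 6*4/(4*15) = 0.6
    res = al.spearman_trend([2, 1, 4, 3], [1, 2, 3, 4])
    assert res.statistic_value == pytest.approx(0.6)
    const = al.spearman_trend([5, 5, 5, 5])
    assert np.isnan(const.statistic_value) and const.note == "constant input"
    with pytest.raises(InferenceError):
        al.spearman_trend([1, 2])


def _delta_table(online, offline=None):
    rows = [{"subject_id": s, "session": 1, "block": 1, "measure": "statistical",
             "kind": "online", "value": v} for s, v in enumerate(online, 1)]
    for s, v in enumerate([] if offline is None else offline, 1):
        rows.append({"subject_id": s, "session": 1, "block": 1,
                     "measure": "statistical", "kind": "offline", "value": v})
    return pd.DataFrame(rows)


def test_one_sample_t_matches_hand_computation():
    res = al.test_deltas(_delta_table([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]))
    online = res["online"]
    assert online.statistic_value == pytest.approx(2 * np.sqrt(3))
    assert online.effect_size_d == pytest.approx(2.0)
    assert online.df == 2.0
    # paired contrast: offline - online = (-1, -2, -3)
    paired = res["online_vs_offline"]
    assert paired.statistic_value == pytest.approx(-2 * np.sqrt(3))
    assert paired.effect_size_d == pytest.approx(-2.0)


def test_zero_variance_deltas_are_flagged():
    res = al.test_deltas(_delta_table([0.0, 0.0, 0.0], [1.0, 1.0, 1.0]))
    assert np.isnan(res["online"].statistic_value)
    assert res["online"].note == "zero variance"


def test_d_equals_t_over_sqrt_n():
    rng = np.random.default_rng(9)
    values = rng.normal(1.0, 2.0, 40)
    res = al.test_deltas(_delta_table(values, values))["online"]
    assert abs(res.effect_size_d) == pytest.approx(
        abs(res.statistic_value) / np.sqrt(res.n_subjects), abs=1e-12
    )
    assert cohens_d_one_sample(values) == pytest.approx(
        values.mean() / values.std(ddof=1)
    )


def test_too_few_subjects_rejected():
    with pytest.raises(InferenceError):
        al.test_deltas(_delta_table([1.0], [1.0]))
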