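"""Group-level statistics for learning scores and online/offline gains.

The inference protocol: repeated-measures ANOVA over blocks (one-way on mean
RT for general skill; two-way block x triplet-type interaction for the
difference measures) with Greenhouse-Geisser-corrected p values; a Spearman
rank correlation between group block means and block position as a trend
check; and one-sample two-tailed t tests against zero on per-subject mean
online/offline gains, with a paired t test comparing practice and rest.
Cohen's d for one-sample/paired tests is mean/SD of the tested values, so
|d| = |t|/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .measures import MEASURES, subject_delta_means

__all__ = [
    "GroupStatResult",
    "InferenceError",
    "rm_anova_block",
    "spearman_trend",
    "test_deltas",
    "cohens_d_one_sample",
]

#: triplet-type contrast entering the two-way ANOVA, per difference measure
_ANOVA_TRIPLET_LEVELS = {
    "statistical": ("mean_rt_random_low", "mean_rt_random_high"),
    "rule": ("mean_rt_random_high", "mean_rt_pattern"),
}


class InferenceError(ValueError):
    """Raised when a test has too few subjects or malformed input."""


@dataclass(frozen=True)
class GroupStatResult:
    """One group-level test: statistic, degrees of freedom, p, effect size."""

    statistic_name: str            # "F", "t" or "r_s"
    statistic_value: float
    df: tuple[float, float] | float
    p_value: float
    n_subjects: int
    effect_size_d: float | None = None
    note: str = ""

    def as_dict(self) -> dict:
        d = {
            "statistic": self.statistic_name,
            "value": None if self.statistic_value is None or np.isnan(self.statistic_value)
            else float(self.statistic_value),
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": None if self.p_value is None or np.isnan(self.p_value)
            else float(self.p_value),
            "n_subjects": int(self.n_subjects),
        }
        if self.effect_size_d is not None and not np.isnan(self.effect_size_d):
            d["cohens_d"] = float(self.effect_size_d)
        if self.note:
            d["note"] = self.note
        return d


def cohens_d_one_sample(values: np.ndarray) -> float:
    """Cohen's d = mean / SD (ddof=1); equals |t|/sqrt(n) up to sign."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    return float(values.mean() / sd) if sd > 0 else float("nan")


def _block_column(block_table: pd.DataFrame) -> pd.Series:
    """Global block index (unique across sessions) for within-subject factors."""
    max_block = int(block_table["block"].max())
    return (block_table["session"] - 1) * max_block + block_table["block"]


def rm_anova_block(
    score_table: pd.DataFrame,
    measure: str,
    with_triplet_factor: bool | None = None,
) -> GroupStatResult:
    """Repeated-measures ANOVA over blocks with GG-corrected p value.

    General-skill measures use a one-way design (block as the within-subject
    factor, main effect reported); difference measures use the two-way design
    on the per-category mean RTs (block x triplet interaction reported).
    Subjects with any missing cell are dropped listwise.
    """
    if measure not in MEASURES:
        raise KeyError(f"unknown measure {measure!r}")
    if with_triplet_factor is None:
        with_triplet_factor = measure in _ANOVA_TRIPLET_LEVELS

    tbl = score_table[~score_table["is_random_block"].astype(bool)].copy()
    tbl["block_id"] = _block_column(tbl)

    if not with_triplet_factor:
        dv, _ = MEASURES[measure]
        long = tbl[["subject_id", "block_id", dv]].rename(columns={dv: "value"})
        within = ["block_id"]
    else:
        lo, hi = _ANOVA_TRIPLET_LEVELS[measure]
        long = tbl.melt(
            id_vars=["subject_id", "block_id"], value_vars=[lo, hi],
            var_name="triplet", value_name="value",
        )
        within = ["block_id", "triplet"]

    # listwise drop: keep subjects with a complete set of cells
    n_cells = long.groupby(["subject_id"])["value"].apply(lambda s: s.notna().all())
    keep = n_cells[n_cells].index
    long = long[long["subject_id"].isin(keep)]
    n_subjects = long["subject_id"].nunique()
    if n_subjects < 3:
        raise InferenceError(
            f"repeated-measures ANOVA needs >=3 complete subjects, got {n_subjects}"
        )

    aov = pg.rm_anova(data=long, dv="value", within=within,
                      subject="subject_id", correction=True, detailed=True)
    if not with_triplet_factor:
        row = aov.loc[aov["Source"] == "block_id"].iloc[0]
        err = aov.loc[aov["Source"] == "Error"].iloc[0]
        df_pair = (float(row["DF"]), float(err["DF"]))
    else:
        row = aov.loc[aov["Source"] == "block_id * triplet"].iloc[0]
        df_pair = (float(row["ddof1"]), float(row["ddof2"]))
    p = row.get("p_GG_corr", np.nan)
    note = "GG-corrected"
    if pd.isna(p):  # GG undefined (e.g. only two blocks)
        p = row["p_unc"]
        note = "uncorrected (GG not applicable)"
    return GroupStatResult("F", float(row["F"]), df_pair, float(p),
                           n_subjects, note=note)


def spearman_trend(block_means: np.ndarray,
                   block_indices: np.ndarray | None = None) -> GroupStatResult:
    """Spearman correlation between group block means and block position."""
    y = np.asarray(block_means, dtype=float)
    if block_indices is None:
        block_indices = np.arange(1, len(y) + 1)
    x = np.asarray(block_indices, dtype=float)
    if len(y) < 3:
        raise InferenceError("Spearman trend needs >=3 blocks")
    if np.all(y == y[0]):
        return GroupStatResult("r_s", float("nan"), float(len(y) - 2),
                               float("nan"), len(y), note="constant input")
    res = stats.spearmanr(x, y)
    return GroupStatResult("r_s", float(res.statistic), float(len(y) - 2),
                           float(res.pvalue), len(y))


def _one_sample(values: pd.Series, label: str) -> GroupStatResult:
    v = values.dropna().to_numpy(dtype=float)
    n = len(v)
    if n < 2:
        raise InferenceError(f"{label}: need >=2 subjects, got {n}")
    if v.std(ddof=1) == 0:
        return GroupStatResult("t", float("nan"), float(n - 1), float("nan"),
                               n, effect_size_d=float("nan"),
                               note="zero variance")
    t, p = stats.ttest_1samp(v, 0.0)
    return GroupStatResult("t", float(t), float(n - 1), float(p), n,
                           effect_size_d=cohens_d_one_sample(v))


def test_deltas(delta_table: pd.DataFrame, measure: str | None = None
                ) -> dict[str, GroupStatResult]:
    """t tests on per-subject mean gains: online vs 0, offline vs 0, paired.

    The paired contrast tests offline - online on subjects contributing both
    kinds; d = mean(difference)/SD(difference).
    """
    t = delta_table
    if measure is not None and "measure" in t.columns:
        t = t[t["measure"] == measure]
    means = subject_delta_means(t)
    if means.empty or "online" not in means or "offline" not in means:
        raise InferenceError("delta table lacks online/offline gains")
    out = {
        "online": _one_sample(means["online"], "online"),
        "offline": _one_sample(means["offline"], "offline"),
    }
    paired = means[["online", "offline"]].dropna()
    out["online_vs_offline"] = _one_sample(
        paired["offline"] - paired["online"], "online_vs_offline"
    )
    return out
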