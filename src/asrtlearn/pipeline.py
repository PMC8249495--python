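"""High-level pipeline: simulate -> label -> score -> decompose -> analyze.

Thin orchestration over the stage modules, shared by the command-line
interface and the validation scripts.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import inference, measures
from .design import build_design
from .io import RunConfig
from .measures import MEASURES, bin_blocks, bin_scores, block_scores
from .simulate import fill_random_positions, simulate_rts

__all__ = ["simulate_experiment", "applicable_measures", "decompose", "analyze"]

logger = logging.getLogger(__name__)


def simulate_experiment(config: RunConfig) -> pd.DataFrame:
    """Build, fill and simulate a complete trial log for one experiment."""
    # independent sub-streams for pattern assignment, position fills, RT noise
    sub = np.random.default_rng(config.seed).integers(0, 2**31, size=3)
    design = build_design(
        config.experiment_id,
        pattern_spec=config.pattern_spec(),
        subject_count=config.subjects,
        seed=int(sub[0]),
    )
    filled = fill_random_positions(design, seed=int(sub[1]))
    params = dataclasses.replace(config.rt_model, seed=int(sub[2]))
    return simulate_rts(filled, params)


def applicable_measures(experiment_id: int) -> list[str]:
    """Measures defined for an experiment (SRT supports only general skill)."""
    if experiment_id == 1:
        return ["general_skill"]
    return list(MEASURES)


def decompose(
    labeled: pd.DataFrame,
    measure: str,
    block_filter: str = "all_blocks",
    random_gap_policy: str = "exclude",
    min_trials: int = 1,
) -> pd.DataFrame:
    """Online/offline/long-offline gains for one measure, tidy table."""
    binned = bin_blocks(labeled) if "bin" not in labeled.columns else labeled
    btab = bin_scores(binned, min_trials=min_trials)
    deltas = measures.online_offline(
        btab, measure, block_filter=block_filter,
        random_gap_policy=random_gap_policy,
    )
    lo = measures.long_offline(btab, measure)
    if lo.empty:
        return deltas
    return pd.concat([deltas, lo], ignore_index=True)


def analyze(
    labeled: pd.DataFrame,
    block_filter: str = "all_blocks",
    random_gap_policy: str = "exclude",
    min_trials: int = 1,
) -> dict:
    """Full inference report for a labeled log (nested JSON-ready dict).

    Per applicable measure: RM-ANOVA over blocks, Spearman trend of the group
    block means, and t tests on online/offline (and long-offline) gains.
    """
    experiment_id = int(labeled["experiment_id"].iloc[0])
    btab_block = block_scores(labeled, min_trials=min_trials)
    binned = bin_blocks(labeled)
    btab_bin = bin_scores(binned, min_trials=min_trials)

    report: dict = {"experiment_id": experiment_id, "block_filter": block_filter,
                    "measures": {}}
    for measure in applicable_measures(experiment_id):
        column, _ = MEASURES[measure]
        entry: dict = {}
        try:
            entry["rm_anova"] = inference.rm_anova_block(btab_block, measure).as_dict()
        except inference.InferenceError as exc:
            entry["rm_anova"] = {"error": str(exc)}
        analyzable = btab_block[~btab_block["is_random_block"].astype(bool)]
        blk_means = analyzable.groupby(["session", "block"])[column].mean()
        try:
            entry["spearman_trend"] = inference.spearman_trend(
                blk_means.to_numpy()
            ).as_dict()
        except inference.InferenceError as exc:
            entry["spearman_trend"] = {"error": str(exc)}

        deltas = measures.online_offline(
            btab_bin, measure, block_filter=block_filter,
            random_gap_policy=random_gap_policy,
        )
        try:
            tests = inference.test_deltas(deltas)
            entry["gains"] = {k: v.as_dict() for k, v in tests.items()}
        except inference.InferenceError as exc:
            entry["gains"] = {"error": str(exc)}

        lo = measures.long_offline(btab_bin, measure)
        if not lo.empty:
            lo_means = measures.subject_delta_means(lo)["long_offline"]
            try:
                entry["long_offline"] = inference._one_sample(
                    lo_means, "long_offline"
                ).as_dict()
            except inference.InferenceError as exc:
                entry["long_offline"] = {"error": str(exc)}
        report["measures"][measure] = entry
    return report
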