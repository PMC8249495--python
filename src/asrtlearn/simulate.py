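"""Generative reaction-time model for SRT/ASRT trial streams.

Fills the random cue positions of a design and simulates per-trial reaction
times from an additive model with separately injectable online (within-block)
and offline (between-rest) components, so the downstream pipeline can be
validated by parameter recovery:

``RT = baseline - skill(rests so far) + fatigue * (bin - 1)
      - stat_gap (high-probability targets) - rule_gap (pattern trials) + noise``

* the *skill* term jumps by ``skill_gain_per_rest`` at every between-block rest
  (general skill improves offline);
* the *fatigue* term rises linearly over the five within-block bins on all
  trial types equally (general speed worsens online);
* the *statistical gap* (random-low minus random-high RT) grows during
  practice and shrinks at rests;
* the *rule gap* (random-high minus pattern RT) grows at rests and shrinks
  during practice.

All deterministic components are constant within a bin, so with zero noise the
bin-level learning scores equal the injected gaps exactly.  Noise is
mean-zero shifted log-normal by default (right-skewed, like empirical RT
distributions) with a millisecond-scale standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import (
    ASRT_BIN_TRIALS,
    ASRT_WARMUP_TRIALS,
    EXPERIMENT_LAYOUTS,
    ROLE_PATTERN,
    ROLE_RANDOM_FILL,
    SRT_BIN_TRIALS,
    infer_patterns,
)

__all__ = ["RTModelParams", "ParameterError", "fill_random_positions", "simulate_rts"]

#: Hard floor on simulated reaction times (ms); RTs are clipped to stay positive.
RT_FLOOR_MS = 1.0

#: Log-scale sigma of the unit noise shape (fixed skewness; the ms-scale
#: spread is controlled by ``noise_sigma``).
_LOGNORMAL_SHAPE = 0.6


class ParameterError(ValueError):
    """Raised when RT-model parameters violate their invariants."""


@dataclass(frozen=True)
class RTModelParams:
    """Parameters of the generative RT model (all RT quantities in ms).

    Defaults encode the effect placement and magnitudes of the study
    conditions this package emulates: within-block fatigue of 6 ms per bin
    (an online general-skill *loss* of 24 ms per block), a 0.5 ms
    general-skill jump at each rest (about 100 ms total improvement over the
    longest, 200-block design, keeping RT far from its floor), a statistical
    gap oscillating around 20 ms (5 ms online growth per block, 5 ms decay at
    each rest), a rule gap oscillating around 10 ms (3 ms growth at each
    rest, 3 ms decay per practiced block), and 65 ms trial noise, calibrated
    so that the between-subject dispersion of the block-averaged
    difference-score gains in the long (200-block) layout lands on the
    6-7 ms scale reported for such tasks.
    """

    baseline_rt: float = 400.0
    skill_gain_per_rest: float = 0.5
    fatigue_slope: float = 6.0
    stat_effect_online_per_block: float = 5.0
    stat_decay_per_rest: float = 5.0
    rule_effect_per_rest: float = 3.0
    rule_decay_online_per_block: float = 3.0
    noise_sigma: float = 65.0
    noise_family: str = "lognormal"
    error_rate: float = 0.05
    seed: int = 0
    # initial (already-acquired) triplet-type gaps at the first block (ms)
    stat_gap_initial: float = 20.0
    rule_gap_initial: float = 10.0
    # multipliers on rest-driven effects at session boundaries / long breaks
    session_rest_multiplier: float = 1.0
    long_break_multiplier: float = 1.0

    def validate(self) -> None:
        if not self.baseline_rt > 0:
            raise ParameterError("baseline_rt must be > 0")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ParameterError("error_rate must be in [0, 1)")
        if self.noise_family not in ("lognormal", "normal"):
            raise ParameterError(f"unknown noise_family {self.noise_family!r}")

    def null(self) -> "RTModelParams":
        """Copy with every learning/fatigue effect set to zero (noise kept)."""
        return replace(
            self,
            skill_gain_per_rest=0.0,
            fatigue_slope=0.0,
            stat_effect_online_per_block=0.0,
            stat_decay_per_rest=0.0,
            rule_effect_per_rest=0.0,
            rule_decay_online_per_block=0.0,
            stat_gap_initial=0.0,
            rule_gap_initial=0.0,
        )


def fill_random_positions(design: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Draw uniform cue positions for every random-role trial.

    Warm-up, random-fill and random-block trials get independent uniform draws
    over {1,2,3,4}; pattern positions are untouched.  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = design.copy()
    mask = (out["role"] != ROLE_PATTERN).to_numpy()
    out.loc[mask, "position"] = rng.integers(1, 5, size=int(mask.sum())).astype(float)
    return out


def _bin_index(trial: np.ndarray, experiment_id: int) -> np.ndarray:
    """Within-block bin (1..5) per trial; ASRT warm-ups are assigned bin 1."""
    if experiment_id == 1:
        return (trial - 1) // SRT_BIN_TRIALS + 1
    k = (trial - ASRT_WARMUP_TRIALS - 1) // ASRT_BIN_TRIALS + 1
    return np.clip(k, 1, None)


def _rest_multipliers(experiment_id: int, n_sessions: int, n_blocks: int,
                      params: RTModelParams) -> np.ndarray:
    """Multiplier on rest-driven effects for each between-block gap.

    Gap g separates global blocks g and g+1 (g = 0..G-2).  Session boundaries
    use ``session_rest_multiplier``; the two long questionnaire breaks of
    Experiment 2 (after blocks 15 and 30) use ``long_break_multiplier``;
    ordinary rests use 1.
    """
    n_gaps = n_sessions * n_blocks - 1
    mult = np.ones(n_gaps)
    # session boundaries: after block n_blocks, 2*n_blocks, ...
    for s in range(1, n_sessions):
        mult[s * n_blocks - 1] = params.session_rest_multiplier
    if experiment_id == 2:
        for b in (15, 30):
            if b <= n_gaps:
                mult[b - 1] = params.long_break_multiplier
    return mult


def _gap_trajectories(n_blocks_total: int, mult: np.ndarray, params: RTModelParams
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-global-block start values of the statistical and rule gaps."""
    s_start = np.zeros(n_blocks_total)
    r_start = np.zeros(n_blocks_total)
    s = max(0.0, params.stat_gap_initial)
    r = max(0.0, params.rule_gap_initial)
    for g in range(n_blocks_total):
        s_start[g] = s
        r_start[g] = r
        if g < n_blocks_total - 1:
            s = max(0.0, s + params.stat_effect_online_per_block
                    - params.stat_decay_per_rest * mult[g])
            r = max(0.0, r - params.rule_decay_online_per_block
                    + params.rule_effect_per_rest * mult[g])
    return s_start, r_start


def simulate_rts(filled_design: pd.DataFrame, params: RTModelParams) -> pd.DataFrame:
    """Simulate reaction times and response correctness for a filled design.

    Requires every cue position to be set (see :func:`fill_random_positions`).
    Returns a complete trial log; RTs are clipped at a 1 ms floor, correctness
    is Bernoulli(1 - error_rate) independently of condition.
    """
    params.validate()
    if filled_design["position"].isna().any():
        raise ParameterError("design has unset cue positions; call fill_random_positions first")

    df = filled_design.copy()
    experiment_id = int(df["experiment_id"].iloc[0])
    n_sessions, n_blocks, _ = EXPERIMENT_LAYOUTS[experiment_id]
    n_blocks_total = n_sessions * n_blocks

    trial = df["trial"].to_numpy()
    session = df["session"].to_numpy()
    block = df["block"].to_numpy()
    role = df["role"].to_numpy()
    position = df["position"].to_numpy().astype(np.int64)

    g = (session - 1) * n_blocks + (block - 1)          # global block index
    k = _bin_index(trial, experiment_id)                 # within-block bin 1..5

    mult = _rest_multipliers(experiment_id, n_sessions, n_blocks, params)
    skill_cum = np.concatenate(
        [[0.0], np.cumsum(params.skill_gain_per_rest * mult)]
    )  # cumulative skill gain before each global block

    det = params.baseline_rt - skill_cum[g] + params.fatigue_slope * (k - 1)

    if experiment_id != 1:
        s_start, r_start = _gap_trajectories(n_blocks_total, mult, params)
        s_gap = np.maximum(
            0.0, s_start[g] + params.stat_effect_online_per_block * (k - 1) / 4.0
        )
        r_gap = np.maximum(
            0.0, r_start[g] - params.rule_decay_online_per_block * (k - 1) / 4.0
        )
        # high-probability targets: pattern trials, and random fills whose
        # triplet (n-2 -> n) follows the subject's transition map
        patterns = infer_patterns(df)
        subjects, subj_idx = np.unique(df["subject_id"].to_numpy(), return_inverse=True)
        tmap = np.zeros((len(subjects), 5), dtype=np.int64)
        for i, s_id in enumerate(subjects):
            tmap[i] = patterns[int(s_id)].transition_array()
        first = np.roll(position, 2)
        has_context = trial >= 3  # triplets never span block boundaries
        conforming = has_context & (tmap[subj_idx, np.where(has_context, first, 1)]
                                    == position)
        is_pattern = role == ROLE_PATTERN
        is_high = is_pattern | ((role == ROLE_RANDOM_FILL) & conforming)
        det = det - s_gap * is_high - r_gap * is_pattern

    rng = np.random.default_rng(params.seed)
    n = len(df)
    if params.noise_sigma > 0:
        z = rng.standard_normal(n)
        if params.noise_family == "lognormal":
            shape = _LOGNORMAL_SHAPE
            x = np.exp(shape * z)
            m1 = np.exp(shape**2 / 2)
            sd1 = np.sqrt((np.exp(shape**2) - 1) * np.exp(shape**2))
            noise = params.noise_sigma * (x - m1) / sd1
        else:
            noise = params.noise_sigma * z
    else:
        noise = 0.0

    df["rt_ms"] = np.maximum(det + noise, RT_FLOOR_MS)
    df["correct"] = (rng.random(n) >= params.error_rate).astype(float)
    return df
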