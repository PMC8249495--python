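# Methods

## Task structure and trial taxonomy

The package analyses four-choice serial reaction time data.  In the **SRT**
task every block replays a fixed 12-element sequence of cue positions
(`2-3-1-4-3-2-4-1-3-4-2-1`, five repetitions per 60-trial block); designated
blocks replace it with fully random cues.  In the **ASRT** task each 85-trial
block opens with five random warm-up trials followed by ten repetitions of an
8-element stream in which every second cue is a fixed 4-element pattern and
the intervening cues are uniform random draws.  Patterns are permutations of
the four positions; rotations of a pattern generate the same stimulus
statistics, so there are 4!/4 = 6 distinct classes, represented canonically
by their lexicographically smallest rotation and assigned to subjects by a
seeded shuffle cycling through the six classes.

Every trial ends a *triplet* (trials n-2, n-1, n).  The pattern's two-apart
transition map sends each position to the pattern element two trials later;
a triplet whose first and third elements follow the map is
**high-probability** (62.5% of continuations per first element in the
stationary alternating stream), any other continuation is **low-probability**
(12.5% each).  Trials are labeled `pattern` (predetermined element),
`random_high` or `random_low` (random elements ending high/low triplets), or
excluded with exactly one reason: warm-up, random block, missing within-block
context, wrong response, repetition (XXX) or trill (XYX).  Repetitions and
trills are provably low-probability under every pattern class (a 4-cycle has
no fixed point) and are removed because of pre-existing response tendencies.

Three labeling conventions deserve note, all chosen where the protocol is
genuinely open:

* **Triplet context never crosses a block boundary** (blocks are separated by
  rests and all measures are within-block), so each block's first two stream
  trials have no context.
* **Warm-up and error trials serve as context** for later trials while being
  excluded as targets: the stimulus stream, not the response, carries the
  transitional statistics.
* **Categories are role-based.**  A block's first pattern trial (trial 6) has
  warm-up context and factually ends a high triplet only ~1/4 of the time; it
  is still a `pattern` trial (a predetermined element ending a triplet).  The
  labeled log carries the factual conformity separately (`triplet_high`).
  SRT trials receive no triplet labels and support only the general-skill
  measure.

## Learning measures and decomposition

Per cell (block, or one of five within-block bins):

* general skill: mean RT over included trials (ASRT also over `random_low`
  only, which strips all predictable structure);
* statistical learning: RT(random_low) − RT(random_high);
* high-order rule learning: RT(random_high) − RT(pattern).

Bins are positional — 12 trials (one sequence) in SRT, 16 trials (two
8-element repetitions) in ASRT, warm-ups unbinned — so exclusions thin bins
without moving their boundaries.  A difference score is missing wherever a
constituent category has fewer than `min_trials` (default 1) trials; subjects
drop from a contrast only when a needed cell is missing, mirroring the
reduced degrees of freedom such analyses show in practice.

**Online** learning of a block is score(last bin) − score(first bin);
**offline** learning of a rest is score(first bin of the next block) −
score(last bin of the previous block); **long-offline** learning spans
session gaps (first analyzable block of the next session vs last analyzable
block of the previous one).  General-skill deltas are negated so learning is
positive for every measure.  In the SRT experiment the random blocks are
removed and, by default, the rests adjacent to a removed block are excluded
from offline averaging (`random_gap_policy="exclude"`); bridging them into
one longer gap is available as `"bridge"` since the original protocol is
silent.  The `first_blocks_of_sessions` filter restricts to each session's
first block and the rest that follows it (the fatigue-free case).  When no
delta is missing, the decomposition telescopes exactly:
Σ online + Σ offline = end − start per session.

## Group inference

Repeated-measures ANOVA over blocks (one-way on mean RT for general skill;
two-way block × triplet-type with the interaction reported for the
difference measures), Greenhouse–Geisser-corrected p values (univariate RM
with GG is assumed; the correction can only raise p).  Listwise deletion for
ANOVA; subjects keep their delta-test entries whenever their mean delta
exists.  A Spearman rank correlation between group block means and block
position serves as a trend check.  One-sample two-tailed t tests against
zero assess online and offline gains; a paired t compares rest vs practice
(offline − online).  Cohen's d = mean/SD of the tested values, so
|d| = |t|/√n exactly.  Two-tailed tests throughout, no multiplicity
correction (planned contrasts).  ANOVA and GG correction are delegated to
`pingouin.rm_anova`; tests verify the F statistics against hand-computed
sums-of-squares oracles to 6 decimals.

## Generative model

The synthetic generator fills random cue positions uniformly and simulates

```
RT = baseline − skill(rests so far) + fatigue·(bin−1)
     − stat_gap (high-probability targets) − rule_gap (pattern trials) + noise
```

with all deterministic components constant within a bin, so zero-noise runs
reproduce the injected gaps exactly at every bin.  The two difference-score
gaps follow floored linear recurrences: the statistical gap grows by
`stat_effect_online_per_block` across a block's five bins and shrinks by
`stat_decay_per_rest` at each rest; the rule gap does the reverse.  Rest
effects at session boundaries and at the long mid-session breaks of the
45-block layout can be scaled by multipliers (default 1: all rests pooled).

Defaults (ms): baseline 400; fatigue 6 per bin (an online general-skill loss
of 24 per block); skill jump 0.5 per rest — deliberately small so that the
across-block improvement stays ~100 ms over the longest 200-block design and
the deterministic RT never approaches the 1 ms floor; statistical gap
oscillating around an initial 20 (+5 online / −5 per rest); rule gap around
an initial 10 (+3 per rest / −3 online); error rate 0.05, independent of
condition so recovery tests stay unconfounded.  Noise is mean-zero shifted
log-normal (fixed log-scale shape 0.6 for realistic right skew; the normal
family is available), with `noise_sigma = 65`, calibrated so the
between-subject SD of the block-averaged difference-score gains in the
200-block layout lands at 6–7 ms, the dispersion scale such studies report.
A useful side effect of the shifted log-normal is a bounded left tail, so
the RT floor never binds at these parameters.

What the generator does **not** model: between-subject heterogeneity in
baseline speed or learning rates (every simulated subject shares one
parameter set, so group t statistics on general skill run larger than in
real cohorts), saturating learning curves, sequence-specific SRT learning,
post-error slowing, and any speed–accuracy coupling.  Passing recovery tests
therefore show that the pipeline's estimators are unbiased and correctly
signed under the assumed effect placement — not that real data will show
effects of this size.

## Numerical and audit choices

* Triplet-probability audits enumerate within-block triplets whose context
  starts at trial ≥ 12.  An 85-trial block truncates the alternation: it has
  39 pattern-context trials (not a multiple of 4), which over-represents
  early pattern elements as triplet context and shifts the conditional
  continuation frequencies to ~63.0% / ~50.6%.  Starting the audit one
  8-element repetition into the block makes the pattern contexts span whole
  4-cycles, so the theoretical 62.5% / 12.5% / 50% hold exactly in
  expectation.  The audit denominator keeps error/trill/repetition trials
  (the stream presented them regardless of the response).
* RTs are clipped at a 1 ms floor; gap recurrences are floored at 0.
* Spearman trend on constant input and one-sample t with zero variance are
  flagged (`note`) rather than raised.
* Validation problem sizes: recovery runs 100 Monte-Carlo replicates of the
  long ASRT layout (25 subjects × 8 sessions × 25 blocks), the size at which
  the small rule effect is detectable; type-I calibration uses 500
  replicates of a 12-subject × 6-block null stream, since the error rate is
  size-free; the stream audit uses ~574k trials (Monte-Carlo SE ≈ 0.12
  percentage points).

## Known limitations

The analysis works in milliseconds end to end.  Real-data ingestion is
limited to the documented CSV schema (an adapter for any particular archive
is out of scope), accuracy-based measures and trial-level mixed models are
not provided, and the two-way ANOVA assumes the univariate RM error
structure.  Units in some published reports of such gains are ambiguous
between ms and s; this package standardizes on ms and makes no attempt to
resolve that ambiguity.
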