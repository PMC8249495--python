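import pandas as pd
import pytest

import asrtlearn as al


@pytest.fixture(scope="session")
def pattern_2134() -> al.PatternSpec:
    return al.PatternSpec((2, 1, 3, 4))


@pytest.fixture(scope="session")
def exp2_log(pattern_2134) -> pd.DataFrame:
    """Two simulated subjects of the single-session ASRT experiment."""
    design = al.build_design(2, pattern_spec=pattern_2134, subject_count=2)
    filled = al.fill_random_positions(design, seed=101)
    return al.simulate_rts(filled, al.RTModelParams(seed=202))


@pytest.fixture(scope="session")
def labeled_exp2(exp2_log, pattern_2134) -> pd.DataFrame:
    return al.label_trials(exp2_log, pattern_2134)


@pytest.fixture(scope="session")
def exp1_log() -> pd.DataFrame:
    """One simulated subject of the two-session SRT experiment."""
    design = al.build_design(1, subject_count=1)
    filled = al.fill_random_positions(design, seed=303)
    return al.simulate_rts(filled, al.RTModelParams(seed=404))
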