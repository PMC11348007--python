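import numpy as np
import pandas as pd
import pytest

from aperiodic import TaskDesign, generate_design


@pytest.fixture
def freqs():
    """1-Hz frequency grid covering the 3-35 Hz fit range."""
    return np.arange(1.0, 46.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    return TaskDesign(n_participants=3, n_trials=32, n_blocks=4)


@pytest.fixture
def small_trials(small_design):
    return generate_design(7, small_design)


def make_exponent_table(rng, n_subjects=10, effects=None, noise_sd=0.05,
                        base=3.4, subject_sd=0.2):
    """Long-format brain-wide exponent table with injected 2-level effects.

    ``effects`` maps factor name -> shift added at the factor's second
    level (alphabetically); noise is i.i.d. per cell.
    """
    effects = effects or {}
    # the shift in ``effects`` is added at the *second* level listed here
    levels = {"period": ["pre_trial", "within_trial"],
              "drug": ["placebo", "mph"],
              "prime": ["congruent", "incongruent"],
              "flanker": ["congruent", "incongruent"]}
    rows = []
    subj = rng.normal(0, subject_sd, n_subjects)
    for s in range(n_subjects):
        for per in levels["period"]:
            for drug in levels["drug"]:
                for prime in levels["prime"]:
                    for fl in levels["flanker"]:
                        v = base + subj[s] + rng.normal(0, noise_sd)
                        lev = {"period": per, "drug": drug, "prime": prime,
                               "flanker": fl}
                        for f, shift in effects.items():
                            if lev[f] == levels[f][1]:
                                v += shift
                        rows.append((s, per, drug, prime, fl, v))
    return pd.DataFrame(rows, columns=["participant", "period", "drug",
                                       "prime", "flanker", "exponent"])
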