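import numpy as np
import pandas as pd
import pytest

from metadrift.behavior import CohortData, drop_censored
from metadrift.cohort import GeneratorConfig, generate_cohort


def make_trials(rts_by_pid, responses_by_pid=None):
    """Deterministic trial table; cells interleave FM/NM x SC/OC."""
    rows = []
    fams = ("FM", "NM")
    ctxs = ("SC", "OC")
    for pid, rts in rts_by_pid.items():
        resp = responses_by_pid.get(pid) if responses_by_pid else None
        for j, rt in enumerate(rts):
            rows.append(
                {
                    "participant_id": pid,
                    "familiarity": fams[j % 2],
                    "context": ctxs[(j // 2) % 2],
                    "rt_s": float(rt),
                    "response": int(resp[j]) if resp is not None else 1,
                    "censored": 0,
                }
            )
    return pd.DataFrame(rows)


def make_covariates(pids, n_tests=7, rng=None):
    rng = rng or np.random.default_rng(0)
    names = ["ANT", "COWAT_Semantic", "COWAT_Phonemic", "GNG", "LNST", "Stroop", "WCST"][:n_tests]
    return pd.DataFrame(
        {name: rng.normal(10, 2, len(pids)) for name in names},
        index=pd.Index(list(pids), name="participant_id"),
    )


def make_cohort(rts_by_pid, responses_by_pid=None, rng=None):
    pids = list(rts_by_pid)
    return CohortData(
        trials=make_trials(rts_by_pid, responses_by_pid),
        covariates=make_covariates(pids, rng=rng),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """8 participants x 32 trials simulated from the default truth."""
    cfg = GeneratorConfig(n_participants=8, trials_per_cell=8, seed=42, dt=5e-4)
    cohort, truth = generate_cohort(cfg)
    return drop_censored(cohort), truth


@pytest.fixture(scope="session")
def default_cohort():
    """Full study-scale cohort: 38 participants x 124 trials."""
    cohort, truth = generate_cohort(GeneratorConfig(seed=1234))
    return cohort, truth
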