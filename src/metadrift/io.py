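"""Reading and writing the cohort file formats.

On-disk schema (all plain CSV):

* trials: participant_id (string), familiarity (FM|NM), context (SC|OC),
  rt_s (float, seconds), response (1 correct / 0 error), censored (0|1).
* covariates: participant_id plus one column per neuropsychological test.

RTs are stored in seconds; milliseconds appear only in human-readable
summaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .behavior import CohortData

__all__ = ["read_cohort", "write_cohort", "write_ledger"]

_VALID = {"familiarity": {"FM", "NM"}, "context": {"SC", "OC"}}


def read_cohort(trials_path, covariates_path) -> CohortData:
    """Load a cohort from trial and covariate CSVs, validating the schema.

    Schema violations are reported with the offending row numbers
    (1-based, excluding the header).
    """
    trials = pd.read_csv(trials_path, dtype={"participant_id": str})
    if "censored" not in trials.columns:
        trials["censored"] = 0
    problems = []
    for col, allowed in _VALID.items():
        if col not in trials.columns:
            problems.append(f"missing column {col!r}")
            continue
        bad = ~trials[col].isin(allowed)
        if bad.any():
            rows = (trials.index[bad] + 1).tolist()[:10]
            problems.append(f"invalid {col} values at rows {rows}")
    if "rt_s" in trials.columns:
        bad = ~(trials["rt_s"] > 0)
        if bad.any():
            rows = (trials.index[bad] + 1).tolist()[:10]
            problems.append(f"non-positive rt_s at rows {rows}")
    else:
        problems.append("missing column 'rt_s'")
    if "response" in trials.columns:
        bad = ~trials["response"].isin((0, 1))
        if bad.any():
            rows = (trials.index[bad] + 1).tolist()[:10]
            problems.append(f"response must be 0 or 1; bad rows {rows}")
    else:
        problems.append("missing column 'response'")
    if problems:
        raise ValueError(f"trial table {trials_path}: " + "; ".join(problems))

    cov = pd.read_csv(covariates_path, dtype={"participant_id": str})
    if "participant_id" not in cov.columns:
        raise ValueError(f"covariate table {covariates_path}: missing participant_id")
    cov = cov.set_index("participant_id")
    return CohortData(trials=trials, covariates=cov)


def write_cohort(cohort: CohortData, outdir) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials_path = outdir / "trials.csv"
    cov_path = outdir / "covariates.csv"
    cohort.trials.to_csv(trials_path, index=False)
    cohort.covariates.to_csv(cov_path, index=True, index_label="participant_id")
    return trials_path, cov_path


def write_ledger(cohort: CohortData, path) -> None:
    Path(path).write_text(
        json.dumps([e.to_dict() for e in cohort.accounting], indent=2) + "\n"
    )
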