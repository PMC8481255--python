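"""Classical behavioral pipeline for the 2x2 two-choice comprehension task.

Implements the conventional analysis chain applied before (and alongside)
the diffusion modelling: outlier exclusion with full accounting, condition
descriptives, the 2x2 within-subject ANOVA, Bonferroni-corrected pairwise
comparisons, the z-scored Pearson correlation table between reaction times
and neuropsychological test scores, and a summary-statistic Welch t-test.

Reaction times are stored in seconds throughout; human-readable summaries
report milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CohortData",
    "LedgerEntry",
    "AnovaResult",
    "CorrelationTable",
    "PipelineHaltError",
    "exclude_participants",
    "exclude_trials",
    "drop_censored",
    "condition_summaries",
    "cell_mean_table",
    "rm_anova_2x2",
    "pairwise_bonferroni",
    "correlation_table",
    "welch_t_from_summary",
]

#: the four condition cells, in the display order used throughout
CONDITIONS = ("SC-FM", "OC-FM", "SC-NM", "OC-NM")

#: the four pairwise contrasts displayed in the descriptive figure
DEFAULT_PAIRS = (
    ("SC-FM", "SC-NM"),
    ("OC-FM", "OC-NM"),
    ("SC-FM", "OC-FM"),
    ("SC-NM", "OC-NM"),
)

TRIAL_COLUMNS = ["participant_id", "familiarity", "context", "rt_s", "response", "censored"]


class PipelineHaltError(RuntimeError):
    """Raised when an exclusion rule would empty the cohort."""


@dataclass
class LedgerEntry:
    """One exclusion-accounting record: what was removed, and how much."""

    rule: str
    trials_before: int
    trials_after: int
    participants_removed: int = 0

    @property
    def trials_removed(self) -> int:
        return self.trials_before - self.trials_after

    @property
    def percent_removed(self) -> float:
        return self.trials_removed / self.trials_before * 100.0

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "trials_before": self.trials_before,
            "trials_after": self.trials_after,
            "trials_removed": self.trials_removed,
            "participants_removed": self.participants_removed,
            "percent_removed": round(self.percent_removed, 2),
        }


@dataclass
class CohortData:
    """Per-trial records, per-participant covariates, and an exclusion ledger.

    ``trials`` columns: participant_id, familiarity (FM|NM), context (SC|OC),
    rt_s (seconds), response (1 correct / 0 error), censored (0|1).
    ``covariates`` is indexed by participant_id with one column per test.
    """

    trials: pd.DataFrame
    covariates: pd.DataFrame
    accounting: list[LedgerEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table is missing columns: {missing}")
        trial_pids = set(self.trials["participant_id"])
        if not trial_pids <= set(self.covariates.index):
            raise ValueError("every trial participant must appear in the covariate table")

    @property
    def participants(self) -> list:
        return list(self.covariates.index[self.covariates.index.isin(self.trials["participant_id"])])

    @property
    def n_participants(self) -> int:
        return self.trials["participant_id"].nunique()

    def condition_labels(self) -> pd.Series:
        return self.trials["context"].astype(str) + "-" + self.trials["familiarity"].astype(str)

    def replace_trials(self, trials: pd.DataFrame, entry: LedgerEntry | None = None) -> "CohortData":
        ledger = list(self.accounting) + ([entry] if entry is not None else [])
        cov = self.covariates.loc[self.covariates.index.isin(trials["participant_id"])]
        return CohortData(trials=trials.reset_index(drop=True), covariates=cov, accounting=ledger)


def drop_censored(cohort: CohortData) -> CohortData:
    """Remove censored (no-response-before-deadline) trials, with accounting."""
    keep = cohort.trials["censored"] == 0
    entry = LedgerEntry(
        rule="censored",
        trials_before=len(cohort.trials),
        trials_after=int(keep.sum()),
    )
    return cohort.replace_trials(cohort.trials.loc[keep], entry)


def exclude_participants(cohort: CohortData) -> tuple[CohortData, LedgerEntry]:
    """Drop participants whose mean RT or mean test score is a 3-SD outlier.

    A participant is removed when their mean RT across trials, or their mean
    across the test battery (each test z-scored first so the scales are
    commensurable), lies strictly more than 3 standard deviations from the
    respective cohort mean.  All their trials go with them.
    """
    pids = cohort.trials["participant_id"].unique()
    if len(pids) < 3:
        raise ValueError("participant screening needs at least 3 participants")

    mean_rt = cohort.trials.groupby("participant_id")["rt_s"].mean().loc[pids]
    cov = cohort.covariates.loc[pids]
    z = (cov - cov.mean()) / cov.std(ddof=1)
    mean_score = z.mean(axis=1)

    flagged = set()
    for metric in (mean_rt, mean_score):
        sd = metric.std(ddof=1)
        if sd > 0:
            dev = (metric - metric.mean()).abs()
            flagged |= set(metric.index[dev > 3.0 * sd])

    keep_trials = ~cohort.trials["participant_id"].isin(flagged)
    if not keep_trials.any():
        raise PipelineHaltError("participant screening removed the entire cohort")
    entry = LedgerEntry(
        rule="participant_3sd",
        trials_before=len(cohort.trials),
        trials_after=int(keep_trials.sum()),
        participants_removed=len(flagged),
    )
    return cohort.replace_trials(cohort.trials.loc[keep_trials], entry), entry


def exclude_trials(cohort: CohortData) -> tuple[CohortData, LedgerEntry]:
    """Drop per-participant 3-SD outlier RTs (single pass).

    The mean and SD are computed per participant on that participant's
    current trials, outlier candidates included; a trial is removed when its
    RT deviates strictly more than 3 SDs from the participant mean.
    Participants with zero RT spread lose no trials.
    """
    g = cohort.trials.groupby("participant_id")["rt_s"]
    if g.size().min() < 3:
        raise ValueError("trial screening needs at least 3 trials per participant")
    m = g.transform("mean")
    s = g.transform("std")  # ddof=1
    keep = ~((cohort.trials["rt_s"] - m).abs() > 3.0 * s.fillna(0.0))
    entry = LedgerEntry(
        rule="trial_3sd",
        trials_before=len(cohort.trials),
        trials_after=int(keep.sum()),
    )
    return cohort.replace_trials(cohort.trials.loc[keep], entry), entry


def cell_mean_table(cohort: CohortData, dependent: str = "rt") -> pd.DataFrame:
    """Participant x condition table of cell means.

    ``dependent="rt"`` gives mean correct-trial RT in seconds;
    ``dependent="accuracy"`` gives the proportion correct.
    """
    trials = cohort.trials.copy()
    trials["condition"] = cohort.condition_labels()
    if dependent == "rt":
        data = trials.loc[trials["response"] == 1]
        table = data.pivot_table(index="participant_id", columns="condition", values="rt_s", aggfunc="mean")
    elif dependent == "accuracy":
        table = trials.pivot_table(index="participant_id", columns="condition", values="response", aggfunc="mean")
    else:
        raise ValueError(f"unknown dependent {dependent!r}")
    return table.reindex(columns=list(CONDITIONS))


def condition_summaries(cohort: CohortData) -> pd.DataFrame:
    """Condition-wise and marginal mean RT (ms, correct trials) and accuracy (%).

    Participant cell means are computed first; the across-participant mean
    and SEM (SD / sqrt(n)) of those are reported.  Marginal rows (FM, NM,
    SC, OC) average the two constituent cell means within each participant
    before aggregating.  Participants lacking a correct trial in a cell are
    excluded from that cell's RT summary.
    """
    rt = cell_mean_table(cohort, "rt") * 1000.0
    acc = cell_mean_table(cohort, "accuracy") * 100.0
    rows = {}
    margins = {"FM": ("SC-FM", "OC-FM"), "NM": ("SC-NM", "OC-NM"),
               "SC": ("SC-FM", "SC-NM"), "OC": ("OC-FM", "OC-NM")}
    frames = {c: (rt[c], acc[c]) for c in CONDITIONS}
    frames.update({m: (rt[list(cols)].mean(axis=1), acc[list(cols)].mean(axis=1))
                   for m, cols in margins.items()})
    for label, (r, a) in frames.items():
        r = r.dropna()
        rows[label] = {
            "mean_rt_ms": r.mean(),
            "sem_rt_ms": r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else 0.0,
            "accuracy_pct": a.mean(),
            "sem_accuracy_pct": a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0,
            "n_participants": len(r),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "condition"
    return out


@dataclass
class AnovaResult:
    """F tests for the two main effects and their interaction, df = (1, n-1)."""

    effects: pd.DataFrame  # index: FAMILIARITY, CONTEXT, interaction

    def __getitem__(self, effect: str) -> pd.Series:
        return self.effects.loc[effect]


def rm_anova_2x2(cell_means: pd.DataFrame) -> AnovaResult:
    """Two-way fully repeated-measures ANOVA on a participant x 4-cell table.

    For two-level within-subject factors every effect is carried by one
    contrast per participant, so each F equals the squared one-sample t of
    that contrast with df (1, n-1) — the standard MS_effect / MS_effect-by-
    subject decomposition.
    """
    table = cell_means[list(CONDITIONS)].dropna()
    if table.isna().any().any() or len(table) < 2:
        raise ValueError("rm_anova_2x2 requires complete cells for at least 2 participants")
    y = table.to_numpy()
    sc_fm, oc_fm, sc_nm, oc_nm = y.T
    contrasts = {
        "FAMILIARITY": (sc_fm + oc_fm - sc_nm - oc_nm) / 2.0,
        "CONTEXT": (oc_fm + oc_nm - sc_fm - sc_nm) / 2.0,
        "interaction": (sc_fm - oc_fm - sc_nm + oc_nm),
    }
    n = len(table)
    rows = {}
    for name, c in contrasts.items():
        se = c.std(ddof=1) / np.sqrt(n)
        f = (c.mean() / se) ** 2 if se > 0 else 0.0
        rows[name] = {
            "F": f,
            "df_num": 1,
            "df_den": n - 1,
            "p": float(sps.f.sf(f, 1, n - 1)),
        }
    return AnovaResult(effects=pd.DataFrame(rows).T)


def pairwise_bonferroni(cell_means: pd.DataFrame, pairs=DEFAULT_PAIRS) -> pd.DataFrame:
    """Paired two-sided t-tests, Bonferroni-corrected over the given pairs."""
    table = cell_means.dropna()
    k = len(pairs)
    rows = []
    for a, b in pairs:
        d = (table[a] - table[b]).to_numpy()
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        elif d.std(ddof=1) == 0:
            raise ValueError(f"zero-variance difference vector for pair {a} vs {b}")
        else:
            t, p = sps.ttest_rel(table[a], table[b])
        rows.append({"pair": f"{a} vs {b}", "t": float(t), "df": len(d) - 1,
                     "p_raw": float(p), "p_adjusted": min(1.0, float(p) * k)})
    return pd.DataFrame(rows).set_index("pair")


@dataclass
class CorrelationTable:
    """Pearson correlations between test scores and condition-wise mean RTs."""

    r: pd.DataFrame      # tests x conditions
    p: pd.DataFrame
    stars: pd.DataFrame  # '', '*', '**', '***' at 0.05 / 0.01 / 0.001 (uncorrected)
    n: int


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(cohort: CohortData) -> CorrelationTable:
    """Correlate each test score with mean correct RT in each condition.

    Both vectors are z-scored across participants first (which leaves
    Pearson r unchanged but matches the reporting convention); two-sided p
    comes from the t transform with n - 2 degrees of freedom.  Zero-variance
    vectors yield undefined (NaN) cells.
    """
    rt = cell_mean_table(cohort, "rt")
    common = rt.dropna().index.intersection(cohort.covariates.dropna().index)
    if len(common) < 4:
        raise ValueError("correlation table needs at least 4 participants with complete data")
    rt = rt.loc[common]
    cov = cohort.covariates.loc[common]
    n = len(common)

    def zs(x):
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else x * np.nan

    r = pd.DataFrame(index=cov.columns, columns=CONDITIONS, dtype=float)
    p = r.copy()
    for test in cov.columns:
        zx = zs(cov[test])
        for cond in CONDITIONS:
            zy = zs(rt[cond])
            if zx.isna().all() or zy.isna().all():
                continue
            rv = float((zx * zy).sum() / (n - 1))
            rv = max(-1.0, min(1.0, rv))
            r.loc[test, cond] = rv
            if abs(rv) == 1.0:
                p.loc[test, cond] = 0.0
            else:
                t = rv * np.sqrt((n - 2) / (1.0 - rv * rv))
                p.loc[test, cond] = 2.0 * float(sps.t.sf(abs(t), n - 2))
    stars = p.map(_stars)
    return CorrelationTable(r=r, p=p, stars=stars, n=n)


def welch_t_from_summary(m1: float, sem1: float, n1: int, m2: float, sem2: float, n2: int):
    """Welch t and Welch-Satterthwaite df from group summaries.

    ``t = (m1 - m2) / sqrt(sem1^2 + sem2^2)``; the df follow the standard
    Satterthwaite approximation with the squared SEMs as the per-group
    variance-of-the-mean terms.
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("standard errors must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    q1, q2 = sem1 ** 2, sem2 ** 2
    t = (m1 - m2) / np.sqrt(q1 + q2)
    df = (q1 + q2) ** 2 / (q1 ** 2 / (n1 - 1) + q2 ** 2 / (n2 - 1))
    return float(t), float(df)
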