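"""Hierarchical Bayesian inference for the condition-dependent diffusion model.

Model families
--------------
* ``null`` — every decision parameter is condition-constant: per-participant
  drift intercept, boundary separation and non-decision time, drawn from
  group-level Normal distributions; shared inter-trial variabilities
  ``sv``/``st``; the starting point is fixed at 0.5 (accuracy coding).
* ``fc`` — adds condition effects on drift only: participant i's drift in
  condition j is ``v_i + bF_i * F_j + bC_i * C_j`` with effect coding
  F (familiar +0.5 / novel -0.5) and C (opposing +0.5 / supporting -0.5),
  so the group means of bF and bC are the familiar-minus-novel and
  opposing-minus-supporting drift differences.
* ``full`` — additionally regresses one between-subject covariate (a
  z-scored test score) on drift, boundary and non-decision time via
  population-level slopes.  Subject-level slopes are not identifiable from
  one score per participant.

Boundary separation and non-decision time are condition-constant within a
participant; condition differences are carried by drift alone.

Sampling is Metropolis-within-Gibbs: single-site Gaussian random-walk
proposals for every node, with per-node step sizes adapted toward a
0.3-0.5 acceptance rate during burn-in and frozen afterwards.  Participants
are conditionally independent given the group level, so the subject-level
updates are proposed and accepted per participant in one vectorized pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import wiener as W
from .behavior import CohortData

__all__ = [
    "FAM_CODE",
    "CTX_CODE",
    "Prior",
    "default_priors",
    "ModelSpec",
    "HierarchicalModel",
    "SamplerState",
    "PosteriorSamples",
    "EffectSummary",
    "FitResult",
    "build_model",
    "log_posterior",
    "sample",
    "geweke_z",
    "dic",
    "hdi",
    "effect_summary",
    "posterior_predictive",
    "fit_model",
    "compare_models",
    "DegenerateChainError",
]

FAM_CODE = {"FM": 0.5, "NM": -0.5}
CTX_CODE = {"OC": 0.5, "SC": -0.5}

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prior:
    """One prior: distribution family, hyperparameters, support bounds."""

    family: str            # normal | halfnormal | gamma | truncnormal0
    params: tuple
    low: float = -np.inf
    high: float = np.inf

    def logpdf(self, x: float) -> float:
        if not (self.low <= x <= self.high) or not np.isfinite(x):
            return -np.inf
        if self.family == "normal":
            mu, sd = self.params
            return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI
        if self.family == "truncnormal0":
            if x < 0:
                return -np.inf
            mu, sd = self.params
            # normalizer: P(X > 0) for the untruncated normal
            log_norm = math.log(0.5 * math.erfc(-mu / (sd * math.sqrt(2.0))))
            return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI - log_norm
        if self.family == "halfnormal":
            (sd,) = self.params
            if x < 0:
                return -np.inf
            return -0.5 * (x / sd) ** 2 - math.log(sd) + math.log(2.0) - 0.5 * _LOG_2PI
        if self.family == "gamma":
            shape, scale = self.params
            if x <= 0:
                return -np.inf
            return (
                (shape - 1.0) * math.log(x) - x / scale
                - math.lgamma(shape) - shape * math.log(scale)
            )
        raise ValueError(f"unknown prior family {self.family!r}")

    def mean(self) -> float:
        """Location used for initialization."""
        if self.family in ("normal", "truncnormal0"):
            return self.params[0]
        if self.family == "halfnormal":
            return self.params[0] * math.sqrt(2.0 / math.pi)
        if self.family == "gamma":
            return self.params[0] * self.params[1]
        raise ValueError(self.family)


def default_priors() -> dict[str, Prior]:
    """Moderately informative priors on the group-level nodes.

    Centred on the range typical of two-choice RT experiments: drift
    intercepts of order 1-3 evidence units/s, boundaries near 1-2,
    non-decision times of a few hundred milliseconds, and effects/slopes of
    order unity or below.
    """
    return {
        "mu_v": Prior("normal", (2.0, 3.0)),
        "sigma_v": Prior("halfnormal", (1.0,), low=0.0),
        "mu_bF": Prior("normal", (0.0, 1.0)),
        "sigma_bF": Prior("halfnormal", (1.0,), low=0.0),
        "mu_bC": Prior("normal", (0.0, 1.0)),
        "sigma_bC": Prior("halfnormal", (1.0,), low=0.0),
        "mu_a": Prior("gamma", (1.5, 1.0), low=0.0),
        "sigma_a": Prior("halfnormal", (1.0,), low=0.0),
        "mu_t0": Prior("truncnormal0", (0.4, 0.2), low=0.0),
        "sigma_t0": Prior("halfnormal", (1.0,), low=0.0),
        "sv": Prior("halfnormal", (2.0,), low=0.0),
        "st": Prior("halfnormal", (0.3,), low=0.0),
        "beta_v": Prior("normal", (0.0, 1.0)),
        "beta_a": Prior("normal", (0.0, 1.0)),
        "beta_t": Prior("normal", (0.0, 1.0)),
    }


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of which parameters vary with what."""

    kind: str                      # null | fc | full
    covariate_name: str | None = None
    factor_coding: dict = field(
        default_factory=lambda: {"FAMILIARITY": dict(FAM_CODE), "CONTEXT": dict(CTX_CODE)}
    )
    parameter_links: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("null", "fc", "full"):
            raise ValueError(f"model kind must be null, fc or full, got {self.kind!r}")
        if self.kind == "full" and not self.covariate_name:
            raise ValueError("a full model requires a covariate name")
        if self.kind != "full" and self.covariate_name:
            raise ValueError(f"{self.kind} model takes no covariate")


class HierarchicalModel:
    """A built model: data arrays, node labels, and density evaluation."""

    def __init__(self, spec: ModelSpec, data: CohortData, priors: dict[str, Prior]):
        self.spec = spec
        self.priors = priors

        trials = data.trials
        if (trials["censored"] != 0).any():
            trials = trials.loc[trials["censored"] == 0]
        pids = sorted(trials["participant_id"].unique())
        if len(pids) < 2:
            raise ValueError("hierarchical inference needs at least 2 participants")
        cells = trials.groupby(
            ["participant_id", "familiarity", "context"], observed=True
        ).size().unstack(["familiarity", "context"])
        if cells.shape[1] < 4 or cells.isna().any().any():
            empty = cells.isna().any(axis=1)
            raise ValueError(
                "every participant needs all four condition cells; incomplete: "
                f"{list(cells.index[empty]) if cells.shape[1] == 4 else 'missing cell levels'}"
            )

        self.participants = pids
        self.n_subjects = len(pids)
        pid_index = {p: i for i, p in enumerate(pids)}
        self.pidx = trials["participant_id"].map(pid_index).to_numpy(np.int64)
        self.rt = trials["rt_s"].to_numpy(float)
        self.is_upper = trials["response"].to_numpy(int) == 1
        self.F = trials["familiarity"].map(FAM_CODE).to_numpy(float)
        self.C = trials["context"].map(CTX_CODE).to_numpy(float)
        self.n_trials = len(self.rt)

        if spec.kind == "full":
            if spec.covariate_name not in data.covariates.columns:
                raise ValueError(f"covariate {spec.covariate_name!r} missing from the covariate table")
            raw = data.covariates.loc[pids, spec.covariate_name].to_numpy(float)
            if not np.all(np.isfinite(raw)):
                raise ValueError(f"covariate {spec.covariate_name!r} has missing scores")
            sd = raw.std(ddof=1)
            if sd == 0:
                raise ValueError(f"covariate {spec.covariate_name!r} has zero variance")
            self.score = (raw - raw.mean()) / sd
        else:
            self.score = np.zeros(self.n_subjects)

        self.families = ("v", "a", "t0") if spec.kind == "null" else ("v", "bF", "bC", "a", "t0")
        gnames = ["mu_v", "sigma_v"]
        if spec.kind != "null":
            gnames += ["mu_bF", "sigma_bF", "mu_bC", "sigma_bC"]
        gnames += ["mu_a", "sigma_a", "mu_t0", "sigma_t0", "sv", "st"]
        if spec.kind == "full":
            gnames += ["beta_v", "beta_a", "beta_t"]
        self.global_names = gnames
        self.labels = list(gnames) + [f"{f}[{p}]" for f in self.families for p in pids]

    # -- density pieces ----------------------------------------------------

    def trial_param_arrays(self, subj: dict, glob: dict):
        """Per-trial (drift, boundary, non-decision time) for a state."""
        drift = subj["v"][self.pidx]
        if self.spec.kind != "null":
            drift = drift + subj["bF"][self.pidx] * self.F + subj["bC"][self.pidx] * self.C
        bound = subj["a"][self.pidx]
        ndt = subj["t0"][self.pidx]
        if self.spec.kind == "full":
            sc = self.score[self.pidx]
            drift = drift + glob["beta_v"] * sc
            bound = bound + glob["beta_a"] * sc
            ndt = ndt + glob["beta_t"] * sc
        return drift, bound, ndt

    def trial_loglik(self, subj: dict, glob: dict) -> np.ndarray:
        drift, bound, ndt = self.trial_param_arrays(subj, glob)
        return W.loglik_trials(self.rt, self.is_upper, drift, bound, ndt, glob["sv"], glob["st"])

    def subject_logprior(self, family: str, values: np.ndarray, glob: dict) -> np.ndarray:
        """Per-subject log prior given the group level (with support)."""
        mu = glob[f"mu_{family}"]
        sd = glob[f"sigma_{family}"]
        if sd <= 0:
            return np.full(values.shape, -np.inf)
        lp = -0.5 * ((values - mu) / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI
        if family in ("a", "t0"):
            lp = np.where(values > 0, lp, -np.inf)
        return lp

    def hyper_logprior(self, glob: dict) -> float:
        return sum(self.priors[name].logpdf(glob[name]) for name in self.global_names)


@dataclass
class SamplerState:
    """Full parameter assignment: subject-level arrays and global scalars."""

    subj: dict
    glob: dict

    def copy(self) -> "SamplerState":
        return SamplerState(
            subj={k: v.copy() for k, v in self.subj.items()},
            glob=dict(self.glob),
        )


def build_model(
    kind: str,
    covariate_name: str | None = None,
    data: CohortData = None,
    priors: dict[str, Prior] | None = None,
) -> HierarchicalModel:
    """Construct the parameter graph for one model family on a cohort."""
    spec = ModelSpec(kind=kind, covariate_name=covariate_name)
    return HierarchicalModel(spec, data, priors or default_priors())


def log_posterior(model: HierarchicalModel, state: SamplerState) -> float:
    """Joint log density: trial likelihoods + subject priors + hyperpriors.

    Returns ``-inf`` on any support violation instead of raising, so
    samplers can reject gracefully.
    """
    hp = model.hyper_logprior(state.glob)
    if not np.isfinite(hp):
        return -np.inf
    sp = 0.0
    for fam in model.families:
        terms = model.subject_logprior(fam, state.subj[fam], state.glob)
        s = terms.sum()
        if not np.isfinite(s):
            return -np.inf
        sp += s
    ll = model.trial_loglik(state.subj, state.glob).sum()
    if not np.isfinite(ll):
        return -np.inf
    return float(ll + sp + hp)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Labelled retained draws from one chain."""

    draws: np.ndarray          # (n_retained, n_params)
    labels: list
    n_total: int
    n_burn: int
    seed: int
    loglik: np.ndarray         # per-draw total trial log likelihood
    accept_rates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0]

    def get(self, label: str) -> np.ndarray:
        if label not in self._index:
            raise KeyError(f"unknown parameter label {label!r}")
        return self.draws[:, self._index[label]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.labels)

    def to_flat_csv(self, path) -> None:
        """Flat long-format CSV: iteration, parameter, value."""
        df = self.to_dataframe()
        df.insert(0, "iteration", np.arange(self.n_burn, self.n_total))
        long = df.melt(id_vars="iteration", var_name="parameter", value_name="value")
        long.to_csv(path, index=False)


_SUBJ_STEP0 = {"v": 0.25, "bF": 0.2, "bC": 0.2, "a": 0.12, "t0": 0.02}
_GLOB_STEP0 = {
    "mu_v": 0.15, "sigma_v": 0.1, "mu_bF": 0.1, "sigma_bF": 0.08,
    "mu_bC": 0.1, "sigma_bC": 0.08, "mu_a": 0.1, "sigma_a": 0.08,
    "mu_t0": 0.02, "sigma_t0": 0.03, "sv": 0.1, "st": 0.02,
    "beta_v": 0.08, "beta_a": 0.05, "beta_t": 0.01,
}


class _Sampler:
    """Metropolis-within-Gibbs with burn-in step-size adaptation."""

    def __init__(self, model: HierarchicalModel, seed: int,
                 adapt_interval: int = 50, hyper_sweeps: int = 3):
        self.model = model
        self.rng = np.random.default_rng(seed)
        self.adapt_interval = adapt_interval
        self.hyper_sweeps = hyper_sweeps
        S = model.n_subjects
        self.steps_subj = {f: np.full(S, _SUBJ_STEP0[f]) for f in model.families}
        self.steps_glob = {g: _GLOB_STEP0[g] for g in model.global_names}
        self.acc_subj = {f: np.zeros(S) for f in model.families}
        self.try_subj = {f: 0 for f in model.families}
        self.acc_glob = {g: 0.0 for g in model.global_names}
        self.try_glob = {g: 0 for g in model.global_names}

    # -- initialization ----------------------------------------------------

    def init_state(self) -> SamplerState:
        model = self.model
        min_rt = float(model.rt.min())
        for _ in range(100):
            glob = {}
            for g in model.global_names:
                glob[g] = model.priors[g].mean()
            if model.spec.kind == "full":
                glob["beta_v"] = glob["beta_a"] = glob["beta_t"] = 0.0
            if model.spec.kind != "null":
                glob["mu_bF"] = glob["mu_bC"] = 0.0
            glob["mu_t0"] = min(glob["mu_t0"], 0.8 * min_rt)
            glob["st"] = min(glob["st"], glob["mu_t0"])
            subj = {}
            for fam in model.families:
                loc = glob[f"mu_{fam}"]
                scale = max(abs(loc), 0.1)
                subj[fam] = loc + 0.01 * scale * self.rng.standard_normal(model.n_subjects)
            # jitter the globals too
            for g in model.global_names:
                glob[g] += 0.01 * max(abs(glob[g]), 0.05) * self.rng.standard_normal()
            glob["st"] = min(abs(glob["st"]), 0.95 * 2 * min(glob["mu_t0"], subj["t0"].min()))
            state = SamplerState(subj=subj, glob=glob)
            if np.isfinite(log_posterior(model, state)):
                return state
        raise RuntimeError("could not find a finite-posterior initialization in 100 restarts")

    # -- update moves ------------------------------------------------------

    def _refresh_cache(self, state: SamplerState) -> None:
        self.trial_ll = self.model.trial_loglik(state.subj, state.glob)
        self.ll_subj = np.bincount(self.model.pidx, weights=self.trial_ll,
                                   minlength=self.model.n_subjects)

    def _update_subject_family(self, state: SamplerState, fam: str) -> None:
        model, rng = self.model, self.rng
        S = model.n_subjects
        cur = state.subj[fam]
        prop = cur + self.steps_subj[fam] * rng.standard_normal(S)
        lp_cur = model.subject_logprior(fam, cur, state.glob)
        lp_new = model.subject_logprior(fam, prop, state.glob)
        subj_new = dict(state.subj)
        subj_new[fam] = prop
        ll_new = model.trial_loglik(subj_new, state.glob)
        with np.errstate(invalid="ignore"):
            s_new = np.bincount(model.pidx, weights=ll_new, minlength=S)
            delta = (s_new - self.ll_subj) + (lp_new - lp_cur)
        delta = np.where(np.isnan(delta), -np.inf, delta)
        acc = np.log(rng.random(S)) < delta
        if acc.any():
            cur[acc] = prop[acc]
            tmask = acc[model.pidx]
            self.trial_ll[tmask] = ll_new[tmask]
            self.ll_subj[acc] = s_new[acc]
        self.acc_subj[fam] += acc
        self.try_subj[fam] += 1

    def _update_hyper(self, state: SamplerState, name: str, fam: str) -> None:
        model, rng = self.model, self.rng
        cur = state.glob[name]
        prop = cur + self.steps_glob[name] * rng.standard_normal()
        self.try_glob[name] += 1
        dp = model.priors[name].logpdf(prop) - model.priors[name].logpdf(cur)
        if not np.isfinite(dp):
            return
        glob_new = dict(state.glob)
        glob_new[name] = prop
        x = state.subj[fam]
        delta = dp + (model.subject_logprior(fam, x, glob_new).sum()
                      - model.subject_logprior(fam, x, state.glob).sum())
        if np.isfinite(delta) and math.log(rng.random()) < delta:
            state.glob[name] = prop
            self.acc_glob[name] += 1

    def _update_global_lik(self, state: SamplerState, name: str) -> None:
        model, rng = self.model, self.rng
        cur = state.glob[name]
        prop = cur + self.steps_glob[name] * rng.standard_normal()
        self.try_glob[name] += 1
        dp = model.priors[name].logpdf(prop) - model.priors[name].logpdf(cur)
        if not np.isfinite(dp):
            return
        glob_new = dict(state.glob)
        glob_new[name] = prop
        ll_new = model.trial_loglik(state.subj, glob_new)
        tot_new = ll_new.sum()
        delta = dp + tot_new - self.ll_subj.sum()
        if np.isfinite(delta) and math.log(rng.random()) < delta:
            state.glob[name] = prop
            self.trial_ll = ll_new
            self.ll_subj = np.bincount(model.pidx, weights=ll_new,
                                       minlength=model.n_subjects)
            self.acc_glob[name] += 1

    def _adapt(self) -> None:
        for fam in self.model.families:
            tries = max(self.try_subj[fam], 1)
            rate = self.acc_subj[fam] / tries
            step = self.steps_subj[fam]
            step[rate < 0.3] *= 0.7
            step[rate > 0.5] *= 1.4
            np.clip(step, 1e-5, 10.0, out=step)
            self.acc_subj[fam][:] = 0.0
            self.try_subj[fam] = 0
        for g in self.model.global_names:
            tries = max(self.try_glob[g], 1)
            rate = self.acc_glob[g] / tries
            if rate < 0.3:
                self.steps_glob[g] *= 0.7
            elif rate > 0.5:
                self.steps_glob[g] *= 1.4
            self.steps_glob[g] = float(np.clip(self.steps_glob[g], 1e-5, 10.0))
            self.acc_glob[g] = 0.0
            self.try_glob[g] = 0

    # -- main loop ---------------------------------------------------------

    def run(self, n_samples: int, n_burn: int) -> tuple[np.ndarray, np.ndarray, dict]:
        model = self.model
        state = self.init_state()
        self._refresh_cache(state)
        n_keep = n_samples - n_burn
        P = len(model.labels)
        draws = np.empty((n_keep, P))
        ll_trace = np.empty(n_keep)
        mu_sigma = [(f"mu_{f}", f"sigma_{f}", f) for f in model.families]
        lik_globals = ["sv", "st"] + (
            ["beta_v", "beta_a", "beta_t"] if model.spec.kind == "full" else []
        )
        for it in range(n_samples):
            for fam in model.families:
                self._update_subject_family(state, fam)
            for _ in range(self.hyper_sweeps):
                for mu, sig, fam in mu_sigma:
                    self._update_hyper(state, mu, fam)
                    self._update_hyper(state, sig, fam)
            for g in lik_globals:
                self._update_global_lik(state, g)
            if it < n_burn and (it + 1) % self.adapt_interval == 0:
                self._adapt()
                if (it + 1) % (self.adapt_interval * 4) == 0:
                    self._refresh_cache(state)  # guard against drift in the cache
            if it >= n_burn:
                row = it - n_burn
                col = 0
                for g in model.global_names:
                    draws[row, col] = state.glob[g]
                    col += 1
                for fam in model.families:
                    draws[row, col:col + model.n_subjects] = state.subj[fam]
                    col += model.n_subjects
                ll_trace[row] = self.ll_subj.sum()
        rates = {f: float(np.mean(self.acc_subj[f] / max(self.try_subj[f], 1)))
                 for f in model.families}
        rates.update({g: self.acc_glob[g] / max(self.try_glob[g], 1)
                      for g in model.global_names})
        return draws, ll_trace, rates


def sample(
    model: HierarchicalModel,
    n_samples: int = 12000,
    n_burn: int = 2000,
    seed: int = 0,
    adapt_interval: int = 50,
    hyper_sweeps: int = 3,
) -> PosteriorSamples:
    """Draw one MCMC chain; the burn-in portion is discarded.

    Deterministic given ``seed``: identical inputs reproduce identical draws.
    """
    if not 0 <= n_burn < n_samples:
        raise ValueError("need 0 <= n_burn < n_samples")
    sampler = _Sampler(model, seed, adapt_interval, hyper_sweeps)
    draws, ll, rates = sampler.run(n_samples, n_burn)
    return PosteriorSamples(
        draws=draws, labels=list(model.labels), n_total=n_samples,
        n_burn=n_burn, seed=seed, loglik=ll, accept_rates=rates,
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

class DegenerateChainError(ValueError):
    """Raised for chains whose variance is zero."""


def geweke_z(chain, first_frac: float = 0.1, last_frac: float = 0.5,
             n_batches: int = 20) -> float:
    """Stationarity z score: early-segment mean vs late-segment mean.

    Standard errors come from batch means (``n_batches`` batches per
    segment), which absorbs autocorrelation within segments.  Because the
    batch count is fixed, the raw statistic follows a Student-t law (about
    38 degrees of freedom via Welch-Satterthwaite) rather than a standard
    normal; the returned value is mapped through the t CDF onto the normal
    scale, so the usual |z| < 2 cut keeps its nominal level.
    """
    x = np.asarray(chain, float)
    if x.size < 100:
        raise ValueError("geweke_z needs a chain of length >= 100")
    if np.var(x) == 0:
        raise DegenerateChainError("constant chain has no stationarity information")
    n = x.size
    seg1 = x[: int(n * first_frac)]
    seg2 = x[n - int(n * last_frac):]

    def batch_se2(seg):
        nb = min(n_batches, seg.size)  # short segments get fewer batches
        m = seg.size // nb
        b = seg[: m * nb].reshape(nb, m).mean(axis=1)
        return b.var(ddof=1) / nb, nb

    (q1, nb1), (q2, nb2) = batch_se2(seg1), batch_se2(seg2)
    denom2 = q1 + q2
    if denom2 == 0:
        raise DegenerateChainError("zero batch-mean variance in both segments")
    t_stat = (seg1.mean() - seg2.mean()) / math.sqrt(denom2)
    df = denom2**2 / (q1**2 / (nb1 - 1) + q2**2 / (nb2 - 1))
    from scipy import stats as _sps

    # two-sided t -> normal quantile transform, numerically safe in the tails
    p_tail = min(math.exp(_sps.t.logsf(abs(t_stat), df)), 0.5)
    z = float(_sps.norm.isf(p_tail))
    if not np.isfinite(z):
        z = 40.0
    return float(math.copysign(z, t_stat))


def geweke_table(samples: PosteriorSamples, labels=None, threshold: float = 2.0) -> pd.DataFrame:
    """Geweke z and pass flag (|z| < threshold) per parameter."""
    labels = list(labels) if labels is not None else list(samples.labels)
    rows = {}
    for lab in labels:
        try:
            z = geweke_z(samples.get(lab))
            rows[lab] = {"z": z, "pass": bool(abs(z) < threshold)}
        except DegenerateChainError:
            rows[lab] = {"z": np.nan, "pass": False}
    return pd.DataFrame(rows).T


def dic(samples: PosteriorSamples, model: HierarchicalModel) -> dict:
    """Deviance information criterion, conditioned on subject-level parameters.

    The deviance is ``-2 *`` the sum of trial log likelihoods given the
    subject-level parameters (the "focused" hierarchical DIC):
    ``d_bar`` averages it over retained draws, ``p_d = d_bar - D(theta_bar)``
    evaluates the deviance at the posterior mean of every
    likelihood-relevant parameter, and ``dic = d_bar + p_d``.
    """
    if samples.n_retained < 50:
        raise ValueError("dic needs at least 50 retained draws")
    d_bar = float(np.mean(-2.0 * samples.loglik))
    mean_state = state_from_draws(model, samples)
    ll_hat = model.trial_loglik(mean_state.subj, mean_state.glob).sum()
    if np.isfinite(ll_hat):
        p_d = d_bar - float(-2.0 * ll_hat)
        return {"d_bar": d_bar, "p_d": p_d, "dic": d_bar + p_d, "p_d_defined": True}
    return {"d_bar": d_bar, "p_d": np.nan, "dic": np.nan, "p_d_defined": False}


def state_from_draws(model: HierarchicalModel, samples: PosteriorSamples,
                     row: int | None = None) -> SamplerState:
    """Rebuild a SamplerState from one draw (or the posterior mean)."""
    def val(lab):
        x = samples.get(lab)
        return float(x[row]) if row is not None else float(x.mean())

    glob = {g: val(g) for g in model.global_names}
    subj = {
        fam: np.array([val(f"{fam}[{p}]") for p in model.participants])
        for fam in model.families
    }
    return SamplerState(subj=subj, glob=glob)


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Exhaustively scans sorted-draw windows of ``ceil(mass * n)`` points;
    ties go to the leftmost window.
    """
    x = np.sort(np.asarray(samples, float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("hdi of an empty sample")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # first occurrence = leftmost
    return float(x[i]), float(x[i + m - 1])


@dataclass(frozen=True)
class EffectSummary:
    """Posterior mean, 95% HDI, and sign probability of one effect."""

    label: str
    posterior_mean: float
    hdi_low: float
    hdi_high: float
    prob_positive: float

    @property
    def credible(self) -> bool:
        """True when the 95% HDI excludes zero (the decision rule)."""
        return self.hdi_low > 0.0 or self.hdi_high < 0.0


def effect_summary(samples: PosteriorSamples, label: str, mass: float = 0.95) -> EffectSummary:
    x = samples.get(label)
    lo, hi = hdi(x, mass)
    return EffectSummary(
        label=label,
        posterior_mean=float(x.mean()),
        hdi_low=lo,
        hdi_high=hi,
        prob_positive=float(np.mean(x > 0.0)),
    )


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

_PPC_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


def _condition_stats(rt, is_upper, F, C):
    stats = {}
    for fam, fcode in FAM_CODE.items():
        for ctx, ccode in CTX_CODE.items():
            m = (F == fcode) & (C == ccode)
            label = f"{ctx}-{fam}"
            acc = float(np.mean(is_upper[m])) if m.any() else np.nan
            stats[(label, "accuracy")] = acc
            crt = rt[m & is_upper]
            qs = (np.quantile(crt, _PPC_QUANTILES) if crt.size
                  else np.full(len(_PPC_QUANTILES), np.nan))
            for q, v in zip(_PPC_QUANTILES, qs):
                stats[(label, f"rt_q{int(q * 100)}")] = float(v)
    return stats


def posterior_predictive(
    model: HierarchicalModel,
    samples: PosteriorSamples,
    n_rep: int,
    seed: int = 0,
    dt: float = 1e-3,
    deadline: float = 5.0,
) -> pd.DataFrame:
    """Simulate replicate datasets from posterior draws and score the fit.

    For each of ``n_rep`` randomly chosen retained draws a full replicate
    (same trial structure) is simulated; per condition the observed accuracy
    and correct-RT deciles are compared with the replicate distribution via
    two-sided posterior predictive p-values (twice the smaller tail
    fraction, counting replicates at or beyond the observed value).
    Censored replicate trials are dropped, mirroring the data pipeline.
    """
    if n_rep < 2:
        raise ValueError("posterior predictive checks need n_rep >= 2")
    rng = np.random.default_rng(seed)
    rows = rng.choice(samples.n_retained, size=min(n_rep, samples.n_retained), replace=False)
    observed = _condition_stats(model.rt, model.is_upper, model.F, model.C)
    reps = []
    for row in rows:
        st = state_from_draws(model, samples, int(row))
        drift, bound, ndt = model.trial_param_arrays(st.subj, st.glob)
        rep_rt, rep_up, rep_cens = W.simulate_trials(
            drift, bound, 0.5, ndt, st.glob["sv"], st.glob["st"],
            rng=rng, dt=dt, deadline=deadline,
        )
        keep = ~rep_cens
        reps.append(_condition_stats(rep_rt[keep], rep_up[keep], model.F[keep], model.C[keep]))

    records = []
    for key, obs in observed.items():
        vals = np.array([r[key] for r in reps], float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0 or not np.isfinite(obs):
            p = np.nan
            pred = np.nan
        else:
            lo = float(np.mean(vals <= obs))
            hi = float(np.mean(vals >= obs))
            p = min(1.0, 2.0 * min(lo, hi))
            pred = float(vals.mean())
        records.append({
            "condition": key[0], "statistic": key[1],
            "observed": obs, "predicted": pred, "p_value": p,
        })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# fitting and model comparison
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Everything one model fit produces."""

    spec: ModelSpec
    samples: PosteriorSamples
    dic: dict
    geweke: pd.DataFrame
    effects: list
    ppc: pd.DataFrame | None = None

    def effects_frame(self) -> pd.DataFrame:
        rows = {
            e.label: {
                "mean": e.posterior_mean, "hdi_low": e.hdi_low,
                "hdi_high": e.hdi_high, "prob_positive": e.prob_positive,
                "credible": e.credible,
            }
            for e in self.effects
        }
        return pd.DataFrame(rows).T

    def summary_dict(self) -> dict:
        return {
            "model": {"kind": self.spec.kind, "covariate": self.spec.covariate_name},
            "dic": {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                    for k, v in self.dic.items()},
            "effects": {
                e.label: {
                    "mean": e.posterior_mean,
                    "hdi_95": [e.hdi_low, e.hdi_high],
                    "prob_positive": e.prob_positive,
                    "credible": e.credible,
                }
                for e in self.effects
            },
            "geweke": {
                lab: {"z": (None if not np.isfinite(r["z"]) else float(r["z"])),
                      "pass": bool(r["pass"])}
                for lab, r in self.geweke.iterrows()
            },
            "sampler": {
                "n_total": self.samples.n_total,
                "n_burn": self.samples.n_burn,
                "seed": self.samples.seed,
            },
        }


def fit_model(
    data: CohortData,
    kind: str,
    covariate_name: str | None = None,
    n_samples: int = 12000,
    n_burn: int = 2000,
    seed: int = 0,
    priors: dict | None = None,
    ppc_reps: int = 0,
    ppc_dt: float = 1e-3,
) -> FitResult:
    """Build, sample, and summarize one model."""
    model = build_model(kind, covariate_name, data, priors)
    samples = sample(model, n_samples=n_samples, n_burn=n_burn, seed=seed)
    effect_labels = []
    if kind != "null":
        effect_labels += ["mu_bF", "mu_bC"]
    if kind == "full":
        effect_labels += ["beta_v", "beta_a", "beta_t"]
    effects = [effect_summary(samples, lab) for lab in effect_labels]
    gw = geweke_table(samples, model.global_names)
    result = FitResult(
        spec=model.spec, samples=samples, dic=dic(samples, model),
        geweke=gw, effects=effects,
    )
    if ppc_reps:
        result.ppc = posterior_predictive(model, samples, ppc_reps, seed=seed, dt=ppc_dt)
    return result


def compare_models(
    data: CohortData,
    covariate_names,
    n_samples: int = 12000,
    n_burn: int = 2000,
    seed: int = 0,
    priors: dict | None = None,
) -> pd.DataFrame:
    """DIC table over Null, FC, and one full model per covariate.

    Rows are ordered base models first, then full models alphabetically by
    covariate.  A failed fit annotates its row instead of aborting the table.
    """
    jobs = [("Null", "null", None), ("FC", "fc", None)]
    for cov in sorted(covariate_names):
        jobs.append((f"Full-{cov}", "full", cov))
    seeds = np.random.SeedSequence(seed).generate_state(len(jobs)) % (2**31)
    rows = []
    for (label, kind, cov), s in zip(jobs, seeds):
        try:
            res = fit_model(data, kind, cov, n_samples=n_samples,
                            n_burn=n_burn, seed=int(s), priors=priors)
            rows.append({"model": label, "dic": res.dic["dic"],
                         "d_bar": res.dic["d_bar"], "p_d": res.dic["p_d"], "error": ""})
        except Exception as exc:  # annotated per row, table still emitted
            rows.append({"model": label, "dic": np.nan, "d_bar": np.nan,
                         "p_d": np.nan, "error": str(exc)})
    return pd.DataFrame(rows).set_index("model")
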