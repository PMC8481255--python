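"""Model graph, log posterior, sampler, diagnostics, DIC, HDI, PPC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from metadrift import inference as I
from metadrift.behavior import CohortData
from metadrift.wiener import DDMParams, TrialOutcome, trial_log_likelihood

from conftest import make_cohort


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def test_modelspec_validation():
    with pytest.raises(ValueError):
        I.ModelSpec(kind="bogus")
    with pytest.raises(ValueError):
        I.ModelSpec(kind="full")  # needs a covariate
    with pytest.raises(ValueError):
        I.ModelSpec(kind="fc", covariate_name="ANT")


def test_graph_contents_per_kind(small_cohort):
    cohort, _ = small_cohort
    null = I.build_model("null", None, cohort)
    assert not any("bF" in lab or "bC" in lab or "beta" in lab for lab in null.labels)

    fc = I.build_model("fc", None, cohort)
    assert "mu_bF" in fc.global_names and "mu_bC" in fc.global_names
    assert not any(lab.startswith("beta") for lab in fc.global_names)

    full = I.build_model("full", "COWAT_Semantic", cohort)
    slopes = [lab for lab in full.global_names if lab.startswith("beta")]
    assert slopes == ["beta_v", "beta_a", "beta_t"]  # drift, boundary, ndt
    # covariate is z-scored across included participants
    assert full.score.mean() == pytest.approx(0.0, abs=1e-12)
    assert full.score.std(ddof=1) == pytest.approx(1.0, rel=1e-12)


def test_build_model_errors(small_cohort):
    cohort, _ = small_cohort
    with pytest.raises(ValueError):
        I.build_model("full", "NoSuchTest", cohort)
    # participant with an empty condition cell
    trials = cohort.trials
    pid = trials["participant_id"].iloc[0]
    mask = ~((trials["participant_id"] == pid) & (trials["familiarity"] == "FM")
             & (trials["context"] == "SC"))
    broken = CohortData(trials=trials.loc[mask], covariates=cohort.covariates)
    with pytest.raises(ValueError):
        I.build_model("fc", None, broken)


# ---------------------------------------------------------------------------
# log posterior
# ---------------------------------------------------------------------------

def _tiny_cohort():
    rts = {"P1": [0.8, 0.9, 1.1, 1.0], "P2": [0.7, 1.2, 0.9, 1.3]}
    resp = {"P1": [1, 1, 0, 1], "P2": [1, 0, 1, 1]}
    return make_cohort(rts, resp)


def test_log_posterior_matches_independent_summation():
    """Sum-of-terms oracle on a 2-participant, 8-trial fixture."""
    cohort = _tiny_cohort()
    model = I.build_model("fc", None, cohort)
    glob = {
        "mu_v": 1.2, "sigma_v": 0.5, "mu_bF": 0.3, "sigma_bF": 0.2,
        "mu_bC": -0.1, "sigma_bC": 0.25, "mu_a": 1.8, "sigma_a": 0.3,
        "mu_t0": 0.35, "sigma_t0": 0.05, "sv": 0.6, "st": 0.1,
    }
    subj = {
        "v": np.array([1.4, 1.0]), "bF": np.array([0.4, 0.2]),
        "bC": np.array([-0.05, 0.1]), "a": np.array([1.7, 2.0]),
        "t0": np.array([0.3, 0.4]),
    }
    state = I.SamplerState(subj=subj, glob=glob)
    got = I.log_posterior(model, state)

    # oracle: per-trial public likelihood + scipy prior densities
    fam_code = {"FM": 0.5, "NM": -0.5}
    ctx_code = {"OC": 0.5, "SC": -0.5}
    pix = {p: i for i, p in enumerate(model.participants)}
    ll = 0.0
    for _, row in cohort.trials.iterrows():
        i = pix[row["participant_id"]]
        v = subj["v"][i] + subj["bF"][i] * fam_code[row["familiarity"]] \
            + subj["bC"][i] * ctx_code[row["context"]]
        p = DDMParams(v=v, a=subj["a"][i], z=0.5, t0=subj["t0"][i],
                      sv=glob["sv"], st=glob["st"])
        ll += trial_log_likelihood(
            TrialOutcome(rt=row["rt_s"], boundary="upper" if row["response"] else "lower"), p
        )
    sp = 0.0
    for fam in model.families:
        sp += sps.norm.logpdf(subj[fam], glob[f"mu_{fam}"], glob[f"sigma_{fam}"]).sum()
    hp = (
        sps.norm.logpdf(glob["mu_v"], 2.0, 3.0)
        + sps.halfnorm.logpdf(glob["sigma_v"], scale=1.0)
        + sps.norm.logpdf(glob["mu_bF"], 0.0, 1.0)
        + sps.halfnorm.logpdf(glob["sigma_bF"], scale=1.0)
        + sps.norm.logpdf(glob["mu_bC"], 0.0, 1.0)
        + sps.halfnorm.logpdf(glob["sigma_bC"], scale=1.0)
        + sps.gamma.logpdf(glob["mu_a"], 1.5, scale=1.0)
        + sps.halfnorm.logpdf(glob["sigma_a"], scale=1.0)
        + sps.truncnorm.logpdf(glob["mu_t0"], -0.4 / 0.2, np.inf, loc=0.4, scale=0.2)
        + sps.halfnorm.logpdf(glob["sigma_t0"], scale=1.0)
        + sps.halfnorm.logpdf(glob["sv"], scale=2.0)
        + sps.halfnorm.logpdf(glob["st"], scale=0.3)
    )
    assert got == pytest.approx(ll + sp + hp, abs=1e-10)


def test_log_posterior_support_violations():
    cohort = _tiny_cohort()
    model = I.build_model("null", None, cohort)
    glob = {"mu_v": 1.0, "sigma_v": 0.5, "mu_a": 1.5, "sigma_a": 0.3,
            "mu_t0": 0.3, "sigma_t0": 0.05, "sv": 0.3, "st": 0.0}
    subj = {"v": np.array([1.0, 1.0]), "a": np.array([-0.5, 1.5]),
            "t0": np.array([0.3, 0.3])}
    assert I.log_posterior(model, I.SamplerState(subj, glob)) == -np.inf


def test_perturbing_prior_only_node_changes_only_its_terms():
    """Group means touch no trial likelihood: the posterior shift equals the
    prior + subject-prior shift exactly."""
    cohort = _tiny_cohort()
    model = I.build_model("null", None, cohort)
    glob = {"mu_v": 1.0, "sigma_v": 0.5, "mu_a": 1.5, "sigma_a": 0.3,
            "mu_t0": 0.3, "sigma_t0": 0.05, "sv": 0.3, "st": 0.0}
    subj = {"v": np.array([1.2, 0.9]), "a": np.array([1.6, 1.5]),
            "t0": np.array([0.28, 0.31])}
    s1 = I.SamplerState(subj, dict(glob))
    lp1 = I.log_posterior(model, s1)
    glob2 = dict(glob)
    glob2["mu_v"] = 1.4
    s2 = I.SamplerState(subj, glob2)
    lp2 = I.log_posterior(model, s2)
    expected = (
        model.priors["mu_v"].logpdf(1.4) - model.priors["mu_v"].logpdf(1.0)
        + model.subject_logprior("v", subj["v"], glob2).sum()
        - model.subject_logprior("v", subj["v"], glob).sum()
    )
    assert lp2 - lp1 == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def test_sampler_is_deterministic(small_cohort):
    cohort, _ = small_cohort
    model = I.build_model("fc", None, cohort)
    s1 = I.sample(model, n_samples=150, n_burn=50, seed=13)
    s2 = I.sample(model, n_samples=150, n_burn=50, seed=13)
    assert np.array_equal(s1.draws, s2.draws)
    assert np.array_equal(s1.loglik, s2.loglik)
    s3 = I.sample(model, n_samples=150, n_burn=50, seed=14)
    assert not np.array_equal(s1.draws, s3.draws)


def test_sample_argument_validation(small_cohort):
    cohort, _ = small_cohort
    model = I.build_model("null", None, cohort)
    with pytest.raises(ValueError):
        I.sample(model, n_samples=100, n_burn=100)


def test_retained_draw_count_and_labels(small_cohort):
    cohort, _ = small_cohort
    model = I.build_model("null", None, cohort)
    s = I.sample(model, n_samples=120, n_burn=20, seed=3)
    assert s.n_retained == 100
    assert s.draws.shape == (100, len(model.labels))
    assert np.isfinite(s.draws).all()
    with pytest.raises(KeyError):
        s.get("nonexistent")


# ---------------------------------------------------------------------------
# Geweke
# ---------------------------------------------------------------------------

def test_geweke_flags_gross_trend():
    chain = np.linspace(0.0, 10.0, 10_000)
    assert abs(I.geweke_z(chain)) > 2.0


def test_geweke_constant_chain_errors():
    with pytest.raises(I.DegenerateChainError):
        I.geweke_z(np.ones(500))


def test_geweke_null_calibration_small():
    rng = np.random.default_rng(15)
    passes = sum(abs(I.geweke_z(rng.standard_normal(1000))) < 2.0 for _ in range(200))
    assert passes >= 180  # ~95% nominal


# ---------------------------------------------------------------------------
# HDI and effect summaries
# ---------------------------------------------------------------------------

def test_hdi_point_mass():
    lo, hi = I.hdi(np.full(50, 3.14))
    assert lo == hi == 3.14


def test_hdi_equals_exhaustive_window_scan():
    rng = np.random.default_rng(16)
    for _ in range(25):
        x = np.sort(rng.normal(size=rng.integers(20, 80)))
        m = math.ceil(0.95 * x.size)
        best = None
        for i in range(x.size - m + 1):
            w = x[i + m - 1] - x[i]
            if best is None or w < best[0]:
                best = (w, x[i], x[i + m - 1])
        lo, hi = I.hdi(x)
        assert (lo, hi) == (best[1], best[2])


@given(st.lists(st.floats(-1e6, 1e6), min_size=20, max_size=200))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_hdi_property_contains_mass_and_is_minimal(xs):
    x = np.asarray(xs, float)
    lo, hi = I.hdi(x, 0.95)
    m = math.ceil(0.95 * x.size)
    inside = np.sum((x >= lo) & (x <= hi))
    assert inside >= m
    # no narrower window over sorted draws holds the same count
    s = np.sort(x)
    widths = s[m - 1:] - s[: s.size - m + 1]
    assert hi - lo <= widths.min() + 1e-12


def test_hdi_standard_normal_quantiles():
    rng = np.random.default_rng(17)
    lo, hi = I.hdi(rng.standard_normal(200_000))
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def _fake_samples(values, label="x"):
    values = np.asarray(values, float)
    return I.PosteriorSamples(
        draws=values[:, None], labels=[label], n_total=values.size,
        n_burn=0, seed=0, loglik=np.zeros(values.size),
    )


def test_effect_summary_all_positive_is_credible():
    e = I.effect_summary(_fake_samples(np.linspace(0.1, 1.0, 200)), "x")
    assert e.prob_positive == 1.0
    assert e.credible


def test_effect_summary_symmetric_is_not_credible():
    rng = np.random.default_rng(18)
    e = I.effect_summary(_fake_samples(rng.standard_normal(5000)), "x")
    assert e.prob_positive == pytest.approx(0.5, abs=0.05)
    assert not e.credible


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

class _ToyNormalModel:
    """Known-variance Gaussian mean estimation, for checking DIC machinery."""

    global_names: list = []
    families = ("m",)
    participants = ["p"]
    labels = ["m[p]"]

    def __init__(self, data):
        self.data = np.asarray(data, float)

    def trial_loglik(self, subj, glob):
        mu = subj["m"][0]
        return sps.norm.logpdf(self.data, mu, 1.0)


def _toy_samples(model, draws):
    draws = np.asarray(draws, float)
    ll = np.array([model.trial_loglik({"m": np.array([d])}, {}).sum() for d in draws])
    return I.PosteriorSamples(
        draws=draws[:, None], labels=["m[p]"], n_total=draws.size, n_burn=0,
        seed=0, loglik=ll,
    )


def test_dic_point_posterior_has_zero_pd():
    rng = np.random.default_rng(19)
    model = _ToyNormalModel(rng.normal(0.3, 1.0, 40))
    samples = _toy_samples(model, np.full(100, 0.25))
    out = I.dic(samples, model)
    assert out["p_d"] == pytest.approx(0.0, abs=1e-9)
    assert out["dic"] == pytest.approx(out["d_bar"], abs=1e-9)


def test_dic_gaussian_toy_effective_parameters():
    """One free mean parameter: p_d must come out ~= 1."""
    rng = np.random.default_rng(20)
    data = rng.normal(0.5, 1.0, 50)
    model = _ToyNormalModel(data)
    n = len(data)
    post = rng.normal(data.mean(), 1.0 / math.sqrt(n), 10_000)  # conjugate, flat prior
    out = I.dic(_toy_samples(model, post), model)
    assert out["p_d"] == pytest.approx(1.0, abs=0.1)


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

def _truth_samples(model, truth, n_rows=40, jitter=0.0):
    g = truth["group"]
    subj = truth["subjects"]
    pix = {p: i for i, p in enumerate(subj["participant_id"])}
    row = []
    for lab in model.labels:
        if "[" in lab:
            fam, pid = lab[:-1].split("[")
            row.append(subj[fam][pix[pid]])
        else:
            row.append(g[lab])
    draws = np.tile(np.asarray(row, float), (n_rows, 1))
    if jitter:
        draws += jitter * np.random.default_rng(0).standard_normal(draws.shape)
    return I.PosteriorSamples(
        draws=draws, labels=list(model.labels), n_total=n_rows, n_burn=0,
        seed=0, loglik=np.zeros(n_rows),
    )


@pytest.fixture(scope="module")
def ppc_cohort():
    """Slope-free truth so the condition model can represent the data exactly."""
    from metadrift.behavior import drop_censored
    from metadrift.cohort import GeneratorConfig, GroupTruth, generate_cohort

    truth = GroupTruth(beta_v=0.0, beta_a=0.0, beta_t=0.0)
    cfg = GeneratorConfig(n_participants=8, trials_per_cell=8, seed=43, dt=5e-4, truth=truth)
    cohort, t = generate_cohort(cfg)
    return drop_censored(cohort), t


def test_ppc_self_consistent_data_not_flagged(ppc_cohort):
    cohort, truth = ppc_cohort
    model = I.build_model("fc", None, cohort)
    samples = _truth_samples(model, truth)
    table = I.posterior_predictive(model, samples, n_rep=40, seed=1, dt=5e-4)
    # two-sided tail p-values: small means misfit; ties in discrete
    # statistics push p toward 1, which is unremarkable
    ok = table["p_value"] > 0.01
    assert ok.mean() >= 0.9


def test_ppc_detects_planted_ndt_misfit(ppc_cohort):
    cohort, truth = ppc_cohort
    shifted = cohort.trials.copy()
    shifted["rt_s"] = shifted["rt_s"] + 0.5  # half-second slower than the draws say
    broken = CohortData(trials=shifted, covariates=cohort.covariates)
    model = I.build_model("fc", None, broken)
    samples = _truth_samples(model, truth)
    table = I.posterior_predictive(model, samples, n_rep=40, seed=2, dt=5e-4)
    med = table.loc[table["statistic"] == "rt_q50", "p_value"]
    assert (med < 0.01).all()


def test_ppc_requires_replicates(small_cohort):
    cohort, truth = small_cohort
    model = I.build_model("fc", None, cohort)
    samples = _truth_samples(model, truth)
    with pytest.raises(ValueError):
        I.posterior_predictive(model, samples, n_rep=1)


# ---------------------------------------------------------------------------
# model comparison table
# ---------------------------------------------------------------------------

def test_compare_models_degenerate_two_rows(small_cohort):
    cohort, _ = small_cohort
    table = I.compare_models(cohort, [], n_samples=250, n_burn=100, seed=4)
    assert list(table.index) == ["Null", "FC"]
    assert np.isfinite(table["dic"]).all()


def test_fit_result_effect_table_shapes(small_cohort):
    cohort, _ = small_cohort
    fc = I.fit_model(cohort, "fc", n_samples=400, n_burn=150, seed=5)
    assert [e.label for e in fc.effects] == ["mu_bF", "mu_bC"]
    full = I.fit_model(cohort, "full", "COWAT_Semantic", n_samples=400, n_burn=150, seed=6)
    assert [e.label for e in full.effects] == [
        "mu_bF", "mu_bC", "beta_v", "beta_a", "beta_t",
    ]
    assert set(full.geweke.index) == set(
        I.build_model("full", "COWAT_Semantic", cohort).global_names
    )
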