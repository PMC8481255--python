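"""Wiener first-passage-time core for the two-boundary drift-diffusion model.

Conventions
-----------
* Diffusion coefficient is fixed at 1.  (The alternative convention used by
  some legacy tools fixes it at 0.1, which rescales drift ``v`` and boundary
  separation ``a`` by a factor of 10; parameters from such tools are not
  directly comparable.)
* ``z`` is the *relative* starting point, a fraction of the boundary
  separation ``a``; the process starts at ``z * a`` between the absorbing
  boundaries at 0 (lower) and ``a`` (upper).
* Densities returned for a single boundary are *defective*: each integrates
  over time to that boundary's absorption probability, and the two boundary
  densities together integrate to 1.

The first-passage density is evaluated with the classical dual series
representation: a small-time expansion in Gaussian images and a large-time
Fourier sine expansion.  For every evaluation the series needing fewer terms
for a truncation error of ``1e-7`` is selected.

Inter-trial variability:

* Gaussian drift variability ``sv`` is integrated out in closed form.
* Uniform non-decision-time variability ``st`` (a range, centred on ``t0``)
  is integrated with fixed-order Gauss-Legendre quadrature (11 nodes).
* Starting-point variability ``sz`` is identically 0 in this package: the
  start point is fixed at the midpoint under accuracy coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DDMParams",
    "TrialOutcome",
    "ParameterError",
    "wiener_fpt_density",
    "trial_log_likelihood",
    "choice_probability",
    "mean_decision_time",
    "simulate_trial",
    "simulate_trials",
]

#: truncation error bound for the series evaluation of the density
SERIES_ERR = 1e-7

#: Gauss-Legendre rule (11 nodes on [-1, 1]) for the st marginalization
_GL_X, _GL_W = np.polynomial.legendre.leggauss(11)


class ParameterError(ValueError):
    """Raised when diffusion parameters violate their domain."""


@dataclass(frozen=True)
class DDMParams:
    """One trial-level parameterization of the diffusion process.

    Parameters
    ----------
    v : float
        Drift rate (evidence units per second).
    a : float
        Boundary separation (> 0).
    z : float
        Relative starting point in (0, 1); 0.5 is unbiased.
    t0 : float
        Non-decision time in seconds (>= 0).
    sv : float
        Inter-trial drift standard deviation (>= 0).
    st : float
        Inter-trial non-decision-time range in seconds (>= 0); the
        per-trial non-decision time is Uniform(t0 - st/2, t0 + st/2),
        so ``t0 - st/2 >= 0`` is required.
    sz : float
        Inter-trial starting-point range; fixed at 0 here.
    """

    v: float
    a: float
    z: float = 0.5
    t0: float = 0.0
    sv: float = 0.0
    st: float = 0.0
    sz: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ParameterError(f"boundary separation a must be > 0, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ParameterError(f"relative start z must lie in (0, 1), got {self.z}")
        if self.t0 < 0:
            raise ParameterError(f"non-decision time t0 must be >= 0, got {self.t0}")
        if self.sv < 0:
            raise ParameterError(f"sv must be >= 0, got {self.sv}")
        if self.st < 0:
            raise ParameterError(f"st must be >= 0, got {self.st}")
        if self.t0 - self.st / 2.0 < 0:
            raise ParameterError("t0 - st/2 must be >= 0 (non-decision time cannot go negative)")
        if self.sz != 0.0:
            raise ParameterError("starting-point variability sz is fixed at 0 in this package")


@dataclass(frozen=True)
class TrialOutcome:
    """Observed outcome of one two-choice trial.

    ``boundary`` is ``"upper"`` or ``"lower"`` (accuracy coding maps correct
    responses to the upper boundary).  ``censored`` marks trials with no
    response before the deadline; the boundary label is meaningless then.
    """

    rt: float
    boundary: str = "upper"
    censored: bool = False

    def __post_init__(self) -> None:
        if self.boundary not in ("upper", "lower"):
            raise ValueError(f"boundary must be 'upper' or 'lower', got {self.boundary!r}")
        if not self.censored and self.rt <= 0:
            raise ValueError("response time must be positive for an observed trial")


# ---------------------------------------------------------------------------
# density core (numpy reference implementation)
# ---------------------------------------------------------------------------

def _density_lower_np(t, v, a, z, sv=0.0, err=SERIES_ERR):
    """Defective first-passage density at the *lower* boundary (vectorized).

    ``t`` is the decision time (response time minus non-decision time).
    Broadcasts over all arguments; returns 0 where ``t <= 0``.
    """
    t, v, a, z = np.broadcast_arrays(
        np.asarray(t, float), np.asarray(v, float), np.asarray(a, float), np.asarray(z, float)
    )
    out = np.zeros(t.shape, float)
    pos = t > 0
    if not np.any(pos):
        return out
    t = t[pos]
    v = v[pos]
    a = a[pos]
    z = z[pos]

    w = t / (a * a)  # normalized time

    # terms needed by each series for truncation error <= err
    with np.errstate(all="ignore"):
        arg_s = 2.0 * err * np.sqrt(2.0 * np.pi * w)
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * w * np.log(np.maximum(arg_s, 1e-300)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(w) + 1.0)
        arg_l = np.pi * w * err
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0.0) / (np.pi * np.pi * w)),
            0.0,
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(w)))

    use_small = ks < kl
    g = np.zeros(w.shape, float)

    if np.any(use_small):
        ws = w[use_small]
        zs = z[use_small]
        kmax = int(np.ceil(np.max(ks[use_small]) / 2.0)) + 1
        kmax = min(kmax, 64)
        s = np.zeros(ws.shape, float)
        with np.errstate(all="ignore"):
            for k in range(-kmax, kmax + 1):
                u = zs + 2.0 * k
                s += u * np.exp(-u * u / (2.0 * ws))
            g[use_small] = np.nan_to_num(s / np.sqrt(2.0 * np.pi * ws**3))

    big = ~use_small
    if np.any(big):
        wl = w[big]
        zl = z[big]
        kmax = int(np.ceil(np.max(kl[big]))) + 1
        kmax = min(kmax, 512)
        s = np.zeros(wl.shape, float)
        for k in range(1, kmax + 1):
            s += k * np.exp(-k * k * np.pi * np.pi * wl / 2.0) * np.sin(k * np.pi * zl)
        g[big] = np.pi * s

    g = np.maximum(g, 0.0)

    sv = float(sv)
    with np.errstate(all="ignore"):
        if sv > 0:
            fac = np.exp(
                ((a * z * sv) ** 2 - 2.0 * a * v * z - v * v * t) / (2.0 * (1.0 + sv * sv * t))
            ) / np.sqrt(1.0 + sv * sv * t)
        else:
            fac = np.exp(-v * a * z - v * v * t / 2.0)
        dens = np.nan_to_num(g / (a * a) * fac)

    out[pos] = dens
    return out


def wiener_fpt_density(t_dec, boundary: str, params: DDMParams):
    """Defective first-passage density at ``boundary`` for decision time ``t_dec``.

    Requires ``sv == st == 0`` (the pure process density); non-positive
    decision times yield 0.  Upper-boundary density equals the lower-boundary
    density with ``v -> -v`` and ``z -> 1 - z`` (reflection symmetry).
    """
    if params.sv != 0 or params.st != 0:
        raise ParameterError("wiener_fpt_density is the pure density; sv and st must be 0")
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    if boundary == "upper":
        v, z = -params.v, 1.0 - params.z
    else:
        v, z = params.v, params.z
    res = _density_lower_np(t_dec, v, params.a, z)
    if np.isscalar(t_dec) or np.ndim(t_dec) == 0:
        return float(res)
    return res


class UnsupportedObservationError(ValueError):
    """Raised when an observation cannot enter the likelihood (e.g. censored)."""


def trial_log_likelihood(outcome: TrialOutcome, params: DDMParams) -> float:
    """Log density of one observed trial under ``params``.

    Marginalizes Gaussian drift variability ``sv`` in closed form and uniform
    non-decision-time variability ``st`` by 11-node Gauss-Legendre
    quadrature.  Returns ``-inf`` (not an error) when the response is faster
    than the minimal non-decision time ``t0 - st/2``.  Censored trials are
    rejected: they are dropped upstream, never scored.
    """
    if outcome.censored:
        raise UnsupportedObservationError("censored trials carry no first-passage density")
    if outcome.boundary == "upper":
        v, z = -params.v, 1.0 - params.z
    else:
        v, z = params.v, params.z
    rt = outcome.rt
    if rt <= params.t0 - params.st / 2.0:
        return -math.inf
    if params.st == 0:
        dens = float(_density_lower_np(rt - params.t0, v, params.a, z, params.sv))
    else:
        tau = params.t0 + 0.5 * params.st * _GL_X
        f = _density_lower_np(rt - tau, v, params.a, z, params.sv)
        dens = float(np.sum(0.5 * _GL_W * f))
    if dens <= 0:
        return -math.inf
    return math.log(dens)


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------

def choice_probability(params: DDMParams) -> float:
    """Probability of absorption at the upper boundary (fixed drift only).

    Closed form ``(1 - exp(-2 v z a)) / (1 - exp(-2 v a))`` with diffusion
    coefficient 1; reduces to ``z`` as ``v -> 0``.
    """
    if params.sv != 0:
        raise ParameterError("choice_probability is defined for fixed drift (sv = 0)")
    v, a, z = params.v, params.a, params.z
    if v == 0:
        return z
    if v > 0:  # overflow-safe branch per drift sign
        return -math.expm1(-2.0 * v * z * a) / -math.expm1(-2.0 * v * a)
    return (math.exp(2.0 * v * a) - math.exp(2.0 * v * a * (1.0 - z))) / math.expm1(2.0 * v * a)


def mean_decision_time(params: DDMParams) -> float:
    """Mean decision time (seconds, pooled over boundaries, excluding t0).

    Closed form ``(a / 2v) * tanh(v a / 2)`` for an unbiased start
    (``z = 0.5``), with the drift-free limit ``a^2 / 4``.
    """
    if params.z != 0.5:
        raise ParameterError("mean_decision_time requires an unbiased start (z = 0.5)")
    if params.sv != 0:
        raise ParameterError("mean_decision_time is defined for fixed drift (sv = 0)")
    v, a = params.v, params.a
    if v == 0:
        return a * a / 4.0
    return (a / (2.0 * v)) * math.tanh(v * a / 2.0)


# ---------------------------------------------------------------------------
# forward simulation (Euler-Maruyama)
# ---------------------------------------------------------------------------

def simulate_trials(
    v,
    a,
    z,
    t0,
    sv: float = 0.0,
    st: float = 0.0,
    *,
    rng: np.random.Generator,
    n: int | None = None,
    dt: float = 1e-4,
    deadline: float = 5.0,
):
    """Simulate many diffusion trials at once.

    Parameters broadcast to a common length ``n``.  Each trial draws its
    own drift from ``Normal(v, sv)`` and its own non-decision time from
    ``Uniform(t0 - st/2, t0 + st/2)``, then accumulates evidence from
    ``z * a`` in Euler-Maruyama steps ``v' dt + sqrt(dt) * noise`` until a
    boundary is hit.  Trials whose response time would exceed ``deadline``
    are returned censored.

    Returns
    -------
    rt : ndarray
        Response times (decision + non-decision), NaN where censored.
    upper : ndarray of bool
        True where the upper boundary was hit (meaningless if censored).
    censored : ndarray of bool
    """
    if dt <= 0 or deadline <= 0:
        raise ParameterError("dt and deadline must be positive")
    v, a, z, t0 = np.broadcast_arrays(
        np.asarray(v, float), np.asarray(a, float), np.asarray(z, float), np.asarray(t0, float)
    )
    if n is None:
        n = v.size
    v = np.broadcast_to(v, (n,)).ravel()
    a = np.broadcast_to(a, (n,)).ravel()
    z = np.broadcast_to(z, (n,)).ravel()
    t0 = np.broadcast_to(t0, (n,)).ravel()
    if np.any(a <= 0) or np.any((z <= 0) | (z >= 1)) or np.any(t0 - st / 2.0 < 0):
        raise ParameterError("invalid simulation parameters")

    v_trial = v + sv * rng.standard_normal(n)
    t0_trial = t0 + st * rng.uniform(-0.5, 0.5, n)

    x = z * a
    rt_dec = np.full(n, np.nan)
    upper = np.zeros(n, bool)
    active = np.arange(n)
    max_steps = int(math.ceil(deadline / dt))
    sqdt = math.sqrt(dt)
    done = 0
    while active.size and done < max_steps:
        m = active.size
        block = max(16, min(1024, int(4_000_000 // max(m, 1))))
        block = min(block, max_steps - done)
        inc = v_trial[active, None] * dt + sqdt * rng.standard_normal((m, block))
        path = x[active, None] + np.cumsum(inc, axis=1)
        hit_up = path >= a[active, None]
        hit_lo = path <= 0.0
        crossed = hit_up | hit_lo
        any_cross = crossed.any(axis=1)
        idx = np.argmax(crossed, axis=1)
        rows = np.nonzero(any_cross)[0]
        sel = active[rows]
        rt_dec[sel] = (done + idx[rows] + 1) * dt
        upper[sel] = hit_up[rows, idx[rows]]
        keep = ~any_cross
        x[active[keep]] = path[keep, -1]
        active = active[keep]
        done += block

    rt = rt_dec + t0_trial
    censored = np.isnan(rt_dec) | (rt > deadline)
    rt[np.isnan(rt_dec)] = np.nan
    return rt, upper, censored


def simulate_trial(
    params: DDMParams,
    rng: np.random.Generator,
    dt: float = 1e-4,
    deadline: float = 5.0,
) -> TrialOutcome:
    """Simulate a single trial; see :func:`simulate_trials`."""
    rt, upper, cens = simulate_trials(
        params.v, params.a, params.z, params.t0, params.sv, params.st,
        rng=rng, n=1, dt=dt, deadline=deadline,
    )
    if cens[0]:
        return TrialOutcome(rt=deadline, boundary="upper", censored=True)
    return TrialOutcome(rt=float(rt[0]), boundary="upper" if upper[0] else "lower")


# ---------------------------------------------------------------------------
# fast trial-likelihood engine (used by the hierarchical sampler)
# ---------------------------------------------------------------------------

def loglik_trials_np(rt, is_upper, drift, bound, ndt, sv, st, err=SERIES_ERR):
    """Per-trial log likelihood, vectorized, accuracy-coded, z fixed at 0.5.

    ``is_upper`` marks upper-boundary (correct) responses.  Under the
    reflection symmetry with z = 0.5, an upper-boundary observation equals a
    lower-boundary observation with the drift negated.  Support violations
    (non-positive boundary, rt at or below the minimal non-decision time,
    ndt < st/2) give ``-inf`` for the affected trials.
    """
    rt = np.asarray(rt, float)
    drift = np.asarray(drift, float)
    bound = np.asarray(bound, float)
    ndt = np.asarray(ndt, float)
    is_upper = np.asarray(is_upper, bool)
    d = np.where(is_upper, -drift, drift)
    bad = (bound <= 0) | (ndt - st / 2.0 < -1e-12) | (rt <= ndt - st / 2.0)
    a_safe = np.where(bound <= 0, 1.0, bound)
    if st == 0:
        dens = _density_lower_np(rt - ndt, d, a_safe, 0.5, sv, err)
    else:
        tau = ndt[..., None] + 0.5 * st * _GL_X
        f = _density_lower_np(
            rt[..., None] - tau, d[..., None], a_safe[..., None], 0.5, sv, err
        )
        dens = np.sum(0.5 * _GL_W * f, axis=-1)
    with np.errstate(divide="ignore"):
        ll = np.where(dens > 0, np.log(np.maximum(dens, 1e-320)), -np.inf)
    ll[bad] = -np.inf
    return ll


_NB_KERNEL = None


def _build_numba_kernel():
    import numba

    err = SERIES_ERR
    glx = _GL_X.copy()
    glw = _GL_W.copy()

    @numba.njit(cache=False, fastmath=False)
    def dens_lower_half(t, v, a, sv):
        # specialized to the unbiased start z = 0.5 used throughout inference
        if t <= 0.0:
            return 0.0
        w = t / (a * a)
        # series-length bounds
        sqw = math.sqrt(w)
        arg_s = 2.0 * err * math.sqrt(2.0 * math.pi) * sqw
        if arg_s < 1.0:
            ks = 2.0 + math.sqrt(max(-2.0 * w * math.log(arg_s), 0.0))
        else:
            ks = 2.0
        if ks < sqw + 1.0:
            ks = sqw + 1.0
        arg_l = math.pi * w * err
        if arg_l < 1.0:
            kl = math.sqrt(max(-2.0 * math.log(arg_l), 0.0) / (math.pi * math.pi * w))
        else:
            kl = 0.0
        if kl < 1.0 / (math.pi * sqw):
            kl = 1.0 / (math.pi * sqw)
        g = 0.0
        if ks < kl:
            # Gaussian-image terms ordered by increasing |offset|: 0.5, -1.5,
            # 2.5, -3.5, ...; magnitudes decay monotonically, so stop once a
            # term is negligible.
            n_terms = int(math.ceil(ks)) + 2
            if n_terms > 128:
                n_terms = 128
            s = 0.0
            for j in range(n_terms):
                u = 0.5 + j
                if j % 2 == 1:
                    u = -u
                e = -u * u / (2.0 * w)
                if e < -700.0:
                    break
                term = u * math.exp(e)
                s += term
                if j >= 2 and abs(term) < 1e-12 * abs(s):
                    break
            g = s / math.sqrt(2.0 * math.pi * w * w * w)
        else:
            # at z = 0.5, sin(k*pi/2) vanishes for even k and alternates sign
            # over odd k: +1, -1, +1, ... for k = 1, 3, 5, ...
            kmax = int(math.ceil(kl)) + 1
            if kmax > 512:
                kmax = 512
            s = 0.0
            sign = 1.0
            for k in range(1, kmax + 1, 2):
                e = -k * k * math.pi * math.pi * w / 2.0
                if e < -700.0:
                    break
                s += sign * k * math.exp(e)
                sign = -sign
            g = math.pi * s
        if g < 0.0:
            g = 0.0
        if sv > 0.0:
            q = ((0.5 * a * sv) ** 2 - a * v - v * v * t) / (2.0 * (1.0 + sv * sv * t))
            if q < -700.0:
                fac = 0.0
            else:
                fac = math.exp(q) / math.sqrt(1.0 + sv * sv * t)
        else:
            q = -0.5 * v * a - v * v * t / 2.0
            if q < -700.0:
                fac = 0.0
            else:
                fac = math.exp(q)
        return g / (a * a) * fac

    @numba.njit(cache=False, fastmath=False)
    def kernel(rt, sign, drift, bound, ndt, sv, st, out):
        for i in range(rt.size):
            a = bound[i]
            nd = ndt[i]
            if a <= 0.0 or nd - st / 2.0 < -1e-12 or rt[i] <= nd - st / 2.0:
                out[i] = -np.inf
                continue
            d = sign[i] * drift[i]
            if st == 0.0:
                f = dens_lower_half(rt[i] - nd, d, a, sv)
            else:
                f = 0.0
                for q in range(glx.size):
                    tau = nd + 0.5 * st * glx[q]
                    f += 0.5 * glw[q] * dens_lower_half(rt[i] - tau, d, a, sv)
            if f > 0.0:
                out[i] = math.log(f)
            else:
                out[i] = -np.inf

    return kernel


def loglik_trials(rt, is_upper, drift, bound, ndt, sv, st):
    """Per-trial log likelihood; compiled fast path with numpy fallback."""
    global _NB_KERNEL
    if _NB_KERNEL is None:
        try:
            _NB_KERNEL = _build_numba_kernel()
        except Exception:  # pragma: no cover - numba unavailable or broken
            _NB_KERNEL = False
    if _NB_KERNEL is False:  # pragma: no cover
        return loglik_trials_np(rt, is_upper, drift, bound, ndt, sv, st)
    rt = np.ascontiguousarray(rt, float)
    sign = np.where(np.asarray(is_upper, bool), -1.0, 1.0)
    drift = np.ascontiguousarray(np.broadcast_to(drift, rt.shape), float)
    bound = np.ascontiguousarray(np.broadcast_to(bound, rt.shape), float)
    ndt = np.ascontiguousarray(np.broadcast_to(ndt, rt.shape), float)
    out = np.empty(rt.shape, float)
    _NB_KERNEL(rt, sign, drift, bound, ndt, float(sv), float(st), out)
    return out
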