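"""Constant-rate birth-death diversification fitting on dated trees.

The model: each lineage speciates at rate ``lam`` and goes extinct at
rate ``mu`` (events/lineage/My), and each extant species is sampled
independently with probability ``f`` (rho-sampling).  The likelihood of
a reconstructed tree is conditioned on the crown age and on both crown
lineages leaving sampled descendants, which matches the behaviour of
standard diversification software for crown-dated trees.

With ``r = lam - mu``, write the probability that a lineage alive
``t`` My ago leaves *no* sampled descendants as

    E(t) = 1 - f r / (f lam + (lam (1 - f) - mu) exp(-r t))

and the density that it leaves exactly one sampled lineage in the
reconstructed tree as

    p1(t) = f r^2 exp(-r t) / (f lam + (lam (1 - f) - mu) exp(-r t))^2.

The crown-conditioned log-likelihood of branching times
``t_1 > t_2 >= ... >= t_{n-1}`` (``t_1`` the crown age, n tips) is

    sum_{i=2}^{n-1} [log lam + log p1(t_i)]
        + 2 log p1(t_1) - 2 log(1 - E(t_1)).

At ``mu = 0, f = 1`` this reduces to the crown-conditioned Yule
log-likelihood ``(n-2) log lam - lam (2 t_1 + sum_{i>=2} t_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

from .trees import DatedTree

__all__ = [
    "BDParams",
    "BDFit",
    "bd_loglik",
    "fit_bd",
    "relative_extinction",
    "transform_for_regression",
]

# chi^2_1 0.95 quantile / 2: the profile-likelihood drop defining 95% CIs
PROFILE_DROP = 1.9207293216431571

# mu-hat below this fraction of lambda-hat is treated as the mu = 0 boundary
_BOUNDARY_FRAC = 1e-6


@dataclass(frozen=True)
class BDParams:
    """Birth-death parameters: speciation ``lam``, extinction ``mu``
    (events/lineage/My) and sampling fraction ``f`` in (0, 1]."""

    lam: float
    mu: float
    f: float = 1.0

    def __post_init__(self):
        if not (self.lam >= 0) or not (self.mu >= 0):
            raise ValueError("lam and mu must be nonnegative")
        if not (0 < self.f <= 1):
            raise ValueError("sampling fraction f must lie in (0, 1]")


@dataclass
class BDFit:
    """Maximum-likelihood birth-death fit with profile-likelihood CIs."""

    mle: BDParams
    loglik: float
    ci_lam: tuple[float, float]
    ci_mu: tuple[float, float]
    epsilon: float
    converged: bool
    boundary: bool  # mu-hat on the mu = 0 boundary
    n_tips: int = 0
    diagnostics: dict = field(default_factory=dict)


def _log_p1_and_survival(t, lam, mu, f):
    """log p1(t) and log(1 - E(t)) for an array of ages t, stably.

    Uses the r -> 0 closed form when the net rate is tiny; for r < 0
    (declining diversity) denom and r are both negative and the same
    expressions remain valid probabilities.
    """
    t = np.asarray(t, dtype=float)
    r = lam - mu
    if abs(r) <= 1e-12 * max(lam, mu, 1.0):
        # critical process: 1 - E(t) = f / (1 + f lam t), p1 = (1-E)^2 / f
        log_surv = np.log(f) - np.log1p(f * lam * t)
        log_p1 = 2.0 * log_surv - np.log(f)
        return log_p1, log_surv
    a = lam * (1.0 - f) - mu
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        denom = f * lam + a * np.exp(-r * t)
        surv = f * r / denom
        p1 = f * r * r * np.exp(-r * t) / (denom * denom)
    ok = (
        np.all(np.isfinite(surv))
        and np.all(surv > 0)
        and np.all(surv <= 1 + 1e-12)
        and np.all(np.isfinite(p1))
        and np.all(p1 > 0)
    )
    if not ok:
        return None, None
    return np.log(p1), np.log(surv)


def _loglik_times(t1, other_times, lam, mu, f):
    """Crown-conditioned log-likelihood from branching times."""
    if lam <= 0 or mu < 0 or not (0 < f <= 1):
        return -np.inf
    t_all = np.concatenate(([t1], np.asarray(other_times, dtype=float)))
    log_p1, log_surv = _log_p1_and_survival(t_all, lam, mu, f)
    if log_p1 is None:
        return -np.inf
    value = (
        len(other_times) * np.log(lam)
        + log_p1[1:].sum()
        + 2.0 * log_p1[0]
        - 2.0 * log_surv[0]
    )
    return float(value) if np.isfinite(value) else -np.inf


def bd_loglik(tree: DatedTree, params: BDParams) -> float:
    """Log-likelihood (nats) of a dated tree under the birth-death model.

    Conditioned on the crown age and on both crown lineages leaving
    sampled descendants; tip sampling fraction ``params.f`` enters the
    survival function (rho-sampling).  Finite for all interior parameter
    values; ``-inf`` only for degenerate input.
    """
    times = tree.branching_times()
    t1, rest = times[0], np.array(times[1:], dtype=float)
    return _loglik_times(t1, rest, params.lam, params.mu, params.f)


def relative_extinction(lam: float, mu: float) -> float:
    """Relative extinction ``epsilon = mu / lam``; exactly 0 when mu = 0."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    return 0.0 if mu == 0 else mu / lam


def transform_for_regression(lam: float, epsilon: float) -> tuple[float, float]:
    """Normalizing transforms for cross-clade regression:
    ``(log10(lam), epsilon**2)``."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    return float(np.log10(lam)), float(epsilon**2)


def _yule_start(t1, other_times, n):
    """Method-of-moments speciation guess: the crown Yule MLE."""
    total = 2.0 * t1 + float(np.sum(other_times))
    return max((n - 2), 1) / total if total > 0 else 1.0


def fit_bd(
    tree: DatedTree,
    f: float = 1.0,
    epsilon_starts: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 0.9),
    compute_ci: bool = True,
) -> BDFit:
    """Maximum-likelihood (lam, mu) with 95% profile-likelihood CIs.

    Optimizes the crown-conditioned log-likelihood over ``lam > 0`` and
    ``mu >= 0`` by bounded quasi-Newton from multiple starts: a
    method-of-moments ``lam`` guess crossed with a grid of relative
    extinction values.  CIs are profile-likelihood intervals at the
    chi-square(1) 95% drop (1.92 units), with the lower mu bound
    truncated at 0.
    """
    if not (0 < f <= 1):
        raise ValueError("sampling fraction f must lie in (0, 1]")
    n = tree.n_tips
    if n < 3:
        raise ValueError("birth-death fitting needs at least 3 tips")
    times = tree.branching_times()
    t1, rest = times[0], np.array(times[1:], dtype=float)

    def nll(theta):
        lam, mu = theta
        value = -_loglik_times(t1, rest, lam, mu, f)
        # keep the quasi-Newton's finite differences finite
        return value if np.isfinite(value) else 1e10

    lam0 = _yule_start(t1, rest, n)
    # under incomplete sampling the Yule guess understates lam
    lam0_adj = lam0 / f
    bounds = [(lam0 * 1e-4, lam0_adj * 1e4), (0.0, lam0_adj * 1e4)]
    best = None
    n_ok = 0
    for eps in epsilon_starts:
        start = np.array([lam0_adj / max(1.0 - eps, 0.05), eps * lam0_adj])
        res = minimize(
            nll,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    if best is None:
        raise RuntimeError(
            f"birth-death optimization failed from all {len(epsilon_starts)} starts"
        )
    lam_hat, mu_hat = best.x
    boundary = mu_hat <= _BOUNDARY_FRAC * lam_hat
    if boundary:
        # re-polish on the boundary
        res0 = minimize_scalar(
            lambda lam: -_loglik_times(t1, rest, lam, 0.0, f),
            bounds=(bounds[0][0], bounds[0][1]),
            method="bounded",
            options={"xatol": 1e-12},
        )
        if -res0.fun >= -best.fun - 1e-9:
            lam_hat, mu_hat = res0.x, 0.0
    loglik = _loglik_times(t1, rest, lam_hat, mu_hat, f)

    ci_lam = (np.nan, np.nan)
    ci_mu = (np.nan, np.nan)
    if compute_ci:
        ci_lam = _profile_ci(
            lambda lam, mu: _loglik_times(t1, rest, lam, mu, f),
            which=0,
            mle=(lam_hat, mu_hat),
            loglik=loglik,
            lower_floor=None,
        )
        ci_mu = _profile_ci(
            lambda mu, lam: _loglik_times(t1, rest, lam, mu, f),
            which=1,
            mle=(mu_hat, lam_hat),
            loglik=loglik,
            lower_floor=0.0,
        )
    mle = BDParams(lam=float(lam_hat), mu=float(mu_hat), f=f)
    return BDFit(
        mle=mle,
        loglik=float(loglik),
        ci_lam=ci_lam,
        ci_mu=ci_mu,
        epsilon=relative_extinction(mle.lam, mle.mu),
        converged=bool(best.success) or n_ok > 0,
        boundary=bool(mu_hat == 0.0),
        n_tips=n,
        diagnostics={"n_starts_ok": n_ok, "optimizer_message": str(best.message)},
    )


def _profile_ci(profiled_loglik, which, mle, loglik, lower_floor):
    """95% profile-likelihood interval for one parameter.

    ``profiled_loglik(theta, other)`` is the log-likelihood with the
    profiled parameter first; the nuisance parameter is re-optimized at
    every fixed value of theta.
    """
    theta_hat, other_hat = mle
    target = loglik - PROFILE_DROP

    def _clamped(value):
        return value if np.isfinite(value) else 1e10

    def profile(theta):
        if which == 0:  # profiling lam; nuisance mu >= 0
            res = minimize_scalar(
                lambda mu: _clamped(-profiled_loglik(theta, mu)),
                bounds=(0.0, max(10.0 * (other_hat + theta), 1e-6)),
                method="bounded",
                options={"xatol": 1e-10},
            )
        else:  # profiling mu; nuisance lam > 0
            res = minimize_scalar(
                lambda lam: _clamped(-profiled_loglik(theta, lam)),
                bounds=(1e-10, max(10.0 * (other_hat + theta), 1e-6)),
                method="bounded",
                options={"xatol": 1e-10},
            )
        return -res.fun

    def g(theta):
        return profile(theta) - target

    scale = max(theta_hat, other_hat, 1e-3)
    # upper bound: expand until profile drops below target
    hi = max(theta_hat, 1e-8)
    step = max(scale, 1e-3)
    upper = np.nan
    for _ in range(60):
        hi_try = hi + step
        if g(hi_try) < 0:
            upper = brentq(g, hi, hi_try, xtol=1e-8 * max(scale, 1.0))
            break
        hi = hi_try
        step *= 1.6
    # lower bound
    floor = 0.0 if lower_floor is None else lower_floor
    lower = np.nan
    if which == 1 and g(floor) >= 0:
        lower = floor  # mu CI truncated at 0
    else:
        lo = theta_hat
        found = False
        if which == 0:
            # lam > 0: shrink geometrically toward 0
            lo_try = theta_hat
            for _ in range(80):
                lo_try = lo_try / 2.0
                if g(lo_try) < 0:
                    lower = brentq(g, lo_try, lo, xtol=1e-10 * max(scale, 1.0))
                    found = True
                    break
                lo = lo_try
            if not found:
                lower = 0.0
        else:
            lower = floor if g(floor) >= 0 else brentq(
                g, floor, theta_hat, xtol=1e-10 * max(scale, 1.0)
            )
    return (float(lower), float(upper))
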