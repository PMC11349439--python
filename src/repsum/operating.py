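"""Operating characteristics of the replication-success criteria.

Three quantities describe how a success criterion behaves:

* the *conditional Type-I error rate* — the probability of declaring
  success given the observed original result when the replication's true
  effect is zero; because every criterion here is of the form
  ``p_r <= t(p_o)``, this rate equals the success threshold ``t(p_o)``
  itself, i.e. the significance level effectively required of the
  replication;
* the *overall Type-I error rate* — the success probability under the
  intersection null (both effects zero), calibrated to ``alpha**2`` for
  every method and verifiable by Monte Carlo;
* the *project power* — the probability of success when both effects are
  non-null, over the randomness of both studies.

The generative model: the original z-value is ``z_o ~ N(mu_o, 1)`` with
``mu_o = z_{1-alpha} + Phi^{-1}(original_power)`` (the noncentrality at
which the original study attains its design power), and the replication
z-value is ``z_r ~ N(d * sqrt(c) * mu_o, 1)`` with effect ratio
``d = theta_r / theta_o`` and relative sample size ``c = n_r / n_o``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from repsum.combine import (
    DEFAULT_ALPHA,
    DEFAULT_WEIGHTS,
    METHODS,
    WeightScheme,
    budget,
    combined_pvalues,
    fisher_critical_product,
)

__all__ = [
    "Scenario",
    "conditional_level",
    "overall_type1_mc",
    "project_power",
    "project_power_limit",
]


@dataclass(frozen=True)
class Scenario:
    """Study-pair scenario for operating-characteristic calculations.

    Parameters
    ----------
    method
        One of ``edgington``, ``edgington_weighted``, ``two_trials``,
        ``fisher``, ``meta``.
    alpha
        One-sided significance level of a single study (default 0.025).
    original_power
        Power of the original study at level ``alpha``; fixes the
        noncentrality ``mu_o = z_{1-alpha} + Phi^{-1}(original_power)``.
    d
        Effect-size ratio ``theta_r / theta_o``.
    c
        Relative sample size ``n_r / n_o`` (equals the variance ratio).
    weights
        Weight scheme for the weighted Edgington variant.
    alpha2
        Overall level; defaults to ``alpha**2`` and should normally be left
        at that calibrated value.
    """

    method: str = "edgington"
    alpha: float = DEFAULT_ALPHA
    original_power: float = 0.8
    d: float = 1.0
    c: float = 1.0
    weights: WeightScheme = DEFAULT_WEIGHTS
    alpha2: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha!r}")
        if not 0.0 < self.original_power < 1.0:
            raise ValueError(f"original_power must be in (0, 1), got {self.original_power!r}")
        if self.d < 0.0:
            raise ValueError(f"effect ratio d must be nonnegative, got {self.d!r}")
        if self.c <= 0.0:
            raise ValueError(f"relative sample size c must be positive, got {self.c!r}")
        if self.alpha2 is None:
            object.__setattr__(self, "alpha2", self.alpha**2)

    @property
    def mu_o(self) -> float:
        """Noncentrality (mean) of the original z-value."""
        return float(stats.norm.isf(self.alpha) + stats.norm.ppf(self.original_power))

    @property
    def mu_r(self) -> float:
        """Noncentrality (mean) of the replication z-value, ``d*sqrt(c)*mu_o``."""
        return self.d * math.sqrt(self.c) * self.mu_o


def _success_threshold(p_o, scenario: Scenario):
    """Largest p_r still giving success at level alpha2, given p_o (vectorised)."""
    s = scenario
    p_o = np.asarray(p_o, dtype=float)
    if s.method == "edgington":
        b = budget(s.alpha)
        return np.clip(b - p_o, 0.0, 1.0)
    if s.method == "edgington_weighted":
        w = s.weights
        b_w = budget(s.alpha, w)
        return np.clip((b_w - w.w_o * p_o) / w.w_r, 0.0, 1.0)
    if s.method == "two_trials":
        return np.where(p_o <= s.alpha, s.alpha, 0.0)
    if s.method == "fisher":
        return np.minimum(fisher_critical_product(s.alpha) / p_o, 1.0)
    if s.method == "meta":
        z_o = stats.norm.isf(p_o)
        z_crit = stats.norm.isf(s.alpha2)
        return stats.norm.sf(z_crit * math.sqrt(s.c + 1.0) - z_o * math.sqrt(s.c))
    raise ValueError(f"unknown method {s.method!r}")


def conditional_level(p_o: float, scenario: Scenario) -> float:
    """Conditional Type-I error rate given the original p-value.

    Equals the largest replication p-value still yielding success, i.e. the
    significance level effectively required of the replication study:
    ``b - p_o`` for unweighted Edgington, ``(b_w - w_o*p_o)/w_r`` for the
    weighted variant, ``min(c_F/p_o, 1)`` for Fisher, a shifted normal tail
    for the meta criterion, and ``alpha`` (or 0 when ``p_o > alpha``) for
    the two-trials rule.  Fisher and meta converge to 1 as ``p_o -> 0``; the
    Edgington variants stay bounded by ``b`` and ``b_w/w_r`` respectively.
    """
    if not 0.0 < p_o < 1.0:
        raise ValueError(f"p_o must be in (0, 1), got {p_o!r}")
    return float(_success_threshold(p_o, scenario))


def overall_type1_mc(
    scenario: Scenario, n_sims: int = 10**7, seed: int | None = None
) -> tuple[float, float]:
    """Monte-Carlo overall Type-I error rate under the intersection null.

    Simulates independent uniform ``(p_o, p_r)`` pairs, applies the
    scenario's success rule at level ``alpha2``, and returns the empirical
    rejection rate with its binomial standard error.  Every calibrated
    method should come out at ``alpha**2`` (0.000625 at alpha = 0.025).
    """
    if n_sims < 10**5:
        raise ValueError(f"n_sims must be at least 1e5 for a meaningful rate, got {n_sims}")
    rng = np.random.default_rng(seed)
    p_o = rng.uniform(size=n_sims)
    p_r = rng.uniform(size=n_sims)
    p = combined_pvalues(p_o, p_r, scenario.method, weights=scenario.weights, c=scenario.c)
    rate = float(np.mean(p <= scenario.alpha2))
    se = math.sqrt(rate * (1.0 - rate) / n_sims)
    return rate, se


def project_power(scenario: Scenario) -> float:
    """Probability of replication success when both effects are non-null.

    Closed forms exist for the two-trials rule (product of two normal
    tails) and the meta criterion (single normal tail at the shifted mean
    of ``z_MA``).  The Edgington variants and Fisher are computed by
    adaptive quadrature over the original z-value: the integrand
    ``phi(z_o - mu_o) * Phi(mu_r - z_{1 - t(p_o)})`` is smooth on the
    z-scale, with ``t`` the method's success threshold on ``p_r``.
    """
    s = scenario
    mu_o, mu_r = s.mu_o, s.mu_r
    if s.method == "two_trials":
        z_a = stats.norm.isf(s.alpha)
        return float(stats.norm.cdf(mu_o - z_a) * stats.norm.cdf(mu_r - z_a))
    if s.method == "meta":
        mean = (mu_o + math.sqrt(s.c) * mu_r) / math.sqrt(1.0 + s.c)
        return float(stats.norm.cdf(mean - stats.norm.isf(s.alpha2)))

    def integrand(z_o: float) -> float:
        t = float(_success_threshold(stats.norm.sf(z_o), s))
        if t <= 0.0:
            return 0.0
        if t >= 1.0:
            return float(stats.norm.pdf(z_o - mu_o))
        return float(stats.norm.pdf(z_o - mu_o) * stats.norm.cdf(mu_r - stats.norm.isf(t)))

    val, err = integrate.quad(
        integrand, mu_o - 8.5, mu_o + 8.5, epsabs=1e-9, epsrel=1e-9, limit=200
    )
    if not math.isfinite(val) or err > 1e-6:
        raise RuntimeError(
            f"project-power quadrature did not converge (value={val!r}, abs err={err:.2e})"
        )
    return min(max(val, 0.0), 1.0)


def project_power_limit(scenario: Scenario) -> float:
    """Project power in the limit of an infinitely large replication study.

    For ``d > 0`` the replication p-value converges to 0 as ``c -> inf``,
    so success reduces to a condition on ``p_o`` alone: ``p_o <= L`` with
    ``L = alpha`` for the two-trials rule, ``L = b`` for unweighted
    Edgington and ``L = b_w / w_o`` for the weighted variant.  The limit is
    then the normal tail ``Phi(mu_o - z_{1-L})``.  Fisher and meta have
    limit 1 (any ``p_o`` can be rescued); they are rejected here because
    the finite-``c`` function should be used instead.
    """
    s = scenario
    if s.d == 0.0:
        raise ValueError(
            "limit undefined for d = 0: the replication p-value stays uniform, "
            "use project_power at finite c"
        )
    if s.method == "two_trials":
        level = s.alpha
    elif s.method == "edgington":
        level = budget(s.alpha)
    elif s.method == "edgington_weighted":
        level = budget(s.alpha, s.weights) / s.weights.w_o
    else:
        raise ValueError(
            f"no nondegenerate large-c limit for method {s.method!r} "
            "(Fisher and meta converge to 1); use project_power at finite c"
        )
    return float(stats.norm.cdf(s.mu_o - stats.norm.isf(min(level, 1.0))))
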