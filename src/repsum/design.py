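"""Replication sample-size planning under conditional or predictive power.

A replication designed for analysis with one of the combination methods
must be powered at the *method-specific* significance level: the largest
replication p-value that still yields success given the observed original
p-value (``b - p_o`` for unweighted Edgington, ``alpha - p_o/2`` for the
1:2-weighted variant, ``alpha`` for the two-trials rule).  Sample sizes
follow the standard balanced two-sample z-test formula, either on the
absolute scale (per-group ``n_r``) or on the relative scale
``c = n_r / n_o``.

Conditional power treats the original effect estimate as the true effect;
predictive power averages over its sampling uncertainty via the
normal-normal predictive distribution ``theta_hat_r | theta_hat_o ~
N(theta_hat_o, sigma_o^2 + sigma_r^2)``, which gives the replication
success probability ``Phi((z_o*sqrt(c) - z_{1-level}) / sqrt(c + 1))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize, stats

from repsum.combine import (
    DEFAULT_ALPHA,
    DEFAULT_WEIGHTS,
    WeightScheme,
    budget,
)

__all__ = [
    "DesignSpec",
    "replication_level",
    "sample_size_absolute",
    "sample_size_relative",
    "predictive_power",
    "predictive_relative_sample_size",
    "sample_size_ratio",
]

_DESIGN_METHODS = ("edgington", "edgington_weighted", "two_trials")


@dataclass(frozen=True)
class DesignSpec:
    """Specification of a replication sample-size calculation.

    Parameters
    ----------
    p_o
        One-sided p-value of the original study.
    method
        Analysis method the replication is designed for: ``edgington``,
        ``edgington_weighted`` or ``two_trials``.
    alpha
        One-sided significance level (default 0.025).
    power
        Target power ``1 - beta`` (default 0.8).
    mode
        ``conditional`` or ``predictive``.
    weights
        Weight scheme for the weighted variant (default 1:2).
    shrinkage
        Fraction in [0, 1) by which the original effect estimate is shrunk
        before use, offsetting inflation of published effects (e.g. 0.25).
    tau, theta_hat_o
        Common standard deviation of the measurements and the original
        effect estimate; required for the absolute (per-group) sample size.
    n_o
        Original per-group size, used only to convert the relative size
        ``c`` into an absolute replication size.
    """

    p_o: float
    method: str = "edgington"
    alpha: float = DEFAULT_ALPHA
    power: float = 0.8
    mode: str = "conditional"
    weights: WeightScheme = DEFAULT_WEIGHTS
    shrinkage: float = 0.0
    tau: float | None = None
    theta_hat_o: float | None = None
    n_o: int | None = None

    def __post_init__(self) -> None:
        if self.method not in _DESIGN_METHODS:
            raise ValueError(
                f"design method must be one of {_DESIGN_METHODS}, got {self.method!r}"
            )
        if not 0.0 < self.p_o < 1.0:
            raise ValueError(f"p_o must be in (0, 1), got {self.p_o!r}")
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power must be in (0, 1), got {self.power!r}")
        if self.mode not in ("conditional", "predictive"):
            raise ValueError(f"mode must be 'conditional' or 'predictive', got {self.mode!r}")
        if not 0.0 <= self.shrinkage < 1.0:
            raise ValueError(f"shrinkage must be in [0, 1), got {self.shrinkage!r}")

    @property
    def z_o(self) -> float:
        """z-value of the original study."""
        return float(stats.norm.isf(self.p_o))

    @property
    def level(self) -> float:
        """Method-specific significance level required of the replication."""
        return replication_level(self.p_o, self.method, self.alpha, self.weights)


def replication_level(
    p_o: float,
    method: str = "edgington",
    alpha: float = DEFAULT_ALPHA,
    weights: WeightScheme = DEFAULT_WEIGHTS,
) -> float:
    """Significance level the replication must attain, given ``p_o``.

    ``b - p_o`` (unweighted Edgington), ``(b_w - w_o*p_o)/w_r`` (weighted),
    or ``alpha`` (two-trials rule).  Raises when replication success is
    impossible for the given original p-value (e.g. ``p_o >= 0.0354``
    unweighted at alpha = 0.025).
    """
    if not 0.0 < p_o < 1.0:
        raise ValueError(f"p_o must be in (0, 1), got {p_o!r}")
    if method == "edgington":
        level = budget(alpha) - p_o
    elif method == "edgington_weighted":
        level = (budget(alpha, weights) - weights.w_o * p_o) / weights.w_r
    elif method == "two_trials":
        level = alpha if p_o <= alpha else 0.0
    else:
        raise ValueError(f"design method must be one of {_DESIGN_METHODS}, got {method!r}")
    if level <= 0.0:
        raise ValueError(
            f"replication success is impossible with {method} for p_o = {p_o:g} "
            f"(required level would be {level:g})"
        )
    return min(level, 1.0)


def sample_size_absolute(spec: DesignSpec) -> tuple[float, int]:
    """Per-group replication sample size for a balanced two-sample z-test.

    ``n_r = 2 * tau^2 * (z_{1-level} + z_{1-beta})^2 / theta_hat_o^2`` with
    the method-specific level in place of ``alpha`` and the (optionally
    shrunk) original estimate in place of the minimal clinically important
    difference.  Returns the real-valued size and its ceiling.
    """
    if spec.tau is None or spec.theta_hat_o is None:
        raise ValueError("absolute sample size requires tau and theta_hat_o")
    theta = spec.theta_hat_o * (1.0 - spec.shrinkage)
    if theta == 0.0:
        raise ValueError("original effect estimate is zero; sample size undefined")
    z_a = stats.norm.isf(spec.level)
    z_b = stats.norm.ppf(spec.power)
    n = 2.0 * spec.tau**2 * (z_a + z_b) ** 2 / theta**2
    return float(n), math.ceil(n)


def sample_size_relative(spec: DesignSpec) -> float:
    """Relative replication sample size ``c = n_r / n_o``.

    Conditional mode: closed form ``(z_{1-level} + z_{1-beta})^2 / z_o^2``.
    Predictive mode: root-solved so the predictive success probability
    attains the target power.
    """
    z_o = spec.z_o
    if z_o <= 0.0:
        raise ValueError(
            f"original estimate points in the wrong direction (p_o = {spec.p_o:g} >= 0.5)"
        )
    if spec.mode == "predictive":
        return predictive_relative_sample_size(z_o, spec.level, spec.power)
    z_a = stats.norm.isf(spec.level)
    z_b = stats.norm.ppf(spec.power)
    return float((z_a + z_b) ** 2 / z_o**2)


def predictive_power(z_o: float, c: float, level: float) -> float:
    """Probability the replication succeeds at ``level``, averaged over the
    uncertainty of the original estimate.

    Normal-normal predictive distribution of the replication z-value gives
    ``Phi((z_o*sqrt(c) - z_{1-level}) / sqrt(c + 1))``; always closer to 1/2
    than the corresponding conditional power.
    """
    if c <= 0.0:
        raise ValueError(f"relative sample size c must be positive, got {c!r}")
    return float(
        stats.norm.cdf((z_o * math.sqrt(c) - stats.norm.isf(level)) / math.sqrt(c + 1.0))
    )


def predictive_relative_sample_size(z_o: float, level: float, power: float) -> float:
    """Relative sample size ``c`` with predictive power ``power`` at ``level``.

    Bisection on ``sqrt(c)`` over [1e-3, 1e3]; the predictive power is
    monotone in ``sqrt(c)`` whenever ``z_o > z_{1-level} * sqrt(c/(c+1))``
    throughout the bracket, which holds for all attainable targets.
    """
    if z_o <= 0.0:
        raise ValueError(f"z_o must be positive, got {z_o!r}")

    def gap(s: float) -> float:
        return predictive_power(z_o, s * s, level) - power

    lo, hi = 1e-3, 1e3
    if gap(lo) * gap(hi) > 0.0:
        raise ValueError(
            f"target predictive power {power:g} not attainable for z_o = {z_o:g} "
            f"at level {level:g} within c in [1e-6, 1e6]"
        )
    s = optimize.brentq(gap, lo, hi, xtol=1e-10)
    return float(s * s)


def sample_size_ratio(
    p_o: float,
    power: float = 0.8,
    method: str = "edgington",
    mode: str = "conditional",
    alpha: float = DEFAULT_ALPHA,
    weights: WeightScheme = DEFAULT_WEIGHTS,
) -> float:
    """Replication sample size of an Edgington design over the two-trials one.

    Conditional mode uses the closed-form ratio
    ``(z_{1-level} + z_{1-beta})^2 / (z_{1-alpha} + z_{1-beta})^2``;
    predictive mode takes the ratio of the two root-solved relative sizes.
    The unweighted conditional ratio equals 1 exactly at
    ``p_o = alpha*(sqrt(2) - 1)``: smaller original p-values need a smaller
    replication than under the two-trials rule, larger ones a bigger one.
    The reported reduction is ``1 - ratio``.
    """
    if not 0.0 < p_o <= alpha:
        raise ValueError(
            f"p_o must be in (0, alpha] for the two-trials comparator, got {p_o!r}"
        )
    level = replication_level(p_o, method, alpha, weights)
    z_b = stats.norm.ppf(power)
    if mode == "conditional":
        num = stats.norm.isf(level) + z_b
        den = stats.norm.isf(alpha) + z_b
        return float((num / den) ** 2)
    if mode == "predictive":
        z_o = float(stats.norm.isf(p_o))
        c_method = predictive_relative_sample_size(z_o, level, power)
        c_2tr = predictive_relative_sample_size(z_o, alpha, power)
        return c_method / c_2tr
    raise ValueError(f"mode must be 'conditional' or 'predictive', got {mode!r}")
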