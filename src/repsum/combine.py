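"""Combined p-values for an original/replication pair of one-sided p-values.

Five success criteria are supported, all calibrated so that the overall
Type-I error rate under the intersection null (both true effects zero)
equals ``alpha**2``:

``two_trials``
    both p-values significant at ``alpha``; combined p is ``max(p_o, p_r)**2``.
``edgington``
    sum of p-values ``E = p_o + p_r`` referred to the Irwin-Hall(2)
    distribution.
``edgington_weighted``
    weighted sum ``E_w = w_o*p_o + w_r*p_r`` referred to the distribution of
    the matching weighted sum of two independent standard uniforms.
``fisher``
    ``-2*log(p_o*p_r)`` referred to a chi-squared distribution with 4 df.
``meta``
    fixed-effect (weighted Stouffer) z-statistic; requires the variance
    ratio ``c = sigma_o**2 / sigma_r**2``, interpretable as the relative
    sample size ``n_r / n_o``.

The scalar entry points return a :class:`CombinedResult`; the underscored
array kernels operate on numpy arrays and back both the scalar API and the
Monte-Carlo machinery, so batch and scalar paths cannot drift apart.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Inputs exactly 0 or 1 are clipped into this open interval so that
#: z-transforms stay finite; ordinary inputs are never altered.
P_EPS = 1e-16

METHODS = ("edgington", "edgington_weighted", "two_trials", "fisher", "meta")

DEFAULT_ALPHA = 0.025


def _as_prob(p: float, name: str) -> float:
    p = float(p)
    if not math.isfinite(p) or p < 0.0 or p > 1.0:
        raise ValueError(f"{name} must be a p-value in [0, 1], got {p!r}")
    if p < P_EPS or p > 1.0 - P_EPS:
        logger.warning("%s = %g clipped to the open unit interval", name, p)
        p = min(max(p, P_EPS), 1.0 - P_EPS)
    return p


@dataclass(frozen=True)
class StudyPair:
    """One-sided p-values of an original and a replication study.

    Parameters
    ----------
    p_o, p_r
        One-sided p-values in (0, 1).  Values above 0.5 indicate an effect
        estimate pointing in the unexpected direction and need no special
        treatment.  Exact 0/1 are clipped to ``[1e-16, 1 - 1e-16]`` with a
        logged warning.
    c
        Optional variance ratio ``sigma_o**2 / sigma_r**2``, interpretable
        as the relative sample size ``n_r / n_o``.  Required by the
        meta-analysis criterion only.
    """

    p_o: float
    p_r: float
    c: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_o", _as_prob(self.p_o, "p_o"))
        object.__setattr__(self, "p_r", _as_prob(self.p_r, "p_r"))
        if self.c is not None:
            c = float(self.c)
            if not math.isfinite(c) or c <= 0.0:
                raise ValueError(f"variance ratio c must be positive, got {c!r}")
            object.__setattr__(self, "c", c)

    @property
    def z_o(self) -> float:
        """z-value of the original study, ``Phi^{-1}(1 - p_o)``."""
        return float(stats.norm.isf(self.p_o))

    @property
    def z_r(self) -> float:
        """z-value of the replication study, ``Phi^{-1}(1 - p_r)``."""
        return float(stats.norm.isf(self.p_r))


@dataclass(frozen=True)
class WeightScheme:
    """Positive weights for the original and replication p-value.

    Only the ratio ``w_r / w_o`` matters: every derived quantity is
    invariant under rescaling both weights by a positive constant.
    """

    w_o: float = 1.0
    w_r: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_o", "w_r"):
            w = float(getattr(self, name))
            if not math.isfinite(w) or w <= 0.0:
                raise ValueError(f"{name} must be positive, got {w!r}")
            object.__setattr__(self, name, w)

    @property
    def ratio(self) -> float:
        """Replication-to-original weight ratio ``w_r / w_o``."""
        return self.w_r / self.w_o


#: Default weighting of the weighted variant: replication counts twice.
DEFAULT_WEIGHTS = WeightScheme(1.0, 2.0)


@dataclass(frozen=True)
class CombinedResult:
    """A combined p-value with its success verdict at the overall level."""

    p_combined: float
    method: str
    statistic: float
    alpha2: float
    success: bool = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_combined <= 1.0:
            raise ValueError(f"combined p-value outside [0, 1]: {self.p_combined!r}")
        # success at exact equality counts as success
        object.__setattr__(self, "success", self.p_combined <= self.alpha2)


# ---------------------------------------------------------------------------
# Irwin-Hall distribution and the weighted two-uniform sum
# ---------------------------------------------------------------------------

_IRWIN_HALL_MAX_N = 10


def irwin_hall_cdf(x, n: int):
    """CDF of the sum of ``n`` independent standard uniform variables.

    Uses the alternating-sum closed form

    .. math:: F(x; n) = \\frac{1}{n!} \\sum_{k=0}^{\\lfloor x \\rfloor}
              (-1)^k \\binom{n}{k} (x - k)^n,

    with compensated summation.  The closed form is numerically unstable
    for large ``n``; since the methods here need at most three studies the
    implementation is restricted to ``n <= 10``.

    Parameters
    ----------
    x : float or array_like
        Evaluation point(s); the CDF is 0 for ``x <= 0`` and 1 for ``x >= n``.
    n : int
        Number of uniform summands, ``1 <= n <= 10``.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise ValueError(f"n must be an integer, got {n!r}")
    if n < 1 or n > _IRWIN_HALL_MAX_N:
        raise ValueError(f"n must be between 1 and {_IRWIN_HALL_MAX_N}, got {n}")

    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    fact = math.factorial(n)
    if scalar:
        xi = float(x_arr)
        if xi <= 0.0:
            return 0.0
        if xi >= n:
            return 1.0
        terms = [
            (-1.0) ** k * math.comb(n, k) * (xi - k) ** n
            for k in range(int(math.floor(xi)) + 1)
        ]
        return min(max(math.fsum(terms) / fact, 0.0), 1.0)
    # array path: the truncated power identity
    # sum_k (-1)^k C(n,k) max(x-k, 0)^n equals n! * F(x) on the whole line
    out = np.zeros_like(x_arr)
    for k in range(n + 1):
        out += (-1.0) ** k * math.comb(n, k) * np.clip(x_arr - k, 0.0, None) ** n
    out /= fact
    return np.clip(out, 0.0, 1.0)


def _weighted_sum_cdf(e, w_o: float, w_r: float):
    """CDF of ``w_o*U1 + w_r*U2`` for independent standard uniforms.

    The three-piece closed form assumes ``w_o <= w_r``; since the
    distribution is symmetric in the weight labels the weights are sorted
    internally, so any positive pair is accepted.  Branch points belong to
    the lower branch (the pieces are closed on the right).
    """
    lo, hi = (w_o, w_r) if w_o <= w_r else (w_r, w_o)
    e = np.asarray(e, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    out = np.empty_like(e)

    below = e <= 0.0
    first = (e > 0.0) & (e <= lo)
    second = (e > lo) & (e <= hi)
    third = (e > hi) & (e <= lo + hi)
    above = e > lo + hi

    out[below] = 0.0
    out[first] = e[first] ** 2 / (2.0 * lo * hi)
    out[second] = (e[second] - lo / 2.0) / hi
    s = lo + hi
    out[third] = 1.0 + (e[third] * s - s * s / 2.0 - e[third] ** 2 / 2.0) / (lo * hi)
    out[above] = 1.0
    np.clip(out, 0.0, 1.0, out=out)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Array kernels (shared by scalar API and Monte-Carlo machinery)
# ---------------------------------------------------------------------------

def _edgington_p(p_o, p_r):
    return irwin_hall_cdf(np.asarray(p_o, dtype=float) + np.asarray(p_r, dtype=float), 2)


def _edgington_weighted_p(p_o, p_r, w: WeightScheme):
    e = w.w_o * np.asarray(p_o, dtype=float) + w.w_r * np.asarray(p_r, dtype=float)
    return _weighted_sum_cdf(e, w.w_o, w.w_r)


def _two_trials_p(p_o, p_r):
    return np.maximum(np.asarray(p_o, dtype=float), np.asarray(p_r, dtype=float)) ** 2


def _fisher_p(p_o, p_r):
    x = -2.0 * (np.log(np.asarray(p_o, dtype=float)) + np.log(np.asarray(p_r, dtype=float)))
    return stats.chi2.sf(x, df=4)


def _meta_z(p_o, p_r, c):
    z_o = stats.norm.isf(np.asarray(p_o, dtype=float))
    z_r = stats.norm.isf(np.asarray(p_r, dtype=float))
    sc = np.sqrt(np.asarray(c, dtype=float))
    return (z_o + sc * z_r) / np.sqrt(1.0 + np.asarray(c, dtype=float))


def _meta_p(p_o, p_r, c):
    return stats.norm.sf(_meta_z(p_o, p_r, c))


def combined_pvalues(p_o, p_r, method: str, *, weights: WeightScheme | None = None, c=None):
    """Vectorised combined p-values for arrays of one-sided p-values."""
    if method == "edgington":
        return _edgington_p(p_o, p_r)
    if method == "edgington_weighted":
        return _edgington_weighted_p(p_o, p_r, weights or DEFAULT_WEIGHTS)
    if method == "two_trials":
        return _two_trials_p(p_o, p_r)
    if method == "fisher":
        return _fisher_p(p_o, p_r)
    if method == "meta":
        if c is None:
            raise ValueError(
                "the meta-analysis criterion requires the variance ratio c = sigma_o^2/sigma_r^2"
            )
        return _meta_p(p_o, p_r, c)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


# ---------------------------------------------------------------------------
# Scalar API
# ---------------------------------------------------------------------------

def p_edgington(pair: StudyPair, alpha: float = DEFAULT_ALPHA) -> CombinedResult:
    """Edgington's combined p-value ``Pr(IrwinHall(2) <= p_o + p_r)``.

    For ``E = p_o + p_r <= 1`` this is simply ``E**2 / 2``.  Success at the
    overall level ``alpha**2`` is equivalent to ``E <= sqrt(2)*alpha``.
    """
    e = pair.p_o + pair.p_r
    return CombinedResult(float(irwin_hall_cdf(e, 2)), "edgington", e, alpha**2)


def p_edgington_weighted(
    pair: StudyPair,
    weights: WeightScheme = DEFAULT_WEIGHTS,
    alpha: float = DEFAULT_ALPHA,
) -> CombinedResult:
    """Weighted Edgington combined p-value for ``E_w = w_o*p_o + w_r*p_r``.

    Reduces exactly to :func:`p_edgington` for equal weights and depends on
    the weights only through the ratio ``w_r / w_o``.
    """
    e = weights.w_o * pair.p_o + weights.w_r * pair.p_r
    p = float(_weighted_sum_cdf(e, weights.w_o, weights.w_r))
    return CombinedResult(p, "edgington_weighted", e, alpha**2)


def p_two_trials(pair: StudyPair, alpha: float = DEFAULT_ALPHA) -> CombinedResult:
    """Two-trials rule: both studies significant at ``alpha``; p is ``max**2``."""
    m = max(pair.p_o, pair.p_r)
    return CombinedResult(m * m, "two_trials", m, alpha**2)


def p_fisher(pair: StudyPair, alpha: float = DEFAULT_ALPHA) -> CombinedResult:
    """Fisher's combination: ``-2*log(p_o*p_r)`` against chi-squared(4)."""
    x = -2.0 * (math.log(pair.p_o) + math.log(pair.p_r))
    return CombinedResult(float(stats.chi2.sf(x, df=4)), "fisher", x, alpha**2)


def p_meta(pair: StudyPair, alpha: float = DEFAULT_ALPHA) -> CombinedResult:
    """Fixed-effect meta-analysis criterion (weighted Stouffer).

    ``z_MA = (z_o + sqrt(c)*z_r) / sqrt(1 + c)`` with the variance ratio
    ``c`` taken from the pair; requires ``pair.c``.
    """
    if pair.c is None:
        raise ValueError(
            "the meta-analysis criterion requires the variance ratio c = sigma_o^2/sigma_r^2"
        )
    z = float(_meta_z(pair.p_o, pair.p_r, pair.c))
    return CombinedResult(float(stats.norm.sf(z)), "meta", z, alpha**2)


def combine(
    pair: StudyPair,
    method: str,
    *,
    weights: WeightScheme | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> CombinedResult:
    """Dispatch to one of the five combination methods by name."""
    if method == "edgington":
        return p_edgington(pair, alpha)
    if method == "edgington_weighted":
        return p_edgington_weighted(pair, weights or DEFAULT_WEIGHTS, alpha)
    if method == "two_trials":
        return p_two_trials(pair, alpha)
    if method == "fisher":
        return p_fisher(pair, alpha)
    if method == "meta":
        return p_meta(pair, alpha)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


# ---------------------------------------------------------------------------
# Budgets
# ---------------------------------------------------------------------------

def budget(alpha: float = DEFAULT_ALPHA, weights: WeightScheme | None = None) -> float:
    """Largest (weighted) p-value sum still achieving success at ``alpha**2``.

    ``b_w = sqrt(2 * w_o * w_r) * alpha``, the inverse of the first branch of
    the weighted-sum CDF at ``alpha**2``.  With unit weights this is the
    unweighted budget ``b = sqrt(2) * alpha`` (about 0.035 at alpha = 0.025).
    Valid only while the budget stays in the first branch,
    ``b_w <= min(w_o, w_r)``; otherwise the full CDF must be inverted
    numerically and an error is raised.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha!r}")
    w = weights or WeightScheme(1.0, 1.0)
    b = math.sqrt(2.0 * w.w_o * w.w_r) * alpha
    if b > min(w.w_o, w.w_r):
        raise ValueError(
            f"budget {b:.6g} exceeds the first CDF branch (min weight "
            f"{min(w.w_o, w.w_r):.6g}); invert the full piecewise CDF numerically"
        )
    return b


def fisher_critical_product(alpha: float = DEFAULT_ALPHA) -> float:
    """Critical product ``c_F``: Fisher success iff ``p_o * p_r <= c_F``.

    ``c_F = exp(-chi2_4 quantile at 1 - alpha^2 / 2)``; about 6e-5 at
    alpha = 0.025, so a tiny ``p_o`` alone can guarantee success.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha!r}")
    return float(math.exp(-0.5 * stats.chi2.isf(alpha**2, df=4)))
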