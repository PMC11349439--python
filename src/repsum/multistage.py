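"""Sum-of-p-value budgets for one original plus two replication studies.

With ``m`` replications the sum of all ``m + 1`` one-sided p-values is
referred to the Irwin-Hall(m + 1) distribution; the budget keeping the
overall Type-I error at ``alpha2`` is the inverse CDF at ``alpha2``, which
on the small-sum branch is simply ``(n! * alpha2)^(1/n)``.

When the replications are run sequentially, an alpha-spending plan splits
``alpha2`` between the analysis after the first replication (budget ``b2``
on ``E2 = p_o + p_r1``) and the final analysis (budget ``b3`` on
``E3 = E2 + p_r2``): stop for success if ``E2 <= b2``, stop for futility if
``E2 > b3`` (success is then arithmetically impossible), otherwise run the
second replication at significance level ``b3 - E2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize

__all__ = [
    "SpendingPlan",
    "SequentialDecision",
    "budget_n",
    "spending_budgets",
    "sequential_assess",
]


def budget_n(alpha2: float, n_studies: int) -> float:
    """Budget on the sum of ``n_studies`` p-values at overall level ``alpha2``.

    Inverts the small-sum branch ``b**n / n! = alpha2`` of the
    Irwin-Hall(n) CDF: ``b = (n! * alpha2)**(1/n)``.  At ``alpha2 =
    0.025**2`` this gives 0.0354 for two studies and 0.1554 for three.
    """
    if not isinstance(n_studies, int) or n_studies < 2:
        raise ValueError(f"n_studies must be an integer >= 2, got {n_studies!r}")
    if not 0.0 < alpha2 < 1.0:
        raise ValueError(f"alpha2 must be in (0, 1), got {alpha2!r}")
    b = (math.factorial(n_studies) * alpha2) ** (1.0 / n_studies)
    if b > 1.0:
        raise ValueError(
            f"budget {b:.4g} leaves the small-sum branch (b > 1); "
            "invert the full Irwin-Hall CDF numerically"
        )
    return b


@dataclass(frozen=True)
class SpendingPlan:
    """Two-stage alpha-spending budgets for one original + two replications.

    ``fraction`` of the overall level ``alpha2`` is spent on the analysis
    after the first replication (budget ``b2`` on ``E2``); the remainder is
    spent at the final analysis (budget ``b3`` on ``E3``).
    """

    alpha2: float
    fraction: float
    b2: float
    b3: float

    def __post_init__(self) -> None:
        if not 0.0 < self.b2 < self.b3:
            raise ValueError(f"budgets must satisfy 0 < b2 < b3, got {self.b2!r}, {self.b3!r}")


def spending_budgets(alpha2: float, fraction: float) -> SpendingPlan:
    """Derive the two-stage budgets from the overall level and the spend split.

    Stage 1 inverts the small-sum CDF of ``E2``: ``b2 = sqrt(2 * fraction *
    alpha2)``.  Stage 2 solves for ``b3`` so the probability of continuing
    past stage 1 and then succeeding equals the remaining level: with the
    density ``f_{E2}(e) = e`` (exact for ``e <= 1``, which all budgets here
    satisfy) and ``p_r2`` uniform,

    ``integral_{b2}^{b3} e * (b3 - e) de = (1 - fraction) * alpha2``,

    solved by bracketed root-finding on ``(b2, 1]``.  At ``alpha2 = 0.025**2``
    with an even split this yields ``b2 = 0.025`` and ``b3 ~= 0.128``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction!r}")
    if not 0.0 < alpha2 < 1.0:
        raise ValueError(f"alpha2 must be in (0, 1), got {alpha2!r}")
    b2 = math.sqrt(2.0 * fraction * alpha2)
    if b2 > 1.0:
        raise ValueError(f"stage-1 budget {b2:.4g} leaves the small-sum branch")
    target = (1.0 - fraction) * alpha2

    def spend(b3: float) -> float:
        return b3 * (b3**2 - b2**2) / 2.0 - (b3**3 - b2**3) / 3.0 - target

    if spend(1.0) < 0.0:
        raise ValueError(
            f"no stage-2 budget in (b2, 1] spends the remaining level {target:g}"
        )
    b3 = float(optimize.brentq(spend, b2, 1.0, xtol=1e-12))
    return SpendingPlan(alpha2=alpha2, fraction=fraction, b2=b2, b3=b3)


@dataclass(frozen=True)
class SequentialDecision:
    """Verdict of the sequential two-replication procedure.

    ``verdict`` is one of ``success``, ``futility_stop``, ``continue``,
    ``failure``; ``remaining_level`` is the significance level ``b3 - E2``
    available to the second replication when the verdict is ``continue``.
    """

    stage: int
    verdict: str
    remaining_level: float | None = None


def sequential_assess(
    p_o: float,
    p_r1: float,
    p_r2: float | None = None,
    plan: SpendingPlan | None = None,
) -> SequentialDecision:
    """Apply the sequential success/futility/continue rule.

    Stage 1 (after the first replication): success if ``E2 <= b2``;
    futility stop if ``E2 > b3`` (no second replication can rescue the
    claim); otherwise continue, with level ``b3 - E2`` for the second
    replication.  Stage 2 (``p_r2`` given): success iff ``E3 <= b3``.
    Supplying ``p_r2`` when stage 1 already stopped is an error.
    """
    if plan is None:
        raise ValueError("a SpendingPlan is required (see spending_budgets)")
    for name, p in (("p_o", p_o), ("p_r1", p_r1)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p!r}")
    e2 = p_o + p_r1
    if e2 <= plan.b2:
        verdict = SequentialDecision(stage=1, verdict="success")
    elif e2 > plan.b3:
        verdict = SequentialDecision(stage=1, verdict="futility_stop")
    else:
        verdict = SequentialDecision(stage=1, verdict="continue", remaining_level=plan.b3 - e2)
    if p_r2 is None:
        return verdict
    if verdict.verdict != "continue":
        raise ValueError(
            f"second replication supplied but stage 1 already decided ({verdict.verdict})"
        )
    if not 0.0 <= p_r2 <= 1.0:
        raise ValueError(f"p_r2 must be in [0, 1], got {p_r2!r}")
    e3 = e2 + p_r2
    return SequentialDecision(stage=2, verdict="success" if e3 <= plan.b3 else "failure")
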