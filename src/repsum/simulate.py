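"""Synthetic study-pair generator and Monte-Carlo success rates.

Generates original/replication pairs under the same normal model the
analytical operating characteristics assume: ``z_o ~ N(mu_o, 1)`` and
``z_r ~ N(d * sqrt(c) * mu_o, 1)`` independently, with one-sided p-values
``p = 1 - Phi(z)``.  With ``mu_o = 0`` both p-values are standard uniform
regardless of ``d`` — the intersection null used for validity checks.

The generator uses numpy's PCG64 with an explicit seed in every entry
point, so identical parameters reproduce identical pairs bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from repsum.combine import (
    DEFAULT_WEIGHTS,
    StudyPair,
    WeightScheme,
    combined_pvalues,
)

__all__ = ["SimulationScenario", "PairSample", "simulate_pairs", "mc_success_rate"]


@dataclass(frozen=True)
class SimulationScenario:
    """Generative settings for synthetic study pairs.

    ``mu_o`` is the noncentrality of the original z-value (0 under the
    null; ``z_{1-alpha} + Phi^{-1}(power)`` for an original study with the
    given design power), ``c`` the relative sample size ``n_r/n_o``, ``d``
    the effect ratio ``theta_r/theta_o``.
    """

    mu_o: float = 0.0
    c: float = 1.0
    d: float = 1.0
    n_pairs: int = 10**5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError(f"n_pairs must be at least 1, got {self.n_pairs!r}")
        if self.c <= 0.0:
            raise ValueError(f"relative sample size c must be positive, got {self.c!r}")
        if self.d < 0.0:
            raise ValueError(f"effect ratio d must be nonnegative, got {self.d!r}")


@dataclass(frozen=True)
class PairSample:
    """A batch of simulated study pairs held as flat arrays.

    Behaves as a sequence of :class:`~repsum.combine.StudyPair`; the raw
    arrays ``p_o`` and ``p_r`` back the vectorised Monte-Carlo paths.
    """

    p_o: np.ndarray
    p_r: np.ndarray
    c: float

    def __len__(self) -> int:
        return len(self.p_o)

    def __getitem__(self, i: int) -> StudyPair:
        return StudyPair(float(self.p_o[i]), float(self.p_r[i]), c=self.c)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"po": self.p_o, "pr": self.p_r, "c": self.c})


def simulate_pairs(scenario: SimulationScenario) -> PairSample:
    """Draw independent study pairs under the scenario's normal model."""
    rng = np.random.default_rng(scenario.seed)
    z_o = rng.standard_normal(scenario.n_pairs) + scenario.mu_o
    mu_r = scenario.d * math.sqrt(scenario.c) * scenario.mu_o
    z_r = rng.standard_normal(scenario.n_pairs) + mu_r
    return PairSample(p_o=stats.norm.sf(z_o), p_r=stats.norm.sf(z_r), c=scenario.c)


def mc_success_rate(
    pairs: PairSample,
    method: str,
    overall_level: float,
    weights: WeightScheme = DEFAULT_WEIGHTS,
) -> tuple[float, float]:
    """Empirical success rate of a method on simulated pairs, with its SE.

    Success means the combined p-value is at most ``overall_level``; the
    standard error is binomial.  Serves as the Monte-Carlo oracle for the
    analytical Type-I error and project-power calculations.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair sample")
    p = combined_pvalues(pairs.p_o, pairs.p_r, method, weights=weights, c=pairs.c)
    rate = float(np.mean(p <= overall_level))
    se = math.sqrt(rate * (1.0 - rate) / len(pairs))
    return rate, se
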