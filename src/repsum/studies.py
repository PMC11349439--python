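"""Study-pair tables and project-level replication assessments.

Reads CSV tables of original/replication study pairs given either as
one-sided p-values directly (columns ``study_id, po, pr[, c]``) or as
correlation-scale effect estimates with sample sizes (columns
``study_id, ro, no, rr, nr``), from which one-sided p-values are
recomputed via Fisher's z-transformation:

.. math:: p = 1 - \\Phi(\\operatorname{atanh}(r) \\cdot \\sqrt{n - 3}).

On top of the records it produces per-study combined p-values and success
flags for any subset of the five methods, project-level success rates,
success-rate curves over a grid of overall levels, and the proportion of
significant replications split by an original-p-value threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from repsum.combine import (
    DEFAULT_ALPHA,
    DEFAULT_WEIGHTS,
    METHODS,
    StudyPair,
    WeightScheme,
    combine,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyRecord",
    "p_from_correlation",
    "read_study_table",
    "assess",
    "success_rate_curve",
    "rate_by_threshold",
]


def p_from_correlation(r: float, n: int) -> float:
    """One-sided p-value from a correlation coefficient via Fisher's z.

    ``atanh(r)`` has standard error ``1/sqrt(n - 3)`` on the z-scale, so
    ``p = 1 - Phi(atanh(r) * sqrt(n - 3))``.  A negative correlation (an
    estimate pointing the wrong way) gives p > 0.5.
    """
    if not -1.0 < r < 1.0:
        raise ValueError(f"correlation must lie strictly in (-1, 1), got {r!r}")
    if n < 4:
        raise ValueError(f"sample size must be at least 4 (standard error undefined), got {n!r}")
    return float(stats.norm.sf(math.atanh(r) * math.sqrt(n - 3.0)))


@dataclass(frozen=True)
class StudyRecord:
    """One original/replication pair, by p-values or correlation effects.

    Either direct one-sided p-values ``p_o, p_r`` or correlation-scale
    estimates with sample sizes ``(r_o, n_o), (r_r, n_r)`` must be present
    for both studies.  When both are given the direct p-values win (with a
    logged warning).  The variance ratio defaults to ``(n_r-3)/(n_o-3)``
    when sample sizes are available — the squared ratio of Fisher-z
    standard errors — and to 1 otherwise.
    """

    study_id: str
    p_o: float | None = None
    p_r: float | None = None
    r_o: float | None = None
    n_o: int | None = None
    r_r: float | None = None
    n_r: int | None = None
    c: float | None = None

    def __post_init__(self) -> None:
        has_direct = self.p_o is not None and self.p_r is not None
        has_effects = None not in (self.r_o, self.n_o, self.r_r, self.n_r)
        if not has_direct and not has_effects:
            raise ValueError(
                f"study {self.study_id!r}: needs direct p-values or (r, n) for both studies"
            )
        if has_direct and has_effects:
            logger.warning(
                "study %s: both p-values and effect estimates given; direct p-values win",
                self.study_id,
            )
        if not has_direct:
            object.__setattr__(self, "p_o", p_from_correlation(self.r_o, self.n_o))
            object.__setattr__(self, "p_r", p_from_correlation(self.r_r, self.n_r))
        if self.c is None and self.n_o is not None and self.n_r is not None:
            if min(self.n_o, self.n_r) >= 4:
                object.__setattr__(self, "c", (self.n_r - 3.0) / (self.n_o - 3.0))

    def to_pair(self) -> StudyPair:
        return StudyPair(p_o=self.p_o, p_r=self.p_r, c=self.c if self.c is not None else 1.0)


_P_COLS = {"po", "pr"}
_EFFECT_COLS = {"ro", "no", "rr", "nr"}


def read_study_table(path) -> list[StudyRecord]:
    """Read study pairs from a CSV file.

    UTF-8 with a header row; either ``study_id, po, pr[, c]`` or
    ``study_id, ro, no, rr, nr`` (both sets may coexist, direct p-values
    take precedence per record).  Missing cells may be left empty.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "study_id" not in cols:
        raise ValueError("study table needs a 'study_id' column")
    if not (_P_COLS <= cols.keys() or _EFFECT_COLS <= cols.keys()):
        raise ValueError(
            "study table needs columns po,pr or ro,no,rr,nr in addition to study_id"
        )

    def get(row, name, cast=float):
        if name not in cols:
            return None
        v = row[cols[name]]
        return None if pd.isna(v) else cast(v)

    records = []
    for _, row in df.iterrows():
        records.append(
            StudyRecord(
                study_id=str(row[cols["study_id"]]),
                p_o=get(row, "po"),
                p_r=get(row, "pr"),
                r_o=get(row, "ro"),
                n_o=get(row, "no", int),
                r_r=get(row, "rr"),
                n_r=get(row, "nr", int),
                c=get(row, "c"),
            )
        )
    return records


def assess(
    records: list[StudyRecord],
    methods: tuple[str, ...] = METHODS,
    overall_level: float = DEFAULT_ALPHA**2,
    weights: WeightScheme = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """Per-study combined p-values and success flags for each method.

    Returns a DataFrame indexed by ``study_id`` with a ``p_<method>`` and
    ``success_<method>`` column per method; attaches the project-level
    success rates (mean of the flags) as ``df.attrs['success_rate']``.  A
    record that a method cannot handle (e.g. meta without a variance
    ratio) yields NaN for that method rather than aborting the table.
    """
    alpha = math.sqrt(overall_level)
    rows = []
    for rec in records:
        row: dict = {"study_id": rec.study_id, "p_o": rec.p_o, "p_r": rec.p_r}
        pair = rec.to_pair()
        for method in methods:
            try:
                res = combine(pair, method, weights=weights, alpha=alpha)
                row[f"p_{method}"] = res.p_combined
                row[f"success_{method}"] = res.success
            except ValueError as exc:
                logger.warning("study %s, method %s: %s", rec.study_id, method, exc)
                row[f"p_{method}"] = np.nan
                row[f"success_{method}"] = np.nan
        rows.append(row)
    columns = ["study_id", "p_o", "p_r"]
    for method in methods:
        columns += [f"p_{method}", f"success_{method}"]
    df = pd.DataFrame(rows, columns=columns).set_index("study_id")
    df.attrs["overall_level"] = overall_level
    df.attrs["success_rate"] = {
        m: (float(df[f"success_{m}"].mean()) if len(df) else float("nan")) for m in methods
    }
    return df


def success_rate_curve(
    records: list[StudyRecord],
    methods: tuple[str, ...] = ("two_trials", "edgington", "edgington_weighted"),
    levels=None,
    weights: WeightScheme = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """Project success rate per method over a grid of overall levels.

    Returns a DataFrame indexed by the overall level with one column per
    method; each column is nondecreasing in the level.
    """
    if levels is None:
        levels = np.logspace(-5, -1, 41)
    levels = np.asarray(levels, dtype=float)
    if np.any((levels <= 0.0) | (levels >= 1.0)):
        raise ValueError("levels must lie in (0, 1)")
    # combined p-values do not depend on the level; compute once
    base = assess(records, methods, overall_level=DEFAULT_ALPHA**2, weights=weights)
    out = {}
    for m in methods:
        p = base[f"p_{m}"].to_numpy()
        out[m] = [float(np.mean(p <= lv)) for lv in levels]
    return pd.DataFrame(out, index=pd.Index(levels, name="overall_level"))


def rate_by_threshold(
    records: list[StudyRecord],
    replication_level: float = DEFAULT_ALPHA,
    thresholds=None,
) -> pd.DataFrame:
    """Replication significance rate split by an original-p-value threshold.

    For each threshold ``t`` reports the proportion of studies with
    ``p_r <= replication_level`` among those with ``p_o <= t`` and among
    those with ``p_o > t``; empty groups are reported as NaN.
    """
    if thresholds is None:
        thresholds = np.array([0.005, 0.01, 0.025, 0.05, 0.1])
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0.0) | (thresholds >= 0.5)):
        raise ValueError("thresholds must lie in (0, 0.5)")
    p_o = np.array([r.p_o for r in records])
    sig = np.array([r.p_r <= replication_level for r in records], dtype=float)
    below, above = [], []
    for t in thresholds:
        mask = p_o <= t
        below.append(float(sig[mask].mean()) if mask.any() else np.nan)
        above.append(float(sig[~mask].mean()) if (~mask).any() else np.nan)
    return pd.DataFrame(
        {"rate_below": below, "rate_above": above},
        index=pd.Index(thresholds, name="threshold"),
    )
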