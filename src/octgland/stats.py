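"""Per-subject densities, cohort comparison, rater agreement, power.

Surface density is the accepted gland count divided by the fixed useful
imaging surface (glands/cm^2).  Groups are compared with the two-sided
Mann-Whitney U test (exact enumeration for small samples, tie-corrected
normal approximation with continuity correction otherwise).  Observer
agreement uses the two-way random-effects, absolute-agreement, single-measures
intraclass correlation, ICC(2,1).  The planning-stage group size comes from
the standard two-sample normal-approximation formula.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "SubjectResult",
    "GroupStats",
    "CohortSummary",
    "ICCResult",
    "PowerSpec",
    "compute_density",
    "mann_whitney_u",
    "summarize_cohorts",
    "icc_agreement",
    "required_sample_size",
]

#: exact enumeration is used when both samples are at most this size
EXACT_ENUMERATION_MAX_N = 8


@dataclass(frozen=True)
class SubjectResult:
    """Accepted gland count and surface density for one imaged subject."""

    subject_id: str
    group: str
    count: int
    density: float  # glands/cm^2

    def __post_init__(self) -> None:
        if self.count < 0 or self.density < 0:
            raise ValueError("count and density must be non-negative")


@dataclass(frozen=True)
class GroupStats:
    n: int
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class CohortSummary:
    groups: dict[str, GroupStats]
    u_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "groups": {
                k: {
                    "n": g.n,
                    "median": g.median,
                    "q1": g.q1,
                    "q3": g.q3,
                    "min": g.minimum,
                    "max": g.maximum,
                }
                for k, g in self.groups.items()
            },
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class ICCResult:
    value: float
    model: str  # e.g. "ICC(2,1) two-way random, absolute agreement, single measures"
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample design: detectable difference ``delta`` and common standard
    deviation ``sd`` share units (e.g. percent of the parameter value)."""

    delta: float
    sd: float
    alpha: float = 0.05
    power: float = 0.84

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.sd <= 0:
            raise ValueError("delta and sd must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def compute_density(count: int, useful_area_cm2: float) -> float:
    """Surface density: accepted glands per cm^2 of useful surface."""
    if useful_area_cm2 <= 0:
        raise ValueError("useful_area_cm2 must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / useful_area_cm2


def _u_from_ranks(rank_sum_x: float, n_x: int) -> float:
    return rank_sum_x - n_x * (n_x + 1) / 2.0


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U_x, p)``.

    Ranks use midranks for ties.  With ``method="auto"``, the p-value is
    computed by full enumeration of all group labelings of the pooled sample
    (exact, valid under ties) when both samples have at most
    ``EXACT_ENUMERATION_MAX_N`` observations, and otherwise by the normal
    approximation with tie-corrected variance and continuity correction;
    ``"exact"`` and ``"asymptotic"`` force one route.
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = _u_from_ranks(float(ranks[:n_x].sum()), n_x)
    mu = n_x * n_y / 2.0

    exact = method == "exact" or (
        method == "auto" and n_x <= EXACT_ENUMERATION_MAX_N and n_y <= EXACT_ENUMERATION_MAX_N
    )
    if exact:
        dev = abs(u_x - mu)
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n_x + n_y), n_x):
            u = _u_from_ranks(float(ranks[list(combo)].sum()), n_x)
            total += 1
            extreme += abs(u - mu) >= dev - 1e-12
        return u_x, extreme / total

    n = n_x + n_y
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return u_x, 1.0
    cc = 0.5 * np.sign(u_x - mu)
    z = (u_x - mu - cc) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return u_x, float(p)


def summarize_cohorts(results: Sequence[SubjectResult]) -> CohortSummary:
    """Per-group order statistics plus the two-group Mann-Whitney comparison.

    Quartiles use linear interpolation between order statistics.
    """
    by_group: dict[str, list[float]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r.density)
    if len(by_group) != 2:
        raise ValueError(f"exactly two groups required, got {sorted(by_group)}")
    for label, vals in by_group.items():
        if len(vals) == 0:
            raise ValueError(f"group {label!r} is empty")

    groups = {}
    for label, vals in by_group.items():
        v = np.asarray(vals, dtype=np.float64)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        groups[label] = GroupStats(
            n=v.size,
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            minimum=float(v.min()),
            maximum=float(v.max()),
        )
    (label_a, vals_a), (label_b, vals_b) = sorted(by_group.items())
    u, p = mann_whitney_u(vals_a, vals_b)
    return CohortSummary(groups=groups, u_statistic=u, p_value=p)


def icc_agreement(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is a subjects x raters matrix with no missing cells.  From the
    two-way ANOVA mean squares (rows=subjects MS_R, columns=raters MS_C,
    residual MS_E)::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)
    """
    m = np.asarray(ratings, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("ratings must not contain missing cells")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    value = 1.0 if denom == 0 and ms_r == ms_e else (ms_r - ms_e) / denom
    return ICCResult(
        value=float(value),
        model="ICC(2,1) two-way random, absolute agreement, single measures",
        n_subjects=n,
        n_raters=k,
    )


def required_sample_size(spec: PowerSpec) -> int:
    """Per-group n for a two-sample comparison at the given design point:
    ``ceil(2 (z_{1-alpha/2} + z_{power})^2 sd^2 / delta^2)``."""
    z_a = norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = norm.ppf(spec.power)
    n = 2.0 * (z_a + z_b) ** 2 * spec.sd**2 / spec.delta**2
    return int(math.ceil(n))
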