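"""Case-control association on carrier counts and power analysis.

Carrier frequencies are compared between groups with the Pearson chi-square
statistic on the 2x2 table, one degree of freedom, *without* continuity
correction, and declared significant below a two-sided alpha (0.05 by
default, uncorrected for multiple comparisons; a Bonferroni option is
provided). Sample sizes for replication screens come from the classical
two-proportion normal approximation (pooled variance under the null,
unpooled under the alternative), and :func:`empirical_power` checks any
such analytic claim by Monte Carlo simulation of binomial 2x2 tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError


@dataclass(frozen=True)
class AssociationResult:
    """One locus or band cluster's 2x2 association summary."""

    site_id: str
    case_pos: int
    case_neg: int
    control_pos: int
    control_neg: int
    case_freq: float
    control_freq: float
    chi2: float | None  # None for monomorphic sites (zero margin)
    p: float | None
    significant: bool
    monomorphic: bool = False


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Uncorrected Pearson chi-square and its 1-df upper tail probability.

    Table layout: rows are groups (cases a,b; controls c,d), columns are
    carrier / non-carrier. Raises on negative counts or a zero margin
    (undefined statistic).
    """
    if min(a, b, c, d) < 0:
        raise DataError("counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DataError("zero margin: chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def association_scan(
    tables: Iterable[tuple[str, int, int, int, int]] | pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[AssociationResult]:
    """Chi-square association for every site.

    ``tables`` is either an iterable of ``(site_id, case_pos, case_n,
    control_pos, control_n)`` or a DataFrame with those columns. Sites that
    are monomorphic across both groups (everyone positive, or everyone
    negative) have no defined statistic and are reported with
    ``chi2 = p = None`` and ``monomorphic = True``.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [
            (r.locus_id if hasattr(r, "locus_id") else str(i),
             int(r.case_pos), int(r.case_n),
             int(r.control_pos), int(r.control_n))
            for i, r in enumerate(tables.itertuples(index=False))
        ]
    tables = list(tables)
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError("alpha must be in [0, 1]")
    thr = alpha / max(len(tables), 1) if bonferroni else alpha
    results = []
    for site_id, case_pos, case_n, control_pos, control_n in tables:
        a, b = case_pos, case_n - case_pos
        c, d = control_pos, control_n - control_pos
        if (a + c == 0) or (b + d == 0):
            results.append(
                AssociationResult(site_id, a, b, c, d,
                                  a / case_n, c / control_n,
                                  None, None, False, monomorphic=True)
            )
            continue
        chi2, p = chi_square_2x2(a, b, c, d)
        results.append(
            AssociationResult(site_id, a, b, c, d,
                              a / case_n, c / control_n,
                              chi2, p, p < thr)
        )
    return results


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "case_pos": r.case_pos, "case_n": r.case_pos + r.case_neg,
                "control_pos": r.control_pos,
                "control_n": r.control_pos + r.control_neg,
                "case_freq": r.case_freq, "control_freq": r.control_freq,
                "chi2": r.chi2, "p": r.p,
                "significant": r.significant, "monomorphic": r.monomorphic,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class PowerSpec:
    p1: float
    p2: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ConfigurationError("proportions must be in [0, 1]")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ConfigurationError("alpha and power must be in (0, 1)")


def sample_size_two_proportions(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Per-group sample size to detect ``|p1 - p2|`` (two-sided normal approx).

    n = (z_{1-a/2} * sqrt(2 p̄ q̄) + z_{1-b} * sqrt(p1 q1 + p2 q2))^2 / (p1-p2)^2

    with p̄ the pooled proportion; the result is rounded up per group.
    """
    spec = PowerSpec(p1, p2, alpha, power)
    if p1 == p2:
        raise ConfigurationError("p1 must differ from p2")
    za = stats.norm.ppf(1 - spec.alpha / 2)
    zb = stats.norm.ppf(spec.power)
    pbar = (p1 + p2) / 2
    num = za * math.sqrt(2 * pbar * (1 - pbar)) + zb * math.sqrt(
        p1 * (1 - p1) + p2 * (1 - p2)
    )
    return math.ceil((num / (p1 - p2)) ** 2)


def empirical_power(
    p1: float,
    p2: float,
    n_per_group: int,
    alpha: float = 0.05,
    n_reps: int = 10000,
    seed: int = 0,
) -> float:
    """Monte Carlo rejection fraction of the chi-square test.

    Simulates ``n_reps`` pairs of binomial carrier counts and applies the
    uncorrected chi-square at ``alpha``; tables with a zero margin count as
    non-rejections. With ``p1 == p2`` this estimates the type-I error rate.
    Deterministic for a fixed seed.
    """
    if n_reps < 100:
        raise ConfigurationError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    n = n_per_group
    a = rng.binomial(n, p1, size=n_reps).astype(np.float64)
    c = rng.binomial(n, p2, size=n_reps).astype(np.float64)
    b, d = n - a, n - c
    c1, c2 = a + c, b + d
    valid = (c1 > 0) & (c2 > 0)
    chi2 = np.zeros(n_reps)
    num = 2 * n * (a * d - b * c) ** 2
    den = n * n * c1 * c2
    chi2[valid] = num[valid] / den[valid]
    crit = stats.chi2.ppf(1 - alpha, df=1) if alpha < 1.0 else 0.0
    if alpha >= 1.0:
        reject = valid
    else:
        reject = valid & (chi2 > crit)
    return float(reject.mean())
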