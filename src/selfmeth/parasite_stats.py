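"""Scaled parasite load, prevalence, and nonparametric group comparisons.

The scaled parasite load normalizes each morphotype's count by the maximum
observed across all individuals in the table and sums the normalized values,
so no single abundant morphotype dominates the composite load. The maximum
is always taken over the whole input table (all sites pooled); a per-site
variant is deliberately not offered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ParasiteTable

logger = logging.getLogger(__name__)

__all__ = [
    "ParasiteSummary",
    "parasite_summary",
    "scaled_parasite_load",
    "prevalence",
    "kruskal_wallis",
    "mann_whitney",
]


@dataclass
class ParasiteSummary:
    """Per-morphotype max/mean/SD/prevalence plus per-individual scaled load."""

    per_morphotype: pd.DataFrame
    scaled_load: pd.Series


def scaled_parasite_load(t: ParasiteTable) -> pd.Series:
    """Per-individual sum over morphotypes of count / morphotype maximum.

    Morphotypes with an all-zero column are dropped with a warning (their
    maximum is undefined), so the load is bounded by the number of retained
    morphotypes.
    """
    counts = t.counts
    if counts.empty:
        raise ValueError("empty parasite table")
    maxima = counts.max(axis=0)
    dead = maxima[maxima == 0].index.tolist()
    if dead:
        logger.warning("all-zero morphotypes dropped from scaled load: %s", dead)
    keep = maxima[maxima > 0].index
    load = (counts[keep] / maxima[keep]).sum(axis=1)
    load.name = "scaled_load"
    return load


def prevalence(t: ParasiteTable, morphotype: str) -> tuple[float, float]:
    """(fraction, percent) of individuals with at least one parasite of the
    morphotype."""
    if morphotype not in t.counts.columns:
        raise KeyError(f"unknown morphotype {morphotype!r}")
    if t.counts.empty:
        raise ValueError("empty parasite table")
    frac = float((t.counts[morphotype] > 0).mean())
    return frac, 100.0 * frac


def parasite_summary(t: ParasiteTable) -> ParasiteSummary:
    c = t.counts
    per = pd.DataFrame(
        {
            "max": c.max(axis=0),
            "mean": c.mean(axis=0),
            "sd": c.std(axis=0, ddof=1),
            "prevalence": (c > 0).mean(axis=0),
        }
    )
    return ParasiteSummary(per, scaled_parasite_load(t))


def kruskal_wallis(
    values: np.ndarray | pd.Series, groups: list[str] | np.ndarray
) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test across groups: (H with tie correction,
    df = k - 1, chi-square p). All values tied gives H = 0, p = 1."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    labels = list(dict.fromkeys(groups.tolist()))
    samples = [values[groups == lab] for lab in labels]
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    if sum(len(s) for s in samples) < 2:
        raise ValueError("needs >= 2 observations")
    df = len(samples) - 1
    if np.ptp(values) == 0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), df, float(p)


def mann_whitney(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U between two groups: (U of the first group, z from the
    normal approximation with tie and continuity corrections, two-sided p).

    z is antisymmetric in the group order; p comes from the normal
    approximation (matching the rank-test reporting convention of z and p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    u1 = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    _, t = np.unique(ranks, return_counts=True)
    tie_term = ((t**3 - t).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
    mu = n1 * n2 / 2
    if sigma2 <= 0:
        return u1, 0.0, 1.0
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(sigma2)
    p = 2 * stats.norm.sf(abs(z))
    return u1, float(z), float(min(p, 1.0))
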