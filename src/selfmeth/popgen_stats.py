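"""Microsatellite diversity, individual homozygosity, selfing rate, and
q-threshold classification of individuals.

Conventions follow the common population-genetics toolchain for selfing
studies: expected heterozygosity is the uncorrected gene diversity
1 - sum(p^2) (an unbiased small-sample correction is available behind a
flag), the multilocus inbreeding coefficient is Nei's F_IS = 1 - Ho/He on
locus-averaged heterozygosities, individual homozygosity uses the
homozygosity-by-locus (HL) index that weights each locus by its expected
heterozygosity, and the selfing rate is the inbreeding-equilibrium moment
estimator s = 2F / (1 + F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, QMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiversitySummary",
    "SelfingEstimate",
    "diversity_summary",
    "homozygosity_by_locus",
    "selfing_rate_from_fis",
    "classify_inbreeding",
]


@dataclass
class DiversitySummary:
    """Per-locus and pooled diversity for each group.

    per_locus : DataFrame with columns group, locus, n, Na, Ho, He.
    pooled : DataFrame indexed by group with unweighted locus means Na, Ho,
        He and the multilocus F_IS = 1 - mean(Ho)/mean(He) (NaN when
        mean(He) = 0).
    """

    per_locus: pd.DataFrame
    pooled: pd.DataFrame


@dataclass
class SelfingEstimate:
    s_hat: float
    method: str = "inbreeding_equilibrium"


def _allele_freqs(calls: np.ndarray) -> dict[int, float]:
    scored = calls[calls[:, 0] >= 0]
    if not len(scored):
        return {}
    alleles, counts = np.unique(scored.ravel(), return_counts=True)
    total = counts.sum()
    return dict(zip(alleles.tolist(), (counts / total).tolist()))


def _locus_stats(calls: np.ndarray, unbiased: bool) -> tuple[int, int, float, float]:
    """(n scored, Na, Ho, He) for one locus' (n, 2) call block."""
    scored = calls[calls[:, 0] >= 0]
    n = len(scored)
    if n == 0:
        return 0, 0, np.nan, np.nan
    na = len(np.unique(scored.ravel()))
    ho = float(np.mean(scored[:, 0] != scored[:, 1]))
    _, counts = np.unique(scored.ravel(), return_counts=True)
    p = counts / counts.sum()
    he = 1.0 - float(np.sum(p**2))
    if unbiased and n > 1:
        he *= 2 * n / (2 * n - 1)
    return n, na, ho, he


def diversity_summary(
    g: GenotypeMatrix,
    groups: list[str] | np.ndarray | None = None,
    unbiased_he: bool = False,
) -> DiversitySummary:
    """Allelic diversity (Na), observed/expected heterozygosity and multilocus
    F_IS per group (default: sites, plus a pooled "all" group).

    Pooled values are unweighted means over loci; F_IS = 1 - Ho_bar/He_bar.
    Loci with no scored call in a group are excluded from that group's means
    with a warning.
    """
    if groups is None:
        groups = list(g.site_labels)
    groups = np.asarray(groups, dtype=object)
    rows = []
    pooled_rows = []
    labels = list(dict.fromkeys(groups.tolist())) + ["all"]
    for lab in labels:
        mask = np.ones(g.n_individuals, bool) if lab == "all" else groups == lab
        sub = g.calls[mask]
        per_locus = []
        for j, loc in enumerate(g.loci_ids):
            n, na, ho, he = _locus_stats(sub[:, j], unbiased_he)
            if n == 0:
                logger.warning("locus %s has no scored calls in group %s", loc, lab)
                continue
            per_locus.append((lab, loc, n, na, ho, he))
            rows.append((lab, loc, n, na, ho, he))
        if per_locus:
            arr = np.array([r[3:] for r in per_locus], dtype=float)
            na_m, ho_m, he_m = arr.mean(axis=0)
            fis = 1.0 - ho_m / he_m if he_m > 0 else np.nan
            pooled_rows.append((lab, int(mask.sum()), na_m, ho_m, he_m, fis))
    per_locus_df = pd.DataFrame(
        rows, columns=["group", "locus", "n", "Na", "Ho", "He"]
    )
    pooled_df = pd.DataFrame(
        pooled_rows, columns=["group", "N", "Na", "Ho", "He", "Fis"]
    ).set_index("group")
    return DiversitySummary(per_locus_df, pooled_df)


def homozygosity_by_locus(g: GenotypeMatrix) -> pd.Series:
    """Homozygosity by locus (HL) per individual.

    HL = sum(E_l over homozygous loci) / sum(E_l over all scored loci), where
    E_l = 1 - sum(p_a^2) is the locus' expected heterozygosity computed from
    the full sample (focal individual included). Missing loci are excluded
    from both sums; an individual with zero scored loci gets NaN.
    """
    E = np.empty(g.n_loci)
    for j in range(g.n_loci):
        _, _, _, he = _locus_stats(g.calls[:, j], unbiased=False)
        E[j] = 0.0 if np.isnan(he) else he
    hom = (~g.missing_mask) & ~g.heterozygous_mask
    het = g.heterozygous_mask
    num = hom @ E
    den = num + het @ E
    with np.errstate(invalid="ignore", divide="ignore"):
        hl = np.where(den > 0, num / den, np.nan)
    zero_loci = ~(~g.missing_mask).any(axis=1)
    hl = np.where(zero_loci, np.nan, hl)
    return pd.Series(hl, index=g.individual_ids, name="HL")


def selfing_rate_from_fis(fis: float) -> SelfingEstimate:
    """Selfing rate from the inbreeding equilibrium F = s / (2 - s), i.e.
    s = 2F / (1 + F). Negative F (heterozygote excess) clamps to s = 0."""
    if np.isnan(fis):
        return SelfingEstimate(np.nan)
    if fis < 0:
        logger.warning("negative F_IS %.4f clamped to selfing rate 0", fis)
        return SelfingEstimate(0.0)
    fis = min(fis, 1.0)
    return SelfingEstimate(2 * fis / (1 + fis))


def classify_inbreeding(q: QMatrix, threshold: float = 0.9) -> pd.DataFrame:
    """Classify individuals as SELFED (max q >= threshold) or OUTCROSSED.

    Returns a DataFrame with assigned_lineage (argmax cluster, ties broken by
    first cluster id in file order, logged), max_q and inbreeding_status.
    """
    vals = q.q.to_numpy()
    arg = vals.argmax(axis=1)
    ties = (vals == vals[np.arange(len(arg)), arg][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info(
            "argmax ties for %d individuals broken by first cluster id", ties.sum()
        )
    max_q = vals[np.arange(len(arg)), arg]
    status = np.where(max_q >= threshold, "SELFED", "OUTCROSSED")
    return pd.DataFrame(
        {
            "assigned_lineage": [q.cluster_ids[a] for a in arg],
            "max_q": max_q,
            "inbreeding_status": status,
        },
        index=q.individual_ids,
    )
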