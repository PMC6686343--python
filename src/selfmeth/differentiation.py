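"""Distance matrices, AMOVA with Phi-statistics, pairwise Phi/F_ST, principal
coordinates analysis and Mantel tests.

The analysis of molecular variance follows the classical squared-distance
formulation: total and within-group sums of squares are assembled from the
pairwise distance matrix, variance components are extracted by equating
observed mean squares to their expectations (with the usual unequal-sample
size coefficient n_bar), and Phi_ST = sigma2_among / (sigma2_among +
sigma2_within). Significance comes from permuting individuals across groups
with group sizes fixed; p-values use the inclusive (1 + exceedances) /
(1 + permutations) estimator and can never be zero. Negative variance
components are retained rather than truncated, so small Phi values may be
slightly negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "PCoAResult",
    "binary_distance",
    "msat_distance",
    "amova",
    "pairwise_phi",
    "pcoa",
    "mantel",
]

_PERM_CHUNK = 500


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: list[str]
    d: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if (self.d < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal")

    def submatrix(self, idx: np.ndarray) -> "DistanceMatrix":
        return DistanceMatrix(
            [self.ids[i] for i in idx], self.d[np.ix_(idx, idx)], self.metric
        )


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    pct_among: float
    pct_within: float
    p_value: float
    n_permutations: int
    seed: int | None

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "df_among": self.df_among,
                "df_within": self.df_within,
                "SS_among": self.ss_among,
                "SS_within": self.ss_within,
                "sigma2_among": self.sigma2_among,
                "sigma2_within": self.sigma2_within,
                "phi_ST": self.phi_st,
                "pct_among": self.pct_among,
                "pct_within": self.pct_within,
                "p_value": self.p_value,
                "n_permutations": self.n_permutations,
            }
        )


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # individuals x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues only


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def binary_distance(x: pd.DataFrame, metric_tag: str = "binary_mismatch") -> DistanceMatrix:
    """Simple mismatch distance on a binary matrix with NaN missing cells.

    d(i, j) = proportion of mismatching entries over jointly scored columns.
    A pair with zero jointly scored columns raises, naming the pair.
    """
    ids = list(x.index)
    X = x.to_numpy(dtype=float)
    scored = ~np.isnan(X)
    joint = scored[:, None, :] & scored[None, :, :]
    n_joint = joint.sum(axis=2)
    diff = (X[:, None, :] != X[None, :, :]) & joint
    bad = (n_joint == 0) & ~np.eye(len(ids), dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"no jointly scored columns for pair ({ids[i]}, {ids[j]})")
    with np.errstate(invalid="ignore"):
        d = diff.sum(axis=2) / np.maximum(n_joint, 1)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d, metric_tag)


def msat_distance(g) -> DistanceMatrix:
    """Mean allelic mismatches per locus between two diploid genotypes.

    Per locus the mismatch is 2 minus the shared-allele count of the two
    unordered pairs (0, 1 or 2); loci missing in either individual are
    excluded; d(i, j) averages over the jointly scored loci.
    """
    a1, a2 = g.calls[:, :, 0], g.calls[:, :, 1]
    scored = ~g.missing_mask
    m11 = a1[:, None, :] == a1[None, :, :]
    m22 = a2[:, None, :] == a2[None, :, :]
    m12 = a1[:, None, :] == a2[None, :, :]
    m21 = a2[:, None, :] == a1[None, :, :]
    shared = np.maximum(
        m11.astype(np.int8) + m22.astype(np.int8),
        m12.astype(np.int8) + m21.astype(np.int8),
    )
    joint = scored[:, None, :] & scored[None, :, :]
    n_joint = joint.sum(axis=2)
    bad = (n_joint == 0) & ~np.eye(g.n_individuals, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"no jointly scored loci for pair ({g.individual_ids[i]}, {g.individual_ids[j]})"
        )
    mism = np.where(joint, 2 - shared, 0).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = mism / np.maximum(n_joint, 1)
    d = 0.5 * (d + d.T)  # guard against asymmetric missing patterns
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(g.individual_ids), d, "allelic_mismatch")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def _group_blocks(groups: np.ndarray) -> tuple[list[np.ndarray], list[str]]:
    labels = list(dict.fromkeys(groups.tolist()))
    return [np.where(groups == lab)[0] for lab in labels], labels


def _phi_from_ss(
    ss_within: np.ndarray, ss_total: float, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Variance components and Phi from within-group SS (vectorized over
    permutations)."""
    N = sizes.sum()
    k = len(sizes)
    ss_among = ss_total - ss_within
    sigma_b = ss_within / (N - k)
    n_bar = (N - (sizes**2).sum() / N) / (k - 1)
    sigma_a = (ss_among / (k - 1) - sigma_b) / n_bar
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = sigma_a / (sigma_a + sigma_b)
    return sigma_a, sigma_b, phi


def _ss_within_obs(d2: np.ndarray, blocks: list[np.ndarray]) -> float:
    return sum(
        d2[np.ix_(m, m)].sum() / (2 * len(m)) for m in blocks if len(m) > 0
    )


def amova(
    dm: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA (among groups / within groups) on squared distances.

    SS_total = sum_{i<j} d^2 / N; SS_within sums each group's internal
    squared distances over its size; variance components follow the standard
    unequal-n expectations. The permutation test shuffles individuals across
    groups with sizes fixed and reports the inclusive-estimator p-value for
    Phi_perm >= Phi_obs.
    """
    groups = np.asarray(groups, dtype=object)
    N = len(dm.ids)
    if len(groups) != N:
        raise ValueError("groups length mismatch")
    blocks, _ = _group_blocks(groups)
    sizes = np.array([len(b) for b in blocks])
    if len(blocks) < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    if (sizes == 0).any():
        raise ValueError("empty group")
    d2 = dm.d**2
    ss_total = d2.sum() / (2 * N)
    ssw = _ss_within_obs(d2, blocks)
    sigma_a, sigma_b, phi = _phi_from_ss(np.array([ssw]), ss_total, sizes)
    sigma_a, sigma_b, phi = float(sigma_a[0]), float(sigma_b[0]), float(phi[0])

    p_value = np.nan
    if n_perm > 0 and np.isfinite(phi):
        rng = np.random.default_rng(seed)
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        exceed = 0
        done = 0
        while done < n_perm:
            chunk = min(_PERM_CHUNK, n_perm - done)
            idx = rng.permuted(
                np.broadcast_to(np.arange(N), (chunk, N)).copy(), axis=1
            )
            ssw_p = np.zeros(chunk)
            for b in range(len(sizes)):
                members = idx[:, bounds[b] : bounds[b + 1]]
                sub = d2[members[:, :, None], members[:, None, :]]
                ssw_p += sub.sum(axis=(1, 2)) / (2 * sizes[b])
            _, _, phi_p = _phi_from_ss(ssw_p, ss_total, sizes)
            exceed += int(np.sum(phi_p >= phi - 1e-12))
            done += chunk
        p_value = (1 + exceed) / (1 + n_perm)

    total = sigma_a + sigma_b
    pct_among = 100 * sigma_a / total if total != 0 else np.nan
    pct_within = 100 * sigma_b / total if total != 0 else np.nan
    return AmovaResult(
        df_among=len(sizes) - 1,
        df_within=N - len(sizes),
        ss_among=ss_total - ssw,
        ss_within=ssw,
        sigma2_among=sigma_a,
        sigma2_within=sigma_b,
        phi_st=phi,
        pct_among=pct_among,
        pct_within=pct_within,
        p_value=p_value,
        n_permutations=n_perm,
        seed=seed,
    )


def pairwise_phi(
    dm: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """AMOVA Phi_ST and permutation p for every pair of groups.

    No multiple-testing correction is applied (raw permutation p-values).
    """
    groups = np.asarray(groups, dtype=object)
    blocks, labels = _group_blocks(groups)
    rows = []
    rng = np.random.default_rng(seed)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            idx = np.concatenate([blocks[i], blocks[j]])
            res = amova(
                dm.submatrix(idx),
                groups[idx],
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append((labels[i], labels[j], res.phi_st, res.p_value))
    return pd.DataFrame(rows, columns=["group1", "group2", "phi_ST", "p_value"])


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Principal coordinates by Gower double-centering of -d^2/2.

    Axes with positive eigenvalues are retained in descending order; negative
    eigenvalues are reported untouched (no Lingoes/Cailliez correction);
    percent variance is over the positive eigenvalues.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("PCoA needs >= 3 individuals")
    a = -0.5 * dm.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    b = J @ a @ J
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(abs(evals[0]), 1.0)
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PCo{i + 1}" for i in range(pos.sum())]
    prop = evals[pos] / evals[pos].sum()
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dm.ids, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over shared ids.

    r is the Pearson correlation of the vectorized upper triangles; the
    permutation test jointly permutes rows/columns of d2 and is one-tailed
    for positive association (r_perm >= r_obs).
    """
    if d1.ids != d2.ids:
        raise ValueError("mismatched ids between distance matrices")
    n = len(d1.ids)
    iu = np.triu_indices(n, k=1)
    v1 = d1.d[iu]
    v2 = d2.d[iu]
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("zero-variance distance matrix: Mantel r undefined")
    v1c = (v1 - v1.mean()) / v1.std()
    r = float(np.mean(v1c * (v2 - v2.mean()) / v2.std()))
    if n_perm <= 0:
        return r, np.nan
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        chunk = min(_PERM_CHUNK, n_perm - done)
        idx = rng.permuted(np.broadcast_to(np.arange(n), (chunk, n)).copy(), axis=1)
        v2p = d2.d[idx[:, iu[0]], idx[:, iu[1]]]
        mean = v2p.mean(axis=1, keepdims=True)
        sd = v2p.std(axis=1)
        num = (v2p - mean) @ v1c / len(v1c)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_p = np.where(sd > 0, num / sd, np.nan)
        exceed += int(np.nansum(r_p >= r - 1e-12))
        done += chunk
    p = (1 + exceed) / (1 + n_perm)
    return r, p
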