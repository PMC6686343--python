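"""Forward-in-time simulator for a mixed-mating (predominantly selfing) fish.

Generates complete synthetic datasets — microsatellite genotypes, dual-digest
MS-AFLP band matrices, ancestry (q-value) matrices and parasite count tables —
with the statistical structure the analysis pipeline assumes: K selfing
lineages with near-complete homozygosity, rare within-site outcrossing,
site/lineage-structured negative-binomial parasite counts, and per-individual
methylation probabilities driven by lineage, scaled parasite load, inbreeding
status and their interactions on the logit scale.

The mating model: each generation every slot in a (site, lineage) deme draws a
parent uniformly from that deme; with probability ``selfing_probability`` the
offspring is produced by selfing (two independent gametes from the same
parent, so heterozygosity halves in expectation per generation), otherwise a
second parent is drawn uniformly from the same site (any lineage). Ancestry
fractions are propagated through the pedigree (child q = mean of parent q's)
and emitted as the q-matrix; they play the role of Bayesian-clustering
membership fractions. Mutation is omitted — allele diversity comes entirely
from lineage-specific founder pools — because the downstream analysis never
estimates mutation parameters and the generation counts are small.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, BandMatrix, GenotypeMatrix, ParasiteTable, QMatrix

__all__ = ["SimulationConfig", "SimulationTruth", "simulate", "default_study_config"]


@dataclass
class SimulationConfig:
    """Parameters of the mixed-mating simulation.

    occupancy : DataFrame, sites (rows) x lineages (columns), individuals per
        deme; zero cells are empty demes. Total must be >= 2.
    selfing_probability : per-reproduction probability of self-fertilization.
    n_generations : reproduction rounds after the founder generation.
    founder_concentration : Dirichlet concentration of lineage-specific founder
        allele frequencies; small values push lineages toward fixing different
        alleles (strong structure).
    founder_frequency_mode : "dirichlet" (lineage-specific random pools) or
        "uniform" (all alleles equifrequent in every lineage; gives exactly
        H0 = 1 - 1/A expected founder heterozygosity).
    lineage_baseline_logit : per-lineage methylation baseline alpha_l.
    effect_parasite / effect_inbreeding : logit-scale slopes for scaled
        parasite load and outcrossed status.
    interaction_* : two-way interaction effects (per-lineage arrays for the
        lineage interactions, scalar for parasite x inbreeding).
    parasite_means : array (n_sites, n_lineages, n_morphotypes) of
        negative-binomial means; parasite_dispersion is the NB shape theta
        (variance = mu + mu^2 / theta).
    ambiguous_probability / missing_probability : per-cell chance that an MSL
        band pattern is replaced by dual absence (0,0) or by a missing cell.
    """

    occupancy: pd.DataFrame
    selfing_probability: float = 0.95
    n_generations: int = 15
    n_msat_loci: int = 27
    alleles_per_locus: int = 8
    founder_concentration: float = 0.4
    founder_frequency_mode: str = "dirichlet"
    n_msap_loci: int = 381
    fraction_msl: float = 0.70
    lineage_baseline_logit: np.ndarray | None = None
    effect_parasite: float = 0.0
    effect_inbreeding: float = 0.0
    interaction_lineage_parasite: np.ndarray | None = None
    interaction_lineage_inbreeding: np.ndarray | None = None
    interaction_parasite_inbreeding: float = 0.0
    morphotype_names: tuple[str, ...] = (
        "bacterial_cysts",
        "protozoan_cysts",
        "nematodes",
    )
    parasite_means: np.ndarray | None = None
    parasite_dispersion: float = 1.5
    ambiguous_probability: float = 0.05
    missing_probability: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        occ = self.occupancy.to_numpy()
        if (occ < 0).any() or occ.sum() < 2:
            raise ValueError("occupancy must be non-negative with total N >= 2")
        if not 0 <= self.selfing_probability <= 1:
            raise ValueError("selfing_probability must be in [0, 1]")
        for p in (self.ambiguous_probability, self.missing_probability):
            if not 0 <= p <= 1:
                raise ValueError("cell probabilities must be in [0, 1]")
        if self.parasite_dispersion <= 0:
            raise ValueError("parasite_dispersion must be > 0")
        if not 0 <= self.fraction_msl <= 1:
            raise ValueError("fraction_msl must be in [0, 1]")
        if self.founder_frequency_mode not in ("dirichlet", "uniform"):
            raise ValueError("founder_frequency_mode must be 'dirichlet' or 'uniform'")
        K = self.n_lineages
        if self.lineage_baseline_logit is None:
            self.lineage_baseline_logit = np.zeros(K)
        self.lineage_baseline_logit = np.asarray(self.lineage_baseline_logit, float)
        if self.interaction_lineage_parasite is None:
            self.interaction_lineage_parasite = np.zeros(K)
        self.interaction_lineage_parasite = np.asarray(
            self.interaction_lineage_parasite, float
        )
        if self.interaction_lineage_inbreeding is None:
            self.interaction_lineage_inbreeding = np.zeros(K)
        self.interaction_lineage_inbreeding = np.asarray(
            self.interaction_lineage_inbreeding, float
        )
        for name, a in (
            ("lineage_baseline_logit", self.lineage_baseline_logit),
            ("interaction_lineage_parasite", self.interaction_lineage_parasite),
            ("interaction_lineage_inbreeding", self.interaction_lineage_inbreeding),
        ):
            if a.shape != (K,):
                raise ValueError(f"{name} must have one entry per lineage")
        M = len(self.morphotype_names)
        if self.parasite_means is None:
            self.parasite_means = np.full((self.n_sites, K, M), 1.0)
        self.parasite_means = np.asarray(self.parasite_means, float)
        if self.parasite_means.shape != (self.n_sites, K, M):
            raise ValueError(
                f"parasite_means must have shape ({self.n_sites}, {K}, {M})"
            )
        if (self.parasite_means < 0).any():
            raise ValueError("parasite_means must be non-negative")

    @property
    def n_sites(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_lineages(self) -> int:
        return self.occupancy.shape[1]

    @property
    def n_individuals(self) -> int:
        return int(self.occupancy.to_numpy().sum())


@dataclass
class SimulationTruth:
    """Ground truth for parameter-recovery tests.

    per_individual columns: lineage (1-based label), selfed (final-generation
    reproduction event was selfing), realized_inbreeding (1 - observed
    heterozygosity over the founder-pool expectation, clipped at 0),
    scaled_load, methylation_p (the per-individual Bernoulli probability).
    """

    per_individual: pd.DataFrame
    ancestry: pd.DataFrame  # true ancestry fractions, rows sum to 1
    msl_loci: list[str]  # the true methylation-susceptible loci
    effects: dict


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, BandMatrix, QMatrix, ParasiteTable, SimulationTruth]:
    """Run the forward simulation and emit the four data tables plus truth."""
    rng = np.random.default_rng(config.rng_seed)
    occ = config.occupancy.to_numpy(dtype=int)
    n_sites, K = occ.shape
    N = occ.sum()
    L = config.n_msat_loci
    A = config.alleles_per_locus

    site_idx = np.repeat(
        np.arange(n_sites), occ.sum(axis=1)
    )  # individuals ordered by site, then lineage
    lineage_idx = np.concatenate(
        [np.repeat(np.arange(K), occ[s]) for s in range(n_sites)]
    ) if N else np.empty(0, int)

    # --- founder allele pools and founder genotypes (Hardy-Weinberg draws) ---
    if config.founder_frequency_mode == "uniform":
        pools = np.full((K, L, A), 1.0 / A)
    else:
        pools = rng.dirichlet(
            np.full(A, config.founder_concentration), size=(K, L)
        )
    cum = np.cumsum(pools, axis=2)
    u = rng.random((N, L, 2))
    # allele codes are 1-based so 0 stays free as the CSV missing sentinel
    calls = 1 + (u[:, :, :, None] >= cum[lineage_idx][:, :, None, :]).sum(axis=3)
    calls = calls.astype(np.int64)

    q = np.zeros((N, K))
    q[np.arange(N), lineage_idx] = 1.0
    selfed = np.ones(N, dtype=bool)

    # deme membership (fixed across generations: offspring fill parental slots)
    deme_members = {
        (s, l): np.where((site_idx == s) & (lineage_idx == l))[0]
        for s in range(n_sites)
        for l in range(K)
        if occ[s, l] > 0
    }
    site_members = {s: np.where(site_idx == s)[0] for s in range(n_sites)}

    loci_arange = np.arange(L)
    for _ in range(config.n_generations):
        p1 = np.empty(N, dtype=int)
        for (s, l), members in deme_members.items():
            p1[members] = rng.choice(members, size=len(members), replace=True)
        self_mask = rng.random(N) < config.selfing_probability
        p2 = np.empty(N, dtype=int)
        for s, members in site_members.items():
            if len(members):
                p2[members] = rng.choice(members, size=len(members), replace=True)
        p2[self_mask] = p1[self_mask]
        c1 = rng.integers(0, 2, size=(N, L))
        c2 = rng.integers(0, 2, size=(N, L))
        a1 = calls[p1[:, None], loci_arange[None, :], c1]
        a2 = calls[p2[:, None], loci_arange[None, :], c2]
        calls = np.stack([a1, a2], axis=2)
        q = 0.5 * (q[p1] + q[p2])
        selfed = self_mask

    calls = np.sort(calls, axis=2)
    ids = [f"ind{i + 1:04d}" for i in range(N)]
    sites = [f"site{s + 1}" for s in site_idx]
    msat_loci = [f"msat{j + 1:02d}" for j in range(L)]
    genotypes = GenotypeMatrix(ids, sites, msat_loci, calls)

    q_df = pd.DataFrame(q, index=ids, columns=[f"lineage{k + 1}" for k in range(K)])
    if K == 1:
        # membership matrices carry >= 2 clusters; a single-lineage run pads
        # an empty second cluster (all mass stays on lineage1)
        q_df["lineage2"] = 0.0
    qmat = QMatrix(q_df)

    # --- parasites: negative binomial per site x lineage x morphotype -------
    M = len(config.morphotype_names)
    mu = config.parasite_means[site_idx, lineage_idx]  # (N, M)
    theta = config.parasite_dispersion
    counts = np.zeros((N, M), dtype=np.int64)
    pos = mu > 0
    if pos.any():
        # Gamma-Poisson mixture == NB(theta, theta/(theta+mu))
        lam = rng.gamma(theta, mu[pos] / theta)
        counts[pos] = rng.poisson(lam)
    parasites = ParasiteTable(
        pd.DataFrame(counts, index=ids, columns=list(config.morphotype_names))
    )

    # scaled load: per morphotype count / sample maximum, summed (all-zero
    # morphotypes contribute 0); identical to parasite_stats.scaled_parasite_load
    maxima = counts.max(axis=0)
    safe = np.where(maxima > 0, maxima, 1)
    scaled_load = (counts / safe).sum(axis=1)

    # --- MS-AFLP band emission ----------------------------------------------
    P = config.n_msap_loci
    n_msl = int(round(config.fraction_msl * P))
    msap_loci = [f"ms{j + 1:04d}" for j in range(P)]
    outcrossed = (~selfed).astype(float)
    logit = (
        config.lineage_baseline_logit[lineage_idx]
        + (config.effect_parasite + config.interaction_lineage_parasite[lineage_idx])
        * scaled_load
        + (config.effect_inbreeding + config.interaction_lineage_inbreeding[lineage_idx])
        * outcrossed
        + config.interaction_parasite_inbreeding * scaled_load * outcrossed
    )
    p_meth = _logistic(logit)

    hpa = np.empty((N, P), dtype=np.int8)
    msp = np.empty((N, P), dtype=np.int8)

    # MSL cells: UNMETH (1,1) or, when methylated, HEMI (1,0) / INTERNAL (0,1)
    u_meth = rng.random((N, n_msl))
    methylated = u_meth < p_meth[:, None]
    hemi = rng.random((N, n_msl)) < 0.5
    hpa_msl = np.where(methylated, np.where(hemi, 1, 0), 1).astype(np.int8)
    msp_msl = np.where(methylated, np.where(hemi, 0, 1), 1).astype(np.int8)
    u_cell = rng.random((N, n_msl))
    ambiguous = u_cell < config.ambiguous_probability
    missing = (u_cell >= config.ambiguous_probability) & (
        u_cell < config.ambiguous_probability + config.missing_probability
    )
    hpa_msl[ambiguous] = 0
    msp_msl[ambiguous] = 0
    hpa_msl[missing] = MISSING
    msp_msl[missing] = MISSING
    hpa[:, :n_msl] = hpa_msl
    msp[:, :n_msl] = msp_msl

    # NML cells: lineage-determined constant presence, identical in both digests
    presence = (rng.random((K, P - n_msl)) < 0.5).astype(np.int8)
    nml = presence[lineage_idx]
    miss_nml = rng.random((N, P - n_msl)) < config.missing_probability
    nml = nml.copy()
    nml[miss_nml] = MISSING
    hpa[:, n_msl:] = nml
    msp[:, n_msl:] = nml

    bands = BandMatrix(ids, msap_loci, hpa, msp)

    founder_het = 1.0 - (pools[lineage_idx] ** 2).sum(axis=2).mean(axis=1)
    obs_het = genotypes.heterozygous_mask.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        realized_f = np.clip(1.0 - obs_het / np.where(founder_het > 0, founder_het, np.nan), 0, 1)
    truth = SimulationTruth(
        per_individual=pd.DataFrame(
            {
                "site": sites,
                "lineage": [f"lineage{k + 1}" for k in lineage_idx],
                "selfed": selfed,
                "realized_inbreeding": realized_f,
                "scaled_load": scaled_load,
                "methylation_p": p_meth,
            },
            index=ids,
        ),
        ancestry=qmat.q.copy(),
        msl_loci=msap_loci[:n_msl],
        effects={
            "lineage_baseline_logit": config.lineage_baseline_logit.tolist(),
            "effect_parasite": config.effect_parasite,
            "effect_inbreeding": config.effect_inbreeding,
            "interaction_lineage_parasite": config.interaction_lineage_parasite.tolist(),
            "interaction_lineage_inbreeding": config.interaction_lineage_inbreeding.tolist(),
            "interaction_parasite_inbreeding": config.interaction_parasite_inbreeding,
        },
    )
    return genotypes, bands, qmat, parasites, truth


def default_study_config(rng_seed: int = 0) -> SimulationConfig:
    """Configuration mirroring the study design: 128 fish in 3 mangrove sites,
    6 selfing lineages (one shared 7/1 across two sites), 27 microsatellite
    loci, 381 MS-AFLP loci of which 70% are methylation-susceptible, selfing
    probability 0.95."""
    occupancy = pd.DataFrame(
        [
            [14, 25, 0, 22, 0, 7],
            [0, 0, 41, 0, 0, 1],
            [0, 0, 0, 0, 18, 0],
        ],
        index=["site1", "site2", "site3"],
        columns=[f"lineage{k}" for k in range(1, 7)],
    )
    # per-site morphotype means follow the observed site-level abundances;
    # lineages within a site share them
    site_means = np.array(
        [
            [3.16, 0.00, 0.16],  # bacterial, protozoan, nematodes
            [2.66, 1.52, 0.02],
            [1.27, 0.33, 0.00],
        ]
    )
    parasite_means = np.repeat(site_means[:, None, :], 6, axis=1)
    return SimulationConfig(
        occupancy=occupancy,
        selfing_probability=0.95,
        n_generations=15,
        n_msat_loci=27,
        alleles_per_locus=8,
        founder_concentration=0.4,
        n_msap_loci=381,
        fraction_msl=0.70,
        lineage_baseline_logit=np.array([-0.20, -0.10, -0.30, -0.40, -0.48, -0.25]),
        effect_parasite=0.20,
        effect_inbreeding=0.30,
        interaction_lineage_parasite=np.array([0.5, -0.5, 0.3, -0.3, 0.0, 0.0]),
        interaction_lineage_inbreeding=np.array([0.4, -0.4, 0.2, -0.2, 0.0, 0.0]),
        interaction_parasite_inbreeding=-0.30,
        parasite_means=parasite_means,
        parasite_dispersion=1.5,
        ambiguous_probability=0.05,
        missing_probability=0.02,
        rng_seed=rng_seed,
    )
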