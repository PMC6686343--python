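"""Binomial-link models of per-individual methylation proportion with
exhaustive candidate enumeration and AICc-based multimodel comparison.

The response is the per-individual (methylated, scored) locus-count pair —
individuals differ in how many loci they carry scorable states, so the
binomial count pair, not the raw proportion, is modeled. Candidate models
are all subsets of the main effects (selfing lineage, sampling site, scaled
parasite load or bacterial-cyst count, inbreeding status) crossed with all
two-way interaction subsets respecting marginality (an interaction enters
only when both its main effects do). Models are ranked by AICc; Akaike
weights w_i = exp(-dAICc_i / 2) normalized, and the evidence ratio of model
i over j is w_i / w_j.

Fitting is maximum likelihood via iteratively reweighted least squares with
a logit link (statsmodels GLM, Binomial family); the log-likelihood includes
the binomial combinatorial constant, which cancels in AICc differences.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ModelTable",
    "aicc",
    "enumerate_models",
    "fit_binomial",
    "model_table",
    "run_methylation_analysis",
    "MethylationBinomialModel",
    "MethylationModelResults",
]

_MAX_TERMS = 6


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: main-effect terms plus two-way interactions."""

    main_effects: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    def label(self) -> str:
        terms = list(self.main_effects) + [f"{a}:{b}" for a, b in self.interactions]
        return "~ " + (" + ".join(["1"] + terms) if terms else "1")


@dataclass
class ModelFit:
    """One fitted binomial GLM."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    separation: bool
    overdispersion: float  # Pearson chi2 / residual df

    @property
    def aic(self) -> float:
        return -2 * self.loglik + 2 * self.k


@dataclass
class ModelTable:
    """Fits ranked by AICc with dAICc, Akaike weights and evidence ratios."""

    table: pd.DataFrame
    fits: list[ModelFit] = field(repr=False, default_factory=list)

    @property
    def best(self) -> ModelFit:
        return self.fits[0]


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 loglik + 2k + 2k(k+1)/(n-k-1).

    Undefined (raises) when n <= k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k+1)")
    return -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def enumerate_models(
    terms: list[str] | tuple[str, ...], marginality: bool = True
) -> list[ModelSpec]:
    """All candidate models over the given main-effect terms.

    With marginality (the default, matching standard exhaustive-screening
    practice) an interaction is included only when both its main effects are
    present; without it, mains and interactions vary freely. Deterministic
    order: by number of mains, then mains lexicographically by position, then
    interaction subsets likewise.
    """
    terms = tuple(terms)
    if len(terms) > _MAX_TERMS:
        raise ValueError(f"too many candidate terms ({len(terms)} > {_MAX_TERMS})")
    all_pairs = list(itertools.combinations(terms, 2))
    specs: list[ModelSpec] = []
    for r in range(len(terms) + 1):
        for mains in itertools.combinations(terms, r):
            pool = (
                [p for p in all_pairs if p[0] in mains and p[1] in mains]
                if marginality
                else all_pairs
            )
            for ri in range(len(pool) + 1):
                for inters in itertools.combinations(pool, ri):
                    specs.append(ModelSpec(mains, inters))
    if not marginality:
        # mains x interactions cross-product duplicates nothing, but the
        # loop above regenerates each interaction pool per mains subset
        seen = set()
        unique = []
        for s in specs:
            key = (s.main_effects, s.interactions)
            if key not in seen:
                seen.add(key)
                unique.append(s)
        specs = unique
    return specs


def _patsy_formula(spec: ModelSpec, data: pd.DataFrame) -> str:
    def wrap(t: str) -> str:
        return t if pd.api.types.is_numeric_dtype(data[t]) else f"C({t})"

    rhs = ["1"]
    rhs += [wrap(t) for t in spec.main_effects]
    rhs += [f"{wrap(a)}:{wrap(b)}" for a, b in spec.interactions]
    return " + ".join(rhs)


def fit_binomial(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit one binomial GLM (logit link, IRLS) of (methylated, scored).

    ``data`` needs columns ``methylated`` and ``scored`` plus every term.
    Raises on rank-deficient design (naming the aliased columns); complete
    separation is flagged on the returned fit rather than raised.
    """
    for col in ("methylated", "scored"):
        if col not in data:
            raise ValueError(f"data lacks required column {col!r}")
    exog = patsy.dmatrix(_patsy_formula(spec, data), data, return_type="dataframe")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog.to_numpy())
        aliased = [
            exog.columns[j] for j in range(exog.shape[1]) if abs(r[j, j]) < 1e-8
        ] if r.shape[0] >= exog.shape[1] else list(exog.columns[rank:])
        raise ValueError(f"rank-deficient design matrix; aliased columns: {aliased}")
    endog = np.column_stack(
        [data["methylated"].to_numpy(), (data["scored"] - data["methylated"]).to_numpy()]
    )
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    k = exog.shape[1]
    n = len(data)
    separation = bool((np.abs(res.params) > 15).any() or (res.bse > 1e3).any())
    df_resid = max(n - k, 1)
    return ModelFit(
        spec=spec,
        params=res.params,
        bse=res.bse,
        zvalues=res.tvalues,
        pvalues=res.pvalues,
        loglik=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
        converged=bool(res.converged),
        separation=separation,
        overdispersion=float(res.pearson_chi2) / df_resid,
    )


def model_table(fits: list[ModelFit]) -> ModelTable:
    """Rank fits by AICc; attach dAICc, Akaike weights and the evidence ratio
    of the best model over each."""
    if not fits:
        raise ValueError("no successful fits")
    fits = sorted(fits, key=lambda f: f.aicc)
    a = np.array([f.aicc for f in fits])
    delta = a - a[0]
    w = np.exp(-delta / 2)
    w /= w.sum()
    with np.errstate(over="ignore"):
        evidence = np.exp(delta / 2)  # inf for hopeless models is meaningful
    table = pd.DataFrame(
        {
            "model": [f.spec.label() for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "AICc": a,
            "dAICc": delta,
            "weight": w,
            "evidence_ratio": evidence,  # best over this model
        }
    )
    return ModelTable(table, fits)


def run_methylation_analysis(
    data: pd.DataFrame,
    scope: str = "all_sites",
    response_predictor: str = "scaled_load",
    marginality: bool = True,
) -> ModelTable:
    """Exhaustive AICc screen of methylation-proportion models.

    ``data`` is the per-individual frame with columns methylated, scored,
    lineage, site, inbreeding, scaled_load and (optionally) bacterial_cysts.
    scope="site1_only" restricts to site1 individuals and drops the site
    term; the lineage term is dropped with a warning when fewer than two
    lineages remain in scope. Models failing to fit (rank deficiency at a
    given subset) are skipped with a warning.
    """
    if scope not in ("all_sites", "site1_only"):
        raise ValueError("scope must be 'all_sites' or 'site1_only'")
    if response_predictor not in data.columns:
        raise ValueError(f"predictor {response_predictor!r} not in data")
    sub = data
    terms = ["lineage", response_predictor, "inbreeding"]
    if scope == "site1_only":
        sub = data[data["site"] == "site1"]
        if sub.empty:
            raise ValueError("no site1 individuals in scope")
    else:
        if data["site"].nunique() > 1:
            terms.append("site")
    if sub["lineage"].nunique() < 2:
        logger.warning("fewer than 2 lineages in scope; lineage term dropped")
        terms.remove("lineage")
    sub = sub.dropna(subset=["methylated", "scored"])
    sub = sub[sub["scored"] > 0]
    fits = []
    for spec in enumerate_models(terms, marginality=marginality):
        try:
            fits.append(fit_binomial(spec, sub))
        except ValueError as exc:
            logger.warning("model %s skipped: %s", spec.label(), exc)
    return model_table(fits)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class MethylationBinomialModel:
    """Binomial GLM screen of per-individual methylation proportions.

    Parameters
    ----------
    data : per-individual DataFrame with the (methylated, scored) response
        pair and predictor columns (lineage, site, inbreeding, scaled_load,
        bacterial_cysts as available).
    scope : "all_sites" or "site1_only".
    predictor : which parasite predictor enters the candidate set
        ("scaled_load" or e.g. "bacterial_cysts").
    """

    def __init__(
        self,
        data: pd.DataFrame,
        scope: str = "all_sites",
        predictor: str = "scaled_load",
        marginality: bool = True,
    ):
        self.data = data
        self.scope = scope
        self.predictor = predictor
        self.marginality = marginality

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "MethylationBinomialModel":
        return cls(data, **kwargs)

    def fit(self) -> "MethylationModelResults":
        """Fit the exhaustive candidate set and rank by AICc."""
        mt = run_methylation_analysis(
            self.data, self.scope, self.predictor, self.marginality
        )
        return MethylationModelResults(self, mt)

    def fit_single(self, spec: ModelSpec) -> ModelFit:
        sub = self.data
        if self.scope == "site1_only":
            sub = sub[sub["site"] == "site1"]
        return fit_binomial(spec, sub)


class MethylationModelResults:
    """Ranked model table plus the best model's coefficient report."""

    def __init__(self, model: MethylationBinomialModel, table: ModelTable):
        self.model = model
        self.model_table = table

    @property
    def best(self) -> ModelFit:
        return self.model_table.best

    @property
    def akaike_weights(self) -> pd.Series:
        return self.model_table.table.set_index("model")["weight"]

    def best_coefficients(self) -> pd.DataFrame:
        b = self.best
        return pd.DataFrame(
            {"coef": b.params, "se": b.bse, "z": b.zvalues, "p": b.pvalues}
        )

    def summary(self, top: int = 10) -> str:
        t = self.model_table.table.head(top)
        lines = [
            "Methylation-proportion binomial GLM screen "
            f"(scope={self.model.scope}, predictor={self.model.predictor})",
            f"{len(self.model_table.fits)} candidate models; top {len(t)} by AICc:",
            t.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
                columns=["model", "k", "AICc", "dAICc", "weight", "evidence_ratio"],
            ),
            "",
            f"Best model: {self.best.spec.label()}  "
            f"(AICc={self.best.aicc:.2f}, overdispersion={self.best.overdispersion:.2f})",
            self.best_coefficients().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
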