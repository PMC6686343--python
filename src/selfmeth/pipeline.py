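"""End-to-end study pipeline.

Chains the modules into the full analysis: q-threshold classification,
diversity and homozygosity summaries (genetic-diversity table analog),
MS-AFLP scoring and locus classification, AMOVA of microsatellite / NML /
MSL differentiation across sites, lineages and inbreeding status
(differentiation table analog), Mantel tests between epigenetic and genetic
distances, and the binomial GLM model screen for methylation proportion
(model table analog).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BandMatrix, GenotypeMatrix, ParasiteTable, PipelineConfig, QMatrix
from .differentiation import (
    DistanceMatrix,
    amova,
    binary_distance,
    mantel,
    msat_distance,
    pcoa,
)
from .methylation_glm import MethylationBinomialModel, MethylationModelResults
from .msap_scoring import (
    LocusClassification,
    classify_loci,
    encode_states,
    group_methylation_percentage,
    methylation_proportion,
    msl_binary_matrix,
    nml_band_matrix,
)
from .parasite_stats import parasite_summary, prevalence, scaled_parasite_load
from .popgen_stats import (
    classify_inbreeding,
    diversity_summary,
    homozygosity_by_locus,
    selfing_rate_from_fis,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyReport", "run_study", "build_model_frame"]


@dataclass
class StudyReport:
    """Collected outputs of the full pipeline."""

    diversity: pd.DataFrame  # per-group Na/Ho/He/Fis/HL/S + parasite summaries
    individual_indices: pd.DataFrame  # HL, lineage, max_q, status per individual
    locus_classification: LocusClassification
    methylation_by_lineage: pd.Series
    methylation_by_status: pd.Series
    amova_table: pd.DataFrame  # marker x grouping rows
    mantel_table: pd.DataFrame
    pcoa_variance: pd.Series  # % variance on axis 1 per marker
    model_results_all: MethylationModelResults
    model_results_site1: MethylationModelResults
    model_frame: pd.DataFrame
    timings: dict = field(default_factory=dict)


def build_model_frame(
    genotypes: GenotypeMatrix,
    bands: BandMatrix,
    qmat: QMatrix,
    parasites: ParasiteTable,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, LocusClassification]:
    """Per-individual modeling frame: (methylated, scored) response over
    polymorphic MSL loci plus lineage, site, inbreeding and parasite
    predictors, aligned on the band-matrix individuals."""
    states = encode_states(bands)
    classification = classify_loci(states, config.error_threshold)
    meth = methylation_proportion(
        states,
        loci=classification.polymorphic_msl,
        include_ambiguous=config.ambiguous_in_proportion,
    )
    cls = classify_inbreeding(qmat, config.q_threshold)
    sites = pd.Series(list(genotypes.site_labels), index=genotypes.individual_ids)
    load = scaled_parasite_load(parasites)
    frame = meth.join(cls, how="inner")
    frame["site"] = sites
    frame["scaled_load"] = load
    if "bacterial_cysts" in parasites.counts.columns:
        frame["bacterial_cysts"] = parasites.counts["bacterial_cysts"]
    frame = frame.rename(
        columns={"assigned_lineage": "lineage", "inbreeding_status": "inbreeding"}
    )
    return frame.dropna(subset=["site", "scaled_load"]), classification


def run_study(
    genotypes: GenotypeMatrix,
    bands: BandMatrix,
    qmat: QMatrix,
    parasites: ParasiteTable,
    config: PipelineConfig | None = None,
) -> StudyReport:
    """Run the complete analysis and return every report table."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.rng_seed)
    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> float:
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %-18s %.2fs", stage, timings[stage])
        return time.perf_counter()

    t0 = time.perf_counter()
    # --- genetic diversity table -------------------------------------------
    cls = classify_inbreeding(qmat, config.q_threshold)
    hl = homozygosity_by_locus(genotypes)
    div = diversity_summary(genotypes)
    psum = parasite_summary(parasites)
    sites = pd.Series(list(genotypes.site_labels), index=genotypes.individual_ids)
    rows = {}
    for grp in list(div.pooled.index):
        mask = (
            np.ones(len(sites), bool) if grp == "all" else (sites == grp).to_numpy()
        )
        ids = sites.index[mask]
        pooled = div.pooled.loc[grp]
        fis = pooled["Fis"]
        row = {
            "N": int(pooled["N"]),
            "Na": pooled["Na"],
            "He": pooled["He"],
            "Ho": pooled["Ho"],
            "Fis": fis,
            "HL": hl.loc[ids].mean(),
            "S": selfing_rate_from_fis(fis).s_hat,
            "n_selfed": int((cls.loc[ids, "inbreeding_status"] == "SELFED").sum()),
            "n_outcrossed": int(
                (cls.loc[ids, "inbreeding_status"] == "OUTCROSSED").sum()
            ),
        }
        sub = ParasiteTable(parasites.counts.loc[parasites.counts.index.isin(ids)])
        for m in parasites.morphotype_names:
            row[f"mean_{m}"] = sub.counts[m].mean()
            row[f"prev_{m}_pct"] = prevalence(sub, m)[1]
        rows[grp] = row
    diversity = pd.DataFrame(rows).T
    individual = cls.join(hl).join(sites.rename("site"))
    t0 = tick("diversity", t0)

    # --- MS-AFLP scoring ----------------------------------------------------
    states = encode_states(bands)
    classification = classify_loci(states, config.error_threshold)
    frame, _ = build_model_frame(genotypes, bands, qmat, parasites, config)
    lineage_of = frame["lineage"]
    status_of = frame["inbreeding"]
    meth_lineage = group_methylation_percentage(
        states, lineage_of.reindex(states.individual_ids).fillna("NA").to_numpy(),
        method=config.group_percentage_method,
    )
    meth_status = group_methylation_percentage(
        states, status_of.reindex(states.individual_ids).fillna("NA").to_numpy(),
        method=config.group_percentage_method,
    )
    t0 = tick("msap_scoring", t0)

    # --- distances ----------------------------------------------------------
    d_msat = msat_distance(genotypes)
    msl_bin = msl_binary_matrix(states, classification.polymorphic_msl)
    nml_bin = nml_band_matrix(bands, classification)
    # drop invariant/empty columns cannot hurt mismatch distances; keep as is
    d_msl = binary_distance(msl_bin, "msl_mismatch")
    d_nml = binary_distance(nml_bin, "nml_mismatch")
    t0 = tick("distances", t0)

    # --- AMOVA across the three groupings, three marker sets ---------------
    groupings = {
        "sites": sites,
        "lineages": individual["assigned_lineage"],
        "status": individual["inbreeding_status"],
    }
    markers = {"msat": d_msat, "NML": d_nml, "MSL": d_msl}
    amova_rows = []
    for mname, dm in markers.items():
        for gname, series in groupings.items():
            labels = series.reindex(dm.ids)
            res = amova(
                dm,
                labels.to_numpy(),
                n_perm=config.n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            amova_rows.append(
                {"marker": mname, "grouping": gname, **res.to_series().to_dict()}
            )
    amova_table = pd.DataFrame(amova_rows)
    t0 = tick("amova", t0)

    # --- Mantel tests: epigenetic vs genetic --------------------------------
    mantel_rows = []
    shared = [i for i in d_msl.ids if i in set(d_msat.ids) and i in set(d_nml.ids)]
    sub = {
        name: dm.submatrix(np.array([dm.ids.index(i) for i in shared]))
        for name, dm in markers.items()
    }
    for a, b in (("MSL", "msat"), ("MSL", "NML")):
        r, p = mantel(
            sub[a], sub[b], n_perm=config.n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        mantel_rows.append({"d1": a, "d2": b, "r": r, "p_value": p})
    mantel_table = pd.DataFrame(mantel_rows)
    t0 = tick("mantel", t0)

    # --- PCoA ---------------------------------------------------------------
    pcoa_var = pd.Series(
        {
            name: 100 * pcoa(dm).proportion_explained[0]
            for name, dm in markers.items()
        },
        name="pct_variance_axis1",
    )
    t0 = tick("pcoa", t0)

    # --- GLM screens --------------------------------------------------------
    results_all = MethylationBinomialModel(frame, scope="all_sites").fit()
    results_site1 = MethylationBinomialModel(frame, scope="site1_only").fit()
    t0 = tick("glm", t0)

    return StudyReport(
        diversity=diversity,
        individual_indices=individual,
        locus_classification=classification,
        methylation_by_lineage=meth_lineage,
        methylation_by_status=meth_status,
        amova_table=amova_table,
        mantel_table=mantel_table,
        pcoa_variance=pcoa_var,
        model_results_all=results_all,
        model_results_site1=results_site1,
        model_frame=frame,
        timings=timings,
    )
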