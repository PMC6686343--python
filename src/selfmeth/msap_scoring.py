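"""MS-AFLP methylation-state scoring and summaries.

The two isoschizomers HpaII and MspI differ in sensitivity to CpG
methylation, so the four dual-digest band patterns carry methylation
information: HPA+/MSP+ is unmethylated, HPA+/MSP- hemimethylated (external
cytosine), HPA-/MSP+ internal cytosine methylation, and HPA-/MSP- is
ambiguous (hypermethylation confounded with absence of the restriction
target). Loci whose fraction of methylation-indicative patterns
(HEMI/INTERNAL) exceeds an error threshold across all scored samples are
methylation-susceptible loci (MSL); the rest are nonmethylated loci (NML)
and double as ordinary dominant AFLP genetic markers via their HpaII
presence profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .core_io import MISSING, BandMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "State",
    "MethylationStateMatrix",
    "LocusClassification",
    "encode_states",
    "classify_loci",
    "methylation_proportion",
    "group_methylation_percentage",
    "replicate_error_rate",
]


class State(IntEnum):
    """Dual-digest band-pattern states; MISSING is the shared -1 sentinel."""

    UNMETHYLATED = 0  # HPA+/MSP+
    HEMI = 1  # HPA+/MSP-
    INTERNAL = 2  # HPA-/MSP+
    AMBIGUOUS = 3  # HPA-/MSP-


@dataclass
class MethylationStateMatrix:
    """Per individual x locus methylation states (int8 codes from State)."""

    individual_ids: list[str]
    loci_ids: list[str]
    states: np.ndarray

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.states, index=self.individual_ids, columns=self.loci_ids
        )

    def subset_loci(self, loci: list[str]) -> "MethylationStateMatrix":
        idx = [self.loci_ids.index(l) for l in loci]
        return MethylationStateMatrix(
            self.individual_ids, list(loci), self.states[:, idx]
        )


@dataclass
class LocusClassification:
    """Per-locus MSL/NML partition.

    table : DataFrame indexed by locus with columns class ("MSL"/"NML"),
        pattern_freq (HEMI+INTERNAL over scored cells, AMBIGUOUS included in
        the denominator), n_scored and polymorphic (MSL only: >= 2 distinct
        non-missing states observed).
    dropped : loci with every cell missing, removed with a warning.
    """

    table: pd.DataFrame
    dropped: list[str]

    @property
    def msl_loci(self) -> list[str]:
        return list(self.table.index[self.table["class"] == "MSL"])

    @property
    def nml_loci(self) -> list[str]:
        return list(self.table.index[self.table["class"] == "NML"])

    @property
    def polymorphic_msl(self) -> list[str]:
        t = self.table
        poly = t["polymorphic"].apply(bool)
        return list(t.index[(t["class"] == "MSL") & poly])


_STATE_BY_BANDS = {
    (1, 1): State.UNMETHYLATED,
    (1, 0): State.HEMI,
    (0, 1): State.INTERNAL,
    (0, 0): State.AMBIGUOUS,
}


def encode_states(b: BandMatrix) -> MethylationStateMatrix:
    """Map dual-digest bands to methylation states, cellwise and total."""
    states = np.full(b.hpa.shape, MISSING, dtype=np.int8)
    scored = b.hpa != MISSING
    # encode via 2*hpa + msp: (1,1)->3, (1,0)->2, (0,1)->1, (0,0)->0
    code = 2 * b.hpa + b.msp
    lut = {3: State.UNMETHYLATED, 2: State.HEMI, 1: State.INTERNAL, 0: State.AMBIGUOUS}
    for c, s in lut.items():
        states[scored & (code == c)] = s
    return MethylationStateMatrix(list(b.individual_ids), list(b.loci_ids), states)


def classify_loci(
    m: MethylationStateMatrix, error_threshold: float = 0.05
) -> LocusClassification:
    """Partition loci into MSL/NML by the frequency of methylation-indicative
    patterns.

    freq = (#HEMI + #INTERNAL) / #scored cells (AMBIGUOUS counts in the
    denominator); a locus is MSL iff freq strictly exceeds the threshold.
    A retained MSL locus is polymorphic iff >= 2 distinct non-missing states
    occur. Loci with all cells missing are dropped with a warning.
    """
    S = m.states
    scored = S != MISSING
    n_scored = scored.sum(axis=0)
    dropped = [l for l, n in zip(m.loci_ids, n_scored) if n == 0]
    if dropped:
        logger.warning("%d loci with all cells missing dropped", len(dropped))
    meth = ((S == State.HEMI) | (S == State.INTERNAL)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_scored > 0, meth / np.maximum(n_scored, 1), np.nan)
    rows = []
    for j, loc in enumerate(m.loci_ids):
        if n_scored[j] == 0:
            continue
        is_msl = freq[j] > error_threshold
        poly = None
        if is_msl:
            poly = len(np.unique(S[scored[:, j], j])) >= 2
        rows.append((loc, "MSL" if is_msl else "NML", freq[j], int(n_scored[j]), poly))
    table = pd.DataFrame(
        rows, columns=["locus", "class", "pattern_freq", "n_scored", "polymorphic"]
    ).set_index("locus")
    return LocusClassification(table, dropped)


def nml_band_matrix(b: BandMatrix, classification: LocusClassification) -> pd.DataFrame:
    """Re-express NML loci as binary AFLP presence markers (HpaII profile).

    Returns a DataFrame individuals x NML loci over {0, 1} with NaN missing.
    """
    idx = [b.loci_ids.index(l) for l in classification.nml_loci]
    block = b.hpa[:, idx].astype(float)
    block[block == MISSING] = np.nan
    return pd.DataFrame(block, index=b.individual_ids, columns=classification.nml_loci)


def msl_binary_matrix(
    m: MethylationStateMatrix, loci: list[str] | None = None
) -> pd.DataFrame:
    """Binary methylated(1)/unmethylated(0) recoding of MSL states.

    HEMI and INTERNAL collapse to 1, UNMETHYLATED to 0; AMBIGUOUS and
    MISSING become NaN.
    """
    sub = m if loci is None else m.subset_loci(loci)
    S = sub.states.astype(float)
    out = np.full(S.shape, np.nan)
    out[S == State.UNMETHYLATED] = 0.0
    out[(S == State.HEMI) | (S == State.INTERNAL)] = 1.0
    return pd.DataFrame(out, index=sub.individual_ids, columns=sub.loci_ids)


def methylation_proportion(
    m: MethylationStateMatrix,
    loci: list[str] | None = None,
    include_ambiguous: bool = False,
) -> pd.DataFrame:
    """Per-individual proportion of loci scored as methylated.

    methylated = HEMI or INTERNAL; the denominator counts UNMETHYLATED, HEMI
    and INTERNAL cells (AMBIGUOUS joins it only when ``include_ambiguous`` —
    the dual-absence pattern confounds hypermethylation with fragment
    absence, so it is excluded by default). Returns a DataFrame with columns
    methylated, scored, proportion (NaN when scored = 0); the count pair
    feeds the binomial models directly.
    """
    sub = m if loci is None else m.subset_loci(loci)
    S = sub.states
    meth = ((S == State.HEMI) | (S == State.INTERNAL)).sum(axis=1)
    scored = ((S == State.UNMETHYLATED) | (S == State.HEMI) | (S == State.INTERNAL)).sum(
        axis=1
    )
    if include_ambiguous:
        scored = scored + (S == State.AMBIGUOUS).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(scored > 0, meth / np.maximum(scored, 1), np.nan)
    return pd.DataFrame(
        {"methylated": meth, "scored": scored, "proportion": prop},
        index=sub.individual_ids,
    )


def group_methylation_percentage(
    m: MethylationStateMatrix,
    groups: list[str] | np.ndarray,
    method: str = "ratio",
) -> pd.Series:
    """Group methylation percentage, pooled over the group's cells.

    method="ratio" follows the band-pattern formula as printed in the MS-AFLP
    literature: 100 x (#HEMI + #INTERNAL) / (#UNMETHYLATED + #AMBIGUOUS).
    method="proportion" is the proportion-of-total reading:
    100 x (#HEMI + #INTERNAL) / #scored cells.
    """
    if method not in ("ratio", "proportion"):
        raise ValueError("method must be 'ratio' or 'proportion'")
    groups = np.asarray(groups, dtype=object)
    if len(groups) != m.n_individuals:
        raise ValueError("groups length mismatch")
    S = m.states
    out = {}
    for lab in dict.fromkeys(groups.tolist()):
        sub = S[groups == lab]
        if sub.size == 0:
            raise ValueError(f"empty group {lab}")
        meth = int(((sub == State.HEMI) | (sub == State.INTERNAL)).sum())
        if method == "ratio":
            den = int(((sub == State.UNMETHYLATED) | (sub == State.AMBIGUOUS)).sum())
        else:
            den = meth + int(
                ((sub == State.UNMETHYLATED) | (sub == State.AMBIGUOUS)).sum()
            )
        if den == 0:
            raise ValueError(f"zero denominator for group {lab}")
        out[lab] = 100.0 * meth / den
    return pd.Series(out, name=f"methylation_pct_{method}")


def replicate_error_rate(original: BandMatrix, replicate: BandMatrix) -> float:
    """Genotyping error rate between original and replicated profiles.

    rate = mismatching cells / (n shared loci x n replicated individuals),
    where a cell compares the (HPA, MSP) band pair jointly and mismatches
    when either digest differs; cells missing in either matrix are skipped
    (they stay in the denominator, which is fixed by design at loci x
    individuals).
    """
    shared_loci = [l for l in original.loci_ids if l in set(replicate.loci_ids)]
    if not shared_loci:
        raise ValueError("no shared loci between original and replicate")
    rep_ids = [i for i in replicate.individual_ids if i in set(original.individual_ids)]
    if not rep_ids:
        raise ValueError("no replicated individuals present in the original matrix")
    oi = [original.individual_ids.index(i) for i in rep_ids]
    ol = [original.loci_ids.index(l) for l in shared_loci]
    ri = [replicate.individual_ids.index(i) for i in rep_ids]
    rl = [replicate.loci_ids.index(l) for l in shared_loci]
    o_h, o_m = original.hpa[np.ix_(oi, ol)], original.msp[np.ix_(oi, ol)]
    r_h, r_m = replicate.hpa[np.ix_(ri, rl)], replicate.msp[np.ix_(ri, rl)]
    comparable = (o_h != MISSING) & (r_h != MISSING)
    mismatch = comparable & ((o_h != r_h) | (o_m != r_m))
    return float(mismatch.sum()) / (len(shared_loci) * len(rep_ids))
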