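"""Shared data model and tabular I/O.

Containers for the four kinds of input the pipeline consumes — codominant
microsatellite genotypes, dual-digest MS-AFLP band matrices, parasite count
tables and cluster-membership (q-value) matrices — plus the pipeline-wide
configuration and the binarization of fragment-analyzer peak tables into
presence/absence bands.

All CSV dialects are UTF-8, comma-delimited, header-required; no sniffing.
Missing genotype calls follow the GenAlEx convention of a 0/0 allele pair.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Sentinel for a missing call/band inside integer arrays.
MISSING = -1


class CoreIOError(ValueError):
    """Raised for any malformed input table, with file/row context."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid codominant genotypes, individuals x loci, with site labels.

    ``calls`` has shape (n_individuals, n_loci, 2) with non-negative allele
    codes; a missing call is (-1, -1) for the whole locus (never one allele).
    Allele pairs are unordered and stored canonically as (min, max).
    """

    individual_ids: list[str]
    site_labels: list[str]
    loci_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.loci_ids)
        if self.calls.shape != (n, L, 2):
            raise CoreIOError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(set(self.individual_ids)) != n:
            raise CoreIOError("duplicate individual ids")
        if len(set(self.loci_ids)) != L:
            raise CoreIOError("duplicate locus ids")
        if len(self.site_labels) != n:
            raise CoreIOError("site_labels length mismatch")
        half = (self.calls < 0).sum(axis=2)
        if np.any(half == 1):
            raise CoreIOError("missing applies to the whole call, not one allele")
        # canonicalize unordered pairs to (min, max)
        self.calls = np.sort(self.calls, axis=2)
        scored = self.calls[:, :, 0] >= 0
        if n and not scored.any(axis=1).all():
            bad = [self.individual_ids[i] for i in np.where(~scored.any(axis=1))[0]]
            raise CoreIOError(f"individuals with zero scored loci: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean, True where the call is missing."""
        return self.calls[:, :, 0] < 0

    @property
    def heterozygous_mask(self) -> np.ndarray:
        """(n, L) boolean, True where scored and the two alleles differ."""
        return (~self.missing_mask) & (self.calls[:, :, 0] != self.calls[:, :, 1])


@dataclass
class BandMatrix:
    """MS-AFLP presence/absence per individual x locus for the two digests.

    ``hpa`` (EcoRI/HpaII) and ``msp`` (EcoRI/MspI) are (n, L) arrays over
    {0, 1, -1}; a cell missing in one digest only is promoted to missing in
    both (a methylation-state call needs both digests), with a warning.
    """

    individual_ids: list[str]
    loci_ids: list[str]
    hpa: np.ndarray
    msp: np.ndarray

    def __post_init__(self) -> None:
        self.hpa = np.asarray(self.hpa, dtype=np.int8)
        self.msp = np.asarray(self.msp, dtype=np.int8)
        n, L = len(self.individual_ids), len(self.loci_ids)
        for name, a in (("hpa", self.hpa), ("msp", self.msp)):
            if a.shape != (n, L):
                raise CoreIOError(f"{name} shape {a.shape} != ({n}, {L})")
            if not np.isin(a, (0, 1, MISSING)).all():
                raise CoreIOError(f"non-binary cells in {name}")
        half = (self.hpa == MISSING) ^ (self.msp == MISSING)
        if half.any():
            logger.warning(
                "%d half-missing band cells promoted to fully missing", half.sum()
            )
            self.hpa[half] = MISSING
            self.msp[half] = MISSING

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.hpa == MISSING

    def subset_loci(self, loci: Sequence[str]) -> "BandMatrix":
        idx = [self.loci_ids.index(l) for l in loci]
        return BandMatrix(
            self.individual_ids, list(loci), self.hpa[:, idx].copy(), self.msp[:, idx].copy()
        )


@dataclass
class ParasiteTable:
    """Non-negative parasite counts per individual x morphotype.

    No missing cells: unscreened individuals are simply absent rows.
    """

    counts: pd.DataFrame  # index: individual ids, columns: morphotype names

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise CoreIOError("duplicate individual ids in parasite table")
        self.counts.index.name = "individual_id"
        if self.counts.isna().any().any():
            raise CoreIOError("missing cells in parasite table")
        if (self.counts.to_numpy() < 0).any():
            raise CoreIOError("negative parasite counts")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def morphotype_names(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class QMatrix:
    """Cluster-membership fractions per individual x cluster.

    Rows live on the simplex: each q in [0, 1], each row sums to 1 (renormalized
    silently when off by <= 1e-3, rejected beyond).
    """

    q: pd.DataFrame  # index: individual ids, columns: cluster ids

    def __post_init__(self) -> None:
        if self.q.shape[1] < 2:
            raise CoreIOError("q-matrix needs >= 2 clusters")
        self.q.index.name = "individual_id"
        vals = self.q.to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1 + 1e-9).any():
            raise CoreIOError("q-values outside [0, 1]")
        sums = vals.sum(axis=1)
        off = np.abs(sums - 1.0)
        if (off > 1e-3).any():
            bad = list(self.q.index[off > 1e-3])
            raise CoreIOError(f"q rows deviating from sum 1 by > 1e-3: {bad}")
        if (off > 1e-6).any():
            self.q = self.q.div(sums, axis=0)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.q.index)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.q.columns)


@dataclass
class PipelineConfig:
    """Pipeline-wide thresholds and settings.

    error_threshold : locus-classification error threshold (fraction).
    q_threshold     : q-value at or above which an individual is called selfed.
    n_permutations  : permutations for AMOVA / Mantel / pairwise tests.
    peak_* : fragment-analysis window (bp) and minimum peak height (RFU).
    ambiguous_in_proportion : if True, (0,0) dual-absence cells count in the
        denominator of the per-individual methylation proportion.
    group_percentage_method : "ratio" (printed-formula reading) or
        "proportion" (methylated / all scored).
    """

    error_threshold: float = 0.05
    q_threshold: float = 0.9
    n_permutations: int = 10_000
    peak_min_size: float = 100.0
    peak_max_size: float = 500.0
    peak_min_height: float = 100.0
    rng_seed: int = 0
    ambiguous_in_proportion: bool = False
    group_percentage_method: str = "ratio"

    def __post_init__(self) -> None:
        if not 0 < self.error_threshold < 1:
            raise CoreIOError("error_threshold must be in (0, 1)")
        if not 0 < self.q_threshold <= 1:
            raise CoreIOError("q_threshold must be in (0, 1]")
        if self.n_permutations < 99:
            raise CoreIOError("n_permutations must be >= 99")
        if self.group_percentage_method not in ("ratio", "proportion"):
            raise CoreIOError("group_percentage_method must be 'ratio' or 'proportion'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh)


# ---------------------------------------------------------------------------
# Genotype CSV
# ---------------------------------------------------------------------------
#
# Layout: header "individual_id,site,<loc>,<loc>_b,..." — two consecutive
# columns per locus; the locus id is the first column's name. A 0/0 pair
# decodes to a missing call.


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype CSV (two allele columns per locus, GenAlEx-style 0/0
    missing sentinel)."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise CoreIOError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 4 or header[0] != "individual_id" or header[1] != "site":
        raise CoreIOError(f"{path}: header must start 'individual_id,site,...'")
    allele_cols = header[2:]
    if len(allele_cols) % 2:
        raise CoreIOError(f"{path}: odd number of allele columns")
    loci = [allele_cols[i] for i in range(0, len(allele_cols), 2)]
    ids, sites, calls = [], [], []
    for r, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise CoreIOError(f"{path}: row {r}: {len(row)} fields, expected {len(header)}")
        ids.append(row[0])
        sites.append(row[1])
        try:
            alleles = np.array([int(x) for x in row[2:]], dtype=np.int64)
        except ValueError as exc:
            raise CoreIOError(f"{path}: row {r}: non-integer allele code ({exc})")
        if (alleles < 0).any():
            raise CoreIOError(f"{path}: row {r}: negative allele code")
        pairs = alleles.reshape(-1, 2)
        miss = (pairs == 0).all(axis=1)
        if ((pairs == 0).any(axis=1) & ~miss).any():
            raise CoreIOError(f"{path}: row {r}: half-zero allele pair")
        pairs = pairs.copy()
        pairs[miss] = MISSING
        calls.append(pairs)
    if len(set(ids)) != len(ids):
        raise CoreIOError(f"{path}: duplicate individual ids")
    try:
        return GenotypeMatrix(ids, sites, loci, np.stack(calls))
    except CoreIOError as exc:
        raise CoreIOError(f"{path}: {exc}")


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        header = ["individual_id", "site"]
        for loc in g.loci_ids:
            header += [loc, f"{loc}_b"]
        w.writerow(header)
        out = g.calls.copy()
        out[out < 0] = 0  # 0/0 missing sentinel
        for i, ind in enumerate(g.individual_ids):
            w.writerow([ind, g.site_labels[i], *out[i].ravel().tolist()])


# ---------------------------------------------------------------------------
# Band matrix CSV (one row per individual x digest)
# ---------------------------------------------------------------------------


def read_band_matrix(path: str | Path) -> BandMatrix:
    """Read a band-matrix CSV with one row per individual x digest.

    Layout: ``individual_id,digest,<locus>,...`` with digest in {HPA, MSP}
    and cells 0, 1 or empty (missing).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"individual_id": str, "digest": str})
    for col in ("individual_id", "digest"):
        if col not in df.columns:
            raise CoreIOError(f"{path}: missing column '{col}'")
    loci = [c for c in df.columns if c not in ("individual_id", "digest")]
    if not loci:
        raise CoreIOError(f"{path}: no locus columns")
    frames = {}
    for dig in ("HPA", "MSP"):
        sub = df[df["digest"] == dig]
        if sub.empty:
            raise CoreIOError(f"{path}: no rows for digest {dig}")
        if sub["individual_id"].duplicated().any():
            raise CoreIOError(f"{path}: duplicate individual rows for digest {dig}")
        frames[dig] = sub.set_index("individual_id")[loci]
    ids = list(frames["HPA"].index)
    if set(ids) != set(frames["MSP"].index):
        raise CoreIOError(f"{path}: HPA/MSP individual sets differ")
    arrs = {}
    for dig in ("HPA", "MSP"):
        block = frames[dig].loc[ids].to_numpy(dtype=float)
        a = np.full(block.shape, MISSING, dtype=np.int8)
        scored = ~np.isnan(block)
        vals = block[scored]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise CoreIOError(f"{path}: non-binary band cells in digest {dig}")
        a[scored] = vals.astype(np.int8)
        arrs[dig] = a
    return BandMatrix(ids, loci, arrs["HPA"], arrs["MSP"])


def write_band_matrix(b: BandMatrix, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for dig, arr in (("HPA", b.hpa), ("MSP", b.msp)):
        block = arr.astype(float)
        block[arr == MISSING] = np.nan
        for i, ind in enumerate(b.individual_ids):
            rows.append([ind, dig, *block[i]])
    df = pd.DataFrame(rows, columns=["individual_id", "digest", *b.loci_ids])
    # Int64 keeps 0/1 cells integral in the CSV while allowing blanks
    for c in b.loci_ids:
        df[c] = df[c].astype("Int64")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parasite and q-matrix CSVs (wide)
# ---------------------------------------------------------------------------


def read_parasites(path: str | Path) -> ParasiteTable:
    """Read a wide parasite-count CSV: ``individual_id,<morphotype>,...``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise CoreIOError(f"{path}: missing column 'individual_id'")
    df = df.set_index("individual_id")
    if df.isna().any().any():
        raise CoreIOError(f"{path}: missing parasite counts")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or (arr < 0).any():
        raise CoreIOError(f"{path}: parasite counts must be non-negative numbers")
    if not np.equal(np.mod(arr, 1), 0).all():
        raise CoreIOError(f"{path}: parasite counts must be integers")
    try:
        return ParasiteTable(df.astype(np.int64))
    except CoreIOError as exc:
        raise CoreIOError(f"{path}: {exc}")


def write_parasites(t: ParasiteTable, path: str | Path) -> None:
    t.counts.rename_axis("individual_id").to_csv(path)


def read_qmatrix(path: str | Path) -> QMatrix:
    """Read a wide q-value CSV: ``individual_id,<cluster>,...``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"individual_id": str}).set_index("individual_id")
    try:
        return QMatrix(df.astype(float))
    except CoreIOError as exc:
        raise CoreIOError(f"{path}: {exc}")


def write_qmatrix(q: QMatrix, path: str | Path) -> None:
    q.q.rename_axis("individual_id").to_csv(path)


# ---------------------------------------------------------------------------
# Peak binarization
# ---------------------------------------------------------------------------


def binarize_peaks(
    peaks: pd.DataFrame,
    config: PipelineConfig,
    locus_bins: Sequence[tuple[str, float, float]],
) -> BandMatrix:
    """Binarize a GeneMapper-style peak table into a dual-digest band matrix.

    ``peaks`` needs columns individual_id, digest (HPA/MSP), fragment_size
    (bp), peak_height (RFU). A band is 1 iff at least one peak with height >=
    ``peak_min_height`` and size inside the analysis window
    [``peak_min_size``, ``peak_max_size``) falls in the locus bin [low, high).
    An individual with no recorded peaks in a digest is missing at every
    locus of that digest (and, via BandMatrix promotion, in both digests).
    """
    required = {"individual_id", "digest", "fragment_size", "peak_height"}
    if not required.issubset(peaks.columns):
        raise CoreIOError(f"peak table missing columns {required - set(peaks.columns)}")
    if (peaks["fragment_size"] <= 0).any() or (peaks["peak_height"] <= 0).any():
        raise CoreIOError("fragment sizes and peak heights must be positive")
    bins = sorted(locus_bins, key=lambda b: b[1])
    for label, low, high in bins:
        if not (config.peak_min_size <= low < high <= config.peak_max_size):
            raise CoreIOError(f"bin {label} [{low},{high}) outside analysis range")
    for (l1, _, h1), (l2, lo2, _) in zip(bins, bins[1:]):
        if lo2 < h1:
            raise CoreIOError(f"overlapping bins {l1} and {l2}")
    loci = [b[0] for b in bins]
    ids = sorted(peaks["individual_id"].astype(str).unique())
    idx = {v: i for i, v in enumerate(ids)}
    arrs = {}
    for dig in ("HPA", "MSP"):
        sub = peaks[peaks["digest"] == dig]
        a = np.full((len(ids), len(loci)), MISSING, dtype=np.int8)
        present = sub["individual_id"].astype(str).unique()
        a[[idx[v] for v in present], :] = 0
        ok = sub[
            (sub["peak_height"] >= config.peak_min_height)
            & (sub["fragment_size"] >= config.peak_min_size)
            & (sub["fragment_size"] < config.peak_max_size)
        ]
        for _, rec in ok.iterrows():
            size = rec["fragment_size"]
            for j, (_, low, high) in enumerate(bins):
                if low <= size < high:
                    a[idx[str(rec["individual_id"])], j] = 1
                    break
        arrs[dig] = a
    return BandMatrix(ids, loci, arrs["HPA"], arrs["MSP"])


def default_locus_bins(
    config: PipelineConfig, width: float = 1.0
) -> list[tuple[str, float, float]]:
    """Uniform half-open bins of the given width spanning the analysis range."""
    edges = np.arange(config.peak_min_size, config.peak_max_size, width)
    return [
        (f"L{int(round(lo))}", float(lo), float(min(lo + width, config.peak_max_size)))
        for lo in edges
    ]
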